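"""Entry-level aggregation, cue-conflict scoring, and bias statistics."""

import numpy as np
import pandas as pd
import pytest

import shadebias as sb
from shadebias.evaluate import (
    ClassifierOutput,
    LabelMap,
    aggregate_entry_level,
    bias_from_accuracies,
    compute_bias,
    condition_gains,
    condition_metrics,
    evaluate_manifest,
    oracle_classifier,
    percent,
    score_cue_conflict,
)


class TestLabelMap:
    def test_default_map_covers_all_categories(self, label_map):
        for cat in sb.CATEGORIES:
            assert len(label_map.labels_for(cat)) >= 1

    def test_elephant_subcategories(self, label_map):
        assert set(label_map.labels_for("elephant")) == {
            "indian elephant", "african elephant"}

    def test_category_without_labels_rejected(self):
        with pytest.raises(ValueError):
            LabelMap(entries={"goldfish": "fish"})


class TestAggregation:
    def test_one_hot_subcategory_decides_entry_level(self, label_map):
        vocab = label_map.vocabulary
        probs = np.zeros(len(vocab))
        probs[vocab.index("african elephant")] = 1.0
        scores, decision = aggregate_entry_level(
            ClassifierOutput(probabilities=probs, vocabulary=vocab), label_map)
        assert decision == "elephant"
        assert scores["elephant"] == 1.0

    def test_uniform_over_large_vocabulary(self):
        """1,000-label vocabulary, 2 labels mapped to elephant: uniform
        probabilities aggregate to exactly 2/1000 for elephant."""
        vocab = tuple(f"label_{i:04d}" for i in range(1000))
        entries = {"label_0000": "elephant", "label_0001": "elephant"}
        for i, cat in enumerate(c for c in sb.CATEGORIES if c != "elephant"):
            entries[f"label_{i + 2:04d}"] = cat
        lm = LabelMap(entries=entries)
        out = ClassifierOutput(probabilities=np.full(1000, 1e-3), vocabulary=vocab)
        scores, _ = aggregate_entry_level(out, lm)
        assert scores["elephant"] == pytest.approx(0.002, abs=1e-12)

    def test_unmapped_mass_gives_none(self, label_map):
        vocab = label_map.vocabulary + ("zeppelin",)
        probs = np.zeros(len(vocab))
        probs[-1] = 1.0
        _, decision = aggregate_entry_level(
            ClassifierOutput(probabilities=probs, vocabulary=vocab), label_map)
        assert decision == "none"

    def test_tie_breaks_lexicographically(self, label_map):
        vocab = label_map.vocabulary
        probs = np.zeros(len(vocab))
        probs[vocab.index("coffee mug")] = 0.5
        probs[vocab.index("goldfish")] = 0.5
        _, decision = aggregate_entry_level(
            ClassifierOutput(probabilities=probs, vocabulary=vocab), label_map)
        assert decision == "fish"  # fish < mug

    def test_scores_bounded_by_total_mass(self, label_map):
        rng = np.random.default_rng(0)
        vocab = label_map.vocabulary + ("unmapped_a", "unmapped_b")
        for _ in range(20):
            p = rng.dirichlet(np.ones(len(vocab)))
            scores, _ = aggregate_entry_level(
                ClassifierOutput(probabilities=p, vocabulary=vocab), label_map)
            assert scores.sum() <= 1 + 1e-6


class TestScoring:
    def _manifest_like(self, rows):
        from shadebias.retexture import MANIFEST_COLUMNS, Manifest

        df = pd.DataFrame(rows)
        for i, col in enumerate(MANIFEST_COLUMNS):
            if col not in df:
                df[col] = i  # distinct filler keeps uniqueness keys intact
        return Manifest(records=df[MANIFEST_COLUMNS])

    def test_outcomes_cover_three_cases(self):
        man = self._manifest_like([
            {"stimulus_id": "a", "shape_category": "fish",
             "texture_category": "mug", "congruent": False},
            {"stimulus_id": "b", "shape_category": "fish",
             "texture_category": "bear", "congruent": False},
            {"stimulus_id": "c", "shape_category": "fish",
             "texture_category": "bird", "congruent": False},
        ])
        out = score_cue_conflict(["fish", "bear", "phone"], man,
                                 exclude_congruent=False)
        assert list(out["outcome"]) == ["shape_correct", "texture_correct", "other"]

    def test_outcomes_mutually_exclusive_on_incongruent(self, lazy_manifest,
                                                        label_map):
        clf = oracle_classifier("mixture", label_map, seed=3, p=0.5)
        sub = lazy_manifest.records.sample(300, random_state=0)
        from shadebias.retexture import Manifest

        man = Manifest(records=sub.reset_index(drop=True),
                       config=lazy_manifest.config)
        out = evaluate_manifest(clf, man, label_map)
        assert set(out["outcome"]) <= {"shape_correct", "texture_correct", "other"}
        both = ((out["decision"] == out["shape_category"])
                & (out["decision"] == out["texture_category"]))
        assert not both.any()

    def test_length_mismatch_rejected(self, lazy_manifest):
        with pytest.raises(ValueError):
            score_cue_conflict(["fish"], lazy_manifest)


class TestBias:
    def test_printed_average_accuracies_give_printed_biases(self):
        """The 2D averages (shape 35%, texture 27%) give 44% texture bias /
        56% shape bias; the 3D averages (45%, 19%) give 70% shape bias."""
        b2 = bias_from_accuracies(0.35, 0.27)
        assert percent(b2["texture_bias"]) == 44
        assert percent(b2["shape_bias"]) == 56
        b3 = bias_from_accuracies(0.45, 0.19)
        assert percent(b3["shape_bias"]) == 70

    def test_counts_route_agrees_with_accuracy_route(self):
        out = pd.DataFrame({"outcome": ["shape_correct"] * 35
                            + ["texture_correct"] * 27 + ["other"] * 38})
        s = compute_bias(out)
        assert s.texture_bias == pytest.approx(27 / 62)
        assert s.shape_bias + s.texture_bias == 1.0

    def test_pure_shape_oracle_has_zero_texture_bias(self):
        out = pd.DataFrame({"outcome": ["shape_correct"] * 10 + ["other"] * 5})
        assert compute_bias(out).texture_bias == 0.0

    def test_undefined_when_no_cue_correct(self):
        out = pd.DataFrame({"outcome": ["other"] * 4})
        s = compute_bias(out)
        assert s.texture_bias is None and s.shape_bias is None

    def test_invariant_to_other_outcomes(self):
        base = pd.DataFrame({"outcome": ["shape_correct"] * 30
                             + ["texture_correct"] * 20})
        padded = pd.concat([base,
                            pd.DataFrame({"outcome": ["other"] * 500})])
        assert compute_bias(base).texture_bias == compute_bias(padded).texture_bias

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            compute_bias(pd.DataFrame({"outcome": []}))

    def test_random_decisions_approach_even_bias(self, lazy_manifest, label_map):
        """Uniform-random guessing makes both cue-correct rates ~1/10, so
        texture bias converges to 0.5."""
        clf = oracle_classifier("uniform_random", label_map, seed=5)
        out = evaluate_manifest(clf, lazy_manifest, label_map)
        s = compute_bias(out)
        n_cue = s.n_shape_correct + s.n_texture_correct
        se = np.sqrt(0.25 / n_cue)
        assert abs(s.texture_bias - 0.5) < 3 * se


class TestOracleCalibration:
    def test_shape_and_texture_oracles(self, lazy_manifest, label_map):
        out_s = evaluate_manifest(oracle_classifier("shape_oracle", label_map),
                                  lazy_manifest, label_map)
        assert compute_bias(out_s).texture_bias == 0.0
        out_t = evaluate_manifest(oracle_classifier("texture_oracle", label_map),
                                  lazy_manifest, label_map)
        assert compute_bias(out_t).texture_bias == 1.0

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_mixture_recovers_complement(self, lazy_manifest, label_map, p):
        """mixture(p) answers by shape with probability p, so the estimated
        texture bias recovers 1-p within 3 binomial standard errors."""
        from shadebias.retexture import Manifest

        sub = lazy_manifest.records[~lazy_manifest.records["congruent"]]
        sub = sub.sample(5000, random_state=17).reset_index(drop=True)
        man = Manifest(records=sub, config=lazy_manifest.config)
        clf = oracle_classifier("mixture", label_map, seed=int(p * 100), p=p)
        out = evaluate_manifest(clf, man, label_map,
                                exclude_congruent=False)
        s = compute_bias(out)
        se = np.sqrt(p * (1 - p) / 5000)
        assert abs(s.texture_bias - (1 - p)) < 3 * se

    def test_unknown_kind_rejected(self, label_map):
        with pytest.raises(ValueError):
            oracle_classifier("psychic", label_map)


class TestProbabilityMatrixAdapter:
    def test_npy_dump_round_trips_to_decisions(self, tmp_path, lazy_manifest,
                                               label_map):
        """A saved softmax matrix + vocabulary file scores identically to
        feeding the same outputs through the record-level path."""
        from shadebias.evaluate import (evaluate_probabilities,
                                        load_probability_matrix)
        from shadebias.retexture import Manifest

        sub = lazy_manifest.records.head(50).reset_index(drop=True)
        man = Manifest(records=sub, config=lazy_manifest.config)
        vocab = label_map.vocabulary
        rng = np.random.default_rng(2)
        matrix = rng.dirichlet(np.ones(len(vocab)), size=len(sub))
        np.save(tmp_path / "probs.npy", matrix)
        (tmp_path / "vocab.txt").write_text("\n".join(vocab))
        outputs = load_probability_matrix(tmp_path / "probs.npy",
                                          tmp_path / "vocab.txt")
        out = evaluate_probabilities(outputs, man, label_map)
        direct = [aggregate_entry_level(
            ClassifierOutput(probabilities=row, vocabulary=vocab),
            label_map)[1] for row in matrix]
        expected = score_cue_conflict(direct, man)
        assert list(out["decision"]) == list(expected["decision"])


class TestConditionMetrics:
    def test_shape_oracle_perfect_in_all_cells(self, lazy_manifest, label_map):
        out = evaluate_manifest(oracle_classifier("shape_oracle", label_map),
                                lazy_manifest, label_map)
        table = condition_metrics(out)
        assert (table["shape_accuracy"] == 1.0).all()
        gains = condition_gains(out)
        assert (gains["gain_3d"] == 0.0).all()

    def test_condition_dependent_accuracy_yields_expected_gain(self,
                                                               lazy_manifest):
        """A synthetic decision rule correct with P=.46 on 3D and P=.35 on 2D
        recovers a ~0.11 gain in both strata, within Monte-Carlo error."""
        rec = lazy_manifest.records
        rng = np.random.default_rng(23)
        p = np.where(rec["condition"] == "3D", 0.46, 0.35)
        correct = rng.random(len(rec)) < p
        wrong = [next(c for c in sb.CATEGORIES
                      if c != s and c != t)
                 for s, t in zip(rec["shape_category"], rec["texture_category"])]
        decisions = np.where(correct, rec["shape_category"], wrong)
        out = score_cue_conflict(list(decisions), lazy_manifest)
        gains = condition_gains(out)
        n = gains["n_pairs"].min()
        se = np.sqrt(0.46 * 0.54 / n + 0.35 * 0.65 / n)
        assert np.all(np.abs(gains["gain_3d"] - 0.11) < 3 * se)

    def test_canonicality_only_classifier_has_zero_gain(self, lazy_manifest):
        """Accuracy depending only on canonicality leaves no 3D gain."""
        rec = lazy_manifest.records
        correct = rec["canonicality"] == "canonical"
        wrong = [next(c for c in sb.CATEGORIES if c != s and c != t)
                 for s, t in zip(rec["shape_category"], rec["texture_category"])]
        decisions = np.where(correct, rec["shape_category"], wrong)
        out = score_cue_conflict(list(decisions), lazy_manifest)
        gains = condition_gains(out)
        assert np.all(gains["gain_3d"] == 0.0)

    def test_marginals_match_pooled_bias(self, lazy_manifest, label_map):
        clf = oracle_classifier("mixture", label_map, seed=9, p=0.6)
        out = evaluate_manifest(clf, lazy_manifest, label_map)
        table = condition_metrics(out)
        pooled = compute_bias(out)
        weighted_shape = (table["shape_accuracy"] * table["n"]).sum() / table["n"].sum()
        assert weighted_shape == pytest.approx(pooled.shape_accuracy)
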