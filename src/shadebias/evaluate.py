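"""Cue-conflict evaluation: entry-level aggregation, outcomes, bias statistics.

Classifiers emit probabilities over a fine-grained label vocabulary (for
ImageNet-trained networks, 1,000 subcategories).  Decisions are made at the
entry level: all probability mass belonging to one of the ten entry-level
categories (elephant, fish, mug, ...) is summed, and the decision is the
entry-level category with the greatest summed probability.

On a cue-conflict stimulus whose shape and texture categories differ, the
decision is scored ``shape_correct`` if it matches the shape category,
``texture_correct`` if it matches the texture category, and ``other``
otherwise.  The texture-bias statistic is

    texture_bias = correct texture / (correct texture + correct shape)

with shape bias its complement; values above 50% indicate texture bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .retexture import Manifest
from .shapes import CATEGORIES

__all__ = [
    "LabelMap",
    "ClassifierOutput",
    "BiasSummary",
    "default_label_map",
    "aggregate_entry_level",
    "score_cue_conflict",
    "compute_bias",
    "bias_from_accuracies",
    "condition_metrics",
    "condition_gains",
    "oracle_classifier",
    "evaluate_manifest",
    "load_probability_matrix",
    "evaluate_probabilities",
    "percent",
]

logger = logging.getLogger(__name__)


def percent(fraction: float) -> int:
    """Fraction -> integer percent, rounding half away from zero."""
    x = fraction * 100.0
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class LabelMap:
    """Many-to-one mapping from classifier output labels to entry-level categories."""

    entries: dict  # label -> entry category

    def __post_init__(self):
        cats = set(self.entries.values())
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown entry categories: {sorted(unknown)}")
        empty = set(CATEGORIES) - cats
        if empty:
            raise ValueError(f"entry categories with no mapped label: {sorted(empty)}")

    @classmethod
    def from_csv(cls, path) -> "LabelMap":
        df = pd.read_csv(path)
        if df["subcategory_label"].duplicated().any():
            raise ValueError("a label maps to more than one entry category")
        return cls(entries=dict(zip(df["subcategory_label"], df["entry_category"])))

    def labels_for(self, category: str) -> list[str]:
        return sorted(l for l, c in self.entries.items() if c == category)

    @property
    def vocabulary(self) -> tuple:
        return tuple(sorted(self.entries))


def default_label_map() -> LabelMap:
    """The shipped ImageNet-subcategory -> entry-level mapping."""
    with resources.files("shadebias.data").joinpath("entry_level_map.csv").open() as fh:
        return LabelMap.from_csv(fh)


@dataclass
class ClassifierOutput:
    """A probability vector over a classifier's label vocabulary."""

    probabilities: np.ndarray
    vocabulary: tuple

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.vocabulary):
            raise ValueError("probability/vocabulary length mismatch")
        if self.probabilities.min() < 0:
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


def aggregate_entry_level(output: ClassifierOutput, label_map: LabelMap):
    """Sum subcategory probabilities per entry-level category and decide.

    Returns ``(scores, decision)`` where ``scores`` is a Series over the ten
    entry-level categories (lexicographic order) and ``decision`` the argmax
    category -- ties broken lexicographically and logged; all-zero scores
    (mass entirely on unmapped labels) yield decision ``"none"``.
    """
    scores = pd.Series(0.0, index=list(CATEGORIES))
    for label, p in zip(output.vocabulary, output.probabilities):
        cat = label_map.entries.get(label)
        if cat is not None:
            scores[cat] += p
    if scores.max() <= 0.0:
        return scores, "none"
    top = scores[scores == scores.max()]
    if len(top) > 1:
        logger.info("entry-level tie among %s; lexicographic break", list(top.index))
    return scores, top.index[0]


def score_cue_conflict(decisions, manifest: Manifest,
                       exclude_congruent: bool = True) -> pd.DataFrame:
    """Score each decision against its stimulus record's shape and texture cue.

    Returns a frame with the manifest's descriptive columns plus ``decision``
    and ``outcome`` in {shape_correct, texture_correct, other}.  Congruent
    records (shape category == texture category, where the two outcomes
    coincide) are dropped by default.
    """
    records = manifest.records
    if len(decisions) != len(records):
        raise ValueError("one decision required per manifest record")
    df = records.copy()
    df["decision"] = list(decisions)
    df["outcome"] = "other"
    df.loc[df["decision"] == df["shape_category"], "outcome"] = "shape_correct"
    incong = df["shape_category"] != df["texture_category"]
    df.loc[incong & (df["decision"] == df["texture_category"]),
           "outcome"] = "texture_correct"
    if exclude_congruent:
        df = df[~df["congruent"]].reset_index(drop=True)
    return df


@dataclass
class BiasSummary:
    """Aggregated cue-conflict outcome counts and the bias statistics."""

    n_shape_correct: int
    n_texture_correct: int
    n_other: int
    shape_accuracy: float
    texture_accuracy: float
    texture_bias: float | None  # None when no cue-correct trials exist
    shape_bias: float | None

    @property
    def n_trials(self) -> int:
        return self.n_shape_correct + self.n_texture_correct + self.n_other


def compute_bias(outcomes: pd.DataFrame) -> BiasSummary:
    """Bias statistics from scored outcomes.

    ``texture_bias`` is the proportion of correct texture classifications
    among all cue-correct (texture or shape) classifications; it is
    independent of the number of ``other`` outcomes.
    """
    if len(outcomes) == 0:
        raise ValueError("outcomes must be nonempty")
    n_s = int((outcomes["outcome"] == "shape_correct").sum())
    n_t = int((outcomes["outcome"] == "texture_correct").sum())
    n_o = int((outcomes["outcome"] == "other").sum())
    n = n_s + n_t + n_o
    if n_s + n_t > 0:
        tb = n_t / (n_s + n_t)
        sb = 1.0 - tb
    else:
        tb = sb = None
    return BiasSummary(
        n_shape_correct=n_s, n_texture_correct=n_t, n_other=n_o,
        shape_accuracy=n_s / n, texture_accuracy=n_t / n,
        texture_bias=tb, shape_bias=sb,
    )


def bias_from_accuracies(shape_accuracy: float, texture_accuracy: float) -> dict:
    """Bias statistics from mean cue accuracies over equal trial counts.

    Equivalent to ``compute_bias`` on any outcome set whose shape- and
    texture-correct proportions equal the given accuracies.
    """
    denom = shape_accuracy + texture_accuracy
    if denom <= 0:
        return {"texture_bias": None, "shape_bias": None}
    return {"texture_bias": texture_accuracy / denom,
            "shape_bias": shape_accuracy / denom}


_PAIR_KEY = ["shape_category", "shape_model_id", "texture_category",
             "texture_id", "viewpoint_index"]


def condition_metrics(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Shape/texture accuracy and texture bias per (condition x canonicality)."""
    rows = []
    for (cond, canon), grp in outcomes.groupby(["condition", "canonicality"]):
        summary = compute_bias(grp)
        rows.append({
            "condition": cond, "canonicality": canon, "n": len(grp),
            "shape_accuracy": summary.shape_accuracy,
            "texture_accuracy": summary.texture_accuracy,
            "texture_bias": summary.texture_bias,
        })
    out = pd.DataFrame(rows)
    order = {"3D": 0, "2D": 1}
    return out.sort_values(["condition", "canonicality"],
                           key=lambda s: s.map(order) if s.name == "condition" else s
                           ).reset_index(drop=True)


def condition_gains(outcomes: pd.DataFrame) -> pd.DataFrame:
    """3D-minus-2D shape-accuracy gain per canonicality stratum.

    Computed on matched stimulus pairs: the same (shape, texture, viewpoint)
    present in both conditions.
    """
    for cond in ("3D", "2D"):
        if not (outcomes["condition"] == cond).any():
            raise ValueError(f"missing condition {cond}")
    d3 = outcomes[outcomes["condition"] == "3D"]
    d2 = outcomes[outcomes["condition"] == "2D"]
    merged = d3.merge(d2, on=_PAIR_KEY + ["canonicality"], suffixes=("_3d", "_2d"))
    rows = []
    for canon, grp in merged.groupby("canonicality"):
        acc3 = (grp["outcome_3d"] == "shape_correct").mean()
        acc2 = (grp["outcome_2d"] == "shape_correct").mean()
        rows.append({"canonicality": canon, "n_pairs": len(grp),
                     "shape_accuracy_3d": acc3, "shape_accuracy_2d": acc2,
                     "gain_3d": acc3 - acc2})
    return pd.DataFrame(rows).sort_values("canonicality").reset_index(drop=True)


def oracle_classifier(kind: str, label_map: LabelMap, noise: float = 0.0,
                      seed: int = 0, p: float = 0.5):
    """Test-double classifiers reading the manifest record, not pixels.

    kind:
      - ``shape_oracle``   answer by the record's shape category
      - ``texture_oracle`` answer by the record's texture category
      - ``mixture``        answer by shape with probability ``p``, else texture
      - ``uniform_random`` answer uniformly over the ten categories
    Probability mass goes on the first mapped subcategory of the chosen
    category, blended with ``noise`` mass spread over the whole vocabulary.
    Deterministic under ``seed`` (one draw per call, in call order).
    """
    if kind not in {"shape_oracle", "texture_oracle", "mixture", "uniform_random"}:
        raise ValueError(f"unknown oracle kind {kind!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("mixture weight p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab = label_map.vocabulary
    index = {l: i for i, l in enumerate(vocab)}

    def classify(record) -> ClassifierOutput:
        if kind == "shape_oracle":
            cat = record["shape_category"]
        elif kind == "texture_oracle":
            cat = record["texture_category"]
        elif kind == "mixture":
            cat = (record["shape_category"] if rng.random() < p
                   else record["texture_category"])
        else:
            cat = CATEGORIES[rng.integers(len(CATEGORIES))]
        probs = np.full(len(vocab), noise / len(vocab))
        probs[index[label_map.labels_for(cat)[0]]] += 1.0 - noise
        return ClassifierOutput(probabilities=probs, vocabulary=vocab)

    return classify


def evaluate_manifest(classifier, manifest: Manifest, label_map: LabelMap,
                      exclude_congruent: bool = True) -> pd.DataFrame:
    """Run a record-level classifier over a manifest and score the outcomes."""
    decisions = []
    for _, record in manifest.records.iterrows():
        _, decision = aggregate_entry_level(classifier(record), label_map)
        decisions.append(decision)
    return score_cue_conflict(decisions, manifest, exclude_congruent=exclude_congruent)


def load_probability_matrix(probs_path, vocabulary_path) -> list[ClassifierOutput]:
    """Adapter for real-model probability dumps.

    ``probs_path`` is an N x V matrix (``.npy``, or CSV with one stimulus
    per row) of softmax outputs in manifest record order; the vocabulary
    file lists the V labels, one per line.  Heavyweight frameworks thus
    stay out of the pipeline: run the network elsewhere, evaluate here.
    """
    path = str(probs_path)
    if path.endswith(".npy"):
        matrix = np.load(path)
    else:
        matrix = pd.read_csv(path, header=None).to_numpy(dtype=float)
    vocab = tuple(l.strip() for l in open(vocabulary_path) if l.strip())
    return [ClassifierOutput(probabilities=row, vocabulary=vocab)
            for row in matrix]


def evaluate_probabilities(outputs: list[ClassifierOutput], manifest: Manifest,
                           label_map: LabelMap,
                           exclude_congruent: bool = True) -> pd.DataFrame:
    """Score pre-computed per-record classifier outputs against a manifest."""
    decisions = [aggregate_entry_level(out, label_map)[1] for out in outputs]
    return score_cue_conflict(decisions, manifest,
                              exclude_congruent=exclude_congruent)
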