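"""Behavioral experiment construction, simulated observers, and 2x2 RM-ANOVA.

Experiment 1 is a two-block design: 160 shape-identification trials (8
stimuli per category x 10 categories, half 3D and half 2D, randomly
interleaved) followed by a symmetric 160-trial texture-identification block.
Every trial is a cue-conflict stimulus -- its shape and texture categories
never coincide.  Experiment 2 is shape identification only, crossing the
presence of 3D cues with viewpoint canonicality: 20 trials per cell, 80
total, randomly interleaved.

Observers are simulated at the cell level: each (task x condition) or
(condition x canonicality) cell has a per-observer accuracy; errors are
uniform over the nine wrong categories; response times are log-normal per
cell.  Accuracy is analyzed on per-subject cell means with a standard
within-subject (repeated-measures) 2x2 ANOVA: each effect is tested against
its own subject-by-effect error stratum, with partial eta squared
SS_effect / (SS_effect + SS_error) and paired contrasts reported with
Cohen's d computed from the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .retexture import Manifest
from .shapes import CATEGORIES

__all__ = [
    "TRIAL_COLUMNS",
    "ObserverParams",
    "EffectStats",
    "ContrastStats",
    "AnovaResult",
    "build_exp1_trials",
    "build_exp2_trials",
    "simulate_observer",
    "accuracy_by_cell",
    "rm_anova_2x2",
    "paired_contrast",
    "simulate_population",
]

TRIAL_COLUMNS = [
    "trial_index", "block", "practice", "stimulus_id", "shape_category",
    "texture_category", "condition", "canonicality", "correct_response",
]


def _sample_cell(pool: pd.DataFrame, n: int, rng, cell_name: str) -> pd.DataFrame:
    if len(pool) < n:
        raise ValueError(
            f"insufficient stimuli for cell {cell_name}: need {n}, have {len(pool)}")
    return pool.iloc[rng.choice(len(pool), size=n, replace=False)]


def _trial_rows(records: pd.DataFrame, block: str, practice: bool) -> list[dict]:
    cue = "shape_category" if block == "shape_task" else "texture_category"
    return [
        {
            "block": block,
            "practice": practice,
            "stimulus_id": r["stimulus_id"],
            "shape_category": r["shape_category"],
            "texture_category": r["texture_category"],
            "condition": r["condition"],
            "canonicality": r["canonicality"],
            "correct_response": r[cue],
        }
        for _, r in records.iterrows()
    ]


def build_exp1_trials(manifest: Manifest, n_per_category: int = 8,
                      n_practice: int = 10, seed: int = 0) -> pd.DataFrame:
    """The two-block shape/texture identification schedule of Experiment 1.

    Per block and condition, ``n_per_category`` incongruent stimuli are drawn
    for each of the ten categories (of the block's task cue), then the block
    is shuffled.  Shape block first.  ``n_practice`` flagged practice trials
    precede each block and are excluded from analysis.
    """
    rng = np.random.default_rng(seed)
    pool = manifest.records[~manifest.records["congruent"]]
    rows: list[dict] = []
    for block, cue in (("shape_task", "shape_category"),
                       ("texture_task", "texture_category")):
        main: list[dict] = []
        for cat in CATEGORIES:
            for cond in ("3D", "2D"):
                cell = pool[(pool[cue] == cat) & (pool["condition"] == cond)]
                picked = _sample_cell(cell, n_per_category, rng,
                                      f"({block}, {cat}, {cond})")
                main.extend(_trial_rows(picked, block, practice=False))
        practice_pool = pool.iloc[rng.choice(len(pool), size=n_practice,
                                             replace=False)]
        rows.extend(_trial_rows(practice_pool, block, practice=True))
        order = rng.permutation(len(main))
        rows.extend(main[i] for i in order)
    df = pd.DataFrame(rows)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df[TRIAL_COLUMNS]


def build_exp2_trials(manifest: Manifest, n_per_condition: int = 20,
                      n_practice: int = 16, seed: int = 0) -> pd.DataFrame:
    """The Experiment 2 schedule: shape task, (3D/2D) x canonicality cells.

    ``n_per_condition`` incongruent stimuli per (condition x canonicality)
    cell, all randomly interleaved, preceded by flagged practice trials.
    """
    rng = np.random.default_rng(seed)
    pool = manifest.records[~manifest.records["congruent"]]
    main: list[dict] = []
    for cond in ("3D", "2D"):
        for canon in ("canonical", "noncanonical"):
            cell = pool[(pool["condition"] == cond)
                        & (pool["canonicality"] == canon)]
            picked = _sample_cell(cell, n_per_condition, rng,
                                  f"({cond}, {canon})")
            main.extend(_trial_rows(picked, "shape_task", practice=False))
    rows = _trial_rows(
        pool.iloc[rng.choice(len(pool), size=n_practice, replace=False)],
        "shape_task", practice=True)
    order = rng.permutation(len(main))
    rows.extend(main[i] for i in order)
    df = pd.DataFrame(rows)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df[TRIAL_COLUMNS]


@dataclass
class ObserverParams:
    """A simulated observer: per-cell accuracy and log-normal RT parameters.

    ``cell_keys`` names the trial columns that define a cell (for Experiment
    1, ``("block", "condition")``; for Experiment 2,
    ``("condition", "canonicality")``); ``accuracy`` maps each cell tuple to
    the probability of a correct response.  With probability ``lapse`` the
    observer instead guesses uniformly over all ten categories.
    """

    accuracy: dict
    cell_keys: tuple = ("condition", "canonicality")
    lapse: float = 0.0
    rt_location: float | dict = -0.3  # log-seconds
    rt_scale: float | dict = 0.25
    seed: int = 0

    def __post_init__(self):
        for cell, acc in self.accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy for cell {cell} outside [0, 1]")
        if isinstance(self.rt_scale, dict):
            bad = [c for c, s in self.rt_scale.items() if s <= 0]
        else:
            bad = [] if self.rt_scale > 0 else ["_"]
        if bad:
            raise ValueError("RT scale must be positive")

    def cell_of(self, trial) -> tuple:
        return tuple(trial[k] for k in self.cell_keys)

    def _rt_param(self, which, cell):
        value = getattr(self, which)
        return value[cell] if isinstance(value, dict) else value


def simulate_observer(params: ObserverParams, trials: pd.DataFrame) -> pd.DataFrame:
    """Simulate one observer over a trial schedule.

    Correct with the trial cell's accuracy, otherwise a uniformly chosen
    wrong category; lapses guess uniformly over all ten categories.
    Deterministic under the observer's seed.
    """
    rng = np.random.default_rng(params.seed)
    responses = []
    for _, trial in trials.iterrows():
        cell = params.cell_of(trial)
        if cell not in params.accuracy:
            raise ValueError(f"no accuracy parameter for cell {cell}")
        target = trial["correct_response"]
        if params.lapse and rng.random() < params.lapse:
            choice = CATEGORIES[rng.integers(len(CATEGORIES))]
        elif rng.random() < params.accuracy[cell]:
            choice = target
        else:
            wrong = [c for c in CATEGORIES if c != target]
            choice = wrong[rng.integers(len(wrong))]
        rt = float(rng.lognormal(params._rt_param("rt_location", cell),
                                 params._rt_param("rt_scale", cell)))
        responses.append({
            "trial_index": trial["trial_index"],
            "response": choice,
            "correct": choice == target,
            "rt": rt,
        })
    out = trials.reset_index(drop=True).merge(pd.DataFrame(responses),
                                              on="trial_index")
    return out


def accuracy_by_cell(responses: pd.DataFrame, cell_keys,
                     subject: str | int = 0) -> pd.DataFrame:
    """Per-cell mean accuracy of one observer's responses (practice excluded)."""
    main = responses[~responses["practice"]]
    rows = [
        {"subject": subject, **dict(zip(cell_keys, cell)),
         "accuracy": grp["correct"].mean()}
        for cell, grp in main.groupby(list(cell_keys))
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA


@dataclass
class EffectStats:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class ContrastStats:
    delta: float
    t: float
    df: int
    p: float
    cohens_d: float


@dataclass
class AnovaResult:
    effects: dict  # {factor_a, factor_b, interaction} -> EffectStats
    contrasts: dict  # simple-effect paired contrasts
    n_subjects: int


def paired_contrast(x, y) -> ContrastStats:
    """Paired comparison x - y: mean difference, t, p, Cohen's d (of differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    delta = float(d.mean())
    if sd == 0:
        t = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
        cd = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        t = delta / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), n - 1))
        cd = delta / sd
    return ContrastStats(delta=delta, t=float(t), df=n - 1, p=p, cohens_d=float(cd))


def rm_anova_2x2(data: pd.DataFrame, dv: str = "accuracy",
                 subject: str = "subject", factor_a: str = "condition",
                 factor_b: str = "canonicality") -> AnovaResult:
    """Two-way fully within-subject ANOVA on a complete balanced 2x2 table.

    Each effect (A, B, A x B) is tested against its own subject-by-effect
    interaction stratum; with 1-df effects sphericity holds trivially.
    Raises on unbalanced or incomplete tables (no imputation).
    """
    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    subjects = sorted(data[subject].unique())
    S = len(subjects)
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    if S < 3:
        raise ValueError("need at least 3 subjects")
    counts = data.groupby([subject, factor_a, factor_b])[dv].count()
    if len(counts) != S * 4 or (counts != 1).any():
        raise ValueError("table must have exactly one value per subject x cell")

    y = (data.set_index([subject, factor_a, factor_b])[dv]
         .unstack([factor_a, factor_b])
         .reindex(index=subjects,
                  columns=pd.MultiIndex.from_product([levels_a, levels_b])))
    Y = y.values.reshape(S, 2, 2)  # subject x A x B

    grand = Y.mean()
    mean_a = Y.mean(axis=(0, 2))  # per A level
    mean_b = Y.mean(axis=(0, 1))
    mean_s = Y.mean(axis=(1, 2))
    mean_sa = Y.mean(axis=2)  # S x A
    mean_sb = Y.mean(axis=1)  # S x B
    mean_ab = Y.mean(axis=0)  # A x B

    ss_a = 2 * S * ((mean_a - grand) ** 2).sum()
    ss_b = 2 * S * ((mean_b - grand) ** 2).sum()
    ss_ab = S * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((mean_sa - mean_a[None, :] - mean_s[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((mean_sb - mean_b[None, :] - mean_s[:, None] + grand) ** 2).sum()
    resid = (Y - mean_sa[:, :, None] - mean_sb[:, None, :] - mean_ab[None]
             + mean_a[None, :, None] + mean_b[None, None, :]
             + mean_s[:, None, None] - grand)
    ss_abs = (resid ** 2).sum()

    tiny = 1e-12 * max(1.0, float((Y**2).sum()))  # floor for degenerate tables

    def effect(ss_eff, ss_err):
        df_den = S - 1
        ms_eff = ss_eff if ss_eff > tiny else 0.0
        ms_err = (ss_err if ss_err > tiny else 0.0) / df_den
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
        denom = ms_eff + ms_err * df_den
        eta = ms_eff / denom if denom > 0 else 0.0
        return EffectStats(F=float(F), df_num=1, df_den=df_den, p=p,
                           partial_eta_sq=float(eta),
                           ss_effect=float(ss_eff), ss_error=float(ss_err))

    effects = {
        "factor_a": effect(ss_a, ss_as),
        "factor_b": effect(ss_b, ss_bs),
        "interaction": effect(ss_ab, ss_abs),
    }
    # simple-effect paired contrasts: A at each level of B, B at each level of A
    contrasts = {}
    for j, lb in enumerate(levels_b):
        contrasts[f"{factor_a}[{levels_a[0]}-{levels_a[1]}]@{factor_b}={lb}"] = (
            paired_contrast(Y[:, 0, j], Y[:, 1, j]))
    for i, la in enumerate(levels_a):
        contrasts[f"{factor_b}[{levels_b[0]}-{levels_b[1]}]@{factor_a}={la}"] = (
            paired_contrast(Y[:, i, 0], Y[:, i, 1]))
    return AnovaResult(effects=effects, contrasts=contrasts, n_subjects=S)


def simulate_population(cell_accuracies: dict, n_subjects: int,
                        n_trials_per_cell: int = 20, subject_sd: float = 0.05,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a population's per-subject cell accuracies, binomially.

    Each subject's true cell accuracy is the population value plus a shared
    normal subject effect (clipped to [0.02, 0.995]); the observed cell mean
    is a binomial proportion over ``n_trials_per_cell`` trials.  Returns a
    long table ready for ``rm_anova_2x2``.
    """
    rng = np.random.default_rng(seed)
    keys = sorted(cell_accuracies)
    rows = []
    for s in range(n_subjects):
        shift = rng.normal(0.0, subject_sd)
        for cell in keys:
            p = float(np.clip(cell_accuracies[cell] + shift, 0.02, 0.995))
            k = rng.binomial(n_trials_per_cell, p)
            cond, canon = cell
            rows.append({"subject": s, "condition": cond, "canonicality": canon,
                         "accuracy": k / n_trials_per_cell})
    return pd.DataFrame(rows)
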