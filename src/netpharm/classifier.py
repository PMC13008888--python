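"""Decoy-controlled ROC analysis of docking scores.

The central refinement this package implements: for each protein target, a
set of known binders and property-matched decoys is docked, and the two
score distributions define a per-target classification threshold. Docking
affinities are in kcal/mol and lower (more negative) is better, so the
orientation is fixed a priori: a compound is called a binder iff its mean
score falls strictly below the threshold. The threshold is chosen on the
ROC curve, by Youden's J (default) or best accuracy.

Candidate thresholds are the midpoints between consecutive distinct pooled
scores, plus finite sentinels below the minimum and above the maximum — the
convention of the standard ROC tooling. AUC is computed by trapezoidal
integration over (FPR, TPR) and agrees with the brute-force binder–decoy
pair statistic (:func:`auc_rank`, ties counted ½) to machine precision;
the two are kept as deliberately independent code paths.

Screening diagnostics per target: two-sided Mann-Whitney U (docking-score
distributions are typically non-normal, so no t-test), Cohen's d with
pooled sample SD (negative when binders score lower), and enrichment
factors at a top fraction of the pooled ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DESIGN_MIN_PER_CLASS = 20  # study-design contract; violation warns, not errors


class InsufficientDataError(ValueError):
    pass


class UndefinedEffectError(ValueError):
    pass


@dataclass
class LabeledScoreSet:
    """Per-target mean docking scores for binders and decoys (kcal/mol).

    ``trial_scores`` optionally maps ligand ids to their per-trial replicate
    scores; the stored mean scores are the arithmetic means of exactly the
    trials provided.
    """

    target_id: str
    binder_scores: np.ndarray
    decoy_scores: np.ndarray
    trial_scores: pd.DataFrame | None = None  # columns: ligand_id, label, trial_*

    def __post_init__(self) -> None:
        self.binder_scores = np.asarray(self.binder_scores, dtype=float)
        self.decoy_scores = np.asarray(self.decoy_scores, dtype=float)
        for name, arr in (("binder", self.binder_scores), ("decoy", self.decoy_scores)):
            if arr.size and arr.size < DESIGN_MIN_PER_CLASS:
                warnings.warn(
                    f"{self.target_id}: only {arr.size} {name} scores; the screen "
                    f"design calls for at least {DESIGN_MIN_PER_CLASS} per class",
                    stacklevel=2,
                )

    @classmethod
    def from_table(cls, table: pd.DataFrame, target_id: str) -> "LabeledScoreSet":
        """Build from a long score table (columns target_id, ligand_id, label,
        trial_1..trial_k); mean scores recomputed from the trial columns."""
        sub = table[table["target_id"] == target_id]
        trial_cols = [c for c in sub.columns if c.startswith("trial_")]
        means = sub[trial_cols].mean(axis=1)
        return cls(
            target_id=target_id,
            binder_scores=means[sub["label"] == "binder"].to_numpy(),
            decoy_scores=means[sub["label"] == "decoy"].to_numpy(),
            trial_scores=sub.reset_index(drop=True),
        )

    def _validate(self) -> None:
        if self.binder_scores.size < 2 or self.decoy_scores.size < 2:
            raise InsufficientDataError(
                f"{self.target_id}: need >= 2 scores per class for ROC analysis "
                f"(got {self.binder_scores.size} binders, {self.decoy_scores.size} decoys)"
            )


@dataclass
class ThresholdResult:
    target_id: str
    roc_points: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    youden_j: float
    optimal_threshold: float
    criterion: str = "youden"
    direction: str = "binder iff score < threshold"


@dataclass
class ScreenDiagnostics:
    target_id: str
    mannwhitney_u: float
    mannwhitney_p: float
    cohens_d: float
    ef_at_fraction: dict[float, float] = field(default_factory=dict)


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct pooled scores, with finite
    sentinels one unit below the minimum and above the maximum."""
    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def roc_curve(scores: LabeledScoreSet, criterion: str = "youden") -> ThresholdResult:
    """ROC analysis of one target's binder/decoy scores.

    At each candidate threshold t, sensitivity is the fraction of binders
    strictly below t and specificity the fraction of decoys at or above t.
    AUC is the trapezoidal area over (FPR, TPR). The optimal threshold
    maximizes Youden's J = sensitivity + specificity − 1 (or accuracy, with
    ``criterion='best_accuracy'``); ties are broken toward the most negative
    (most stringent) threshold.
    """
    scores._validate()
    b, d = scores.binder_scores, scores.decoy_scores
    n1, n2 = b.size, d.size
    thresholds = _candidate_thresholds(np.concatenate([b, d]))
    # integer counts keep the trapezoid exact so it matches the pair statistic
    tp = np.searchsorted(np.sort(b), thresholds, side="left").astype(np.int64)
    fp = np.searchsorted(np.sort(d), thresholds, side="left").astype(np.int64)
    sens = tp / n1
    fpr = fp / n2
    spec = 1.0 - fpr

    area2 = int(((tp[:-1] + tp[1:]) * np.diff(fp)).sum())  # 2 * AUC * n1 * n2
    auc = area2 / (2.0 * n1 * n2)

    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "best_accuracy":
        objective = (tp + (n2 - fp)) / (n1 + n2)
    else:
        raise ValueError(f"unknown threshold criterion: {criterion!r}")
    # ties within numerical noise keep the most negative (stringent) threshold
    best = int(np.flatnonzero(objective >= objective.max() - 1e-12)[0])
    j_best = float(sens[best] + spec[best] - 1.0)

    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    return ThresholdResult(
        target_id=scores.target_id,
        roc_points=points,
        auc=float(auc),
        youden_j=j_best,
        optimal_threshold=float(thresholds[best]),
        criterion=criterion,
    )


def auc_rank(scores: LabeledScoreSet) -> float:
    """AUC as the tie-corrected pair statistic: the mean over all binder–decoy
    pairs of 1 if the binder scores lower, ½ on a tie, 0 otherwise.

    Independent O(n₁n₂) brute force; the oracle route for :func:`roc_curve`.
    """
    scores._validate()
    total = 0.0
    for bs in scores.binder_scores:
        for ds in scores.decoy_scores:
            if bs < ds:
                total += 1.0
            elif bs == ds:
                total += 0.5
    return total / (scores.binder_scores.size * scores.decoy_scores.size)


def youden_threshold(result: ThresholdResult) -> tuple[float, float]:
    """(optimal threshold, J) from a ThresholdResult; recomputed from the ROC
    points so a result built under another criterion still yields Youden's J."""
    pts = result.roc_points
    if pts.empty:
        raise InsufficientDataError("empty ROC point set")
    j = (pts["sensitivity"] + pts["specificity"] - 1.0).to_numpy()
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(pts["threshold"].iloc[best]), float(j[best])


def classify_interactions(
    interactions: pd.DataFrame, thresholds: dict[str, ThresholdResult]
) -> pd.DataFrame:
    """Attach a classification column to an interaction table.

    probable_binder iff mean_score strictly below the target's optimal
    threshold; a mean exactly at the threshold is a probable nonbinder.
    Interactions whose target has no threshold are marked unclassified.
    """
    out = interactions.copy()
    labels = []
    for _, row in out.iterrows():
        thr = thresholds.get(row["target_id"])
        if thr is None:
            labels.append("unclassified")
        elif row["mean_score"] < thr.optimal_threshold:
            labels.append("probable_binder")
        else:
            labels.append("probable_nonbinder")
    out["classification"] = labels
    return out


def mann_whitney(scores: LabeledScoreSet) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on binder vs decoy scores.

    U counts binder–decoy pairs where the binder scores *higher* (ties ½),
    so U = 0 under perfect binder-below separation and
    AUC = 1 − U/(n₁n₂). Exact null distribution when n₁n₂ ≤ 400 and there
    are no ties; normal approximation with tie correction otherwise.
    """
    scores._validate()
    b, d = scores.binder_scores, scores.decoy_scores
    pooled = np.concatenate([b, d])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (b.size * d.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(b, d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(scores: LabeledScoreSet) -> float:
    """Standardized mean difference (binders − decoys) over the pooled sample
    SD; negative whenever binders score lower on average."""
    scores._validate()
    b, d = scores.binder_scores, scores.decoy_scores
    n1, n2 = b.size, d.size
    pooled_var = ((n1 - 1) * b.var(ddof=1) + (n2 - 1) * d.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise UndefinedEffectError(f"{scores.target_id}: zero pooled SD")
    return float((b.mean() - d.mean()) / math.sqrt(pooled_var))


def enrichment_factor(
    scores: LabeledScoreSet, fraction: float, ids: list[str] | None = None
) -> float:
    """Enrichment factor at a top fraction of the pooled ascending ranking.

    EF = (binder fraction among the top ⌈fraction·N⌉ scores) / (overall
    binder fraction). Ties at the cut are resolved by a stable sort on
    (score, ligand id).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    b, d = scores.binder_scores, scores.decoy_scores
    pooled = np.concatenate([b, d])
    is_binder = np.concatenate([np.ones(b.size, bool), np.zeros(d.size, bool)])
    if ids is None:
        ids = [f"b{i}" for i in range(b.size)] + [f"d{i}" for i in range(d.size)]
    order = sorted(range(pooled.size), key=lambda i: (pooled[i], str(ids[i])))
    n = pooled.size
    n_top = math.ceil(fraction * n)
    top_binders = sum(is_binder[i] for i in order[:n_top])
    overall = is_binder.sum() / n
    return float((top_binders / n_top) / overall)


def screen_diagnostics(
    scores: LabeledScoreSet, ef_fractions: tuple[float, ...] = (0.2,)
) -> ScreenDiagnostics:
    u, p = mann_whitney(scores)
    return ScreenDiagnostics(
        target_id=scores.target_id,
        mannwhitney_u=u,
        mannwhitney_p=p,
        cohens_d=cohens_d(scores),
        ef_at_fraction={f: enrichment_factor(scores, f) for f in ef_fractions},
    )


def export_distribution_summary(
    score_sets: list[LabeledScoreSet],
    thresholds: dict[str, ThresholdResult] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready export of per-target score distributions.

    Returns ``(long, summary)``: a long-format (target_id, label, score)
    table for distribution plots, and a per-target/label summary with n,
    mean, SD and the optimal threshold (NaN when no threshold exists).
    Targets with an empty class are emitted for the populated class only,
    with a warning.
    """
    long_rows = []
    summary_rows = []
    for s in score_sets:
        thr = thresholds.get(s.target_id) if thresholds else None
        thr_value = thr.optimal_threshold if thr is not None else float("nan")
        for label, arr in (("binder", s.binder_scores), ("decoy", s.decoy_scores)):
            if arr.size == 0:
                warnings.warn(
                    f"{s.target_id}: no {label} scores; summary emitted for the "
                    "other class only",
                    stacklevel=2,
                )
                continue
            for v in arr:
                long_rows.append((s.target_id, label, float(v)))
            summary_rows.append(
                (
                    s.target_id,
                    label,
                    int(arr.size),
                    float(arr.mean()),
                    float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                    thr_value,
                )
            )
    long = pd.DataFrame(long_rows, columns=["target_id", "label", "score"])
    summary = pd.DataFrame(
        summary_rows,
        columns=["target_id", "label", "n", "mean", "sd", "optimal_threshold"],
    )
    return long, summary
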