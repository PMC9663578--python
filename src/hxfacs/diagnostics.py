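"""Diagnostic performance: ROC/AUC with ties, Youden cut-offs, confusion
matrices with exact binomial CIs, rank and correlation tests.

AUC is computed twice on every call — as the tie-corrected pair statistic
(number of positive-negative pairs ordered correctly, ties counting one
half) and as the trapezoidal area under the empirical ROC — and the two
are asserted equal; they are the same quantity by construction, and the
dual computation guards the threshold bookkeeping.

Cut-off selection follows the Youden index over midpoints between
consecutive distinct observed values, with the decision rule "positive if
value >= cutoff" applied consistently throughout the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LabeledScores:
    """Per-specimen percentages with a binary reference label."""

    values: tuple[float, ...]
    labels: tuple[bool, ...]
    parameter_name: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must have equal length")

    @classmethod
    def from_arrays(cls, values, labels, parameter_name: str = "") -> "LabeledScores":
        return cls(
            tuple(float(v) for v in values),
            tuple(bool(b) for b in labels),
            parameter_name,
        )

    @property
    def pos(self) -> np.ndarray:
        v = np.asarray(self.values)
        return v[np.asarray(self.labels)]

    @property
    def neg(self) -> np.ndarray:
        v = np.asarray(self.values)
        return v[~np.asarray(self.labels)]


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]   # (fpr, tpr), monotone
    auc: float
    se_auc: float
    ci95: tuple[float, float]                 # Wald, deliberately uncapped
    youden_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float                        # %
    specificity: float
    accuracy: float
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]
    accuracy_ci95: tuple[float, float]


class UndefinedROCError(ValueError):
    """ROC requires both classes to be represented."""


def _check_two_classes(scores: LabeledScores) -> None:
    if len(scores.pos) == 0 or len(scores.neg) == 0:
        raise UndefinedROCError("both classes must be non-empty")


def _pair_statistic_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def _roc_points(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Empirical ROC points under "positive if value >= threshold",
    swept from above the maximum down through every distinct value."""
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1]))
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    return np.column_stack([fpr, tpr])


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Asymptotic SE of the empirical AUC (Hanley & McNeil 1982)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))


def roc_auc(scores: LabeledScores) -> ROCResult:
    """ROC curve with tie-corrected AUC, Hanley-McNeil CI and Youden cut-off."""
    _check_two_classes(scores)
    pos, neg = scores.pos, scores.neg
    auc = _pair_statistic_auc(pos, neg)
    points = _roc_points(pos, neg)
    trapezoid = float(np.trapezoid(points[:, 1], points[:, 0]))
    assert abs(trapezoid - auc) < 1e-9, (
        f"trapezoidal area {trapezoid} disagrees with pair statistic {auc}"
    )
    se = hanley_mcneil_se(auc, len(pos), len(neg))
    try:
        cutoff, j = youden_cutoff(scores)
    except ValueError:  # all scores identical: AUC = 0.5, no usable cut-off
        cutoff, j = float("nan"), float("nan")
    return ROCResult(
        points=tuple(map(tuple, points)),
        auc=float(auc),
        se_auc=se,
        ci95=(float(auc - 1.96 * se), float(auc + 1.96 * se)),
        youden_cutoff=cutoff,
        youden_j=j,
    )


def youden_cutoff(scores: LabeledScores) -> tuple[float, float]:
    """Maximize J = sensitivity + specificity - 1 over midpoints between
    consecutive distinct values; ties in J break toward higher sensitivity.
    """
    _check_two_classes(scores)
    values = np.unique(np.asarray(scores.values))
    if len(values) < 2:
        raise ValueError("all values identical: no cut-off exists")
    midpoints = (values[:-1] + values[1:]) / 2.0
    pos, neg = scores.pos, scores.neg
    best: tuple[float, float, float] | None = None  # (J, sens, -cutoff)
    best_cut = np.nan
    for c in midpoints:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12))
        if best is None or key > best:
            best = key
            best_cut = float(c)
    return best_cut, float(best[0])


def confusion(scores: LabeledScores, cutoff: float) -> ConfusionSummary:
    """Confusion matrix at a fixed cut-off ("positive if value >= cutoff"),
    with exact Clopper-Pearson 95% CIs on each rate."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    v = np.asarray(scores.values)
    lab = np.asarray(scores.labels)
    pred = v >= cutoff
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    tn = int((~pred & ~lab).sum())
    n = tp + fp + fn + tn
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=100.0 * (tp + tn) / n,
        sensitivity_ci95=clopper_pearson(tp, tp + fn) if tp + fn else (float("nan"),) * 2,
        specificity_ci95=clopper_pearson(tn, tn + fp) if tn + fp else (float("nan"),) * 2,
        accuracy_ci95=clopper_pearson(tp + tn, n),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI via beta quantiles, returned in percent."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * lo, 100.0 * hi


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and the pooled data are tie-free, otherwise the
    tie-corrected normal approximation (with continuity correction).
    Returns (U, p) with U counted for the first sample (pairs where x > y,
    ties half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_summary(scores: LabeledScores) -> dict[str, dict[str, float | None]]:
    """Per-class mean, sample SD (n-1) and SEM, keyed 'positive'/'negative'.

    A single-element class has undefined spread; its sd and sem are None.
    """
    out = {}
    for key, vals in (("positive", scores.pos), ("negative", scores.neg)):
        if len(vals) == 0:
            raise ValueError(f"{key} class is empty")
        if len(vals) == 1:
            sd = sem = None
        else:
            sd = float(np.std(vals, ddof=1))
            sem = sd / np.sqrt(len(vals))
        out[key] = {"n": len(vals), "mean": float(np.mean(vals)), "sd": sd, "sem": sem}
    return out


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paper_display(cutoff: float) -> float:
    """One-decimal display rounding for cut-offs (half rounds up).

    Cut-offs are midpoints between observed values, so any displayed
    value between the two flanking observations classifies the data
    identically under the ">= cutoff" rule; the full-precision midpoint
    remains the authoritative threshold.
    """
    return float(np.floor(cutoff * 10 + 0.5) / 10)
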