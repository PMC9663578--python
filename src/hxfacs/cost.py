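"""Decision-analytic testing-cost model for FACS-first triage vs NGS-only.

Three branches: (1) NGS on everyone (cost C_N per patient); (2) FACS
first, probe-positive patients go straight to therapy (cost C_F); (3)
FACS-negative patients still need NGS (cost C_F + C_N).  The expected
cost of the triage strategy therefore depends only on the probability
that a patient tests FACS-positive, which the assay's sensitivity and
specificity map from the mutation prevalence.

The model prices testing only: treatment costs and the downstream
consequences of false positives/negatives are outside it by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CostScenario:
    """Prevalence, assay operating characteristics, and per-test costs."""

    prevalence: float
    sensitivity: float = 0.733
    specificity: float = 1.0
    cost_facs: float = 14.0    # itemized assay cost, currency units per sample
    cost_ngs: float = 140.0

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cost_facs <= 0 or self.cost_ngs <= 0:
            raise ValueError("costs must be positive")


@dataclass(frozen=True)
class StrategyCosts:
    ngs_only: float
    facs_first: float
    p_facs_positive: float


def p_facs_positive(prevalence: float, sensitivity: float, specificity: float) -> float:
    """Marginal probability of a FACS-positive call:
    ``pi*s + (1 - pi)*(1 - sp)``."""
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return prevalence * sensitivity + (1 - prevalence) * (1 - specificity)


def expected_costs(scn: CostScenario) -> StrategyCosts:
    """Expected per-patient testing cost of each strategy."""
    p_pos = p_facs_positive(scn.prevalence, scn.sensitivity, scn.specificity)
    return StrategyCosts(
        ngs_only=scn.cost_ngs,
        facs_first=scn.cost_facs + (1 - p_pos) * scn.cost_ngs,
        p_facs_positive=p_pos,
    )


def breakeven_ratio(prevalence: float, sensitivity: float, specificity: float) -> float:
    """NGS:FACS cost ratio ``r* = 1 / P(FACS positive)`` at cost equality.

    FACS-first triage is cheaper than NGS-only exactly when the actual
    ratio C_N/C_F exceeds r*.  Returns ``inf`` when no patient can test
    positive.
    """
    p_pos = p_facs_positive(prevalence, sensitivity, specificity)
    if p_pos == 0:
        return float("inf")
    return 1.0 / p_pos


def sweep(prevalence_grid, sensitivity_grid, specificity: float = 1.0) -> pd.DataFrame:
    """Break-even ratios over a prevalence x sensitivity grid.

    Returns a tidy frame (prevalence, sensitivity, breakeven_ratio); the
    ratio is checked to be non-increasing in both prevalence and
    sensitivity.
    """
    pis = np.asarray(list(prevalence_grid), dtype=float)
    ss = np.asarray(list(sensitivity_grid), dtype=float)
    if pis.size == 0 or ss.size == 0:
        raise ValueError("grids must be non-empty")
    rows = [
        {"prevalence": pi, "sensitivity": s,
         "breakeven_ratio": breakeven_ratio(pi, s, specificity)}
        for pi in pis
        for s in ss
    ]
    table = pd.DataFrame(rows)
    wide = table.pivot(index="prevalence", columns="sensitivity", values="breakeven_ratio")
    wide = wide.sort_index().sort_index(axis=1)
    assert (wide.diff().fillna(0) <= 1e-12).all().all(), "r* must decrease with prevalence"
    assert (wide.diff(axis=1).fillna(0).to_numpy() <= 1e-12).all(), "r* must decrease with sensitivity"
    return table


def display_ratio(ratio: float) -> int:
    """'~n times' display: nearest integer."""
    return int(round(ratio))
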