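"""Probe-kinase binding, competition, dose-response and turn-on brightness.

The fluorogenic probe is an ATP-competitive quinazoline carrying an
environment-sensitive fluorophore: it is nearly dark in water and bright
once buried in the hydrophobic kinase pocket.  The module provides the
equilibrium occupancy of the probe on active EGFR (with or without a
competing TKI), saturation-binding and four-parameter-logistic fits for
parameter recovery, and the expected per-cell fluorescence used by the
event simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


class FitFailureError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed on degenerate data."""


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium parameters of the competitive binding isotherm.

    Parameters
    ----------
    kd : float
        Probe dissociation constant, in uM.  Cellular apparent values for
        mutant EGFR run 0.8-2.9 uM.
    probe_conc : float
        Free probe concentration, uM (assay default 5 uM).
    competitor_conc : float
        Concentration of the ATP-competitive TKI, uM (blocking default
        50 uM gefitinib; 0 means no competitor).
    ki_competitor : float or None
        Competitor dissociation constant, uM.  None disables competition
        regardless of competitor_conc.
    """

    kd: float
    probe_conc: float = 5.0
    competitor_conc: float = 0.0
    ki_competitor: float | None = 0.5

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.probe_conc < 0 or self.competitor_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.ki_competitor is not None and not self.ki_competitor > 0:
            raise ValueError("ki_competitor must be positive when present")


@dataclass(frozen=True)
class DoseResponseParams:
    """Four-parameter logistic (variable-slope) dose-response parameters."""

    ic50: float  # nM
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")


@dataclass(frozen=True)
class FluorophoreModel:
    """Turn-on fluorophore brightness model.

    The free probe has quantum yield ``phi_free`` in aqueous buffer; on
    binding the hydrophobic pocket the yield rises to ``phi_bound``
    (proxied by the measurement in an aprotic solvent).  Unbound probe is
    washed away, so only the bound fraction contributes specific signal.
    """

    phi_free: float = 0.058
    phi_bound: float = 0.424
    per_molecule_gain: float = 0.005
    autofluorescence_mean: float = 100.0
    autofluorescence_sd: float = 30.0

    def __post_init__(self) -> None:
        for phi in (self.phi_free, self.phi_bound):
            if not (0 < phi <= 1):
                raise ValueError("quantum yields must lie in (0, 1]")
        if not self.per_molecule_gain > 0:
            raise ValueError("per_molecule_gain must be positive")

    @property
    def turn_on_ratio(self) -> float:
        """Bound/free brightness ratio (7.31 at the default yields)."""
        return self.phi_bound / self.phi_free


def fractional_occupancy(params: BindingParams) -> float:
    """Equilibrium fraction of active receptors occupied by probe.

    Standard competitive isotherm
    ``theta = P / (P + Kd * (1 + I / Ki))``; reduces to the simple
    binding isotherm when the competitor concentration is zero or no
    Ki is supplied.
    """
    alpha = 1.0
    if params.ki_competitor is not None and params.competitor_conc > 0:
        alpha += params.competitor_conc / params.ki_competitor
    p = params.probe_conc
    return p / (p + params.kd * alpha)


def _hyperbola(c, bmax, kd):
    return bmax * c / (c + kd)


def saturation_binding_fit(
    conc: Sequence[float], response: Sequence[float]
) -> dict[str, float]:
    """Fit a one-site saturation binding curve ``B = Bmax*c/(c+Kd)``.

    Returns point estimates and asymptotic standard errors
    (``kd``, ``bmax``, ``kd_se``, ``bmax_se``).

    Raises
    ------
    FitFailureError
        For degenerate data (constant response, too few concentrations,
        or a non-converging fit).
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.shape != y.shape:
        raise ValueError("conc and response must have equal length")
    if np.unique(c).size < 4:
        raise FitFailureError("need >= 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise FitFailureError("constant response: Kd is unidentifiable")
    # starting values from the data extremes and the mid-response point
    bmax0 = float(y.max()) * 1.2 or 1.0
    kd0 = float(np.exp(np.mean(np.log(c[c > 0])))) if np.any(c > 0) else 1.0
    try:
        popt, pcov = curve_fit(
            _hyperbola, c, y, p0=[bmax0, kd0],
            bounds=([0, 1e-12], [np.inf, np.inf]), method="trf", maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy message varies
        raise FitFailureError(f"saturation fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(popt)):
        raise FitFailureError("saturation fit returned non-finite estimates")
    return {"bmax": popt[0], "kd": popt[1], "bmax_se": se[0], "kd_se": se[1]}


def four_param_logistic(conc, params: DoseResponseParams):
    """Forward variable-slope logistic on log10 concentration (conc in nM).

    ``y = bottom + (top - bottom) / (1 + 10**((log10 IC50 - log10 c) * hill))``
    so ``y(ic50) = (top + bottom) / 2`` for any slope.
    """
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        expo = (np.log10(params.ic50) - np.log10(c)) * params.hill
    return params.bottom + (params.top - params.bottom) / (1.0 + 10.0 ** expo)


def fit_ic50(conc: Sequence[float], response: Sequence[float]) -> dict[str, float]:
    """Fit the four-parameter logistic and return estimates with 95% CIs.

    Requires >= 5 concentrations bracketing the inflection.  Returns keys
    ``ic50``, ``hill``, ``top``, ``bottom`` plus ``<name>_se`` and
    ``ic50_ci95`` (asymptotic, on the log10 scale back-transformed).
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.unique(c).size < 5:
        raise FitFailureError("need >= 5 distinct concentrations")
    if np.ptp(y) == 0:
        raise FitFailureError("constant response: IC50 is unidentifiable")

    def model(logc, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))

    logc = np.log10(c)
    p0 = [float(np.median(logc)), 1.0, float(y.max()), float(y.min())]
    try:
        popt, pcov = curve_fit(model, logc, y, p0=p0, method="trf", maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"logistic fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    log_ic50, hill, top, bottom = popt
    ic50 = 10.0 ** log_ic50
    return {
        "ic50": ic50,
        "hill": hill,
        "top": top,
        "bottom": bottom,
        "hill_se": se[1],
        "top_se": se[2],
        "bottom_se": se[3],
        "ic50_ci95": (10.0 ** (log_ic50 - 1.96 * se[0]), 10.0 ** (log_ic50 + 1.96 * se[0])),
    }


def expected_cell_fluorescence(
    n_active_receptors: float,
    occupancy: float,
    fluor: FluorophoreModel = FluorophoreModel(),
) -> float:
    """Expected probe-channel signal for one cell, in arbitrary units.

    Affine in ``n_active_receptors * occupancy``; the stochastic noise is
    applied by the simulator, this is the deterministic expectation:
    ``autofluorescence_mean + gain * (phi_bound/phi_free) * n * theta``.
    """
    if n_active_receptors < 0 or occupancy < 0:
        raise ValueError("inputs must be non-negative")
    return (
        fluor.autofluorescence_mean
        + fluor.per_molecule_gain * fluor.turn_on_ratio * n_active_receptors * occupancy
    )
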