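"""Six-step gating: scatter gate, CD45 depletion, control-derived
thresholds, quadrant statistics, DMSO background correction, and the
gefitinib-competition specificity check.

The strategy mirrors a manual quadrant analysis: (i) debris is removed on
a forward/side-scatter floor; (ii) CD45(+) leukocytes are excluded;
(iii) the probe-channel threshold is set so the DMSO vehicle tube has no
positive events (its maximum, or a configurable quantile), and the
EGFR-antibody threshold likewise from the isotype tube; (iv) quadrants of
the antibody-vs-probe plot give raw EGFR(+) = Q1+Q2, HX103(+) = Q2+Q3 and
EGFR(+)HX103(+) = Q2 percentages; (v) percentages are background-corrected
by subtracting the DMSO tube's raw values; (vi) specificity is checked by
the reduction of probe MFI in a gefitinib-preblocked tube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EventTable, SamplePanel


class MissingControlError(ValueError):
    """A required control tube is missing or has too few gated events."""


class EmptyGateError(ValueError):
    """No events survive a gating stage; names the stage."""


@dataclass(frozen=True)
class GateConfig:
    """Tunable gating parameters (arbitrary units are instrument-specific)."""

    fsc_min: float = 1e4
    ssc_min: float = 5e3
    control_quantile: float = 1.0    # 1.0 = "no positive events" rule
    cd45_quantile: float = 0.999
    blocking_ratio_min: float = 0.8

    def __post_init__(self) -> None:
        for q in (self.control_quantile, self.cd45_quantile):
            if not (0 < q <= 1):
                raise ValueError("quantiles must lie in (0, 1]")
        if not (0 <= self.blocking_ratio_min <= 1):
            raise ValueError("blocking_ratio_min must lie in [0, 1]")


@dataclass(frozen=True)
class GateThresholds:
    """Positivity cuts derived from the control tubes of one panel."""

    hx103_cut: float
    egfr_cut: float
    cd45_cut: float
    n_events_after_scatter: int
    n_events_after_cd45: int


@dataclass(frozen=True)
class LabelingResult:
    """Raw and background-corrected labeling percentages for one specimen.

    Corrected values are stained-minus-DMSO and may be slightly negative.
    ``blocking_ratio`` is the fractional reduction of background-subtracted
    probe MFI under gefitinib pre-blocking, clamped to [0, 1]; it is None
    (and ``specificity_pass`` False) when the stained tube shows no signal
    above the DMSO background, which makes the ratio not evaluable.
    """

    specimen_id: str
    raw_egfr_pos: float
    raw_hx103_pos: float
    raw_double_pos: float
    egfr_pos: float
    hx103_pos: float
    double_pos: float
    mfi_stained: float
    mfi_dmso: float
    mfi_blocked: float
    blocking_ratio: float | None
    specificity_pass: bool


def _scatter_mask(df: pd.DataFrame, cfg: GateConfig) -> pd.Series:
    return (df["fsc"] >= cfg.fsc_min) & (df["ssc"] >= cfg.ssc_min)


def derive_cd45_cut(panel: SamplePanel, cfg: GateConfig) -> float:
    """CD45 positivity cut: the ``cd45_quantile`` of the isotype tube's
    EGFR-ab channel among scatter-gated events.

    That channel carries no specific stain, so it measures the
    autofluorescence background that CD45-negative cells show on the CD45
    channel, independent of how many leukocytes the specimen contains.
    """
    try:
        isotype = panel.tube("isotype_control").data
    except KeyError as exc:
        raise MissingControlError(str(exc)) from exc
    iso_scatter = isotype[_scatter_mask(isotype, cfg)]
    if len(iso_scatter) < 100:
        raise MissingControlError(
            f"isotype control: only {len(iso_scatter)} events survive the scatter gate"
        )
    return float(iso_scatter["egfr_ab"].quantile(cfg.cd45_quantile))


def derive_thresholds(panel: SamplePanel, cfg: GateConfig) -> GateThresholds:
    """Set positivity cuts from the DMSO (probe channel), isotype (EGFR-ab
    channel) and isotype-background (CD45) controls."""
    cd45_cut = derive_cd45_cut(panel, cfg)
    try:
        dmso = panel.tube("dmso_control").data
    except KeyError as exc:
        raise MissingControlError(str(exc)) from exc
    isotype = panel.tube("isotype_control").data
    iso_scatter = isotype[_scatter_mask(isotype, cfg)]

    dmso_scatter = dmso[_scatter_mask(dmso, cfg)]
    dmso_gated = dmso_scatter[dmso_scatter["cd45"] <= cd45_cut]
    iso_gated = iso_scatter[iso_scatter["cd45"] <= cd45_cut]
    for name, gated in (("dmso", dmso_gated), ("isotype", iso_gated)):
        if len(gated) < 100:
            raise MissingControlError(
                f"{name} control: only {len(gated)} events survive scatter+CD45 gates"
            )

    hx103_cut = float(dmso_gated["hx103"].quantile(cfg.control_quantile))
    egfr_cut = float(iso_gated["egfr_ab"].quantile(cfg.control_quantile))
    return GateThresholds(
        hx103_cut=hx103_cut,
        egfr_cut=egfr_cut,
        cd45_cut=cd45_cut,
        n_events_after_scatter=int(len(dmso_scatter)),
        n_events_after_cd45=int(len(dmso_gated)),
    )


def apply_gates(events: EventTable, th: GateThresholds, cfg: GateConfig) -> pd.DataFrame:
    """Scatter-gate, CD45-deplete, and assign quadrants.

    Positivity is strict (``value > cut``); an event exactly at a cut is
    negative, consistent with thresholds defined as control maxima.
    Returns the gated events with a ``quadrant`` column in {Q1..Q4}:
    Q1 = EGFR(+) only, Q2 = double positive, Q3 = HX103(+) only, Q4 = double
    negative.
    """
    df = events.data
    df = df[_scatter_mask(df, cfg)]
    if len(df) == 0:
        raise EmptyGateError("no events survive the FSC/SSC scatter gate")
    df = df[df["cd45"] <= th.cd45_cut]
    if len(df) == 0:
        raise EmptyGateError("no events survive the CD45 exclusion gate")
    df = df.copy()
    egfr_pos = df["egfr_ab"] > th.egfr_cut
    hx_pos = df["hx103"] > th.hx103_cut
    df["quadrant"] = np.select(
        [egfr_pos & ~hx_pos, egfr_pos & hx_pos, ~egfr_pos & hx_pos],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    return df


def _raw_percentages(gated: pd.DataFrame) -> tuple[float, float, float]:
    counts = gated["quadrant"].value_counts()
    n = len(gated)
    q = {k: counts.get(k, 0) / n * 100.0 for k in ("Q1", "Q2", "Q3", "Q4")}
    return q["Q1"] + q["Q2"], q["Q2"] + q["Q3"], q["Q2"]


def quantify(panel: SamplePanel, cfg: GateConfig | None = None) -> LabelingResult:
    """Full per-specimen readout: corrected percentages, MFIs, blocking ratio.

    Corrected percentage = raw(stained) - raw(DMSO) for each of EGFR(+),
    HX103(+) and EGFR(+)HX103(+).  MFIs are arithmetic means of the probe
    channel among gated events of each tube.  Blocking ratio =
    ``1 - (MFI_blocked - MFI_dmso) / (MFI_stained - MFI_dmso)`` clamped to
    [0, 1].
    """
    cfg = cfg or GateConfig()
    th = derive_thresholds(panel, cfg)

    gated = {
        cond: apply_gates(panel.tube(cond), th, cfg)
        for cond in ("dmso_control", "stained", "gefitinib_blocked")
    }
    raw_stained = _raw_percentages(gated["stained"])
    raw_dmso = _raw_percentages(gated["dmso_control"])

    mfi = {cond: float(g["hx103"].mean()) for cond, g in gated.items()}
    denom = mfi["stained"] - mfi["dmso_control"]
    if denom <= 0:
        blocking_ratio = None
        specificity_pass = False
    else:
        ratio = 1.0 - (mfi["gefitinib_blocked"] - mfi["dmso_control"]) / denom
        blocking_ratio = float(np.clip(ratio, 0.0, 1.0))
        specificity_pass = blocking_ratio >= cfg.blocking_ratio_min

    return LabelingResult(
        specimen_id=panel.specimen_id,
        raw_egfr_pos=raw_stained[0],
        raw_hx103_pos=raw_stained[1],
        raw_double_pos=raw_stained[2],
        egfr_pos=raw_stained[0] - raw_dmso[0],
        hx103_pos=raw_stained[1] - raw_dmso[1],
        double_pos=raw_stained[2] - raw_dmso[2],
        mfi_stained=mfi["stained"],
        mfi_dmso=mfi["dmso_control"],
        mfi_blocked=mfi["gefitinib_blocked"],
        blocking_ratio=blocking_ratio,
        specificity_pass=specificity_pass,
    )
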