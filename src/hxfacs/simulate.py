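"""Synthetic four-tube cytometry panels with retained ground truth.

Emulates dissociated-tissue single-cell suspensions measured on a
five-channel panel (FSC, SSC, CD45, total-EGFR antibody, turn-on probe)
under four matched tube conditions: a DMSO vehicle control, an isotype
antibody control, the probe-stained tube, and a tube pre-blocked with
excess gefitinib.  Every event carries its generating population and an
active/inactive EGFR indicator, so the downstream gating pipeline can be
scored against truth.

The model, per cell:

* scatter channels are log-normal per population;
* a per-cell total receptor count ``R ~ 10**Normal(m, s)``;
* the cell is "active" with the population's ``active_fraction``; an
  active cell presents all R receptors in the probe-bindable
  conformation, an inactive cell presents none (EGFR autoinhibition is
  treated as all-or-none per cell, which is what makes dot plots
  bimodal);
* probe signal = per-cell expectation from
  :func:`hxfacs.binding.expected_cell_fluorescence` with the occupancy
  of the tube's condition, times multiplicative log-normal noise, plus a
  Gaussian autofluorescence floor, truncated at zero.

No spectral spillover, doublets, or instrument drift are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .binding import BindingParams, FluorophoreModel, fractional_occupancy

TUBE_CONDITIONS = ("dmso_control", "isotype_control", "stained", "gefitinib_blocked")

EVENT_COLUMNS = ["event_id", "fsc", "ssc", "cd45", "egfr_ab", "hx103"]
TRUTH_COLUMNS = ["truth_population", "truth_active"]


@dataclass(frozen=True)
class PopulationSpec:
    """One cellular population of the suspension.

    ``fsc_mean``/``ssc_mean`` are the scale (median) of log-normal scatter
    distributions and ``*_sd`` their log-space sigma.  ``cd45_level`` is the
    expected specific CD45 stain signal (0 for CD45-negative cells).
    Receptor counts are log10-normal per cell; ``active_fraction`` is the
    probability that a cell presents its receptors in the active,
    probe-bindable conformation; ``kd_apparent`` is the cellular apparent
    probe dissociation constant in uM.
    """

    name: str
    fraction: float
    fsc_mean: float = 5e4
    fsc_sd: float = 0.25
    ssc_mean: float = 3e4
    ssc_sd: float = 0.3
    cd45_level: float = 0.0
    egfr_receptor_log10_mean: float = 4.7
    egfr_receptor_log10_sd: float = 0.25
    active_fraction: float = 0.0
    kd_apparent: float = 2.7

    def __post_init__(self) -> None:
        if not (0 <= self.active_fraction <= 1):
            raise ValueError("active_fraction must lie in [0, 1]")
        if min(self.fsc_sd, self.ssc_sd, self.egfr_receptor_log10_sd) < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.fraction < 0:
            raise ValueError("fraction must be non-negative")


@dataclass
class EventTable:
    """Per-event channel measurements for one tube."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("EventTable must contain at least one event")
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_truth(self) -> bool:
        return all(c in self.data.columns for c in TRUTH_COLUMNS)


@dataclass
class SamplePanel:
    """Matched tube set for one specimen; the unit the gating consumes."""

    specimen_id: str
    tubes: dict[str, EventTable]
    tissue_type: str = "surgical"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [t for t in TUBE_CONDITIONS if t not in self.tubes]
        if missing:
            raise ValueError(f"panel is missing tubes: {missing}")

    def tube(self, condition: str) -> EventTable:
        if condition not in TUBE_CONDITIONS:
            raise KeyError(f"unknown tube condition {condition!r}")
        return self.tubes[condition]


@dataclass(frozen=True)
class AssaySpec:
    """Staining chemistry shared by all tubes of a panel."""

    probe_conc: float = 5.0       # uM probe in stained/blocked tubes
    blocking_conc: float = 50.0   # uM gefitinib in the blocked tube
    ki_competitor: float = 0.5    # uM; order-of-magnitude gefitinib Ki
    fluor: FluorophoreModel = field(default_factory=FluorophoreModel)
    antibody_gain: float = 0.1    # a.u. per receptor on the EGFR-ab channel
    signal_cv: float = 0.25       # multiplicative log-normal CV on specific signal


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _occupancy(pop: PopulationSpec, assay: AssaySpec, condition: str) -> float:
    if condition in ("dmso_control",):
        return 0.0
    competitor = assay.blocking_conc if condition == "gefitinib_blocked" else 0.0
    return fractional_occupancy(
        BindingParams(
            kd=pop.kd_apparent,
            probe_conc=assay.probe_conc,
            competitor_conc=competitor,
            ki_competitor=assay.ki_competitor,
        )
    )


def simulate_panel(
    populations: Iterable[PopulationSpec],
    n_events: int,
    seed: int,
    assay: AssaySpec | None = None,
    specimen_id: str = "synthetic",
    tissue_type: str = "surgical",
) -> SamplePanel:
    """Generate a matched four-tube panel; same seed, same panel, bit for bit.

    Each tube draws ``n_events`` events from the same population mixture
    (independent aliquots of one suspension).  The DMSO vehicle tube is
    background-only on both fluorescence channels (it anchors the "no
    positive events" thresholds and the percentage subtraction); the
    isotype tube replaces the EGFR antibody with an irrelevant isotype
    (background only on that channel) but carries the probe; the blocked
    tube is pre-incubated with excess gefitinib before the probe,
    lowering probe occupancy through the competitive isotherm.
    """
    pops = list(populations)
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    fractions = np.array([p.fraction for p in pops], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions must sum to 1, got {fractions.sum()}")
    assay = assay or AssaySpec()
    rng = np.random.default_rng(seed)
    fl = assay.fluor

    tubes: dict[str, EventTable] = {}
    for condition in TUBE_CONDITIONS:
        counts = rng.multinomial(n_events, fractions)
        frames = []
        for pop, count in zip(pops, counts):
            if count == 0:
                continue
            fsc = rng.lognormal(np.log(pop.fsc_mean), pop.fsc_sd, count)
            ssc = rng.lognormal(np.log(pop.ssc_mean), pop.ssc_sd, count)
            receptors = 10.0 ** rng.normal(
                pop.egfr_receptor_log10_mean, pop.egfr_receptor_log10_sd, count
            )
            active = rng.random(count) < pop.active_fraction

            auto = lambda n=count: rng.normal(fl.autofluorescence_mean, fl.autofluorescence_sd, n)
            cd45 = pop.cd45_level * _lognormal_noise(rng, assay.signal_cv, count) + auto()

            if condition in ("isotype_control", "dmso_control"):
                egfr_ab = auto()
            else:
                egfr_ab = (
                    assay.antibody_gain * receptors * _lognormal_noise(rng, assay.signal_cv, count)
                    + auto()
                )

            theta = _occupancy(pop, assay, condition)
            n_active_receptors = np.where(active, receptors, 0.0)
            specific = (
                fl.per_molecule_gain * fl.turn_on_ratio * n_active_receptors * theta
            )
            hx103 = specific * _lognormal_noise(rng, assay.signal_cv, count) + auto()

            frames.append(
                pd.DataFrame(
                    {
                        "fsc": fsc,
                        "ssc": ssc,
                        "cd45": cd45,
                        "egfr_ab": egfr_ab,
                        "hx103": hx103,
                        "truth_population": pop.name,
                        "truth_active": active.astype(int),
                    }
                )
            )
        tube = pd.concat(frames, ignore_index=True)
        for ch in ("fsc", "ssc", "cd45", "egfr_ab", "hx103"):
            tube[ch] = tube[ch].clip(lower=0.0)
        tube.insert(0, "event_id", np.arange(len(tube)))
        tubes[condition] = EventTable(tube)

    return SamplePanel(specimen_id=specimen_id, tubes=tubes, tissue_type=tissue_type, seed=seed)


# ---------------------------------------------------------------------------
# Preset archetypes
# ---------------------------------------------------------------------------

_LEUKOCYTE = dict(
    fsc_mean=3e4, fsc_sd=0.25, ssc_mean=2e4, ssc_sd=0.3, cd45_level=5000.0,
    egfr_receptor_log10_mean=2.0, egfr_receptor_log10_sd=0.3,
    active_fraction=0.0,
)
_DEBRIS = dict(
    fsc_mean=2.5e3, fsc_sd=0.5, ssc_mean=1.5e3, ssc_sd=0.5, cd45_level=0.0,
    egfr_receptor_log10_mean=0.0, egfr_receptor_log10_sd=0.0,
    active_fraction=0.0,
)

# (tumor_fraction, leukocyte, debris, active_fraction, receptor_log10, kd_apparent)
_PRESETS: Mapping[str, dict] = {
    # constitutively active mutant, high receptor load
    "mutant_high": dict(tumor=0.85, leuko=0.10, debris=0.05,
                        active=0.95, log10_r=4.7, kd=0.8),
    # activating mutant with low total EGFR expression
    "mutant_low_egfr": dict(tumor=0.85, leuko=0.10, debris=0.05,
                            active=0.90, log10_r=3.3, kd=0.8),
    # wild-type receptor massively overexpressed (A431-like)
    "wt_overexpressing": dict(tumor=0.85, leuko=0.10, debris=0.05,
                              active=0.60, log10_r=5.5, kd=2.7),
    # wild-type, mostly autoinhibited
    "wt_normal": dict(tumor=0.85, leuko=0.10, debris=0.05,
                      active=0.05, log10_r=4.3, kd=2.7),
    # adjacent normal tissue: sparse epithelium, more leukocytes and debris
    "adjacent_normal": dict(tumor=0.55, leuko=0.30, debris=0.15,
                            active=0.03, log10_r=4.0, kd=2.7),
}


def tumor_mixture(
    active_fraction: float,
    tumor_fraction: float = 0.85,
    leukocyte_fraction: float = 0.10,
    receptor_log10_mean: float = 4.7,
    kd_apparent: float = 0.8,
) -> list[PopulationSpec]:
    """Standard tumor + leukocyte + debris mixture used by presets and tests."""
    debris_fraction = 1.0 - tumor_fraction - leukocyte_fraction
    if debris_fraction < 0:
        raise ValueError("tumor and leukocyte fractions exceed 1")
    return [
        PopulationSpec(
            name="tumor", fraction=tumor_fraction,
            active_fraction=active_fraction,
            egfr_receptor_log10_mean=receptor_log10_mean,
            kd_apparent=kd_apparent,
        ),
        PopulationSpec(name="leukocyte", fraction=leukocyte_fraction, **_LEUKOCYTE),
        PopulationSpec(name="debris", fraction=debris_fraction, **_DEBRIS),
    ]


def preset_panel(
    archetype: str, seed: int, n_events: int | None = None
) -> SamplePanel:
    """A panel whose truth parameters are documented constants.

    ``n_events`` defaults to 100000 (surgical-scale yield); pass 10000 for
    a biopsy-scale panel.
    """
    if archetype not in _PRESETS:
        raise KeyError(
            f"unknown archetype {archetype!r}; choose from {sorted(_PRESETS)}"
        )
    p = _PRESETS[archetype]
    populations = tumor_mixture(
        active_fraction=p["active"],
        tumor_fraction=p["tumor"],
        leukocyte_fraction=p["leuko"],
        receptor_log10_mean=p["log10_r"],
        kd_apparent=p["kd"],
    )
    n = int(n_events) if n_events is not None else 100_000
    return simulate_panel(
        populations, n_events=n, seed=seed, specimen_id=archetype,
        tissue_type="surgical",
    )


def truth_active_share(
    panel: SamplePanel, exclude: tuple[str, ...] = ("leukocyte", "debris")
) -> float:
    """Ground-truth share of active cells among (non-leukocyte, non-debris)
    events of the stained tube; the quantity the corrected double-positive
    percentage estimates."""
    tube = panel.tube("stained")
    if not tube.has_truth:
        raise ValueError("panel carries no truth labels")
    df = tube.data
    mask = ~df["truth_population"].isin(exclude)
    return float(df.loc[mask, "truth_active"].mean())


# ---------------------------------------------------------------------------
# Panel CSV / manifest IO
# ---------------------------------------------------------------------------

def write_panel(panel: SamplePanel, out_dir: str | Path) -> Path:
    """Write one CSV per tube plus a YAML manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for condition, tube in panel.tubes.items():
        fname = f"{panel.specimen_id}_{condition}.csv"
        tube.data.to_csv(out / fname, index=False)
        files[condition] = fname
    manifest = {
        "specimen_id": panel.specimen_id,
        "tissue_type": panel.tissue_type,
        "seed": panel.seed,
        "tubes": files,
    }
    manifest_path = out / f"{panel.specimen_id}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_panel(manifest_path: str | Path) -> SamplePanel:
    """Load a panel previously written by :func:`write_panel`."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    tubes = {
        condition: EventTable(pd.read_csv(manifest_path.parent / fname))
        for condition, fname in manifest["tubes"].items()
    }
    return SamplePanel(
        specimen_id=manifest["specimen_id"],
        tubes=tubes,
        tissue_type=manifest.get("tissue_type", "surgical"),
        seed=manifest.get("seed"),
    )
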