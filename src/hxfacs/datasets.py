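"""Packaged reference cohorts and their validation.

Two clinical cohorts ship with the package as plain CSV, transcribed
exactly as printed (mixed significant figures and negative
background-corrected percentages included; nothing is re-rounded on
load):

* the **surgical cohort** — 23 resected NSCLC tumor specimens with
  Sanger mutation status and the three labeling percentages;
* the **biopsy cohort** — 31 NSCLC patients with mutation status,
  first-line treatment, RECIST response, and the same three percentages.

A third file carries the published cohort summary counts; because a few
of its cells disagree with a direct recount of the per-patient table,
:func:`validate_summary` recomputes every recomputable cell and reports
agreements and discrepancies rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

DOUBLE_POS_CUTOFF = 30.1   # operating thresholds used throughout the cohorts
EGFR_POS_CUTOFF = 36.3
HX103_POS_CUTOFF = 31.0

RESPONDER_CATEGORIES = ("CR", "PR")
EVALUABLE_CATEGORIES = ("CR", "PR", "SD", "PD")

_SCHEMA_SURGICAL = [
    "sample_code", "sex", "ajcc_stage", "sanger_status",
    "double_pos_pct", "egfr_pos_pct", "hx103_pos_pct", "ddpcr_status",
]
_SCHEMA_BIOPSY = [
    "patient_no", "mutation", "first_line_treatment", "response",
    "double_pos_pct", "egfr_pos_pct", "hx103_pos_pct",
]


@dataclass(frozen=True)
class SurgicalRecord:
    sample_code: int
    sex: str
    ajcc_stage: str
    sanger_status: str          # L858R / 19del / none
    double_pos_pct: float
    egfr_pos_pct: float
    hx103_pos_pct: float
    ddpcr_status: str | None    # populated only where ddPCR was run

    @property
    def mutation_positive(self) -> bool:
        """Sanger-based reference label (ddPCR findings deliberately not
        folded in, so confusion matrices follow the published orientation)."""
        return self.sanger_status != "none"


@dataclass(frozen=True)
class BiopsyRecord:
    patient_no: int
    mutation: str               # L858R / 19del / none
    first_line_treatment: str
    response: str               # CR / PR / SD / PD / NE
    double_pos_pct: float
    egfr_pos_pct: float
    hx103_pos_pct: float

    @property
    def mutation_positive(self) -> bool:
        return self.mutation != "none"

    @property
    def tki_treated(self) -> bool:
        return self.mutation_positive

    @property
    def response_evaluable(self) -> bool:
        return self.tki_treated and self.response in EVALUABLE_CATEGORIES

    @property
    def responder(self) -> bool:
        return self.response_evaluable and self.response in RESPONDER_CATEGORIES


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hxfacs.data").joinpath(name)))


def _read(name: str, path: str | Path | None, schema: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path if path is not None else _data_path(name))
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    return df


def load_surgical(path: str | Path | None = None) -> list[SurgicalRecord]:
    """The 23-specimen surgical cohort (or a user CSV with the same schema)."""
    df = _read("surgical_cohort.csv", path, _SCHEMA_SURGICAL)
    records = [
        SurgicalRecord(
            sample_code=int(r.sample_code),
            sex=str(r.sex),
            ajcc_stage=str(r.ajcc_stage),
            sanger_status=str(r.sanger_status),
            double_pos_pct=float(r.double_pos_pct),
            egfr_pos_pct=float(r.egfr_pos_pct),
            hx103_pos_pct=float(r.hx103_pos_pct),
            ddpcr_status=None if pd.isna(r.ddpcr_status) else str(r.ddpcr_status),
        )
        for r in df.itertuples()
    ]
    if path is None:
        if len(records) != 23:
            raise ValueError(f"surgical cohort must have 23 records, got {len(records)}")
        if sum(r.mutation_positive for r in records) != 12:
            raise ValueError("surgical cohort must contain 12 Sanger-positive samples")
    for r in records:
        for v in (r.double_pos_pct, r.egfr_pos_pct, r.hx103_pos_pct):
            if not (0 <= v <= 100):
                raise ValueError(f"sample {r.sample_code}: percentage {v} out of [0, 100]")
    return records


def load_biopsy(path: str | Path | None = None) -> list[BiopsyRecord]:
    """The 31-patient biopsy cohort (or a user CSV with the same schema)."""
    df = _read("biopsy_cohort.csv", path, _SCHEMA_BIOPSY)
    records = [
        BiopsyRecord(
            patient_no=int(r.patient_no),
            mutation=str(r.mutation),
            first_line_treatment=str(r.first_line_treatment),
            response=str(r.response),
            double_pos_pct=float(r.double_pos_pct),
            egfr_pos_pct=float(r.egfr_pos_pct),
            hx103_pos_pct=float(r.hx103_pos_pct),
        )
        for r in df.itertuples()
    ]
    if path is None:
        if len(records) != 31:
            raise ValueError(f"biopsy cohort must have 31 records, got {len(records)}")
        if sum(r.mutation_positive for r in records) != 15:
            raise ValueError("biopsy cohort must contain 15 mutation-positive patients")
        if sum(r.response_evaluable for r in records) != 13:
            raise ValueError("biopsy cohort must contain 13 response-evaluable patients")
    return records


def load_summary(path: str | Path | None = None) -> pd.DataFrame:
    """The published cohort summary counts, as a tidy frame."""
    return pd.read_csv(path if path is not None else _data_path("cohort_summary.csv"))


def scores(records, parameter: str, label: str = "mutation"):
    """(values, labels) for a labeling parameter against a reference label.

    ``parameter`` is one of double_pos / egfr_pos / hx103_pos; ``label``
    is 'mutation' (all records) or 'response' (evaluable TKI-treated
    biopsy records only, responders positive).
    """
    attr = f"{parameter}_pct"
    if label == "mutation":
        subset = records
        labels = [r.mutation_positive for r in subset]
    elif label == "response":
        subset = [r for r in records if r.response_evaluable]
        labels = [r.responder for r in subset]
    else:
        raise ValueError(f"unknown label {label!r}")
    return [getattr(r, attr) for r in subset], labels


def validate_summary(
    records: list[BiopsyRecord] | None = None,
    summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recompute every summary cell derivable from the per-patient table.

    Returns a frame with columns (characteristic, category, column,
    published, recomputed, agree).  Known discrepancy: the summary's
    threshold bucket for the double-positive parameter counts 10 patients
    at >= 30.1 (5 per mutation class) where a direct recount of the
    per-patient percentages gives 11 (6 in the 19del class); reported
    here, not raised.
    """
    records = records if records is not None else load_biopsy()
    summary = summary if summary is not None else load_summary()

    classes = {"total": lambda r: True,
               "L858R": lambda r: r.mutation == "L858R",
               "19del": lambda r: r.mutation == "19del",
               "WT": lambda r: r.mutation == "none"}

    def counts(pred):
        return {col: sum(1 for r in records if cls(r) and pred(r))
                for col, cls in classes.items()}

    recomputable = {
        ("patients_n", ""): counts(lambda r: True),
        ("double_pos_pct", "ge_30.1"): counts(lambda r: r.double_pos_pct >= DOUBLE_POS_CUTOFF),
        ("double_pos_pct", "lt_30.1"): counts(lambda r: r.double_pos_pct < DOUBLE_POS_CUTOFF),
        ("egfr_tki_therapy", ""): counts(lambda r: r.tki_treated),
        ("tki_response", "CR/PR"): counts(lambda r: r.responder),
        ("tki_response", "SD"): counts(lambda r: r.response_evaluable and r.response == "SD"),
        ("tki_response", "PD"): counts(lambda r: r.response_evaluable and r.response == "PD"),
        ("tki_response", "NE"): counts(lambda r: r.tki_treated and r.response == "NE"),
    }

    rows = []
    for (char, cat), computed in recomputable.items():
        pub = summary[(summary["characteristic"] == char)
                      & (summary["category"].fillna("") == cat)]
        if pub.empty:
            continue
        pub = pub.iloc[0]
        for col_csv, col_key in (("total", "total"), ("L858R", "L858R"),
                                 ("19del", "19del"), ("WT", "WT")):
            published = pub[col_csv]
            if pd.isna(published) or str(published).strip() in ("", "-"):
                continue
            published = int(published)
            rows.append({
                "characteristic": char, "category": cat, "column": col_key,
                "published": published, "recomputed": computed[col_key],
                "agree": published == computed[col_key],
            })
    return pd.DataFrame(rows)
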