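# hxfacs

Quantifying **active EGFR** in non-small-cell lung cancer specimens by
multicolor flow cytometry with a turn-on fluorogenic TKI probe (HX103),
and turning that readout into clinical decisions.

DNA sequencing tells you whether a tumor *carries* an EGFR-activating
mutation (L858R, exon-19 deletions); it does not tell you whether the
kinase is actually in its active conformation, which is what a TKI binds.
A quinazoline probe carrying an environment-sensitive fluorophore lights
up only inside the hydrophobic kinase pocket, so the fraction of
EGFR(+) tumor cells that also stain with the probe — the
**EGFR(+)HX103(+)** or *double-positive* percentage — is a per-cell,
functional measure of EGFR activation. This package implements the full
analysis chain for that assay, for analysts who want to reproduce,
stress-test, or extend it:

* `hxfacs.binding` — competitive occupancy isotherm
  θ = P/(P + K_d(1 + I/K_i)), saturation-binding and four-parameter
  logistic (IC50) fits, and the turn-on brightness model;
* `hxfacs.simulate` — a seeded event-level simulator of matched
  four-tube panels (DMSO vehicle / isotype / stained /
  gefitinib-blocked) with retained ground truth;
* `hxfacs.gating` — scatter gate, CD45 depletion, control-derived
  thresholds ("no positive events" in the vehicle tube), quadrant
  percentages, DMSO background correction, gefitinib-blocking
  specificity check;
* `hxfacs.diagnostics` — tie-corrected ROC/AUC (pair statistic,
  asserted equal to the trapezoidal area), Youden cut-offs over
  midpoints, confusion matrices with exact Clopper–Pearson CIs,
  Mann–Whitney and Pearson tests;
* `hxfacs.cost` — expected testing cost of FACS-first triage vs
  NGS-only and the break-even cost ratio r* = 1/P(FACS+);
* `hxfacs.datasets` — two bundled reference cohorts (23 surgical
  specimens, 31 biopsy patients) transcribed at printed precision, with
  a validator that recounts the published summary table.

The numbered scripts under `analysis/` walk the same chain as a
narrative: simulate archetype specimens, gate them, evaluate both
cohorts, and sweep the cost model. `docs/methods.md` documents the
models, defaults and design decisions.

## Worked example

Simulate a specimen dominated by constitutively active mutant tumor
cells, gate it, and read off the corrected labeling:

```python
from hxfacs import preset_panel, quantify, truth_active_share

panel = preset_panel("mutant_high", seed=1, n_events=20_000)
res = quantify(panel)
print(f"truth active-tumor share {100 * truth_active_share(panel):.1f}%")
print(f"corrected EGFR(+)HX103(+) {res.double_pos:.1f}%")
print(f"blocking ratio {res.blocking_ratio:.2f}  specific: {res.specificity_pass}")
```

prints

```
truth active-tumor share 94.7%
corrected EGFR(+)HX103(+) 94.7%
blocking ratio 0.93  specific: True
```

i.e. the pipeline recovers the simulated ground truth (94.7 % of tumor
cells in this draw are active), and pre-blocking with 50 µM gefitinib
removes 93 % of the
background-subtracted probe signal, confirming on-target labeling.

On the bundled surgical cohort the same statistics reproduce the
assay's published performance:

```python
from hxfacs import load_surgical, roc_auc, confusion
from hxfacs.datasets import scores
from hxfacs.diagnostics import LabeledScores

sc = LabeledScores.from_arrays(*scores(load_surgical(), "double_pos"))
print(f"AUC {roc_auc(sc).auc:.2f}")
c = confusion(sc, 30.1)
print(f"sens {c.sensitivity:.1f}% (CI {c.sensitivity_ci95[0]:.1f}-{c.sensitivity_ci95[1]:.1f}), acc {c.accuracy:.1f}%")
```

```
AUC 0.85
sens 83.3% (CI 51.6-97.9), acc 82.6%
```

The CLI wraps the same steps: `hxfacs simulate`, `hxfacs gate`,
`hxfacs classify`, `hxfacs cost`, and `hxfacs reproduce` (which prints
the reference checklist and exits nonzero on any mismatch).

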