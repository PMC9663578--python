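# Methods

`hxfacs` quantifies *active* EGFR — receptor molecules whose kinase
pocket is in the catalytically competent conformation — in dissociated
tumor specimens, using a turn-on fluorogenic TKI probe (HX103) read out
by multicolor flow cytometry. The package covers the full chain: a
binding/brightness model, an event-level simulator, the gating pipeline,
diagnostic-performance statistics over two bundled reference cohorts,
and a decision-analytic model of testing costs. This note records the
models, defaults, and the design choices that were genuinely open.

## Binding and brightness model

Probe occupancy of an active receptor follows the competitive
equilibrium isotherm

θ = P / (P + K_d·(1 + I/K_i)),

with probe concentration P (default 5 µM), competitor (gefitinib)
concentration I (default 50 µM in the blocked tube), and cellular
apparent dissociation constants K_d in the 0.8–2.9 µM range depending
on receptor genotype (0.8 µM for the constitutively active L858R
archetype, 2.7 µM for wild-type). K_i of gefitinib for this competition
is not separately measured; the default 0.5 µM is an order-of-magnitude
choice that makes 50 µM competitor suppress ≥ 90 % of occupancy at these
K_d values, and it is exposed in `AssaySpec`.

The fluorophore is environment-sensitive: quantum yield 5.8 % in
aqueous buffer versus 42.4 % in an aprotic solvent, the latter used as a
proxy for the protein-bound state because no bound-state yield is
available — hence a turn-on brightness ratio of ≈ 7.31. Expected
per-cell probe signal is affine in (bound receptors):

E[hx103] = autofluorescence + gain · (φ_bound/φ_free) · N_active · θ,

with `per_molecule_gain` = 0.005 a.u. chosen so that, at the default
receptor loads (10^4–10^5.5 per cell), stained active cells sit well
above the control-derived threshold while the residual occupancy in the
gefitinib-blocked tube straddles it — giving the strong-but-incomplete
blocking picture seen in real specimens.

Saturation-binding (B = B_max·c/(c+K_d)) and variable-slope logistic
dose-response fits use trust-region nonlinear least squares on
log-concentration, with starting values from the data extremes and the
geometric-mean concentration; degenerate inputs (constant response, too
few concentrations) raise `FitFailureError` rather than returning
garbage. IC50 CIs are asymptotic on the log10 scale.

## Event simulator

`simulate_panel` draws matched four-tube panels (DMSO vehicle, isotype,
stained, gefitinib-blocked) from one mixture of populations: tumor (or
epithelial) cells, CD45(+) leukocytes, and debris. Per cell: scatter
channels are log-normal; total receptor count is log10-normal; the cell
is *active* with the population's `active_fraction`, and activation is
all-or-none per cell (an active cell presents all its receptors to the
probe, an inactive one none). The all-or-none choice is what produces
the bimodal antibody-vs-probe dot plots the quadrant gating assumes, and
it makes the ground-truth "active-tumor share" a directly recoverable
quantity. Channel noise is multiplicative log-normal with CV 25 % on
specific signal plus an additive Gaussian autofluorescence floor
(mean 100, SD 30 a.u.), truncated at zero.

Tube semantics: the DMSO tube is background-only on both fluorescence
channels — it anchors the "no positive events" thresholds and the
background subtraction; the isotype tube is background-only on the
EGFR-antibody channel but carries the probe; stained and blocked tubes
differ only in occupancy (θ at I = 0 vs I = 50 µM). Each tube is an
independent draw of `n_events` from the same mixture, as aliquots of one
suspension would be; a fixed seed makes the whole panel bit-identical.

Five preset archetypes (`mutant_high`, `mutant_low_egfr`,
`wt_overexpressing`, `wt_normal`, `adjacent_normal`) encode documented
constants spanning the clinically relevant corners: high/low receptor
load, high/low activation, and normal-tissue composition. Surgical-scale
panels default to 10^5 events per tube, biopsy-scale to 10^4.

What the simulator does **not** emulate: spectral spillover and
compensation, doublets, viability, PMT/area-height instrument effects,
time drift, or partial per-cell activation. Passing the recovery tests
therefore shows the pipeline is correct *given* compensated, bimodal,
single-cell data — not that it is robust to those artifacts.

## Gating pipeline

1. Scatter floor (`fsc_min` = 10^4, `ssc_min` = 5·10^3 a.u., config) —
   removes ≥ 99 % of simulated debris; units are instrument-specific, so
   these are configuration, not constants.
2. CD45 depletion. The CD45 cut is the 0.999 quantile of the isotype
   tube's EGFR-antibody channel among scatter-gated events: that channel
   is pure background, so it estimates the autofluorescence that
   CD45-negative cells show on the CD45 channel, and the rule works for
   any specimen composition — including a leukocyte-only suspension,
   where a quantile of the CD45 channel itself would sit above the
   leukocytes and exclude nothing.
3. Thresholds: probe cut = `control_quantile` of the gated DMSO tube's
   probe channel; antibody cut likewise from the isotype tube. The
   default quantile 1.0 implements "no positive events in the control";
   0.999 is the recommended robust value when single-event outliers are
   a concern.
4. Quadrants by strict inequality (a value equal to the cut is
   negative — ties go to the conservative side). EGFR(+) = Q1+Q2,
   HX103(+) = Q2+Q3, double-positive = Q2, as percentages of gated
   events.
5. Background correction: corrected_X = raw_X(stained) − raw_X(DMSO).
   Corrected values may be slightly negative; they are reported as-is.
6. Specificity: blocking ratio
   1 − (MFI_blocked − MFI_DMSO)/(MFI_stained − MFI_DMSO), clamped to
   [0, 1]; MFIs are arithmetic means on the untransformed scale (a
   deliberate choice — median-based MFI differs little on log-normal
   signal but means match how MFI is usually exported). When the
   stained-minus-DMSO denominator is ≤ 0 the ratio is not evaluable and
   is reported as missing, not raised. The specificity flag defaults to
   blocking ratio ≥ 0.8.

## Diagnostic statistics

* **AUC** is the tie-corrected pair statistic
  (#{pos > neg} + ½·#{pos = neg})/(n₊·n₋); every call also computes the
  trapezoidal area under the empirical ROC and asserts the two agree,
  which pins down the threshold bookkeeping. SE is Hanley–McNeil and
  the 95 % Wald interval is deliberately left uncapped (small samples
  with AUC near 1 produce upper bounds above 1; truncating would hide
  that).
* **Cut-off selection** maximizes Youden's J = sens + spec − 1 over
  midpoints between consecutive distinct values, under the rule
  "positive if value ≥ cutoff", with J-ties broken toward higher
  sensitivity. For the bundled surgical cohort this reproduces the
  30.15 and 30.95 midpoints behind the 30.1 %/31.0 % operating
  thresholds for the double-positive and probe parameters. For
  total-EGFR staining the J-maximizing midpoint is 62.05 (J = 0.742);
  the cohort's published 36.3 % operating threshold instead maximizes
  *accuracy* (it ties 62.05 at 20/23 and wins on sensitivity). No
  single selection rule yields all three published thresholds, so the
  package implements the Youden rule and treats the three published
  values as fixed operating thresholds (`hxfacs.datasets` constants)
  when computing confusion matrices — which reproduces every published
  count.
* **Confusion matrices** use "≥ cutoff" everywhere; sensitivity,
  specificity and accuracy carry exact Clopper–Pearson 95 % CIs (beta
  quantiles; closed at 0 and 100 for degenerate counts).
* **Mann–Whitney U** takes the exact null distribution when the smaller
  group has ≤ 8 observations and the pooled values are tie-free, else
  the tie-corrected normal approximation with continuity correction.
  The exact two-sided p is the doubled minimal inclusive tail
  2·min(P(U ≥ u), P(U ≤ u)) — for the bundled 9-vs-4 responder
  comparison this gives p = 76/715 ≈ 0.1063. Software that excludes
  the observed value from the tail prints ≈ 0.1007 on the same data;
  the inclusive convention is the standard (conservative) one and is
  what the brute-force enumeration oracle in the tests checks.
* **Group summaries** report mean, sample SD (n−1) and SEM per class;
  single-member classes have undefined spread, reported as missing. No
  multiple-testing correction is applied anywhere, matching how such
  cohort analyses are conventionally reported.

## Reference cohorts

Two cohort tables ship inside the package, transcribed exactly as
printed (mixed significant figures; negative background-corrected
percentages preserved): 23 surgical specimens with Sanger mutation
status, and 31 biopsy patients with mutation status, first-line
treatment and RECIST response. Loaders validate counts (23/31 records,
12/15 mutation-positive, 13 response-evaluable). One surgical sample is
Sanger-negative but 19del-positive by droplet digital PCR; the ddPCR
finding is stored as a separate flag so that confusion matrices keep the
Sanger-based orientation while the discordance stays visible.

`validate_summary` recomputes every cohort-summary cell derivable from
the per-patient table. The threshold-bucket row disagrees with a direct
recount by one patient (published 10 at ≥ 30.1 % among mutants vs 11
recounted — one 19del patient at 30.8 % appears to have been
bookkept below threshold); the validator reports both numbers rather
than raising, and the tests assert the discrepancy explicitly.

Because the per-patient inputs are themselves printed-precision
roundings, statistics recomputed from them can drift from published
values in the last digit (e.g. a group SD of 28.95 vs a published 28.9);
tests allow one display unit on spread estimates and half a unit
elsewhere.

## Cost model

Expected testing cost per patient: NGS-only costs C_N; FACS-first costs
C_F + (1 − p₊)·C_N, where p₊ = π·s + (1−π)·(1−sp) is the probability of
a FACS-positive call at mutation prevalence π. The break-even
NGS:FACS cost ratio is r* = 1/p₊ (with sp = 1, exactly 1/(π·s));
FACS-first is cheaper iff C_N/C_F > r*. At the biopsy cohort's
operating characteristics (s = 0.733, sp = 1), r* ≈ 2.7 at π = 0.5 and
9.1–13.6 over π = 0.15–0.10. The model prices testing only — no
treatment costs, no penalty for false calls, no discounting — and the
itemized ≈ $14 per-sample assay cost is carried as a configuration
default, not a modelled quantity.

## Problem sizes and determinism

All cohort statistics are exact desk-scale computations (n ≤ 31).
Simulation-based tests use 2·10^4 events per tube for construction
checks and 10^5 events per tube across a nine-point ground-truth grid
for the recovery guarantee (corrected double-positive within ±5
percentage points of the true active-tumor share, strictly monotone,
Spearman ρ = 1). Every stochastic stage funnels through one
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
panels, gate tables and reports.

## Known limitations

* Per-cell activation is binary; graded receptor-level activation would
  blur the quadrant structure and is not modelled.
* Channel noise and autofluorescence defaults are plausible placeholders
  (no patient-tissue noise calibration exists); they are exposed in
  `FluorophoreModel`/`AssaySpec`.
* Apparent cellular K_d values are used interchangeably with
  recombinant-protein constants in the isotherm.
* The AUC confidence interval is a Wald interval on the Hanley–McNeil
  SE; for n in the low twenties it is approximate and can exceed [0, 1].
* FCS file import is not implemented; panels move as CSV plus manifest.
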