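# Methods

This note documents the statistical models, simulators and numerical choices
behind `synlethnet`, including the places where the design was genuinely
open and what the package chose.

## Viability normalization

Each imaged well contributes a nuclei count. Within an experiment (one
batch, identified by `experiment_id`), every count is divided by the mean
count of the normalization-control wells (GAPDH-silenced by default) and
expressed in percent; a condition's summary is the mean and SEM
(sample sd / √n) of its normalized wells. Consequences worth knowing:

* **Scale equivariance.** Multiplying all raw counts by a constant changes
  nothing — exposure time, cell-line growth rate and plating density drop
  out.
* **No clamping.** Viability above 100% (proliferation faster than control)
  is reported as-is.
* **Batch structure.** Wells are normalized against the control of their own
  batch; pass each day's (or plate's) wells as a separate `experiment_id`
  to choose the granularity.
* **Preconditions.** At least two control wells with positive mean and at
  least two wells per condition; violations raise with the offending
  condition named, never silently.

## Multiplicative interaction model and the lethality call

The null for a double knockdown is `v_pred = v_A v_B / 100` (percent scale);
the interaction statistic is the proliferative defect `δ = v_pred − v_obs`,
positive when the double proliferates worse than expected and negative for
alleviating interactions. A pair is synthetic lethal when `δ ≥ m·SEM̄` with
multiplier `m = 3` (inclusive) and `SEM̄` the experiment's average SEM.

**Which SEMs enter the average** was an open design point, and it matters.
With multiplicative (CV-type) count noise, a condition's SEM scales with its
viability. If double-knockdown conditions entered the average, strong planted
interactions — which push doubles toward zero viability and hence shrink
their SEMs — would *deflate* the threshold exactly when interactions are
present, inflating the false-positive rate on the remaining null pairs
(measured: 7.1% per pair at CV 0.05, n = 6). The package therefore averages
SEMs over the **single-knockdown conditions only**: singles are unaffected by
pairwise interactions, so the noise estimate is independent of effect
presence. Under the same conditions this yields sensitivity 1.00 for planted
ε = 0.4 effects, a 3.2% per-pair false-positive rate, and a 3.3% call rate
under a global null. Averaging over all non-control conditions remains
available (`scope="all"` / `sem_scope="all"`). Normalization and
non-silencing controls are always excluded: the threshold should reflect
assay noise of test conditions.

The caller applies no multiple-testing correction — the rule is a fixed
threshold by design. An optional annotation (`add_fdr=True`) attaches a
one-sided normal p-value per pair (defect SE propagated from the three
condition SEMs by the delta method) and a Benjamini–Hochberg q-value, without
altering the calls.

## Conservation network

Edges are the tested central × cancer pairs; `yeast_predicted` comes from the
user-supplied prediction list, `human_observed` from the lethality call.
Percent conserved / not conserved are fractions **of the predicted edges**,
rounded half-up to integers, with the complement defined as
`100 − pct_conserved` so the two always sum to 100; with zero predicted
edges the percentages are undefined (`None`) while the tallies are still
returned. Hub ranking sorts central genes by flagged-edge degree
(descending, ties alphabetical) over a `networkx` bipartite graph that is
also exposed directly. Genes with no observed interactions stay in the edge
table — absence of edges is data, not an exclusion. A packaged yeast↔human
ortholog alias table supports symbol canonicalization; unknown symbols warn
and pass through rather than erroring.

## Plate simulator

`simulate_plate` emits, for every condition (non-silencing control,
normalization control, each single, each central × cancer double),
`wells_per_condition` integer counts with expected value

    E[count] = baseline × v_A × v_B × (1 − ε_AB)

(singles use one viability factor; controls use 1). ε ∈ [0, 1] is the
planted interaction strength: ε = 0 satisfies the multiplicative null
exactly, ε = 1 is full lethality. Counts are lognormal with exactly the
configured CV (σ² = ln(1+CV²), mean-preserving), rounded to integers and
floored at zero — the simplest strictly positive, mildly right-skewed law
with exact CV control; the true count distribution of an imaging assay is
not known, so this is a modeling choice, not a data-derived fact. Wells are
laid out row-major over 96-well plates; each plate draws from its own
substream of the master seed, so output is a pure function of config + seed
and extending a run never perturbs existing plates.

Defaults mirror the study design the package emulates: baseline 1000
nuclei/control well, CV 0.05, 6 wells per condition, threshold multiplier 3.
One calibration subtlety: with n = 6 wells the studentized control mean has
t(5) tails, so a "within 3 SEM" band covers ~97.0% of runs, not the ~99.7%
a normal intuition suggests — the test suite checks the generator against
the t-distribution prediction.

## Kinetic simulator and the artifact model

The fluorescence-quench assay reads flap-endonuclease activity as rising
fluorescence: cleavage releases the fluorophore from the quencher. Traces
follow

    F(t) = baseline + f_max (1 − e^(−k_eff t)),
    k_eff = k_uninhibited / (1 + (C / IC50)^h),

over a ~10-minute read window (default k = 0.2/min, f_max = 1000 RFU), with
optional additive Gaussian read noise.

**Artifact compounds** exist to exercise the counterscreen. A static
fluorescence offset alone would not fool a rate-based readout (constant
offsets drop out of slopes), so artifacts are modeled as optical
interferents: they attenuate the whole kinetic amplitude by the occupancy
factor `1/(1+(C/IC50)^h)` (inner-filter/quenching of the product signal,
with `true_ic50` acting as apparent quench potency) *and* add a
concentration-proportional autofluorescence offset (default 5 RFU/µM). In
the primary assay an artifact is thus indistinguishable from a genuine
inhibitor of equal potency. In the quencherless counterscreen — where the
substrate fluoresces regardless of cleavage, so the trace is flat at
`baseline + f_max` — genuine inhibitors leave the signal untouched while
artifacts still attenuate it; apparent signal inhibition ≥ 50% (configurable)
removes a hit. Note the two artifact effects pull the counterscreen signal in
opposite directions: at high dose the autofluorescence (∝ C) back-fills the
quenched signal, so counterscreens are best run at the screening dose
(~10 µM in the packaged configurations), not far above it.

## Initial rates, percent inhibition, IC50 fits

Initial rates are ordinary least-squares slopes of RFU vs time, by default
over the full read window (matching the assay's short, nearly linear span);
`window_fraction` restricts the fit to the leading part of the trace for
strongly curved traces. The bias is quantifiable: for k = 0.05/min the
full-window slope sits ~22% below the t→0 tangent `k·f_max`, while a 0–3 min
window tracks it within 15%. Because saturation compresses the *vehicle*
slope more than inhibited slopes, rate-based percent inhibition
(`100(1 − slope/slope_vehicle)`, capped at 100) mildly underestimates strong
inhibition and the demo's fitted IC50s for genuine inhibitors run ~2–3× above
the planted values; artifacts, whose attenuation is exactly multiplicative,
recover their planted potency exactly.

Dose-response series are fit as a four-parameter logistic, parameterized in
log10 concentration (so unit rescaling of concentrations rescales the IC50
and nothing else), with bounds bottom ≥ −10% (tolerates noise below zero),
hill ∈ (0.001, 20], and |log10 IC50 − data span| ≤ 6. The default weighting
is relative: after an unweighted fit, two reweighted passes with
σ = |fitted| + 1 — the standard 1/Y²-style scheme, appropriate for readouts
whose error scales with signal (plate-reader activity data); with a 5% CV on
an 8-point half-log series it recovers a centered IC50 within 20% in ~93% of
runs (insensitive to the σ floor over 1–5). Uniform weighting is available.
Failures return `converged=False` instead of raising; a fitted span below
5% of the observed data spread marks the IC50 unidentifiable
(`converged=False`), and an IC50 outside the tested dose range is flagged
via `ic50_in_range` — flat/inactive series trip one or both.

## Screening funnel and selectivity

The funnel is: primary hits (rate-based inhibition at the screening dose ≥
50%, configurable — a real campaign's hit cutoff depends on library size and
assay window, so this default is a package choice) → counterscreen (drop apparent inhibition ≥ 50%
against the quencherless substrate) → Lipinski rule of five (pass iff
MW < 500 Da, cLogP ≤ 5, H-bond donors ≤ 5, acceptors ≤ 10; strict `<` for
MW, `≤` elsewhere; any single violation fails). On noiseless simulated
libraries the funnel output equals the planted drug-like true inhibitors
exactly. Genotype selectivity comparisons are a thin wrapper over standard
routines: one-way ANOVA (`scipy.stats.f_oneway`) followed by Tukey's HSD
(`scipy.stats.tukey_hsd`), cross-checked in the test suite against
statsmodels.

## What the simulations do and do not show

The generators emulate the *structure* of the study's data — planted
multiplicative-null deviations, CV-type well noise, saturating
fluorescence kinetics, optical artifacts, descriptor-based drug-likeness —
with exactly known ground truth. They do not emulate siRNA off-target
effects or partial knockdown, imaging segmentation errors, plate-position
effects, day-to-day batch drift, compound solubility/aggregation, or any
chemistry. Passing tests therefore demonstrate that the *analysis* is
correct and well calibrated under its stated noise model, not that the
biological assay itself had these operating characteristics.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to give
tight Monte-Carlo estimates: 1000 simulated experiments for the caller's
operating characteristics in the tests (300 planted + 400 null in the
acceptance script), 100 experiments for oracle-equivalence checks, 500
(tests) / 200 (script) noisy dose-response series, and a 3×10 gene matrix
with 6 wells per condition throughout.
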