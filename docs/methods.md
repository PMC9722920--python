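# Methods

This note documents the models and procedures implemented in `milkguard`,
the assumptions behind the synthetic study generator, the numerical
choices, and the known limitations. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Detection models

**Squared Mahalanobis distance.** The reference population (normal-labelled
training samples only) defines the centroid μ and the n−1 sample
covariance Σ. Queries are scored by MD²(x) = (x−μ)ᵀ(Σ+λI)⁻¹(x−μ). The
ridge λ defaults to 1e−8·tr(Σ)/p, which leaves well-conditioned problems
numerically untouched while keeping the metric defined when Σ is singular
(e.g. replicate-collapsed small batches); a pseudo-inverse was rejected
because the ridge keeps scores continuous in the data. The decision cutoff
is the grid value with the highest F1 on training scores (spiked flagged
when score > cutoff, strict inequality; ties toward the smallest cutoff;
default grid 200 even values from 0 to the 99.9th percentile of training
scores, so one stray extreme score cannot stretch the grid).

**Tree ensembles.** ExtraTrees (300 trees) and XGBoost (learning rate
0.01, maximum depth 5, minimum child weight 0.5, column subsample 0.8,
500 boosting rounds, binary-logistic objective) via scikit-learn and
xgboost. A squared-error ("linear") objective is available as an option;
its raw output is clipped to [0,1] and thresholded like a probability.
Scores ≥ 0.5 are called spiked, ties to positive. XGBoost uses exact
greedy splits: at the sample sizes this package targets (hundreds to a
thousand rows) the histogram approximation was observed to place split
boundaries at the edge of the class gap and misclassify clearly separated
samples, and exact splitting costs nothing here. `min_child_weight` and
`colsample_bytree` can be grid-searched under 10-fold cross-validated
binary cross-entropy, with a distinct fold-shuffling seed per grid cell
and ties resolved toward the first cell in grid order.

**Fusion.** Majority voting requires an odd member count. F1-proportional
weighting solves w₁+…+w_k = 1 with fᵢ/wᵢ constant, i.e. wᵢ = fᵢ/Σf; the
fused score Σwᵢrᵢ is thresholded at 0.5 with ties flagged spiked — in a
safety screen the tied case should err toward inspection. Member F1 scores
for the weights are computed on a 20% calibration slice held out of the
member-fitting data, never on test data; the members fused at test time
are the ones trained on the remaining 80%, which avoids any leakage at the
cost of slightly less training data. If every member scores F1 = 0 on the
calibration slice the weights are undefined and the protocol layer falls
back to equal weights (the library call itself raises).

## Evaluation

Spiked is the positive class. Seven metrics are computed directly from
TP/TN/FP/FN; any zero denominator yields `Undetermined`, a distinct
sentinel that propagates (F1 is undetermined if precision or sensitivity
is) and is never coerced to 0 — a detector that flags nothing has no
precision, not perfect precision. Aggregation over repeated splits
reports mean ± n−1 SD over the determined repeats only.

Selection sweeps follow the protocol: training:testing ratios
{50:50, 60:40, 70:30, 80:20, 90:10} × 3 repeats (ties toward the larger
training fraction), iteration counts {1, 5, 10, 50, 100} (ties toward
fewer), and sample-size fractions {0.2, …, 1.0} at a 90:10 split. All
splits are stratified by label refined by adulterant, preserving the
rare-positive structure; whether the original protocol stratified is
unknown, so this is a design choice of this package.

## Drift statistics

Seasons are the three calendar bins Jan–Mar, Apr–Aug, Sep–Dec. Annual
comparisons use one-way fixed-effects ANOVA per feature with Fisher's LSD
post hoc (pairwise t statistics on the pooled within-group variance,
N−k df, deliberately uncorrected — that is what LSD is). Performance
metrics between years are compared by Welch's unequal-variance t-test
(Satterthwaite df), two-sided, α = 0.05. Zero-variance-on-both-sides
inputs are resolved by convention (equal means → p = 1, else p = 0,
flagged degenerate) rather than returning NaN.

## The synthetic study generator

The generator exists because the archives this protocol was designed for
are proprietary. It emulates the *structure* the pipeline assumes, with
order-of-magnitude-plausible constants for bovine raw milk that are
explicitly **not** estimates of any real producer's distributions:

* **Composition.** 8-variate normal, mean (fat 3.8, protein 3.2, NFS 8.7,
  TS 12.5, lactose 4.8 g/100 g; RD 1.030; FPD 0.525 °C; acidity 16 °T),
  SDs (0.40, 0.25, 0.30, 0.50, 0.15, 0.0015, 0.010, 1.0) and a hand-built
  PSD correlation structure (TS tracks fat and NFS, NFS drives RD, etc.).
  Additive season shifts lower fat/protein/NFS/TS/acidity in Apr–Aug and
  raise them in Sep–Dec with lactose moving oppositely; a per-year additive
  vector shifts the later batch (≈0.1–0.5 SD per feature).
* **Spectra.** 1056 ascending grid points over 1000–3550 cm⁻¹; absorbance
  is a sum of eight Gaussian bands (carbohydrate doublet, fingerprint band,
  amide II, ester carbonyl, CH₂ doublet, O–H stretch) whose heights are
  modulated by the sample's lactose, NFS, protein, fat and (negatively)
  TS, plus i.i.d. noise of SD 0.005 AU.
* **Spiking.** Linear in concentration — the simplest model consistent
  with serial dilution: profile += c·Δ and spectrum gains c-scaled
  Gaussian bands. Every signature combines a specific fingerprint with a
  shared "dissolved solute" component (RD +0.015, FPD +0.08 per unit, a
  fingerprint-band contribution), the physical basis on which a
  non-targeted detector can generalize to unseen adulterants. Hydrogen
  peroxide carries almost none of it (it decomposes to water) and is the
  designed hard case; water is a diluent with negative deltas. All
  signatures are illustrative, not measured.
* **Study design.** Training batch: 372 normals + 19 adulterants × 15
  spikes (3 per concentration in {0.01, 0.02, 0.05, 0.1, 0.2} g/100 g),
  dated in 2020. Cross-validation batch: 65 normals + 6 adulterants × 15
  spikes dated in 2021, with hydrogen peroxide, sodium hydroxide and salt
  appearing only there. A uniform 15 spikes per adulterant is used even
  where the motivating design had 4–30 for particular rows, and the
  "improper storage"/"cow smell" treatment arms are omitted because they
  have no concentration semantics.
* **Drift mechanism.** Besides the additive annual shift, the later batch
  expresses only a fraction (default 0.2) of each spike's nominal signal
  (`annual_spike_attenuation`), emulating procedural/matrix batch effects
  such as reagent handling or chemical decomposition. This choice is
  deliberate: with training normals coming only from the old batch, a
  purely additive normal-baseline drift produces false-positive failure
  that adding new-batch spikes cannot repair, whereas attenuated spike
  expression produces the observed-in-practice failure mode — a stale
  model whose sensitivity collapses while specificity survives, and which
  recovers when same-batch spiked samples (the sugars) are added to
  training. The attenuation value was fixed once against the final
  learner configuration by the 5-seed drift-recovery experiment that the
  acceptance suite runs.

What passing tests on this generator do **not** show: performance on real
milk (real matrices have non-Gaussian composition, baseline/scatter
effects in FTIR, nonlinear mixing, and adulterant signatures that differ
from the shipped ones), robustness to instrument recalibration beyond the
modelled additive/attenuation drift, or behaviour on mixtures of
adulterants.

## Protocol stages and problem sizes

Model selection evaluates the five candidates (MD, ExtraTrees, XGBoost,
voting, weighting — also the tie-break order) on each requested view with
3 stratified 70:30 splits. Blinded cross-validation trains the 2-member
weighting ensemble on the training batch plus, depending on drift mode,
none / sugar / all non-held-out crossval spikes, and tests on crossval
normals + held-out spikes; crossval normals and held-out spikes can never
enter training, and every stage asserts train/test sample-id disjointness.
Leave-one-adulterant-out reserves a fixed 30% of normals (drawn once per
call from the protocol seed) as a shared test pool for comparability
across adulterants. LOD is the lowest tested concentration with ≥ 1
flagged spiked sample; if none, it is reported as above the highest tested
concentration. Default problem sizes (657 + 155 samples, 300-tree /
500-round ensembles) keep any full protocol run in the tens of seconds on
one CPU; the test suite uses smaller ensembles where the property under
test does not depend on ensemble size.

## Degenerate inputs and tie-breaks (summary)

Closed QC interval: values exactly on mean ± 3 SD are retained; filtering
is single-pass. Spectral peak ties break toward the lower wavenumber;
windows without an interior maximum fall back to the window's global
maximum, marked in the coordinate provenance; optional 5-point moving-
average smoothing (detection *and* reported height) suppresses the
extreme-value bias of picking maxima from noisy points. The two printed
spectral-range conventions in the source material (descending 3000→1000
vs 1000–3550 cm⁻¹) conflict; the canonical grid is ascending 1000–3550 so
that every extraction window, including 3450–3550, lies on-grid, and
ingest accepts either orientation. The peaks-per-window allocation
(2,1,1,2,1) is a documented guess — the source names five windows and
seven peaks without allocating them — motivated by the carbohydrate and
C–H doublets of milk mid-IR spectra, and is configurable.

## Known limitations

* The GB 19,301-2010 pass/fail comparison is a pluggable predicate only;
  the actual limit values are not distributed with the package.
* No baseline correction, scatter correction or derivative spectroscopy;
  no robust (MCD) covariance; no ROC analysis (the protocol is
  fixed-threshold); no mixture-of-adulterants modelling.
* Replicate spectra are averaged point-wise before feature extraction;
  replicate-level variance is not propagated.
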