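# Methods

## Tracer model and estimator

The rate estimator is the classical ¹⁵N mass balance: the excess atom% the
particulate pool gains over an incubation, divided by the excess atom% of the
enriched substrate pool, scaled by PON and time,

    V = (AP_s − AP_NA) / (AP_Enr − AP_NA) · PON / T.

Assumptions: the substrate pool's atom% is constant over the incubation (no
isotope dilution), uptake is linear in time, and the particulate pool is well
mixed. Violations are handled as follows:

* **Isotope dilution.** Regeneration of unlabeled substrate during the
  incubation lowers the substrate atom%, so the estimator reads *net* uptake.
  No correction is applied in the estimator (gross-uptake inversion is a
  non-goal); instead the simulator carries an explicit regeneration term and
  the bias has the closed form net/gross = (S/(rT))(1 − e^(−rT/S)), exposed
  by `simulate.bias_curve`. The factor → 1 as T → 0, which is why short
  (~60 min) incubations are the protocol's defence against the bias.
* **Sub-natural-abundance cells.** Measurement noise (or fractionation) can
  leave post-incubation atom% below the pre-incubation value. Such records
  return a *signed* rate plus a warning and a `flagged` mark; they are never
  clipped, and pooled aggregations exclude flagged rows by default so QC can
  find them.
* **Degenerate enrichment** (substrate atom% not above the cells' baseline)
  is an error, not a zero.

Constants and units: natural abundance 0.36630 atom% from R_air = 0.0036765
(δ¹⁵N = 0 by construction); spike label defaults to 98 atom% (configurable);
PON enters the equation in µmol N L⁻¹, with an explicit mg N L⁻¹ converter
(÷14.0067 g mol⁻¹ × 1000) because field reports typically use mass units.
Specific uptake uses a ×24 hour→day factor: volumetric rates are tabulated
per hour and specific rates per day, and the conversion is our documented
choice since no canonical statement exists.

Spike design: `spike_for_target_fraction` targets 10% of ambient by default;
`percent_addition` warns above 15% — the protocol targets ~10% and achieved
additions average below that, so 15% flags genuinely unusual over-enrichment
without rejecting routine variation.

## Preference aggregation

Within a group (default: lake × fraction) rates are summed per N form across
dates and then normalized — a **ratio of sums**, with missing cells
contributing zero. This convention, rather than the mean of per-date ratios,
is what reproduces the published multi-date percentages from the printed rate
tables (verified in the acceptance suite for four of the five lakes). Lake
Agawam's published percentages are not reproducible from the printed table
under either convention (they appear to derive from replicate-level data);
it is therefore excluded from the reproduction targets and documented here.
Percentages keep full precision internally; rounding (half away from zero,
matching the printed integers) happens only at the reporting layer.

## Trophic state

Carlson's log-linear sub-indices: TSI(SD) = 60 − 14.41 ln SD,
TSI(chl) = 9.81 ln chl + 30.6, TSI(TP) = 14.42 ln TP + 4.15 (SD in m, chl
and TP in µg L⁻¹). The source study cites secondary literature without
printing equations, so the coefficients are configuration-exposed with these
defaults, and the orthophosphate sub-index — for which no canonical form
exists — defaults to the TP coefficients. The composite is the unweighted
mean of available sub-indices (weights configurable); this combination rule
is an assumption. Band edges are closed on the upper side (a composite of
exactly 74 is eutrophic) because the hypereutrophic band is stated strictly
(">74"). The published composites themselves are not recomputable (the Secchi
record is unpublished); they are classification inputs only.

## Community layer

Feature tables (taxa × samples, TSV or BIOM 1.0 JSON) are normalized to
per-sample proportions; counts vs proportions are auto-detected from column
sums. Taxonomy is the 7-level semicolon dialect with tolerant rank-prefix
stripping. Clade subsetting re-normalizes within the clade per sample and
drops (rather than zero-divides) samples lacking the clade. Shannon
diversity is reported in nats with Pielou evenness H/ln(richness), undefined
below two taxa. Bray–Curtis uses scipy's implementation and is cross-checked
against scikit-bio in the tests.

## Statistics

* **Normality gate**: Shapiro–Wilk at α = 0.05 decides parametric vs rank
  routes; fewer than 3 observations or zero variance defaults to rank.
* **Factorial comparisons**: parametric two-way ANOVA (type-II) with
  interaction, Tukey HSD per factor. The rank route rank-transforms responses
  across all observations and tests each effect's rank sum of squares against
  the total rank mean square with a χ² reference (the Scheirer–Ray–Hare
  family): a "two-way ANOVA on ranks" in the Kruskal–Wallis spirit is
  internally inconsistent as literally stated, so this documented variant is
  implemented instead. Type-I error of the parametric route is calibrated on
  200 null simulations in the acceptance suite.
* **Correlations**: Spearman ρ with significance stars at 0.05/0.01/0.001.
  Variables failing a normality screen are ln(x + ε) transformed with ε =
  half the smallest positive value (admitting zeros); Spearman is invariant
  to this monotone transform — asserted as a property — and the transform
  map is returned so parametric follow-ups know which variables were logged.
* **Permutation tests** (Mantel, PERMANOVA): the statistic is computed on the
  observed labeling, then on permuted labelings. Instances with ≤7 samples
  enumerate all n! permutations and report the exact p (fraction of
  permutations, identity included, with statistic ≥ observed, ties at 1e-12);
  larger instances Monte-Carlo sample with a seeded generator and report
  (b + 1)/(m + 1). PERMANOVA's pseudo-F uses among/within sums of squared
  distances; the statistic is verified against scikit-bio and the exact p
  against brute-force enumeration in the tests. These are implemented
  in-package because no installed library offers exhaustive enumeration.
* **SIMPER**: per-taxon Bray–Curtis contributions |x_k − y_k| / Σ(x_k + y_k)
  averaged over all between-group pairs; contributions sum to the mean
  between-group dissimilarity, percentages to 100. More than two groups are
  decomposed pairwise.
* **CCA**: canonical *correspondence* analysis (the community-matrix,
  species-scores ordination), chosen over canonical correlation since the
  inputs are abundances: chi-square-transformed community matrix regressed on
  weighted, centered constraints; the SVD of the fitted matrix gives the
  constrained axes. Collinear constraints are dropped by pivoted-QR rank
  detection with a warning. Axis proportions are non-increasing and sum to 1
  over constrained axes.
* Defaults: 999 permutations, α = 0.05, no multiple-testing correction — a
  documented limitation mirroring common field practice.

## Simulators

* **Incubation**: substrate enriched at t = 0 by concentration-weighted mass
  balance; with regeneration r the substrate atom% decays exponentially with
  rate r/S while the *concentration* is held constant (regeneration balances
  uptake) — a stated simplification that keeps the cell-labeling integral and
  the bias factor closed-form and mirrors short-incubation conditions. A
  depletion mode is out of scope. Measured post-incubation atom% adds
  Gaussian noise (default sd 0.005 atom%, an instrument-scale engineering
  choice, not a published value). Noise-free, regeneration-free outputs are
  recovered by the estimator to < 1e-9 relative error (property-tested on a
  100-scenario grid), and a conservation check equates the ¹⁵N gained by PON
  with V·T·(AP_Enr − NA)/100.
* **Community**: per-sample compositions from Dirichlet(concentration ×
  target), with colony-fraction targets dominated by *Microcystis* (0.75,
  mid-range of the observed 66–84% dominance) and a diverse free-living
  fraction; precision defaults to 100, giving realistic sample-to-sample
  scatter while means recover targets within ±0.05 at n = 50.
* **Environment**: Gaussian copula with Pearson ρ = 2 sin(πρ_s/6) so planted
  *Spearman* correlations are matched; lognormal marginals. Infeasible
  (non-PSD) correlation sets raise.

All scenario types carry mandatory seeds; every stream derives from one root
seed.

## What the synthetic data does and does not show

The generators emulate the *structure* of the field data — tracer mass
balance with dilution and noise, Microcystis-dominated colony communities,
monotone environment–rate associations — but not its full messiness:
replicate structure, detection limits, copy-number variation in 16S,
seasonal autocorrelation and colony-size physics are absent. Passing tests
therefore demonstrate that the estimators and statistics are correct and
calibrated under their stated models, not that field-specific published
p-values or variance fractions are reproduced; sequencing-derived published
quantities require the deposited reads and replicate-level rates and are
explicitly out of reach at desk scale.

## Problem sizes

Test and acceptance runs use deliberately modest sizes — 100 incubation
scenarios, 6-sample exhaustive-enumeration instances (720 permutations),
200-replicate null calibrations, 50-sample community tables, n = 200
copula draws — chosen as the smallest sizes at which each property is
sharply testable.

## Known limitations

* Gross-uptake inversion (isotope-dilution correction) is not implemented —
  the bias is only forward-quantified.
* BIOM 2.1 (HDF5) feature tables are not read; use TSV or BIOM 1.0 JSON.
* The glutamic-acid environment values flagged in the packaged table carry an
  asterisk whose footnote is illegible in the source; they are stored
  verbatim with a flag and never interpreted.
* The rank-route factorial test is approximate under heavy ties and severe
  cell imbalance.
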