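# Methods

## Scope and model of the data

`msapdiv` analyses dominant fingerprint markers: each locus is a band scored
present (1) or absent (0) per individual, with no access to allele
frequencies or heterozygosity. Two assays are supported. AFLP yields one
binary matrix per species. MSAP yields two aligned matrices per species —
the MseI/HpaII and MseI/MspI profiles — whose joint pattern at each
CCGG-anchored epilocus encodes a methylation state (see the truth table in
the README). All downstream statistics are band-based, which is the
standard way to avoid the unreliable allele-frequency estimators for
dominant markers.

The intended study design is paired and hierarchical: genera each
contribute one restricted-endemic and one widespread congener, with three
populations sampled per species. `msapdiv.study_design` carries the
concrete 7-genus / 14-species / 42-population sampling table with its
per-population sample sizes (1088 individuals in total), which the
synthetic generator mirrors.

## Epigenotyping (Mix1)

`classify_epilocus` is the total function over the four (HpaII, MspI) bit
pairs; `mix1_encode` maps states to (U, M) marker bits, so vectorially
U = HpaII AND MspI and M = HpaII XOR MspI. Choices made where the scoring
convention is underdetermined:

- The uninformative pair (0,0) scores **0 in both** U and M, not missing:
  every downstream index assumes complete binary matrices, and treating
  (0,0) as missing would make the diversity denominators
  individual-specific.
- `min_poly` (default 2) is the minimum count of the minority bit over all
  individuals of the species dataset for a polymorphic locus to be kept;
  monomorphic-locus deletion is a separate switch. Filtering runs
  independently in U and M (their retained locus sets differ) and per
  species dataset with its populations pooled, before any per-population
  index is computed.

## Replicate quality control

Technical replicates are full protocol repeats. The package models every
recorded profile (original or replicate) as the true profile plus
independent per-cell flips at the scoring error rate ε, so a replicate pair
disagrees at a locus with probability 2ε(1−ε). QC computes the per-locus
mismatch fraction across pairs, drops loci with mismatch above
`drop_threshold` (default 0.5 — a band wrong in the majority of pairs), and
reports the overall error rate as mismatches / (pairs × retained loci), the
convention used for AFLP repeatability figures. Dropping loci can only
remove mismatches, so the reported rate never increases. For an MSAP
bundle, both profiles are screened with the same pairs and an epilocus
dropped in either is dropped from both, keeping the bundle aligned.
Replicates are excluded from all diversity and model computations.

## Diversity indices

All four indices are computed inside one species dataset after filtering:

- **PPOL**: share of the species' retained loci with both states present in
  the population. The denominator is the species-level locus set, so the
  three populations of a species are directly comparable.
- **SI**: per-locus two-state entropy −(p ln p + (1−p) ln(1−p)) with
  0 ln 0 := 0, averaged over loci; bounded by ln 2 ≈ 0.693 nats.
- **PPRIV**: bands present in the focal population and absent from the
  species' other populations, divided by the bands present in the focal
  population. The denominator makes PPRIV a bounded, population-local
  proportion; dividing by all species-level bands would conflate private
  richness with total richness.
- **RI**: RI_x = Σᵢ s_ix / Dᵢ with Dᵢ the occurrence count of marker i over
  **all analysis individuals of the species dataset** (populations pooled);
  the population value is the mean over its members. The pooled denominator
  is the only self-consistent reading: with strictly within-population
  denominators the population mean collapses algebraically to
  (markers present)/k regardless of the data. The pooled version satisfies
  the conservation law Σₓ RI_x = number of markers present, which the test
  suite checks to 1e-10.

AFLP matrices get monomorphic-locus deletion at species level but no
`min_poly` threshold by default; the threshold is part of the MSAP
extraction convention, not of AFLP practice.

## The comparison stage

Responses are the 126 population × marker-type index values (42 populations
× 3 marker sets). Fixed effects: Markers (3 levels), Distribution
(2 levels), and their interaction. Random effects: intercepts for species
and for population nested in species — the pairing structure that makes
populations the repeated observational units. Families:

- PPOL, PPRIV → binomial with logit link; counts are
  round(index × n_loci) out of n_loci trials (rounding error ≤ 0.5/n_loci).
- SI, RI → Gaussian with case weights proportional to n_loci, normalized to
  mean 1 (the normalization leaves fixed effects invariant to the weights'
  scale).

**Fitting.** No installed Python library fits weighted nested linear mixed
models or maximum-likelihood binomial GLMMs, so `msapdiv.mixed_models`
implements both directly. The Gaussian likelihood is profiled analytically
over the fixed effects and the residual scale, leaving a bounded 2-D
quasi-Newton search over the two variance ratios (ML for tests, REML for
marginal means). The binomial likelihood uses the Laplace approximation
with fixed effects profiled into the penalized inner Newton solve — the
same approximation `lme4::glmer` uses at its default settings — and a
bounded 2-D search over the two random-effect standard deviations, which
handles boundary (σ → 0) fits cleanly. The test suite cross-checks both
engines against statsmodels `MixedLM` and against `lmer`/`glmer` via
Rscript on a fixed synthetic table; the weighted Gaussian fit matches lme4
to ~1e-4 and the Laplace binomial fit to ~1e-2 on coefficients.

**Testing protocol.** Likelihood-ratio tests compare nested ML fits: the
interaction by full vs no-interaction; each main effect by dropping it from
the no-interaction model. This marginal protocol is symmetric in the two
main effects. Reduced-model solutions seed the larger fits, which
guarantees χ² ≥ 0 up to optimizer tolerance; χ² is clipped at 0.

**Marginal means and contrasts.** Cell means per Markers × Distribution
combination come from the REML (Gaussian) or Laplace (binomial) fit, with
Wald intervals (t with n−p df for Gaussian, z for binomial) and logit
back-transformation for proportions. The post-hoc family is the three
pairwise marker contrasts inside one distribution class; the family-wise
(Tukey-style) adjusted p is P(max |T| ≥ t) under the joint
multivariate-t/normal distribution of the three contrast statistics,
evaluated by a fixed-seed Monte-Carlo draw (2×10⁵ samples) and floored at
the unadjusted p so adjustment monotonicity holds exactly.

**Correlations.** Per distribution class, index and epigenetic marker set,
Pearson r over the class's population values (n = 21 in the full design),
with the exact two-sided p from t = r√(n−2)/√(1−r²) on n−2 df. Pearson
rather than rank correlation is used because the published p values at
n = 21 are exactly reproduced by this transform. Zero-variance inputs are
flagged rather than silently dropped.

## The synthetic generator

The generator produces the statistical structure the comparison stage
assumes, not sequence-level realism:

- Base locus panels are drawn per **genus** and shared by the two
  congeners — congeners are assayed with the same primer combinations, and
  the paired design exists precisely so genus-level variation cancels from
  restricted-vs-widespread contrasts. Species perturb the panel (logit sd
  `species_sd` = 0.3 for AFLP; Dirichlet resampling with concentration
  `state_species_concentration` = 40 for MSAP state probabilities) and
  populations perturb the species level (`pop_sd` = 0.5;
  `state_pop_concentration` = 12). Dirichlet resampling keeps the expected
  state probabilities equal to the genus-level values at every depth, which
  makes `expected_state_fractions` closed-form under the null.
- AFLP presence probabilities come from Beta(0.2, 1.0) — most bands rare,
  a few common, matching the skewed frequency spectra of real AFLP panels;
  the Dirichlet base (0.35, 0.18, 0.32, 0.25) makes methylated conditions
  somewhat commoner than the unmethylated one, so M-MSAP ends up more
  polymorphic than U-MSAP as observed in real MSAP datasets. These defaults
  put the simulated indices in the empirically reported ranges (PPOL
  ~0.5–0.9, SI ~0.3–0.45, AFLP PPRIV ~0.1, RI ~1–4).
- `restricted_effect` δ multiplies restricted species' locus logits by e^δ
  and sharpens their state probabilities by the same power: δ > 0 pushes
  band frequencies toward fixation, lowering every diversity index in the
  restricted class; δ = 0 makes the classes exchangeable by construction.
- Scoring noise flips every recorded cell independently with probability
  `scoring_error` = 0.01, giving replicate mismatch rates around 2 %,
  the magnitude reported for real AFLP/MSAP repeatability studies;
  `replicate_fraction` = 0.12 of individuals per species are replicated.

What the generator does **not** emulate: linkage and spatial structure,
fragment-size homoplasy, shared restriction-site genealogy between U and M
markers beyond the latent state model, per-primer-panel batch effects, and
species-specific marker counts. Passing calibration and power checks on
synthetic data therefore demonstrates correctness of the pipeline's
arithmetic and the adequacy of its inference under the stated hierarchy,
not robustness to every artefact of real fingerprint data.

## Simulation studies (calibration and power)

`msapdiv.calibration` runs the generate → epigenotype → diversity → model
loop at desk scale: 7 genera, 3 populations × 12 individuals, 120 AFLP and
100 MSAP loci, no replicates — small enough for hundreds of replicates in a
few minutes on one CPU while keeping the full 42-population pairing. With
`restricted_effect = 0` the SI interaction LRT rejects at ~3–5 % (nominal
5 %); with the package's stated power effect size δ = 0.7 (an e^0.7 ≈ 2×
dispersion shift) the Distribution-or-interaction test detects the deficit
in essentially every replicate. Both rates are recomputed by
`scripts/acceptance.py` and asserted by the test suite.

## Numerical notes and limitations

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; pipeline outputs contain no timestamps, so identical config + seed
  reproduces byte-identical CSVs.
- Constant-response model fits short-circuit to a degenerate solution
  (all χ² = 0) rather than chasing an unbounded likelihood.
- LRT p values use the χ² reference; with 42 populations this is accurate
  for the fixed-effect tests but, as always, would be conservative for
  variance components (not tested here).
- The binomial family inherits the Laplace approximation's small-cluster
  bias (3 observations per population); this matches the behaviour of the
  standard tools rather than improving on it.
- PPRIV's binomial trials use the species-level locus count, although its
  natural denominator is the population's present-band count; the induced
  rounding/denominator mismatch is ≤ the model's other approximations and
  keeps one count convention across both proportion indices.
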