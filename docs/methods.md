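# Methods

This note documents the models, numerical choices and known limitations of
`hydroscreen`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Assay kinetics

The fluorometric assay model is linear product accumulation at V_max:
fluorescence `F(t) = a + b·t + ε`, with `b` proportional to the hydrolysis
rate. The estimator:

- **Standard curve.** OLS of mean fluorescence on MUF concentration, fit per
  slurry matrix (active vs heat-inactivated) so each well is calibrated
  against standards subject to the same quenching. The linear range is the
  widest low-concentration prefix with r² ≥ 0.99 (configurable); the study
  setting does not state its standard series, so the generator defaults to a
  decade-spanning 0–50 µmol L⁻¹ series.
- **Window rule.** The initial rate uses the longest window *starting at the
  first reading* with linear r² ≥ 0.98 and ≥ 4 points (whole series below 6
  points). A prefix-anchored window is correct here because product
  accumulation and substrate depletion can only slow the reaction: the
  earliest segment is the zero-order regime. The rule's accuracy is bounded
  by what the r² threshold admits: with a plateau midway through the run the
  default threshold tolerates a few plateau points and biases the slope low
  by several percent, while a stricter threshold (0.999) excludes the bend
  entirely. For end-of-run saturation — the expected situation when the
  assay is read within its linear window — the bias is well under 5 %. Both
  behaviours are exercised in the tests.
- **Units.** slope [AU min⁻¹] ÷ curve slope [AU per µmol L⁻¹] × 60 ×
  0.17617 mg µmol⁻¹ (MUF molar mass 176.17 g mol⁻¹) ÷ dilution
  → mg MUF L⁻¹ h⁻¹ of undiluted slurry. The intercept cancels, so rates are
  invariant to affine fluorescence offsets.
- **Corrections.** Blank subtraction is floored at zero (negative activities
  are physically meaningless) with a `high_blank` flag when the blank
  exceeds 20 % of the sample rate. The two substrate concentrations are
  averaged; a flag marks > 25 % relative discrepancy (evidence the assay was
  not substrate-saturated). Replicate wells are averaged on the fluorescence
  traces before fitting by default (per-well mode available); the source
  protocol does not state which order was used.
- **No temperature correction** is applied (assay temperature is metadata
  only), and no Michaelis–Menten fitting is attempted: the assay is defined
  at V_max.

## Community profiling

- Depth filter: samples with totals strictly below 10,000 reads are removed,
  *before* computing relative abundances (the alternative order is not
  documented in the source protocol; filtering first is the conventional
  choice).
- Chao1 is the bias-corrected form `S_obs + f₁(f₁−1)/(2(f₂+1))`, defined
  even when doubletons are absent. Shannon uses the natural log (the base is
  configurable in principle; nats are the package convention). Both are
  computed via scikit-bio behind this module's surface.
- Taxon aggregation sums counts over the lineage prefix at the requested
  rank; ASVs unresolved at that rank pool under their nearest classified
  parent (labelled `"<parent> (unclassified <rank>)"`), so sample totals are
  conserved exactly.

## Ordination

- **CA** decomposes the standardised chi-square residuals
  `(p_ij − r_i c_j)/√(r_i c_j)` by SVD; eigenvalues sum to χ²/N. Axis signs
  are canonicalised (first non-zero feature loading positive) so score files
  are reproducible.
- **RDA** with a single constraint is implemented directly: per-species OLS
  on the centred constraint, `R² = SS(fitted)/SS(total)`,
  `p = (1 + #{R²_perm ≥ R²_obs})/(1 + n_perm)` permuting constraint values
  across samples. With one constraint there is exactly one canonical axis;
  two residual PCA axes are attached for plotting. The Hellinger transform
  (√ of row-relative abundance) is applied by default — raw counts make a
  linear ordination depth- and dominance-driven — and can be switched off to
  reproduce the untransformed convention. R² is reported unadjusted.
  999 permutations by default, consistent with a minimum attainable p of
  0.001; the seed is mandatory whenever permutations run.

## Screening

- **Alignment** pairs each activity day with the nearest sequencing day
  within 3 days, injectively, greedy by gap with ties to the earlier day.
  When both duplicate reactors are present and no replicate is specified,
  the first sample id per day (sorted) stands in for the assayed replicate.
- **z-scoring** uses the sample (n−1) standard deviation. Constant and
  low-prevalence ASVs (< 4 non-zero samples) are excluded before testing:
  their z-scores are degenerate. Inside the screen, z-vectors are rounded to
  9 decimals so trajectories identical up to affine maps compare as exact
  ties (D = 0) despite floating-point rounding.
- **KS selection.** "Similar distribution" is operationalised as
  *non-rejection* of the two-sample KS test at α = 0.05 (configurable). D is
  the supremum ECDF distance evaluated at every pooled value (handles ties).
  The p-value is exact — enumeration over all C(m+n, m) label assignments —
  for m + n ≤ 16, and the asymptotic Kolmogorov tail with effective size
  mn/(m+n) otherwise. At ~10 weekly points the exact path always applies.
  Two caveats are inherent to the named test and documented rather than
  patched: it is order-blind (a time-mirrored trajectory has the same
  z-value distribution), and at n ≈ 10 it has little power, so the retained
  set is large and the regression step does most of the selection.
- **Ranking.** Retained ASVs are ranked by R² of the OLS regression of
  z-abundance on z-activity (descending); on z-scored pairs R² = r² and the
  slope is the Pearson correlation. Ties break toward higher mean relative
  abundance, then lexicographic ASV id, making candidate tables
  byte-reproducible. "Normalised by the enzymatic activity" is genuinely
  ambiguous; the z-on-z reading is the default, and an alternative
  ratio-trend reading (abundance/activity regressed on day) is available via
  `ScreenConfig(regression="ratio_trend")` but is not the default.

## Synthetic data: the stated world

The generator emulates the study design it is meant to test against:
weekly sampling days 13–81 (10 points; benchmarks that require 11 weekly
samples pass an explicit 13–83 grid), three reactors, sequencing depth
drawn from N(54,495, 21,312²) truncated at 1,000 reads, thousands of
background ASVs on a log-normal rank-abundance curve (σ = 2), Dirichlet
compositional noise (concentration 5,000 × mean), and responder taxa at
0.01–0.5 % mean relative abundance. Default activity shapes use a
cellulase profile rising from 4.0 to a day-62 peak of 70.4 mg MUF L⁻¹ h⁻¹
(17.6-fold) for the reference reactor, with reactor-specific variants.

Responder coupling acts on log-proportions, `p(day) ∝ exp(k·w(day))` with
k = 1, where `w = ρ·z_act + √(1−ρ²)·η` mixes the z-scored activity with an
orthogonalised unit-variance noise trajectory, so the *expected* trajectory
correlates with the activity at exactly the tracking level ρ. Because exp
is monotone but not affine, the z-scores of a perfectly tracking responder
match the activity's z-scores in rank, not value; the noiseless-limit test
asserts perfect rank agreement accordingly. Realized mean relative
abundances are guaranteed to land inside the stated band by drawing targets
from a 1.5×-inset interior and redrawing the sampling stage (deterministic;
the rng stream continues) if sampling noise pushes any responder outside —
low-depth days otherwise produce realized/target ratios as extreme as
~0.4.

What the generator does **not** emulate: phylogenetic correlation between
ASVs, true taxonomies (placeholder lineages only), overdispersion beyond
Dirichlet-multinomial, temporal autocorrelation of the background, reactor
crashes, or primer/chimera artefacts. A green recovery benchmark therefore
establishes that the screening procedure recovers planted monotone-coupled
responders at the stated noise and depth — not that it identifies true
hydrolytic taxa in real digesters, where association is not function.

## Numerical conventions

- All randomness flows from `numpy.random.default_rng` on integer seeds;
  pipeline stages derive their seeds by hashing `root_seed:stage_name`
  (keeping values below 2³¹).
- OLS r² on a constant response is defined as 1 (a flat blank trace is a
  perfect zero-slope fit).
- Eigenvalues below 1e−12 are dropped as rank deficiency, not errors.
- KS comparisons use a 1e−12 tolerance when counting permuted statistics
  ≥ the observed one.

## Known limitations

- The KS retention step is conservative at small n (attainable size below
  nominal α) and weakly selective; candidate quality rests on the
  regression ranking.
- The recovery benchmark's tracking grid conflates biological coupling and
  sampling noise; recovery at ρ = 0.9 does not translate to a detection
  probability for real taxa.
- `estimate_initial_rate` trusts the first reading; a lag *before* the
  linear regime (enzyme activation) would require a sliding window, which
  the prefix rule deliberately does not implement.
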