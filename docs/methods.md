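# Methods

## The analysis model

The package quantifies extra-territorial excursions (ETEs) by animals
living in a contiguous territory mosaic. Its assumptions:

- **Planar metric coordinates.** All inputs are projected planar metres;
  the readers refuse coordinate ranges that look like lon/lat degrees
  rather than silently mis-measuring distances. Reprojection is a
  pre-processing concern.
- **Territory = summer 95% MCP.** Because ranging is maximal in summer,
  the convex hull of the ⌈0.95 n⌉ summer fixes nearest the fix centroid
  approximates the territory. The percent-MCP peeling rule used here —
  Euclidean distance to the arithmetic-mean centroid, ties broken by
  earliest timestamp then (x, y) — is the common convention; other peeling
  variants exist and would shift boundaries slightly. Groups without
  June–August data fall back to the full calendar year (configurable).
  Because MCPs hug the fixes, they systematically under-cover the true
  territory (IoU ≈ 0.6 against the generator's mosaic in the default
  campaign); where accuracy at the boundary matters, supply digitised
  polygons (`source=provided`) — the detection stage is agnostic to how
  polygons were made.
- **One map per calendar year**; each fix is scored against its night-year's
  map. A single map may be passed when territories are known to be stable.
- **Night structure.** A badger-night runs from the night-start hour
  (default 18:00) through the night-end hour (default 06:00) of the next
  morning; the night's date is the evening's date, and its month is the
  month of that date. Fixes outside the window are dropped with a warning.
- **ETE rule.** Per badger-night the farthest fix beyond the home boundary
  is retained; the night is an ETE iff that distance is **strictly**
  greater than 15 m, the nominal GPS accuracy — so a fix *at* 15 m is not
  an excursion, and short hops to boundary latrines are excluded by
  construction. On a contiguous mosaic this "beyond home" definition
  coincides with "inside a neighbour's territory", which the tests verify.
- **fETE** = ETE nights / active nights per badger-month (range
  1/31 ≈ 0.032 for a single excursion in a 31-night month up to 1.0).
  Months with zero active nights yield no record: an uncollared month and
  an excursion-free month are indistinguishable. Animal-periods flagged as
  dispersal or super-ranging are excluded at month granularity (any
  overlap removes the record), because 'home' is undefined mid-dispersal.
- **Investment** = month fETE × the night's retained distance, one record
  per excursion night (metres). The month-level value used in cohort
  summaries is the mean of the badger's nightly records in that month;
  daily granularity is primary.
- **Seasons**: high activity April–September, low October–March.
  **Age cohorts**: Juvenile (0–1 yr), Young Adult (2–3), Older Adult (>3),
  with age = calendar year − birth year.

## Statistical machinery

- **Wilcoxon signed-rank** (paired, two-sided): W = sum of mid-ranks of
  positive differences, zeros dropped and counted. Exact p by a rank-sum
  counting recursion over all 2ⁿ sign assignments for n ≤ 15 without ties;
  otherwise the normal approximation with tie correction. The test suite
  checks the exact path against a literal 2ⁿ enumeration and against
  scipy.
- **Pearson correlation** with t = r√(df/(1−r²)), df = n − 2, two-sided.
- **GLMMs.** Monthly fETE is fitted as a zero-inflated binomial GLMM:
  counts `ete_count` of `active_nights` on a logit link, an intercept-only
  logistic structural-zero component, and random intercepts for year and
  for animal nested in social group (the guard against pseudoreplication).
  Log excursion distance and log investment use the same random structure
  with a Gaussian response. Estimation is delegated to **glmmTMB** in R
  through a batch subprocess bridge (`src/foray/r/fit_glmmtmb.R`), the
  standard engine for this model class; coefficients, Wald SEs, the
  conditional-model covariance, logLik and convergence diagnostics come
  back as JSON. Non-convergence — including a non-positive-definite
  Hessian from a variance component at the zero boundary, which yields NaN
  standard errors — is flagged on the result, never silent. A model whose
  data genuinely contain no structural zeros or no between-year variation
  *will* sit at such a boundary; that is a property of the data, not a
  bridge failure.
- **Month coding.** `month_coding="categorical"` (default) fits 11
  month contrasts; `"linear"` fits a single numeric slope, reproducing the
  single-df month term some analyses report. Both are exposed because the
  two printed table shapes imply different codings.
- **Model selection**: every fixed-effect subset of the saturated model
  that respects marginality (an interaction only with both main effects)
  is fitted in one R session and ranked by AICc = AIC + 2k(k+1)/(n−k−1),
  with k the fitted-parameter count from the model's logLik df and n the
  record count. Non-convergent subsets are ranked but excluded from
  "best".
- **Post-hoc contrasts**: all pairwise level differences of a main-effect
  factor from the treatment-coded coefficients and their covariance,
  Holm-adjusted. With interactions present these are contrasts at the
  reference levels of the other factors.
- Quartiles throughout are linear-interpolation (type 7); boxplot
  summaries report 1.5×IQR whiskers and the proportion of animals with at
  least one excursion.

## The synthetic-data generator

`foray.simulate` emulates the study design so that every stage has ground
truth (`SimTruth`: per active night, whether an excursion was scheduled,
the target group, and the true depth beyond the home boundary):

- **Mosaic**: setts sampled with a minimum-spacing rejection rule
  (default 0.45·√(area/n), 10 groups in a 5 × 5 km region ⇒ 2.5 km²
  territories, a plausible medium-density badger scale); territories are
  the Voronoi cells clipped to the region — contiguous by construction.
- **Fix schedule**: 4 fixes per active night at 22:00, 23:00, 01:00,
  02:00. Nightly activity probability 0.9, dropping to 0.75 in
  Feb/Nov and 0.5 in Dec–Jan (winter lethargy).
- **Within-territory movement**: a discrete-time mean-reverting walk
  anchored at the sett (φ = 0.6), stationary spread 0.5 × the territory's
  effective radius, contracted in winter (×0.4–0.6) so summer fixes
  delineate boundaries the way the MCP step assumes. Proposals are
  rejected until the fix lies ≥ 30 m *inside* the home boundary: with
  7.5 m GPS noise (≈ "up to 15 m" at 2 sd), a false-positive excursion
  then requires a > 45 m (6 σ) noise shift.
- **Excursions**: per-night Bernoulli with probability from a
  (sex, age-cohort, month) table — defaults: 0.13 base April–September,
  0.06 shoulder months, 0.03 December–January; ×1.3 for young adults and
  ×0.6 for juveniles; ×1.3 for males outside summer; ×2 for breeding
  females in November (the late-autumn mating window). On an excursion
  night exactly one scheduled fix is displaced along the boundary's
  outward normal to a depth drawn log-normal (σ_log = 0.5; median 85 m in
  April–September, 180 m in October–March), landing inside a neighbouring
  cell and ≥ 6 noise-sd inside the study region; depths that cannot fit in
  the neighbour are halved (bounded, logged). The single displaced fix
  mirrors the per-night max-retention rule, making truth and detection
  comparable night for night.
- **Heterogeneity and zero inflation** (defaults only): animal, group and
  year intercepts on the log-odds of excursion (sd 0.3 / 0.25 / 0.25) and
  a structural-zero mass — each badger-month is excursion-free outright
  with probability 0.15. These make the GLMM's variance components and
  zero-inflation genuinely present in default campaigns. **An explicitly
  supplied `excursion_prob` (scalar or table) is honoured exactly**, with
  no heterogeneity and no structural zeros, so controlled experiments
  (recovery of a known per-night probability, designed zero fractions)
  stay controlled.
- **Collar failure**: per-night hazard 0.002, permanent truncation.
- Determinism: one seed drives everything; identical config + seed gives
  byte-identical output files.

### What the generator does *not* emulate

Path tortuosity and autocorrelation structure beyond first order; social
interactions or avoidance; territory drift between years (the mosaic is
year-invariant); collar re-deployment after failure; fix-success bias by
habitat. Passing tests therefore demonstrate the pipeline's correctness
under the stated sampling design, not that real badger data meet those
assumptions — in particular real MCPs inherit digitisation error the
generator does not model.

## Numerical and design choices

- Strict inequality at the 15 m threshold; distance ties within a night
  broken by earliest fix; MCP retention ties broken by timestamp then
  (x, y) — all outputs deterministic.
- `distance_beyond_boundary` is shapely's exact point–polygon distance
  (0 inside or on the ring).
- Contiguity check: pairwise interior overlap and region under-coverage
  both below tol × region area (default 1e-6 for the simulated mosaic).
- Problem sizes: the default analysis campaign is 40 collared badgers in
  10 groups over 36 months (~65k fixes, ~16k badger-nights, ~680 monthly
  records), and the recovery experiments use 40 badgers × 6 months at
  full activity (~7200 nights per probability level) — scaled-down but
  structurally faithful counterparts of the 83-badger, 6-year field
  campaign, chosen so a full run completes in minutes on one CPU.
- Zero-inflated fits on data with *animal-level* all-zero subpopulations
  are ill-posed (the animal random intercept and the zi component compete
  for the same zeros); the generator therefore plants structural zeros at
  the badger-month level, which is also what the monthly-frequency data
  structure implies.

## Known limitations

- The glmmTMB bridge requires `Rscript` on the PATH; the pure-Python parts
  (geometry, detection, metrics, classical tests, simulator) run without R.
- Percent-MCP conventions differ across software; only the
  centroid-distance peeling rule is implemented.
- Exclusion periods are applied at month granularity for monthly records;
  night-level exclusion requires filtering fixes upstream.
- `pairwise_contrasts` operates on main-effect coefficients; it does not
  average over interaction partners (no marginal-means machinery).
- The Wilcoxon normal approximation is used whenever ties are present,
  even at small n (no exact tie-aware enumeration).
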