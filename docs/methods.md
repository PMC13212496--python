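# Methods

## The model

`cartkin` models a two-phase real-time impedance cytotoxicity assay of
CAR-T cell products against an adherent tumor line. Three cell
populations share a well: tumor cells `T`, CAR-expressing T cells
`CART`, and untransduced T cells `TC` (the effector product is a mix of
the last two, split by the transduction efficiency TE).

Tumor cells grow logistically and are killed by a ratio-dependent
Hill-type cytolysis term; CAR-T cells expand in response to the killing
they produce, limited by a Gompertz crowding factor; both T-cell
populations decay at a shared basal rate:

    dT/dt    = kp1 · T · (1 − T/CT) − FC
    dCART/dt = FP · ln(CE / (CART + TC)) − kd · CART
    dTC/dt   = −kd · TC

    FC = kc · r^n / (Kmr^n + r^n) · T,     r = CART / T
    FP = kp2 · FC² / (Kmp² + FC²) · CART

The ratio `r` plays the role a drug concentration plays in a standard
Hill dose-response: `Kmr` is the effector:tumor ratio at half-maximal
killing and `n` measures how cooperatively killing switches on with the
ratio. `FP` makes effector expansion a saturating function of the
cytolysis rate itself (half-constant `Kmp`, units cells/hour): products
with low `Kmp` expand at low levels of killing — a "responsive" product.
Untransduced T cells are assumed inert against the antigen-negative-free
target line and only decay.

A mass-action variant (`FC = kc·CART·T`, `FP = kp2·CART·T`) is retained
as `legacy_derivatives` for comparison; it cannot fit assays across
several seeding ratios with one parameter set, which is precisely why
the ratio-dependent form is used.

### Conventions and numerical choices

* **Gompertz orientation.** The crowding factor is `ln(CE/N)` with
  `N = CART + TC`: positive below the effector carrying capacity, zero
  at capacity. The opposite orientation is exposed behind a flag
  (`gompertz_inverted`) for sensitivity checks. The logarithm is
  evaluated at `max(N, 1 cell)` so an emptying well never produces an
  infinite rate.
* **`CT` carries units of cells** (it divides `T` inside the logistic
  term); a carrying capacity in inverse cells would not type-check
  against the growth equation.
* **Integration.** User-facing simulation uses LSODA with relative
  tolerance 1e-8 and absolute tolerance 1e-6 cells; states are clipped
  at zero inside the right-hand side. Effector addition is an
  instantaneous state jump at the addition time, and integration
  restarts there; the stored sample at the addition timepoint is the
  post-addition state, matching the instrument's first post-addition
  reading.
* **Fitting fast path.** The estimation objective evaluates the
  post-addition trajectory with a compiled fixed-step RK4 integrator
  (step = sampling interval / 4). With the bounded parameter space the
  largest rates are a few per hour, so the step error (~1e-7 relative at
  the reference parameters, verified against LSODA in the test suite) is
  orders of magnitude below the measurement noise. The reported SSR is
  computed with the same integrator as the objective, so optimizer and
  report agree to rounding.
* **Percent cytolysis** is defined against the simulated target-only
  control at the same timepoint, `100·(1 − T_cc(t)/T_ctrl(t))`, clipped
  to [0, 100] — untreated tumor wells keep growing, so the initial seed
  would be the wrong reference.

## Preprocessing and calibration

Raw traces are normalized per product with the pooled min/max onto
[0, 4] CI, the effector-addition time is resolved (declared time wins;
otherwise the largest positive single-step CI jump across co-culture
wells in a 20-28 h window), and the whole product is shifted by one
additive offset so the mean CI of target-bearing wells is 1 at time
zero. A single product-wide offset (rather than per-trace shifts) keeps
wells mutually comparable; effector-control wells contain no targets at
time zero and cannot be anchored individually.

The CI/cell calibration is linear with separate slopes for adherent
targets and suspended effectors plus a background term:

* **Background** is estimated from the effector-control wells'
  pre-addition readings (medium only). The pooled minimum is *not* used:
  with additive noise it is biased low by the most negative excursion,
  which propagated into a consistent underestimate of `kd` before this
  choice was made.
* **Target slope** = (mean target-control CI at t = 0 − background) /
  seeded target count.
* **Effector slope** comes from the CI jumps at effector addition in the
  co-culture wells, corrected for the target-control CI increment over
  the same sampling step (the tumor keeps growing during the addition
  interval), and combined by a through-origin regression of jump on
  bolus size. The regression (rather than an unweighted per-ratio mean)
  is the minimum-variance estimate under homoscedastic reading noise;
  the 1:1 well's jump is mostly noise and an equal-weight mean lets it
  dominate.
* For datasets whose addition reading was missed and imputed (the
  CD4:CD8 enrichment scenario), the imputed value carries the
  effector-*control* bolus, so the effector slope must instead be
  derived from the effector-control wells' own jump
  (`fit_calibration(effector_slope_from="effector_control")`,
  `FitConfig(calibrate_effector_from_control=True)`).

Dead cells contribute no CI.

## Staged estimation

1. **Stage 1 — tumor growth.** `kp1`, `CT` from target-control wells by
   bounded least squares of the logistic closed form (seeded at the
   known target count) in CI units, multi-started from 12 uniform draws.
2. **Stage 2 — basal decay.** `kd` from effector-control wells:
   `baseline + A_i·exp(−kd·(t − t_add))` with a shared rate and one free
   amplitude per well. Freeing the amplitudes keeps this stage
   independent of the co-culture-derived calibration (a perturbation of
   co-culture data cannot move `kd`).
3. **Stage 3 — effector parameters.** `kc, Kmr, n, kp2, Kmp, CE` from
   all co-culture wells jointly: unweighted SSR between model CI and
   observed CI over post-addition timepoints, every replicate entering
   individually. Initial guesses are uniform in the (linear) bounds;
   each start is refined by trust-region-reflective least squares on
   log10 parameters (the bounds span decades) with tolerances 1e-10
   (objective) and 1e-8 (parameters). The draw stream is nested in the
   number of starts, so enlarging a run can only improve the selected
   optimum. Exact SSR ties break toward the smaller bounds-normalized
   parameter norm, then the lower start index.

Default bounds (config-overridable): kp1 ∈ [1e-3, 0.2]/h,
CT ∈ [1e5, 1e7] cells, kc ∈ [1e-3, 1]/h, Kmr ∈ [1e-2, 1e2], n ∈ [0.1, 5],
kp2 ∈ [1e-3, 1]/h, Kmp ∈ [1, 1e5] cells/h, CE ∈ [1e4, 1e7] cells,
kd ∈ [1e-5, 0.1]/h. They span the magnitudes implied by the assay scale
(10^4–10^6 cells/well) and plausible cooperativity exponents.

The default number of starts is 1000; the validation studies in this
repository use 100 starts per product, which the recovery benchmark
shows is ample for this problem size. The stage-2 amplitude model needs
the effector-control seeding count, which defaults to 2.5e5 cells (the
mid-ratio bolus).

Reported fit quality: R² per condition/ratio (SST about the scope's
observed mean), pooled R² over all conditions, and the total SSR across
target-control, effector-control and co-culture residuals. Because
stages 1–2 are fit independently, control residuals are constants of the
stage-3 optimization; a config flag merely books them into the recorded
stage-3 objective value.

## Sensitivity and identifiability

* **Error sensitivity**: one-at-a-time relative perturbations (±10, ±25,
  ±50% by default) of each effector parameter, recording ΔSSR on the
  co-culture objective. On noise-free data at the generating truth every
  ΔSSR is non-negative (local-optimality certificate, asserted in
  tests).
* **Parameter correlations**: default method is the Gauss-Newton
  (Fisher-information) approximation at the optimum — finite-difference
  Jacobian of the residuals with respect to log-parameters, covariance
  = inverse information, normalized to correlations — with |r| > 0.80
  flagged high and |r| > 0.93 flagged practically non-identifiable
  (conventional thresholds). Exactly confounded parameters are reported
  as |r| = 1 via the pseudoinverse route. An empirical alternative
  correlates near-optimal multi-start refits.
* **Global sensitivity**: one-at-a-time geometric sweeps of each
  effector parameter across its bounds crossed with an E:T grid
  (default 1:4 … 25:1), response = percent cytolysis 48 h after
  effector addition. Variance-based decompositions are out of scope.
* **E:T sweep summaries**: the "saturation ratio" is the smallest ratio
  within 5 percentage points (config) of the top ratio's cytolysis; the
  "negligible" summary is the largest ratio below 10% cytolysis
  (config). At the reference parameters killing is negligible at or
  below 1:2 and saturates between 6.25:1 and 12.5:1.

## Cohort statistics

Products are grouped by day-28 response, day-90 response, relapse
through day 180 (among initial responders — responder at day 28 or
day 90 by default; day-28-only and day-90-only base populations are
selectable), CRS, and neurotoxicity, optionally within one disease
subset. For each grouping the six effector parameters are compared with
a two-sided Wilcoxon rank-sum test at α = 0.05: exact null when the
combined sample is ≤ 12 and tie-free, otherwise the normal approximation
with tie and continuity corrections. `kp1`/`CT` (tumor control) and `kd`
(negligible magnitude) are excluded. No multiplicity correction is
applied by default; Benjamini–Hochberg is available behind a flag.

Effect sizes are rank-biserial correlation magnitudes
(|1 − 2U/(n₁n₂)|) with bootstrap percentile confidence intervals
(2000 resamples, seeded). Composition relationships (e.g. parameter `n`
versus CD4:CD8 ratio) use Spearman rank correlation.

## The synthetic cohort generator

No public per-product assay data exist for this problem, so the
generator is the test bed; its defaults are the study conditions.

* **Cohort size** 45 products; transduction efficiency from a truncated
  normal, mean 24.87%, SD 8.75%, truncated to [9.8%, 48.8%] — the
  clinically observed spread.
* **Kinetic priors**: truncated normals centered on the reference set
  (kp1 = 0.04/h, CT = 1e6, kc = 0.25/h, Kmr = 2, n = 1, kp2 = 0.08/h,
  Kmp = 2e4 cells/h, CE = 2e6, kd = 0.008/h) with CVs of 15–35%,
  truncated to the estimation bounds. The reference set was chosen once
  to reproduce the qualitative assay phenotype: negligible cytolysis at
  or below 1:2, strong and saturating cytolysis at high ratios, and the
  ratio pivot (`Kmr`) above the initial 1:1 CAR-T:tumor ratio so that
  raising `n` deepens killing at 25:1 while suppressing it at low
  ratios.
* **Traces**: forward simulation per condition (triplicate target
  controls, triplicate effector controls with a 2.5e5-cell bolus,
  triplicate co-cultures at 1:1, 6.25:1 and 25:1; 289 readings per well
  at 15-min sampling over 72 h), pushed through a product-specific
  linear calibration with ±20% slope jitter. The effector per-cell CI
  contribution is 10% of the target's: suspension cells impede the
  electrode far less than adherent cells, and this ratio is what makes
  the model (correctly) insensitive to `kd`. Noise is multiplicative
  (CV 2%) then additive (SD 0.01 CI), independent per reading and per
  replicate. The CI noise level is an assumption chosen to match the
  tightness of replicate bands in published trace figures; it is
  config-exposed.
* **Outcomes**: relapse probability = logistic(β₀ + β_Kmp·z(Kmp) −
  β_n·z(n)) with β₀ = −0.3, β_Kmp = 2, β_n = 1, where z uses the exact
  truncated-prior moments; day-28 (82%) and day-90 (73%) responses, CRS
  (50%) and neurotoxicity (30%) are independent draws; relapse is
  defined only for initial responders. The link encodes the clinical
  directions (relapse associated with higher Kmp and lower n); the
  magnitudes are free configuration because patient-level values are
  not public.
* **Determinism**: every draw derives from `SeedSequence([seed, index,
  stream])`, so any product regenerates in isolation and serialized
  cohorts are byte-identical across runs.
* **CD4:CD8 scenario**: one base product cloned at ratios 1:1, 4:1,
  10:1 and CD4-only, with `n` decreasing through a bounded link
  `n = n_base − slope·(ratio/(1+ratio) − ½)`; emitted with the addition
  reading blanked to exercise the imputation path.

### What the generator does not emulate

Instrument drift and well-edge effects; sigmoidal (rather than linear)
CI-vs-cell-count response at high density; donor-level correlation
between kinetic parameters; competing-risk structure in outcomes;
antigen escape (not observed for this construct and excluded from the
model). Passing tests therefore demonstrate correctness of the
algorithms under the stated assay model, not robustness to every
real-world artifact.

## Validation studies and problem sizes

The packaged studies (also run by `scripts/acceptance.py`) use sizes
chosen to give stable estimates at desk scale:

* **Recovery**: 20 products, 2% noise, 100 starts — median relative
  errors ~1–4% for kp1, CT, kd, kc, Kmr, n; all products with pooled
  R² > 0.80 (cohort benchmark ≥ 90%).
* **Type-I error**: 1000 null cohorts (outcome link zeroed, n = 45),
  day-28 comparisons of six parameters on ground-truth tables —
  rejection rate ≈ 0.05.
* **Power**: 200 cohorts of 28 responders at the default link strength —
  power ≈ 0.9 for the Kmp-relapse comparison, direction recovered in
  every cohort.

The statistical calibration studies deliberately use ground-truth
parameter tables: they validate the inference machinery downstream of
fitting, and the recovery study separately establishes that fitting
reproduces the truth to a few percent.

## Known limitations

* `kp2`, `Kmp` and `CE` are weakly identified from CI data when the
  effector CI contribution is small (as it is in this assay type);
  their estimates can be off by large factors even when the fit is
  visually and statistically excellent. The error-sensitivity and
  correlation tools quantify this per dataset.
* The exact Wilcoxon path refuses ties; tied data fall back to the
  corrected normal approximation even for small samples.
* The linear CI calibration ignores saturation of the impedance signal
  at confluence; fits of wells far above the seeding density inherit
  that approximation.
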