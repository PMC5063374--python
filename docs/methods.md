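# Methods

This note documents the models, estimators, and design choices behind
`scfc`, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic study does and
does not emulate.

## The question and the analysis frame

Whole-brain functional connectivity (FC) is a statistical summary of
region-level activity; structural connectivity (SC) is the anatomical
wiring it runs on. The pipeline asks how many *reproducible linear
dimensions* a cohort of connectivity patterns spans. Every analysis shares
one engine: arrange patterns as a feature × observation matrix `X`
(features are links, triplets, or flattened BOLD samples; observations are
subjects or subject–condition pairs), decompose `X = U S V^T`, and read
variance fractions `s_i^2 / sum_j s_j^2` off the singular values.

**Uncentered SVD.** The decomposition is applied to `X` directly, with no
row or column centering. This is deliberate and changes every number: the
structure of interest is a common positive core whose subject-to-subject
variation is approximately a global multiplicative constant, and centering
would subtract precisely that core. Variance fractions are therefore
shares of the raw sum of squares.

**Bootstrap over subjects.** Reproducibility is assessed by resampling
subjects with replacement (B = 1000 by default; the desk-scale experiment
default is B = 200), recomputing the SVD per replicate, and forming
percentile confidence intervals on each `s_i` (95% by default; the CI
construction is configurable). All columns belonging to a subject move
together, so pooled matrices resample subjects, not columns. Replicates
that collapse onto a single subject are redrawn and counted.

**Reproducible dimension.** `d` is the number of leading singular values
whose CI does not overlap the next one. Two readings of "the last such
singular value" exist: requiring the separation contiguously from `i = 1`
(default) or taking the last separated pair regardless of earlier
overlaps. Both are implemented (`rule="contiguous" | "last"`); the
contiguous rule is the default because a dimension whose CI is entangled
with its predecessor has no stable identity as "dimension i".

**Sign convention.** SVD components are sign-ambiguous. Each component is
oriented so that the average projection of the data onto it is
nonnegative (equivalently, by the sign of `mean(v_i)`, falling back to the
mean entry of `u_i` in the degenerate case). Orienting by the mean entry
of `u_i` alone fails after global-signal regression, which makes the FC
core's feature-space mean slightly negative and would anti-align `u_1`
with the data. Reported patterns are average projections
`(mean_j u_i^T x_j) u_i`, which are invariant to the sign choice.

**Bootstrap summaries.** Per-dimension means and standard deviations are
reported both for variance fractions and for raw singular values; replicate
left-singular vectors are not retained (the CIs need only the singular
values, ranked within each replicate).

## Synthetic cohort

No empirical dataset ships with the package; the generator produces
cohorts with the statistical structure the analyses assume.

- **Atlas**: `n` regions (even), left hemisphere at indices `0..n/2-1`,
  right at `n/2..n-1`, region `i` homotopically paired with `i + n/2`.
- **Ground-truth SC**: within-hemisphere edges with probability 0.35,
  interhemispheric with probability 0.02; nonzero weights lognormal with
  median 0.01 and log-sd 0.8 (connectome indices span orders of
  magnitude); homotopic pairs set to a fixed weight (default 0.02); the
  two intra-hemispheric subgraphs are resampled until connected.
- **Subjects**: `SC_s = g_s · core + E_s` with `g_s = exp(N(0, 0.2^2))`,
  symmetric entry noise of sd 5e-4, clipping at 0, then thresholding at
  0.001 (measure first, threshold second — matching how tractography
  indices are processed). This plants the rank-1-plus-residual structure
  the subspace analysis is designed to detect.
- **Degradation**: each interhemispheric link is deleted with probability
  0.8 (per unordered pair, preserving symmetry), emulating the systematic
  false negatives of diffusion tractography for interhemispheric and
  especially homotopic fibers. The *degraded* SC is what the generative
  models receive; the *intact* SC drives the "empirical" reference signal.
  This planted asymmetry is what gives the residual-FC and
  average-subject analyses something real to find.
- **Planted low-rank datasets**: `X = sum_i s_i u_i v_i^T + noise` with
  singular values sized so each component captures its requested share of
  the expected total sum of squares (noise energy included). Left vectors
  are random orthonormal; *right* vectors (subject loadings) are
  near-uniform in magnitude — component 1 loads every subject equally,
  later components are orthogonalized sign patterns. Even loadings are
  the planted analog of "every subject carries the core": they are what
  makes subject-bootstrap CIs tight. With fully random loadings the
  bootstrap correctly reports wide CIs and a smaller reproducible
  dimension — that is a property of such cohorts, not an estimator
  failure.
- All randomness flows from one integer seed through per-operation
  substreams (`numpy.random.SeedSequence` spawn keys), so adding a stage
  never perturbs another stage's draws.

## Generative models

The connectome enters every model as `G · W`, with `W` the row-normalized
SC and `G` a single global coupling constant. Row normalization is a
choice (it keeps the stability condition G-controlled regardless of SC
scale). Model equations follow standard textbook formulations; all
constants live in `ModelConfig` defaults and are overridable.

- **SAR** (spatial autoregressive): `x = G W x + e` gives the closed-form
  covariance `sigma^2 (I - G W)^{-1} (I - G W)^{-T}`; FC is its
  correlation matrix. Requires spectral radius of `G W` below 1. The SAR
  is a model of the BOLD pattern itself: no hemodynamics and no
  global-signal regression are applied to it.
- **Rate**: `tau dx = (-x + G W x) dt + sigma dW`, tau = 1 s.
- **Wilson–Cowan**: one excitatory/inhibitory pair per region with
  logistic gain (classic constants c1=16, c2=12, c3=15, c4=3, a_e=1.3,
  th_e=4, a_i=2, th_i=3.7; tau = 10 ms), coupled through the excitatory
  populations. The drive is set below the oscillation threshold
  (P = 0.8), putting each node in a noise-driven fluctuation regime: in
  the classic oscillatory regime the local limit cycle dominates the
  covariance and decouples FC from SC, which defeats the purpose of an
  SC-conditioned generative model.
- **Kuramoto**: phase oscillators, natural frequencies `2 pi N(0.05 Hz,
  0.01 Hz)`, observable `sin(theta)`. Operated in the weak-coupling
  regime (default G = 0.2): at strong coupling the network locks into
  synchronized clusters whose block structure swamps the graded SC
  signature.
- **FitzHugh–Nagumo**: fast–slow excitable pair (a=0.7, b=0.8,
  tau_w=12.5, I=0.4), noise-driven, observable the fast variable.

Integration is Euler–Maruyama at dt = 1 ms, burn-in 10 s discarded,
observable recorded every 10 ms; the compiled kernels report the exact
time of any divergence. Identical (seed, config) pairs produce identical
trajectories.

**Hemodynamics.** Neuronal activity drives the Balloon–Windkessel system
per region (vasodilatory signal, inflow, venous volume,
deoxyhemoglobin; kappa=0.65 s^-1, gamma=0.41 s^-1, tau=0.98 s, alpha=0.32,
E0=0.34, V0=0.02), integrated at the neural sampling step and read out as
percent signal change at tr = 3.29 s. The first 20 s of BOLD are dropped
to clear the hemodynamic onset transient. Default runs are 200 samples
(~11 min), matching the windowed-FC arithmetic (windows of
{8, 10, 20, 25, 40, 50, 100} samples give {25, 20, 10, 8, 5, 4, 2}
windows; 8 samples = 26.32 s).

**Coupling tuning.** `tune_global_coupling` evaluates a grid with a fixed
seed, maximizes the Pearson correlation between simulated and target FC
vectors, breaks ties toward the smaller coupling, and skips (but logs)
unstable SAR grid points. The experiment defaults (SAR 0.4, rate 0.7,
Kuramoto 0.2, Wilson–Cowan 3.0, FitzHugh–Nagumo 0.1) were fixed once for
the desk-scale cohort by this criterion and are recorded in
`DEFAULT_COUPLINGS`.

## FC measures

- **cFC**: Pearson correlation per region pair, sample normalization. A
  constant region is an error by default (an explicit `on_constant="zero"`
  opt-out exists) rather than silent NaN propagation.
- **GSR**: per region, the residual of a least-squares regression on
  (intercept, across-region mean). Idempotent; residuals exactly
  orthogonal to the global mean; a constant global signal degrades to
  intercept-only removal with a warning.
- **mFC / CT3**: Kraskov k-nearest-neighbor estimates (algorithm 1 and
  its multi-variable generalization), k = 4 by default, natural log,
  brute-force max-norm neighbor search in a compiled kernel (sample
  counts are small enough that the quadratic scan beats tree
  construction). Ties resolve deterministically; no jitter. Small
  negative estimates are a known artifact of the estimator and are
  retained, not clipped (documented tolerance 0.1). The full
  160-region CT3 sweep (669 920 triplets) is gated behind
  `allow_large=True`; the desk scale is 40 regions (9 880 triplets).
- **Gaussian closed forms**: `-1/2 ln(1 - rho^2)` per pair and
  `-1/2 ln det R` per triplet (computed via the expanded determinant
  `1 + 2 r_ij r_jk r_ik - (r_ij^2 + r_jk^2 + r_ik^2)`). On Gaussian data
  these are the exact values the kNN estimators must approach, which the
  tests exploit as oracles.
- **Dynamic FC**: Pearson FC per non-overlapping window, concatenated in
  temporal order. Window sizes must divide the run length (all default
  sizes divide 200); an explicit truncate-tail option exists for other
  data. No per-window demeaning beyond Pearson's internal centering.
- **Vectorization**: lexicographic `(i, j), i < j` (pairs) and
  `(i, j, k), i < j < k` (triplets); at 160 regions this gives 12 720
  pair and 669 920 triplet coefficients, 6 320 of the pairs
  intrahemispheric.

## Inversion of the SC–FC relationship

The proof-of-concept estimator assumes (i) a single monotone relationship
between the SC core and the FC core, insensitive to the dynamical regime,
and (ii) that deviations from it at the first-dimension level reflect SC
measurement error. Steps:

1. First-dimension average-projection patterns from bootstrap SVD of the
   SC cohort and of the pooled (empirical + simulated) FC.
2. `SC' = ln(SC / 0.0001)` on entries ≥ 1e-6; sub-floor entries are
   dropped from the fit (dropped pairs, not zero-filled).
3. Least-squares polynomial fit `FC ≈ P4(SC')`, order 4. ("Interpolation"
   through thousands of points is ill-posed; regression is the usable
   reading.)
4. Numerical inversion of `P4` on its dominant monotone branch — the
   derivative's real roots split the fit domain, and the piece covering
   the most of the central 90% of fitted SC' mass is used; if no piece
   covers at least half of it, a multi-branch error lists the turning
   points. Inversion is vectorized bisection to well below 1e-10; FC
   values outside the branch's range are clamped to the boundary and
   flagged.
5. `SC_hat = 0.001 exp(P4^{-1}(FC))` applied to the empirical FC
   first-dimension pattern. Entries masked from the forward fit still
   receive estimates — recovering links the input SC missed is the point
   — and are flagged as extrapolated.

The two reference constants differ by a factor of 10 between the forward
transform (0.0001) and the inversion (0.001). Both defaults are kept
exactly as printed in the source method and are independently
configurable; the mismatch is surfaced, never silently reconciled, so
default-parameter estimates carry a ×10 scale relative to the input SC.
Round-trip accuracy is measured with `ref_out = ref`.

## The desk-scale study

The default experiment configuration is 40 regions, 5 subjects, 200 BOLD
samples at tr = 3.29 s, three simulated models (SAR, Kuramoto, rate) and a
held-out Wilson–Cowan "empirical" generator, B = 200 bootstrap replicates.
These sizes keep the full 13-experiment battery within a few minutes on
one CPU; 160 regions, 21 subjects and B = 1000 are supported through the
same configuration object. The "empirical" signal is generated from each
subject's intact SC while the simulated models see the degraded SC, so
empirical-minus-simulated residuals and the pooled second dimension carry
the planted homotopic/interhemispheric error structure.

## What the synthetic study does and does not show

The generator reproduces the *statistical skeleton* the analyses assume: a
rank-1-plus-residual SC cohort, SC-conditioned dynamics with distinct
regimes, hemodynamic filtering, systematically missing interhemispheric
links. It does not emulate spatial autocorrelation of parcels, distance-
dependent connection weights, subject-specific hemodynamics, scanner
noise spectra, motion artifacts, or non-stationary (task-like) dynamics.
Passing tests therefore certify the machinery — estimators against their
oracles, the bootstrap rule against planted truth, the inversion against
its own forward model — not claims about any empirical dataset.

Known limitations:

- At small atlases (~16 regions) the homotopy-preserving permutation
  control retains partial structure simply because only n/2 labels are
  shuffled; the control behaves as intended from ~40 regions up.
- The reproducible-dimension rule needs a handful of subjects to be
  meaningful; with 3 subjects the bootstrap resample space is degenerate
  and the rule over-detects.
- Bootstrap CIs require every subject to contribute the same number of
  columns (true for all built-in experiment designs).
- kNN information estimates at 200 samples carry bias of order 0.05–0.1
  nat; the Gaussian-oracle tests quantify this at their sample sizes.
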