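# Methods

## The model

Participants of a multi-arm behaviour-change trial are classified at
each observation wave into four stages of readiness: unmotivated (1),
indecisive (2), motivated (3) and former smoker (4). Staging is
deterministic from two questionnaire items: a "no" on the 7-day smoking
item yields stage 4 regardless of the motivation score; otherwise the
0–10 motivation score is binned 0–3 / 4–7 / 8–10 into stages 1–3. The
bins are configurable but these defaults are the instrument's standard
reading.

### Step one: panel CTMC

The latent stage process per subject is modelled as a first-order,
time-homogeneous continuous-time Markov chain with generator

    Q = [q_lk],  q_lk >= 0 (l != k),  q_ll = -sum_{k != l} q_lk,

with stage 4 absorbing (zero row). The two modelling assumptions are
the Markov property (the future depends on the present stage only) and
stationarity (intensities do not drift over the study window). Neither
is testable from three waves; the simulator generates data satisfying
both, and the parameter-recovery tests are the operational check that
the estimator is correct *under* them.

Panel observations enter the likelihood only through interval
transitions: for equal design intervals Δ,

    log L(Q) = sum_{l,k} n_lk log P(Δ)_lk,   P(Δ) = expm(Δ Q),

with n_lk the 4×4 interval transition-count matrix (the sufficient
statistic). Irregular spacings are handled by the product form — one
count matrix per distinct interval length. Wave labels are nominal:
follow-ups at calendar weeks 12 and 26 in a design with two equal
13-week intervals are treated as one design interval each (a spacing
within 12% of an integer multiple of the mean grid step snaps to that
multiple; anything else is kept exact).

Estimation is by maximum likelihood over log-intensities, which makes
positivity free and matches the scale on which the asymptotic normal
approximation is applied. Gradients are analytic via the Fréchet
derivative of the matrix exponential (`scipy.linalg.expm_frechet`);
optimisation is multi-start L-BFGS-B (default 5 starts: a
method-of-moments initial from the matrix logarithm of the empirical
transition matrix, plus seeded N(0, 0.5) perturbations of it), bounded
to [1e-8, 1e4] per week. The floor absorbs arrows with no observed
evidence; the cap keeps the surface bounded while exceeding the
largest rate scale seen in fitted systems (order 10^3). The covariance
of the log-intensities is the inverse observed information (central
finite differences of the analytic gradient, step 1e-5).

Derived quantities: sojourn times −1/q_ll (mean length of one visit to
a transient stage); prevalence curves 100·π₀P(t) from an initial stage
distribution; absorption probabilities P(t)_l4. Confidence intervals
for rates and sojourns are percentile intervals from (by default) 1000
draws of the asymptotic multivariate normal on log-intensities — the
simulated-MVN scheme rather than the delta method, because it respects
positivity and the sojourn transform exactly. A non-PSD covariance is
repaired by eigenvalue clipping with a warning.

### Efficacy and effectiveness

Given per-arm prevalence curves on a common grid (model-based weekly
curves by default; the three observed waves also work):

    sigma_g(t) = F_g(t) / F_max
    rho_g(t)   = (dF_g(t) - alpha (dU_g(t) - dM_g(t))) / N_max

where d· is the change since the baseline week (week 0: every arm
starts with F = 0, so dF = F and the two metrics are directly
comparable), alpha = 0.20 by default, F_max is the scalar maximum of F
over arms and grid, and N_max normalises the numerator. N_max is
global (one scalar over arms and grid) by default so curves are
comparable over time; a per-time mode (N_max recomputed each week) is
available since the definition "maximum among the interventions" does
not fix the time treatment. In per-time mode the baseline week, where
every numerator is identically zero, is reported as rho = 0 rather
than an error; a week where every arm is strictly worse than baseline
is a genuinely degenerate configuration and raises.

### Step two: compartmental ODE

The deterministic flow on stage prevalences (percent, conserved total
100) is x′ = Ax on x = (U, I, M) with

    A = [ -(d12+d13+d14)   d21              d31
          d12              -(d21+d23+d24)   d32
          d13              d23              -(d31+d32+d34) ],

F(t) = 100 − (U+I+M). A is a compartmental matrix: eigenvalues have
nonpositive real parts, trace(A) = −Σ d_ij exactly (a tested
identity). If all eigenvalues are negative the trivial equilibrium
(0, 0, 0, 100) is globally stable; a zero eigenvalue makes the system
under-determined — the equilibria form the null space of A intersected
with the nonnegative simplex, full absorption is lost, and the
limiting state from a given start is the spectral projection of the
initial condition onto the zero-eigenvalue subspace.

The nine rates are estimated by bounded least squares (trust-region
reflective, lower bounds zero) against target prevalence curves — in
the two-step workflow, the chain's weekly curves on [0, 26] (27 points
× 4 compartments). The forward model inside the residual is the exact
matrix-exponential solution, so fitting accuracy is limited only by
the optimiser. The 9-parameter problem is multi-modal; 20 seeded
multistarts (one neutral start at 0.05, the rest log-uniform on
[1e-3, 10]) are used by default and the best SSE kept. An exactly
constant target is reproduced by the zero-rate flow and returned
directly. Large SSE (> 50 by default) is recorded as a warning, not an
error — a nearly-singular flow can be structurally unable to chase the
chain's curves, and such poor fits are informative.

Numerical integration for trajectories uses BDF with the analytic
Jacobian at rtol = atol = 1e-9, which handles the stiffest fitted
systems (eigenvalue magnitudes spanning ~10^4); every trajectory is
validated against the closed-form expm path to 1e-6 in tests. Average
prevalence over [0, T] is a composite trapezoid on the simulation grid
(with interpolation at T). Time to absorption is the first time
max(U, I, M) stays below epsilon (default 0.5 percentage points),
located by horizon doubling, a 4097-point grid scan for the last
exceedance, and bisection; an "equilibrium" mode measures distance to
the asymptotic state instead. The published year-scale convergence
figures for this quantity depend on an unstated criterion, so they are
reported under this package's epsilon convention and not asserted
against the reference values.

## Synthetic data

`synthdata` draws latent paths per subject by event-driven simulation
(exponential holding times, embedded jump chain), observes them at the
wave grid (default 0/13/26: two equal 13-week follow-up intervals, the
design the likelihood assumes), and emits questionnaire-level records
whose staging reproduces the latent stage. Missingness is injected by
deleting follow-up waves uniformly at random at a configurable rate;
relapse injection (off by default, since the model's absorbing
assumption forbids it) flips a post-absorption wave back to a smoking
stage purely to exercise the censoring step. Identical spec + seed
gives byte-identical output.

What the generator does *not* emulate: covariate heterogeneity between
subjects, time-varying intensities, misclassification of the
questionnaire items, and informative missingness. Passing recovery
tests therefore show correctness of the estimator under the model's
own assumptions, not robustness of the model on real trial data.

Two kinds of reference fixtures are packaged. The printed per-arm
stage-count margins and nine-rate ODE sets are transcribed verbatim
(the rate directions follow the arms' described flow structure and are
confirmed by the eigenvalue analysis reproducing the published spectra
to <0.1%; one arm's margin table is internally inconsistent by one
subject at two waves and is preserved as printed). The per-arm
*intensity* matrices were published only as supplementary material, so
`study_like_intensities()` provides synthetic stand-ins: weekly rates
chosen once so the arms show the qualitatively described dynamics —
HE with the strongest quit flow plus a demotivation cascade
3 → 2 → 1, BA with a slow 1 ↔ 2 exchange and a small quit flow, MI
with fast mixing (short sojourns) — and margins near the observed
tables. The efficacy/effectiveness dissociation test runs on these
stand-ins; it asserts orderings, not values.

The recovery/coverage simulations use a dedicated truth generator
(all nine arrows in the 0.02–0.035/week band, initial mix roughly
uniform over the transient stages) designed so every arrow carries
enough expected events over two 13-week intervals at n = 2000 to be
identifiable; with three waves the per-rate asymptotic relative SE is
~10–13%, so rate recovery is asserted on the mean over 10 replicates
(a bias check) and interval calibration on per-rate coverage over 100
replicates.

## Problem sizes and determinism

Simulation studies in the shipped tests use n = 2000 subjects per
panel (recovery: 10 replicates; coverage: 100 replicates; sampling
checks: n = 5000 once), sizes at which the asymptotic approximations
are visibly accurate while the whole suite stays fast. All stochastic
steps take explicit integer seeds; fits are deterministic given data,
seed and multistart schedule.

## Known limitations

- Stage 4 is absorbing by construction; observed relapse is censored
  (truncation at first absorption by default, subject deletion as an
  option), not modelled.
- No covariate effects on intensities, no hidden-Markov
  misclassification layer, no imputation of missing waves
  (complete-case by default, partial sequences optionally retained).
- The ODE step inherits the time unit of its target curves; year-scale
  summaries assume 52 weeks/year.
- The published HE equilibrium (73.31, 0, 0, 26.68) is not derivable
  from the rounded published HE rates together with the week-0 stage
  mix (which contains no motivated mass, so the triangular HE flow
  freezes at F* = week-0 F); the package computes the equilibrium
  family and spectral projection exactly and leaves the discrepancy —
  presumably an unrounded-rate or initial-condition difference —
  documented rather than tuned away. Started from the week-12 mix the
  projection lands near (70.3, 0, 0, 29.7), the same qualitative
  split.
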