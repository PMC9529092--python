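# Methods

## The decision model

A trial is modelled as a one-dimensional diffusion of a decision
variable dv between symmetric absorbing bounds:

    dv_{t+dt} = dv_t + v·dt + σ·√dt·ε,   ε ~ N(0,1),   σ = 1

The upper bound +BO codes the objectively correct option; a first
passage through −BO is an error; response time is the first-passage time
plus a constant non-decision time NDT (encoding and motor latency).
Trial drift follows the distance-compression law

    v = DR · d^SYM,   d = ln(num_a) − ln(num_b) > 0,

where SYM ∈ [0, 1] interpolates between distance-independent drift
(SYM = 0, symbols fully cancel the distance effect) and raw logarithmic
distance scaling (SYM = 1). The starting point is jittered uniformly on
(−IC, +IC); IC is interpreted as the **half-width** of that range — the
published group-level IC values are only comparable under one such
convention, so this one is stated prominently. Diffusion noise is fixed
at σ = 1 because the DDM likelihood is invariant to a joint rescaling of
(DR, BO, IC, σ): one scale parameter must be pinned, and all fitted
magnitudes are relative to that convention.

Parameters, units, defaults (the reference group means of the first
experiment's positive-numeral fits):

| parameter | meaning | units | reference value |
|---|---|---|---|
| DR | drift rate | evidence/s | 2.46 |
| SYM | distance compression | — | 0.09 |
| BO | bound magnitude | evidence | 0.77 |
| IC | start-jitter half-width | evidence | 0.22 |
| NDT | non-decision time | s | 0.41 |
| UN | inference uncertainty | evidence | 2.5 (never fitted) |

## Simulation

Trials are simulated by Euler–Maruyama with dt = 1 ms under a 3-s
response deadline (timeouts are a valid outcome, excluded from fitting
and confidence analysis). Naive end-of-step threshold checks detect
crossings late and bias accuracy and mean decision time by O(√dt);
the simulator therefore applies Brownian-bridge crossing detection
within each step (absorb with probability
exp(−2·(B−x_prev)·(B−x_cur)/σ²dt) per bound), which removes the bias:
simulated accuracy and mean decision time agree with the closed forms
1/(1+e^(−2vB)) and (B/v)·tanh(vB) to within Monte-Carlo error over a
(drift, bound) grid. A numba kernel accelerates the walk when numba is
importable; a vectorized numpy path is the fallback (both use the same
scheme; streams differ, so a given backend is bit-reproducible but the
two backends are not interchangeable draws).

## First-passage densities and the likelihood

Two independent routes to the first-passage densities are implemented:

1. **Series densities** (`fpt_density`): the classical small-time
   (image-sum) and large-time (sine-series) expansions of the Wiener
   first-passage density on [0, a], switched at normalized time 0.15
   where both are accurate far beyond 1e-10; start-point jitter is
   integrated by 7-point Gauss–Legendre quadrature. These are exact,
   fast, and deterministic — they are the fitting likelihood.
2. **A Crank–Nicolson forward solver** (`first_passage_density`): the
   Fokker–Planck equation with absorbing bounds on a uniform grid
   (defaults dt = 2 ms, 301 space points; time steps above 5 ms are
   rejected). Outflowing probability per step is split between the two
   bounds in proportion to the boundary-adjacent densities, so
   upper + lower + survivor mass is conserved to accounting precision
   by construction. The solver cross-checks the series densities and
   the logistic hit probability (agreement ~5e-4 at the default grids).

The joint choice/RT negative log-likelihood of a trial with decision
time t = rt − NDT is −log f_choice(t) with the defective density of the
chosen bound at the trial's drift; infeasible RTs (t ≤ 0) and vanishing
densities contribute a density floor of 1e-10, keeping the objective
finite over the whole search box.

## Fitting

(DR, SYM, BO, IC, NDT) are estimated per participant × numeral type by
seeded differential evolution over the box DR ∈ [0.2, 8], SYM ∈ [0, 1],
BO ∈ [0.3, 4], IC ∈ [0, 0.95·BO], NDT ∈ [0.05, 1.5] s, followed by a
Nelder–Mead polish (out-of-box polish steps receive a graded penalty).
The optimizer works in (DR, SYM, BO, IC/0.95BO, NDT) coordinates so
every candidate keeps the starting distribution strictly inside the
bounds. Fits are bit-reproducible given (data, bounds, seed). UN never
enters the likelihood. Participants with fewer than 50 analyzable
trials raise an insufficient-data error; before fitting, the one-sided
slow-RT rule (drop rt > mean + 2·SD, moments pooled over all trials)
mirrors the task-level exclusion, which loses a few percent of
right-skewed RTs.

Self-consistency (simulate 72 trials at each of the ten design
distances under the reference means, refit): DR and BO are recovered
within a few percent and NDT within ~0.01 s (median of 3 seeds). IC is
weakly identified at 720 trials — single-seed fits can push it toward 0
while compensating with drift — which is why recovery targets are DR,
BO and NDT. SYM trades off against DR at this design's distance range
and recovers with more scatter.

Parameter comparisons between numeral types use one-sample t-tests on
per-subject absolute differences |θ_a − θ_b| against zero, with a
step-down Holm–Šidák adjustment p̃_(i) = 1 − (1 − p_(i))^(m−i+1)
(monotone-enforced); the family size m may exceed the five parameters
to match a wider comparison family.

## The confidence readout

With a normal likelihood for the decision-variable samples and a flat
(improper) prior on their mean, the posterior after n samples is
Normal(dv̄, UN/√n) and confidence is Φ(dv̄·√n/UN), evaluated at the
moment the trace hits a bound. dv̄ is the arithmetic time-average of
the post-step trace values up to and including the crossing sample.
Error trials use the same formula — dv̄ is typically negative there, so
confidence falls below 0.5 — because confidence is the probability that
the **objectively correct** side was favoured, not the chosen side.

Two conventions deserve emphasis:

- **Sample count.** n is counted on a 5-ms sampling of the decision
  stream (`DEFAULT_SAMPLE_DT`), not on the 1-ms integration grid. The
  reference UN values are calibrated to a 5-ms decision-variable
  stream; applying them to a 5× finer stream tightens the posterior by
  √5 and saturates the readout, which distorts every mean-confidence
  comparison.
- **Trial subset for type-level comparisons.** The uncertainty-ordering
  comparison (equal-UN vs lower-positive-UN) is computed on correct
  trials, following the correct-trials plotting convention of the
  corresponding by-distance figures. With error trials included, the
  orderings' second half is numerically knife-edged: lowering UN pushes
  correct trials toward 1 (a bounded gain) but error trials toward 0
  (an unbounded loss), and the two nearly cancel at the reference
  parameter values.

A related model-level observation: at fixed difficulty, confidence
*decreases* with decision time under this readout (measured r ≈ −0.16
on correct trials), because the time-average of a slow, meandering path
decays faster than √n grows. The sample-count mechanism — more samples
tighten the posterior at fixed evidence — is real but is dominated by
the evidence decay at the trial level. A positive trial-level RT–
confidence relation therefore does not follow from this readout; it
would require a readout whose evidence term does not decay with
decision time (e.g. the terminal value ±BO).

## Confidence-signature diagnostics

The three signatures of statistical confidence are implemented as sign
tests on contrasts from ordinary least-squares linear-probability
models with per-subject intercepts (10 equal-count proxy bins by
default; within-subject median splits with ties assigned to the low
half). Full random-effects panel estimators with robust covariance are
deliberately not reproduced: the signatures are monotonicity claims,
and subject intercepts suffice for them. A check passes when the 95%
CI of its contrast excludes zero on the expected side. The normative
illustration generates the same three curves from a model-free setup
(difficulty U(0,1), percept N(±d, 0.3), exact posterior confidence);
percept_sd = 0.3 is a documented choice producing accuracies in the
0.8–0.95 range typical of the task. The log-vs-linear distance
diagnostic compares BIC of otherwise identical subject-intercept
models.

## The synthetic cohort

The generator emulates the experiments' structure: ten fixed digit
pairs {2,3,5,7,8} spanning ten unique logarithmic distances × three
numeral types (defaults: 24 repetitions and 150 dummies for the
first-experiment layout, i.e. 870 trials of which 720 are analyzable),
dummy trials with digits up to 15 that are flagged and never analyzed,
random left/right placement, and a 3-s deadline. Subjects are drawn
around the published group means/SDs per numeral type; one standard-
normal factor per parameter is **shared across numeral types** within a
subject (value = mean_type + sd_type·z, clipped to the fit bounds).
Independent per-type draws would treat one person's positive- and
negative-numeral parameters as unrelated, inflating the between-type
contrast variance far beyond what repeated cohorts of real participants
would show; the shared factor preserves the published marginals while
keeping within-subject consistency.

Button pressure is generated by an explicit stand-in transfer — no
published confidence→motor-output transfer function exists — as
raw = clip(300 + 400·confidence + N(0, 80), 0, 1023) on the sensor
scale, then normalized by each subject's per-side session maximum so
the maximal press maps to exactly 1 and normalized values span roughly
(0.03, 1]. A zero-gain setting is the falsification control: all three
signature checks must fail on it. What passing signature checks on this
cohort shows is that the pipeline detects a monotone confidence signal
when one exists and not otherwise — not that human pressure follows
this particular transfer. Sequential effects (post-error slowing,
feedback carry-over), color cues and experiment-order effects are not
generated; the DDM is static across trials.

## Problem sizes and numerical choices

Default analysis sizes: 720 trials per recovery fit, 3 seeded
replicates per recovery (medians reported); 150 simulations per
distance per subject and 50-subject cohorts for the uncertainty-
ordering comparison (20 replicate cohorts for sign-consistency); 20
subjects for the signature-check cohorts; 1e4 trials per point for the
simulator-vs-closed-form grid; 1e5 trials for the RT-exclusion and
normative-illustration checks. Oracle comparisons against the infinite-
horizon closed forms run the simulator with a long deadline (120 s) so
that truncation does not bias the comparison. Tolerances follow the
source of error: 3 Monte-Carlo standard errors for stochastic
comparisons, 1e-3 for the forward solver's integrated hit probability,
1e-6 for mass conservation.

## Known limitations

- Absolute fitted magnitudes are convention-dependent (σ = 1, IC as a
  half-width); comparisons with values fitted under other toolchains'
  conventions are only meaningful if the conventions match, which is
  why recovery targets are defined self-consistently.
- The likelihood ignores deadline censoring (timeout mass at the
  reference parameters is negligible) and models no across-trial drift
  variability, collapsing bounds, or leakage.
- IC is weakly identified at single-participant trial counts.
- The pressure transfer is a construction of this package; its defaults
  are plausible, not estimated.
- The cohort generator produces no explicit-report confidence and no
  serial dependencies, so diagnostics that rely on those features of
  real data cannot be validated against it.
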