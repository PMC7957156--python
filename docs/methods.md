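# Methods

## Model

A drug's development program in one indication is modelled as a
continuous-time Markov chain on five states — Phase I (1), Phase II
(2), Phase III (3), Approved (4), Failed (5) — with absorbing states 4
and 5 and allowed transitions 1→2, 2→3, 3→4 (progression) and 1→5,
2→5, 3→5 (failure). Direct phase skipping (1→3) is disallowed; a
program first observed in Phase II or III simply starts its history
there. The chain is time-homogeneous: intensities do not depend on
calendar time or time already spent in a state. That is the model's
central simplification — sojourn times are exponential, and secular
trends over the observation window (e.g. changing regulatory practice)
are not represented.

Covariates act by proportional intensities, `q_rs(z) = q0_rs ·
exp(beta_rs' z)`, and `exp(beta)` is the intensity ratio reported as a
hazard ratio. By default the covariate is attached to the three
progression transitions only; failure intensities are covariate-free.
Both per-transition betas and a single beta shared across the attached
transitions are supported — the shared fit supplies the "overall"
hazard ratio, the per-transition fit the hazard-by-phase summaries —
because a drug-level covariate can plausibly act differently at each
phase. Attaching the covariate to failure transitions as well is a
one-line spec change (`attach_to`).

## From trial records to state histories

Classification is deterministic. A phase is **successful** when a
later-phase trial exists for the same indication (Phase III: FDA
approval); a **failure** when the manufacturer withdrew the drug,
declared its primary endpoints missed, or more than two calendar years
(730 days; the boundary day counts as inside the window) passed after
the phase's last trial completion with no further development;
otherwise **ongoing**. Per-phase entry is the earliest trial start in
the phase; the failure event is pinned to the failing phase's last
completion date, treating the two-year rule as a discovery delay rather
than an event time — the convention for exactly observed absorbing
states in panel models. Ongoing programs contribute a terminal
right-censored observation at the data-collection date.

Biomarker labels: a biomarker used for enrolment or exclusion is
*exploratory* until two years after its first FDA approval in the same
indication and *validated* afterwards; drugs with no
enrolment/exclusion biomarker are the reference level. At drug level a
program counts as biomarker-selected if any of its trials used one
(`rule="any"`, configurable to `"all"`).

Time is measured in years from the drug's first phase entry in the
indication, so intensities are per year. Hazard ratios are unit-free.

## Observation semantics and the likelihood

Two observation schemes are implemented, selected by
`ModelSpec.exact_transition_times`:

* **Exact transition times** (default). Phase-entry, approval and
  failure dates are public, so observations sit at the transition
  times themselves. A pair (r → s, interval dt) contributes the
  exact-jump density `exp(-q_r· dt) · q_rs` (survival in r, then the
  jump), and a terminal censored observation contributes survival in
  the last entered state, `exp(-q_r· dt)`: when every entry and
  failure is observed, "nothing further observed by T" means the
  program is still in its last entered phase. This matters in
  practice: treating observations taken *at* the transition times as
  panel snapshots makes the likelihood degenerate (the first-phase
  intensity diverges), and combining exact entries with a
  "not-yet-failed" censoring term produced measurable bias in
  simulation (Phase III→Approved log-intensity bias ≈ +0.23 and 58%
  CI coverage over 40 replicates at n = 1000; both disappear under
  the survival term).

* **Sparse panel** (`exact_transition_times=False`). States are
  snapshots at arbitrary times: exact-state pairs contribute
  `P_rs(dt)` entries of `expm(Q dt)`, a terminal censoring set C
  contributes `Σ_{s∈C} P_rs(dt)`, and an exactly dated absorbing entry
  contributes the standard exact-death term `Σ_m P_rm(dt) · q_m,abs`
  summed over transient m. This is the scheme for data observed at
  fixed check-ups, and the censoring-set monotonicity property holds
  here.

Absorbing entries are exactly observed by default for both Failed and
Approved (per-state flags `exact_absorbing`).

## Estimation

Maximum likelihood on the unconstrained scale (log intensities,
betas), BFGS quasi-Newton, gradient tolerance 1e-6, at most 500
iterations. Initial values are log crude rates — observed direct
transitions divided by total time at risk, floored at 1e-6 per year —
with betas at zero; the floor also pins never-observed transitions at
a harmless boundary with a warning. The covariance is the inverse of a
central-finite-difference observed information (relative step 1e-4) at
the optimum; a singular information matrix yields a fit with absent
intervals rather than an error. Hazard-ratio and intensity intervals
are Wald intervals formed on the log scale and exponentiated.
Likelihood-ratio statistics are `2·(ll_alt − ll_null)` clamped at zero
against chi-square with df equal to the parameter-count difference;
nesting is checked structurally from the model specs (a shared beta is
recognised as nested in per-transition betas), and constraints the
spec machinery cannot express — equality of the exploratory and
validated betas — pass their df explicitly.

Numerics: the public `transition_probability` uses scaling-and-squaring
Padé (`scipy.linalg.expm`) with no diagonalizability assumption. Inside
the optimizer a compiled evaluator groups subjects by covariate vector
and, when the eigenvector matrix of Q is well conditioned (condition
number < 1e8 — the generic case for a progression DAG with distinct
exit rates), batches all interval propagators through one spectral
decomposition, falling back to per-interval Padé otherwise. Agreement
between the compiled and reference likelihoods, and between the
spectral and Padé routes, is enforced in the test suite. Probabilities
are clipped to [0, 1] against roundoff; a zero-probability observation
makes the log-likelihood −∞ with a diagnostic rather than raising.

## Analyses

`run_indication_analysis` / `run_pooled_analysis` fit the no-covariate
and covariate models, report the LRT (df = number of attached
transitions), per-phase fitted intensities at each covariate level
with delta-method intervals, and the shared-beta overall hazard ratio.
The pooled analysis ignores indication entirely. The subtype analysis
uses exploratory/validated indicator covariates with shared betas so
each contrast is one degree of freedom: any-biomarker vs none (base vs
single any-biomarker beta), exploratory vs validated (equal-betas
null), and exploratory vs none (fitted on the cohort excluding
validated drugs, which also yields the exploratory hazard ratio). The
subtype covariate is drug-level, set at first biomarker use. LRT
p-values are reported raw; no multiple-testing adjustment is applied.

## Synthetic cohorts

The generator simulates the embedded chain with competing exponential
clocks per state, covariate multipliers on the clock rates, program
start dates uniform over an enrolment window, and administrative
censoring at a fixed horizon — emitting both the latent trajectory and
the observed panel records. Per-drug RNG sub-streams are derived from
(seed, drug index), so growing a cohort never reshuffles existing
drugs.

Defaults emulate the qualitative regime of 1998–2017 oncology
development: baseline intensities (per year) 0.35/0.30 out of Phase I,
0.25/0.30 out of Phase II, 0.20/0.25 out of Phase III
(progression/failure), giving 1.5–2.2-year expected sojourns, stepwise
advance probabilities of 0.54/0.45/0.44 and ≈ 11% overall approval for
non-biomarker drugs; biomarker prevalence 0.5; progression intensity
ratio 5 for biomarker drugs; cohort size 745; a 15-year enrolment
window inside a 19-year observation horizon; indication mix
0.245/0.262/0.109/0.384 (breast/colorectal/melanoma/NSCLC, proportional
to the Phase I sample sizes of the motivating cohorts). These defaults
are a statistical stand-in, not estimates of any real cohort.

What the generator does **not** emulate: non-exponential sojourns,
calendar-time trends, indication-specific intensities, drug-level
frailty, informative censoring, misclassified outcomes, or the
discovery delay of the two-year failure rule (simulated failures are
observed at the event time). Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own
assumptions — not robustness to their violation.

## Experiment sizes

Test-suite and acceptance-script experiments use problem sizes chosen
to keep Monte-Carlo resolution meaningful on a single CPU: parameter
recovery at n = 1000 drugs × 100 replicates (bias threshold 3
Monte-Carlo SE, coverage ≥ 0.89 — the binomial resolution of 100
replicates around 0.95); LRT null calibration at n = 500 drugs × 200
replicates (acceptance band 0.02–0.08 around the nominal 0.05); the
Monte-Carlo occupancy oracle at 100,000 trajectories per (Q, t) with a
3-binomial-SE tolerance; the acceptance script scales recovery to 60
and calibration to 100 replicates.

## Limitations

* Absolute intensities are only interpretable given the year time
  unit; comparisons across datasets with different clocks need
  rescaling (hazard ratios are unaffected).
* Wald intervals can be poor for transitions with few events (e.g. the
  wide Phase III→Approved intervals in small indications);
  profile-likelihood intervals are not implemented.
* The exact-transition-time scheme assumes entries and failures are
  observed at their true dates; for real registry data the failure
  date inherits the completion-date convention, and ongoing programs
  whose failure has occurred but is not yet discoverable are treated
  as still in phase.
* Time-inhomogeneous intensities, hidden-Markov extensions, frailty
  and Bayesian estimation are out of scope.
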