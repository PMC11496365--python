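# Methods

## Scope and model assumptions

`triageq` computes mean queue waits per priority class in a radiology
reading queue operated under preemptive-resume priority, with and without
an AI triage (CADt) device, and reports the diseased / non-diseased mean
wait differences.  The modelling assumptions are:

- Poisson arrivals of all images at rate λ (per minute); independent
  Bernoulli thinning into interrupting (fraction *f*), diseased (prevalence
  π among non-interrupting images) and AI-call (Se/Sp given disease status)
  subgroups.
- Exponential read times per subgroup: rate μ_f for interrupting images,
  μ_D / μ_ND for diseased / non-diseased ones.  Class-level read times are
  therefore hyperexponential mixtures weighted by π, PPV, or 1−NPV.
- Preemptive-resume discipline: an arriving higher-priority image
  immediately displaces a lower-priority read, which later resumes where it
  stopped.  FIFO within each class.  Because interrupting images preempt
  everything, their own wait is unaffected by the device and is not
  reported.
- Stationarity: every per-class analysis requires the aggregate utilization
  of that class and all higher ones to be below capacity (checked
  explicitly; violations raise an instability error rather than returning
  numbers).

Two analytic workflow models are covered; the simulator covers both plus
any radiologist count.

| Model | read rates | radiologists | state space |
|-------|------------|--------------|-------------|
| 1     | μ_D = μ_ND | 1 or 2       | per-class counts |
| 2     | μ_D ≠ μ_ND | 1            | counts + disease status of the image in service |

Distinct read rates with two or more radiologists have no analytic chain
here (the in-service status bookkeeping grows combinatorially); such
configurations raise `UnsupportedConfigurationError` and can be studied
with the simulator.

## Chain construction (RDR truncation)

For each tagged class the environment of higher-priority work is truncated:
states in which all radiologists are busy with higher-priority images are
collapsed into *busy periods*, replaced by phase-type distributions matched
on the busy period's first three moments.  The chain over (tagged count,
environment phase) is then a level-structured quasi-birth-death process.

Busy-period moments come from three routes:

1. **Single high class, one server** — M/M/1 busy period, closed form:
   m₁ = 1/(μ(1−ρ)), m₂ = 2/(μ²(1−ρ)³), m₃ = 6(1+ρ)/(μ³(1−ρ)⁵).
2. **Pooled high classes, one server** — with one work-conserving server
   the busy period depends only on total workload, so it is the M/G/1
   *delay* busy period of the pooled stream (hyperexponential service mix),
   initiated by the service time of the job that opens it.  This yields
   Model 1's aggregated (interrupting + AI-positive) busy period and Model
   2's three busy periods B1 (opened by an interrupting image), B2 / B3
   (opened by an AI-positive image whose read turns out diseased /
   non-diseased).  Closed form, hence exact.
3. **Two high classes, two servers** — the six busy periods of the
   two-radiologist with-CADt chain (start states (2,0), (1,1), (0,2) of the
   (interrupting, AI-positive) sub-chain; end states (1,0), (0,1)).  The
   conditional end probabilities and conditional moments are obtained from
   first-passage linear systems on the truncated sub-chain (truncation cap
   adaptive from total count 40, doubled to at most 200, until third
   moments are stable to 1e-10 relative; the cap is logged).

In Model 2 the in-service phase carries the disease status, and truncated
busy states are duplicated per the status of the interrupted image ("→D",
"→ND") so the radiologist resumes the correct case; both copies share one
set of fitted rates, since the busy-period law itself does not depend on
what was interrupted.  A third, "fresh" copy covers busy periods that begin
with no tagged image in service (reachable from the empty level); when it
ends, the next tagged read's status is drawn from the class mix.  The
figure-level descriptions of the chains omit the empty column; this
completion is validated by the Pollaczek–Khinchine and model-consistency
checks below.

Mean-wait exactness: for one radiologist the tagged queue sees an on/off
server whose off periods are i.i.d. busy periods triggered at the pooled
high-priority arrival rate; the stationary mean queue length depends on the
off-period law only through its first two moments, so the three-moment
phase-type replacement reproduces the closed-form preemptive-priority means
to solver precision (verified to 1e-6 relative in the tests).  For two
radiologists the RDR construction is a genuine approximation; its error is
small (work conservation holds to ~4e-4 relative at the default scenario)
and the two-server results are validated against the paired simulator's
confidence intervals rather than against closed forms.

## Phase-type (Erlang–Coxian) fitting

Busy periods are fitted by matching three raw moments inside the
Erlang–Coxian family: an optional Erlang run (rate λ_Y, the first phase
carrying an early-exit branch 1−p_EC) feeding a two-phase Coxian
(λ_X1, p_X, λ_X2).  The embedded transition rates obey
t₁ = (1−p_X)λ_X1, t₁₂ = p_X λ_X1, t₂ = λ_X2, and, when an Erlang phase is
present, t₀ = (1−p_EC)λ_Y, t₀₁ = p_EC λ_Y.

- Triples with squared coefficient of variation c² ≥ 1/2 and a compatible
  third moment are matched by the two-phase Coxian alone, in closed form:
  with h₂ = m₂/2, h₃ = m₃/6 the first-phase mean A = 1/λ_X1 solves
  (h₂−m₁²)A² + (m₁h₂−h₃)A + (m₁h₃−h₂²) = 0, then B = (Am₁−h₂)/(A−m₁) and
  p_X = (m₁−A)/B.  The region test (`needs_erlang_stage`) is exact: it is
  the validity of this solution.
- Other triples are solved numerically inside structured EC sub-families
  (shared-rate Coxian with free p_X; pure hypoexponential chain; early-exit
  branch; full five-parameter family), with the Erlang count started at
  ⌈1/c²⌉−2 and increased as needed.
- A few conditional busy periods of the two-radiologist model (moderate c²
  with an unusually small third moment) lie outside every single-entry
  Erlang–Coxian shape.  For these a forward phase chain with a *free entry
  vector* (`ECParams.alpha`) is fitted, in the spirit of canonical acyclic
  phase-type matching; chain builders embed such fits by splitting the
  opening transition across entry phases.

Every fit, whatever the route, must round-trip through the closed-form
moment oracle (`phase_type_moments`, E[Xᵏ] = k!·α(−T)⁻ᵏ1) to 1e-8 relative
accuracy; infeasible triples (negative variance, E[X³]E[X] < E[X²]²) raise
instead of being projected.

## Matrix-geometric solver

The rate matrix R solves A₀ + RA₁ + R²A₂ = 0 by successive substitution
from R = 0 (tolerance 1e-12 on the iteration, residual checked below
1e-10; iteration cap 10⁶).  Stability is pre-checked via the drift
condition θA₀1 < θA₂1 of the repeating generator.  Boundary levels (as many
as there are radiologists, plus the empty level in Model 2) are solved as
one linear system with the normalization Σπᵢ1 + π_m(I−R)⁻¹1 = 1.  The mean
class count uses the closed-form geometric-tail sum
Σ_k (m+k)R^k = m(I−R)⁻¹ + R(I−R)⁻², never a finite truncation.  Negative
probabilities below −1e-9 raise; smaller negative round-off is clipped.
Waits follow Little's law; a class with zero arrivals is assigned zero wait
so the Se/Sp-weighted mixtures remain defined at degenerate operating
points (the weight on the empty class is zero there).

## Metrics

W_D^CADt = W₊Se + W₋(1−Se) and W_ND^CADt = W₊(1−Sp) + W₋Sp; the outputs
are the signed differences δW_D and δW_ND in minutes (negative = saving),
with the with/without ratio as a supplementary field.  The stroke-outcome
scaling maps a saving linearly — 15 min ⇒ 3.9% of LVO stroke patients with
less disability — clamped at zero for delays.

## Simulator

The simulator is the package's synthetic-data generator and verification
tool.  Per run it draws, in fixed order per patient: interarrival time,
interrupting flag, disease flag, AI-call flag, unit-exponential read
duration (scaled by the subgroup rate).  Each image then lives in two
worlds sharing those draws — without CADt (two classes) and with CADt
(three classes) — so per-image wait differences are paired.  Both worlds
run preemptive-resume with FIFO within class; when a higher-priority image
arrives with all servers busy, the server working on the
lowest-priority, most-recently-started job is preempted (distributionally
immaterial under exponential service, fixed for reproducibility).
Remaining work is stored and resumed, never resampled, so total service
equals the drawn duration and Model 2's status memory is honored.  Waits
are queue waits: departure − arrival − read duration.

Defaults follow the verification protocol: 200 runs of 2000 patients, zero
burn-in (configurable; short runs bias waits low, which is visible in both
worlds and largely cancels in δW).  Two 95% intervals are reported for
δW_D: the 2.5/97.5 percentiles of per-run means and the normal-theory
interval of the grand mean — the underlying protocol statement does not fix
which is meant, so both are labelled and emitted.  Pre-arrival class counts
are recorded per image; by PASTA their empirical distribution estimates the
chain's stationary probabilities, which the tests exploit.

Randomness: one root seed spawns independent per-run child streams
(`numpy` `SeedSequence`), so run k's results do not depend on how many runs
follow.

What the simulator does *not* emulate (hence what passing tests cannot
show): non-exponential or backlog-dependent read times, radiologist
fatigue, reading-rate differences between TP/FP/TN/FN subgroups, multiple
simultaneous triage devices.

## Problem sizes used in the checks

The automated checks run at sizes chosen to keep the full suite around a
minute while leaving Monte-Carlo noise well below the tested effects:
busy-period cross-checks use ~2×10⁴ simulated cycles against a 3.5-standard
-error band; the theory-vs-simulation acceptance check uses 20 random
stable scenarios at 50 runs × 1000 patients with the ≥18/20 coverage rule;
trend checks that need simulation use 50–60 runs of 1000 patients.  The
moment-fit property test draws 150 random hypoexponential targets; a
separate one-off check ran 1000 without failure.

## Known limitations

- Two-radiologist with-CADt results inherit the RDR approximation
  (sub-percent error in the mean at the scenarios examined, but not exact).
- Model 2 is restricted to one radiologist; Model 1 chains to at most two.
  The simulator has no such limit.
- Means only: wait-time distributions and analytic CIs (e.g. via the
  distributional Little's law) are out of scope; CIs come from simulation.
- The ρ→λ conversion defines μ_eff as the arrival-weighted harmonic mean of
  read times — the natural reading of ρ = λ/(μN_rad) with heterogeneous
  classes, and the one that reproduces the reference scenarios (ρ = 0.8,
  10-min reads, one radiologist ⇒ λ = 0.08/min) — but other conventions are
  conceivable when μ_f differs strongly from the non-interrupting rates.
- The example ROC curve family (equal-variance binormal, parametrized by
  AUC) is a convenience, not a canonical choice; any monotone curve can be
  supplied.
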