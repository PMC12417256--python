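# Methods

## Scope and model assumptions

`atopt` treats an incurable, heterogeneous tumor as two competing
populations under a binary drug schedule (maximum tolerated dose or
holiday; dose-modulation protocols are out of scope).  Progression, not
cure, is the endpoint: every model contains a compartment that treatment
cannot eliminate, so the objective is to maximize the time to progression
(TTP), defined as 20% growth over the initial burden (plus, in the
waning-competition model, growth of the resistant population to 10% of its
carrying capacity, whichever comes first).  Treatment decisions are made
only at appointments spaced τ days apart, from noise-free measurements of
the simulated state; a measurement-noise hook exists in the protocol layer
but defaults off.

The three models and their roles:

- **Lotka–Volterra (`lv`)** — sensitive/resistant competition through a
  shared logistic term, equal natural death rate `d`, Norton–Simon kill
  `(1 − d_D·D)` on the sensitive growth term.  The analytically cleanest
  case: τ\*(N\*) and N\*(τ) in closed form.
- **Waning competition (`wc`)** — generalized logistic growth (exponent
  `α`) with the *other* species entering each crowding term with weight
  `1/(1 + e^{γt})`, so inter-species competition fades on a 1/γ timescale.
  The closed-form threshold uses the fastest-recovery worst case (wholly
  sensitive tumor, γ = 0), deliberately conservative for γ > 0.
- **Stem-cell (`sc`)** — drug-immune stem-like cells dividing at rate λ,
  self-renewing with probability `p_S` under feedback `S/(S+D)`; the
  differentiated bulk dies under treatment at rate `d_D`.  Off-drug the
  exact solution keeps `N·S^(−1/p_S)` constant, giving the regrowth law
  `dN/dt = λ S(t₀) (N/N(t₀))^{p_S}` from any holiday start — regrowth
  accelerates as stem cells accumulate, which is why the optimal threshold
  must fall over time.

## The threshold derivation

The optimal interval for a threshold N\* is the worst-case drug-free travel
time from N\* to the progression limit: τ\*(N\*) = ∫ dN/g(N).  The package
exposes each model's `g` (`drug_free_total_growth`), the closed forms
(`lv_tau_star`/`lv_optimal_threshold`, `wc_optimal_threshold`), the
implicit stem-cell solve (`sc_optimal_threshold`), and a model-agnostic
quadrature oracle (`numeric_tau_star`) used by the tests to cross-check
every closed form to 1e−6 days.

The stem-cell threshold solves
`x^{1−p} + λ(1−p)·S·τ·x^{−p} = (1.2·N(0))^{1−p}` by bracketed root-finding
(Brent, relative tolerance 1e−12) on `[x_min, 1.2·N(0)]`, where
`x_min = p·λ·S·τ` is the function's unique interior minimum.  The equation
has at most two roots; the *larger* one is the meaningful threshold (the
travel-time curve τ(N\*) vanishes at both ends of the bracket).  When no
root exists — the stem population has grown so large that any holiday of
length τ overshoots — `None` is returned and the time-varying protocol
degenerates to continuous treatment.  Fixed-point iteration was rejected:
it has no monotonicity guarantee here.

## Simulation engine

Courses are integrated piecewise (dose constant between appointments) with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e−8, atol 1e−10; refining both
tenfold moves default-scenario TTPs by far less than 0.1 day).  Progression
is detected *continuously* by terminal event functions — crossings usually
fall strictly between appointments — and the event time is the reported
TTP.  Courses that never progress report an infinite sentinel, not the
horizon (default 5000 days; grid exporters cap at the horizon with a
`progressed` flag).  Populations are clamped nonnegative inside the
right-hand sides and at segment boundaries; the clamp is inactive beyond
roundoff on all default scenarios.

**Premature progression** is progression while the dose is 0 *via the
total-size criterion*: sensitive regrowth that tighter monitoring would
have interrupted.  A resistant-population crossing (`R ≥ 0.1·K_R`) during a
holiday is deliberately not flagged — it is not avoidable by more frequent
appointments, which is the meaning the flag carries.

**Worst-case offsets.** A protocol (N\*, τ) is evaluated by the minimum TTP
over 20 schedules offset by an initial treatment period `k·τ/20`
(k = 0…19).  Even spacing is deterministic and reproducible; the offset
family realizes the derivation's worst case (a holiday starting with the
tumor exactly at N\*) to within the offset resolution.  A protocol grid's
`premature` flag is true if *any* offset run progressed prematurely.

## Default parameterizations

Bundled in `src/atopt/configs/`.  Populations are dimensionless (fractions
of a reference carrying capacity), rates per day.

- **LV**: r_S = 0.027, d_D = 1.5 (published prostate-cancer fits, Strobl et
  al. 2021), r_R = 0.5·r_S (cost of resistance within that study's tested
  range), K = 0.75, zero turnover, N₀ = 0.75·K with 1% resistant.  These
  give the two analytic anchors the package's tests pin: τ\*(N₀) = 40.7
  days by ln(3)/r_S, and — in the turnover variant (N₀ = 0.4·K,
  d = 0.3·r_S) — τ\*(N₀) = 26.1 days.
- **WC**: nondimensional K_S = K_R = 1, r_S = 0.027, γ = 0.01/day,
  α ∈ {1, 3} in the experiments; the resistant species is a 0.1% minority
  with a 70% cost of resistance and a three-fold reduced drug response.
  The minority must stay negligible for the wholly-sensitive worst case to
  be sharp; see limitations.
- **SC**: λ = 0.57/day (published fits, Brady-Nicholls & Enderling);
  p_S = 0.05 and d_D = 0.05/day sit in the fitted patient-specific range
  and place the dynamics in the regime of interest: under a fixed threshold
  (N\* = 0.5–0.6, τ = 40 d) the burden is initially held far below the
  limit, yet stem-cell accumulation eventually makes a 40-day holiday fatal
  (premature progression around day ~1100 in this parameterization), while
  the time-varying threshold — starting near 0.97 and falling as S(t) grows
  — extends TTP by several hundred days and never fails off-drug.

S(t) for the time-varying threshold is read from the simulated state at the
appointment; integrating the conservation law over the treatment history
would give the same value and is unnecessary in simulation.

## What the synthetic experiments do and do not show

All experiments run on simulated trajectories of the models themselves:
they validate the *derivations* (that the analytic threshold is exactly the
feasibility boundary of the worst-case simulation), not the models'
fidelity to any patient.  Virtual cohorts draw parameters uniformly and
independently within per-field boxes — a stand-in distribution, not a
fitted population.  Real treatment courses add PSA measurement noise,
appointment jitter, pharmacokinetic tails, and model misspecification, none
of which are represented here; passing tests therefore demonstrate internal
consistency of the scheduling framework, not clinical performance.

## Numerical choices and degenerate inputs

- Threshold formulas clamp one-ulp overshoot so N\*(τ) never exceeds
  1.2·N₀, and return the limit exactly at τ = 0 (also at S = 0 for the
  stem-cell case: no stem cells, no drug-free growth).
- Threshold ties treat (`N ≥ N\*`), matching the protocol definitions; the
  AT50 upper window bound is likewise inclusive.
- AT50 starts in its treating phase; the window fractions (0.5, 1.0) are
  configurable, upper fractions above 1 give range-bounded variants.
- The all-zero state is a (unstable) fixed point in every model; the
  stem-cell feedback `S/(S+D)` is defined as 0 there to preserve it.
- A trajectory that starts at or above the progression limit has TTP 0.
- `numeric_tau_star` probes the growth law on a 101-point grid and reports
  an infinite interval if growth is nonpositive anywhere on it (the tumor
  stalls below the limit).

## Known limitations

- The WC feasibility boundary is exactly sharp only while the resistant
  minority is negligible.  At long TTPs (≳600 days under the defaults) R
  reaches a few percent and, because the competition weight has decayed, it
  adds its own growth to N during holidays; worst-case runs can then
  progress prematurely a few percent *below* the analytic curve.  The
  strict two-sided sharpness property is asserted for the LV model, where
  it holds at ±2% across intervals of 20–60 days.
- The stem-cell premature-failure time and the time-varying rescue margin
  depend strongly on (p_S, d_D, S₀); the package asserts the regime and the
  strict dominance of the time-varying protocol, not particular day counts.
- No pharmacokinetics: dose changes are instantaneous, appropriate only
  when the drug's elimination half-life is short against the holiday
  length.
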