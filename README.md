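# atopt — optimal adaptive-therapy thresholds under discrete monitoring

Adaptive therapy (AT) delays progression of incurable, partially
drug-resistant tumors by scheduling treatment holidays: a large
drug-sensitive population competitively suppresses the resistant clone that
treatment cannot touch.  Published optimal AT schedules assume the tumor
burden is monitored continuously.  In the clinic it is not — treatment can
only be changed at appointments, typically every τ ≈ 30 days — and a
holiday that runs unsupervised for a full interval can carry the tumor
straight past the progression limit ("premature progression").

`atopt` is a small library + CLI for deriving and validating
**threshold-based AT protocols (AT-N\*)** under discrete monitoring: treat
exactly when the measured burden satisfies N ≥ N\*.  It is aimed at
mathematical oncologists studying treatment scheduling for competition-based
tumor models (its default parameterizations come from intermittent androgen
suppression of metastatic prostate cancer).

## The core result

For a tumor with worst-case drug-free regrowth law dN/dt = g(N), the
largest threshold that a monitoring interval τ can support solves

τ = ∫ from N\* to 1.2·N₀ of dN / g(N),

where 1.2·N₀ (20% growth over the initial burden) is clinical progression.
The package implements this for three models:

- **Lotka–Volterra competition** (sensitive S vs. resistant R, shared
  carrying capacity K, Norton–Simon drug kill).  Closed form:

  τ\*(N\*) = 1/(r_S−d_S) · ln[ (1.2N₀/N\*) · (K(r_S−d_S) − r_S N\*) /
  (K(r_S−d_S) − 1.2 r_S N₀) ],

  with an explicit inverse N\*(τ).
- **Waning competition** (generalized-logistic growth with exponent α and
  exponentially decaying inter-species competition):
  N\* = K_S [((K_S/1.2N₀)^α − 1)·e^{α r_S τ} + 1]^{−1/α}.
- **Stem-cell driven growth** (drug-immune stem cells S feeding a
  drug-sensitive differentiated bulk D).  Off-drug regrowth accelerates as
  stem cells accumulate, so the optimal threshold is **time-varying**:
  N\*(t) solves an implicit equation in the current stem population S(t)
  and is recomputed at every appointment.

Simulation validates the thresholds by the worst case over 20 shifted
appointment grids: slightly above N\*(τ) some schedule progresses
prematurely, slightly below none does.

## Worked example

Default Lotka–Volterra tumor (r_S = 0.027/day, r_R = 0.0135/day, K = 0.75,
d = 0, d_D = 1.5, N₀ = 0.5625 with a 1% resistant minority — bundled as
`src/atopt/configs/lv_default.yaml`):

```text
$ atopt threshold --model lv --tau 30
N* = 0.600112
```

With monthly appointments the threshold can safely sit ~7% *above* the
initial size 0.5625: the optimal schedule starts with a treatment break.

```text
$ atopt threshold --model lv --nstar 0.5625
tau* = 40.6893 d
```

A threshold at the initial size — the upper bound of the window-based AT50
protocol used in the pilot clinical trial — is only safe if appointments
are at most ~40 days apart; longer gaps risk premature progression.

```text
$ atopt compare --model lv --tau 30
 protocol         ttp  premature  worst_offset
       CT  631.553565      False           0.0
     AT50  967.218942      False           3.0
ATN_fixed 1551.390413      False           0.0
```

Worst-case times to progression (days) at 30-day appointments: continuous
therapy progresses at day 632, window-based AT50 at day 967, and the
threshold protocol AT-N\*(N₀) at day 1551 — holding the tumor high
maximizes competitive suppression of the resistant clone, without premature
progression (`premature = False`).

The same machinery drives `atopt sweep` ((τ, N\*) TTP heatmaps with the
analytic feasibility boundary), `atopt simulate` (single courses, trajectory
CSV export), and `atopt cohort` (per-patient thresholds over sampled
virtual cohorts).  See `docs/methods.md` for model details, default
parameter provenance, and numerical choices.

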