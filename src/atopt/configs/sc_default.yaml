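# Stem-cell model (Brady-Nicholls & Enderling style).  Division rate
# lambda = 0.57/day from that model's published prostate fits; the
# self-renewal probability and drug-kill rate sit in the fitted
# patient-specific range and place the dynamics in the regime where a fixed
# threshold eventually fails by premature progression while the time-varying
# threshold does not.  Sizes are normalized to the initial burden (N0 = 1)
# with a 1% initial stem fraction.
model: sc
lambda_: 0.57
p_S: 0.05
d_D: 0.05
N0: 1.0
S0: 0.01
D0: 0.99
protocol:
  kind: ATN_timevarying
  tau: 40.0
horizon: 5000.0
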