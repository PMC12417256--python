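# Lotka-Volterra competition model: default parameterization.
# Rates follow the prostate-cancer fits of Strobl et al. (2021): sensitive
# proliferation 0.027/day, Norton-Simon kill factor 1.5, zero baseline
# turnover, 50% cost of resistance.  The tumor starts at 75% of its
# carrying capacity with a 1% resistant fraction.
model: lv
r_S: 0.027
r_R: 0.0135
K: 0.75
d: 0.0
d_D: 1.5
N0: 0.5625
S0: 0.556875
R0: 0.005625
protocol:
  kind: ATN_fixed
  N_star: 0.5625   # threshold at the initial size, as in window-based AT
  tau: 30.0
horizon: 5000.0
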