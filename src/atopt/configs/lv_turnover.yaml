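# Lotka-Volterra variant with natural turnover: a smaller tumor
# (N0 = 0.4 K) whose cells die at 30% of the sensitive proliferation rate.
# Used to illustrate how turnover shortens the safe appointment interval.
model: lv
r_S: 0.027
r_R: 0.0135
K: 0.75
d: 0.0081        # 0.3 * r_S
d_D: 1.5
N0: 0.3
S0: 0.297
R0: 0.003
protocol:
  kind: ATN_fixed
  N_star: 0.3
  tau: 26.0
horizon: 5000.0
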