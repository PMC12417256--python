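# Waning-competition model (Lu et al. style), nondimensionalized so both
# carrying capacities are 1.  The resistant species starts as a 0.1%
# minority with a strong (70%) cost of resistance and a three-fold reduced
# drug response (resistance is relative, not absolute); competition decays
# with resistance index gamma = 0.01/day.  This keeps the tumor in the
# nearly-wholly-sensitive regime the threshold derivation assumes.
# Progression: R >= 0.1 K_R, capped at N >= 1.2 N0.
model: wc
r_S: 0.027
r_R: 0.0081
K_S: 1.0
K_R: 1.0
d_S: 1.5
d_R: 0.5
alpha: 1.0
gamma: 0.01
N0: 0.75
S0: 0.74925
R0: 0.00075
protocol:
  kind: ATN_fixed
  N_star: 0.7
  tau: 60.0
horizon: 5000.0
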