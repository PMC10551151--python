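"""The non-rectangular hyperbola forward model.

Evaluates net photosynthesis A_N over a light gradient for one set of curve
parameters and shows the two limiting shapes (rectangular hyperbola at
theta -> 0, Blackman response at theta = 1).
"""

import numpy as np

from mblrc import LrcParameters, nrh_mean, nrh_mean_theta_zero

params = LrcParameters(a_max=25.0, alpha=0.05, r_d=1.5, theta=0.8)
par = np.array([0, 50, 200, 600, 1200, 2400])

print("PAR (umol m-2 s-1) ->  A_N (umol CO2 m-2 s-1)")
for I, a in zip(par, nrh_mean(params, par)):
    print(f"  {I:6.0f}            {a:8.3f}")

print("\nAt PAR=0 the leaf only respires (A_N = -r_d = -1.5); the curve")
print("rises with initial slope alpha and saturates toward a_max - r_d = 23.5.")

blackman = LrcParameters(25.0, 0.05, 1.5, 1.0)
print(f"\ntheta=1 (Blackman) at PAR=400:  {nrh_mean(blackman, 400):.3f}"
      "  == min(alpha*I, a_max) - r_d = 18.5")
print(f"theta->0 (rectangular) at PAR=500: {nrh_mean_theta_zero(params, 500):.3f}")
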