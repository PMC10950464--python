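"""Simulate the cross-repressilator and inspect its stability structure.

Integrates one deterministic and one stochastic cell trajectory at strong
oscillation (alpha = 1000), locates the Hopf-type loss of stability of the
symmetric multi-potent state, and prints the terminal fate.
"""

import numpy as np

from cfrlineage import (
    CFRParams,
    SignalParams,
    SimSettings,
    hopf_scan,
    linear_stability,
    signal_g,
    simulate_ode,
    simulate_sde,
)

p = CFRParams(alpha=1000.0)

onset = hopf_scan(p, SignalParams(), np.linspace(1.0, 2000.0, 400))
res = linear_stability(p, signal_g(onset))
print(f"symmetric state loses stability near t = {onset:.0f}")
print(
    f"  at that point x* = {res.x_star:.4f}, complex pair "
    f"{res.eig_real_pair:+.4f} +/- {res.eig_imag_pair:.4f}i"
)

ode = simulate_ode(p)
sde = simulate_sde(p, settings=SimSettings(sigma=0.01, seed=1))
for name, traj in (("deterministic", ode), ("sigma=0.01 sample path", sde)):
    x = traj.states[-1]
    fate = int(np.argmax(x))
    print(
        f"{name}: terminal state ({x[0]:.3g}, {x[1]:.3g}, {x[2]:.3g})"
        f" -> TF {fate + 1} dominates"
    )
print(
    "The dominant TF ends near (b + g(2000))/d = 20 while the other two are "
    "suppressed to ~0.01-0.04; which TF wins depends on noise and alpha."
)
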