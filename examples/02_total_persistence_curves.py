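"""Track loops and cavities over time with total-persistence curves.

Computes the Rips persistence diagram of every window of the five-epoch
scenario and sums bar lifetimes per homology dimension.  TP_1 (loops)
peaks while the signal traces a circle; TP_2 (cavities) peaks while it
traces a sphere.
"""

import numpy as np

from tdabreak import FiltrationParams, build_scenario, tv_total_persistence

signal, preset = build_scenario("example1", rng=np.random.default_rng(0))
curves = tv_total_persistence(
    signal, preset.window_config, FiltrationParams(max_homology_dim=2)
)

t = curves.times
epochs = {"gauss-1": (0, 30), "circle": (30, 60), "gauss-2": (60, 90),
          "sphere": (90, 120), "gauss-3": (120, 150)}
print(f"{'epoch':8s} {'TP0':>7s} {'TP1':>7s} {'TP2':>7s}")
for name, (lo, hi) in epochs.items():
    sel = (t >= lo) & (t < hi)
    print(f"{name:8s} " + " ".join(f"{curves[k][sel].mean():7.2f}" for k in (0, 1, 2)))
print("TP1 roughly doubles in the circle epoch and TP2 rises an order of")
print("magnitude in the sphere epoch: the windowed clouds really carry a")
print("loop and a cavity there.")
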