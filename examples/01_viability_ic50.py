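"""Dose-viability curve and IC50 from a simulated alamarBlue plate.

Simulates one 7-dose plate (triplicate wells, logistic midpoint 75 µM),
summarizes it into a curve and estimates the IC50 two ways.
"""

from radsyn import build_curve, estimate_ic50
from radsyn.simulate import SimulationConfig, simulate_viability_plate

config = SimulationConfig(seed=1)
wells = simulate_viability_plate(config)
curve = build_curve(wells)

print("dose (µM)   viability %   se")
for d, v, se in zip(curve.doses, curve.mean_viability, curve.se_viability):
    print(f"{d:9.0f}   {v:11.1f}   {se:.2f}")

for method in ("log_interp", "four_pl"):
    print(f"IC50 ({method}): {estimate_ic50(curve, method):.1f} µM")

# The IC50 is the concentration at which viability crosses 50%; the plate
# was generated with a true midpoint of 75 µM, so both estimates should be
# close to 75.
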