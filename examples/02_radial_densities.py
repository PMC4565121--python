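"""Analytic radial densities of the occupied cytoskeleton.

Computes the occupancy profile eps(rho), the radial contour density
Q1(r) of mitochondria-carrying fiber, and the occupied-crossing density
S11(r) for the reference cell, and verifies mass conservation.
"""
import numpy as np

from mitoreticulum import CellDensities, SimulationConfig, occupancy

cfg = SimulationConfig()  # the reference cell, psi = 0
dens = CellDensities(cfg)

eps = occupancy(cfg)
print(f"occupancy eps = {eps(5.0):.5f} on [{cfg.l1}, {cfg.l2}] um (uniform, psi = 0)")

print(f"{'r (um)':>7} {'Q1 (um/um)':>11} {'S11 (um^2/um)':>14} {'S11/Q1^2 (um)':>14}")
for r in (2.0, 4.0, 8.0, 12.0):
    q1 = dens.Q1(np.array([r]))[0]
    s11 = dens.S11(np.array([r]))[0]
    print(f"{r:7.1f} {q1:11.2f} {s11:14.4f} {s11 / q1**2:14.6f}")

rr = np.linspace(1e-3, cfg.L - 1e-3, 4001)
print(f"\nintegral of Q1 over r: {np.trapezoid(dens.Q1(rr), rr):8.1f} um (M = {cfg.M})")
# Q1 is nearly flat (mitochondria cover the radially diverging fibers
# uniformly), while the occupied-crossing density S11 falls off like
# 1/r^2: branching substrate is concentrated near the centrosome.
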