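"""Generate a small centrosome-organized microtubule array and inspect it.

Builds 120 freely-rotating chains grafted at the origin, detects the
two-fiber crossing spots (axis distance below sigma = 0.2 um) and recovers
the imposed persistence length from the tangent-tangent correlation decay.
"""
import numpy as np

from mitoreticulum import (
    SimulationConfig,
    detect_crossings,
    estimate_persistence,
    generate_cytoskeleton,
)

cfg = SimulationConfig(n_f=120, L=16.0, L_p=32.0, seed=1)
array = generate_cytoskeleton(cfg)

crossings = detect_crossings(array, cfg.sigma)
fit = estimate_persistence(array)

r2 = np.mean([c.end_to_end() ** 2 for c in array.chains])
print(f"chains:                {array.n_f} x {array.chains[0].n_bonds} bonds")
print(f"mean squared end-to-end: {r2:8.1f} um^2 (WLC closed form: 218.2)")
print(f"persistence estimate:  {fit.L_p:8.1f} um (imposed: {cfg.L_p})")
bulk = crossings.r > 4 * cfg.sigma
print(f"crossing spots:        {len(crossings)} (axis distance < {cfg.sigma} um)")
print(
    f"beyond 4 sigma:        {bulk.sum()} crossings, median radius "
    f"{np.median(crossings.r[bulk]):.2f} um"
)
# Every fiber pair meets at the grafting point, so most crossing spots sit
# at the centrosome itself; the bulk crossings beyond 4 sigma thin out
# with radius -- the geometric driver of the model's perinuclear branching.
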