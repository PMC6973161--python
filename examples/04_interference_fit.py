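"""Fit the two-pathway gamma interference model to simulated marker data.

Simulates gametes for a chromosome-1-like map with interference strength
nu = 3 and 10% non-interfering crossovers, then estimates (nu, p) by
simulated composite likelihood with a bootstrap-calibrated confidence
interval for nu.
"""

import numpy as np

from invcross.interference import (
    GammaParams,
    _fit_switches,
    _flatten,
    build_reference_tables,
    positions_to_switches,
    simulate_two_pathway,
)

L = 1.17  # Morgans, male chromosome 1
boundaries = np.linspace(0.0, L, 26)
rng = np.random.default_rng(8)

truth = GammaParams(nu=3.0, p=0.10, map_length_morgans=L)
pos, idx = _flatten(simulate_two_pathway(truth, 2000, rng))
switches = positions_to_switches(pos, idx, boundaries, 2000)

reference = build_reference_tables(
    boundaries, nu_grid=(1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0, 13.0),
    p_grid=(0.0, 0.1, 0.2), n_ref=10_000, seed=9,
)
fit = _fit_switches(switches, reference, n_boot=60, rng=rng, boundaries=boundaries)

print(f"true (nu, p) = (3.0, 0.10); fitted nu = {fit.params.nu:.1f}, p = {fit.params.p:.2f}")
print(f"95% bootstrap-calibrated interval for nu: [{fit.ci_nu[0]:.1f}, {fit.ci_nu[1]:.1f}]")
print("\nnu > 1 means crossovers repel each other (interference); the interval "
      "is wide because 2000 binary switch vectors carry limited information "
      "about spacing regularity -- but nu = 1 (no interference) is excluded "
      "when the lower bound stays above 1.")
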