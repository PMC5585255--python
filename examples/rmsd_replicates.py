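"""Replicate RMSD statistics via Kabsch superposition.

Generates four seeded replicates of a 400-atom Cα cloud with per-coordinate
Gaussian noise σ = 3.4/√3 Å (so the minimized RMSD concentrates at 3.4 Å),
then reports the per-replicate time means and the across-replicate
mean ± sample SD (n = 4).
"""

import numpy as np

from trpgate import (
    aggregate_replicates,
    reference_ca_structure,
    rmsd_to_reference,
    simulate_noisy_replicate,
)

target = 3.4  # Å
sigma = target / np.sqrt(3.0)
top, ref = reference_ca_structure(n_atoms=400, seed=0)

series = []
for seed in (1, 2, 3, 4):
    traj = simulate_noisy_replicate(top, ref, sigma, n_frames=600, seed=seed)
    s = rmsd_to_reference(traj, reference=ref)
    series.append(s)
    print(f"replicate seed {seed}: time-mean RMSD = {s.time_mean_A:.3f} Å")

agg = aggregate_replicates(series)
print(f"grand mean: {agg.mean:.2f} ± {agg.sd:.2f} Å (n = {agg.n})")
# Each frame is also rigidly rotated/translated at random; the Kabsch
# alignment removes that motion, leaving only the calibrated noise level.
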