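"""Map binding events back to kinetic clusters and build weighted densities.

Runs the inference on a small synthetic dataset, assigns each event's
frame range to its most probable cluster, and accumulates
probability-weighted 3D densities of toy ligand coordinates: slow-
cluster frames are placed near the origin, fast-cluster frames farther
out, so the weighted densities separate the two poses.
"""

import numpy as np

from restime import GibbsConfig, run_gibbs
from restime.kinetic_map import assign_frames, top_frames, weighted_density
from restime.postprocess import correct_labels, membership_matrix, remove_noise
from restime.synthetic import SCENARIOS, durations_to_events, sample_hyperexponential

truth = SCENARIOS["two_component"](n=2000, seed=7)
durations, _ = sample_hyperexponential(truth)
series = durations_to_events(durations, residue_id=1)

chain = run_gibbs(series.durations,
                  GibbsConfig(n_iter=4000, burn_in=1000, thin=6, seed=7, K=10),
                  log_every=0)
model = correct_labels(chain)
mm = membership_matrix(chain, model)
model = remove_noise(model, mm)

assignments = assign_frames(series.events, mm, frame_interval=1.0)
counts = np.bincount([a.cluster for a in assignments if a.cluster >= 0],
                     minlength=model.k_prime)
print(f"K' = {model.k_prime}; events per hard-assigned cluster: {counts}")
best = top_frames(assignments, cluster=model.k_prime - 1, n=5)
print(f"5 frames most confidently in the slowest cluster: {best}")

# toy coordinates: one particle per bound frame; slow-cluster events
# sit near the origin, fast ones ~5 A away
rng = np.random.default_rng(7)
frames, fmap, coords = [], [], []
for a in assignments[:200]:
    center = 0.0 if a.cluster == model.k_prime - 1 else 5.0
    for f in a.frames:
        fmap.append(a.event_index)
        coords.append(center + rng.normal(0, 0.8, (1, 3)))

origin, shape = np.full(3, -4.0), (14, 14, 14)
dens = {c: weighted_density(coords, fmap, mm, c, origin=origin, shape=shape)
        for c in range(model.k_prime)}
for c, d in dens.items():
    com = np.array(np.unravel_index(np.argmax(d.counts), shape)) + origin
    print(f"cluster {c}: weighted density peak voxel at {com}, "
          f"total weighted mass {d.counts.sum():.1f}")

print("\nThe slowest cluster's density peaks near the origin, the fast "
      "cluster's near (5,5,5): the membership weights separate binding "
      "poses by timescale. Use restime.kinetic_map.export_dx to write "
      "OpenDX files for visualization.")
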