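"""Reconstruct confining microdomains from single-particle trajectories.

Generates synthetic SPT tracks over two planted disk domains, classifies
trajectory points slow/fast by jump size over several lags, clusters the
slow points (single linkage, linking distance L) and contours each cluster
with its convex hull. The recovered contours are scored against the
planted truth by area Jaccard overlap.
"""

import numpy as np

from prebcr import (
    DomainMap,
    domain_recovery_score,
    generate_synthetic_spt,
    reconstruct_domains,
)


def disk(radius, center, n=24):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


truth = DomainMap(contours=[disk(0.15, (0.4, 0.4)), disk(0.15, (1.1, 1.1))],
                  exit_probability=0.02)
spt = generate_synthetic_spt(truth, d_free=0.16, n_tracks=40, frames=200,
                             frame_dt=0.1, seed=17)
print(f"{spt.frame.track_id.nunique()} tracks, {len(spt.frame)} points, "
      f"{(spt.in_domain >= 0).mean():.0%} confined (ground truth)")

rec = reconstruct_domains(spt, L=0.1, slow_threshold=0.35,
                          min_cluster_size=30)
scores = domain_recovery_score(rec, truth)
print(f"reconstructed {len(rec)} contours; "
      f"Jaccard vs planted disks: {[f'{s:.2f}' for s in scores]}")

# Both planted domains are typically recovered with Jaccard > 0.8; free
# (unconfined) trajectories would instead give scattered slow points and
# near-zero overlap.
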