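"""QT conformational clustering, reference labelling and weighted energetics.

Frames are grouped by pairwise Kabsch RMSD with the Quality-Threshold
algorithm; each cluster center is labelled by its nearest reference
conformation and scored, and the per-cluster scores are weighted by the
fraction of simulation time each cluster represents.
"""
import numpy as np

from trajkit import (
    contact_interaction_energy,
    label_clusters,
    pairwise_rmsd_matrix,
    qt_cluster,
    resolve_selection,
    weighted_interaction_score,
)
from trajkit.synthetic import make_study_pair

pair = make_study_pair(seed=9, n_frames=100)
traj = pair.variant
top = traj.topology

sel = resolve_selection(top, "chain U and backbone")
matrix = pairwise_rmsd_matrix(traj, sel)
clusters = qt_cluster(matrix, cutoff=1.75, min_size_frac=0.01)
records = label_clusters(traj, clusters, pair.references, chain="U")

kinase = resolve_selection(top, "chain A")
substrate = resolve_selection(top, "chain U")
raw = [contact_interaction_energy(traj.frame(c.center), kinase, substrate)
       for c in clusters.clusters]
report = weighted_interaction_score(raw, clusters.frequencies())

print("cluster  size  freq%   label   raw_dG    weighted_dG  (kcal/mol)")
for rec, c, r, w in zip(records, clusters.clusters, report.raw, report.weighted):
    print(f"{rec['cluster']:>7d} {len(c.members):>5d} {100 * c.frequency:6.1f}"
          f"  {rec['label']:>6s} {r:8.2f} {w:13.3f}")
print(f"rejected frames: {clusters.rejected.size} "
      f"({100 * clusters.rejection_rate:.1f}%)")
print(f"\nfrequency-weighted interaction score: {report.total:.3f} kcal/mol")
print("the dominant CR-like cluster carries most of the weight, mirroring "
      "the planted 80% retracted-state occupancy")
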