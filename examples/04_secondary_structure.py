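"""DSSP-style assignment and occupancy statistics on ideal fixtures.

Backbone H-bonds are scored with the Kabsch-Sander electrostatic energy;
helices, 3-10 helices, strands and turns follow from the bond pattern.
Occupancy answers questions like "what fraction of simulation time does
this region spend as a turn?".
"""
import numpy as np

from trajkit import (
    TwoStateSpec,
    assign_secondary_structure,
    build_ideal_helix,
    build_peptide,
    occupancy,
    simulate_two_state,
    ss_timeline,
)
from trajkit.synthetic import ALPHA_HELIX, BETA_STRAND, build_ideal_hairpin

for name, s in (
    ("alpha helix  ", build_ideal_helix(12)),
    ("3-10 helix   ", build_peptide([(-49.0, -26.0)] * 12)),
    ("beta hairpin ", build_ideal_hairpin(5)),
):
    _, codes = assign_secondary_structure(s)
    print(f"{name}: {''.join(codes)}")
print("codes: H alpha, G 3-10, E strand, B bridge, T turn, C coil\n")

# a helix/coil mixture: occupancy tracks the planted state fractions
helix = build_peptide([ALPHA_HELIX] * 10)
coil = build_peptide([BETA_STRAND] * 10)
traj = simulate_two_state(TwoStateSpec(helix, coil, occupancy_b=0.3, seed=4),
                          n_frames=1000)
tl = ss_timeline(traj)
interior = [("A", r) for r in range(3, 9)]
h_occ = occupancy(tl, interior, {"H"}, mode="per_residue_mean")
print(f"helix occupancy of interior residues: {h_occ:.1f}% "
      "(the planted helix-state fraction is 70%)")
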