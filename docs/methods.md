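# Methods

This note documents the models, conventions and numerical choices behind
trajkit, in the spirit of the methods documentation of mature simulation
and analysis packages: what is computed, under which assumptions, which
knobs matter, and what the validation on synthetic data does and does not
establish.

## Coordinate model and alignment

A trajectory is a fixed topology (ordered atoms with chain, author
residue numbering, element, mass and van der Waals radius) plus T frames
of N×3 coordinates in Å and a frame spacing in picoseconds (default
250 ps, a common frame-dump interval for microsecond-scale runs).
Analyses are preceded by removing global rigid motion: each frame is
superposed onto a reference frame (frame 0) by weighted least squares on
a fit selection — by default the backbone C, O, N, CA atoms of the kinase
chain — and the fitted transform is applied to *all* atoms, so the
substrate chain's motion is measured in the kinase's frame of reference.

Superposition uses the SVD form of the Kabsch solution with the standard
reflection correction (sign flip of the smallest singular direction), so
the rotation is always proper. Degenerate point sets (fewer than three
atoms, or rank < 2) are rejected rather than silently fitted.

Atomic masses come from the standard atomic-mass table; van der Waals
radii from one fixed Bondi-style set (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å) declared in a single place (`model_io.VDW_RADII`). Unknown
elements receive a documented default (12.011 amu, 1.70 Å) and a warning.
Altloc records keep the highest-occupancy conformer (tie → first seen).
Hydrogens are retained when present, but every analysis is well defined
on heavy-atom-only backbones.

## Fluctuations and covariance

Per-atom RMSF is `sqrt(⟨‖r − ⟨r⟩‖²⟩)` over frames of the aligned
trajectory. Per-residue RMSF is the mass-weighted mean of the residue's
selected atomic RMSF values; the combination rule matters only when the
selection mixes atom types, and it is fixed and stated rather than left
to a tool default.

The covariance of motions is computed per residue: the representative
displacement of residue i in frame t is the mass-weighted mean position
of its selected atoms minus the time average, and

    C(i,j) = ⟨Δr_i·Δr_j⟩ / sqrt(⟨‖Δr_i‖²⟩⟨‖Δr_j‖²⟩).

This scalar-product normalization bounds C in [−1, 1] with unit diagonal.
For CA-only selections the mass weighting cancels. Whether to use all
heavy atoms or CA only is a genuine convention choice among MD covariance
tools; the pipeline uses CA and echoes the convention in its settings
block. A residue with zero variance (possible in synthetic data) gets a
zeroed row/column, diagonal 1, and a warning rather than NaNs. Partners
with |C| ≥ 0.75 are labelled highly significant, the conventional
threshold for "strong" correlated motion.

## Secondary structure

The assigner is DSSP-style because the Kabsch–Sander energy model is
fully published and therefore unit-testable:

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

with a bond when E < −0.5 kcal/mol. Amide hydrogens are reconstructed at
1.01 Å from N, anti to the bisector of the N→C(prev) and N→CA directions;
the first residue of a chain (no i−1 carbonyl) and prolines donate
nothing. From the bond pattern: two consecutive n-turns start a helix
(n = 4 → H, 3 → G, 5 → I), bridge ladders give E and isolated bridges B,
turn interiors and CA-path bends above 70° give T, the rest is C, with
priority H > E > B > G > I > T > C. Bonds are evaluated within chains;
inter-chain sheets are not assigned (none of the shipped analyses need
them). Note this is an independent re-implementation choice, not a clone
of any particular viewer's assigner (STRIDE-based tools will differ at
helix caps and marginal turns); the assignment metadata names the
algorithm.

Occupancy statistics come in two modes, both reported: `per_residue_mean`
(mean over residues of the per-residue fraction of frames in the code
set) and `all_residues` (fraction of frames in which *every* listed
residue is in the code set). Statements like "the region is a turn X% of
the time" default to `per_residue_mean`.

## Surface areas

SASA is Shrake–Rupley quadrature: points on a deterministic Fibonacci
(golden-angle) lattice over each atom's solvent sphere of radius
r_vdw + probe (probe 1.4 Å), a point being occluded when it lies inside
any neighbour's solvent sphere. The lattice has no RNG, so results are
bit-reproducible; 960 points per atom keeps the quadrature error under
~0.5% (doubling the count moves totals by less than that) and ~1% against
the isolated-sphere closed form. A KD-tree restricts occlusion tests to
neighbours within reach; this is exact, not approximate. Buried surface
area of a two-chain complex is `(SASA_A + SASA_B − SASA_AB)/2` per frame,
clamped at 0 if quadrature noise drives it infinitesimally negative.
Waters and ions are excluded from the context at the file-reading stage,
the usual convention for protein SASA. "SASA of Ser65" means all atoms of
substrate-chain residue 65 in the context of the whole complex;
side-chain-only scope is available through the selection language.

## Hydrogen bonds

Geometric criteria: donor-heavy-atom to acceptor distance ≤ 3.5 Å plus,
when an explicit hydrogen is attached, a D–H⋯A deviation from linearity
≤ 30°. On heavy-atom-only data the distance criterion alone applies.
Upstream tools differ in their defaults and versions, so both cutoffs are
config keys and are echoed into every report. Donor/acceptor roles come
from a fixed chemistry table (backbone N donates except proline, backbone
O accepts, standard side-chain N/O roles); there is no pKa or tautomer
logic. Counts between two selections include both donation directions.

## Conformational metrics

Backbone dihedrals follow the IUPAC sign convention, in (−180, 180].
Terminal residues get an explicit "undefined" flag for the missing angle
instead of NaN, and collinear degeneracies raise an error. Ramachandran
proximity to a reference conformation uses a wrap-aware Euclidean metric
on the (φ, ψ) torus with a 30° default radius — an artifact convention
(reference figures show clouds and dots; the radius makes "the cloud sits
on the dot" quantitative). The retraction distance defaults to CA–CA
between the landmark residues (authors name residues, not atoms; the atom
choice is a config key echoed in reports). Moving averages use a centered
window of round(window/frame_dt) frames, forced odd, truncated
symmetrically at the series edges, so output length equals input length
and a constant series is exactly preserved; the default window is
5000 ps.

## QT clustering

The pairwise frame distance is the Kabsch-minimized RMSD over the
clustering selection (default: substrate-chain backbone — whether to
cluster on the substrate or the whole complex is another genuine
convention; it is a config key). The matrix is computed by a batched
formulation: per-pair 3×3 cross-covariances via BLAS matmuls and a
closed-form eigendecomposition of the Gram matrix, which is exactly the
per-pair Kabsch result (asserted in tests) and makes 5000-frame matrices
a matter of seconds. The batched expression cancels catastrophically for
near-identical frames, so entries below 1e-4 Å are recomputed with the
direct per-pair algorithm. Memory is quadratic in frames; a frame-stride
config key is the intended control for very long trajectories.

QT clustering commits, each round, the largest candidate cluster over all
unassigned seeds, where a candidate is every unassigned frame within the
RMSD cutoff *of the seed* (not a pairwise-diameter criterion — seed
semantics match common MD clustering practice and are echoed in the
result metadata). Ties break to the lowest seed index. The loop stops
when the largest candidate falls below the minimum cluster size (default
1% of all frames); leftovers are rejected, and a rejection rate above 5%
warns. The default cutoff is 1.75 Å. Partition invariants (disjointness,
exhaustiveness, cutoff satisfaction, frequencies + rejection = 1) are
asserted on every run. Cluster centers minimize the summed RMSD to their
cluster mates; centers are labelled by nearest reference structure
(common vs retracted substrate conformations) using Kabsch RMSD over
paired backbone atoms.

## Weighted energetics

The aggregate is exact arithmetic: total = Σ raw_i · freq_i, with
frequencies measured over *all* frames so rejected frames dilute the
total. The built-in per-cluster raw energy is a contact score,
E = −ε · #(inter-chain heavy-atom pairs ≤ 4.5 Å) with ε = 0.1 kcal/mol
per contact, evaluated on the cluster's center frame. This scorer is
deliberately non-physical — deterministic, monotone in interface size,
and sufficient to exercise the weighting logic; reproducing published
absolute ΔG values requires an external empirical force-field scorer,
whose per-cluster outputs can be supplied via a two-column TSV
(`energy_provider: file`).

## Synthetic data: what it emulates and what it does not

The generator produces exactly the statistical structure the analyses
consume, with ground truth recorded in trajectory metadata:

- **Ideal backbones** built by natural-extension (NeRF) from standard
  bond lengths/angles and per-residue (φ, ψ): helices (−57, −47), 3-10
  helices, strands (−135, 135), type II′ hairpins, and two-chain helical
  complexes at a controlled contact gap.
- **Fluctuation trajectories**: per-frame iid Gaussian residue-rigid
  displacements. The amplitude convention makes the planted value the
  residue's expected RMSF (per-axis σ = a/√3). Correlations are planted
  through a shared latent 3-vector per block, giving exactly the target
  normalized covariance (±1 exactly at |c| = 1); a residue may belong to
  one block, and the implied correlation matrix is verified positive
  semi-definite before sampling. Optional global rigid noise exercises
  the alignment stage.
- **Two-state mixtures**: frames drawn from two fixed conformers (iid or
  Markov "block" switching with a stated mean dwell) plus iid Gaussian
  jitter; realized occupancy and per-frame labels are recorded.
- **The study pair**: a 24-residue helical "kinase" (chain A, numbered
  from 400) bound to a 31-residue "substrate" (chain U, ubiquitin-like
  numbering 46–76) whose common pose has an extended C-terminal tail and
  whose retracted pose chains two tight turns (tail curls back ~10 Å,
  tail residues 73–75 become turns) and spins the substrate so residue 65
  faces solvent instead of the interface. The flexible trajectory mixes
  25% retracted state at 0.45 Å jitter; the stabilized one 80% at
  0.25 Å. Those four numbers plant the qualitative contrasts the
  comparison pipeline must reproduce: lower RMSF, higher retracted-like
  cluster frequency, shorter retraction distance, higher Ser65 exposure,
  higher tail-turn occupancy in the stabilized trajectory.

The generator makes no claim of physical realism: no force field,
thermostat, solvent, or temporal correlation (beyond block switching),
and Cartesian jitter is isotropic rather than along soft modes. Passing
the recovery tests therefore establishes that the *estimators* are
correct and unbiased under their own model assumptions — that RMSF
recovers planted amplitudes within sampling error, covariance recovers
planted correlations, QT frequencies and Ramachandran fractions recover
planted occupancies — not that any particular biological conclusion
drawn from real trajectories is right. One practical consequence of the
jitter model is worth knowing: dihedral-space metrics amplify Cartesian
noise, so Ramachandran proximity fractions are sharp at small jitter
(≤ ~0.1 Å) and blur toward the cloud at thermal-scale jitter, while
cluster frequencies remain exact as long as jitter ≪ cutoff.

## Problem sizes and determinism

The shipped validation uses 5000-frame trajectories of small (8–16
residue) systems for parameter recovery, 120–160-frame trajectories of
the 55-residue study-pair complex for the end-to-end comparison (with 240
sphere points for per-frame surface series), and 960 sphere points for
the geometry oracles — sizes chosen so the whole suite runs on a laptop
in a few minutes while keeping sampling error well inside the asserted
tolerances. Everything is deterministic: fixed seeds drive the
generators, the SASA lattice is seedless, and identical configs and
inputs produce byte-identical report files.

## Known limitations

- PDB only (multi-model for trajectories); no mmCIF or binary formats.
- No PCA/normal-mode analysis, no side-chain χ dihedrals, no salt-bridge
  or π-interaction detection, no analytic (LCPO-style) SASA.
- Secondary structure is intra-chain; no inter-chain sheet ladders, and
  no STRIDE-style refinements beyond the Kabsch–Sander pattern rules.
- The contact energy is a stand-in; absolute energetics require an
  external scorer through the file provider.
- The pairwise RMSD matrix is O(T²) in memory; use `frame_stride` for
  trajectories beyond ~10⁴ frames.
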