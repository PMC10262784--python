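# trajkit

Comparative molecular-dynamics trajectory analysis for kinase–substrate
complexes, built as a library with a thin command-line layer.

## The problem

A recurring question in structural studies of the mitochondrial kinase
PINK1 and its substrate ubiquitin is how a point mutation shifts the
conformational ensemble of the complex: does the kinase fold stabilize,
and does bound ubiquitin move toward its minor, C-terminally retracted
conformation (Ub-CR) that better exposes the phospho-acceptor Ser65?
Answering that from MD simulations requires a standard battery of
per-frame analyses applied identically to two trajectories and compared —
superposition and RMSD/RMSF, covariance of motions, secondary-structure
occupancy, solvent accessibility and buried interface area, hydrogen-bond
counts, Ramachandran and retraction-distance metrics, conformational
clustering, and cluster-weighted interaction energetics.

trajkit implements that battery as tested, reusable components for anyone
who needs to compare two MD ensembles of a two-chain complex, together
with a synthetic-data module that generates trajectories with *planted*
statistical properties so every analysis stage can be validated by
parameter recovery rather than by eyeballing plots.

## The statistics it computes

With frames aligned by weighted least-squares (Kabsch) superposition of a
fit selection onto the first frame:

- **RMSF** per atom: `sqrt(⟨‖r − ⟨r⟩‖²⟩)` over frames; per residue, the
  mass-weighted mean over the residue's selected atoms.
- **Covariance of motions**, mass-weighted and normalized:
  `C(i,j) = ⟨Δr_i·Δr_j⟩ / sqrt(⟨‖Δr_i‖²⟩⟨‖Δr_j‖²⟩) ∈ [−1, 1]`, where Δr_i
  is the mass-weighted mean displacement of residue i's selected atoms.
  Partners with `|C| ≥ 0.75` are reported as highly significant.
- **Secondary structure** per residue per frame, DSSP-style: backbone
  H-bonds scored by the Kabsch–Sander energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (bond if
  `E < −0.5`), then n-turn/ladder patterns → codes H, G, I, E, B, T, C;
  occupancy = percent of simulation time a region carries a code set.
- **SASA** by Shrake–Rupley quadrature (Fibonacci sphere lattice, probe
  1.4 Å) and **BSA** `= (SASA_A + SASA_B − SASA_AB)/2` per frame.
- **H-bond counts** between selections (donor–acceptor ≤ 3.5 Å, D–H⋯A
  within 30° of linear when hydrogens exist; both cutoffs configurable).
- **Ramachandran distributions** of a residue with wrap-aware proximity
  fractions to reference conformations; **retraction distance** between
  landmark residues (CA–CA for Ala46–Gly76 by default) with 5-ns moving
  averages.
- **QT clustering** on a pairwise Kabsch-RMSD matrix (cutoff 1.75 Å to the
  candidate seed, minimum cluster ≈ 1% of frames, rejection warning above
  5%), centers labelled by nearest reference structure.
- **Weighted energetics**: per-cluster interaction energy of the center
  frame times the cluster's fraction of all frames, summed. The built-in
  scorer is a deliberately non-physical contact count (−ε per inter-chain
  heavy-atom pair within 4.5 Å); per-cluster energies from an external
  force-field scorer can be supplied as a TSV instead.

## Worked example

`examples/07_full_comparison.py` generates the packaged synthetic study
pair — a "flexible" trajectory (minor retracted population, large thermal
jitter) and a "stabilized" one (dominant retracted population, small
jitter) — and runs the full comparison:

```text
== wt ==
  mean substrate RMSF          2.94 A
  tail turn occupancy          13.7 %
  CR-like cluster freq         0.26
  mean Ser65 SASA              24.8 A^2
  mean 46-76 distance          43.7 A
  weighted dG                 -4.98 kcal/mol
== variant ==
  mean substrate RMSF          2.79 A
  tail turn occupancy          32.5 %
  CR-like cluster freq         0.75
  mean Ser65 SASA              42.9 A^2
  mean 46-76 distance          38.4 A
  weighted dG                 -4.33 kcal/mol
```

Reading the deltas: the stabilized trajectory fluctuates less (lower
RMSF), its substrate tail spends more time in turns and sits ~5 Å more
retracted (shorter 46–76 distance), its Ser65 analog is ~18 Å² more
solvent-exposed, and three quarters of its frames cluster with the
retracted reference — exactly the contrasts planted by the generator.
The other examples (`examples/01…06`) each exercise one capability with
the numbers it prints explained inline.

The same pipeline runs from the shell:

```bash
trajkit generate --outdir study --seed 1 --frames 160
trajkit compare study/config.yaml --out study/report
trajkit report study/report/summary.json
```

## Selection mini-language

Selections combine clauses with `and`, `or`, `not` and parentheses:

```text
expr    := term ("or" term)*
term    := factor ("and" factor)*
factor  := "(" expr ")" | "not" factor | clause
clause  := "chain" ID | "resid" RANGE[,RANGE...] | "name" NAME+
           | "backbone" | "all"
```

`backbone` expands to atom names N, CA, C, O; residue ranges are
inclusive author numbering (`resid 46-76`, `resid 65`). Resolution is
deterministic and indices come back in topology order; an expression that
matches nothing is an error, never a silent empty set.

## File formats

Reference structures are single-model PDB files; trajectories are
multi-model PDB files (MODEL/ENDMDL), the interchange format desktop MD
viewers export. HETATM waters/ions are filtered on read by default.
Binary trajectory formats (DCD/XTC) are out of scope; `read_pdb` is the
adapter point where such readers would plug in.

## Layout

- `src/trajkit/model_io.py` — structures, trajectories, multi-model PDB
  I/O, selection language
- `src/trajkit/synthetic.py` — ideal backbones, planted-statistics
  trajectory generators, the packaged study pair
- `src/trajkit/dynamics.py` — Kabsch superposition, alignment, RMSD/RMSF,
  covariance
- `src/trajkit/surface.py` — Shrake–Rupley SASA, buried surface area
- `src/trajkit/secstruct.py` — Kabsch–Sander secondary structure,
  occupancy
- `src/trajkit/hbonds.py` — geometric hydrogen-bond detection/counting
- `src/trajkit/conformation.py` — dihedrals, Ramachandran, distances,
  moving averages
- `src/trajkit/clustering.py` — pairwise RMSD matrix, QT clustering,
  reference labelling
- `src/trajkit/energetics.py` — contact scoring, frequency-weighted totals
- `src/trajkit/pipeline.py`, `src/trajkit/cli.py` — config-driven
  orchestration and the `trajkit` command

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
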