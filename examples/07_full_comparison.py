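"""The full two-trajectory comparison pipeline, end to end.

Generates the packaged synthetic study pair (a flexible wild-type-like
complex vs a stabilized variant-like one), writes it to disk, runs the
config-driven comparison and prints the deltas. Every planted contrast —
lower substrate RMSF, higher retracted-state cluster frequency, shorter
retraction distance, more exposed phospho-acceptor residue, higher tail
turn occupancy — appears with the expected sign.
"""
import tempfile
from pathlib import Path

import yaml

from trajkit import run_analysis, validate_config, write_pdb
from trajkit.synthetic import make_study_pair

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    pair = make_study_pair(seed=1, n_frames=80)
    write_pdb(pair.wt, tmp / "wt.pdb")
    write_pdb(pair.variant, tmp / "variant.pdb")
    write_pdb(pair.references["common"], tmp / "ref_common.pdb")
    write_pdb(pair.references["CR"], tmp / "ref_cr.pdb")
    (tmp / "config.yaml").write_text(yaml.safe_dump({
        "trajectories": [str(tmp / "wt.pdb"), str(tmp / "variant.pdb")],
        "labels": ["wt", "variant"],
        "reference_common": str(tmp / "ref_common.pdb"),
        "reference_cr": str(tmp / "ref_cr.pdb"),
        "rama_residue": 72,
        "n_sphere_points": 240,
    }))
    config = validate_config(tmp / "config.yaml")
    report = run_analysis(config, outdir=tmp / "report")

    for res in report.results:
        s = res.summary()
        print(f"== {s['label']} ==")
        print(f"  mean substrate RMSF      {s['mean_rmsf_substrate']:8.2f} A")
        print(f"  tail turn occupancy      {s['turn_occupancy_mean_pct']:8.1f} %")
        print(f"  CR-like cluster freq     {s['cr_like_frequency']:8.2f}")
        print(f"  mean Ser65 SASA          {s['mean_sasa_s65']:8.1f} A^2")
        print(f"  mean 46-76 distance      {s['mean_retraction_distance']:8.1f} A")
        print(f"  weighted dG              {s['weighted_dg_total']:8.2f} kcal/mol")
    print("== deltas (variant - wt) ==")
    for key, val in report.deltas.items():
        print(f"  {key:35s} {val:+.3f}")
    print("\nreport files (TSV tables + summary.json) were written alongside "
          "the inputs; the same pipeline runs from the shell via "
          "`trajkit compare config.yaml`")
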