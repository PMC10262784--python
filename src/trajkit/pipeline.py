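"""Config-driven orchestration: analyze one trajectory or compare two.

The full analytical sequence mirrors how a comparative MD study of a
kinase-substrate complex is reported: load and align, RMSD/RMSF/covariance,
secondary-structure occupancy, SASA of the substrate phospho-acceptor
residue, buried surface area, the retraction distance with its moving
average, inter-selection hydrogen-bond counts, QT conformational clustering
with reference labelling, and cluster-frequency-weighted interaction
energetics. Every numeric setting is echoed in the report together with
its provenance label ("published" for defaults taken from the study
design this pipeline emulates, "convention" for artifact defaults), so a
report is always self-describing.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustering, conformation, dynamics, energetics, hbonds, secstruct, surface
from .errors import ConfigError, TrajkitError
from .model_io import (
    Selection,
    Structure,
    Trajectory,
    assign_masses_radii,
    read_pdb,
    resolve_selection,
)

log = logging.getLogger("trajkit")

# key -> (default, provenance, type)
_SCHEMA: dict[str, tuple[Any, str, type]] = {
    "trajectories": (None, "input", list),
    "labels": (None, "input", list),
    "kinase_chain": ("A", "convention", str),
    "substrate_chain": ("U", "convention", str),
    "fit_selection": (None, "published", str),  # default derived from kinase chain
    "loop3_selection": (None, "convention", str),
    "substrate_residue": (65, "published", int),
    "retraction_residues": ([46, 76], "published", list),
    "retraction_atom": ("CA", "convention", str),
    "clustering_selection": (None, "convention", str),
    "rama_residue": (10, "published", int),
    "turn_region": ([73, 76], "published", list),
    "probe_radius": (1.4, "published", float),
    "n_sphere_points": (960, "convention", int),
    "qt_cutoff": (1.75, "published", float),
    "min_cluster_frac": (0.01, "published", float),
    "hbond_distance": (3.5, "convention", float),
    "hbond_angle_dev": (30.0, "convention", float),
    "covariance_threshold": (0.75, "published", float),
    "moving_average_ps": (5000.0, "published", float),
    "frame_dt": (250.0, "published", float),
    "frame_stride": (1, "convention", int),
    "reference_common": (None, "input", str),
    "reference_cr": (None, "input", str),
    "rama_near_radius": (30.0, "convention", float),
    "contact_epsilon": (0.1, "convention", float),
    "contact_cutoff": (4.5, "convention", float),
    "energy_provider": ("contact", "convention", str),
    "raw_energies_tsv": (None, "input", str),
    "seed": (0, "convention", int),
}


@dataclass
class RunConfig:
    """Validated, fully-resolved run settings. See module docstring."""

    trajectories: list[str]
    labels: list[str]
    kinase_chain: str = "A"
    substrate_chain: str = "U"
    fit_selection: str = ""
    loop3_selection: str = ""
    substrate_residue: int = 65
    retraction_residues: tuple[int, int] = (46, 76)
    retraction_atom: str = "CA"
    clustering_selection: str = ""
    rama_residue: int = 10
    turn_region: tuple[int, int] = (73, 76)
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    qt_cutoff: float = 1.75
    min_cluster_frac: float = 0.01
    hbond_distance: float = 3.5
    hbond_angle_dev: float = 30.0
    covariance_threshold: float = 0.75
    moving_average_ps: float = 5000.0
    frame_dt: float = 250.0
    frame_stride: int = 1
    reference_common: str | None = None
    reference_cr: str | None = None
    rama_near_radius: float = 30.0
    contact_epsilon: float = 0.1
    contact_cutoff: float = 4.5
    energy_provider: str = "contact"
    raw_energies_tsv: str | None = None
    seed: int = 0

    def settings_echo(self) -> dict:
        """Settings with provenance labels, embedded in every report."""
        out = {}
        d = asdict(self)
        for key, (_, provenance, _t) in _SCHEMA.items():
            out[key] = {"value": d[key], "source": provenance}
        return out


def _resolve_defaults(cfg: RunConfig) -> RunConfig:
    if not cfg.fit_selection:
        cfg.fit_selection = f"chain {cfg.kinase_chain} and backbone"
    if not cfg.loop3_selection:
        cfg.loop3_selection = f"chain {cfg.kinase_chain} and backbone"
    if not cfg.clustering_selection:
        cfg.clustering_selection = f"chain {cfg.substrate_chain} and backbone"
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML config; aggregate all problems.

    Unknown keys are rejected (typo safety); referenced files must exist.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: unparsable YAML: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    for key in raw:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    values: dict[str, Any] = {}
    for key, (default, _prov, typ) in _SCHEMA.items():
        if key in raw and raw[key] is not None:
            v = raw[key]
            if typ in (float, int) and isinstance(v, (int, float)):
                v = typ(v)
            elif not isinstance(v, typ):
                errors.append(f"key {key!r}: expected {typ.__name__}, got {type(v).__name__}")
                continue
            values[key] = v
        elif default is not None:
            values[key] = default
    if "trajectories" not in values or not values.get("trajectories"):
        errors.append("at least one trajectory path is required")
    else:
        for p in values["trajectories"]:
            if not Path(p).exists():
                errors.append(f"trajectory path {p!r} does not exist")
    if "labels" not in values and "trajectories" in values:
        values["labels"] = [
            Path(p).stem for p in values.get("trajectories", [])
        ]
    for key in ("reference_common", "reference_cr", "raw_energies_tsv"):
        p = values.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} path {p!r} does not exist")
    for key in ("probe_radius", "qt_cutoff", "hbond_distance", "frame_dt",
                "moving_average_ps", "contact_cutoff"):
        if key in values and values[key] <= 0:
            errors.append(f"{key} must be positive")
    if "min_cluster_frac" in values and not (0 <= values["min_cluster_frac"] <= 1):
        errors.append("min_cluster_frac must be in [0, 1]")
    if "frame_stride" in values and values["frame_stride"] < 1:
        errors.append("frame_stride must be >= 1")
    if errors:
        raise ConfigError(
            f"{path}: invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    retr = values.get("retraction_residues", [46, 76])
    values["retraction_residues"] = (int(retr[0]), int(retr[1]))
    turn = values.get("turn_region", [73, 76])
    values["turn_region"] = (int(turn[0]), int(turn[1]))
    cfg = RunConfig(**values)
    return _resolve_defaults(cfg)


@dataclass
class TrajectoryResult:
    """Per-trajectory analysis bundle (one column of the comparison)."""

    label: str
    n_frames: int
    rmsd: np.ndarray
    rmsf_kinase: dynamics.RMSFProfile
    rmsf_substrate: dynamics.RMSFProfile
    covariance: dynamics.CovarianceMatrix
    ss: secstruct.SSTimeline
    turn_occupancy_mean: float
    turn_occupancy_all: float
    sasa_s65: np.ndarray
    sasa_s65_smoothed: np.ndarray
    bsa: surface.BSASeries
    retraction: conformation.DistanceSeries
    retraction_smoothed: np.ndarray
    hbond_counts: np.ndarray
    rama: conformation.RamaDistribution | None
    clusters: clustering.ClusterSet
    cluster_labels: list[dict]
    energy: energetics.WeightedEnergyReport

    def summary(self) -> dict:
        cr_freq = sum(
            rec["frequency"] for rec in self.cluster_labels if rec["label"] == "CR"
        )
        return {
            "label": self.label,
            "n_frames": self.n_frames,
            "mean_rmsd": float(np.mean(self.rmsd)),
            "mean_rmsf_kinase": float(np.mean(self.rmsf_kinase.values)),
            "mean_rmsf_substrate": float(np.mean(self.rmsf_substrate.values)),
            "turn_occupancy_mean_pct": self.turn_occupancy_mean,
            "turn_occupancy_all_pct": self.turn_occupancy_all,
            "mean_sasa_s65": float(np.mean(self.sasa_s65)),
            "mean_bsa": float(np.mean(self.bsa.values)),
            "mean_retraction_distance": float(np.mean(self.retraction.values)),
            "mean_hbond_count": float(np.mean(self.hbond_counts)),
            "n_clusters": len(self.clusters.clusters),
            "rejection_rate": self.clusters.rejection_rate,
            "cr_like_frequency": float(cr_freq),
            "rama_near_fractions": dict(self.rama.near_fractions) if self.rama else {},
            "weighted_dg_total": self.energy.total,
        }


@dataclass
class ComparisonReport:
    results: list[TrajectoryResult]
    deltas: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "trajectories": [r.summary() for r in self.results],
            "deltas": self.deltas,
            "settings": self.settings,
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise TrajkitError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _load_trajectory(path: str, cfg: RunConfig) -> Trajectory:
    obj = read_pdb(path, frame_dt=cfg.frame_dt)
    if isinstance(obj, Structure):
        raise TrajkitError(f"{path} holds a single model, not a trajectory")
    if cfg.frame_stride > 1:
        obj = Trajectory(
            obj.topology, obj.frames[:: cfg.frame_stride],
            cfg.frame_dt * cfg.frame_stride, dict(obj.metadata),
        )
    obj.topology.atoms = assign_masses_radii(obj.topology).atoms
    return obj


def analyze_trajectory(
    traj: Trajectory,
    cfg: RunConfig,
    label: str = "traj",
    references: dict[str, Structure] | None = None,
) -> TrajectoryResult:
    """Run the full single-trajectory analysis sequence."""
    top = traj.topology
    fit = resolve_selection(top, cfg.fit_selection)
    kin_bb = resolve_selection(top, f"chain {cfg.kinase_chain} and backbone")
    sub_bb = resolve_selection(top, f"chain {cfg.substrate_chain} and backbone")
    sub_all = resolve_selection(top, f"chain {cfg.substrate_chain}")
    kin_all = resolve_selection(top, f"chain {cfg.kinase_chain}")
    s65 = resolve_selection(
        top, f"chain {cfg.substrate_chain} and resid {cfg.substrate_residue}"
    )
    clus_sel = resolve_selection(top, cfg.clustering_selection)
    loop3 = resolve_selection(top, cfg.loop3_selection)

    aligned = _stage("align")(dynamics.align_trajectory)(traj, fit, 0)
    rmsd = _stage("rmsd")(dynamics.rmsd_series)(aligned, fit, 0, False)
    rmsf_k = _stage("rmsf")(dynamics.rmsf_profile)(aligned, kin_bb)
    rmsf_s = dynamics.rmsf_profile(aligned, sub_bb)
    ca_sel = resolve_selection(top, "name CA")
    cov = _stage("covariance")(dynamics.covariance_matrix)(aligned, ca_sel)

    ss = _stage("secondary_structure")(secstruct.ss_timeline)(aligned)
    turn_res = [
        (cfg.substrate_chain, r)
        for r in range(cfg.turn_region[0], cfg.turn_region[1] + 1)
    ]
    occ_mean = secstruct.occupancy(ss, turn_res, {"T"}, "per_residue_mean")
    occ_all = secstruct.occupancy(ss, turn_res, {"T"}, "all_residues")

    sasa = _stage("sasa")(surface.sasa_series)(
        aligned, s65, None, cfg.probe_radius, cfg.n_sphere_points
    )
    sasa_smooth = conformation.moving_average(
        sasa, cfg.moving_average_ps, aligned.frame_dt
    )
    bsa = _stage("bsa")(surface.buried_surface_area)(
        aligned, kin_all, sub_all, cfg.probe_radius, cfg.n_sphere_points
    )
    retr = _stage("retraction")(conformation.distance_series)(
        aligned,
        (cfg.substrate_chain, cfg.retraction_residues[0], cfg.retraction_atom),
        (cfg.substrate_chain, cfg.retraction_residues[1], cfg.retraction_atom),
    )
    retr_smooth = conformation.moving_average(
        retr.values, cfg.moving_average_ps, aligned.frame_dt
    )
    crit = hbonds.HBondCriteria(cfg.hbond_distance, cfg.hbond_angle_dev)
    hb = _stage("hbonds")(hbonds.hbond_count_series)(aligned, loop3, sub_all, crit)

    rama = None
    ref_list = [(lab, ref) for lab, ref in (references or {}).items()]
    try:
        rama = _stage("ramachandran")(conformation.rama_distribution)(
            aligned, cfg.substrate_chain, cfg.rama_residue,
            ref_list, cfg.rama_near_radius,
        )
    except TrajkitError:
        log.warning("Ramachandran residue %s not assignable; skipped", cfg.rama_residue)

    matrix = _stage("pairwise_rmsd")(clustering.pairwise_rmsd_matrix)(aligned, clus_sel)
    cs = _stage("qt_cluster")(clustering.qt_cluster)(
        matrix, cfg.qt_cutoff, cfg.min_cluster_frac
    )
    labels = (
        clustering.label_clusters(
            aligned, cs, references, chain=cfg.substrate_chain
        )
        if references
        else [
            {"cluster": k, "center_frame": c.center, "frequency": c.frequency,
             "rmsd_to": {}, "label": None}
            for k, c in enumerate(cs.clusters)
        ]
    )

    if cfg.energy_provider == "file":
        if not cfg.raw_energies_tsv:
            raise TrajkitError("energy_provider 'file' requires raw_energies_tsv")
        table = energetics.read_raw_energies_tsv(cfg.raw_energies_tsv)
        raw = [table[k] for k in range(len(cs.clusters))]
        provider = f"file:{cfg.raw_energies_tsv}"
    else:
        raw = [
            energetics.contact_interaction_energy(
                aligned.frame(c.center), kin_all, sub_all,
                cfg.contact_epsilon, cfg.contact_cutoff,
            )
            for c in cs.clusters
        ]
        provider = "contact"
    energy = energetics.weighted_interaction_score(
        raw, cs.frequencies(), provider=provider
    )

    return TrajectoryResult(
        label=label, n_frames=aligned.n_frames, rmsd=rmsd,
        rmsf_kinase=rmsf_k, rmsf_substrate=rmsf_s, covariance=cov, ss=ss,
        turn_occupancy_mean=occ_mean, turn_occupancy_all=occ_all,
        sasa_s65=sasa, sasa_s65_smoothed=sasa_smooth, bsa=bsa,
        retraction=retr, retraction_smoothed=retr_smooth, hbond_counts=hb,
        rama=rama, clusters=cs, cluster_labels=labels, energy=energy,
    )


def run_analysis(
    config: RunConfig, outdir: str | Path | None = None
) -> ComparisonReport:
    """Analyze one trajectory or compare two, per the validated config.

    Deterministic for fixed config and inputs. On a stage failure, a
    FAILED marker naming the stage is flushed to ``outdir`` (when given)
    before the error propagates.
    """
    references: dict[str, Structure] = {}
    if config.reference_common:
        references["common"] = assign_masses_radii(
            _as_structure(read_pdb(config.reference_common))
        )
    if config.reference_cr:
        references["CR"] = assign_masses_radii(
            _as_structure(read_pdb(config.reference_cr))
        )
    results: list[TrajectoryResult] = []
    try:
        for path, label in zip(config.trajectories, config.labels):
            log.info("analyzing %s (%s)", label, path)
            traj = _load_trajectory(path, config)
            results.append(
                analyze_trajectory(traj, config, label, references or None)
            )
    except Exception as exc:
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text(f"{exc}\n")
        raise

    deltas: dict = {}
    if len(results) == 2:
        a, b = results[0].summary(), results[1].summary()
        for key in (
            "mean_rmsf_kinase", "mean_rmsf_substrate", "turn_occupancy_mean_pct",
            "turn_occupancy_all_pct", "mean_sasa_s65", "mean_bsa",
            "mean_retraction_distance", "mean_hbond_count",
            "cr_like_frequency", "weighted_dg_total",
        ):
            deltas[f"delta_{key}"] = b[key] - a[key]
    report = ComparisonReport(
        results=results, deltas=deltas, settings=config.settings_echo()
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def _as_structure(obj: Structure | Trajectory) -> Structure:
    if isinstance(obj, Trajectory):
        return obj.frame(0)
    return obj


def write_report(report: ComparisonReport, outdir: str | Path) -> None:
    """Serialize the report: per-trajectory TSV tables plus summary.json.

    Output is byte-identical across runs with the same config and inputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"
    for r in report.results:
        tag = r.label
        pd.DataFrame({
            "residue": [f"{c}:{i}" for c, i in r.rmsf_substrate.labels],
            "rmsf_A": r.rmsf_substrate.values,
        }).to_csv(out / f"{tag}_rmsf_substrate.tsv", sep="\t", index=False,
                  float_format=ff)
        pd.DataFrame({
            "residue": [f"{c}:{i}" for c, i in r.rmsf_kinase.labels],
            "rmsf_A": r.rmsf_kinase.values,
        }).to_csv(out / f"{tag}_rmsf_kinase.tsv", sep="\t", index=False,
                  float_format=ff)
        cov_df = pd.DataFrame(
            r.covariance.values,
            index=[f"{c}:{i}" for c, i in r.covariance.labels],
            columns=[f"{c}:{i}" for c, i in r.covariance.labels],
        )
        cov_df.to_csv(out / f"{tag}_covariance.tsv", sep="\t", float_format=ff)
        pd.DataFrame(
            r.ss.codes,
            columns=[f"{c}:{i}" for c, i in r.ss.labels],
        ).to_csv(out / f"{tag}_ss_timeline.tsv", sep="\t", index_label="frame")
        pd.DataFrame({
            "frame": np.arange(r.n_frames),
            "rmsd_A": r.rmsd,
            "sasa_s65_A2": r.sasa_s65,
            "sasa_s65_smoothed_A2": r.sasa_s65_smoothed,
            "bsa_A2": r.bsa.values,
            "retraction_A": r.retraction.values,
            "retraction_smoothed_A": r.retraction_smoothed,
            "hbond_count": r.hbond_counts,
        }).to_csv(out / f"{tag}_series.tsv", sep="\t", index=False, float_format=ff)
        rows = []
        for rec, c in zip(r.cluster_labels, r.clusters.clusters):
            row = {
                "cluster": rec["cluster"],
                "size": len(c.members),
                "frequency": c.frequency,
                "center_frame": rec["center_frame"],
                "label": rec["label"],
            }
            for lab, v in rec["rmsd_to"].items():
                row[f"rmsd_to_{lab}_A"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / f"{tag}_clusters.tsv", sep="\t",
                                  index=False, float_format=ff)
        pd.DataFrame({
            "cluster": np.arange(len(r.energy.raw)),
            "frequency_pct": r.energy.frequencies * 100.0,
            "raw_dg_kcal_mol": r.energy.raw,
            "weighted_dg_kcal_mol": r.energy.weighted,
        }).to_csv(out / f"{tag}_energetics.tsv", sep="\t", index=False,
                  float_format=ff)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
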