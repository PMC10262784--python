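"""Structures, trajectories, multi-model PDB I/O and the selection language.

The on-disk formats are deliberately minimal: single-model PDB files for
reference structures and MODEL/ENDMDL multi-model PDB files for trajectory
frames, which is how desktop MD viewers exchange frame dumps. Binary
trajectory formats (DCD/XTC) are out of scope; :func:`read_pdb` is the
adapter point where such readers would plug in.

Selection mini-language (documented in the README)::

    expr     := term ("or" term)*
    term     := factor ("and" factor)*
    factor   := "(" expr ")" | "not" factor | clause
    clause   := "chain" ID | "resid" RANGE[,RANGE...] | "name" NAME+
                | "backbone" | "all"

``backbone`` expands to atom names N, CA, C, O. Residue ranges are
inclusive author numbering, e.g. ``resid 46-76`` or ``resid 65``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    PDBFormatError,
    SelectionError,
    TopologyMismatchError,
    TrajkitError,
)

# Standard atomic masses (amu) for elements that occur in protein PDB files.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "NA": 22.990, "MG": 24.305, "K": 39.098,
    "CL": 35.45, "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546,
    "CA": 40.078,
}

# Fixed Bondi-style van der Waals radii (Angstrom); one documented table
# used by every surface-area computation in the package.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
}
DEFAULT_VDW_RADIUS = 1.70  # applied to unknown elements, with a warning
DEFAULT_MASS = 12.011

# HETATM residue names filtered out by default (solvent and common ions).
WATER_ION_RESNAMES = {
    "HOH", "WAT", "TIP", "TIP3", "TIP4", "SOL", "SPC", "DOD",
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "BR", "IOD",
    "SO4", "PO4", "NO3",
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "SE", "NA", "MG", "ZN", "FE", "MN", "CU"}

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """One atom of a topology; coordinates live in Structure/Trajectory."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_index: int  # author numbering from the PDB file
    chain_id: str
    mass: float | None = None
    vdw_radius: float | None = None
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class Structure:
    """An ordered atom list with a single coordinate set (Angstrom)."""

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise TrajkitError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if len(self.atoms) and not np.all(np.isfinite(self.coords)):
            raise TrajkitError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure([replace(a) for a in self.atoms], self.coords.copy())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.asarray(coords, dtype=float).copy())

    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id)
        return list(seen)

    def atom_indices_by_residue(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def find_atom(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_index == residue_index
                and a.atom_name == atom_name
            ):
                return i
        raise TrajkitError(
            f"atom {atom_name} of residue {chain_id}:{residue_index} not found"
        )

    def masses(self) -> np.ndarray:
        m = np.array([a.mass if a.mass is not None else np.nan for a in self.atoms])
        if np.any(np.isnan(m)):
            raise TrajkitError("masses not assigned; call assign_masses_radii first")
        return m

    def vdw_radii(self) -> np.ndarray:
        r = np.array(
            [a.vdw_radius if a.vdw_radius is not None else np.nan for a in self.atoms]
        )
        if np.any(np.isnan(r)):
            raise TrajkitError("radii not assigned; call assign_masses_radii first")
        return r


@dataclass
class Trajectory:
    """T frames of the same topology; frame spacing in picoseconds."""

    topology: Structure
    frames: np.ndarray  # (T, N, 3) Angstrom
    frame_dt: float = 250.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise TrajkitError(
                f"frame array shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.frames.shape[0] < 1:
            raise TrajkitError("trajectory must contain at least one frame")
        if self.frame_dt <= 0:
            raise TrajkitError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def iter_frames(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.topology.copy(), self.frames.copy(), self.frame_dt,
            dict(self.metadata),
        )


@dataclass(frozen=True)
class Selection:
    """A resolved, ordered atom-index set over a fixed topology."""

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise SelectionError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        return ""
    two = name[:2].upper()
    resname = residue_name.strip().upper()
    # Monatomic ions are named after their element (CA the calcium ion vs
    # CA the alpha-carbon); selenium in selenomethionine is atom 'SE'.
    if two in _TWO_LETTER_ELEMENTS and (resname == two or name.upper() == "SE"):
        return two
    return name[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(b_field) if b_field else 0.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: unparsable PDB record field ({exc})")
    if not element:
        element = _infer_element(atom_name, residue_name)
    rec = AtomRecord(
        serial=serial,
        atom_name=atom_name,
        element=element,
        residue_name=residue_name,
        residue_index=residue_index,
        chain_id=chain_id,
        occupancy=occupancy,
        bfactor=bfactor,
    )
    return rec, np.array([x, y, z]), altloc


def _dedupe_altlocs(
    records: list[AtomRecord], coords: list[np.ndarray], altlocs: list[str]
) -> tuple[list[AtomRecord], list[np.ndarray]]:
    """Keep the highest-occupancy alternate conformer (tie: first seen)."""
    best: dict[tuple, int] = {}
    for i, (rec, alt) in enumerate(zip(records, altlocs)):
        key = (rec.chain_id, rec.residue_index, rec.residue_name, rec.atom_name)
        if key not in best:
            best[key] = i
        elif alt and records[best[key]].occupancy < rec.occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [records[i] for i in keep], [coords[i] for i in keep]


def read_pdb(
    path: str | Path,
    exclude_waters: bool = True,
    frame_dt: float = 250.0,
) -> Structure | Trajectory:
    """Read a PDB file; multi-model files become a :class:`Trajectory`.

    Parameters
    ----------
    path:
        PDB file with fixed-column ATOM/HETATM records; MODEL/ENDMDL
        delimit trajectory frames.
    exclude_waters:
        Drop HETATM water/ion records (default). Protein atom order is
        never affected by the filter.
    frame_dt:
        Frame spacing (psec) attached to multi-model files.
    """
    path = Path(path)
    models: list[tuple[list[AtomRecord], list[np.ndarray], list[str]]] = []
    current: tuple[list, list, list] | None = None
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec_type = line[:6].strip()
            if rec_type == "MODEL":
                saw_model_record = True
                current = ([], [], [])
                models.append(current)
            elif rec_type == "ENDMDL":
                current = None
            elif rec_type in ("ATOM", "HETATM"):
                rec, xyz, alt = _parse_atom_line(line, lineno)
                if (
                    rec_type == "HETATM"
                    and exclude_waters
                    and rec.residue_name.upper() in WATER_ION_RESNAMES
                ):
                    continue
                if current is None:
                    if saw_model_record:
                        # stray atoms between models; treat as format error
                        raise PDBFormatError(
                            f"line {lineno}: ATOM record outside MODEL/ENDMDL block"
                        )
                    current = ([], [], [])
                    models.append(current)
                current[0].append(rec)
                current[1].append(xyz)
                current[2].append(alt)

    models = [m for m in models if m[0]]
    if not models:
        raise PDBFormatError(f"{path}: no ATOM records found")

    deduped = [_dedupe_altlocs(*m) for m in models]
    first_atoms, first_coords = deduped[0]
    first_key = [
        (a.chain_id, a.residue_index, a.atom_name) for a in first_atoms
    ]
    for model_no, (atoms, _) in enumerate(deduped[1:], start=2):
        key = [(a.chain_id, a.residue_index, a.atom_name) for a in atoms]
        if key != first_key:
            raise TopologyMismatchError(
                f"model {model_no} has {len(atoms)} atoms and does not match "
                f"model 1 ({len(first_atoms)} atoms) in atom identity/order"
            )

    topology = Structure(first_atoms, np.array(first_coords))
    if len(deduped) == 1:
        return topology
    frames = np.array([np.array(c) for _, c in deduped])
    return Trajectory(topology, frames, frame_dt=frame_dt, metadata={"source": str(path)})


def _format_atom_line(rec: AtomRecord, xyz: np.ndarray) -> str:
    name = rec.atom_name
    # PDB convention: 1-letter element names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 and len(rec.element) < 2 else f"{name:<4s}"
    return (
        f"ATOM  {rec.serial % 100000:>5d} {name_field}{'':1s}{rec.residue_name:>3s} "
        f"{rec.chain_id:1s}{rec.residue_index:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{rec.occupancy:6.2f}{rec.bfactor:6.2f}          {rec.element:>2s}\n"
    )


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks).

    Round-trips through :func:`read_pdb` at PDB precision (1e-3 Angstrom).
    """
    path = Path(path)
    if isinstance(obj, Structure):
        if obj.n_atoms == 0:
            raise TrajkitError("refusing to write an empty structure")
        frames = obj.coords[None]
        topology = obj
    else:
        topology = obj.topology
        if topology.n_atoms == 0:
            raise TrajkitError("refusing to write an empty trajectory")
        frames = obj.frames
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for f in range(frames.shape[0]):
            if multi:
                fh.write(f"MODEL     {f + 1:>4d}\n")
            for rec, xyz in zip(topology.atoms, frames[f]):
                if rec.residue_index > 9999 or rec.residue_index < -999:
                    raise TrajkitError(
                        f"residue index {rec.residue_index} overflows PDB columns"
                    )
                fh.write(_format_atom_line(rec, xyz))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def assign_masses_radii(structure: Structure) -> Structure:
    """Return a copy with atomic masses and vdW radii filled in.

    Masses come from the standard atomic-mass table, radii from the fixed
    Bondi-style set in :data:`VDW_RADII`. Unknown elements receive the
    documented defaults and raise a warning.
    """
    if structure.n_atoms == 0:
        raise TrajkitError("cannot assign masses/radii on an empty structure")
    out = structure.copy()
    unknown: set[str] = set()
    for a in out.atoms:
        el = a.element.upper()
        if el in ATOMIC_MASSES:
            a.mass = ATOMIC_MASSES[el]
        else:
            a.mass = DEFAULT_MASS
            unknown.add(el or "?")
        a.vdw_radius = VDW_RADII.get(el, DEFAULT_VDW_RADIUS)
        if el not in VDW_RADII:
            unknown.add(el or "?")
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: default mass "
            f"{DEFAULT_MASS} amu / radius {DEFAULT_VDW_RADIUS} A applied",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

class _SelParser:
    """Recursive-descent parser producing a boolean mask over atoms."""

    def __init__(self, tokens: list[str], topology: Structure):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.n = topology.n_atoms

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        if tok == "not":
            self.next()
            return ~self.factor()
        return self.clause()

    def clause(self) -> np.ndarray:
        tok = self.next()
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "backbone":
            names = set(BACKBONE_NAMES)
            return np.array([a.atom_name in names for a in self.top.atoms])
        if tok == "chain":
            cid = self.next()
            return np.array([a.chain_id.upper() == cid.upper() for a in self.top.atoms])
        if tok == "resid":
            spec = self.next()
            ranges: list[tuple[int, int]] = []
            for part in spec.split(","):
                try:
                    lo = hi = int(part)
                except ValueError:
                    sep = part.find("-", 1)  # allow a leading minus sign
                    try:
                        lo, hi = int(part[:sep]), int(part[sep + 1:])
                    except (ValueError, IndexError):
                        raise SelectionError(f"bad residue range {part!r}")
                ranges.append((lo, hi))
            return np.array(
                [any(lo <= a.residue_index <= hi for lo, hi in ranges)
                 for a in self.top.atoms]
            )
        if tok == "name":
            names = []
            while self.peek() not in (None, "and", "or", ")"):
                names.append(self.next().upper())
            if not names:
                raise SelectionError("'name' clause requires at least one atom name")
            name_set = set(names)
            return np.array([a.atom_name.upper() in name_set for a in self.top.atoms])
        raise SelectionError(f"unknown selection keyword {tok!r}")


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        tok = raw.lower() if raw.lower() in {"and", "or", "not", "chain", "resid",
                                             "name", "backbone", "all", "(", ")"} else raw
        out.append(tok)
    return out


def resolve_selection(topology: Structure, expression: str) -> Selection:
    """Resolve a selection expression against a topology.

    Deterministic and order-stable: indices come back strictly increasing
    in topology order. An expression that matches nothing raises
    :class:`EmptySelectionError` rather than returning an empty selection.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(f"selection {expression!r} matched no atoms")
    return Selection(expression, idx)


def subset_structure(structure: Structure, selection: Selection) -> Structure:
    """New Structure containing only the selected atoms (order preserved)."""
    idx = selection.indices
    atoms = [replace(structure.atoms[i]) for i in idx]
    return Structure(atoms, structure.coords[idx].copy())


def selection_from_indices(indices: Sequence[int], label: str = "<indices>") -> Selection:
    """Build a Selection directly from atom indices (sorted, deduplicated)."""
    idx = np.unique(np.asarray(indices, dtype=int))
    if idx.size == 0:
        raise EmptySelectionError("empty index list")
    return Selection(label, idx)
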