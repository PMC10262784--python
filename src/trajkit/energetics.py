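"""Per-cluster interaction scoring and the frequency-weighted aggregate.

The aggregate statistic is simple and exact: each cluster's raw
interaction energy (kcal/mol), evaluated on the cluster's center frame, is
multiplied by the fraction of all simulation frames that cluster
represents, and the products are summed. Rejected frames carry no weight
and therefore dilute the total.

The built-in raw-energy provider is a deliberately non-physical contact
score, E = -epsilon x (number of inter-chain heavy-atom pairs within a
cutoff): deterministic, fast and monotone in interface size, which is all
the weighting logic needs. Reproducing published numbers from an external
empirical force-field scorer is supported by loading per-cluster raw
energies from a TSV instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import TrajkitError
from .model_io import Selection, Structure

DEFAULT_EPSILON = 0.1  # kcal/mol per contact
DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom


def contact_interaction_energy(
    frame: Structure,
    chain_a: Selection,
    chain_b: Selection,
    epsilon: float = DEFAULT_EPSILON,
    r_cut: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """Contact stand-in interaction energy between two disjoint selections.

    E = -epsilon * #{(i, j) : i in A, j in B heavy atoms, d_ij <= r_cut},
    in kcal/mol. Not a physical potential; see the module docstring.
    """
    ia, ib = chain_a.indices, chain_b.indices
    if np.intersect1d(ia, ib).size:
        raise TrajkitError("selections overlap")
    ia = np.array([i for i in ia if frame.atoms[i].element != "H"])
    ib = np.array([i for i in ib if frame.atoms[i].element != "H"])
    if ia.size == 0 or ib.size == 0:
        raise TrajkitError("empty heavy-atom selection")
    tree = cKDTree(frame.coords[ib])
    count = sum(len(hits) for hits in tree.query_ball_point(frame.coords[ia], r_cut))
    return -epsilon * count


@dataclass(frozen=True)
class WeightedEnergyReport:
    raw: np.ndarray  # kcal/mol per cluster
    frequencies: np.ndarray  # fraction of all frames per cluster
    weighted: np.ndarray  # raw * frequency, kcal/mol
    total: float  # sum of weighted terms, kcal/mol
    provider: str


def weighted_interaction_score(
    raw, frequencies, provider: str = "contact"
) -> WeightedEnergyReport:
    """Frequency-weighted interaction score over clusters.

    total = sum_i raw_i * freq_i exactly; frequencies must be non-negative
    and sum to at most 1 (the remainder being rejected frames).
    """
    raw = np.asarray(raw, dtype=float)
    freq = np.asarray(frequencies, dtype=float)
    if raw.shape != freq.shape or raw.ndim != 1:
        raise TrajkitError("raw energies and frequencies must be equal-length 1-D")
    if np.any(freq < 0):
        raise TrajkitError("frequencies must be non-negative")
    if freq.sum() > 1.0 + 1e-9:
        raise TrajkitError("frequencies sum beyond 1")
    weighted = raw * freq
    return WeightedEnergyReport(
        raw=raw,
        frequencies=freq,
        weighted=weighted,
        total=float(weighted.sum()),
        provider=provider,
    )


def read_raw_energies_tsv(path: str | Path) -> dict[int, float]:
    """Read a per-cluster raw-energy table: two columns, cluster id and
    kcal/mol, tab-separated, '#' comments allowed."""
    out: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TrajkitError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                out[int(parts[0])] = float(parts[1])
            except ValueError as exc:
                raise TrajkitError(f"{path}:{lineno}: {exc}")
    if not out:
        raise TrajkitError(f"{path}: no energies found")
    return out
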