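"""Geometric hydrogen-bond detection and local-network classification.

A hydrogen bond is declared between two waters when the oxygen–oxygen
distance is below a cutoff (default 3.5 Å) and the angle at the donor oxygen
between the O→O axis and the donating O→H bond is below a threshold (default
30°).  Each water's local hydrogen-bonding environment is classified by its
(donor, acceptor) counts: DDAA is the tetrahedral motif, DDA/DAA/DA are
partially bonded, and a water with no bonds is free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError
from .frames import WaterFrame

__all__ = [
    "HBondCriterion",
    "HBondGraph",
    "detect_hbonds",
    "mean_hbonds_per_molecule",
    "classify_local_network",
    "classify_frame_networks",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion: R_OO < r_oo_max and ∠OOH < angle_ooh_max."""

    r_oo_max: float = 3.5
    angle_ooh_max_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.r_oo_max <= 0:
            raise DomainError(f"r_oo_max must be > 0, got {self.r_oo_max}")
        if not (0.0 < self.angle_ooh_max_deg < 180.0):
            raise DomainError(
                f"angle_ooh_max_deg must be in (0, 180), got {self.angle_ooh_max_deg}"
            )


@dataclass
class HBondGraph:
    """Directed hydrogen-bond graph of one frame.

    ``edges`` has shape (E, 3) with rows (donor_index, hydrogen_index,
    acceptor_index); each (donor, hydrogen) pair donates to at most one
    acceptor (nearest-oxygen tie-break).  ``donor_counts`` and
    ``acceptor_counts`` are per-molecule tallies; a molecule's degree is
    their sum.
    """

    n_molecules: int
    edges: np.ndarray
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray

    @property
    def n_bonds(self) -> int:
        return self.edges.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.donor_counts + self.acceptor_counts


def detect_hbonds(frame: WaterFrame, criterion: HBondCriterion | None = None) -> HBondGraph:
    """Detect hydrogen bonds in a frame under the geometric criterion.

    The angle is measured at the donor oxygen between the donor→acceptor
    oxygen axis and the donating O→H bond.  With a periodic box, distances
    use the minimum-image convention.  When more than one acceptor satisfies
    the criterion for the same donated hydrogen, the nearest oxygen wins so
    that each hydrogen is donated at most once.
    """
    criterion = criterion or HBondCriterion()
    frame.validate()
    n = frame.n_waters
    empty = HBondGraph(
        n_molecules=n,
        edges=np.empty((0, 3), dtype=int),
        donor_counts=np.zeros(n, dtype=int),
        acceptor_counts=np.zeros(n, dtype=int),
    )
    if n < 2:
        return empty

    oxy = frame.oxygen_positions
    if frame.box is not None:
        tree = cKDTree(np.mod(oxy, frame.box), boxsize=frame.box)
    else:
        tree = cKDTree(oxy)
    pairs = tree.query_pairs(criterion.r_oo_max, output_type="ndarray")
    if pairs.size == 0:
        return empty

    # Both orientations of each unordered pair are donor candidates.
    donors = np.concatenate([pairs[:, 0], pairs[:, 1]])
    acceptors = np.concatenate([pairs[:, 1], pairs[:, 0]])
    doo = frame.minimum_image(oxy[acceptors] - oxy[donors])
    dist = np.linalg.norm(doo, axis=-1)
    keep = dist < criterion.r_oo_max  # strict, KD-tree query is inclusive
    donors, acceptors, doo, dist = donors[keep], acceptors[keep], doo[keep], dist[keep]
    if donors.size == 0:
        return empty

    cos_max = np.cos(np.radians(criterion.angle_ooh_max_deg))
    cand_key, cand_dist, cand_acc = [], [], []
    for h in (0, 1):
        oh = frame.minimum_image(frame.hydrogen_positions[donors, h, :] - oxy[donors])
        cosang = np.einsum("ij,ij->i", doo, oh) / (dist * np.linalg.norm(oh, axis=-1))
        ok = cosang > cos_max  # strict angle < threshold
        cand_key.append(donors[ok] * 2 + h)
        cand_dist.append(dist[ok])
        cand_acc.append(acceptors[ok])
    key = np.concatenate(cand_key)
    if key.size == 0:
        return empty
    d = np.concatenate(cand_dist)
    acc = np.concatenate(cand_acc)
    # Nearest acceptor per (donor, hydrogen); acceptor index breaks exact ties.
    order = np.lexsort((acc, d, key))
    key, d, acc = key[order], d[order], acc[order]
    first = np.concatenate([[True], key[1:] != key[:-1]])
    key, acc = key[first], acc[first]
    edges = np.column_stack([key // 2, key % 2, acc]).astype(int)
    return HBondGraph(
        n_molecules=n,
        edges=edges,
        donor_counts=np.bincount(edges[:, 0], minlength=n),
        acceptor_counts=np.bincount(edges[:, 2], minlength=n),
    )


def mean_hbonds_per_molecule(graph: HBondGraph, subset: Iterable[int] | None = None) -> float:
    """Mean number of hydrogen bonds (donated + accepted) per molecule.

    ``subset`` restricts the average to the given molecule indices; an
    explicitly empty subset has no mean and raises.  A frame with no
    molecules (or no bonds) averages to 0.
    """
    deg = graph.degrees
    if subset is not None:
        idx = np.asarray(list(subset), dtype=int)
        if idx.size == 0:
            raise DomainError("mean over an empty subset is undefined")
        deg = deg[idx]
    if deg.size == 0:
        return 0.0
    return float(np.mean(deg))


def classify_local_network(d: int, a: int) -> str:
    """Local hydrogen-bond class from (donor, acceptor) counts.

    Counts are capped at 2 for classification; combinations outside the five
    named motifs (e.g. a double donor with no acceptor) map to ``other``
    rather than being forced into a listed class.
    """
    if d < 0 or a < 0:
        raise DomainError(f"counts must be >= 0, got d={d}, a={a}")
    d, a = min(int(d), 2), min(int(a), 2)
    table = {
        (2, 2): "DDAA",
        (2, 1): "DDA",
        (1, 2): "DAA",
        (1, 1): "DA",
        (0, 0): "free",
    }
    return table.get((d, a), "other")


def classify_frame_networks(graph: HBondGraph) -> list[str]:
    """Per-molecule local-network classes for a whole frame."""
    return [
        classify_local_network(int(d), int(a))
        for d, a in zip(graph.donor_counts, graph.acceptor_counts)
    ]
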