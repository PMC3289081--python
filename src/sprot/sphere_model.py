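"""The aa-sphere representation of residue neighborhoods.

Each residue A is represented by the set of residues with at least one
heavy atom inside a Euclidean ball of fixed radius centered at A's
alpha-carbon.  Membership is split into four sequence-ordered
categories: the *spherical backbone* (the maximal contiguous sequence
run through the center, split into upstream/downstream halves) and the
upstream/downstream *neighborhoods* (members that are sequence-distant
from the center but spatially close).  The per-category member counts
are the sphere's *quantity characteristics*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure

DEFAULT_RADIUS = 9.0  # Angstroms; trade-off between locality and cost


@dataclass(frozen=True)
class QuantityCharacteristics:
    """Member counts per category: upstream/downstream backbone and
    upstream/downstream neighborhood (the center itself is not counted)."""

    q_ub: int
    q_db: int
    q_un: int
    q_dn: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.q_ub, self.q_db, self.q_un, self.q_dn)

    @property
    def total_members(self) -> int:
        """Total sphere membership including the center."""
        return self.q_ub + self.q_db + self.q_un + self.q_dn + 1


@dataclass
class AASphere:
    """Spherical neighborhood of one residue.

    The four index lists are ascending and pairwise disjoint; together
    with the center they form the full member set.  ``ca``, ``bb_coords``
    and the two neighborhood coordinate arrays are cached views used by
    the similarity hot path.
    """

    center_index: int
    upstream_backbone: list[int]
    downstream_backbone: list[int]
    upstream_neighborhood: list[int]
    downstream_neighborhood: list[int]
    qc: QuantityCharacteristics
    radius: float
    protein_ca: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.protein_ca is not None:
            c = self.center_index
            self.ca = self.protein_ca[c]
            # backbone is contiguous: slice once
            self.bb_coords = self.protein_ca[c - self.qc.q_ub : c + self.qc.q_db + 1]
            self.up_nb_coords = self.protein_ca[self.upstream_neighborhood]
            self.down_nb_coords = self.protein_ca[self.downstream_neighborhood]

    def members(self) -> list[int]:
        """All member indices (center included), ascending."""
        return sorted(
            self.upstream_neighborhood
            + self.upstream_backbone
            + [self.center_index]
            + self.downstream_backbone
            + self.downstream_neighborhood
        )


def _membership(protein: ProteinStructure, center: int, radius: float, tree: Optional[cKDTree] = None) -> np.ndarray:
    """Sorted residue indices with any heavy atom within ``radius`` of the
    center residue's alpha-carbon (closed ball)."""
    coords, owner = protein.heavy_atom_table()
    if tree is None:
        tree = cKDTree(coords)
    hits = tree.query_ball_point(protein.ca_coords[center], radius)
    idx = np.unique(owner[hits]) if hits else np.array([], dtype=int)
    # the center belongs by definition (its CA is at distance 0)
    if center not in idx:
        idx = np.union1d(idx, [center])
    return idx


def _categorize(members: np.ndarray, center: int, radius: float, protein_ca: np.ndarray) -> AASphere:
    mset = set(int(i) for i in members)
    lo = center
    while lo - 1 in mset:
        lo -= 1
    hi = center
    while hi + 1 in mset:
        hi += 1
    ub = list(range(lo, center))
    db = list(range(center + 1, hi + 1))
    un = sorted(i for i in mset if i < lo)
    dn = sorted(i for i in mset if i > hi)
    qc = QuantityCharacteristics(len(ub), len(db), len(un), len(dn))
    return AASphere(center, ub, db, un, dn, qc, radius, protein_ca)


def build_aa_sphere(protein: ProteinStructure, center: int, radius: float = DEFAULT_RADIUS) -> AASphere:
    """Build the aa-sphere for one residue.

    A residue is a member iff any of its heavy atoms lies within
    ``radius`` (closed ball) of the center residue's alpha-carbon.
    """
    if not (0 <= center < len(protein)):
        raise IndexError(f"center {center} out of range for length {len(protein)}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    members = _membership(protein, center, radius)
    return _categorize(members, center, radius, protein.ca_coords)


def build_all_spheres(protein: ProteinStructure, radius: float = DEFAULT_RADIUS) -> list[AASphere]:
    """One aa-sphere per residue, in residue order (shared k-d tree)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords, owner = protein.heavy_atom_table()
    tree = cKDTree(coords)
    ca = protein.ca_coords
    spheres = []
    hit_lists = tree.query_ball_point(ca, radius)
    for center in range(len(protein)):
        hits = hit_lists[center]
        idx = np.unique(owner[hits]) if len(hits) else np.array([], dtype=int)
        if center not in idx:
            idx = np.union1d(idx, [center])
        spheres.append(_categorize(idx, center, radius, ca))
    return spheres


def dump_spheres_tsv(spheres: list[AASphere], path) -> None:
    """Debug dump: one row per (sphere, category, member)."""
    with open(path, "w") as fh:
        fh.write("center\tcategory\tmember\n")
        for s in spheres:
            for cat, lst in (
                ("upstream_backbone", s.upstream_backbone),
                ("downstream_backbone", s.downstream_backbone),
                ("upstream_neighborhood", s.upstream_neighborhood),
                ("downstream_neighborhood", s.downstream_neighborhood),
            ):
                for m in lst:
                    fh.write(f"{s.center_index}\t{cat}\t{m}\n")
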