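"""Signature dynamics: comparing intrinsic motions across a fold family.

Members of a protein family sharing a fold (here, 12-TM major facilitator
superfamily transporters) are compared along three axes computed on the
columns of a shared multiple alignment: sequence (normalized Hamming
distance), 3D structure (Cα RMSD after Kabsch superposition), and intrinsic
dynamics (arccosine of the covariance overlap between their lowest GNM
modes). Reordering the sequence and structure matrices by the dynamics-based
clustering exposes whether dynamics tracks sequence or fold divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform

from .structio import CAModel
from .enm import build_kirchhoff, covariance_overlap, eig_modes

__all__ = [
    "FamilyMember",
    "FamilyEnsemble",
    "DistanceTriplet",
    "hamming_distance",
    "superpose_kabsch",
    "identity_filter",
    "family_distances",
    "reorder_by_similarity",
]

GAP_CHARS = frozenset("-.")
MIN_SHARED_COLUMNS = 10


@dataclass
class FamilyMember:
    label: str
    camodel: CAModel
    aligned_seq: str

    def column_map(self) -> dict[int, int]:
        """alignment column -> residue node index (ungapped positions)."""
        mapping = {}
        node = 0
        for col, ch in enumerate(self.aligned_seq):
            if ch not in GAP_CHARS:
                mapping[col] = node
                node += 1
        if node != self.camodel.n_nodes:
            raise ValueError(
                f"member {self.label}: alignment row has {node} residues, "
                f"model has {self.camodel.n_nodes}"
            )
        return mapping


@dataclass
class FamilyEnsemble:
    members: list[FamilyMember]

    def __post_init__(self):
        lengths = {len(m.aligned_seq) for m in self.members}
        if len(lengths) > 1:
            raise ValueError("aligned sequence rows differ in length")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DistanceTriplet:
    labels: list[str]
    sequence: np.ndarray    # normalized Hamming
    structure: np.ndarray   # RMSD, Å
    dynamics: np.ndarray    # arccos(covariance overlap), radians

    def __post_init__(self):
        for name in ("sequence", "structure", "dynamics"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValueError(f"{name} distance matrix not symmetric")
            if np.any(np.abs(np.diag(m)) > 1e-12):
                raise ValueError(f"{name} distance matrix has nonzero diagonal")
        if np.any(self.dynamics < -1e-12) or np.any(self.dynamics > np.pi / 2 + 1e-9):
            raise ValueError("dynamics distances outside [0, π/2]")


def hamming_distance(row_a: str, row_b: str) -> float:
    """Normalized mismatch fraction over aligned rows.

    Gap-vs-gap columns are skipped entirely; gap-vs-residue counts as a
    mismatch.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    mismatches = 0
    counted = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in GAP_CHARS and b in GAP_CHARS:
            continue
        counted += 1
        if a != b or a in GAP_CHARS or b in GAP_CHARS:
            mismatches += 1
    if counted == 0:
        return 0.0
    return mismatches / counted


def superpose_kabsch(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A (Kabsch, proper rotation).

    Returns (rotation, translation, RMSD) such that B @ Rᵀ + t best matches A.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    if a.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


def identity_filter(family: FamilyEnsemble, min_identity: float = 0.10) -> FamilyEnsemble:
    """Drop members whose identity (1 − Hamming) to the first member falls
    below the threshold; the reference member is always kept."""
    if len(family) == 0:
        return family
    ref = family.members[0]
    kept = [ref]
    for m in family.members[1:]:
        if 1.0 - hamming_distance(ref.aligned_seq, m.aligned_seq) >= min_identity:
            kept.append(m)
    return FamilyEnsemble(members=kept)


def family_distances(
    family: FamilyEnsemble,
    mode_count: int = 1,
    gnm_cutoff: float = 10.0,
) -> DistanceTriplet:
    """Pairwise sequence/structure/dynamics distance matrices over a family.

    For each pair, alignment columns occupied in both members define the
    shared residue set; structural distance is the Kabsch RMSD over shared
    Cα positions and the dynamics distance is arccos of the covariance
    overlap between GNM modes computed on the shared-column submodels
    (``mode_count`` lowest modes, default the single softest mode).
    """
    n = len(family)
    if n < 2:
        raise ValueError("family must contain at least 2 members")
    maps = [m.column_map() for m in family.members]
    seq_d = np.zeros((n, n))
    str_d = np.zeros((n, n))
    dyn_d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = family.members[i], family.members[j]
            seq_d[i, j] = seq_d[j, i] = hamming_distance(mi.aligned_seq, mj.aligned_seq)
            shared = sorted(set(maps[i]) & set(maps[j]))
            if len(shared) < MIN_SHARED_COLUMNS:
                raise ValueError(
                    f"pair ({mi.label}, {mj.label}) shares only {len(shared)} "
                    f"alignment columns (< {MIN_SHARED_COLUMNS})"
                )
            xi = mi.camodel.xyz[[maps[i][c] for c in shared]]
            xj = mj.camodel.xyz[[maps[j][c] for c in shared]]
            _, _, rmsd = superpose_kabsch(xi, xj)
            str_d[i, j] = str_d[j, i] = rmsd
            sub_i = CAModel(
                xyz=xi, res_index=list(range(1, len(shared) + 1)),
                res_name=["ALA"] * len(shared), chain=["A"] * len(shared),
            )
            sub_j = CAModel(
                xyz=xj, res_index=list(range(1, len(shared) + 1)),
                res_name=["ALA"] * len(shared), chain=["A"] * len(shared),
            )
            modes_i = eig_modes(build_kirchhoff(sub_i, rc=gnm_cutoff), n_modes=mode_count)
            modes_j = eig_modes(build_kirchhoff(sub_j, rc=gnm_cutoff), n_modes=mode_count)
            _, dist = covariance_overlap(modes_i, modes_j, k=mode_count)
            dyn_d[i, j] = dyn_d[j, i] = dist
    return DistanceTriplet(
        labels=[m.label for m in family.members],
        sequence=seq_d, structure=str_d, dynamics=dyn_d,
    )


def reorder_by_similarity(
    matrix: np.ndarray, height: float | None = None
) -> tuple[list[int], np.ndarray]:
    """Average-linkage leaf ordering of a symmetric distance matrix.

    Returns (member ordering, flat cluster labels). Clusters are cut at
    ``height``; with no height given every member falls in one cluster.
    Deterministic: scipy's linkage on the condensed matrix with stable input
    order.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("distance matrix not symmetric (beyond 1e-9)")
    n = m.shape[0]
    if n == 1:
        return [0], np.array([1])
    condensed = squareform(m, checks=False)
    z = linkage(condensed, method="average")
    order = dendrogram(z, no_plot=True)["leaves"]
    if height is None:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(z, t=height, criterion="distance")
    return [int(i) for i in order], labels


def to_newick(matrix: np.ndarray, labels: list[str]) -> str:
    """Average-linkage dendrogram of a distance matrix as a Newick string."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n == 1:
        return f"{labels[0]};"
    z = linkage(squareform(m, checks=False), method="average")
    names = {i: labels[i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        names[n + k] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
        heights[n + k] = h
    return names[n + len(z) - 1] + ";"
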