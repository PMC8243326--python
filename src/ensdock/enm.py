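"""Elastic network models with implicit-membrane scaling and RTB coarse-graining.

Gaussian network models (GNM) describe isotropic residue fluctuations via the
Kirchhoff (graph Laplacian) matrix of the Cα contact graph; anisotropic
network models (ANM) resolve directions through a 3n×3n Hessian of pairwise
harmonic springs. Two extensions drive conformer generation for membrane
transporters:

* implicit-membrane scaling — springs between residue pairs inside the
  membrane slab are stiffened in the membrane plane (x, y) relative to the
  normal (z), suppressing radial motions the bilayer would resist;
* rotation–translation block (RTB) projection — the Hessian is restricted
  to rigid translations/rotations of secondary-structure blocks, removing
  nonphysical internal distortions from the sampled modes.

Default cutoffs (GNM 10 Å, ANM 15 Å) and γ = 1 are the conventional ENM
choices; fluctuation profiles are in arbitrary units of kT/γ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .structio import CAModel, MembraneSlab, RigidBlocks

logger = logging.getLogger("ensdock.enm")

__all__ = [
    "GNMModel",
    "ANMModel",
    "ModeSet",
    "RTBProjection",
    "build_kirchhoff",
    "build_hessian",
    "apply_membrane_restraints",
    "rtb_project",
    "eig_modes",
    "rmsf",
    "cross_correlation",
    "covariance_overlap",
]


@dataclass
class GNMModel:
    kirchhoff: np.ndarray
    rc: float
    gamma: float

    @property
    def matrix(self) -> np.ndarray:
        return self.kirchhoff

    @property
    def resolution(self) -> str:
        return "per-residue"


@dataclass
class ANMModel:
    hessian: np.ndarray
    rc: float
    gamma: float
    coords: np.ndarray | None = None
    membrane: dict | None = None  # {"factor": s, "mask": bool array} when scaled

    @property
    def matrix(self) -> np.ndarray:
        return self.hessian

    @property
    def resolution(self) -> str:
        return "per-coordinate"


@dataclass
class ModeSet:
    """Nonzero eigenpairs in ascending order; eigenvectors are unit columns."""

    eigenvalues: np.ndarray           # (k,)
    eigenvectors: np.ndarray          # (dim, k)
    resolution: str                   # "per-residue" | "per-coordinate"

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(self.eigenvalues <= 0):
            raise ValueError("ModeSet requires strictly positive eigenvalues")

    @property
    def count(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nodes(self) -> int:
        dim = self.eigenvectors.shape[0]
        return dim // 3 if self.resolution == "per-coordinate" else dim


@dataclass
class RTBProjection:
    """Orthonormal rigid-body basis P (3n × m) mapping block dof to full space."""

    operator: np.ndarray
    blocks: RigidBlocks
    block_dof: list[int] = field(default_factory=list)

    def back_project(self, reduced_vectors: np.ndarray) -> np.ndarray:
        """Lift reduced-space vectors (m × k) to full 3n space."""
        return self.operator @ reduced_vectors


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_kirchhoff(camodel: CAModel, rc: float = 10.0, gamma: float = 1.0) -> GNMModel:
    """Kirchhoff matrix: Γ_ij = −γ for contacts within rc, diagonal = degree·γ."""
    n = camodel.n_nodes
    if n < 2:
        raise ValueError("GNM requires at least 2 nodes")
    d = squareform(pdist(camodel.xyz))
    contact = (d <= rc) & ~np.eye(n, dtype=bool)
    gamma_mat = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(gamma_mat, -gamma_mat.sum(axis=1))
    return GNMModel(kirchhoff=gamma_mat, rc=rc, gamma=gamma)


def _collinear(xyz: np.ndarray, tol: float = 1e-8) -> bool:
    centered = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def build_hessian(camodel: CAModel, rc: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Standard ANM Hessian from pairwise springs V = (γ/2)Σ(|r_ij|−|r_ij⁰|)²."""
    xyz = camodel.xyz
    n = camodel.n_nodes
    if n < 3:
        raise ValueError("ANM requires at least 3 nodes")
    if _collinear(xyz):
        raise ValueError("ANM nodes are collinear: the Hessian is degenerate")
    h = np.zeros((3 * n, 3 * n))
    d = squareform(pdist(xyz))
    for i in range(n):
        for j in range(i + 1, n):
            r = d[i, j]
            if r > rc or r < 1e-9:
                continue
            dv = (xyz[j] - xyz[i]) / r
            block = -gamma * np.outer(dv, dv)
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return ANMModel(hessian=h, rc=rc, gamma=gamma, coords=xyz.copy())


def apply_membrane_restraints(
    anm: ANMModel, slab: MembraneSlab, factor: float = 16.0
) -> ANMModel:
    """Stiffen in-plane spring components for contacts fully inside the slab.

    Each in-slab contact's super-element is rebuilt as
    ``−(γ/r²)(Dd)(Dd)ᵀ`` with ``D = diag(√factor, √factor, 1)``: the xx/yy
    components gain the full factor, the zz component is untouched, and the
    block stays symmetric positive semidefinite. Diagonal blocks are rebuilt
    as negative row sums, so translational invariance is preserved.
    """
    if factor <= 0:
        raise ValueError("membrane scaling factor must be positive")
    if anm.coords is None:
        raise ValueError("ANM model lacks reference coordinates")
    n = anm.coords.shape[0]
    if len(slab.mask) != n:
        raise ValueError("slab mask length does not match node count")
    if factor == 1.0:
        return ANMModel(
            hessian=anm.hessian.copy(), rc=anm.rc, gamma=anm.gamma,
            coords=anm.coords.copy(), membrane={"factor": 1.0, "mask": slab.mask.copy()},
        )
    xyz = anm.coords
    scale = np.full(3, np.sqrt(factor))
    scale[slab.axis] = 1.0
    h = anm.hessian.copy()
    d = squareform(pdist(xyz))
    for i in range(n):
        for j in range(i + 1, n):
            r = d[i, j]
            if r > anm.rc or r < 1e-9:
                continue
            if not (slab.mask[i] and slab.mask[j]):
                continue
            dv = (xyz[j] - xyz[i]) / r
            old_block = -anm.gamma * np.outer(dv, dv)
            sv = scale * dv
            new_block = -anm.gamma * np.outer(sv, sv)
            delta = new_block - old_block
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += delta
            h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += delta
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= delta
            h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= delta
    return ANMModel(
        hessian=h, rc=anm.rc, gamma=anm.gamma, coords=xyz.copy(),
        membrane={"factor": factor, "mask": slab.mask.copy()},
    )


# ---------------------------------------------------------------------------
# RTB projection
# ---------------------------------------------------------------------------

def _block_basis(xyz_block: np.ndarray) -> np.ndarray:
    """Orthonormal rigid-body basis (3m × dof) for one block of m nodes.

    Three translations plus up to three rotations about the centroid;
    rank-revealing QR drops degenerate rotational dof (single node → 3,
    two nodes → 5).
    """
    m = xyz_block.shape[0]
    centered = xyz_block - xyz_block.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((m, 3))
        t[:, ax] = 1.0
        cols.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rot = np.cross(np.broadcast_to(e, (m, 3)), centered)
        cols.append(rot.ravel())
    basis = np.column_stack(cols)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def rtb_project(anm: ANMModel, blocks: RigidBlocks) -> tuple[np.ndarray, RTBProjection]:
    """Project the Hessian onto per-block rigid translations/rotations.

    Returns the reduced matrix PᵀHP and the projection (for lifting reduced
    modes back to 3n space).
    """
    if anm.coords is None:
        raise ValueError("ANM model lacks reference coordinates")
    n = anm.coords.shape[0]
    if blocks.blocks[-1][1] != n:
        raise ValueError("blocks do not partition the node set")
    cols = []
    block_dof = []
    for start, stop in blocks.blocks:
        q = _block_basis(anm.coords[start:stop])
        block_dof.append(q.shape[1])
        full = np.zeros((3 * n, q.shape[1]))
        full[3 * start:3 * stop, :] = q
        cols.append(full)
    p = np.hstack(cols)
    reduced = p.T @ anm.hessian @ p
    reduced = 0.5 * (reduced + reduced.T)
    return reduced, RTBProjection(operator=p, blocks=blocks, block_dof=block_dof)


# ---------------------------------------------------------------------------
# Modes and derived quantities
# ---------------------------------------------------------------------------

def eig_modes(
    model: GNMModel | ANMModel | np.ndarray,
    n_modes: int = 20,
    zero_tol: float = 1e-8,
    resolution: str | None = None,
    projection: RTBProjection | None = None,
) -> ModeSet:
    """Lowest nonzero eigenpairs of an ENM matrix.

    Eigenvalues ≤ ``zero_tol · λ_max`` are treated as rigid-body modes and
    removed. When ``projection`` is given (RTB reduced matrix), reduced
    eigenvectors are lifted back to full 3n space.
    """
    if isinstance(model, np.ndarray):
        mat = model
        res = resolution or "per-coordinate"
    else:
        mat = model.matrix
        res = model.resolution
    if not np.all(np.isfinite(mat)):
        raise ValueError("model matrix contains non-finite entries")
    vals, vecs = eigh(mat)
    lam_max = max(vals[-1], 1e-300)
    nonzero = vals > zero_tol * lam_max
    if not np.any(nonzero):
        raise ValueError("all eigenvalues fall below the zero-mode tolerance")
    vals, vecs = vals[nonzero], vecs[:, nonzero]
    avail = len(vals)
    if n_modes > avail:
        logger.info("requested %d modes, only %d available", n_modes, avail)
    k = min(n_modes, avail)
    vals, vecs = vals[:k], vecs[:, :k]
    if projection is not None:
        vecs = projection.back_project(vecs)
        vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, resolution=res)


def _covariance(modeset: ModeSet, k: int) -> np.ndarray:
    """Rank-k pseudo-inverse covariance Σ u_m u_mᵀ / λ_m (arbitrary units)."""
    u = modeset.eigenvectors[:, :k]
    inv_l = 1.0 / modeset.eigenvalues[:k]
    return (u * inv_l) @ u.T


def rmsf(modeset: ModeSet, k: int | None = None, per_axis: bool = False) -> np.ndarray:
    """Per-node mean-square fluctuation profile from the k lowest modes.

    GNM: MSF_i = Σ_m u_{m,i}²/λ_m. ANM: trace of the i-th 3×3 diagonal
    block of the rank-k pseudo-inverse (or the (x, y, z) components when
    ``per_axis``). Arbitrary units.
    """
    if k is None:
        k = modeset.count
    if k < 1:
        raise ValueError("k must be at least 1")
    k = min(k, modeset.count)
    u = modeset.eigenvectors[:, :k]
    inv_l = 1.0 / modeset.eigenvalues[:k]
    per_coord = (u ** 2) @ inv_l
    if modeset.resolution == "per-residue":
        if per_axis:
            raise ValueError("per-axis profile undefined for GNM modes")
        return per_coord
    per_node = per_coord.reshape(-1, 3)
    return per_node if per_axis else per_node.sum(axis=1)


def cross_correlation(modeset: ModeSet, k: int | None = None) -> np.ndarray:
    """Normalized residue cross-correlation C_ij/√(C_ii C_jj) in [−1, 1]."""
    if k is None:
        k = modeset.count
    if k < 1:
        raise ValueError("k must be at least 1")
    k = min(k, modeset.count)
    cov = _covariance(modeset, k)
    if modeset.resolution == "per-coordinate":
        n = modeset.n_nodes
        node_cov = np.zeros((n, n))
        for a in range(3):
            node_cov += cov[a::3, a::3]
        cov = node_cov
    diag = np.diag(cov).copy()
    if np.any(diag <= 1e-300):
        raise ValueError("zero-variance node: cannot normalize cross-correlations")
    norm = np.sqrt(np.outer(diag, diag))
    c = cov / norm
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def covariance_overlap(
    modes_a: ModeSet, modes_b: ModeSet, k: int | None = None
) -> tuple[float, float]:
    """Covariance overlap of two rank-k mode covariances, and its arccosine.

    Overlap Ω ∈ [0, 1] follows the Hess measure

        Ω = 1 − sqrt( (Σ_a σ_a + Σ_b σ_b − 2 Σ_{ab} √(σ_a σ_b) (u_a·u_b)²)
                      / (Σ_a σ_a + Σ_b σ_b) ),   σ = 1/λ,

    which is 1 for identical covariances and 0 for disjoint subspaces.
    The dynamics distance is arccos(Ω) in radians.
    """
    if modes_a.eigenvectors.shape[0] != modes_b.eigenvectors.shape[0]:
        raise ValueError("mode sets have mismatched dimensions")
    ka = modes_a.count if k is None else min(k, modes_a.count)
    kb = modes_b.count if k is None else min(k, modes_b.count)
    if ka < 1 or kb < 1:
        raise ValueError("k must be at least 1")
    sa = 1.0 / modes_a.eigenvalues[:ka]
    sb = 1.0 / modes_b.eigenvalues[:kb]
    ua = modes_a.eigenvectors[:, :ka]
    ub = modes_b.eigenvectors[:, :kb]
    dots2 = (ua.T @ ub) ** 2
    cross = np.sqrt(np.outer(sa, sb)) * dots2
    total = sa.sum() + sb.sum()
    arg = (total - 2.0 * cross.sum()) / total
    overlap = 1.0 - np.sqrt(max(arg, 0.0))
    overlap = float(np.clip(overlap, 0.0, 1.0))
    return overlap, float(np.arccos(overlap))
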