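"""Conformer sampling along low-frequency modes, diversity selection, and
clash-based model ranking.

The generation protocol mirrors normal-mode ensemble docking practice:
sample many alternate conformations along the two softest (lowest-frequency)
modes of the membrane-restrained, block-projected ANM, keep a small diverse
subset near a target RMSD from the ensemble average, and rank candidate
models per conformer by a steric clashscore (significant non-bonded overlaps
per 1000 atoms), retaining the best few models per conformer.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structio import (
    COVALENT_RADII,
    DEFAULT_COVALENT,
    CAModel,
    Structure,
    read_structure,
    write_structure,
)
from .enm import ModeSet

logger = logging.getLogger("ensdock.ensemble")

__all__ = [
    "ConformerEnsemble",
    "ModelScore",
    "sample_along_modes",
    "select_diverse",
    "clashscore",
    "rank_and_retain",
    "minimize_hook",
    "coordinate_rmsd",
]


@dataclass
class ConformerEnsemble:
    reference: CAModel
    coords: np.ndarray              # (n_conf, n_nodes, 3)
    coefficients: np.ndarray        # (n_conf, 2) mode coefficients (a1, a2)
    seed: int
    max_rmsd: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.reference.n_nodes:
            raise ValueError("conformer node count differs from reference")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite mode coefficients")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    conformer_id: str
    clashscore: float
    rank: int | None = None

    def __post_init__(self):
        if self.clashscore < 0:
            raise ValueError("clashscore must be non-negative")


def coordinate_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two same-shape coordinate sets (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate shape mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def sample_along_modes(
    reference: CAModel,
    modeset: ModeSet,
    n: int = 1000,
    max_rmsd: float = 3.0,
    seed: int = 0,
) -> ConformerEnsemble:
    """Sample conformers along the two lowest-frequency modes.

    Coefficient pairs (a₁, a₂) are drawn uniformly on a disc scaled so the
    maximum displacement RMSD equals ``max_rmsd`` (for orthonormal
    per-coordinate modes, RMSD = |a|/√n_nodes). Deterministic per seed.
    """
    if max_rmsd < 0:
        raise ValueError("max_rmsd must be non-negative")
    if modeset.resolution != "per-coordinate":
        raise ValueError("mode sampling requires per-coordinate (ANM) modes")
    if modeset.count < 2:
        raise ValueError("mode sampling requires at least two modes")
    n_nodes = reference.n_nodes
    u = modeset.eigenvectors[:, :2]
    if u.shape[0] != 3 * n_nodes:
        raise ValueError("mode dimension does not match reference node count")
    rng = np.random.default_rng(seed)
    radius_max = max_rmsd * np.sqrt(n_nodes)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = radius_max * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    coeffs = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    disp = coeffs @ u.T                       # (n, 3n)
    coords = reference.xyz[None, :, :] + disp.reshape(n, n_nodes, 3)
    return ConformerEnsemble(
        reference=reference, coords=coords, coefficients=coeffs,
        seed=seed, max_rmsd=max_rmsd,
    )


def select_diverse(
    ensemble: ConformerEnsemble,
    rmsd_cutoff: float = 3.0,
    target_count: int = 20,
    min_pairwise: float = 0.5,
) -> ConformerEnsemble:
    """Greedy selection of conformers near the cutoff RMSD from the average.

    Candidates are visited in order of |RMSD-to-average − cutoff| (ties by
    index), skipping any within ``min_pairwise`` Å of an already-selected
    conformer; selection stops at ``target_count`` or exhaustion.
    """
    if target_count < 1:
        raise ValueError("target_count must be at least 1")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    avg = ensemble.coords.mean(axis=0)
    dist_to_avg = np.array([coordinate_rmsd(c, avg) for c in ensemble.coords])
    order = np.lexsort((np.arange(len(ensemble)), np.abs(dist_to_avg - rmsd_cutoff)))
    selected: list[int] = []
    for idx in order:
        if len(selected) >= target_count:
            break
        if any(
            coordinate_rmsd(ensemble.coords[idx], ensemble.coords[s]) < min_pairwise
            for s in selected
        ):
            continue
        selected.append(int(idx))
    return ConformerEnsemble(
        reference=ensemble.reference,
        coords=ensemble.coords[selected],
        coefficients=ensemble.coefficients[selected],
        seed=ensemble.seed,
        max_rmsd=ensemble.max_rmsd,
    )


# ---------------------------------------------------------------------------
# Clashscore
# ---------------------------------------------------------------------------

_HBOND_ELEMENTS = {"N", "O", "F", "S"}
_HBOND_MIN, _HBOND_MAX = 2.4, 3.5


def _bond_graph(structure: Structure) -> dict[int, set[int]]:
    """Covalent connectivity inferred from covalent radii (+0.45 Å slack)."""
    coords = structure.coords()
    radii = np.array(
        [COVALENT_RADII.get(a.element, DEFAULT_COVALENT) for a in structure.atoms]
    )
    tree = cKDTree(coords)
    adj: dict[int, set[int]] = {i: set() for i in range(len(structure))}
    for i, j in tree.query_pairs(r=float(2 * radii.max() + 0.45)):
        d = np.linalg.norm(coords[i] - coords[j])
        if 0.4 < d < radii[i] + radii[j] + 0.45:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def clashscore(structure: Structure, overlap_threshold: float = 0.4) -> float:
    """Significant steric clashes per 1000 atoms.

    A clash is an unordered non-bonded atom pair whose vdW overlap
    ``r_i + r_j − dist`` strictly exceeds the threshold. Pairs connected by
    one or two covalent bonds (1-2/1-3) and plausible hydrogen-bond
    donor–acceptor pairs (both N/O/F/S heavy atoms at 2.4–3.5 Å) are
    excluded.
    """
    n = len(structure)
    if n == 0:
        raise ValueError("empty structure")
    coords = structure.coords()
    radii = np.array([a.vdw for a in structure.atoms])
    adj = _bond_graph(structure)
    excluded: set[tuple[int, int]] = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excluded.add((min(i, j), max(i, j)))          # 1-2
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))  # 1-3
    tree = cKDTree(coords)
    clashes = 0
    for i, j in tree.query_pairs(r=float(2 * radii.max())):
        pair = (min(i, j), max(i, j))
        if pair in excluded:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        ei, ej = structure.atoms[i].element, structure.atoms[j].element
        if ei in _HBOND_ELEMENTS and ej in _HBOND_ELEMENTS and _HBOND_MIN <= d <= _HBOND_MAX:
            continue
        if radii[i] + radii[j] - d > overlap_threshold:
            clashes += 1
    return clashes / n * 1000.0


def rank_and_retain(scores: list[ModelScore], top_k: int = 3) -> list[ModelScore]:
    """Keep the ``top_k`` lowest-clashscore models per conformer.

    Ties are broken lexicographically by model id; retained entries carry
    their within-conformer rank (1-based).
    """
    groups: dict[str, list[ModelScore]] = {}
    for s in scores:
        groups.setdefault(s.conformer_id, []).append(s)
    retained: list[ModelScore] = []
    for conformer_id in groups:
        group = sorted(groups[conformer_id], key=lambda s: (s.clashscore, s.model_id))
        for rank, s in enumerate(group[:top_k], start=1):
            retained.append(
                ModelScore(
                    model_id=s.model_id, conformer_id=s.conformer_id,
                    clashscore=s.clashscore, rank=rank,
                )
            )
    return retained


def minimize_hook(conformer: Structure, backend_command: str | None = None) -> Structure:
    """Delegate energy minimization to an external backend, or pass through.

    The command template receives ``{input}``/``{output}`` PDB paths. With no
    backend configured the conformer is returned unchanged (logged notice);
    a nonzero backend exit raises with the log tail attached.
    """
    if backend_command is None:
        logger.info("minimize_hook: no backend configured, returning input unchanged")
        return conformer
    with tempfile.TemporaryDirectory(prefix="ensdock-min-") as tmp:
        pin = Path(tmp) / "in.pdb"
        pout = Path(tmp) / "out.pdb"
        pin.write_text(write_structure(conformer))
        cmd = [part.format(input=str(pin), output=str(pout))
               for part in shlex.split(backend_command)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            tail = (proc.stderr or proc.stdout or "").splitlines()[-10:]
            raise RuntimeError(
                "minimizer backend failed (exit %d): %s" % (proc.returncode, " | ".join(tail))
            )
        try:
            out_text = pout.read_text() if pout.exists() else proc.stdout
            minimized = read_structure(out_text, source=conformer.source)
        except Exception as exc:
            raise RuntimeError(f"minimizer backend emitted malformed output: {exc}") from exc
        if len(minimized) != len(conformer):
            raise RuntimeError("minimizer backend changed the atom count")
        return minimized
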