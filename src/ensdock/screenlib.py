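"""Screening-library curation and two-round enrichment evaluation.

Receptor model ensembles are prioritized by their ability to rank known
active compounds above inactives and property-matched decoys under a
docking backend. The library contract follows common virtual-screening
benchmarks: activity classes from μM thresholds (with an excluded band
between the active and inactive cutoffs), DUD-E-style decoy augmentation to
a 1:36 active:nonactive ratio, rank-based ROC AUC with midrank tie handling,
and the enrichment factor at the top 1% of the ranked list. Round one docks
into the full transmembrane region; round two restricts the search space to
the contact region of the round-one active poses.

The docking engine is a process-boundary adapter. A deterministic mock
backend (compound pharmacophore centroid distance to a planted site plus
seeded noise) makes every stage testable offline; an external-engine wrapper
carries the screening configuration (exhaustiveness 10; 20 with 10 modes
for focused steroid docking) but is never required by tests.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("ensdock.screenlib")

__all__ = [
    "CompoundRecord",
    "ActivityProfile",
    "BindingSiteBox",
    "ModelPerformance",
    "ReceptorModel",
    "MockDockingBackend",
    "VinaCommandBackend",
    "classify_activity",
    "augment_with_decoys",
    "roc_auc",
    "enrichment_factor",
    "contact_region",
    "run_enrichment_round",
    "rank_models",
    "read_library_csv",
    "write_library_csv",
]

ACTIVITY_CLASSES = ("active", "inactive", "decoy", "excluded")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    parent_id: str
    smiles: str
    activity_um: float | None
    activity_class: str
    target: str = ""
    centroid: tuple[float, float, float] | None = None  # latent pharmacophore site
    affinity: float = 0.0                               # hidden mock-backend field

    def __post_init__(self):
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.activity_class!r}")
        if self.activity_um is not None and self.activity_um < 0:
            raise ValueError("activity must be non-negative")
        if self.activity_class == "decoy" and self.activity_um is not None:
            raise ValueError("decoys carry no activity value")


@dataclass(frozen=True)
class ActivityProfile:
    """Activity thresholds in μM; the band between them is excluded."""

    active_um: float = 1.0
    inactive_um: float = 10.0

    def __post_init__(self):
        if not self.active_um < self.inactive_um:
            raise ValueError("active threshold must be below inactive threshold")


@dataclass
class BindingSiteBox:
    center: np.ndarray           # (3,)
    extents: np.ndarray          # (3,) full edge lengths, Å
    provenance: str = ""

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        if np.any(self.extents <= 0):
            raise ValueError("box extents must be positive")

    def contains(self, point: np.ndarray) -> bool:
        return bool(np.all(np.abs(np.asarray(point) - self.center) <= self.extents / 2))

    def distance(self, point: np.ndarray) -> float:
        """Euclidean distance from a point to the box (0 if inside)."""
        d = np.abs(np.asarray(point, dtype=float) - self.center) - self.extents / 2
        return float(np.linalg.norm(np.clip(d, 0.0, None)))


@dataclass(frozen=True)
class ModelPerformance:
    model_id: str
    auc: float
    ef: float
    ef_fraction: float = 0.01
    n_actives: int = 0
    n_inactives: int = 0
    n_decoys: int = 0

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if self.ef < 0 or self.ef > 1.0 / self.ef_fraction + 1e-9:
            raise ValueError("EF outside [0, 1/fraction]")


@dataclass(frozen=True)
class ReceptorModel:
    """A receptor model as seen by the docking adapter."""

    model_id: str
    site_center: tuple[float, float, float] | None = None  # mock backend's docking site
    receptor_path: str | None = None                       # PDBQT for external engines


# ---------------------------------------------------------------------------
# Library curation
# ---------------------------------------------------------------------------

def classify_activity(value_um: float, profile: ActivityProfile) -> str:
    """active (≤ active cutoff), inactive (> inactive cutoff), else excluded."""
    if value_um < 0:
        raise ValueError("activity value must be non-negative")
    if value_um <= profile.active_um:
        return "active"
    if value_um > profile.inactive_um:
        return "inactive"
    return "excluded"


def augment_with_decoys(
    n_actives: int,
    n_inactives: int,
    decoy_pool: list,
    ratio: int = 36,
    seed: int = 0,
) -> list:
    """Sample decoys so nonactives reach ``ratio`` per active.

    n_decoys = max(0, ratio·n_actives − n_inactives), drawn without
    replacement (seeded); an undersized pool is taken whole with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_decoys = max(0, ratio * n_actives - n_inactives)
    if n_decoys == 0:
        return []
    if not decoy_pool:
        logger.warning("decoy pool empty: %d decoys needed but none available", n_decoys)
        return []
    if n_decoys > len(decoy_pool):
        logger.warning(
            "decoy pool holds %d < %d requested: taking all", len(decoy_pool), n_decoys
        )
        return list(decoy_pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
    return [decoy_pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Enrichment metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, lower_is_better: bool = True) -> float:
    """Rank-based ROC AUC with midrank tie handling.

    Equals the probability that a random active is ranked better than a
    random nonactive (ties count one half). By docking convention, lower
    (more negative) scores rank first.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranked = rankdata(-s if lower_is_better else s)
    return float((ranked[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def enrichment_factor(
    scores, labels, top_fraction: float = 0.01, lower_is_better: bool = True
) -> float:
    """EF = (actives in top ⌈f·N⌉ / ⌈f·N⌉) / (actives / N).

    Ties at the boundary resolve by input order for determinism.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = len(s)
    n_actives = int(y.sum())
    if n_actives == 0:
        raise ValueError("EF requires at least one active")
    n_top = max(1, math.ceil(top_fraction * n))
    order = np.lexsort((np.arange(n), s if lower_is_better else -s))
    top_actives = int(y[order[:n_top]].sum())
    return (top_actives / n_top) / (n_actives / n)


# ---------------------------------------------------------------------------
# Contact region (round-2 search space)
# ---------------------------------------------------------------------------

def contact_region(active_poses, padding: float = 2.0, grid: float = 1.0) -> BindingSiteBox:
    """Bounding box of the vdW-dilated volume occupied by active poses.

    Each pose must expose ``coords`` (n×3 Å) and ``radii`` (n,). Atom spheres
    (vdW + padding) are voxelized on a ``grid``-Å lattice; the box is the
    bounding box of occupied voxels.
    """
    if not active_poses:
        raise ValueError("empty pose set")
    voxels: set[tuple[int, int, int]] = set()
    for pose in active_poses:
        coords = np.asarray(pose.coords, dtype=float)
        radii = np.asarray(pose.radii, dtype=float)
        if coords.size == 0:
            continue
        for p, r in zip(coords, radii):
            rr = r + padding
            lo = np.floor((p - rr) / grid).astype(int)
            hi = np.ceil((p + rr) / grid).astype(int)
            for ix in range(lo[0], hi[0] + 1):
                for iy in range(lo[1], hi[1] + 1):
                    for iz in range(lo[2], hi[2] + 1):
                        c = np.array([ix, iy, iz], dtype=float) * grid
                        if np.sum((c - p) ** 2) <= rr * rr:
                            voxels.add((ix, iy, iz))
    if not voxels:
        raise ValueError("no atoms in pose set")
    v = np.array(sorted(voxels), dtype=float) * grid
    lo = v.min(axis=0) - grid / 2
    hi = v.max(axis=0) + grid / 2
    return BindingSiteBox(
        center=(lo + hi) / 2, extents=hi - lo, provenance="round-1 active poses"
    )


# ---------------------------------------------------------------------------
# Docking backends
# ---------------------------------------------------------------------------

def _stable_rng(seed: int, *keys: str) -> np.random.Generator:
    parts = [seed % (2 ** 31)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(parts)


class _MockPose:
    """Minimal pose: a single pseudo-atom at the docked centroid."""

    def __init__(self, center: np.ndarray, radius: float = 3.5):
        self.coords = np.asarray(center, dtype=float).reshape(1, 3)
        self.radii = np.array([radius])


class MockDockingBackend:
    """Deterministic stand-in for an external docking engine.

    A compound's latent pharmacophore centroid (assigned by the library
    generator) is scored against the model's docking site:

        score = ‖centroid − site‖ + dist(centroid, box) + ε,  ε ~ N(0, σ²)

    with ε seeded per (model, compound). Lower is better. Models whose site
    coincides with the planted site therefore rank actives (centroids near
    the planted site) best; models with scrambled sites separate nothing.
    """

    lower_is_better = True

    def __init__(self, noise_sigma: float = 0.25, seed: int = 0):
        self.noise_sigma = noise_sigma
        self.seed = seed

    def score(self, model: ReceptorModel, compound: CompoundRecord,
              box: BindingSiteBox) -> float:
        if compound.centroid is None:
            raise ValueError(f"compound {compound.compound_id} has no centroid")
        rng_null = _stable_rng(self.seed, "null", model.model_id, compound.compound_id)
        if model.site_center is None:
            # scrambled model: no coherent site, scores carry no signal
            return float(rng_null.uniform(0.0, 30.0))
        c = np.asarray(compound.centroid, dtype=float)
        s = np.asarray(model.site_center, dtype=float)
        rng = _stable_rng(self.seed, model.model_id, compound.compound_id)
        noise = rng.normal(0.0, self.noise_sigma)
        return float(np.linalg.norm(c - s) + box.distance(c) + noise)

    def best_pose(self, model: ReceptorModel, compound: CompoundRecord,
                  box: BindingSiteBox) -> _MockPose:
        c = np.asarray(compound.centroid, dtype=float)
        rng = _stable_rng(self.seed, "pose", model.model_id, compound.compound_id)
        return _MockPose(c + rng.normal(0.0, 0.2, size=3))


class VinaCommandBackend:
    """Process-boundary adapter for an AutoDock-Vina-style executable.

    Holds the screening configuration (exhaustiveness 10 for library
    screening; 20 with 10 binding modes for focused steroid docking) and the
    command template; never invoked by the test suite.
    """

    lower_is_better = True

    def __init__(self, executable: str = "vina", exhaustiveness: int = 10,
                 num_modes: int = 9):
        self.executable = executable
        self.exhaustiveness = exhaustiveness
        self.num_modes = num_modes

    def score(self, model: ReceptorModel, compound: CompoundRecord,
              box: BindingSiteBox) -> float:
        import subprocess

        if model.receptor_path is None:
            raise ValueError("external backend requires a receptor PDBQT path")
        ligand_path = getattr(compound, "ligand_path", None)
        if ligand_path is None:
            raise ValueError("external backend requires a ligand PDBQT path")
        cmd = [
            self.executable,
            "--receptor", model.receptor_path,
            "--ligand", str(ligand_path),
            "--center_x", str(box.center[0]),
            "--center_y", str(box.center[1]),
            "--center_z", str(box.center[2]),
            "--size_x", str(box.extents[0]),
            "--size_y", str(box.extents[1]),
            "--size_z", str(box.extents[2]),
            "--exhaustiveness", str(self.exhaustiveness),
            "--num_modes", str(self.num_modes),
        ]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
        for line in out.splitlines():
            fields = line.split()
            if len(fields) >= 2 and fields[0] == "1":
                return float(fields[1])
        raise RuntimeError("could not parse a best score from engine output")


# ---------------------------------------------------------------------------
# Enrichment rounds and model ranking
# ---------------------------------------------------------------------------

MAX_FAILURE_FRACTION = 0.10


def run_enrichment_round(
    models: list[ReceptorModel],
    library: list[CompoundRecord],
    box: BindingSiteBox,
    backend,
    ef_fraction: float = 0.01,
) -> list[ModelPerformance]:
    """Score the library against every model; return AUC and EF per model.

    Compounds in the excluded activity band are dropped. Backend failures
    skip the compound with a warning; a model with more than 10% failures is
    skipped entirely.
    """
    usable = [c for c in library if c.activity_class != "excluded"]
    if not usable:
        raise ValueError("library has no usable compounds")
    lower = getattr(backend, "lower_is_better", True)
    performances = []
    for model in models:
        scores, labels = [], []
        failures = 0
        for compound in usable:
            try:
                s = backend.score(model, compound, box)
            except Exception as exc:  # backend contract: skip + warn
                failures += 1
                logger.warning(
                    "backend failed on %s / %s: %s", model.model_id,
                    compound.compound_id, exc,
                )
                continue
            scores.append(s)
            labels.append(compound.activity_class == "active")
        if failures > MAX_FAILURE_FRACTION * len(usable):
            logger.warning(
                "model %s skipped: %d/%d compounds failed", model.model_id,
                failures, len(usable),
            )
            continue
        auc = roc_auc(scores, labels, lower_is_better=lower)
        ef = enrichment_factor(scores, labels, top_fraction=ef_fraction,
                               lower_is_better=lower)
        counts = {
            "active": 0, "inactive": 0, "decoy": 0,
        }
        for c in usable:
            counts[c.activity_class] += 1
        performances.append(
            ModelPerformance(
                model_id=model.model_id, auc=auc, ef=ef, ef_fraction=ef_fraction,
                n_actives=counts["active"], n_inactives=counts["inactive"],
                n_decoys=counts["decoy"],
            )
        )
    return performances


AUC_TIE_DELTA = 0.01


def rank_models(performances: list[ModelPerformance], top_n: int = 5) -> list[str]:
    """Order models by AUC descending; near-ties (ΔAUC < 0.01) fall back to
    EF1% descending, then model id. Returns the ``top_n`` model ids."""
    ranked = sorted(performances, key=lambda p: (-p.auc, p.model_id))
    changed = True
    while changed:  # bubble pass with the tie comparator; deterministic
        changed = False
        for i in range(len(ranked) - 1):
            a, b = ranked[i], ranked[i + 1]
            if abs(a.auc - b.auc) < AUC_TIE_DELTA and (
                (b.ef, a.model_id) > (a.ef, b.model_id)
            ):
                ranked[i], ranked[i + 1] = b, a
                changed = True
    return [p.model_id for p in ranked[:top_n]]


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ["compound_id", "parent_id", "smiles", "activity_um", "class", "target"]


def write_library_csv(library: list[CompoundRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id, "parent_id": c.parent_id,
                "smiles": c.smiles, "activity_um": c.activity_um,
                "class": c.activity_class, "target": c.target,
            }
            for c in library
        ],
        columns=_LIB_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_library_csv(path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        activity = row["activity_um"]
        activity = None if pd.isna(activity) else float(activity)
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]), parent_id=str(row["parent_id"]),
                smiles=str(row["smiles"]), activity_um=activity,
                activity_class=str(row["class"]),
                target=str(row.get("target", "") or ""),
            )
        )
    return records
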