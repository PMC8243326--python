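"""Steroid pose clustering, interaction fingerprints, and site geometry.

Docked poses are reduced to their Murcko scaffold, mapped onto a common
sterane-type tetracyclic core via a bond-order-flexible SMARTS pattern, and
clustered by receptor-frame RMSD (no re-superposition — binding-site
location is the clustering signal) with average linkage at a 2 Å cutoff.
Clusters holding more than half the unique active compounds are prioritized
for interaction analysis: per-residue protein–ligand interaction
fingerprints (PLIFs) with geometric criteria, salt-bridge and halogen-bond
geometry detectors, grid-based pocket volume, and radius of gyration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import label as cc_label
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .structio import DEFAULT_VDW, VDW_RADII, Structure

logger = logging.getLogger("ensdock.poselab")

__all__ = [
    "Pose",
    "ScaffoldPose",
    "PoseClusterSet",
    "STEROID_MCS_SMARTS",
    "murcko_scaffold",
    "map_mcs",
    "cluster_poses",
    "prioritize_clusters",
    "plif",
    "interaction_frequency",
    "detect_salt_bridges",
    "halogen_bond_geometry",
    "pocket_volume",
    "radius_of_gyration",
]

# Sterane-type tetracyclic core with the C18 angular methyl; ring-bond orders
# kept flexible (-,=,: alternatives) so aromatic-A-ring estranes match too.
STEROID_MCS_SMARTS = (
    "[#6]1-,:[#6]-,:[#6]-,=,:[#6]2-,:[#6](-,:[#6]-,=,:1)-[#6]1-[#6]-,=[#6]-"
    "[#6]3(-[#6](-[#6]-1-[#6]-[#6]-2)-[#6]-[#6]-[#6]-3)-[#6]"
)

_KNOWN_ELEMENTS = set(VDW_RADII) | {"B", "SI"}
_METALS = {"ZN", "MG", "MN", "FE", "CU", "NA", "K", "CA"}


@dataclass
class Pose:
    """A docked ligand pose in the receptor frame."""

    pose_id: str
    compound_id: str
    elements: list[str]
    xyz: np.ndarray                    # (n, 3) Å
    charges: np.ndarray | None = None  # formal charges per atom
    score: float | None = None
    model_id: str = ""
    rings: list[list[int]] = field(default_factory=list)  # aromatic ring atom indices
    mol: object | None = None          # optional RDKit mol with matching atom order

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.elements), 3):
            raise ValueError("pose coordinate/element length mismatch")
        if self.charges is None:
            self.charges = np.zeros(len(self.elements))
        self.charges = np.asarray(self.charges, dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.xyz

    @property
    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(e.upper(), DEFAULT_VDW) for e in self.elements])


@dataclass
class ScaffoldPose:
    pose_id: str
    compound_id: str
    coords: np.ndarray   # MCS-mapped atoms in canonical match order

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class PoseClusterSet:
    clusters: list[list[ScaffoldPose]]

    def __post_init__(self):
        seen = set()
        for cl in self.clusters:
            for sp in cl:
                if sp.pose_id in seen:
                    raise ValueError("clusters do not partition poses")
                seen.add(sp.pose_id)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, cl in enumerate(self.clusters):
            rows.append(
                {
                    "cluster": i,
                    "n_poses": len(cl),
                    "n_compounds": len({sp.compound_id for sp in cl}),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scaffold reduction and MCS mapping
# ---------------------------------------------------------------------------

def murcko_scaffold(mol: Chem.Mol) -> Chem.Mol:
    """Ring systems plus linkers, side chains removed (empty for acyclic)."""
    if mol is None:
        raise ValueError("unparsable molecule")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        logger.info("acyclic molecule: empty Murcko scaffold")
    return scaffold


def map_mcs(
    poses: list[Pose], smarts: str = STEROID_MCS_SMARTS
) -> list[ScaffoldPose]:
    """Extract MCS-core atom coordinates from each pose in canonical match order.

    Each pose must carry an RDKit mol whose atom order matches its
    coordinates. Poses that do not contain the pattern are excluded with a
    warning; zero matches overall is an error.
    """
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise ValueError("invalid SMARTS pattern")
    out = []
    for pose in poses:
        if pose.mol is None:
            raise ValueError(f"pose {pose.pose_id} carries no molecule")
        match = pose.mol.GetSubstructMatch(query)
        if not match:
            logger.warning("pose %s does not match the MCS pattern: excluded",
                           pose.pose_id)
            continue
        out.append(
            ScaffoldPose(
                pose_id=pose.pose_id, compound_id=pose.compound_id,
                coords=pose.xyz[list(match)],
            )
        )
    if not out:
        raise ValueError("no pose matches the MCS pattern")
    return out


# ---------------------------------------------------------------------------
# Pose clustering and prioritization
# ---------------------------------------------------------------------------

def cluster_poses(
    scaffold_poses: list[ScaffoldPose], cutoff: float = 2.0
) -> PoseClusterSet:
    """Average-linkage clustering of receptor-frame core RMSDs, cut at 2 Å.

    Pairwise distance is RMSD over mapped atoms without re-superposition:
    poses share the docking frame, so superposing would erase the
    binding-site location that the clustering is meant to resolve.
    """
    if not scaffold_poses:
        raise ValueError("no scaffold poses to cluster")
    counts = {sp.coords.shape[0] for sp in scaffold_poses}
    if len(counts) > 1:
        raise ValueError(f"mixed mapped-atom counts: {sorted(counts)}")
    n = len(scaffold_poses)
    if n == 1:
        return PoseClusterSet(clusters=[list(scaffold_poses)])
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = scaffold_poses[i].coords - scaffold_poses[j].coords
            dm[i, j] = dm[j, i] = math.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    z = linkage(squareform(dm, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: dict[int, list[ScaffoldPose]] = {}
    for sp, lab in zip(scaffold_poses, labels):
        clusters.setdefault(int(lab), []).append(sp)
    # deterministic cluster order: by first pose id in each cluster
    ordered = sorted(clusters.values(), key=lambda cl: cl[0].pose_id)
    return PoseClusterSet(clusters=ordered)


def prioritize_clusters(
    clusterset: PoseClusterSet, active_ids: set[str], min_fraction: float = 0.5
) -> list[dict]:
    """Clusters covering strictly more than ``min_fraction`` of unique actives.

    Coverage counts unique active compounds (a compound may pose repeatedly
    in one cluster); returns per-cluster coverage, pose count, and unique
    compound count, in descending coverage order.
    """
    if not active_ids:
        raise ValueError("active id set must be non-empty")
    out = []
    for i, cl in enumerate(clusterset.clusters):
        compounds = {sp.compound_id for sp in cl}
        coverage = len(compounds & active_ids) / len(active_ids)
        if coverage > min_fraction:
            out.append(
                {
                    "cluster": i,
                    "coverage": coverage,
                    "n_poses": len(cl),
                    "n_compounds": len(compounds),
                }
            )
    return sorted(out, key=lambda d: (-d["coverage"], d["cluster"]))


# ---------------------------------------------------------------------------
# Interaction fingerprints
# ---------------------------------------------------------------------------

INTERACTION_TYPES = ("H-donor", "H-acceptor", "ionic", "metal", "arene")

HBOND_DIST = 3.5      # donor–acceptor heavy-atom distance, Å
HBOND_ANGLE = 120.0   # minimum D–H···A angle, degrees
IONIC_DIST = 4.0
ARENE_DIST = 4.5
METAL_DIST = 2.8

# Charged side-chain atoms by residue template (formal sign at pH 7)
_RES_CHARGES = {
    ("ASP", "OD1"): -1, ("ASP", "OD2"): -1,
    ("GLU", "OE1"): -1, ("GLU", "OE2"): -1,
    ("LYS", "NZ"): +1,
    ("ARG", "NH1"): +1, ("ARG", "NH2"): +1, ("ARG", "NE"): +1,
}
_AROMATIC_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def _residue_key(chain: str, res_index: int, res_name: str) -> str:
    return f"{chain}:{res_name}{res_index}"


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident points: angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _ligand_hydrogens(pose: Pose) -> dict[int, list[np.ndarray]]:
    """heavy-atom index -> attached H positions (inferred by distance)."""
    attached: dict[int, list[np.ndarray]] = {}
    h_idx = [i for i, e in enumerate(pose.elements) if e.upper() == "H"]
    heavy = [i for i, e in enumerate(pose.elements) if e.upper() != "H"]
    for h in h_idx:
        if not heavy:
            break
        dists = [(float(np.linalg.norm(pose.xyz[h] - pose.xyz[i])), i) for i in heavy]
        d, i = min(dists)
        if d < 1.3:
            attached.setdefault(i, []).append(pose.xyz[h])
    return attached


def plif(pose: Pose, receptor: Structure) -> dict[tuple[str, str], bool]:
    """Per-residue interaction bits for one pose.

    Geometric criteria: H-bond — donor/acceptor N,O heavy atoms ≤ 3.5 Å and
    D–H···A angle ≥ 120° whenever the donor hydrogen position is available
    (distance-only otherwise); ionic — opposite formal charges ≤ 4.0 Å;
    arene — aromatic ring centroids ≤ 4.5 Å; metal — receptor metal ion
    ≤ 2.8 Å from a ligand N/O. Bits are named from the residue's perspective
    (``H-donor`` = residue donates).
    """
    untyped = [
        f"{i}:{e}" for i, e in enumerate(pose.elements)
        if e.upper() not in _KNOWN_ELEMENTS
    ]
    if untyped:
        raise ValueError(f"untyped ligand atoms: {', '.join(untyped)}")

    lig_h = _ligand_hydrogens(pose)
    lig_no = [i for i, e in enumerate(pose.elements) if e.upper() in ("N", "O")]
    lig_charged = [i for i in range(len(pose.elements)) if pose.charges[i] != 0]
    lig_ring_centroids = [pose.xyz[list(r)].mean(axis=0) for r in pose.rings]

    bits: dict[tuple[str, str], bool] = {}

    for (chain, res_index, _icode), atoms in receptor.residues():
        res_name = atoms[0].res_name
        key = _residue_key(chain, res_index, res_name)
        named = {a.name: np.array(a.xyz) for a in atoms}

        # --- hydrogen bonds ---------------------------------------------
        res_donors = []     # (heavy pos, [H positions])
        res_acceptors = []  # heavy pos
        for a in atoms:
            el = a.element.upper()
            if el not in ("N", "O"):
                continue
            pos = np.array(a.xyz)
            h_pos = [
                np.array(b.xyz) for b in atoms
                if b.element.upper() == "H"
                and np.linalg.norm(np.array(b.xyz) - pos) < 1.3
            ]
            if el == "N":
                res_donors.append((pos, h_pos))
            else:
                res_acceptors.append(pos)
                if a.name in ("OG", "OG1", "OH"):  # hydroxyl oxygens also donate
                    res_donors.append((pos, h_pos))

        for dpos, hs in res_donors:          # residue donates to ligand N/O
            for li in lig_no:
                apos = pose.xyz[li]
                if np.linalg.norm(dpos - apos) > HBOND_DIST:
                    continue
                if hs and all(_angle_deg(dpos, h, apos) < HBOND_ANGLE for h in hs):
                    continue
                bits[(key, "H-donor")] = True
        for apos in res_acceptors:           # ligand donates to residue O
            for li in lig_no:
                dpos = pose.xyz[li]
                if np.linalg.norm(dpos - apos) > HBOND_DIST:
                    continue
                hs = lig_h.get(li, [])
                if hs and all(_angle_deg(dpos, h, apos) < HBOND_ANGLE for h in hs):
                    continue
                bits[(key, "H-acceptor")] = True

        # --- ionic -------------------------------------------------------
        for a in atoms:
            sign = _RES_CHARGES.get((res_name, a.name))
            if sign is None:
                continue
            for li in lig_charged:
                if sign * pose.charges[li] < 0 and (
                    np.linalg.norm(np.array(a.xyz) - pose.xyz[li]) <= IONIC_DIST
                ):
                    bits[(key, "ionic")] = True

        # --- arene -------------------------------------------------------
        ring_atoms = _AROMATIC_RING_ATOMS.get(res_name)
        if ring_atoms and lig_ring_centroids:
            pts = [named[n] for n in ring_atoms if n in named]
            if len(pts) >= 5:
                centroid = np.mean(pts, axis=0)
                for lc in lig_ring_centroids:
                    if np.linalg.norm(centroid - lc) <= ARENE_DIST:
                        bits[(key, "arene")] = True

        # --- metal -------------------------------------------------------
        for a in atoms:
            if a.element.upper() in _METALS:
                for li in lig_no:
                    if np.linalg.norm(np.array(a.xyz) - pose.xyz[li]) <= METAL_DIST:
                        bits[(key, "metal")] = True

    return bits


def interaction_frequency(
    plif_rows: list[dict[tuple[str, str], bool]], min_fraction: float = 0.10
) -> pd.DataFrame:
    """Per (residue, type) frequency over a pose set, flagged at ≥ min_fraction."""
    if not plif_rows:
        raise ValueError("no PLIF rows")
    counts: dict[tuple[str, str], int] = {}
    for row in plif_rows:
        for key, on in row.items():
            if on:
                counts[key] = counts.get(key, 0) + 1
    records = [
        {
            "residue": res, "interaction": itype,
            "frequency": c / len(plif_rows),
            "key_residue": c / len(plif_rows) >= min_fraction,
        }
        for (res, itype), c in sorted(counts.items())
    ]
    return pd.DataFrame(records, columns=["residue", "interaction", "frequency",
                                          "key_residue"])


# ---------------------------------------------------------------------------
# Geometry detectors
# ---------------------------------------------------------------------------

_ACID_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
SALT_BRIDGE_DIST = 4.0


def detect_salt_bridges(receptor: Structure) -> list[tuple[str, str, float]]:
    """Asp/Glu carboxylate – Lys/Arg guanidinium/amine pairs within 4 Å."""
    acids, bases = [], []
    for (chain, res_index, _icode), atoms in receptor.residues():
        res_name = atoms[0].res_name
        key = _residue_key(chain, res_index, res_name)
        for a in atoms:
            if (res_name, a.name) in _ACID_ATOMS:
                acids.append((key, np.array(a.xyz)))
            elif (res_name, a.name) in _BASE_ATOMS:
                bases.append((key, np.array(a.xyz)))
    pairs: dict[tuple[str, str], float] = {}
    for akey, apos in acids:
        for bkey, bpos in bases:
            d = float(np.linalg.norm(apos - bpos))
            if d <= SALT_BRIDGE_DIST:
                cur = pairs.get((akey, bkey))
                if cur is None or d < cur:
                    pairs[(akey, bkey)] = d
    return [(a, b, d) for (a, b), d in sorted(pairs.items())]


def halogen_bond_geometry(
    carbon: np.ndarray, halogen: np.ndarray, acceptor_oxygen: np.ndarray,
    dist_range: tuple[float, float] = (2.5, 6.0),
    angle_range: tuple[float, float] = (120.0, 180.0),
) -> tuple[float, float, bool]:
    """C–X···O distance (X to O), angle at X, and a plausibility flag.

    Halogen bonds are directional: favorable geometries sit roughly at
    2.5–6.0 Å and 120–180°, with sub-120° angles geometrically unfavorable.
    """
    c = np.asarray(carbon, dtype=float)
    x = np.asarray(halogen, dtype=float)
    o = np.asarray(acceptor_oxygen, dtype=float)
    if np.linalg.norm(c - x) < 1e-9 or np.linalg.norm(x - o) < 1e-9:
        raise ValueError("coincident points in halogen-bond geometry")
    dist = float(np.linalg.norm(x - o))
    angle = _angle_deg(c, x, o)
    plausible = dist_range[0] <= dist <= dist_range[1] and \
        angle_range[0] <= angle <= angle_range[1]
    return dist, angle, plausible


def pocket_volume(
    receptor: Structure,
    site_center: np.ndarray,
    site_radius: float,
    grid: float = 1.0,
) -> float:
    """Solvent-accessible site volume (ų) by grid counting.

    Grid points inside the site sphere and outside every receptor atom's vdW
    sphere are counted if they belong to the cavity region contiguous with
    the site center (flood fill on the free-point lattice, POVME-style
    seeded contiguity), so isolated crevices elsewhere do not contribute.
    """
    if grid <= 0:
        raise ValueError("grid spacing must be positive")
    center = np.asarray(site_center, dtype=float)
    coords = receptor.coords()
    radii = np.array([a.vdw for a in receptor.atoms])
    pad = site_radius + grid
    axes = [np.arange(c - pad, c + pad + grid / 2, grid) for c in center]
    nx, ny, nz = (len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    free = np.ones(len(pts), dtype=bool)
    tree = cKDTree(pts)
    for p, r in zip(coords, radii):
        if np.linalg.norm(p - center) > site_radius + r + 2 * grid:
            continue
        for idx in tree.query_ball_point(p, r):
            free[idx] = False
    free3 = free.reshape(nx, ny, nz)
    labels, _n = cc_label(free3)
    seed_idx = np.unravel_index(int(np.argmin(np.sum((pts - center) ** 2, axis=1))),
                                (nx, ny, nz))
    seed_label = labels[seed_idx]
    if seed_label == 0:  # center itself blocked: nothing contiguous with it
        return 0.0
    in_sphere = (np.sum((pts - center) ** 2, axis=1) <= site_radius ** 2).reshape(
        nx, ny, nz
    )
    count = int(np.sum((labels == seed_label) & in_sphere))
    return count * grid ** 3


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """√(Σ mᵢ|rᵢ − r̄|² / Σ mᵢ); unit masses by default."""
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    if c.size == 0:
        raise ValueError("radius of gyration needs at least one point")
    m = np.ones(len(c)) if masses is None else np.asarray(masses, dtype=float)
    com = np.average(c, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((c - com) ** 2, axis=1), weights=m)))
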