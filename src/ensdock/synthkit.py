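"""Synthetic fixtures: helical bundles, compound libraries, and pose fields.

Every generator is deterministic per seed and states its world explicitly:

* :func:`make_helical_bundle` — an idealized 12-transmembrane-helix (MFS-like)
  fold: ideal α-helices (φ = −57°, ψ = −47°; rise ≈ 1.5 Å, ≈ 100°/residue)
  built with full backbone (N, CA, C, O) on a ring, axes along z (the
  membrane normal), alternating direction as in an antiparallel bundle.
* :func:`make_compound_library` — steroid-template actives/inactives plus
  non-steroid decoys, each carrying a latent pharmacophore centroid and a
  hidden affinity consumed by the mock docking backend: actives sit at the
  planted binding site, nonactives are scattered.
* :func:`make_pose_field` — steroid-core poses planted at well-separated
  sites with Gaussian jitter, retaining ground-truth site labels for
  cluster-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .structio import Atom, Structure, VDW_RADII
from .screenlib import ActivityProfile, CompoundRecord, classify_activity
from .poselab import Pose

logger = logging.getLogger("ensdock.synthkit")

__all__ = [
    "FixtureSpec",
    "make_helical_bundle",
    "make_compound_library",
    "make_pose_field",
]

FIXTURE_KINDS = ("helical_bundle", "compound_library", "pose_field", "family")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Ideal-helix backbone construction (NeRF internal-coordinate chain build)
# ---------------------------------------------------------------------------

# Standard backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 117.2, 121.7, 120.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom from three predecessors (NeRF)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_helix_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Backbone coordinates of an ideal α-helix, one dict entry per atom kind."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(_place(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, _PSI))
        CA.append(_place(CA[-1], C[-1], N[-1], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_place(C[-1], N[-1], CA[-1], _B_CA_C, _A_N_CA_C, _PHI))
    O = []
    for i in range(n_res):
        O.append(_place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, _PSI + 180.0))
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O)}


def _align_to_z(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rotate the helix so its axis (first principal component of CA) is +z."""
    ca = atoms["CA"]
    centered = ca - ca.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        c = float(axis @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    center = ca.mean(axis=0)
    return {k: (v_ - center) @ rot.T for k, v_ in atoms.items()}


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_helical_bundle(
    n_helices: int = 12,
    len_per_helix: int = 25,
    ring_radius: float = 18.0,
    seed: int = 0,
    jitter_sigma: float = 0.05,
) -> Structure:
    """Ideal antiparallel α-helix bundle on a ring, axes along z.

    One chain per helix, residue numbering restarting per chain; a small
    seeded coordinate jitter (σ = 0.05 Å) decorrelates replicate fixtures
    without disturbing secondary structure. Deterministic per seed.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    rng = np.random.default_rng(seed)
    template = _align_to_z(_ideal_helix_backbone(len_per_helix))
    flip = np.diag([1.0, -1.0, -1.0])   # 180° about x: reverses helix direction
    atoms: list[Atom] = []
    for h in range(n_helices):
        phi = 2.0 * np.pi * h / n_helices
        offset = np.array([ring_radius * np.cos(phi), ring_radius * np.sin(phi), 0.0])
        chain = _CHAIN_IDS[h % len(_CHAIN_IDS)]
        placed = {
            k: (v @ flip.T if h % 2 else v) + offset for k, v in template.items()
        }
        for i in range(len_per_helix):
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                xyz = placed[name][i] + rng.normal(0.0, jitter_sigma, 3)
                atoms.append(
                    Atom(
                        element=element, name=name, res_index=i + 1, res_name="ALA",
                        chain=chain, xyz=tuple(xyz), vdw=VDW_RADII[element],
                    )
                )
    return Structure(atoms=atoms, source=f"helical_bundle(seed={seed})")


# ---------------------------------------------------------------------------
# Compound libraries
# ---------------------------------------------------------------------------

_STEROID_TEMPLATE = "CC12CCC3c4cc{halo}c({r3})cc4CCC3C1CC{d17}"
_R3_GROUPS = ["O", "OC", "OCC", "OCc5ccccc5", "OP(=O)(O)O", "N", "OC(C)=O", "OS(=O)(=O)O"]
_HALO_GROUPS = ["", "(F)", "(Cl)", "(Br)", "(I)"]
_D17_GROUPS = ["C2=O", "C2O", "C2"]
_DECOY_TEMPLATES = [
    "c1ccccc1{r}", "c1ccncc1{r}", "C1CCCCC1{r}", "c1ccc2ccccc2c1{r}",
]
_DECOY_R = ["O", "C", "CC", "N", "C(=O)O", "S(=O)(=O)O", "OC", "F"]


def _steroid_smiles(i: int) -> tuple[str, int]:
    """Deterministic enumeration of steroid-template variants; returns
    (smiles, variant index) where equal variant index ⇒ protomer siblings."""
    n = len(_R3_GROUPS) * len(_HALO_GROUPS) * len(_D17_GROUPS)
    v = i % n
    r3 = _R3_GROUPS[v % len(_R3_GROUPS)]
    halo = _HALO_GROUPS[(v // len(_R3_GROUPS)) % len(_HALO_GROUPS)]
    d17 = _D17_GROUPS[(v // (len(_R3_GROUPS) * len(_HALO_GROUPS))) % len(_D17_GROUPS)]
    return _STEROID_TEMPLATE.format(halo=halo, r3=r3, d17=d17), v


def make_compound_library(
    n_actives: int,
    n_inactives: int,
    n_decoys: int,
    seed: int = 0,
    profile: ActivityProfile | None = None,
    planted_site: tuple[float, float, float] = (0.0, 0.0, 0.0),
    target: str = "SYN1",
    box_halfwidth: float = 20.0,
) -> tuple[list[CompoundRecord], np.ndarray]:
    """Steroid-template screening library with a planted binding site.

    Actives receive μM activities at or below the active threshold and
    pharmacophore centroids at the planted site (σ = 0.5 Å); inactives get
    activities above the inactive threshold and decoys no activity, both
    with centroids scattered uniformly in a ±``box_halfwidth`` Å cube around
    the site. Classes are self-consistent with :func:`classify_activity`.
    Returns (records, planted site coordinates).
    """
    if min(n_actives, n_inactives, n_decoys) < 0:
        raise ValueError("counts must be non-negative")
    profile = profile or ActivityProfile()
    rng = np.random.default_rng(seed)
    site = np.asarray(planted_site, dtype=float)
    records: list[CompoundRecord] = []

    def scatter() -> tuple[float, float, float]:
        return tuple(site + rng.uniform(-box_halfwidth, box_halfwidth, 3))

    for i in range(n_actives):
        smiles, variant = _steroid_smiles(i)
        activity = float(rng.uniform(0.01, profile.active_um))
        records.append(
            CompoundRecord(
                compound_id=f"act{i:04d}", parent_id=f"steroid_v{variant}",
                smiles=smiles, activity_um=activity,
                activity_class=classify_activity(activity, profile), target=target,
                centroid=tuple(site + rng.normal(0.0, 0.5, 3)),
                affinity=float(rng.uniform(0.7, 1.0)),
            )
        )
    for i in range(n_inactives):
        smiles, variant = _steroid_smiles(n_actives + i)
        activity = float(rng.uniform(profile.inactive_um + 1.0, 100.0))
        records.append(
            CompoundRecord(
                compound_id=f"ina{i:04d}", parent_id=f"steroid_v{variant}",
                smiles=smiles, activity_um=activity,
                activity_class=classify_activity(activity, profile), target=target,
                centroid=scatter(), affinity=0.0,
            )
        )
    for i in range(n_decoys):
        template = _DECOY_TEMPLATES[i % len(_DECOY_TEMPLATES)]
        r = _DECOY_R[(i // len(_DECOY_TEMPLATES)) % len(_DECOY_R)]
        records.append(
            CompoundRecord(
                compound_id=f"dcy{i:04d}", parent_id=f"decoy_{i}",
                smiles=template.format(r=r), activity_um=None,
                activity_class="decoy", target=target,
                centroid=scatter(), affinity=0.0,
            )
        )
    if n_actives == 0:
        logger.warning("library has no actives: unusable for AUC/EF evaluation")
    return records, site


# ---------------------------------------------------------------------------
# Pose fields
# ---------------------------------------------------------------------------

_CORE_SMILES = "CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O"   # estrone-like template


def _embedded_core() -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(_CORE_SMILES))
    if AllChem.EmbedMolecule(mol, randomSeed=2024) != 0:
        raise RuntimeError("steroid core embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_pose_field(
    n_sites: int = 3,
    poses_per_site: int = 10,
    jitter_sigma: float = 0.3,
    seed: int = 0,
    site_spacing: float = 12.0,
) -> tuple[list[Pose], list[int]]:
    """Steroid-core poses planted at well-separated sites with Gaussian jitter.

    Site centers sit on a line ``site_spacing`` Å apart (≥ 8 Å guaranteed);
    each pose is the embedded core under one per-site rigid rotation,
    translated to its site plus N(0, σ²) jitter. Returns (poses,
    ground-truth site labels).
    """
    if n_sites < 1 or poses_per_site < 1:
        raise ValueError("counts must be at least 1")
    if site_spacing < 8.0:
        raise ValueError("site spacing below the 8 Å separation guarantee")
    rng = np.random.default_rng(seed)
    mol = _embedded_core()
    core = mol.GetConformer().GetPositions()
    core = core - core.mean(axis=0)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    poses: list[Pose] = []
    labels: list[int] = []
    for s in range(n_sites):
        center = np.array([site_spacing * s, 0.0, 0.0])
        rot = _random_rotation(rng)    # one orientation per site
        for p in range(poses_per_site):
            xyz = core @ rot.T + center + rng.normal(0.0, jitter_sigma, 3)
            poses.append(
                Pose(
                    pose_id=f"site{s}_pose{p}",
                    compound_id=f"cmpd{p:03d}",   # each compound poses once per site
                    elements=elements, xyz=xyz, mol=mol,
                )
            )
            labels.append(s)
    return poses, labels
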