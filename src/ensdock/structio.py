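"""Structure I/O, secondary structure, rigid blocks, and membrane-slab tagging.

This module holds the coordinate-level plumbing for the pipeline: a plain
PDB reader/writer built around a flat atom table, Cα extraction, a
Kabsch–Sander style hydrogen-bond secondary-structure assignment (with the
option of parsing a classic DSSP output file instead), decomposition of the
chain into rigid blocks (one block per contiguous helix/strand element,
single-residue blocks for coil), and membership tagging for an implicit
membrane slab of half-width ``z0`` centred on z = 0.

Units are Å throughout; residue indexing is 1-based and strictly increasing
within a chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("ensdock.structio")

__all__ = [
    "Atom",
    "Structure",
    "CAModel",
    "SecondaryStructureAssignment",
    "RigidBlocks",
    "MembraneSlab",
    "PDBParseError",
    "VDW_RADII",
    "read_structure",
    "write_structure",
    "extract_ca",
    "assign_secondary_structure",
    "parse_dssp",
    "decompose_rigid_blocks",
    "assign_membrane_slab",
]

# Bondi-style van der Waals radii (Å); DEFAULT_VDW covers odd elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31,
    "FE": 1.63, "MN": 1.61, "CU": 1.40,
}
DEFAULT_VDW = 1.70

# Single-bond covalent radii (Å) used to infer connectivity for clash checks.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}
DEFAULT_COVALENT = 0.77


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted; names the offending line."""


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    res_index: int          # 1-based author residue number
    res_name: str
    chain: str
    xyz: tuple[float, float, float]
    vdw: float
    icode: str = ""
    occupancy: float = 1.0
    hetero: bool = False

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if self.vdw <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Structure:
    """Flat atom table plus chain bookkeeping; substrate of all geometry ops."""

    atoms: list[Atom]
    source: str = ""

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=tuple(map(float, p))) for a, p in zip(self.atoms, xyz)]
        return Structure(atoms=atoms, source=self.source)

    def residues(self) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Group atoms by (chain, res_index, icode) preserving file order."""
        out: list[tuple[tuple[str, int, str], list[Atom]]] = []
        key_to_pos: dict[tuple[str, int, str], int] = {}
        for a in self.atoms:
            key = (a.chain, a.res_index, a.icode)
            if key not in key_to_pos:
                key_to_pos[key] = len(out)
                out.append((key, []))
            out[key_to_pos[key]][1].append(a)
        return out

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class CAModel:
    """One node per residue at Cα resolution."""

    xyz: np.ndarray                 # (n, 3)
    res_index: list[int]
    res_name: list[str]
    chain: list[str]

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.xyz)
        if not (len(self.res_index) == len(self.res_name) == len(self.chain) == n):
            raise ValueError("CAModel field lengths disagree")

    @property
    def n_nodes(self) -> int:
        return len(self.xyz)


@dataclass
class SecondaryStructureAssignment:
    """Per-residue class: H (helix), E (strand), C (coil)."""

    classes: list[str]

    def __post_init__(self):
        bad = set(self.classes) - {"H", "E", "C"}
        if bad:
            raise ValueError(f"invalid secondary-structure classes: {bad}")

    def __len__(self) -> int:
        return len(self.classes)

    def __str__(self) -> str:
        return "".join(self.classes)


@dataclass
class RigidBlocks:
    """Contiguous, non-overlapping residue-index ranges partitioning the chain.

    Ranges are half-open 0-based node ranges ``(start, stop)`` over the
    residue order of the model they were derived from.
    """

    blocks: list[tuple[int, int]]

    def __post_init__(self):
        prev_stop = 0
        for start, stop in self.blocks:
            if start != prev_stop or stop <= start:
                raise ValueError("blocks must partition residues contiguously")
            prev_stop = stop

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def labels(self) -> np.ndarray:
        """Per-residue block index."""
        n = self.blocks[-1][1] if self.blocks else 0
        lab = np.empty(n, dtype=int)
        for b, (start, stop) in enumerate(self.blocks):
            lab[start:stop] = b
        return lab


@dataclass
class MembraneSlab:
    axis: int = 2                   # z by default
    z0: float = 15.35
    mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self):
        if self.z0 <= 0:
            raise ValueError("slab half-width z0 must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_from_record(line: str, name: str) -> str:
    el = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not el:
        # Fall back on the atom name; first alphabetic char, two-letter
        # elements only when the name starts in column 13.
        stripped = name.strip()
        el = "".join(c for c in stripped if c.isalpha())[:2].upper()
        if el and el not in VDW_RADII:
            el = el[0]
    return el or "C"


def read_structure(pdb_text: str, source: str = "") -> Structure:
    """Parse ATOM/HETATM records into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered); insertion codes are preserved.
    """
    if not pdb_text or not pdb_text.strip():
        raise PDBParseError("empty PDB input")

    # key -> (atom, occupancy) for altloc resolution; key identifies the atom site
    best: dict[tuple, tuple[Atom, float]] = {}
    order: list[tuple] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            name = line[12:16]
            altloc = line[16]
            res_name = line[17:20].strip()
            chain = line[21].strip() or "A"
            res_index = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occ = float(occ_field) if occ_field else 1.0
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed PDB record at line {lineno}: {line!r}") from exc
        element = _element_from_record(line, name)
        atom = Atom(
            element=element,
            name=name.strip(),
            res_index=res_index,
            res_name=res_name,
            chain=chain,
            xyz=(x, y, z),
            vdw=VDW_RADII.get(element, DEFAULT_VDW),
            icode=icode,
            occupancy=occ,
            hetero=(rec == "HETATM"),
        )
        key = (chain, res_index, icode, atom.name)
        if key not in best:
            best[key] = (atom, occ if altloc.strip() else math.inf)
            order.append(key)
        else:
            _, prev_occ = best[key]
            if occ > prev_occ:
                best[key] = (atom, occ)
    atoms = [best[k][0] for k in order]
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    return Structure(atoms=atoms, source=source)


def write_structure(structure: Structure) -> str:
    """Serialize to PDB text (ATOM/HETATM/TER/END)."""
    lines = []
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER")
        prev_chain = a.chain
        serial += 1
        rec = "HETATM" if a.hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.xyz
        lines.append(
            f"{rec}{serial:5d} {name[:4]:<4s} {a.res_name:<3s} {a.chain:1s}"
            f"{a.res_index:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cα extraction
# ---------------------------------------------------------------------------

def extract_ca(structure: Structure) -> CAModel:
    """One node per residue that carries a CA atom; others skipped with a warning."""
    xyz, idx, names, chains = [], [], [], []
    skipped = 0
    for (chain, res_index, _icode), atoms in structure.residues():
        if all(a.hetero for a in atoms):
            continue
        ca = next((a for a in atoms if a.name == "CA" and a.element != "CA"), None)
        if ca is None:
            skipped += 1
            continue
        xyz.append(ca.xyz)
        idx.append(res_index)
        names.append(atoms[0].res_name)
        chains.append(chain)
    if skipped:
        logger.warning("extract_ca: skipped %d residue(s) lacking a CA atom", skipped)
    if not xyz:
        raise ValueError("no CA atoms found in structure")
    return CAModel(xyz=np.array(xyz), res_index=idx, res_name=names, chain=chains)


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander hydrogen-bond energies)
# ---------------------------------------------------------------------------

# E = f * (1/r(ON) + 1/r(CH) - 1/r(OH) - 1/r(CN)), f = q1*q2*332 kcal·Å/mol
_KS_FACTOR = 0.42 * 0.20 * 332.0
_KS_CUTOFF = -0.5   # kcal/mol
_NH_LENGTH = 1.0    # Å, amide H placed along the C(i-1)/CA bisector


def _backbone_table(structure: Structure):
    """Per-residue backbone coordinates (N, CA, C, O) in residue order.

    Returns None entries where a backbone atom is missing.
    """
    rows = []
    for (chain, res_index, _icode), atoms in structure.residues():
        if all(a.hetero for a in atoms):
            continue
        named = {a.name: np.array(a.xyz) for a in atoms}
        rows.append(
            {
                "chain": chain,
                "res_index": res_index,
                "N": named.get("N"),
                "CA": named.get("CA"),
                "C": named.get("C"),
                "O": named.get("O"),
                "res_name": atoms[0].res_name,
            }
        )
    return rows


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector in geometry construction")
    return v / n


def ks_hbond_energy(donor_N, donor_H, acceptor_C, acceptor_O) -> float:
    """Kabsch–Sander electrostatic hydrogen-bond energy in kcal/mol."""
    r_on = np.linalg.norm(acceptor_O - donor_N)
    r_ch = np.linalg.norm(acceptor_C - donor_H)
    r_oh = np.linalg.norm(acceptor_O - donor_H)
    r_cn = np.linalg.norm(acceptor_C - donor_N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atoms essentially on top of each other; treat as bonded
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(
    structure: Structure | None = None, dssp_text: str | None = None
) -> SecondaryStructureAssignment:
    """Assign H/E/C per residue.

    Either computes the assignment from backbone geometry via Kabsch–Sander
    hydrogen-bond energies (amide hydrogens placed geometrically when
    absent), or copies classes from a classic DSSP output file when
    ``dssp_text`` is given.
    """
    if dssp_text is not None:
        return parse_dssp(dssp_text)
    if structure is None:
        raise ValueError("provide a structure or a DSSP file")

    rows = _backbone_table(structure)
    n = len(rows)
    if n == 0:
        raise ValueError("structure has no polymer residues")
    for r in rows:
        if any(r[k] is None for k in ("N", "CA", "C", "O")):
            raise ValueError(
                f"missing backbone atoms in residue {r['chain']}{r['res_index']} "
                "and no DSSP file provided"
            )

    # Amide H for residue i needs C of i-1 (same chain, consecutive in order).
    H_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if rows[i]["chain"] != rows[i - 1]["chain"]:
            continue
        v = _unit(rows[i]["N"] - rows[i - 1]["C"]) + _unit(rows[i]["N"] - rows[i]["CA"])
        H_pos[i] = rows[i]["N"] + _NH_LENGTH * _unit(v)

    # hb[i][j]: NH of residue i donates to C=O of residue j
    hb = np.zeros((n, n), dtype=bool)
    ca = np.array([r["CA"] for r in rows])
    # cheap CA-distance prefilter: H-bond partners are always < 9 Å apart
    d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        if H_pos[i] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2 or d2[i, j] > 81.0:
                continue
            e = ks_hbond_energy(rows[i]["N"], H_pos[i], rows[j]["C"], rows[j]["O"])
            hb[i, j] = e < _KS_CUTOFF

    classes = ["C"] * n
    # Strand: Kabsch–Sander parallel / antiparallel bridges, |i-j| >= 3
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i + 1, j - 1] and hb[j + 1, i - 1])
            if parallel or antiparallel:
                classes[i] = "E"
                classes[j] = "E"
    # Helix: two consecutive i->i+4 turns give a minimal helix i..i+3
    # (turn4 at t means NH(t+4) donates to CO(t)); helix wins over strand.
    turn4 = [t + 4 < n and hb[t + 4, t] for t in range(n)]
    for t in range(1, n - 4):
        if turn4[t - 1] and turn4[t]:
            for k in range(t, t + 4):
                classes[k] = "H"
    return SecondaryStructureAssignment(classes=classes)


_DSSP_TO_CLASS = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
}


def parse_dssp(dssp_text: str) -> SecondaryStructureAssignment:
    """Parse a classic DSSP output file into H/E/C classes (verbatim copy)."""
    lines = dssp_text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a classic DSSP file: missing '#  RESIDUE' header")
    classes = []
    for line in lines[start:]:
        if len(line) < 17 or line[13] == "!":
            continue
        ss = line[16]
        classes.append(_DSSP_TO_CLASS.get(ss, "C"))
    if not classes:
        raise ValueError("DSSP file contains no residue records")
    return SecondaryStructureAssignment(classes=classes)


# ---------------------------------------------------------------------------
# Rigid blocks & membrane slab
# ---------------------------------------------------------------------------

def decompose_rigid_blocks(ss: SecondaryStructureAssignment) -> RigidBlocks:
    """One block per contiguous H or E element; each coil residue its own block."""
    if len(ss) == 0:
        raise ValueError("empty secondary-structure assignment")
    blocks: list[tuple[int, int]] = []
    i = 0
    n = len(ss)
    while i < n:
        c = ss.classes[i]
        if c == "C":
            blocks.append((i, i + 1))
            i += 1
        else:
            j = i
            while j < n and ss.classes[j] == c:
                j += 1
            blocks.append((i, j))
            i = j
    return RigidBlocks(blocks=blocks)


def assign_membrane_slab(camodel: CAModel, z0: float = 15.35, axis: int = 2) -> MembraneSlab:
    """Tag residues inside the implicit membrane slab |z| <= z0 (closed interval)."""
    if z0 <= 0:
        raise ValueError("slab half-width z0 must be positive")
    mask = np.abs(camodel.xyz[:, axis]) <= z0
    return MembraneSlab(axis=axis, z0=z0, mask=mask)
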