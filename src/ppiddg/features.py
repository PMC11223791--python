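"""Non-graph (tabular) features and feature normalization.

Covers substitution-matrix scores (BLOSUM62, PAM250), physicochemical
property deltas from a curated per-residue table, relative solvent
accessibility (Shrake-Rupley with 92 sphere points, probe 1.4 A, normalized
by theoretical max ASA), residue depth (mean distance of residue atoms to
the nearest solvent-exposed atom), dihedral-window secondary structure, and
importers for externally computed PSSM and empirical-force-field ddG
columns.  Missing optional columns are explicit NaN sentinels, never silent
zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from .structures import (
    CANONICAL_AA,
    ComplexStructure,
    ResidueKey,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

SENTINEL = np.nan

PROPERTY_NAMES = ("hydrophobicity", "volume", "charge", "polarity", "mass", "pi")


def _load_property_table() -> dict[str, np.ndarray]:
    text = resources.files("ppiddg.data").joinpath("aa_properties.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        table[parts[0]] = np.array([float(x) for x in parts[1:]])
    return table


PROPERTY_TABLE = _load_property_table()

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_PAM250 = substitution_matrices.load("PAM250")


class SubstitutionLookupError(KeyError):
    """Amino-acid letter outside the canonical alphabet."""


def substitution_scores(wt_aa: str, mut_aa: str) -> dict[str, float]:
    """Symmetric BLOSUM62 and PAM250 scores for a substitution."""
    for aa in (wt_aa, mut_aa):
        if aa not in CANONICAL_AA:
            raise SubstitutionLookupError(f"unknown amino acid letter {aa!r}")
    return {
        "blosum62": float(_BLOSUM62[wt_aa][mut_aa]),
        "pam250": float(_PAM250[wt_aa][mut_aa]),
    }


def property_deltas(wt_aa: str, mut_aa: str) -> dict[str, float]:
    """Per-property mutant minus wild type deltas."""
    for aa in (wt_aa, mut_aa):
        if aa not in CANONICAL_AA:
            raise SubstitutionLookupError(f"unknown amino acid letter {aa!r}")
    delta = PROPERTY_TABLE[mut_aa] - PROPERTY_TABLE[wt_aa]
    return {f"d_{name}": float(v) for name, v in zip(PROPERTY_NAMES, delta)}


# ---------------------------------------------------------------------------
# Solvent accessibility, depth, secondary structure
# ---------------------------------------------------------------------------

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 92

_SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "Se": 1.90}

#: Theoretical maximum accessible surface areas (A^2) per residue type.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def _sphere_points(n: int = N_SPHERE_POINTS) -> np.ndarray:
    """Near-uniform unit-sphere points via the golden spiral."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


_UNIT_SPHERE = _sphere_points()


def atom_sasa(structure: ComplexStructure) -> np.ndarray:
    """Per-heavy-atom solvent-accessible surface area (Shrake-Rupley)."""
    atoms = structure.heavy_atoms()
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_SASA_RADII.get(a.element, 1.8) + PROBE_RADIUS for a in atoms])
    n = len(atoms)
    sasa = np.zeros(n)
    if n == 0:
        return sasa
    tree_d = cdist(coords, coords)
    for i in range(n):
        pts = coords[i] + radii[i] * _UNIT_SPHERE
        neighbors = np.nonzero((tree_d[i] < radii[i] + radii.max()) & (np.arange(n) != i))[0]
        neighbors = neighbors[tree_d[i, neighbors] < radii[i] + radii[neighbors]]
        buried = np.zeros(len(pts), dtype=bool)
        for j in neighbors:
            buried |= np.linalg.norm(pts - coords[j], axis=1) < radii[j]
        sasa[i] = (1.0 - buried.mean()) * 4.0 * np.pi * radii[i] ** 2
    return sasa


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone(structure: ComplexStructure, key: ResidueKey) -> dict[str, np.ndarray] | None:
    try:
        atoms = {a.name: a.coords for a in structure.residue_atoms(key)}
    except KeyError:
        return None
    if not {"N", "CA", "C"} <= atoms.keys():
        return None
    return atoms


def phi_psi(structure: ComplexStructure, key: ResidueKey) -> tuple[float | None, float | None]:
    """Backbone dihedrals using the adjacent indexed residues of the same chain."""
    residues = structure.residues()
    i = residues.index(key)
    atoms = _backbone(structure, key)
    if atoms is None:
        return None, None
    phi = psi = None
    if i > 0 and residues[i - 1].chain_id == key.chain_id:
        prev = _backbone(structure, residues[i - 1])
        if prev is not None:
            phi = _dihedral(prev["C"], atoms["N"], atoms["CA"], atoms["C"])
    if i + 1 < len(residues) and residues[i + 1].chain_id == key.chain_id:
        nxt = _backbone(structure, residues[i + 1])
        if nxt is not None:
            psi = _dihedral(atoms["N"], atoms["CA"], atoms["C"], nxt["N"])
    return phi, psi


def secondary_structure(phi: float | None, psi: float | None) -> str:
    """Dihedral-window assignment: helix / strand / coil (coil when undefined)."""
    if phi is None or psi is None:
        return "coil"
    if -145.0 <= phi <= -35.0 and -70.0 <= psi <= 50.0:
        return "helix"
    if -180.0 <= phi <= -40.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
        return "strand"
    return "coil"


SS_CLASSES = ("helix", "strand", "coil")


def accessibility_depth_ss(
    structure: ComplexStructure,
    residue: ResidueKey,
    sasa: np.ndarray | None = None,
) -> dict[str, float]:
    """RSA, residue depth (A) and secondary-structure one-hot for one residue.

    ``sasa`` may carry a precomputed per-heavy-atom SASA for the structure to
    avoid recomputation across residues.  Missing backbone atoms yield NaN
    sentinels for rsa/depth and the coil convention for secondary structure.
    """
    atoms = structure.heavy_atoms()
    if sasa is None:
        sasa = atom_sasa(structure)
    res_idx = [i for i, a in enumerate(atoms) if a.residue_key == residue]
    if not res_idx:
        raise KeyError(f"residue {residue} not in structure")
    bb = _backbone(structure, residue)
    if bb is None:
        out = {"rsa": SENTINEL, "depth": SENTINEL}
        out.update({f"ss_{c}": 1.0 if c == "coil" else 0.0 for c in SS_CLASSES})
        return out
    one = THREE_TO_ONE.get(structure.residue_name(residue), None)
    max_asa = MAX_ASA.get(one, 200.0)
    rsa = float(sasa[res_idx].sum() / max_asa)

    exposed = np.nonzero(sasa > 0)[0]
    coords = np.array([a.coords for a in atoms])
    if len(exposed) == 0:
        depth = SENTINEL
    else:
        d = cdist(coords[res_idx], coords[exposed]).min(axis=1)
        depth = float(d.mean())

    phi, psi = phi_psi(structure, residue)
    ss = secondary_structure(phi, psi)
    out = {"rsa": rsa, "depth": depth}
    out.update({f"ss_{c}": 1.0 if c == ss else 0.0 for c in SS_CLASSES})
    return out


# ---------------------------------------------------------------------------
# Importers for externally computed feature columns
# ---------------------------------------------------------------------------


class JoinError(ValueError):
    """Duplicate keys in an imported feature table."""


def import_pssm(text: str, chain: str) -> dict[tuple[str, int], dict[str, float]]:
    """Parse a PSI-BLAST ASCII matrix into per-(chain, position) score rows.

    Accepts the standard ``-out_ascii_pssm`` layout: a header line listing the
    20 amino-acid columns followed by ``pos aa s1 ... s20`` rows (only the
    first 20 score columns are used).
    """
    rows: dict[tuple[str, int], dict[str, float]] = {}
    alphabet: list[str] | None = None
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if alphabet is None and len(parts) >= 20 and all(p in CANONICAL_AA for p in parts[:20]):
            alphabet = parts[:20]
            continue
        if alphabet and parts[0].isdigit() and len(parts) >= 22:
            pos = int(parts[0])
            key = (chain, pos)
            if key in rows:
                raise JoinError(f"duplicate PSSM position {pos}")
            scores = [float(x) for x in parts[2:22]]
            rows[key] = dict(zip(alphabet, scores))
    return rows


def import_foldx(text: str) -> dict[str, float]:
    """Parse a delimited ``mutation<TAB>ddg`` table keyed by mutation string."""
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        *key_parts, value = line.replace("\t", " ").rsplit(" ", 1)
        key = key_parts[0].strip() if key_parts else ""
        if key in table:
            raise JoinError(f"duplicate mutation key {key!r}")
        table[key] = float(value)
    return table


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class NormalizerFitError(ValueError):
    """Normalizer fitted with an empty or too-small training mask."""


@dataclass
class Normalizer:
    """Per-column z-scoring with statistics learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray
    columns: list[str] | None = None

    @classmethod
    def fit(cls, rows: np.ndarray, training_mask: np.ndarray | None = None,
            columns: list[str] | None = None) -> "Normalizer":
        rows = np.asarray(rows, dtype=float)
        if training_mask is None:
            training_mask = np.ones(rows.shape[0], dtype=bool)
        train = rows[np.asarray(training_mask, dtype=bool)]
        if train.shape[0] < 2:
            raise NormalizerFitError("need at least 2 training rows to fit")
        mean = np.nanmean(train, axis=0)
        sd = np.nanstd(train, axis=0, ddof=0)
        constant = sd < 1e-12
        if constant.any():
            logger.warning("%d constant feature column(s) pass through unscaled",
                           int(constant.sum()))
        scale = np.where(constant, 1.0, sd)
        mean = np.where(constant, 0.0, mean)
        return cls(mean=mean, scale=scale, columns=columns)

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        return (rows - self.mean) / self.scale
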