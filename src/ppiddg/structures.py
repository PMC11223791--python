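"""Protein complex structures, mutation strings and pharmacophore typing.

The in-memory model is deliberately flat: a :class:`ComplexStructure` is an
ordered list of :class:`AtomRecord` plus an index from :class:`ResidueKey`
(chain, author residue number, insertion code) to the atom span of that
residue.  Author (PDB) numbering with insertion codes is the coordinate
convention throughout the package; positions are 1-based exactly as printed
in mutation strings such as ``L45G``.

Hydrogens are ignored everywhere downstream (contact rules and solvent
accessibility are defined over heavy atoms), and waters/hetero records are
kept in the atom list but excluded from the residue index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_AA = frozenset(ONE_TO_THREE)

#: Backbone atom names retained (together with CB) by the naive mutant builder.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Base error for structure handling."""


class PDBParseError(StructureError):
    """A malformed fixed-width record; the message names the line number."""


class EmptyStructureError(StructureError):
    """Input contained no ATOM records."""


class MutationFormatError(ValueError):
    """A mutation string does not follow the accepted grammar."""


class DegenerateMutationError(MutationFormatError):
    """Wild-type and mutant amino acids are identical."""


class ChainResolutionError(MutationFormatError):
    """No chain given in the mutation string and no default chain supplied."""


class WildTypeMismatchError(StructureError):
    """Residue at the mutation position does not match the stated wild type."""


class MissingResidueError(StructureError, KeyError):
    """Requested residue is absent from the structure."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identifies a residue by chain, author sequence number and insertion code."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_seq}{self.insertion_code}"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


class PharmacophoreClass(str, Enum):
    """Eight atom categories used by the cutoff-scanning signatures."""

    HYDROPHOBIC = "hydrophobic"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    ACCEPTOR = "acceptor"
    DONOR = "donor"
    AROMATIC = "aromatic"
    SULPHUR = "sulphur"
    NEUTRAL = "neutral"


PHARMACOPHORE_ORDER: tuple[PharmacophoreClass, ...] = tuple(PharmacophoreClass)


def _load_pharmacophore_table() -> dict[tuple[str, str], frozenset[PharmacophoreClass]]:
    table: dict[tuple[str, str], frozenset[PharmacophoreClass]] = {}
    text = resources.files("ppiddg.data").joinpath("pharmacophores.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        res, atom, classes = line.split("\t")
        table[(res, atom)] = frozenset(PharmacophoreClass(c) for c in classes.split(","))
    return table


PHARMACOPHORE_TABLE = _load_pharmacophore_table()

#: Ring-system membership (aromatic side-chain atoms of HIS/PHE/TYR/TRP),
#: derived from the bundled pharmacophore table rather than perceived from geometry.
AROMATIC_ATOMS = frozenset(
    key for key, classes in PHARMACOPHORE_TABLE.items()
    if PharmacophoreClass.AROMATIC in classes
)


def classify_pharmacophore(atom: AtomRecord) -> frozenset[PharmacophoreClass]:
    """Pharmacophore classes of a heavy atom; unknown pairs fall back to neutral."""
    key = (atom.residue_name, atom.name)
    try:
        return PHARMACOPHORE_TABLE[key]
    except KeyError:
        logger.warning("no pharmacophore entry for %s %s; classified neutral", *key)
        return frozenset({PharmacophoreClass.NEUTRAL})


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution: ``L45G`` on some chain."""

    chain_id: str
    wt_aa: str
    position: int
    mut_aa: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise MutationFormatError(f"non-canonical amino acid letter {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise DegenerateMutationError(
                f"degenerate mutation {self.wt_aa}{self.position}{self.mut_aa}"
            )

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.position, self.insertion_code)

    def reversed(self) -> "MutationSpec":
        return replace(self, wt_aa=self.mut_aa, mut_aa=self.wt_aa)

    def __str__(self) -> str:
        return f"{self.chain_id} {self.wt_aa}{self.position}{self.insertion_code}{self.mut_aa}"


@dataclass
class ComplexStructure:
    """An ordered atom table with a residue index over polymer residues."""

    atoms: list[AtomRecord]
    naive_mutant: bool = False
    _index: dict[ResidueKey, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._index = {}
        for i, atom in enumerate(self.atoms):
            if atom.is_hetero or atom.residue_name in WATER_NAMES:
                continue
            self._index.setdefault(atom.residue_key, []).append(i)

    @property
    def residue_index(self) -> dict[ResidueKey, list[int]]:
        return self._index

    @property
    def chains(self) -> set[str]:
        return {key.chain_id for key in self._index}

    def residues(self) -> list[ResidueKey]:
        """Residue keys in canonical (chain, seq, icode) order."""
        return sorted(self._index)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        try:
            idx = self._index[key]
        except KeyError:
            raise MissingResidueError(f"residue {key} not in structure") from None
        return [self.atoms[i] for i in idx]

    def residue_name(self, key: ResidueKey) -> str:
        return self.residue_atoms(key)[0].residue_name

    def heavy_atoms(self) -> list[AtomRecord]:
        """Non-hydrogen atoms of indexed (polymer) residues."""
        return [
            self.atoms[i]
            for idx in self._index.values()
            for i in idx
            if not self.atoms[i].is_hydrogen
        ]

    def coords(self, keys: Iterable[ResidueKey] | None = None) -> np.ndarray:
        if keys is None:
            atoms = self.heavy_atoms()
        else:
            atoms = [a for k in keys for a in self.residue_atoms(k) if not a.is_hydrogen]
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].upper() in ("CL", "BR", "ZN", "MG", "FE", "NA", "MN", "CU", "NI", "CO"):
        return stripped[:2].capitalize()
    return stripped[0]


def read_structure(pdb_text: str) -> ComplexStructure:
    """Parse fixed-width ATOM/HETATM records into a :class:`ComplexStructure`.

    Altloc conformers are resolved to the highest occupancy (ties broken by
    file order).  HETATM and water records are retained in the atom list with
    ``is_hetero`` set but excluded from the residue index.
    """
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip()
            residue_seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            elem_field = line[76:78].strip() if len(line) >= 78 else ""
            element = elem_field.capitalize() if elem_field else _guess_element(name)
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed record at line {lineno}: {exc}") from exc
        coords = np.array([x, y, z], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise PDBParseError(f"non-finite coordinates at line {lineno}")
        if not chain_id:
            raise PDBParseError(f"blank chain identifier at line {lineno}")
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, residue_name=residue_name,
            chain_id=chain_id, residue_seq=residue_seq, insertion_code=icode,
            coords=coords, is_hetero=(rec == "HETATM" or residue_name in WATER_NAMES),
            occupancy=occupancy, altloc=altloc,
        ))
    if not any(not a.is_hetero for a in atoms):
        raise EmptyStructureError("no ATOM records in input")
    return ComplexStructure(_resolve_altlocs(atoms))


def _resolve_altlocs(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    best: dict[tuple, int] = {}  # (residue key, atom name) -> index into atoms
    order: list[tuple] = []
    for i, atom in enumerate(atoms):
        key = (atom.residue_key, atom.name, atom.is_hetero)
        if key not in best:
            best[key] = i
            order.append(key)
        elif atoms[i].occupancy > atoms[best[key]].occupancy:
            best[key] = i
    resolved = []
    for key in order:
        atom = atoms[best[key]]
        atom.altloc = ""
        resolved.append(atom)
    return resolved


def write_structure(structure: ComplexStructure) -> str:
    """Serialize back to fixed-width PDB text (coordinates to 3 decimals)."""
    lines = []
    for atom in structure.atoms:
        rec = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"{rec}{atom.serial:>5d} {name}{'':1s}{atom.residue_name:>3s} "
            f"{atom.chain_id}{atom.residue_seq:>4d}{atom.insertion_code or '':1s}   "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)([A-Za-z])$")


def parse_mutation(text: str, default_chain: str | None = None) -> list[MutationSpec]:
    """Parse ``"L45G"`` / ``"I D46A; I R48K"`` style mutation strings.

    Each semicolon-separated segment is either ``<chain> <mutation>`` or a bare
    mutation resolved against ``default_chain``.  Order is preserved.
    """
    if not text or not text.strip():
        raise MutationFormatError("empty mutation string")
    specs = []
    for segment in text.split(";"):
        segment = segment.strip()
        if not segment:
            continue
        parts = segment.split()
        if len(parts) == 2:
            chain, token = parts
        elif len(parts) == 1:
            if default_chain is None:
                raise ChainResolutionError(
                    f"no chain in {segment!r} and no default chain given"
                )
            chain, token = default_chain, parts[0]
        else:
            raise MutationFormatError(f"cannot parse mutation segment {segment!r}")
        m = _MUTATION_RE.match(token)
        if not m:
            raise MutationFormatError(f"cannot parse mutation token {token!r}")
        wt, pos, icode, mut = m.groups()
        specs.append(MutationSpec(
            chain_id=chain, wt_aa=wt.upper(), position=int(pos),
            mut_aa=mut.upper(), insertion_code=icode.upper(),
        ))
    if not specs:
        raise MutationFormatError("mutation string contains no mutations")
    return specs


def build_mutant(structure: ComplexStructure, spec: MutationSpec) -> ComplexStructure:
    """Naive mutant: rename the residue, keep backbone (+ CB where shared).

    This is an explicit approximation in place of template-based mutant
    modelling: the renamed residue keeps N/CA/C/O, and CB when both the
    wild-type and mutant residue types have one; remaining side-chain atoms
    are dropped.  No other atom is touched.
    """
    key = spec.residue_key
    res_atoms = structure.residue_atoms(key)  # raises MissingResidueError
    found = res_atoms[0].residue_name
    expected = ONE_TO_THREE[spec.wt_aa]
    if found != expected:
        raise WildTypeMismatchError(
            f"residue {key} is {found}, expected {expected} for {spec}"
        )
    mut_three = ONE_TO_THREE[spec.mut_aa]
    keep = set(BACKBONE_ATOMS)
    if spec.mut_aa != "G" and spec.wt_aa != "G":
        keep.add("CB")
    keep.add("OXT")
    new_atoms = []
    for atom in structure.atoms:
        if atom.residue_key == key and not atom.is_hetero:
            if atom.name not in keep:
                continue
            atom = replace(atom, residue_name=mut_three, coords=atom.coords.copy())
        new_atoms.append(atom)
    return ComplexStructure(new_atoms, naive_mutant=True)


def apply_mutations(structure: ComplexStructure, specs: Iterable[MutationSpec]) -> ComplexStructure:
    """Apply several point substitutions, each at a distinct position."""
    out = structure
    for spec in specs:
        out = build_mutant(out, spec)
    return out
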