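"""Atomic interaction detection and mutation-induced contact changes.

Ten interaction types are distinguished (van der Waals, aromatic,
hydrophobic, carbonyl-carbonyl, polar, ring, covalent, hydrogen bond,
halogen bond, metal complex).  The built-in detector types heavy-atom pairs
with a geometric rule table bundled in ``data/contact_rules.yaml``;
externally computed contact files in a simple delimited dialect can be
imported instead and are interchangeable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structures import (
    AtomRecord,
    AROMATIC_ATOMS,
    ComplexStructure,
    PharmacophoreClass,
    ResidueKey,
    classify_pharmacophore,
)

logger = logging.getLogger(__name__)


class InteractionType(str, Enum):
    VDW = "vdw"
    AROMATIC = "aromatic"
    HYDROPHOBIC = "hydrophobic"
    CARBONYL = "carbonyl"
    POLAR = "polar"
    RING = "ring"
    COVALENT = "covalent"
    HYDROGEN_BOND = "hydrogen_bond"
    HALOGEN_BOND = "halogen_bond"
    METAL_COMPLEX = "metal_complex"


INTERACTION_ORDER: tuple[InteractionType, ...] = tuple(InteractionType)

_POLAR_CLASSES = frozenset({
    PharmacophoreClass.DONOR, PharmacophoreClass.ACCEPTOR,
    PharmacophoreClass.POSITIVE, PharmacophoreClass.NEGATIVE,
})


class ElementRadiusError(KeyError):
    """Element missing from the radius tables."""


class ArpeggioMappingError(ValueError):
    """Imported contact rows referencing residues/atoms absent from the structure."""


@dataclass
class ContactRules:
    """Thresholds of the built-in geometric detector (Angstrom)."""

    capture_radius: float
    vdw_slack: float
    covalent_slack: float
    hydrogen_bond_max: float
    hydrophobic_max: float
    aromatic_max: float
    polar_max: float
    halogen_max: float
    metal_max: float
    carbonyl_max: float
    vdw_radii: dict[str, float]
    covalent_radii: dict[str, float]
    metals: frozenset[str]
    halogens: frozenset[str]

    @classmethod
    def default(cls) -> "ContactRules":
        raw = yaml.safe_load(
            resources.files("ppiddg.data").joinpath("contact_rules.yaml").read_text()
        )
        return cls(
            capture_radius=raw["capture_radius"],
            vdw_slack=raw["vdw_slack"],
            covalent_slack=raw["covalent_slack"],
            hydrogen_bond_max=raw["hydrogen_bond_max"],
            hydrophobic_max=raw["hydrophobic_max"],
            aromatic_max=raw["aromatic_max"],
            polar_max=raw["polar_max"],
            halogen_max=raw["halogen_max"],
            metal_max=raw["metal_max"],
            carbonyl_max=raw["carbonyl_max"],
            vdw_radii=raw["vdw_radii"],
            covalent_radii=raw["covalent_radii"],
            metals=frozenset(raw["metals"]),
            halogens=frozenset(raw["halogens"]),
        )

    def vdw_radius(self, element: str) -> float:
        try:
            return self.vdw_radii[element]
        except KeyError:
            raise ElementRadiusError(f"no van der Waals radius for element {element!r}")

    def covalent_radius(self, element: str) -> float:
        try:
            return self.covalent_radii[element]
        except KeyError:
            raise ElementRadiusError(f"no covalent radius for element {element!r}")


@dataclass
class Contact:
    atom_a: AtomRecord
    atom_b: AtomRecord
    types: frozenset[InteractionType]
    distance: float

    @property
    def residues(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.atom_a.residue_key, self.atom_b.residue_key)

    @property
    def cross_chain(self) -> bool:
        return self.atom_a.chain_id != self.atom_b.chain_id


def _pair_types(a: AtomRecord, b: AtomRecord, d: float, rules: ContactRules) -> set[InteractionType]:
    types: set[InteractionType] = set()
    a_metal = a.is_hetero and a.element in rules.metals
    b_metal = b.is_hetero and b.element in rules.metals
    if a_metal or b_metal:
        other = b if a_metal else a
        if d <= rules.metal_max and other.element in ("N", "O", "S"):
            types.add(InteractionType.METAL_COMPLEX)
        return types
    classes_a = classify_pharmacophore(a)
    classes_b = classify_pharmacophore(b)
    if d <= rules.vdw_radius(a.element) + rules.vdw_radius(b.element) + rules.vdw_slack:
        types.add(InteractionType.VDW)
    if d < rules.covalent_radius(a.element) + rules.covalent_radius(b.element) + rules.covalent_slack:
        types.add(InteractionType.COVALENT)
    if d <= rules.hydrogen_bond_max and (
        (PharmacophoreClass.DONOR in classes_a and PharmacophoreClass.ACCEPTOR in classes_b)
        or (PharmacophoreClass.DONOR in classes_b and PharmacophoreClass.ACCEPTOR in classes_a)
    ):
        types.add(InteractionType.HYDROGEN_BOND)
    if (
        d <= rules.hydrophobic_max
        and a.element == "C" and b.element == "C"
        and PharmacophoreClass.HYDROPHOBIC in classes_a
        and PharmacophoreClass.HYDROPHOBIC in classes_b
    ):
        types.add(InteractionType.HYDROPHOBIC)
    if (
        d <= rules.aromatic_max
        and (a.residue_name, a.name) in AROMATIC_ATOMS
        and (b.residue_name, b.name) in AROMATIC_ATOMS
    ):
        types.add(InteractionType.AROMATIC)
        types.add(InteractionType.RING)
    if d <= rules.polar_max and (classes_a & _POLAR_CLASSES) and (classes_b & _POLAR_CLASSES):
        types.add(InteractionType.POLAR)
    if d <= rules.halogen_max and (
        (a.element in rules.halogens and PharmacophoreClass.ACCEPTOR in classes_b)
        or (b.element in rules.halogens and PharmacophoreClass.ACCEPTOR in classes_a)
    ):
        types.add(InteractionType.HALOGEN_BOND)
    if d <= rules.carbonyl_max and a.name == "C" and b.name == "C":
        types.add(InteractionType.CARBONYL)
    return types


def detect_contacts(structure: ComplexStructure, rules: ContactRules | None = None) -> list[Contact]:
    """Type every heavy-atom pair within the capture radius against the rule table.

    Pairs within one residue are not reported; a pair may carry several types.
    Metal HETATM atoms participate only in the metal-complex rule.
    """
    rules = rules or ContactRules.default()
    atoms = structure.heavy_atoms()
    atoms += [
        a for a in structure.atoms
        if a.is_hetero and a.element in rules.metals and not a.is_hydrogen
    ]
    if not atoms:
        return []
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    contacts = []
    for i, j in sorted(tree.query_pairs(rules.capture_radius)):
        a, b = atoms[i], atoms[j]
        if a.residue_key == b.residue_key and a.is_hetero == b.is_hetero:
            continue
        d = float(np.linalg.norm(a.coords - b.coords))
        types = _pair_types(a, b, d, rules)
        if types:
            contacts.append(Contact(atom_a=a, atom_b=b, types=frozenset(types), distance=d))
    return contacts


#: Labels accepted by the importer, mapped onto the closed type set.
_IMPORT_LABELS = {
    "vdw": InteractionType.VDW,
    "van_der_waals": InteractionType.VDW,
    "aromatic": InteractionType.AROMATIC,
    "hydrophobic": InteractionType.HYDROPHOBIC,
    "carbonyl": InteractionType.CARBONYL,
    "polar": InteractionType.POLAR,
    "weak_polar": InteractionType.POLAR,
    "ring": InteractionType.RING,
    "covalent": InteractionType.COVALENT,
    "hbond": InteractionType.HYDROGEN_BOND,
    "hydrogen_bond": InteractionType.HYDROGEN_BOND,
    "weak_hbond": InteractionType.HYDROGEN_BOND,
    "xbond": InteractionType.HALOGEN_BOND,
    "halogen_bond": InteractionType.HALOGEN_BOND,
    "metal_complex": InteractionType.METAL_COMPLEX,
    "metal": InteractionType.METAL_COMPLEX,
}


def import_contacts(text: str, structure: ComplexStructure) -> list[Contact]:
    """Import an external contact file.

    Dialect (documented in the README): one contact per line, whitespace- or
    tab-separated columns ``chain/seq[icode]/atom  chain/seq[icode]/atom
    label[,label...]  distance``; ``#`` lines are comments.  Unknown labels
    are ignored with a warning; rows whose residues or atoms cannot be
    resolved in the structure raise a mapping error listing the rows.
    """
    contacts: list[Contact] = []
    bad_rows: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            bad_rows.append(lineno)
            continue
        try:
            atom_a = _resolve_atom(parts[0], structure)
            atom_b = _resolve_atom(parts[1], structure)
            distance = float(parts[3])
        except (KeyError, ValueError):
            bad_rows.append(lineno)
            continue
        types = set()
        for label in parts[2].split(","):
            mapped = _IMPORT_LABELS.get(label.lower())
            if mapped is None:
                logger.warning("ignoring unknown interaction label %r (line %d)", label, lineno)
            else:
                types.add(mapped)
        if types:
            contacts.append(Contact(atom_a=atom_a, atom_b=atom_b,
                                    types=frozenset(types), distance=distance))
    if bad_rows:
        raise ArpeggioMappingError(f"unresolvable contact rows: lines {bad_rows}")
    return contacts


def _resolve_atom(token: str, structure: ComplexStructure) -> AtomRecord:
    chain, seq, name = token.split("/")
    icode = ""
    if seq and seq[-1].isalpha():
        seq, icode = seq[:-1], seq[-1]
    key = ResidueKey(chain, int(seq), icode)
    for atom in structure.residue_atoms(key):
        if atom.name == name:
            return atom
    raise KeyError(token)


# Backwards-compatible alias matching the external tool the dialect emulates.
import_arpeggio = import_contacts


@dataclass
class ContactDelta:
    """Signed per-type contact count changes (mutant minus wild type)."""

    counts: dict[tuple[InteractionType, str], int] = field(default_factory=dict)

    STRATA = ("intra", "cross")

    def __getitem__(self, key: tuple[InteractionType, str]) -> int:
        return self.counts.get(key, 0)

    def as_vector(self) -> np.ndarray:
        """20-vector ordered by (interaction type, stratum)."""
        return np.array([
            self.counts.get((t, s), 0)
            for t in INTERACTION_ORDER for s in self.STRATA
        ], dtype=float)

    @staticmethod
    def column_names() -> list[str]:
        return [f"dcontact_{s}_{t.value}" for t in INTERACTION_ORDER for s in ContactDelta.STRATA]


def _count_types(contacts: list[Contact], focus: set[ResidueKey] | None) -> dict:
    counts: dict[tuple[InteractionType, str], int] = {}
    for c in contacts:
        if focus is not None and not (set(c.residues) & focus):
            continue
        stratum = "cross" if c.cross_chain else "intra"
        for t in c.types:
            counts[(t, stratum)] = counts.get((t, stratum), 0) + 1
    return counts


def contact_delta(
    wt: list[Contact],
    mut: list[Contact],
    focus: set[ResidueKey] | None = None,
) -> ContactDelta:
    """Per-type mutant-minus-wild-type contact counts restricted to focus residues."""
    wt_counts = _count_types(wt, focus)
    mut_counts = _count_types(mut, focus)
    keys = set(wt_counts) | set(mut_counts)
    return ContactDelta({k: mut_counts.get(k, 0) - wt_counts.get(k, 0) for k in keys})
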