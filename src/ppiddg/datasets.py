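"""Mutation datasets: records, tables, reverse augmentation, grouped CV splits
and synthetic complexes/datasets for testing and calibration.

Sign convention (fixed package-wide): the label ``y`` is the experimental
binding free energy change in kcal/mol with ``y > 0`` meaning enhanced
binding and ``y <= 0`` reduced binding.  Readers never reinterpret signs;
callers must pre-convert tables using other conventions.

Every forward record can be paired with a hypothetical reverse record whose
label is the exact negation (ddG(Mut->WT) = -ddG(WT->Mut)); reverse records
always travel with their forward partner through cross-validation splits.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features
from .contacts import ContactDelta, contact_delta, detect_contacts, ContactRules
from .interface import interface_residues
from .structures import (
    AtomRecord,
    ComplexStructure,
    MutationSpec,
    ONE_TO_THREE,
    ResidueKey,
    THREE_TO_ONE,
    apply_mutations,
    parse_mutation,
)

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


class SchemaError(ValueError):
    """Required column missing from a mutation table."""


class GroupingError(ValueError):
    """Grouping key absent on records for the requested split."""


class AugmentationError(ValueError):
    """Reverse augmentation applied to an already-augmented dataset."""


@dataclass
class MutationRecord:
    record_id: str
    complex_id: str
    partner1: str
    partner2: str
    specs: list[MutationSpec]
    y: float
    binding_site_label: str | None = None
    direction: str = FORWARD
    pair_id: str | None = None

    @property
    def is_multi(self) -> bool:
        return len(self.specs) > 1

    def mutation_string(self) -> str:
        return "; ".join(str(s) for s in self.specs)


REQUIRED_COLUMNS = ("pdb", "partner1", "partner2", "mutations", "ddg")


def read_skempi_table(text: str) -> list[MutationRecord]:
    """Read a SKEMPI-style delimited table into forward records.

    Expected columns: ``pdb, partner1, partner2, mutations, ddg`` and an
    optional ``binding_site``; comma- or tab-separated.  The ``mutations``
    cell uses the chain-aware grammar (``I D46A; I R48K``); multi-mutation
    cells become one record with several specs.  Rows whose mutations do not
    parse are rejected with row-level diagnostics.
    """
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            specs = parse_mutation(str(row["mutations"]))
            y = float(row["ddg"])
        except (ValueError, KeyError) as exc:
            logger.warning("rejecting row %d (%r): %s", i, row["mutations"], exc)
            continue
        label = row.get("binding_site")
        records.append(MutationRecord(
            record_id=f"row{i}",
            complex_id=str(row["pdb"]),
            partner1=str(row["partner1"]),
            partner2=str(row["partner2"]),
            specs=specs,
            y=y,
            binding_site_label=None if pd.isna(label) else str(label),
        ))
    return records


def write_records_jsonl(records: list[MutationRecord]) -> str:
    """Serialize records to JSON-lines for provenance."""
    import json

    lines = []
    for r in records:
        lines.append(json.dumps({
            "record_id": r.record_id, "complex_id": r.complex_id,
            "partner1": r.partner1, "partner2": r.partner2,
            "mutations": r.mutation_string(), "y": r.y,
            "binding_site": r.binding_site_label, "direction": r.direction,
            "pair_id": r.pair_id,
        }))
    return "\n".join(lines) + ("\n" if lines else "")


def augment_with_reverse(records: list[MutationRecord]) -> list[MutationRecord]:
    """Add one hypothetical reverse record per forward record (label negated)."""
    if any(r.direction == REVERSE for r in records):
        raise AugmentationError("input already contains reverse records")
    out = list(records)
    for r in records:
        out.append(MutationRecord(
            record_id=f"{r.record_id}_rev",
            complex_id=r.complex_id,
            partner1=r.partner1,
            partner2=r.partner2,
            specs=[s.reversed() for s in r.specs],
            y=-r.y,
            binding_site_label=r.binding_site_label,
            direction=REVERSE,
            pair_id=r.record_id,
        ))
    return out


def filter_single_mutations(records: list[MutationRecord]) -> list[MutationRecord]:
    return [r for r in records if not r.is_multi]


@dataclass
class DatasetSplit:
    """Ordered disjoint folds of record ids, grouped by a leakage key."""

    folds: list[list[str]]
    grouping: str
    fold_keys: list[str] = field(default_factory=list)

    def training_ids(self, fold: int) -> list[str]:
        return [rid for i, f in enumerate(self.folds) if i != fold for rid in f]


def _grouped_split(records: list[MutationRecord], key_of, grouping: str) -> DatasetSplit:
    by_forward = {r.record_id: r for r in records if r.direction == FORWARD}
    groups: dict[str, list[str]] = {}
    for r in records:
        anchor = r if r.direction == FORWARD else by_forward.get(r.pair_id, r)
        key = key_of(anchor)
        if key is None:
            raise GroupingError(f"record {r.record_id} lacks a {grouping} label")
        groups.setdefault(str(key), []).append(r.record_id)
    keys = sorted(groups)
    return DatasetSplit(folds=[groups[k] for k in keys], grouping=grouping, fold_keys=keys)


def split_leave_one_complex_out(records: list[MutationRecord]) -> DatasetSplit:
    """One fold per protein-protein complex (shared PDB id)."""
    return _grouped_split(records, lambda r: r.complex_id, "complex")


def split_leave_one_binding_site_out(records: list[MutationRecord]) -> DatasetSplit:
    """One fold per binding-site (interaction-type) label."""
    return _grouped_split(records, lambda r: r.binding_site_label, "binding_site")


# ---------------------------------------------------------------------------
# Synthetic structures and datasets
# ---------------------------------------------------------------------------

#: Gamma-level side-chain atom included in idealized synthetic residues.
_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

_SYNTH_AA = sorted(set(ONE_TO_THREE) - {"G"})  # GLY excluded so every residue has a CB


def generate_synthetic_complex(
    n_residues_per_chain: int = 10,
    seed: int = 0,
    contact_pairs: int = 4,
    separated: bool = False,
) -> ComplexStructure:
    """Two idealized backbone chains with a configurable contact interface.

    Chains A and B run parallel; the first ``contact_pairs`` residue pairs
    face each other with CB-CB distances under the 5 A interface cutoff, the
    remainder are held apart.  ``separated`` pushes the chains out of contact
    entirely.  Deterministic for a given seed.
    """
    if n_residues_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1

    def add_atom(name, element, res3, chain, seq, pos):
        nonlocal serial
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, residue_name=res3,
            chain_id=chain, residue_seq=seq, insertion_code="",
            coords=np.asarray(pos, dtype=float),
        ))
        serial += 1

    for chain, sign in (("A", 1.0), ("B", -1.0)):
        for i in range(n_residues_per_chain):
            res1 = _SYNTH_AA[rng.integers(len(_SYNTH_AA))]
            res3 = ONE_TO_THREE[res1]
            in_contact = i < contact_pairs
            y0 = 0.0 if chain == "A" else (6.4 if in_contact else 14.0)
            if chain == "B" and separated:
                y0 += 100.0
            jitter = lambda: rng.uniform(-0.15, 0.15)  # noqa: E731
            ca = np.array([3.8 * i + jitter(), y0 + jitter(), jitter()])
            add_atom("N", "N", res3, chain, i + 1, ca + [-1.2, 0.5 * sign, 0.4])
            add_atom("CA", "C", res3, chain, i + 1, ca)
            add_atom("C", "C", res3, chain, i + 1, ca + [1.2, 0.4 * sign, -0.3])
            add_atom("O", "O", res3, chain, i + 1, ca + [1.5, 1.4 * sign, -0.4])
            add_atom("CB", "C", res3, chain, i + 1, ca + [0.0, 1.3 * sign, 0.6])
            # gamma atoms stop short of the midplane so facing side chains
            # meet at van-der-Waals range, never covalent range
            gamma = _GAMMA_ATOM.get(res3)
            if gamma is not None:
                add_atom(gamma, gamma[0], res3, chain, i + 1,
                         ca + [0.4, 2.0 * sign, 1.0])
    return ComplexStructure(atoms)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Linear label model over declared feature columns, for recovery tests."""

    coefficients: dict[str, float] = field(default_factory=lambda: {
        "d_hydrophobicity": 0.25,
        "d_volume": 0.012,
        "d_charge": 0.9,
        "dcontact_cross_hydrogen_bond": 0.35,
        "dcontact_cross_hydrophobic": 0.15,
    })
    noise_sd: float = 0.3
    seed: int = 0


def _truth_features(
    structure: ComplexStructure,
    mutant: ComplexStructure,
    specs: list[MutationSpec],
    rules: ContactRules,
    wt_contacts,
) -> dict[str, float]:
    row: dict[str, float] = {}
    for spec in specs:
        for name, v in features.property_deltas(spec.wt_aa, spec.mut_aa).items():
            row[name] = row.get(name, 0.0) + v
    mut_contacts = detect_contacts(mutant, rules)
    delta = contact_delta(wt_contacts, mut_contacts, {s.residue_key for s in specs})
    for name, v in zip(ContactDelta.column_names(), delta.as_vector()):
        row[name] = row.get(name, 0.0) + float(v)
    return row


def generate_synthetic_dataset(
    n_records: int,
    truth: SyntheticGroundTruth = SyntheticGroundTruth(),
    n_complexes: int | None = None,
    n_residues_per_chain: int = 10,
    contact_pairs: int = 4,
) -> tuple[list[MutationRecord], dict[str, ComplexStructure]]:
    """Sample single-point mutations on synthetic complexes with linear labels.

    Mutation sites are drawn uniformly over interface residues and target
    amino acids; ``y`` is the truth's linear combination of property deltas
    and contact-change counts plus Gaussian noise.  Fully deterministic for
    a given truth seed.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(truth.seed)
    if n_complexes is None:
        n_complexes = int(np.clip(round(n_records / 60), 3, 12))
    rules = ContactRules.default()
    structures: dict[str, ComplexStructure] = {}
    iface: dict[str, list[ResidueKey]] = {}
    wt_contacts: dict[str, list] = {}
    labels = [f"site{j % max(2, n_complexes // 2)}" for j in range(n_complexes)]
    for j in range(n_complexes):
        cid = f"SYN{j:03d}"
        structures[cid] = generate_synthetic_complex(
            n_residues_per_chain, seed=int(rng.integers(2**31)),
            contact_pairs=contact_pairs)
        iface[cid] = sorted(interface_residues(structures[cid]))
        wt_contacts[cid] = detect_contacts(structures[cid], rules)
    records = []
    cids = sorted(structures)
    aa_list = sorted(ONE_TO_THREE)
    for i in range(n_records):
        cid = cids[rng.integers(len(cids))]
        structure = structures[cid]
        key = iface[cid][rng.integers(len(iface[cid]))]
        wt_aa = THREE_TO_ONE[structure.residue_name(key)]
        mut_aa = wt_aa
        while mut_aa == wt_aa:
            mut_aa = aa_list[rng.integers(len(aa_list))]
        spec = MutationSpec(chain_id=key.chain_id, wt_aa=wt_aa,
                            position=key.residue_seq, mut_aa=mut_aa)
        mutant = apply_mutations(structure, [spec])
        row = _truth_features(structure, mutant, [spec], rules, wt_contacts[cid])
        signal = sum(c * row.get(name, 0.0) for name, c in truth.coefficients.items())
        y = signal + rng.normal(0.0, truth.noise_sd)
        records.append(MutationRecord(
            record_id=f"rec{i:05d}", complex_id=cid, partner1="A", partner2="B",
            specs=[spec], y=float(y),
            binding_site_label=labels[cids.index(cid)],
        ))
    return records, structures
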