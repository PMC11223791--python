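"""Featurization pipeline: structures + mutations -> Siamese model inputs.

Each mutation (or multi-mutation variant) yields a *pair* of direction
inputs: the forward direction is featurized on the wild-type structure
(toward the mutant), the reverse direction on the mutant structure (toward
the wild type).  A user-supplied mutant structure always takes precedence
over the built-in naive mutant builder.

Per direction the model consumes three blocks:

* the interface graph (embedding node features, normalized adjacency),
* the cutoff-scanning signature at the mutation site(s),
* a tabular vector (substitution scores, property deltas, RSA/depth/
  secondary structure, contact-change counts, network-metric deltas and
  optional imported PSSM / force-field ddG columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from .contacts import Contact, ContactDelta, ContactRules, contact_delta, detect_contacts
from .datasets import MutationRecord
from .interface import (
    DEFAULT_INTERFACE_CUTOFF,
    EmbeddingProvider,
    InterfaceGraph,
    build_interface_graph,
    stub_embedding_provider,
)
from .netmetrics import MetricDelta, compute_metrics, delta_metrics
from .signatures import CutoffSchedule, multi_site_signature, signature_column_names
from .structures import ComplexStructure, MutationSpec, apply_mutations


def normalized_adjacency(graph: InterfaceGraph, weighted: bool = True) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    n = graph.n_nodes
    if n == 0:
        return np.empty((0, 0))
    a = graph.adjacency(weighted=weighted) + np.eye(n)
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


@dataclass
class DirectionInputs:
    """Raw (un-normalized) inputs for one Siamese direction."""

    node_features: np.ndarray      # (n_nodes, embed_dim)
    adjacency_norm: np.ndarray     # (n_nodes, n_nodes)
    signature: np.ndarray          # (n_cutoffs * 36,)
    tabular: np.ndarray            # (n_tabular,)


@dataclass
class PairFeatures:
    """Forward/reverse direction inputs for one mutation record."""

    forward: DirectionInputs
    reverse: DirectionInputs
    y: float | None = None
    record_id: str = ""
    complex_id: str = ""


@dataclass
class FeatureDataset:
    """A featurized set of mutation pairs sharing one schema."""

    pairs: list[PairFeatures]
    tabular_columns: list[str]
    signature_columns: list[str]
    embed_dim: int
    n_cutoffs: int

    def __len__(self) -> int:
        return len(self.pairs)

    def labels(self) -> np.ndarray:
        return np.array([p.y for p in self.pairs])

    def column_index(self, column: str) -> tuple[str, int]:
        if column in self.tabular_columns:
            return "tabular", self.tabular_columns.index(column)
        if column in self.signature_columns:
            return "signature", self.signature_columns.index(column)
        raise KeyError(f"unknown feature column {column!r}")


class FeaturePipeline:
    """Computes :class:`PairFeatures`; caches per-structure work.

    Parameters
    ----------
    provider:
        Per-residue embedding provider; defaults to the deterministic stub.
    rules, schedule, interface_cutoff:
        Contact rule table, signature cutoff schedule, interface radius (A).
    foldx, pssm:
        Optional imported feature tables (mutation string -> ddG; (chain,
        position) -> per-amino-acid scores).  When absent the corresponding
        columns are omitted from the schema entirely.
    """

    def __init__(
        self,
        provider: EmbeddingProvider | None = None,
        rules: ContactRules | None = None,
        schedule: CutoffSchedule = CutoffSchedule(),
        interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
        weighted_adjacency: bool = True,
        foldx: dict[str, float] | None = None,
        pssm: dict[tuple[str, int], dict[str, float]] | None = None,
    ):
        self.provider = provider or stub_embedding_provider(dimension=32, seed=0)
        self.rules = rules or ContactRules.default()
        self.schedule = schedule
        self.interface_cutoff = interface_cutoff
        self.weighted_adjacency = weighted_adjacency
        self.foldx = foldx
        self.pssm = pssm
        self._cache: dict[int, tuple] = {}

    # -- per-structure cached computations ---------------------------------

    def structure_context(self, structure: ComplexStructure):
        # key on identity, but pin the structure in the cache entry so a
        # garbage-collected mutant's id can never alias a live one
        key = id(structure)
        entry = self._cache.get(key)
        if entry is None or entry[0] is not structure:
            contacts = detect_contacts(structure, self.rules)
            graph = build_interface_graph(
                structure, contacts, self.provider, self.interface_cutoff
            )
            metrics = compute_metrics(graph) if graph.n_nodes else None
            sasa = ft.atom_sasa(structure)
            entry = (structure, contacts, graph, metrics, sasa)
            self._cache[key] = entry
        return entry[1:]

    # -- schema ------------------------------------------------------------

    def tabular_columns(self) -> list[str]:
        cols = ["blosum62", "pam250"]
        cols += [f"d_{name}" for name in ft.PROPERTY_NAMES]
        cols += ["rsa", "depth", "ss_helix", "ss_strand", "ss_coil"]
        cols += ContactDelta.column_names()
        cols += MetricDelta.column_names()
        if self.pssm is not None:
            cols += ["pssm_wt", "pssm_mut"]
        if self.foldx is not None:
            cols += ["foldx_ddg"]
        return cols

    def signature_columns(self) -> list[str]:
        return signature_column_names(self.schedule)

    # -- featurization ------------------------------------------------------

    def _direction(
        self,
        start: ComplexStructure,
        end: ComplexStructure,
        specs: list[MutationSpec],
    ) -> DirectionInputs:
        start_contacts, start_graph, start_metrics, start_sasa = self.structure_context(start)
        end_contacts, end_graph, end_metrics, _ = self.structure_context(end)
        sites = [s.residue_key for s in specs]

        row: dict[str, float] = {"blosum62": 0.0, "pam250": 0.0}
        for spec in specs:
            for name, v in ft.substitution_scores(spec.wt_aa, spec.mut_aa).items():
                row[name] += v
            for name, v in ft.property_deltas(spec.wt_aa, spec.mut_aa).items():
                row[name] = row.get(name, 0.0) + v
        site_rows = [
            ft.accessibility_depth_ss(start, key, sasa=start_sasa) for key in sites
        ]
        for name in ("rsa", "depth", "ss_helix", "ss_strand", "ss_coil"):
            row[name] = float(np.mean([sr[name] for sr in site_rows]))
        delta = contact_delta(start_contacts, end_contacts, set(sites))
        for name, v in zip(ContactDelta.column_names(), delta.as_vector()):
            row[name] = float(v)
        if start_metrics is not None and end_metrics is not None:
            mdelta = delta_metrics(start_metrics, end_metrics).as_vector()
        else:
            mdelta = np.zeros(len(MetricDelta.column_names()))
        for name, v in zip(MetricDelta.column_names(), mdelta):
            row[name] = float(v)
        if self.pssm is not None:
            wt_scores, mut_scores = [], []
            for spec in specs:
                entry = self.pssm.get((spec.chain_id, spec.position))
                wt_scores.append(entry.get(spec.wt_aa, np.nan) if entry else np.nan)
                mut_scores.append(entry.get(spec.mut_aa, np.nan) if entry else np.nan)
            row["pssm_wt"] = float(np.sum(wt_scores))
            row["pssm_mut"] = float(np.sum(mut_scores))
        if self.foldx is not None:
            key = "; ".join(str(s) for s in specs)
            row["foldx_ddg"] = self.foldx.get(key, np.nan)

        signature = multi_site_signature(start, sites, self.schedule).astype(float)
        return DirectionInputs(
            node_features=start_graph.node_features,
            adjacency_norm=normalized_adjacency(start_graph, self.weighted_adjacency),
            signature=signature,
            tabular=np.array([row[c] for c in self.tabular_columns()]),
        )

    def featurize(
        self,
        structure: ComplexStructure,
        specs: list[MutationSpec],
        mutant: ComplexStructure | None = None,
        y: float | None = None,
        record_id: str = "",
        complex_id: str = "",
    ) -> PairFeatures:
        """Build forward and reverse direction inputs for one variant."""
        if mutant is None:
            mutant = apply_mutations(structure, specs)
        reverse_specs = [s.reversed() for s in specs]
        return PairFeatures(
            forward=self._direction(structure, mutant, specs),
            reverse=self._direction(mutant, structure, reverse_specs),
            y=y,
            record_id=record_id,
            complex_id=complex_id,
        )

    def featurize_dataset(
        self,
        records: list[MutationRecord],
        structures: dict[str, ComplexStructure],
    ) -> FeatureDataset:
        """Featurize the forward records of a dataset (reverse directions are
        generated internally, matching the forward/reverse pairing used by
        the anti-symmetric training loss)."""
        pairs = []
        for rec in records:
            if rec.direction != "forward":
                continue
            pairs.append(self.featurize(
                structures[rec.complex_id], rec.specs,
                y=rec.y, record_id=rec.record_id, complex_id=rec.complex_id,
            ))
        return FeatureDataset(
            pairs=pairs,
            tabular_columns=self.tabular_columns(),
            signature_columns=self.signature_columns(),
            embed_dim=self.provider.dimension,
            n_cutoffs=len(self.schedule.cutoffs),
        )
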