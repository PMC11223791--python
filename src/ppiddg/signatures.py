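"""Cutoff-scanning pharmacophore signatures of a mutation-site environment.

For every unordered heavy-atom pair in the environment of a site, the
pharmacophore class pair(s) of the two atoms are counted cumulatively at
every distance cutoff of an increasing schedule; atoms carrying multiple
classes contribute one count per class-pair combination.  The result is a
vector of length ``n_cutoffs * 36`` (8 classes -> 36 unordered pairs),
non-decreasing along the cutoff axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial.distance import cdist

from .structures import (
    ComplexStructure,
    PHARMACOPHORE_ORDER,
    PharmacophoreClass,
    ResidueKey,
    classify_pharmacophore,
)

#: Canonical ordering of the 36 unordered pharmacophore class pairs.
CLASS_PAIRS: tuple[tuple[PharmacophoreClass, PharmacophoreClass], ...] = tuple(
    combinations_with_replacement(PHARMACOPHORE_ORDER, 2)
)
_PAIR_INDEX = {pair: i for i, pair in enumerate(CLASS_PAIRS)}
_CLASS_INDEX = {c: i for i, c in enumerate(PHARMACOPHORE_ORDER)}


def pair_index(a: PharmacophoreClass, b: PharmacophoreClass) -> int:
    """Index of the unordered class pair in the signature layout."""
    if _CLASS_INDEX[a] > _CLASS_INDEX[b]:
        a, b = b, a
    return _PAIR_INDEX[(a, b)]


@dataclass(frozen=True)
class CutoffSchedule:
    """Distance cutoffs ``start, start+step, ..., <= stop`` in Angstrom."""

    start: float = 2.0
    stop: float = 10.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.start <= 0 or self.step <= 0 or self.stop < self.start:
            raise ValueError("schedule requires start > 0, step > 0, stop >= start")

    @property
    def cutoffs(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


def signature_column_names(schedule: CutoffSchedule) -> list[str]:
    return [
        f"sig_{cutoff:g}A_{a.value}_{b.value}"
        for cutoff in schedule.cutoffs
        for a, b in CLASS_PAIRS
    ]


def cutoff_scan_signature(
    structure: ComplexStructure,
    center: ResidueKey,
    schedule: CutoffSchedule = CutoffSchedule(),
) -> np.ndarray:
    """Cumulative class-pair counts around ``center``.

    The environment is every heavy atom within ``schedule.stop`` of any atom
    of the center residue (the center's own atoms included); pair distances
    are compared to cutoffs inclusively.
    """
    center_coords = structure.coords([center])  # raises MissingResidueError
    atoms = structure.heavy_atoms()
    coords = np.array([a.coords for a in atoms])
    cutoffs = schedule.cutoffs
    n_pairs = len(CLASS_PAIRS)
    signature = np.zeros((len(cutoffs), n_pairs), dtype=np.int64)
    if coords.size == 0 or center_coords.size == 0:
        return signature.reshape(-1)
    near = cdist(coords, center_coords).min(axis=1) <= schedule.stop
    env_atoms = [a for a, keep in zip(atoms, near) if keep]
    env_coords = coords[near]
    n = len(env_atoms)
    if n < 2:
        return signature.reshape(-1)
    class_lists = [
        sorted(classify_pharmacophore(a), key=lambda c: _CLASS_INDEX[c])
        for a in env_atoms
    ]
    dmat = cdist(env_coords, env_coords)
    iu, ju = np.triu_indices(n, k=1)
    # smallest cutoff index covering each pair distance (inclusive boundaries)
    level = np.searchsorted(cutoffs, dmat[iu, ju] - 1e-12)
    within = level < len(cutoffs)
    for i, j, lv in zip(iu[within], ju[within], level[within]):
        for ca in class_lists[i]:
            for cb in class_lists[j]:
                signature[lv:, pair_index(ca, cb)] += 1
    return signature.reshape(-1)


def multi_site_signature(
    structure: ComplexStructure,
    centers: list[ResidueKey],
    schedule: CutoffSchedule = CutoffSchedule(),
) -> np.ndarray:
    """Elementwise sum of per-site signatures (additive multi-mutation design)."""
    total = np.zeros(len(schedule.cutoffs) * len(CLASS_PAIRS), dtype=np.int64)
    for center in centers:
        total += cutoff_scan_signature(structure, center, schedule)
    return total
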