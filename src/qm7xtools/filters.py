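"""Equilibrium-structure selection rules.

Three deterministic filters shape the equilibrium side of the dataset:

* :func:`energy_window_filter` — pre-optimization pruning: keep conformers
  within 50 kcal/mol of the most stable one that differ by at least 0.5 A
  minimized RMSD from every conformer already kept (greedy, ascending
  energy).
* :func:`select_distinct_conformers` — post-optimization selection: the
  lowest-energy structure is conformer 1, and a candidate becomes a new
  conformer only if its minimized RMSD to *all* previously accepted
  conformers is strictly larger than 1.0 A.
* :func:`detect_property_duplicates` — a posteriori duplicate detection:
  two structures are duplicates when they agree within 1e-3 (in each
  property's own unit) on all six of PBE0 energy, MBD energy, HOMO-LUMO
  gap, HOMO energy, isotropic molecular polarizability, and scalar dipole
  moment.  Duplicates are grouped by transitive closure; the first
  occurrence in input order is kept.

Equal energies are tie-broken by input index, so all three filters are
stable and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structures import Structure, min_rmsd
from .units import KCAL_PER_MOL_EV

__all__ = [
    "ConformerRecord",
    "DuplicateReport",
    "DUPLICATE_PROPERTY_KEYS",
    "DEFAULT_ENERGY_WINDOW_EV",
    "energy_window_filter",
    "select_distinct_conformers",
    "detect_property_duplicates",
]

#: The six physicochemical properties compared during duplicate detection
#: (HDF5 schema keys).
DUPLICATE_PROPERTY_KEYS = ("ePBE0", "eMBD", "HLgap", "eH", "mPOL", "DIP")

#: 50 kcal/mol in eV.
DEFAULT_ENERGY_WINDOW_EV = 50.0 * KCAL_PER_MOL_EV


@dataclass(eq=False)
class ConformerRecord:
    """One conformer: geometry, its energy (eV), and optional properties.

    Compares by identity, so filter outputs can be matched against inputs.
    """

    structure: Structure
    energy: float
    properties: Mapping | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("conformer energy must be finite")


def _ascending_energy_order(records: Sequence[ConformerRecord]) -> list[int]:
    # stable sort: equal energies keep input order
    return sorted(range(len(records)), key=lambda i: (records[i].energy, i))


def energy_window_filter(
    records: Sequence[ConformerRecord],
    window: float = DEFAULT_ENERGY_WINDOW_EV,
    rmsd_min: float = 0.5,
) -> list[ConformerRecord]:
    """Energy-window + RMSD-diversity pruning (defaults 50 kcal/mol, 0.5 A).

    Records more than ``window`` eV above the lowest energy are dropped;
    the survivors are swept in ascending energy and kept only if their
    minimized RMSD to every record already kept is >= ``rmsd_min``.
    Returns kept records in input order.
    """
    if not records:
        raise ValueError("energy_window_filter needs at least one record")
    e_min = min(r.energy for r in records)
    eligible = [i for i in range(len(records)) if records[i].energy - e_min <= window]
    kept: list[int] = []
    for i in sorted(eligible, key=lambda i: (records[i].energy, i)):
        if all(
            min_rmsd(records[i].structure, records[j].structure) >= rmsd_min
            for j in kept
        ):
            kept.append(i)
    return [records[i] for i in sorted(kept)]


def select_distinct_conformers(
    records: Sequence[ConformerRecord], rmsd_min: float = 1.0
) -> list[ConformerRecord]:
    """Distinct-conformer selection: strict ``min_rmsd > rmsd_min`` (default 1.0 A).

    The lowest-energy record is always conformer 1; later candidates (in
    ascending energy, ties by input index) must differ from *every*
    accepted conformer by strictly more than ``rmsd_min``.  Returns kept
    records in acceptance (ascending-energy) order.
    """
    if not records:
        raise ValueError("select_distinct_conformers needs at least one record")
    kept: list[int] = []
    for i in _ascending_energy_order(records):
        if all(
            min_rmsd(records[i].structure, records[j].structure) > rmsd_min
            for j in kept
        ):
            kept.append(i)
    return [records[i] for i in kept]


@dataclass
class DuplicateReport:
    """Outcome of property-based duplicate detection.

    ``groups`` lists the index sets (size >= 2) of mutually duplicate
    records after transitive closure; ``keep`` flags the records retained
    (first occurrence of each group plus all singletons).
    """

    groups: list[list[int]]
    keep: list[bool]

    @property
    def dropped(self) -> list[int]:
        return [i for i, k in enumerate(self.keep) if not k]


def detect_property_duplicates(
    records: Sequence[ConformerRecord], threshold_scale: float = 1e-3
) -> DuplicateReport:
    """Flag records that agree on all six duplicate-check properties.

    A pair is duplicate iff |difference| < ``threshold_scale`` (x 1 unit of
    the property) for *every* key in :data:`DUPLICATE_PROPERTY_KEYS`; a
    single property differing by more vetoes the pair.  The duplicate
    relation is closed transitively (union-find) so keep/drop is
    well-defined for chains.
    """
    vals = np.empty((len(records), len(DUPLICATE_PROPERTY_KEYS)))
    for i, rec in enumerate(records):
        if rec.properties is None:
            raise ValueError(f"record {i} has no properties")
        for c, key in enumerate(DUPLICATE_PROPERTY_KEYS):
            if key not in rec.properties:
                raise ValueError(f"record {i} is missing property {key!r}")
            vals[i, c] = float(rec.properties[key])

    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if np.all(np.abs(vals[i] - vals[j]) < threshold_scale):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    members: dict[int, list[int]] = {}
    for i in range(len(records)):
        members.setdefault(find(i), []).append(i)
    groups = [g for g in members.values() if len(g) > 1]
    keep = [True] * len(records)
    for g in groups:
        for i in g[1:]:
            keep[i] = False
    return DuplicateReport(groups=sorted(groups), keep=keep)
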