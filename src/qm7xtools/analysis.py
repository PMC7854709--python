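"""Dataset statistics and post-processing formulas.

Covers the descriptive statistics used to validate a structure dataset —
atom-pairwise distance distributions split into equilibrium-only and
all-structures series, heavy-element composition counts, and the
per-heavy-atom-count summary table with its counting identity
``total = equilibrium * (1 + n_neq)`` — plus two scalar post-processing
formulas: atomization energies from atomic reference energies, and the
SCS-rescaled van der Waals radius.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .qm7x_io import PropertyRecord, StructureLabel, parse_label, record_to_structure
from .structures import ATOMIC_NUMBERS, Structure

__all__ = [
    "DistanceHistogram",
    "pair_distance_distribution",
    "CompositionStats",
    "composition_stats",
    "summary_table",
    "totals_from_counts",
    "coverage_percent",
    "atomization_energy",
    "vdw_radius_scs",
    "property_distribution",
]


def _is_equilibrium(s: Structure) -> bool:
    """A structure counts as equilibrium when its label's variant is 'opt'."""
    if s.label is None:
        return False
    try:
        return parse_label(s.label).is_equilibrium
    except ValueError:
        return False


def _as_z(element: int | str) -> int:
    if isinstance(element, str):
        return ATOMIC_NUMBERS[element.capitalize()]
    return int(element)


@dataclass
class DistanceHistogram:
    """Binned intramolecular distances for one element pair.

    ``counts_all`` covers every structure, ``counts_equilibrium`` only the
    ``u = opt`` subset; on any dataset containing its equilibrium subset
    the former dominates the latter bin-wise.
    """

    element_pair: tuple[int, int]
    edges: np.ndarray
    counts_all: np.ndarray
    counts_equilibrium: np.ndarray


def _pair_distances(s: Structure, z1: int, z2: int) -> np.ndarray:
    p1 = s.positions[s.atomic_numbers == z1]
    if z1 == z2:
        return pdist(p1) if len(p1) > 1 else np.empty(0)
    p2 = s.positions[s.atomic_numbers == z2]
    if len(p1) == 0 or len(p2) == 0:
        return np.empty(0)
    return cdist(p1, p2).ravel()


def pair_distance_distribution(
    structures: Sequence[Structure],
    pair: tuple[int | str, int | str],
    bin_width: float = 0.1,
) -> DistanceHistogram:
    """Histogram of all intramolecular Z1-Z2 distances (each pair once).

    Structures labeled ``...-opt`` contribute to both series; everything
    else only to the all-structures series.  Bins are uniform with the
    given width from 0 to the largest observed distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z1, z2 = sorted((_as_z(pair[0]), _as_z(pair[1])))
    dists_all: list[np.ndarray] = []
    dists_eq: list[np.ndarray] = []
    for s in structures:
        d = _pair_distances(s, z1, z2)
        if d.size:
            dists_all.append(d)
            if _is_equilibrium(s):
                dists_eq.append(d)
    if not dists_all:
        warnings.warn(
            f"element pair ({z1}, {z2}) absent from every structure", stacklevel=2
        )
        edges = np.array([0.0, bin_width])
        zero = np.zeros(1, dtype=int)
        return DistanceHistogram((z1, z2), edges, zero, zero.copy())
    flat_all = np.concatenate(dists_all)
    n_bins = max(int(np.ceil(flat_all.max() / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts_all, _ = np.histogram(flat_all, bins=edges)
    flat_eq = np.concatenate(dists_eq) if dists_eq else np.empty(0)
    counts_eq, _ = np.histogram(flat_eq, bins=edges)
    return DistanceHistogram((z1, z2), edges, counts_all, counts_eq)


@dataclass
class CompositionStats:
    """Structure counts by heavy-element content.

    ``at_least_pairs`` / ``at_least_triples`` count structures whose heavy
    elements include a given 2- or 3-element combination (a molecule
    containing C, N and O is counted under {C,N}, {C,O} and {N,O});
    ``exact`` counts structures by their exact heavy-element set.
    """

    at_least_pairs: dict[frozenset[int], int]
    at_least_triples: dict[frozenset[int], int]
    exact: dict[frozenset[int], int]
    n_structures: int

    def containing(self, *elements: int | str) -> int:
        """Structures whose heavy elements include all those given."""
        want = frozenset(_as_z(e) for e in elements)
        if len(want) == 2:
            return self.at_least_pairs.get(want, 0)
        if len(want) == 3:
            return self.at_least_triples.get(want, 0)
        return sum(c for s, c in self.exact.items() if want <= s)


def composition_stats(structures: Iterable[Structure]) -> CompositionStats:
    """Count structures by heavy (Z != 1) element combinations."""
    pairs: Counter = Counter()
    triples: Counter = Counter()
    exact: Counter = Counter()
    n = 0
    for s in structures:
        n += 1
        heavy = frozenset(int(z) for z in np.unique(s.atomic_numbers) if z != 1)
        exact[heavy] += 1
        for combo in combinations(sorted(heavy), 2):
            pairs[frozenset(combo)] += 1
        for combo in combinations(sorted(heavy), 3):
            triples[frozenset(combo)] += 1
    return CompositionStats(dict(pairs), dict(triples), dict(exact), n)


def summary_table(
    dataset: Mapping[StructureLabel, PropertyRecord],
    expect_n_neq: int | None = None,
) -> pd.DataFrame:
    """Dataset content per heavy-atom count, with a Total row.

    Columns: ``molecules`` (distinct r), ``stereoisomers`` (distinct
    (r, s)), ``equilibrium_structures`` (u = opt count) and
    ``total_structures``.  With ``expect_n_neq`` given, the identity
    ``total = equilibrium * (1 + n_neq)`` is enforced row-wise and an
    incomplete dataset raises ``ValueError``.
    """
    rows: dict[int, dict[str, set | int]] = {}
    for label, record in dataset.items():
        z = np.asarray(record["atNUM"])
        heavy = int((z != 1).sum())
        row = rows.setdefault(
            heavy,
            {"molecules": set(), "stereo": set(), "equilibrium": 0, "total": 0},
        )
        row["molecules"].add(label.r)
        row["stereo"].add((label.r, label.s))
        row["total"] += 1
        if label.is_equilibrium:
            row["equilibrium"] += 1

    columns = [
        "molecules", "stereoisomers", "equilibrium_structures", "total_structures",
    ]
    if not rows:
        return pd.DataFrame(
            columns=columns, index=pd.Index([], name="heavy_atoms"), dtype=int
        )
    records = {
        heavy: {
            "molecules": len(row["molecules"]),
            "stereoisomers": len(row["stereo"]),
            "equilibrium_structures": row["equilibrium"],
            "total_structures": row["total"],
        }
        for heavy, row in sorted(rows.items())
    }
    df = pd.DataFrame.from_records(
        list(records.values()), index=pd.Index(records.keys(), name="heavy_atoms")
    )
    df.loc["Total"] = df.sum()
    if expect_n_neq is not None and not df.empty:
        expected = df["equilibrium_structures"] * (1 + expect_n_neq)
        bad = df.index[df["total_structures"] != expected]
        if len(bad):
            raise ValueError(
                f"dataset incomplete: total != equilibrium * (1 + {expect_n_neq}) "
                f"for heavy-atom rows {list(bad)}"
            )
    return df


def totals_from_counts(
    equilibrium_counts: Mapping[int | str, int], n_neq: int = 100
) -> pd.DataFrame:
    """Counting identity on a symbolic table of equilibrium-structure counts.

    Given equilibrium-structure counts per heavy-atom bin, returns the
    implied ``total_structures = equilibrium * (1 + n_neq)`` per bin plus a
    Total row — the bookkeeping that relates e.g. 41,537 equilibrium
    structures to 4,195,237 structures overall at n_neq = 100.
    """
    if n_neq < 0:
        raise ValueError("n_neq must be >= 0")
    df = pd.DataFrame(
        {"equilibrium_structures": pd.Series(dict(equilibrium_counts), dtype=int)}
    )
    df.index.name = "heavy_atoms"
    df["total_structures"] = df["equilibrium_structures"] * (1 + n_neq)
    df.loc["Total"] = df.sum()
    return df


def coverage_percent(n_total: int, n_failed: int) -> float:
    """Percentage of molecular formulae retained: 100 (n_total - n_failed) / n_total."""
    if n_total <= 0 or not 0 <= n_failed <= n_total:
        raise ValueError("need 0 <= n_failed <= n_total with n_total > 0")
    return 100.0 * (n_total - n_failed) / n_total


def atomization_energy(
    molecular_energy: float,
    atomic_numbers: Sequence[int] | np.ndarray,
    atomic_reference_energies: Mapping[int, float],
) -> float:
    """Molecular energy minus the sum of free-atom reference energies (eV).

    The result is exactly the subtraction
    ``E_molecule - sum_a E_ref(Z_a)``: negative for a bound molecule when
    the references are free-atom total energies of the same method.
    """
    total = 0.0
    for z in np.asarray(atomic_numbers, dtype=int):
        if int(z) not in atomic_reference_energies:
            raise KeyError(f"no atomic reference energy for Z={int(z)}")
        total += atomic_reference_energies[int(z)]
    return float(molecular_energy - total)


def vdw_radius_scs(alpha_scs: float, alpha_ts: float, r_ts: float) -> float:
    """SCS-rescaled van der Waals radius: (alpha_scs / alpha_ts)^(1/3) * r_ts.

    All quantities in atomic units (polarizabilities in bohr^3, radius in
    bohr).  The cube-root polarizability ratio rescales the pairwise
    (TS) radius by how much the screened atomic polarizability deviates
    from the unscreened one.
    """
    if min(alpha_scs, alpha_ts, r_ts) <= 0:
        raise ValueError("polarizabilities and radius must be positive")
    return float((alpha_scs / alpha_ts) ** (1.0 / 3.0) * r_ts)


def property_distribution(
    dataset: Mapping[StructureLabel, PropertyRecord],
    key: str,
    bins: int | str | Sequence[float] = "fd",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equilibrium vs. all-structures histogram of any scalar/array property.

    Array-valued properties (per-atom quantities) are flattened, so the
    histogram runs over atom-in-a-molecule values.  Returns
    ``(edges, counts_all, counts_equilibrium)``; the default binning is
    Freedman-Diaconis over the pooled values.
    """
    vals_all: list[np.ndarray] = []
    vals_eq: list[np.ndarray] = []
    for label, record in dataset.items():
        if key not in record:
            continue
        v = np.asarray(record[key], dtype=float).ravel()
        vals_all.append(v)
        if label.is_equilibrium:
            vals_eq.append(v)
    if not vals_all:
        raise KeyError(f"property {key!r} absent from every record")
    flat_all = np.concatenate(vals_all)
    _, edges = np.histogram(flat_all, bins=bins)
    counts_all, _ = np.histogram(flat_all, bins=edges)
    flat_eq = np.concatenate(vals_eq) if vals_eq else np.empty(0)
    counts_eq, _ = np.histogram(flat_eq, bins=edges)
    return edges, counts_all, counts_eq
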