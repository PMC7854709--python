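"""Reader/writer for the QM7-X-style HDF5 property schema.

Every structure carries a bundle of up to 42 physicochemical properties
stored under fixed HDF5 keys ('atNUM', 'atXYZ', 'ePBE0+MBD', ...), and is
addressed by a label of the form ``Geom-m{r}-i{s}-c{t}-{u}`` where *r*
enumerates the SMILES strings, *s* the stereoisomers, *t* the
(meta-)stable conformational isomers, and *u* is either ``opt`` (the
optimized equilibrium structure) or ``1..100`` (its displaced
non-equilibrium variants).

On disk, each molecule prefix ``Geom-m{r}-i{s}-c{t}`` is a top-level HDF5
group holding one subgroup per ``u``; the reader also tolerates a flat
layout with one top-level group per full label.  Numeric round-trips are
bit-exact.  Reading supports an exclusion list of equilibrium labels
(DupMols.dat style, one label per line): excluding an ``opt`` label also
drops all non-equilibrium variants sharing its (r, s, t) prefix.
"""

from __future__ import annotations

import re
import warnings
from collections.abc import MutableMapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import h5py
import numpy as np

from .calculators import random_geometry
from .structures import Structure

__all__ = [
    "SCHEMA",
    "UNITS",
    "MANDATORY_KEYS",
    "PropertyRecord",
    "StructureLabel",
    "LabelError",
    "parse_label",
    "format_label",
    "write_dataset",
    "read_dataset",
    "make_fixture_dataset",
    "read_exclusion_list",
    "write_exclusion_list",
    "record_to_structure",
]

# key -> shape kind:
#   scalar      one float
#   vec3        length-3 vector
#   ten9        3x3 tensor stored as 9 elements
#   per_atom    length-N array
#   per_atom_3  N x 3 array
#   var         variable-length 1-D array (Kohn-Sham eigenvalues)
SCHEMA: dict[str, str] = {
    "atNUM": "per_atom",
    "atXYZ": "per_atom_3",
    "sRMSD": "scalar",
    "sMIT": "ten9",
    "ePBE0+MBD": "scalar",
    "eDFTB+MBD": "scalar",
    "eAT": "scalar",
    "ePBE0": "scalar",
    "eMBD": "scalar",
    "eTS": "scalar",
    "eNN": "scalar",
    "eKIN": "scalar",
    "eNE": "scalar",
    "eEE": "scalar",
    "eXC": "scalar",
    "eX": "scalar",
    "eC": "scalar",
    "eXX": "scalar",
    "eKSE": "scalar",
    "KSE": "var",
    "eH": "scalar",
    "eL": "scalar",
    "HLgap": "scalar",
    "DIP": "scalar",
    "vDIP": "vec3",
    "vTQ": "vec3",
    "vIQ": "vec3",
    "vEQ": "vec3",
    "mC6": "scalar",
    "mPOL": "scalar",
    "mTPOL": "ten9",
    "totFOR": "per_atom_3",
    "pbe0FOR": "per_atom_3",
    "vdwFOR": "per_atom_3",
    "hVOL": "per_atom",
    "hRAT": "per_atom",
    "hCHG": "per_atom",
    "hDIP": "per_atom",
    "hVDIP": "per_atom_3",
    "atC6": "per_atom",
    "atPOL": "per_atom",
    "vdwR": "per_atom",
}

#: Unit of each dataset, stored as an HDF5 attribute on write.
UNITS: dict[str, str] = {
    "atNUM": "",
    "atXYZ": "Ang",
    "sRMSD": "Ang",
    "sMIT": "amu*Ang^2",
    "ePBE0+MBD": "eV", "eDFTB+MBD": "eV", "eAT": "eV", "ePBE0": "eV",
    "eMBD": "eV", "eTS": "eV", "eNN": "eV", "eKIN": "eV", "eNE": "eV",
    "eEE": "eV", "eXC": "eV", "eX": "eV", "eC": "eV", "eXX": "eV",
    "eKSE": "eV", "KSE": "eV", "eH": "eV", "eL": "eV", "HLgap": "eV",
    "DIP": "e*Ang",
    "vDIP": "e*Ang",
    "vTQ": "e*Ang^2", "vIQ": "e*Ang^2", "vEQ": "e*Ang^2",
    "mC6": "hartree*bohr^6",
    "mPOL": "bohr^3",
    "mTPOL": "bohr^3",
    "totFOR": "eV/Ang", "pbe0FOR": "eV/Ang", "vdwFOR": "eV/Ang",
    "hVOL": "bohr^3",
    "hRAT": "",
    "hCHG": "e",
    "hDIP": "e*bohr",
    "hVDIP": "e*bohr",
    "atC6": "hartree*bohr^6",
    "atPOL": "bohr^3",
    "vdwR": "bohr",
}

MANDATORY_KEYS = ("atNUM", "atXYZ")


class LabelError(ValueError):
    """Raised on a malformed structure label."""


@dataclass(frozen=True)
class StructureLabel:
    """Parsed ``Geom-m{r}-i{s}-c{t}-{u}`` label; ``u`` is 'opt' or int >= 1.

    Orders by (r, s, t) with the equilibrium structure before its
    non-equilibrium variants.
    """

    r: int
    s: int
    t: int
    u: int | str = "opt"

    def __post_init__(self) -> None:
        if min(self.r, self.s, self.t) < 1:
            raise LabelError("label indices r, s, t must be >= 1")
        if self.u != "opt" and (not isinstance(self.u, int) or self.u < 1):
            raise LabelError("variant u must be 'opt' or an integer >= 1")

    @property
    def is_equilibrium(self) -> bool:
        return self.u == "opt"

    def _sort_key(self) -> tuple:
        return (self.r, self.s, self.t, 0 if self.is_equilibrium else int(self.u))

    def __lt__(self, other: "StructureLabel") -> bool:
        if not isinstance(other, StructureLabel):
            return NotImplemented
        return self._sort_key() < other._sort_key()

    @property
    def molecule_prefix(self) -> str:
        return f"Geom-m{self.r}-i{self.s}-c{self.t}"

    def __str__(self) -> str:
        return f"{self.molecule_prefix}-{self.u}"


_LABEL_RE = re.compile(r"^Geom-m(\d+)-i(\d+)-c(\d+)-(opt|\d+)$")


def parse_label(text: str) -> StructureLabel:
    """Parse a ``Geom-m{r}-i{s}-c{t}-{u}`` label; inverse of :func:`format_label`."""
    m = _LABEL_RE.match(text.strip())
    if m is None:
        raise LabelError(f"malformed structure label: {text!r}")
    r, s, t = int(m.group(1)), int(m.group(2)), int(m.group(3))
    u: int | str = "opt" if m.group(4) == "opt" else int(m.group(4))
    return StructureLabel(r, s, t, u)


def format_label(label: StructureLabel) -> str:
    return str(label)


class PropertyRecord(MutableMapping):
    """Per-structure property bundle keyed by the HDF5 schema keys.

    Behaves like a dict; :meth:`validate` enforces the schema dimensions
    and the internal consistency identities
    ``HLgap = eL - eH`` and ``ePBE0+MBD = ePBE0 + eMBD`` (to 1e-6 eV)
    whenever the participating keys are present.  Unknown keys are allowed
    (and preserved on round-trip) to stay forward compatible.
    """

    def __init__(self, data: Mapping | None = None, **kwargs):
        self._data: dict[str, object] = {}
        if data:
            for k, v in data.items():
                self[k] = v
        for k, v in kwargs.items():
            self[k] = v

    def __setitem__(self, key: str, value) -> None:
        if key in SCHEMA and SCHEMA[key] != "scalar":
            value = np.asarray(value)
        self._data[key] = value

    def __getitem__(self, key: str):
        return self._data[key]

    def __delitem__(self, key: str) -> None:
        del self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"PropertyRecord(keys={sorted(self._data)})"

    @property
    def n_atoms(self) -> int:
        return int(np.asarray(self._data["atNUM"]).size)

    def validate(self) -> None:
        """Raise ``ValueError`` on any schema-dimension or identity violation."""
        for key in MANDATORY_KEYS:
            if key not in self._data:
                raise ValueError(f"record is missing mandatory key {key!r}")
        n = self.n_atoms
        if n < 1:
            raise ValueError("'atNUM' must contain at least one atom")
        for key, kind in SCHEMA.items():
            if key not in self._data:
                continue
            val = np.asarray(self._data[key])
            if kind == "scalar":
                if val.size != 1:
                    raise ValueError(f"{key!r} must be a scalar, got shape {val.shape}")
            elif kind == "vec3":
                if val.shape != (3,):
                    raise ValueError(f"{key!r} must have shape (3,), got {val.shape}")
            elif kind == "ten9":
                if val.shape not in ((9,), (3, 3)):
                    raise ValueError(
                        f"{key!r} must have 9 elements, got shape {val.shape}"
                    )
            elif kind == "per_atom":
                if val.shape != (n,):
                    raise ValueError(
                        f"{key!r} must have shape ({n},) to match 'atNUM', "
                        f"got {val.shape}"
                    )
            elif kind == "per_atom_3":
                if val.shape != (n, 3):
                    raise ValueError(
                        f"{key!r} must have shape ({n}, 3), got {val.shape}"
                    )
            elif kind == "var":
                if val.ndim != 1:
                    raise ValueError(f"{key!r} must be a 1-D array")
        if all(k in self._data for k in ("eH", "eL", "HLgap")):
            gap = float(np.asarray(self["eL"])) - float(np.asarray(self["eH"]))
            if abs(gap - float(np.asarray(self["HLgap"]))) > 1e-6:
                raise ValueError("'HLgap' != 'eL' - 'eH' beyond 1e-6 eV")
        if all(k in self._data for k in ("ePBE0+MBD", "ePBE0", "eMBD")):
            tot = float(np.asarray(self["ePBE0"])) + float(np.asarray(self["eMBD"]))
            if abs(tot - float(np.asarray(self["ePBE0+MBD"]))) > 1e-6:
                raise ValueError("'ePBE0+MBD' != 'ePBE0' + 'eMBD' beyond 1e-6 eV")


def record_to_structure(record: PropertyRecord, label: str | None = None) -> Structure:
    """Extract the geometry ('atNUM' + 'atXYZ') from a record."""
    return Structure(
        np.asarray(record["atNUM"], dtype=np.int64),
        np.asarray(record["atXYZ"], dtype=np.float64),
        label=label,
    )


# ---------------------------------------------------------------------------
# HDF5 persistence


def write_dataset(
    entries: Mapping, path: str | Path, validate: bool = True
) -> None:
    """Write a label -> :class:`PropertyRecord` map as an HDF5 file.

    Labels may be strings or :class:`StructureLabel`.  Invariant-violating
    records are rejected before anything is written.
    """
    parsed: list[tuple[StructureLabel, PropertyRecord]] = []
    for label, record in entries.items():
        lab = label if isinstance(label, StructureLabel) else parse_label(str(label))
        rec = record if isinstance(record, PropertyRecord) else PropertyRecord(record)
        if validate:
            rec.validate()
        parsed.append((lab, rec))

    with h5py.File(path, "w") as f:
        for lab, rec in parsed:
            grp = f.require_group(lab.molecule_prefix).create_group(str(lab.u))
            for key, val in rec.items():
                ds = grp.create_dataset(key, data=val)
                if key in UNITS and UNITS[key]:
                    ds.attrs["unit"] = UNITS[key]


def _load_record(grp: h5py.Group, label: str) -> PropertyRecord:
    rec = PropertyRecord()
    for key in grp:
        if key not in SCHEMA:
            warnings.warn(
                f"{label}: unknown key {key!r} preserved as-is", stacklevel=3
            )
        val = grp[key][()]
        rec[key] = float(val) if np.asarray(val).ndim == 0 else np.asarray(val)
    for key in MANDATORY_KEYS:
        if key not in rec:
            raise ValueError(f"{label}: missing mandatory dataset {key!r}")
    return rec


def read_dataset(
    path: str | Path,
    exclude_labels: Iterable[str | StructureLabel] | None = None,
) -> dict[StructureLabel, PropertyRecord]:
    """Load an HDF5 dataset into a label -> :class:`PropertyRecord` map.

    ``exclude_labels`` lists equilibrium labels to drop; every structure
    sharing the (r, s, t) prefix of an excluded label — i.e. its
    non-equilibrium variants too — is removed, matching the createDB-style
    duplicate exclusion workflow.
    """
    excluded_prefixes: set[tuple[int, int, int]] = set()
    if exclude_labels:
        for label in exclude_labels:
            lab = label if isinstance(label, StructureLabel) else parse_label(str(label))
            excluded_prefixes.add((lab.r, lab.s, lab.t))

    out: dict[StructureLabel, PropertyRecord] = {}
    with h5py.File(path, "r") as f:
        for top in f:
            node = f[top]
            try:
                # flat layout: the top-level group is a full label
                lab = parse_label(top)
                if (lab.r, lab.s, lab.t) not in excluded_prefixes:
                    out[lab] = _load_record(node, top)
                continue
            except LabelError:
                pass
            # nested layout: molecule prefix group -> one subgroup per u
            for sub in node:
                lab = parse_label(f"{top}-{sub}")
                if (lab.r, lab.s, lab.t) not in excluded_prefixes:
                    out[lab] = _load_record(node[sub], str(lab))
    return out


def read_exclusion_list(path: str | Path) -> list[StructureLabel]:
    """Read a DupMols.dat-style file: one label per line, blanks ignored."""
    labels = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            labels.append(parse_label(line))
    return labels


def write_exclusion_list(labels: Iterable[str | StructureLabel], path: str | Path) -> None:
    Path(path).write_text("".join(f"{label}\n" for label in labels))


# ---------------------------------------------------------------------------
# synthetic fixture generation


def _base_properties(rng: np.random.Generator, geom: Structure) -> PropertyRecord:
    """One synthetic equilibrium record with plausible magnitudes.

    Magnitudes imitate small organic molecules (total energies of order
    -10^3..-10^4 eV, gaps of a few eV, Hirshfeld volumes of tens of
    bohr^3); they are random numbers, not electronic-structure results.
    """
    n = geom.n_atoms
    z = geom.atomic_numbers
    masses = geom.masses
    pos = geom.positions
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    rel = pos - com
    inertia = ((masses * (rel**2).sum(axis=1)).sum() * np.eye(3)
               - np.einsum("a,ai,aj->ij", masses, rel, rel))

    e_pbe0 = float(-250.0 * z.sum() * rng.uniform(0.95, 1.05))
    e_mbd = float(-rng.uniform(0.05, 0.5))
    e_h = float(-rng.uniform(5.0, 9.0))
    gap = float(rng.uniform(3.0, 9.0))
    vdip = rng.normal(scale=0.15, size=3)
    n_occ = int(z.sum() // 2) or 1
    kse = np.sort(rng.uniform(-25.0, -0.5, size=n_occ))

    charges = rng.normal(scale=0.15, size=n)
    charges -= charges.mean()  # neutral molecule
    heavy = z != 1
    at_pol = np.where(heavy, rng.uniform(6.0, 14.0, n), rng.uniform(1.5, 4.0, n))
    at_c6 = np.where(heavy, rng.uniform(20.0, 50.0, n), rng.uniform(2.0, 7.0, n))
    hvdip = rng.normal(scale=0.1, size=(n, 3))

    return PropertyRecord({
        "atNUM": z.copy(),
        "atXYZ": pos.copy(),
        "sRMSD": 0.0,
        "sMIT": inertia.ravel(),
        "ePBE0": e_pbe0,
        "eMBD": e_mbd,
        "ePBE0+MBD": e_pbe0 + e_mbd,
        "eDFTB+MBD": e_pbe0 * float(rng.uniform(0.99, 1.01)),
        "eAT": float(-rng.uniform(2.0, 6.0) * n),
        "eTS": e_mbd * float(rng.uniform(0.8, 1.2)),
        "eNN": float(rng.uniform(50.0, 500.0)),
        "eKIN": float(-e_pbe0 * rng.uniform(0.9, 1.1)),
        "eNE": float(2.2 * e_pbe0),
        "eEE": float(-0.4 * e_pbe0),
        "eXC": float(0.12 * e_pbe0),
        "eX": float(0.11 * e_pbe0),
        "eC": float(0.01 * e_pbe0),
        "eXX": float(0.03 * e_pbe0),
        "eKSE": float(kse.sum()),
        "KSE": kse,
        "eH": e_h,
        "eL": e_h + gap,
        "HLgap": gap,
        "DIP": float(np.linalg.norm(vdip)),
        "vDIP": vdip,
        "vTQ": rng.normal(scale=1.0, size=3),
        "vIQ": rng.normal(scale=5.0, size=3),
        "vEQ": rng.normal(scale=5.0, size=3),
        "mC6": float(at_c6.sum() * rng.uniform(1.5, 2.5)),
        "mPOL": float(at_pol.sum() * rng.uniform(0.9, 1.1)),
        "mTPOL": (np.eye(3) * at_pol.sum() + rng.normal(scale=1.0, size=(3, 3))).ravel(),
        "totFOR": np.zeros((n, 3)),
        "pbe0FOR": np.zeros((n, 3)),
        "vdwFOR": np.zeros((n, 3)),
        "hVOL": np.where(heavy, rng.uniform(25.0, 60.0, n), rng.uniform(4.0, 9.0, n)),
        "hRAT": rng.uniform(0.6, 1.0, n),
        "hCHG": charges,
        "hDIP": np.linalg.norm(hvdip, axis=1),
        "hVDIP": hvdip,
        "atC6": at_c6,
        "atPOL": at_pol,
        "vdwR": np.where(heavy, rng.uniform(3.1, 3.9, n), rng.uniform(2.3, 2.7, n)),
    })


def _displaced_variant(
    rng: np.random.Generator, base: PropertyRecord
) -> PropertyRecord:
    """A synthetic non-equilibrium variant of an equilibrium record."""
    rec = PropertyRecord({k: (np.array(v, copy=True) if isinstance(v, np.ndarray) else v)
                          for k, v in base.items()})
    n = rec.n_atoms
    disp = rng.normal(scale=0.08, size=(n, 3))
    rec["atXYZ"] = np.asarray(base["atXYZ"]) + disp
    rec["sRMSD"] = float(np.sqrt((disp**2).sum(axis=1).mean()))
    de = float(rng.uniform(0.05, 2.0))
    rec["ePBE0"] = float(np.asarray(base["ePBE0"])) + de
    rec["ePBE0+MBD"] = float(rec["ePBE0"]) + float(np.asarray(rec["eMBD"]))
    rec["eDFTB+MBD"] = float(np.asarray(base["eDFTB+MBD"])) + de * float(rng.uniform(0.9, 1.1))
    for key in ("totFOR", "pbe0FOR", "vdwFOR"):
        rec[key] = rng.normal(scale=1.0, size=(n, 3))
    e_h = float(np.asarray(base["eH"])) + float(rng.normal(scale=0.2))
    gap = max(float(np.asarray(base["HLgap"])) + float(rng.normal(scale=0.3)), 0.5)
    rec["eH"], rec["eL"], rec["HLgap"] = e_h, e_h + gap, gap
    vdip = np.asarray(base["vDIP"]) + rng.normal(scale=0.05, size=3)
    rec["vDIP"], rec["DIP"] = vdip, float(np.linalg.norm(vdip))
    rec["mPOL"] = float(np.asarray(base["mPOL"])) * float(rng.uniform(0.95, 1.05))
    return rec


def make_fixture_dataset(
    n_molecules: int,
    n_conformers: int,
    n_neq: int,
    seed: int,
    plant_duplicates: bool = True,
) -> dict[StructureLabel, PropertyRecord]:
    """Seeded synthetic dataset emulating the deposited schema.

    Produces ``n_molecules * n_conformers * (1 + n_neq)`` records, all
    passing :meth:`PropertyRecord.validate`.  With ``plant_duplicates``,
    every even-indexed molecule with >= 2 conformers gets conformer 2's
    equilibrium six duplicate-check properties within 1e-4 of conformer
    1's, so duplicate detection has known ground truth (its geometry is
    untouched).
    """
    if min(n_molecules, n_conformers) < 1 or n_neq < 0:
        raise ValueError("counts must be positive (n_neq >= 0)")
    rng = np.random.default_rng(seed)
    out: dict[StructureLabel, PropertyRecord] = {}
    for r in range(1, n_molecules + 1):
        n_atoms = int(rng.integers(4, 9))
        geom = random_geometry(n_atoms, rng)
        first_conf: PropertyRecord | None = None
        for t in range(1, n_conformers + 1):
            conf_geom = Structure(
                geom.atomic_numbers,
                geom.positions + rng.normal(scale=0.4, size=geom.positions.shape),
            )
            rec = _base_properties(rng, conf_geom)
            if t == 1:
                first_conf = rec
            elif plant_duplicates and r % 2 == 0 and t == 2 and first_conf is not None:
                # duplicate in all six checked properties, distinct elsewhere
                e_pbe0 = float(np.asarray(first_conf["ePBE0"])) + float(rng.uniform(-1, 1)) * 1e-4
                e_mbd = float(np.asarray(first_conf["eMBD"])) + float(rng.uniform(-1, 1)) * 1e-4
                e_h = float(np.asarray(first_conf["eH"])) + float(rng.uniform(-1, 1)) * 1e-4
                gap = float(np.asarray(first_conf["HLgap"])) + float(rng.uniform(-1, 1)) * 1e-4
                rec["ePBE0"], rec["eMBD"] = e_pbe0, e_mbd
                rec["ePBE0+MBD"] = e_pbe0 + e_mbd
                rec["eH"], rec["HLgap"], rec["eL"] = e_h, gap, e_h + gap
                rec["mPOL"] = float(np.asarray(first_conf["mPOL"])) + float(rng.uniform(-1, 1)) * 1e-4
                rec["DIP"] = float(np.asarray(first_conf["DIP"])) + float(rng.uniform(-1, 1)) * 1e-4
            out[StructureLabel(r, 1, t, "opt")] = rec
            for u in range(1, n_neq + 1):
                out[StructureLabel(r, 1, t, u)] = _displaced_variant(rng, rec)
    return out
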