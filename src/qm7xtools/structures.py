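"""Molecular geometries, multi-frame XYZ I/O, and minimized RMSD.

A :class:`Structure` is the lightest possible container for one molecular
geometry: atomic numbers plus Cartesian coordinates in Angstrom.  The
minimized RMSD here superimposes two conformable structures by centroid
translation and an optimal proper rotation (Kabsch); permutations of
identical atoms are deliberately not searched, so atom order matters, and
reflections are excluded so enantiomers keep a nonzero RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "XYZFormatError",
    "IncomparableStructuresError",
    "read_xyz",
    "write_xyz",
    "min_rmsd",
    "ELEMENT_SYMBOLS",
    "ATOMIC_NUMBERS",
    "ATOMIC_MASSES",
]


class XYZFormatError(ValueError):
    """Raised when an XYZ file cannot be parsed; the message names the line."""


class IncomparableStructuresError(ValueError):
    """Raised when two structures differ in length or element sequence."""


# Periodic table, Z = 1..103.
ELEMENT_SYMBOLS = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr",
)

ATOMIC_NUMBERS = {sym: z for z, sym in enumerate(ELEMENT_SYMBOLS, start=1)}

# Standard atomic weights (amu) for the elements the toolkit works with
# routinely; other Z fall back to 2.0 * Z which is adequate for toy models.
ATOMIC_MASSES = {
    1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 9: 18.998,
    15: 30.974, 16: 32.06, 17: 35.45, 35: 79.904, 53: 126.904,
}


def atomic_mass(z: int) -> float:
    """Standard atomic weight in amu for atomic number ``z``."""
    return ATOMIC_MASSES.get(int(z), 2.0 * int(z))


@dataclass(eq=False)
class Structure:
    """One molecular geometry: atomic numbers and Cartesian coordinates (A).

    Instances compare by identity (coordinates are float arrays; use
    :func:`min_rmsd` for geometric comparison).

    Parameters
    ----------
    atomic_numbers
        Length-N sequence of positive integers.
    positions
        N x 3 array of Cartesian coordinates in Angstrom.
    label
        Optional text identifier, carried on the XYZ comment line.
    """

    atomic_numbers: np.ndarray
    positions: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size < 1:
            raise ValueError("atomic_numbers must be a non-empty 1-D sequence")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be positive integers")
        if self.positions.shape != (self.atomic_numbers.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.atomic_numbers.size} atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.size)

    @property
    def masses(self) -> np.ndarray:
        """Per-atom standard atomic weights, amu."""
        return np.array([atomic_mass(z) for z in self.atomic_numbers])

    @property
    def symbols(self) -> list[str]:
        return [ELEMENT_SYMBOLS[z - 1] for z in self.atomic_numbers]

    def copy(self) -> "Structure":
        return Structure(self.atomic_numbers.copy(), self.positions.copy(), self.label)

    def same_species(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and bool(np.array_equal(self.atomic_numbers, other.atomic_numbers))
        )


def _require_comparable(a: Structure, b: Structure) -> None:
    if not a.same_species(b):
        raise IncomparableStructuresError(
            "structures differ in atom count or element sequence; "
            "minimized RMSD is only defined for identical atom orderings"
        )


def read_xyz(path: str | Path) -> list[Structure]:
    """Read a (multi-frame) XYZ file into a list of :class:`Structure`.

    Element symbols are mapped to atomic numbers; bare atomic numbers are
    also accepted in the element column.  The comment line, if non-empty,
    becomes the structure label.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    structures: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank lines between frames
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZFormatError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if n < 1:
            raise XYZFormatError(f"{path}: line {i + 1}: atom count must be >= 1")
        if i + 1 + n >= len(lines) + 1 and i + 1 >= len(lines):
            raise XYZFormatError(f"{path}: line {i + 1}: truncated frame (missing comment line)")
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        numbers = np.empty(n, dtype=np.int64)
        coords = np.empty((n, 3))
        for a in range(n):
            ln = i + 2 + a
            if ln >= len(lines) or not lines[ln].strip():
                raise XYZFormatError(
                    f"{path}: line {i + 1}: frame declares {n} atoms but "
                    f"only {a} atom lines follow"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZFormatError(
                    f"{path}: line {ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            sym = parts[0]
            if sym in ATOMIC_NUMBERS:
                numbers[a] = ATOMIC_NUMBERS[sym]
            elif sym.capitalize() in ATOMIC_NUMBERS:
                numbers[a] = ATOMIC_NUMBERS[sym.capitalize()]
            elif sym.isdigit() and int(sym) >= 1:
                numbers[a] = int(sym)
            else:
                raise XYZFormatError(
                    f"{path}: line {ln + 1}: unknown element symbol {sym!r}"
                )
            try:
                coords[a] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise XYZFormatError(
                    f"{path}: line {ln + 1}: cannot parse coordinates in {lines[ln]!r}"
                ) from None
        structures.append(Structure(numbers, coords, label=comment or None))
        i += 2 + n
    return structures


def write_xyz(structures: Iterable[Structure], path: str | Path) -> None:
    """Write structures as a standard multi-frame XYZ file (1e-10 A precision)."""
    path = Path(path)
    out: list[str] = []
    for s in structures:
        out.append(str(s.n_atoms))
        out.append(s.label or "")
        for sym, (x, y, z) in zip(s.symbols, s.positions):
            out.append(f"{sym:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


def raw_rmsd(a: Structure, b: Structure) -> float:
    """RMSD without any superposition (same frame, same atom order)."""
    _require_comparable(a, b)
    return float(np.sqrt(np.mean(np.sum((a.positions - b.positions) ** 2, axis=1))))


def min_rmsd(a: Structure, b: Structure, heavy_only: bool = False) -> float:
    """Minimized RMSD (A) after centroid alignment and optimal proper rotation.

    Atom i of ``a`` is matched to atom i of ``b``: no permutation search is
    attempted, and only proper rotations are allowed, so mirror images of a
    chiral structure retain a nonzero RMSD.

    Parameters
    ----------
    heavy_only
        If True, superimpose and measure over non-hydrogen atoms only.
    """
    _require_comparable(a, b)
    pa, pb = a.positions, b.positions
    if heavy_only:
        mask = a.atomic_numbers != 1
        if not mask.any():
            raise IncomparableStructuresError("heavy_only RMSD on an all-hydrogen structure")
        pa, pb = pa[mask], pb[mask]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    if len(pa) == 1:
        return 0.0
    # align_vectors solves the Wahba/Kabsch problem with a proper rotation;
    # the residual is recomputed explicitly (the rssd it returns loses
    # precision to cancellation for near-perfect superpositions).
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Optimal rotation is not uniquely"
        )
        rot, _ = Rotation.align_vectors(pa, pb)
    return float(np.sqrt(np.mean(np.sum((pa - rot.apply(pb)) ** 2, axis=1))))
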