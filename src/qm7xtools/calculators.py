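"""Pluggable energy backends and toy potentials.

The sampling pipeline only ever talks to an :class:`EnergyBackend` — an
object with ``evaluate(structure) -> float`` (eV).  In production that role
is played by a tight-binding or DFT code; here two fully analytic stand-ins
make every downstream stage testable:

* :class:`HarmonicBackend` — a quadratic expansion ``E0 + 1/2 d^T H d``
  around a reference geometry, for which normal-mode energy bookkeeping is
  exact.
* :class:`MorseBackend` — an anharmonic Morse-bond + harmonic-angle force
  field, rigid-motion invariant, whose minimum sits at a prescribed
  geometry.  It exercises the sampler's explicit energy re-evaluation the
  way a real electronic-structure backend would.

:func:`make_toy_molecule` builds a seeded random molecule together with a
consistent pair of models: the anharmonic topology has its minimum exactly
at the generated geometry, and the harmonic Hessian is the analytic Hessian
of that topology at the minimum.  The Hessian is assembled from internal
coordinates (Gauss–Newton form ``sum_q k_q (grad q)(grad q)^T``, exact at a
stationary point), so rigid translations and rotations lie in its null
space by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .structures import Structure, IncomparableStructuresError

__all__ = [
    "EnergyBackend",
    "HarmonicModel",
    "HarmonicBackend",
    "MorseBond",
    "HarmonicAngle",
    "MorseTopology",
    "MorseBackend",
    "harmonic_energy",
    "morse_bond_energy",
    "make_toy_molecule",
    "random_geometry",
    "read_hessian_text",
    "write_hessian_text",
]


@runtime_checkable
class EnergyBackend(Protocol):
    """Contract for anything that can score a geometry, in eV."""

    def evaluate(self, structure: Structure) -> float: ...


@dataclass
class HarmonicModel:
    """Quadratic potential ``E0 + 1/2 d^T H d`` around a reference geometry.

    ``hessian`` is the 3N x 3N Cartesian Hessian in eV/A^2; ``d`` is the
    flattened displacement from ``reference`` in Angstrom.
    """

    reference: Structure
    hessian: np.ndarray
    reference_energy: float = 0.0

    def __post_init__(self) -> None:
        self.hessian = np.asarray(self.hessian, dtype=np.float64)
        n3 = 3 * self.reference.n_atoms
        if self.hessian.shape != (n3, n3):
            raise ValueError(f"hessian must be {n3}x{n3}, got {self.hessian.shape}")
        scale = np.abs(self.hessian).max() or 1.0
        if np.abs(self.hessian - self.hessian.T).max() > 1e-10 * scale:
            raise ValueError("hessian is not symmetric")


def harmonic_energy(model: HarmonicModel, s: Structure) -> float:
    """Energy of ``s`` under the quadratic model (eV)."""
    if not model.reference.same_species(s):
        raise IncomparableStructuresError(
            "structure is not conformable with the harmonic model's reference"
        )
    d = (s.positions - model.reference.positions).ravel()
    return float(model.reference_energy + 0.5 * d @ model.hessian @ d)


class HarmonicBackend:
    """:class:`EnergyBackend` view of a :class:`HarmonicModel`."""

    def __init__(self, model: HarmonicModel):
        self.model = model

    def evaluate(self, structure: Structure) -> float:
        return harmonic_energy(self.model, structure)


@dataclass(frozen=True)
class MorseBond:
    """Morse pair term ``D_e (1 - exp(-a (r - r0)))^2``."""

    i: int
    j: int
    d_e: float  # well depth, eV
    a: float    # stiffness, 1/A
    r0: float   # equilibrium distance, A


@dataclass(frozen=True)
class HarmonicAngle:
    """Harmonic bend ``1/2 k_theta (theta - theta0)^2`` at vertex ``j``."""

    i: int
    j: int
    k: int
    k_theta: float  # eV/rad^2
    theta0: float   # rad


@dataclass
class MorseTopology:
    """Anharmonic toy force field: Morse bonds plus harmonic angle bends."""

    bonds: list[MorseBond] = field(default_factory=list)
    angles: list[HarmonicAngle] = field(default_factory=list)

    def validate(self, n_atoms: int) -> None:
        for b in self.bonds:
            if not (0 <= b.i < n_atoms and 0 <= b.j < n_atoms and b.i != b.j):
                raise IndexError(f"bond ({b.i},{b.j}) out of range for {n_atoms} atoms")
            if b.d_e <= 0 or b.a <= 0:
                raise ValueError("Morse parameters D_e and a must be positive")
        for t in self.angles:
            if len({t.i, t.j, t.k}) != 3 or not all(
                0 <= x < n_atoms for x in (t.i, t.j, t.k)
            ):
                raise IndexError(f"angle ({t.i},{t.j},{t.k}) out of range")
            if t.k_theta <= 0:
                raise ValueError("angle force constant must be positive")


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def morse_bond_energy(topology: MorseTopology, s: Structure) -> float:
    """Energy of the Morse + angle toy potential (eV); zero at its minimum."""
    topology.validate(s.n_atoms)
    pos = s.positions
    e = 0.0
    for b in topology.bonds:
        r = float(np.linalg.norm(pos[b.i] - pos[b.j]))
        e += b.d_e * (1.0 - np.exp(-b.a * (r - b.r0))) ** 2
    for t in topology.angles:
        th = _angle(pos[t.i] - pos[t.j], pos[t.k] - pos[t.j])
        e += 0.5 * t.k_theta * (th - t.theta0) ** 2
    return float(e)


class MorseBackend:
    """:class:`EnergyBackend` view of a :class:`MorseTopology`."""

    def __init__(self, topology: MorseTopology):
        self.topology = topology

    def evaluate(self, structure: Structure) -> float:
        return morse_bond_energy(self.topology, structure)


# ---------------------------------------------------------------------------
# fixture generation


_TOY_ELEMENTS = np.array([1, 6, 7, 8, 16, 17])
_TOY_WEIGHTS = np.array([0.35, 0.30, 0.12, 0.12, 0.06, 0.05])


def random_geometry(n_atoms: int, rng: np.random.Generator) -> Structure:
    """Seeded connected random geometry with elements from {H,C,N,O,S,Cl}.

    Atoms are grown one at a time at bonding distance (~1.5 A) from a random
    existing atom, rejecting placements closer than 1.1 A to any other atom,
    so the result is connected and free of clashes.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    numbers = rng.choice(_TOY_ELEMENTS, size=n_atoms, p=_TOY_WEIGHTS / _TOY_WEIGHTS.sum())
    numbers[0] = 6  # anchor on carbon so the molecule is organic-like
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(200):
            parent = int(rng.integers(0, i))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = pos[parent] + direction * rng.uniform(1.35, 1.65)
            if np.min(np.linalg.norm(pos[:i] - candidate, axis=1)) > 1.1:
                pos[i] = candidate
                break
        else:  # pragma: no cover - rejection loop essentially never exhausts
            raise RuntimeError("could not place atom without clashes")
    return Structure(numbers, pos)


def _internal_coordinate_hessian(
    s: Structure, topology: MorseTopology
) -> np.ndarray:
    """Analytic Cartesian Hessian of the topology at its own minimum.

    At a stationary point of every internal coordinate the exact Hessian
    reduces to sum_q V''(q0) (grad q)(grad q)^T; for a Morse bond
    V''(r0) = 2 D_e a^2, for a harmonic bend V'' = k_theta.  Because the
    internal-coordinate gradients are rigid-motion invariant, the six
    translation/rotation directions are exact null vectors.
    """
    n3 = 3 * s.n_atoms
    h = np.zeros((n3, n3))
    pos = s.positions
    for b in topology.bonds:
        u = pos[b.i] - pos[b.j]
        u /= np.linalg.norm(u)
        g = np.zeros(n3)
        g[3 * b.i : 3 * b.i + 3] = u
        g[3 * b.j : 3 * b.j + 3] = -u
        h += 2.0 * b.d_e * b.a**2 * np.outer(g, g)
    for t in topology.angles:
        u = pos[t.i] - pos[t.j]
        v = pos[t.k] - pos[t.j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / nu, v / nv
        cos = float(np.clip(uh @ vh, -1.0, 1.0))
        sin = float(np.sqrt(max(1.0 - cos * cos, 1e-14)))
        gi = (cos * uh - vh) / (nu * sin)
        gk = (cos * vh - uh) / (nv * sin)
        g = np.zeros(n3)
        g[3 * t.i : 3 * t.i + 3] = gi
        g[3 * t.k : 3 * t.k + 3] = gk
        g[3 * t.j : 3 * t.j + 3] = -(gi + gk)
        h += t.k_theta * np.outer(g, g)
    return h


def make_toy_molecule(
    n_atoms: int, seed: int
) -> tuple[Structure, HarmonicModel, MorseTopology]:
    """Seeded random molecule with matching harmonic and anharmonic models.

    Returns a connected geometry, a :class:`HarmonicModel` whose Hessian has
    exactly the 6 rigid-motion null modes (5 for a diatomic) and positive
    vibrational eigenvalues, and a :class:`MorseTopology` whose minimum is
    the generated geometry with the same curvature there.

    Morse terms are placed on *every* atom pair (strong at bonding
    distances, weak beyond), which guarantees the curvature spans the full
    3N-6 shape space; bends are added along the growth chain.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    rng = np.random.default_rng(seed)
    s = random_geometry(n_atoms, rng)
    pos = s.positions

    bonds: list[MorseBond] = []
    neighbors: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            r0 = float(np.linalg.norm(pos[i] - pos[j]))
            if r0 < 1.8:  # bonding distance: stiff Morse well
                d_e, a = float(rng.uniform(3.0, 5.0)), float(rng.uniform(1.8, 2.2))
                neighbors[i].append(j)
                neighbors[j].append(i)
            else:  # long-range tether keeping the shape space full-rank
                d_e, a = 0.35, 0.9
            bonds.append(MorseBond(i, j, d_e, a, r0))

    angles: list[HarmonicAngle] = []
    for j, nb in neighbors.items():
        for ai in range(len(nb)):
            for ak in range(ai + 1, len(nb)):
                i, k = nb[ai], nb[ak]
                th0 = _angle(pos[i] - pos[j], pos[k] - pos[j])
                if 0.35 < th0 < np.pi - 0.35:
                    angles.append(
                        HarmonicAngle(i, j, k, float(rng.uniform(1.0, 2.0)), th0)
                    )

    topology = MorseTopology(bonds=bonds, angles=angles)
    hessian = _internal_coordinate_hessian(s, topology)
    model = HarmonicModel(reference=s.copy(), hessian=hessian, reference_energy=0.0)
    return s, model, topology


# ---------------------------------------------------------------------------
# Hessian text format: whitespace-separated 3N x 3N matrix in eV/A^2


def write_hessian_text(hessian: np.ndarray, path: str | Path) -> None:
    """Write a 3N x 3N Hessian (eV/A^2) as whitespace-separated text."""
    hessian = np.asarray(hessian)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be a square matrix")
    np.savetxt(path, hessian, fmt="%.12e")


def read_hessian_text(path: str | Path, n_atoms: int | None = None) -> np.ndarray:
    """Read a square plain-text Hessian; optionally check it is 3N x 3N."""
    h = np.atleast_2d(np.loadtxt(path))
    if h.shape[0] != h.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {h.shape}")
    if n_atoms is not None and h.shape[0] != 3 * n_atoms:
        raise ValueError(
            f"{path}: matrix is {h.shape[0]}x{h.shape[0]}, expected "
            f"{3 * n_atoms}x{3 * n_atoms} for {n_atoms} atoms"
        )
    return h
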