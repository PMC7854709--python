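"""Harmonic vibrational analysis.

The Cartesian Hessian (eV/A^2) is mass-weighted, the rigid-body subspace
(3 translations + 3 rotations, or 2 rotations for a linear molecule) is
projected out, and the projected matrix is diagonalized.  Eigenvalues are
angular-frequency squares in the internal unit system (eV, A, amu); the
frequency convention is chosen so that displacing a single mode by the
mass-weighted amplitude ``A_i = sqrt(2 de_i) / w_i`` raises the harmonic
energy by exactly ``de_i`` — the identity the non-equilibrium sampler is
built on.

Equilibria that are saddle points produce negative eigenvalues; those modes
are reported separately as imaginary frequencies and excluded from
sampling, as are near-zero modes below a 10 cm^-1 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calculators import EnergyBackend
from .structures import Structure
from .units import INV_CM_TO_OMEGA, OMEGA_TO_INV_CM

__all__ = [
    "NormalModeSet",
    "harmonic_analysis",
    "finite_difference_hessian",
    "DEFAULT_LOW_FREQ_CUTOFF_CM",
    "LINEAR_MOMENT_THRESHOLD",
]

#: Modes with |frequency| below this (cm^-1) are treated as numerically zero
#: and excluded from sampling.
DEFAULT_LOW_FREQ_CUTOFF_CM = 10.0

#: Smallest principal moment of inertia (amu A^2) below which a geometry is
#: classified as linear (project 5 rigid-body modes instead of 6).
LINEAR_MOMENT_THRESHOLD = 1e-4


@dataclass
class NormalModeSet:
    """Vibrational modes of one equilibrium structure.

    ``frequencies`` holds the real modes as angular frequencies in
    sqrt(eV/(amu A^2)), sorted ascending; ``eigenvectors`` are the matching
    mass-weighted displacement vectors (rows, orthonormal).  Imaginary
    modes (saddle-point directions) are stored separately with the
    magnitude of their frequency.
    """

    frequencies: np.ndarray          # (M_real,) angular, internal units
    eigenvectors: np.ndarray         # (M_real, 3N) mass-weighted, orthonormal
    masses: np.ndarray               # (N,) amu
    n_projected: int                 # 5 or 6
    imaginary_frequencies: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )                                # |w| of negative-curvature modes
    imaginary_eigenvectors: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0))
    )
    low_freq_cutoff_cm: float = DEFAULT_LOW_FREQ_CUTOFF_CM

    @property
    def n_atoms(self) -> int:
        return int(self.masses.size)

    @property
    def n_modes(self) -> int:
        """Total vibrational modes (real + imaginary) = 3N - n_projected."""
        return int(self.frequencies.size + self.imaginary_frequencies.size)

    @property
    def frequencies_cm(self) -> np.ndarray:
        """Real-mode frequencies in cm^-1."""
        return self.frequencies * OMEGA_TO_INV_CM

    @property
    def active_mask(self) -> np.ndarray:
        """True for real modes above the low-frequency cutoff (sampling-safe)."""
        return self.frequencies >= self.low_freq_cutoff_cm * INV_CM_TO_OMEGA

    @property
    def has_imaginary(self) -> bool:
        return self.imaginary_frequencies.size > 0


def _rigid_body_basis(geometry: Structure, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, columns."""
    pos = geometry.positions
    n = len(masses)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    rel = pos - com
    vecs = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = sqm
        vecs.append(v.ravel())
    for ax in range(3):  # rotations about principal-frame axes
        e = np.zeros(3)
        e[ax] = 1.0
        v = sqm[:, None] * np.cross(e, rel)
        vecs.append(v.ravel())
    b = np.array(vecs).T  # (3N, 6)
    # Orthonormalize; drop numerically null columns (e.g. rotation about a
    # linear molecule's axis).
    q, r = np.linalg.qr(b)
    keep = np.abs(np.diag(r)) > 1e-8 * np.sqrt(masses.sum())
    return q[:, keep]


def _principal_moments(geometry: Structure, masses: np.ndarray) -> np.ndarray:
    pos = geometry.positions
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    rel = pos - com
    r2 = (rel**2).sum(axis=1)
    inertia = (masses * r2).sum() * np.eye(3) - np.einsum(
        "a,ai,aj->ij", masses, rel, rel
    )
    return np.sort(np.linalg.eigvalsh(inertia))


def harmonic_analysis(
    hessian: np.ndarray,
    masses: np.ndarray,
    geometry: Structure,
    low_freq_cutoff_cm: float = DEFAULT_LOW_FREQ_CUTOFF_CM,
) -> NormalModeSet:
    """Mass-weight, project rigid-body motion, and diagonalize a Hessian.

    Parameters
    ----------
    hessian
        3N x 3N Cartesian Hessian, eV/A^2.  Small asymmetry (< 1e-6
        relative) is symmetrized away; worse asymmetry is an error.
    masses
        Length-N atomic masses, amu; must be positive.
    geometry
        The equilibrium geometry the Hessian belongs to (used for the
        rigid-rotation vectors and linearity detection).
    """
    hessian = np.asarray(hessian, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    n = geometry.n_atoms
    if masses.shape != (n,):
        raise ValueError(f"expected {n} masses, got {masses.shape}")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError(f"hessian must be {3*n}x{3*n}, got {hessian.shape}")
    scale = np.abs(hessian).max() or 1.0
    if np.abs(hessian - hessian.T).max() > 1e-6 * scale:
        raise ValueError("hessian asymmetric beyond 1e-6 relative tolerance")
    hessian = 0.5 * (hessian + hessian.T)

    inv_sqm = 1.0 / np.sqrt(np.repeat(masses, 3))
    h_mw = hessian * np.outer(inv_sqm, inv_sqm)

    moments = _principal_moments(geometry, masses)
    linear = n == 2 or moments[0] < LINEAR_MOMENT_THRESHOLD
    basis = _rigid_body_basis(geometry, masses)
    n_projected = 5 if linear else 6
    # For a genuinely linear geometry QR already dropped the axial rotation.
    if basis.shape[1] != n_projected:
        n_projected = basis.shape[1]

    proj = np.eye(3 * n) - basis @ basis.T
    h_proj = proj @ h_mw @ proj
    h_proj = 0.5 * (h_proj + h_proj.T)
    evals, evecs = np.linalg.eigh(h_proj)

    # Discard the n_projected eigenvectors living in the rigid-body subspace
    # (they have eigenvalue ~0 and near-unit overlap with the basis).
    overlap = np.linalg.norm(basis.T @ evecs, axis=0)
    rigid_idx = set(np.argsort(-overlap)[:n_projected])
    keep = [i for i in range(3 * n) if i not in rigid_idx]

    lam = evals[keep]
    vecs = evecs[:, keep].T
    cutoff_omega = low_freq_cutoff_cm * INV_CM_TO_OMEGA
    neg = lam < -(cutoff_omega**2)
    imag_freqs = np.sqrt(-lam[neg])
    imag_vecs = vecs[neg]
    real_lam = lam[~neg]
    real_vecs = vecs[~neg]
    freqs = np.sqrt(np.clip(real_lam, 0.0, None))
    order = np.argsort(freqs, kind="stable")
    return NormalModeSet(
        frequencies=freqs[order],
        eigenvectors=real_vecs[order],
        masses=masses.copy(),
        n_projected=n_projected,
        imaginary_frequencies=np.sort(imag_freqs),
        imaginary_eigenvectors=imag_vecs[np.argsort(imag_freqs)] if imag_vecs.size else imag_vecs,
        low_freq_cutoff_cm=low_freq_cutoff_cm,
    )


def finite_difference_hessian(
    backend: EnergyBackend, s: Structure, step: float = 1e-3
) -> np.ndarray:
    """Central-difference Hessian (eV/A^2) of any energy backend.

    Uses the four-point mixed formula
    ``[E(+i+j) - E(+i-j) - E(-i+j) + E(-i-j)] / (4 step^2)`` for every
    coordinate pair; exact for quadratic potentials up to round-off, error
    O(step^2) otherwise.  The output is explicitly symmetrized.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n3 = 3 * s.n_atoms
    flat = s.positions.ravel()

    def energy_at(d: np.ndarray) -> float:
        probe = Structure(s.atomic_numbers, (flat + d).reshape(-1, 3))
        try:
            return float(backend.evaluate(probe))
        except Exception as exc:  # pragma: no cover - context propagation
            raise RuntimeError(
                f"backend failed at displacement {d.nonzero()[0]}"
            ) from exc

    h = np.empty((n3, n3))
    for a in range(n3):
        for b in range(a, n3):
            d = np.zeros(n3)
            d[a] += step
            d[b] += step
            epp = energy_at(d)
            d[b] -= 2 * step
            epm = energy_at(d)
            d[a] -= 2 * step
            emm = energy_at(d)
            d[b] += 2 * step
            emp = energy_at(d)
            h[a, b] = h[b, a] = (epp - epm - emp + emm) / (4.0 * step**2)
    return 0.5 * (h + h.T)
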