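"""Non-equilibrium structure generation with Boltzmann-histogram enforcement.

Each equilibrium structure receives a fixed number of displaced structures
(default 100) whose energy rises above the minimum, DeltaE, (i) average
``<DeltaE> = (3/2) N kB T`` in analogy with equipartition and (ii) follow an
exponential (Boltzmann-like) distribution truncated at ``4.5 <DeltaE>``.

Candidates are built by drawing a per-mode energy partition, converting
each mode's share ``de_i`` into a mass-weighted displacement amplitude
``A_i = sqrt(2 de_i) / w_i`` with a random sign, and displacing along all
modes at once.  Because the linear combination trusts the harmonic
approximation, the true DeltaE of every candidate is re-evaluated with the
energy backend, and acceptance is judged on that value only: a candidate
enters the sample only if its true DeltaE lands in a histogram bin with
remaining capacity and it differs by more than ``0.0075 N`` A (minimized
RMSD) from every previously accepted structure.  The run finishes when all
bins are full.

A note on the exponential scale: an exponential with scale ``kB T`` cannot
have mean ``(3/2) N kB T`` for N > 1.  By default the histogram therefore
keeps the exponential *shape* and root-solves its scale so that the
truncated distribution's mean equals the equipartition target exactly; the
literal ``kB T`` scale is available via ``scale="literal"`` for experts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .calculators import EnergyBackend
from .normal_modes import NormalModeSet
from .structures import Structure, min_rmsd
from .units import KB_EV

__all__ = [
    "SamplingConfig",
    "EnergyHistogram",
    "ModeEnergyAllocation",
    "SamplingResult",
    "IncompleteHistogramError",
    "mean_target_energy",
    "truncated_exponential_scale",
    "build_target_histogram",
    "allocate_mode_energies",
    "displace",
    "sample_nonequilibrium",
]


@dataclass
class SamplingConfig:
    """Parameters of one non-equilibrium sampling run.

    Defaults are the production settings: T = 1500 K, 100 structures per
    equilibrium geometry, DeltaE window [0, 4.5 <DeltaE>] split into 45
    bins (width 0.1 <DeltaE>), and an RMSD floor of 0.0075 N Angstrom
    between accepted structures.
    """

    temperature: float = 1500.0
    n_structures: int = 100
    histogram_max_factor: float = 4.5
    n_bins: int = 45
    rmsd_coeff: float = 0.0075
    max_attempts: int | None = None  # defaults to 200 * n_structures
    seed: int = 0
    scale: Literal["fitted", "literal"] = "fitted"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.histogram_max_factor <= 1:
            raise ValueError("histogram_max_factor must exceed 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.rmsd_coeff < 0:
            raise ValueError("rmsd_coeff must be >= 0")
        if self.max_attempts is None:
            self.max_attempts = 200 * self.n_structures


@dataclass
class EnergyHistogram:
    """Target/filled counts over uniform DeltaE bins on [0, max_factor*<DeltaE>]."""

    edges: np.ndarray          # (n_bins + 1,), eV, ascending from 0
    target_counts: np.ndarray  # (n_bins,), ints summing to n_structures
    filled_counts: np.ndarray  # (n_bins,), ints, <= target elementwise

    @property
    def n_bins(self) -> int:
        return int(self.target_counts.size)

    @property
    def remaining(self) -> np.ndarray:
        return self.target_counts - self.filled_counts

    @property
    def complete(self) -> bool:
        return bool(np.all(self.filled_counts == self.target_counts))

    def bin_index(self, delta_e: float) -> int:
        """Bin containing ``delta_e``, or -1 if outside [0, max]."""
        if delta_e < self.edges[0] or delta_e > self.edges[-1]:
            return -1
        idx = int(np.searchsorted(self.edges, delta_e, side="right") - 1)
        return min(idx, self.n_bins - 1)  # right edge belongs to last bin

    def fill(self, bin_idx: int) -> None:
        if self.filled_counts[bin_idx] >= self.target_counts[bin_idx]:
            raise ValueError(f"bin {bin_idx} is already full")
        self.filled_counts[bin_idx] += 1


@dataclass
class ModeEnergyAllocation:
    """Per-mode energy shares and the displacement amplitudes they imply.

    Arrays run over the real modes of a :class:`NormalModeSet`; inactive
    (near-zero) modes carry exactly zero energy and amplitude.
    """

    mode_energies: np.ndarray  # (M,), eV, >= 0
    amplitudes: np.ndarray     # (M,), amu^1/2 * A
    signs: np.ndarray          # (M,), +-1


@dataclass
class AttemptRecord:
    """One candidate evaluation inside :func:`sample_nonequilibrium`."""

    attempt: int
    target_bin: int
    proposed_energy: float
    true_delta_e: float
    true_bin: int
    accepted: bool
    reason: str


@dataclass
class SamplingResult:
    structures: list[Structure]
    delta_e: list[float]
    histogram: EnergyHistogram
    attempts: list[AttemptRecord] = field(default_factory=list)

    @property
    def acceptance_rate(self) -> float:
        return len(self.structures) / max(len(self.attempts), 1)


class IncompleteHistogramError(RuntimeError):
    """The attempt budget ran out before every bin was filled.

    Mirrors the production pipeline's behaviour of excluding molecular
    formulae for which a complete energy distribution could not be
    obtained.  Carries the partial result for inspection.
    """

    def __init__(self, result: SamplingResult, max_attempts: int):
        self.result = result
        unfilled = np.nonzero(result.histogram.remaining)[0].tolist()
        super().__init__(
            f"histogram incomplete after {max_attempts} attempts: "
            f"{len(result.structures)} accepted "
            f"(acceptance rate {result.acceptance_rate:.3f}), "
            f"unfilled bins {unfilled}"
        )


def mean_target_energy(n_atoms: int, temperature: float) -> float:
    """Equipartition-style mean displacement energy (3/2) N kB T, in eV."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.5 * n_atoms * KB_EV * temperature


def truncated_exponential_scale(mean_energy: float, upper: float) -> float:
    """Scale s of an exponential truncated to [0, upper] with a given mean.

    The truncated mean is ``m(s) = s - upper / (exp(upper/s) - 1)``, which
    increases monotonically from 0 (s -> 0) to upper/2 (s -> inf); a root
    exists iff ``mean_energy < upper / 2``.
    """
    if not 0 < mean_energy < upper / 2:
        raise ValueError(
            f"no exponential truncated to [0, {upper:g}] has mean {mean_energy:g}; "
            "need 0 < mean < upper/2 (histogram_max_factor must exceed 2)"
        )

    def g(s: float) -> float:
        x = upper / s
        return s - upper / np.expm1(x) - mean_energy

    lo = mean_energy            # m(s) < s, so g(lo) < 0 always
    hi = 2.0 * mean_energy
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * mean_energy:  # pragma: no cover - guarded by check above
            raise RuntimeError("failed to bracket truncated-exponential scale")
    return float(brentq(g, lo, hi, xtol=1e-15, rtol=1e-14))


def build_target_histogram(
    mean_energy: float, config: SamplingConfig
) -> EnergyHistogram:
    """Integer target counts with exponential shape over [0, max_factor*mean].

    Bin probabilities integrate ``exp(-DeltaE/s)`` over each uniform bin;
    with ``scale="fitted"`` (default) s is solved so the truncated
    distribution's mean equals ``mean_energy`` exactly, with
    ``scale="literal"`` s = kB T.  Counts are rounded to integers by the
    largest-remainder method so they sum to ``n_structures`` exactly; the
    decreasing density guarantees non-increasing counts.
    """
    if mean_energy <= 0:
        raise ValueError("mean_energy must be positive")
    upper = config.histogram_max_factor * mean_energy
    if config.scale == "literal":
        s = KB_EV * config.temperature
    else:
        s = truncated_exponential_scale(mean_energy, upper)
    edges = np.linspace(0.0, upper, config.n_bins + 1)
    weights = np.exp(-edges[:-1] / s) - np.exp(-edges[1:] / s)
    probs = weights / weights.sum()
    quota = probs * config.n_structures
    counts = np.floor(quota).astype(int)
    short = config.n_structures - counts.sum()
    # Largest remainder; ties favour lower bins, preserving monotonicity.
    order = np.lexsort((np.arange(config.n_bins), -(quota - counts)))
    counts[order[:short]] += 1
    return EnergyHistogram(
        edges=edges, target_counts=counts, filled_counts=np.zeros_like(counts)
    )


def allocate_mode_energies(
    modes: NormalModeSet, total: float, rng: np.random.Generator
) -> ModeEnergyAllocation:
    """Randomly split ``total`` eV over the active modes.

    Unit-exponential weights rescaled to the total (a symmetric
    Dirichlet(1, ..., 1) split — every partition of the energy is equally
    likely) give each active mode its share ``de_i``; the amplitude follows
    as ``A_i = sqrt(2 de_i) / w_i`` with an independent random sign.
    """
    if total < 0:
        raise ValueError("total energy must be >= 0")
    active = modes.active_mask
    m = int(active.sum())
    if m == 0:
        raise ValueError("no active vibrational modes to displace")
    energies = np.zeros(modes.frequencies.size)
    if total > 0:
        w = rng.exponential(size=m)
        energies[active] = total * w / w.sum()
    else:
        rng.exponential(size=m)  # keep the stream layout draw-stable
    signs = rng.integers(0, 2, size=modes.frequencies.size) * 2 - 1
    amplitudes = np.zeros_like(energies)
    amplitudes[active] = np.sqrt(2.0 * energies[active]) / modes.frequencies[active]
    return ModeEnergyAllocation(
        mode_energies=energies, amplitudes=amplitudes, signs=signs.astype(np.int64)
    )


def displace(
    equilibrium: Structure, modes: NormalModeSet, alloc: ModeEnergyAllocation
) -> Structure:
    """Perturb a geometry along every mode at once.

    The Cartesian displacement of atom a is
    ``sum_i sign_i A_i v_i[a] / sqrt(m_a)`` with ``v_i`` the mass-weighted
    eigenvector, so a single mode at energy ``de`` raises the harmonic
    energy by exactly ``de``.
    """
    if modes.n_atoms != equilibrium.n_atoms:
        raise ValueError("mode set and structure have different atom counts")
    coeff = alloc.signs * alloc.amplitudes
    disp_mw = coeff @ modes.eigenvectors          # (3N,) mass-weighted
    disp = disp_mw.reshape(-1, 3) / np.sqrt(modes.masses)[:, None]
    out = equilibrium.copy()
    out.positions = out.positions + disp
    return out


def sample_nonequilibrium(
    equilibrium: Structure,
    modes: NormalModeSet,
    backend: EnergyBackend,
    config: SamplingConfig,
) -> SamplingResult:
    """Generate the full non-equilibrium set for one equilibrium structure.

    Proposal loop: pick a bin with probability proportional to its
    remaining capacity, draw a harmonic-estimate total uniformly inside
    that bin, allocate it over the modes, displace, then re-evaluate the
    true DeltaE with ``backend``.  The candidate is accepted only if the
    true DeltaE lands in a bin with remaining capacity and its minimized
    RMSD to every previously accepted structure exceeds
    ``rmsd_coeff * N`` Angstrom.  Fully reproducible from ``config.seed``.

    Raises
    ------
    IncompleteHistogramError
        If ``max_attempts`` candidates did not fill the histogram.
    """
    rng = np.random.default_rng(config.seed)
    n = equilibrium.n_atoms
    mean = mean_target_energy(n, config.temperature)
    hist = build_target_histogram(mean, config)
    e0 = float(backend.evaluate(equilibrium))
    rmsd_floor = config.rmsd_coeff * n

    result = SamplingResult(structures=[], delta_e=[], histogram=hist)
    for attempt in range(1, int(config.max_attempts) + 1):
        remaining = hist.remaining
        if remaining.sum() == 0:
            break
        target_bin = int(rng.choice(hist.n_bins, p=remaining / remaining.sum()))
        proposed = float(
            rng.uniform(hist.edges[target_bin], hist.edges[target_bin + 1])
        )
        alloc = allocate_mode_energies(modes, proposed, rng)
        candidate = displace(equilibrium, modes, alloc)
        true_de = float(backend.evaluate(candidate)) - e0
        true_bin = hist.bin_index(true_de)

        if true_bin < 0:
            accepted, reason = False, "outside_range"
        elif remaining[true_bin] <= 0:
            accepted, reason = False, "bin_full"
        elif any(min_rmsd(candidate, s) <= rmsd_floor for s in result.structures):
            accepted, reason = False, "rmsd_too_close"
        else:
            accepted, reason = True, "accepted"
            hist.fill(true_bin)
            base = equilibrium.label or "structure"
            candidate.label = f"{base}-{len(result.structures) + 1}"
            result.structures.append(candidate)
            result.delta_e.append(true_de)

        result.attempts.append(
            AttemptRecord(
                attempt=attempt,
                target_bin=target_bin,
                proposed_energy=proposed,
                true_delta_e=true_de,
                true_bin=true_bin,
                accepted=accepted,
                reason=reason,
            )
        )
        if hist.complete:
            return result

    if not hist.complete:
        raise IncompleteHistogramError(result, int(config.max_attempts))
    return result
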