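"""The non-equilibrium sampler: target histogram, allocation, displacement,
and the full histogram-enforced acceptance loop."""

import numpy as np
import pytest

from qm7xtools.calculators import HarmonicBackend, MorseBackend
from qm7xtools.sampler import (
    EnergyHistogram,
    IncompleteHistogramError,
    SamplingConfig,
    allocate_mode_energies,
    build_target_histogram,
    displace,
    mean_target_energy,
    sample_nonequilibrium,
    truncated_exponential_scale,
)
from qm7xtools.structures import min_rmsd
from qm7xtools.units import KB_EV


class TestMeanTargetEnergy:
    def test_five_atoms_at_1500K(self):
        assert mean_target_energy(5, 1500.0) == pytest.approx(0.96945, abs=1e-5)

    def test_linear_in_atom_count(self):
        assert mean_target_energy(23, 1500.0) == pytest.approx(
            23 / 5 * mean_target_energy(5, 1500.0), rel=1e-12
        )

    def test_vanishes_at_low_temperature(self):
        assert mean_target_energy(1, 1e-9) < 1e-12

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mean_target_energy(0, 1500.0)
        with pytest.raises(ValueError):
            mean_target_energy(5, -1.0)


def bisection_scale_oracle(mean, factor=4.5, lo=1.0, hi=3.0, iters=200):
    """Independent 1-D bisection for the truncated-exponential scale."""
    def g(s):
        x = factor * mean / s
        return s - factor * mean * np.exp(-x) / (1.0 - np.exp(-x)) - mean

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestTargetHistogram:
    def test_counts_sum_and_monotonicity(self):
        for mean in (0.3, 0.96945, 4.2):
            h = build_target_histogram(mean, SamplingConfig(n_structures=100))
            assert h.target_counts.sum() == 100
            assert np.all(np.diff(h.target_counts) <= 0)
            assert h.edges[0] == 0.0
            assert h.edges[-1] == pytest.approx(4.5 * mean)

    def test_scale_matches_bisection_oracle(self):
        assert truncated_exponential_scale(1.0, 4.5) == pytest.approx(
            bisection_scale_oracle(1.0), abs=1e-9
        )

    def test_fitted_scale_reproduces_target_mean(self):
        mean = 0.96945
        s = truncated_exponential_scale(mean, 4.5 * mean)
        x = 4.5 * mean / s
        trunc_mean = s - 4.5 * mean / np.expm1(x)
        assert trunc_mean == pytest.approx(mean, rel=1e-12)

    def test_literal_scale_is_kbt(self):
        cfg = SamplingConfig(scale="literal", n_bins=5)
        h = build_target_histogram(1.0, cfg)
        s = KB_EV * 1500.0
        w = np.exp(-h.edges[:-1] / s) - np.exp(-h.edges[1:] / s)
        expected = np.floor(w / w.sum() * 100)
        # literal kB*T decays so fast everything lands in bin 0
        assert h.target_counts[0] >= expected[0]
        assert h.target_counts.sum() == 100

    def test_unreachable_mean_is_an_error(self):
        with pytest.raises(ValueError, match="max_factor|mean"):
            truncated_exponential_scale(1.0, 1.5)

    def test_bin_index_edges(self):
        h = build_target_histogram(1.0, SamplingConfig(n_bins=45))
        assert h.bin_index(-0.1) == -1
        assert h.bin_index(0.0) == 0
        assert h.bin_index(h.edges[-1]) == 44  # right edge belongs to last bin
        assert h.bin_index(h.edges[-1] + 1e-9) == -1


class TestAllocation:
    def test_zero_total_gives_zero_everything(self, toy5_modes, rng):
        alloc = allocate_mode_energies(toy5_modes, 0.0, rng)
        assert np.all(alloc.mode_energies == 0)
        assert np.all(alloc.amplitudes == 0)

    def test_shares_sum_to_total(self, toy5_modes, rng):
        for total in (0.01, 0.5, 3.7):
            alloc = allocate_mode_energies(toy5_modes, total, rng)
            assert alloc.mode_energies.sum() == pytest.approx(total, rel=1e-12)
            np.testing.assert_allclose(
                alloc.amplitudes,
                np.sqrt(2 * alloc.mode_energies) / toy5_modes.frequencies,
                rtol=1e-12,
            )

    def test_dirichlet_symmetry_monte_carlo(self, toy5_modes):
        # Dirichlet(1,...,1): every mode's mean share is total/9
        rng = np.random.default_rng(777)
        total, n_draws, m = 0.9, 10_000, 9
        shares = np.array([
            allocate_mode_energies(toy5_modes, total, rng).mode_energies
            for _ in range(n_draws)
        ])
        var_share = (1 / m) * (1 - 1 / m) / (m + 1) * total**2
        se = np.sqrt(var_share / n_draws)
        assert np.all(np.abs(shares.mean(axis=0) - total / m) < 3 * se)

    def test_signs_are_plus_minus_one(self, toy5_modes, rng):
        alloc = allocate_mode_energies(toy5_modes, 1.0, rng)
        assert set(np.unique(alloc.signs)) <= {-1, 1}


class TestDisplace:
    def test_zero_allocation_is_identity(self, toy5, toy5_modes, rng):
        s, _, _ = toy5
        alloc = allocate_mode_energies(toy5_modes, 0.0, rng)
        out = displace(s, toy5_modes, alloc)
        np.testing.assert_array_equal(out.positions, s.positions)

    def test_single_mode_energy_identity(self, toy5, toy5_modes, toy5_backend, rng):
        s, _, _ = toy5
        e0 = toy5_backend.evaluate(s)
        for mode in rng.choice(9, size=4, replace=False):
            de = float(rng.uniform(0.05, 1.5))
            alloc = allocate_mode_energies(toy5_modes, 0.0, rng)
            alloc.mode_energies[mode] = de
            alloc.amplitudes[mode] = np.sqrt(2 * de) / toy5_modes.frequencies[mode]
            out = displace(s, toy5_modes, alloc)
            rise = toy5_backend.evaluate(out) - e0
            assert rise == pytest.approx(de, rel=1e-9)

    def test_multimode_energies_add(self, toy5, toy5_modes, toy5_backend, rng):
        # mode orthogonality: the harmonic energy rise is the sum of shares
        s, _, _ = toy5
        e0 = toy5_backend.evaluate(s)
        alloc = allocate_mode_energies(toy5_modes, 1.3, rng)
        out = displace(s, toy5_modes, alloc)
        assert toy5_backend.evaluate(out) - e0 == pytest.approx(
            alloc.mode_energies.sum(), rel=1e-9
        )


class TestSampleNonequilibrium:
    def test_harmonic_run_fills_histogram_exactly(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        res = sample_nonequilibrium(
            s, toy5_modes, toy5_backend, SamplingConfig(seed=0)
        )
        h = res.histogram
        assert len(res.structures) == 100
        np.testing.assert_array_equal(h.filled_counts, h.target_counts)
        # realized counts recomputed from the accepted energies agree
        recomputed = np.histogram(res.delta_e, bins=h.edges)[0]
        np.testing.assert_array_equal(recomputed, h.target_counts)

    def test_mean_delta_e_near_equipartition_target(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        res = sample_nonequilibrium(
            s, toy5_modes, toy5_backend, SamplingConfig(seed=0)
        )
        target = mean_target_energy(5, 1500.0)
        assert np.mean(res.delta_e) == pytest.approx(target, rel=0.05)

    def test_pairwise_rmsd_floor_holds(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        res = sample_nonequilibrium(
            s, toy5_modes, toy5_backend, SamplingConfig(seed=4, n_structures=40)
        )
        floor = 0.0075 * 5
        for i in range(len(res.structures)):
            for j in range(i + 1, len(res.structures)):
                assert min_rmsd(res.structures[i], res.structures[j]) > floor

    def test_determinism_bitwise(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        cfg = SamplingConfig(seed=9, n_structures=25)
        r1 = sample_nonequilibrium(s, toy5_modes, toy5_backend, cfg)
        r2 = sample_nonequilibrium(s, toy5_modes, toy5_backend, cfg)
        assert len(r1.structures) == len(r2.structures)
        for a, b in zip(r1.structures, r2.structures):
            assert np.array_equal(a.positions, b.positions)
        assert r1.delta_e == r2.delta_e

    def test_anharmonic_backend_still_fills(self, toy5, toy5_modes):
        # re-evaluation decouples acceptance from the harmonic estimate
        s, _, topo = toy5
        cfg = SamplingConfig(seed=1, n_structures=30)
        res = sample_nonequilibrium(s, toy5_modes, MorseBackend(topo), cfg)
        h = res.histogram
        np.testing.assert_array_equal(h.filled_counts, h.target_counts)
        upper = 4.5 * mean_target_energy(5, 1500.0)
        assert all(0.0 <= de <= upper for de in res.delta_e)

    def test_incomplete_histogram_is_structured_error(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        cfg = SamplingConfig(seed=0, max_attempts=5)
        with pytest.raises(IncompleteHistogramError) as exc:
            sample_nonequilibrium(s, toy5_modes, toy5_backend, cfg)
        assert "unfilled bins" in str(exc.value)
        assert exc.value.result.histogram.remaining.sum() > 0

    def test_filled_never_exceeds_target(self, toy5, toy5_modes, toy5_backend):
        s, _, _ = toy5
        res = sample_nonequilibrium(
            s, toy5_modes, toy5_backend, SamplingConfig(seed=2, n_structures=30)
        )
        h = res.histogram
        assert np.all(h.filled_counts <= h.target_counts)
        assert h.filled_counts.sum() == 30
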