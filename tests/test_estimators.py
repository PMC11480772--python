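import math

import numpy as np
import pytest
from scipy.integrate import quad

from bindfe.constants import kbt
from bindfe.core import BiasPotential, UmbrellaWindow, UmbrellaWindowSet
from bindfe.estimators import (DisconnectedWindowsError, PmfProfile, bar,
                               block_error, exponential_averaging,
                               histogram_overlap, mbar, pmf_to_I_star, wham_1d)
from bindfe.synthetic import AnalyticPotential, generate_umbrella_dataset

KT300 = kbt(300.0)


def _flat_window(n=100_000, seed=0):
    rng = np.random.default_rng(seed)
    bias = BiasPotential("harmonic_distance", 5.0, 0.0, "full")
    return UmbrellaWindowSet("x", [UmbrellaWindow(bias, rng.uniform(0, 10, n), 300.0)])


class TestWham:
    def test_unbiased_uniform_gives_flat_profile(self):
        pmf = wham_1d(_flat_window(), bin_width=0.5)
        bound = 3.0 * np.maximum(pmf.stderr, 1e-3)
        assert np.all(np.abs(pmf.free_energy - pmf.free_energy.mean())
                      <= bound + pmf.free_energy.mean())
        assert pmf.free_energy.max() < 0.05  # ~kT/100 wiggle at this n

    def test_recovers_harmonic_potential(self):
        """Metropolis windows on U = 2 x^2 reconstruct it within RMS 0.1."""
        pot = AnalyticPotential("harmonic", {"prefactor": 2.0})
        ds = generate_umbrella_dataset(pot, np.linspace(-2, 2, 11), 10.0, "full",
                                       n_per_window=5000, seed=1)
        pmf = wham_1d(ds.windows, bin_width=0.1)
        truth = 2.0 * pmf.bin_centers**2
        mask = np.abs(pmf.bin_centers) <= 2.0
        resid = (pmf.free_energy - (truth - truth[mask].min()))[mask]
        assert math.sqrt(np.mean(resid**2)) < 0.1

    def test_recovers_double_well_barrier(self):
        """(x^2-1)^2 landscape: barrier at x=0 is 1.0 +- 0.1 kcal/mol."""
        pot = AnalyticPotential("double_well", {})
        ds = generate_umbrella_dataset(pot, np.linspace(-1.6, 1.6, 11), 10.0,
                                       "full", n_per_window=5000, seed=2)
        pmf = wham_1d(ds.windows, bin_width=0.1)
        barrier = pmf.interp(0.0) - min(pmf.interp(-1.0), pmf.interp(1.0))
        assert barrier == pytest.approx(1.0, abs=0.1)

    def test_shift_invariance(self):
        """Adding a constant to every window's bias leaves the PMF unchanged."""
        class ShiftedBias:
            """Duck-typed bias: the packaged harmonic plus a constant."""

            def __init__(self, bias, offset):
                self._bias = bias
                self.center = bias.center
                self.offset = offset

            def energy(self, x):
                return self._bias.energy(x) + self.offset

        pot = AnalyticPotential("harmonic", {"prefactor": 1.0})
        ds = generate_umbrella_dataset(pot, np.linspace(-1, 1, 5), 8.0, "full",
                                       n_per_window=2000, seed=3)
        pmf1 = wham_1d(ds.windows, n_error_blocks=0)
        shifted = [UmbrellaWindow(ShiftedBias(w.bias, 7.5), w.samples, w.temperature)
                   for w in ds.windows.windows]
        pmf2 = wham_1d(UmbrellaWindowSet("x", shifted), n_error_blocks=0)
        assert np.allclose(pmf1.free_energy, pmf2.free_energy, atol=1e-6)

    def test_disconnected_windows_raise(self):
        b1 = BiasPotential("harmonic_distance", 0.0, 100.0, "full")
        b2 = BiasPotential("harmonic_distance", 10.0, 100.0, "full")
        rng = np.random.default_rng(0)
        ws = UmbrellaWindowSet("x", [
            UmbrellaWindow(b1, rng.normal(0, 0.05, 500), 300.0),
            UmbrellaWindow(b2, rng.normal(10, 0.05, 500), 300.0)])
        with pytest.raises(DisconnectedWindowsError):
            wham_1d(ws)

    def test_agrees_with_mbar_on_same_windows(self):
        """WHAM and mBAR estimates of the window free energies coincide."""
        pot = AnalyticPotential("harmonic", {"prefactor": 2.0})
        ds = generate_umbrella_dataset(pot, np.linspace(-1, 1, 5), 10.0, "full",
                                       n_per_window=3000, seed=4)
        pmf = wham_1d(ds.windows, bin_width=0.05, n_error_blocks=0)
        # mBAR on the unbinned samples with the bias potentials as states
        windows = ds.windows.windows
        pooled = np.concatenate([w.samples for w in windows])
        u_kn = np.array([w.bias.energy(pooled) for w in windows])
        f_k, _ = mbar(u_kn, [len(w.samples) for w in windows], temperature=300.0)
        # window free energies implied by the WHAM profile
        beta = 1.0 / KT300
        dx = np.diff(pmf.bin_centers).mean()
        f_wham = []
        for w in windows:
            boltz = np.exp(-beta * (pmf.free_energy + w.bias.energy(pmf.bin_centers)))
            f_wham.append(-KT300 * math.log(boltz.sum() * dx))
        f_wham = np.array(f_wham) - f_wham[0]
        assert np.allclose(f_wham, f_k, atol=0.02)


class TestBar:
    def test_constant_work_is_exact(self):
        est = bar(np.full(100, 2.5), np.full(80, -2.5), 300.0)
        assert est.value == pytest.approx(2.5, abs=1e-9)

    def test_harmonic_closed_form(self):
        """U1 = x^2 vs U2 = 4 x^2: dF = (kT/2) ln 4 ~ 0.413 kcal/mol."""
        rng = np.random.default_rng(3)
        s1 = rng.normal(0, math.sqrt(KT300 / 2.0), 100_000)
        s2 = rng.normal(0, math.sqrt(KT300 / 8.0), 100_000)
        est = bar(3 * s1**2, -3 * s2**2, 300.0)
        exact = 0.5 * KT300 * math.log(4.0)
        assert abs(est.value - exact) < 3 * est.stderr
        assert est.value == pytest.approx(0.413, abs=0.01)

    def test_identical_states_give_zero(self):
        rng = np.random.default_rng(4)
        du = rng.normal(0, 0.5, 20_000)
        est = bar(du, -du[::-1], 300.0)
        assert abs(est.value) <= 3 * max(est.stderr, 1e-3)

    def test_stderr_shrinks_like_sqrt_n(self):
        """log-log regression of BAR stderr vs n has slope in [-0.6, -0.4]."""
        rng = np.random.default_rng(5)
        sizes = [500, 2000, 8000, 32000]
        errs = []
        for n in sizes:
            s1 = rng.normal(0, math.sqrt(KT300 / 2.0), n)
            s2 = rng.normal(0, math.sqrt(KT300 / 8.0), n)
            errs.append(bar(3 * s1**2, -3 * s2**2, 300.0).stderr)
        slope = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        assert -0.6 < slope < -0.4


class TestMbar:
    def test_two_states_equals_bar(self):
        rng = np.random.default_rng(6)
        n = 20_000
        s1 = rng.normal(0, math.sqrt(KT300 / 2.0), n)
        s2 = rng.normal(0, math.sqrt(KT300 / 8.0), n)
        pooled = np.concatenate([s1, s2])
        u_kn = np.array([pooled**2, 4 * pooled**2])
        f_k, _ = mbar(u_kn, [n, n], temperature=300.0)
        est = bar(3 * s1**2, -3 * s2**2, 300.0)
        assert f_k[1] == pytest.approx(est.value, abs=1e-6)

    def test_three_state_harmonic_ladder(self):
        """Pairwise closed forms (kT/2) ln(k_j / k_i) recovered within 3 sigma."""
        rng = np.random.default_rng(7)
        ks = [1.0, 2.0, 4.0]          # U_i = k_i x^2 (full convention)
        n = 15_000
        samples = [rng.normal(0, math.sqrt(KT300 / (2 * k)), n) for k in ks]
        pooled = np.concatenate(samples)
        u_kn = np.array([k * pooled**2 for k in ks])
        f_k, cov = mbar(u_kn, [n] * 3, temperature=300.0)
        for j in (1, 2):
            exact = 0.5 * KT300 * math.log(ks[j] / ks[0])
            sigma = math.sqrt(max(cov[j, j], 1e-12))
            assert abs(f_k[j] - exact) < 3 * max(sigma, 1e-3)

    def test_duplicated_state_gets_equal_free_energy(self):
        rng = np.random.default_rng(8)
        n = 5000
        s1 = rng.normal(0, math.sqrt(KT300 / 2.0), n)
        s2 = rng.normal(0, math.sqrt(KT300 / 8.0), n)
        pooled = np.concatenate([s1, s2])
        u_kn = np.array([pooled**2, 4 * pooled**2, 4 * pooled**2])
        f_k, _ = mbar(u_kn, [n, n, 0], temperature=300.0)
        assert f_k[1] == pytest.approx(f_k[2], abs=1e-9)


class TestBlockError:
    def test_constant_series_zero(self):
        assert block_error(np.full(100, 3.3)) == 0.0

    def test_hand_value_ten_blocks(self):
        """Series 1..10 in 10 blocks: stdev{1..10}/sqrt(10) ~ 0.957."""
        err = block_error(np.arange(1.0, 11.0), n_blocks=10)
        assert err == pytest.approx(np.std(np.arange(1.0, 11.0), ddof=1) / math.sqrt(10))
        assert err == pytest.approx(0.957, abs=5e-4)

    def test_iid_gaussian_matches_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 2.0, 10_000)
        assert block_error(x) == pytest.approx(2.0 / 100.0, rel=0.5)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            block_error(np.arange(5), n_blocks=10)

    def test_remainder_discarded(self):
        x = np.concatenate([np.zeros(100), [1e6]])
        assert block_error(x, n_blocks=10) == 0.0


class TestHistogramOverlap:
    def test_identical_sets_give_one(self):
        rng = np.random.default_rng(10)
        s = rng.normal(0, 1, 5000)
        b = BiasPotential("harmonic_distance", 0.0, 1.0, "full")
        b2 = BiasPotential("harmonic_distance", 0.1, 1.0, "full")
        ws = UmbrellaWindowSet("x", [UmbrellaWindow(b, s, 300.0),
                                     UmbrellaWindow(b2, s, 300.0)])
        assert histogram_overlap(ws)[0] == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        b = BiasPotential("harmonic_distance", 0.0, 1.0, "full")
        b2 = BiasPotential("harmonic_distance", 10.0, 1.0, "full")
        ws = UmbrellaWindowSet("x", [
            UmbrellaWindow(b, np.random.default_rng(0).uniform(0, 1, 1000), 300.0),
            UmbrellaWindow(b2, np.random.default_rng(1).uniform(9, 10, 1000), 300.0)])
        assert histogram_overlap(ws)[0] == pytest.approx(0.0)

    def test_gaussians_one_sigma_apart_match_quadrature(self):
        """Empirical Bhattacharyya overlap matches the quadrature value."""
        rng = np.random.default_rng(11)
        n = 400_000
        s1 = rng.normal(0, 1, n)
        s2 = rng.normal(1, 1, n)
        b = BiasPotential("harmonic_distance", 0.0, 1.0, "full")
        b2 = BiasPotential("harmonic_distance", 1.0, 1.0, "full")
        ws = UmbrellaWindowSet("x", [UmbrellaWindow(b, s1, 300.0),
                                     UmbrellaWindow(b2, s2, 300.0)])
        emp = histogram_overlap(ws, n_bins=60)[0]
        lo, hi = min(s1.min(), s2.min()), max(s1.max(), s2.max())
        edges = np.linspace(lo, hi, 61)

        def gauss_bin(mu, a, b_):
            return quad(lambda x: math.exp(-(x - mu) ** 2 / 2) / math.sqrt(2 * math.pi),
                        a, b_)[0]

        p = np.array([gauss_bin(0, edges[i], edges[i + 1]) for i in range(60)])
        q = np.array([gauss_bin(1, edges[i], edges[i + 1]) for i in range(60)])
        oracle = np.sum(np.sqrt(p * q))
        assert emp == pytest.approx(oracle, abs=0.01)


class TestIStar:
    def test_flat_pmf_gives_site_width(self):
        r = np.linspace(0, 20, 201)
        pmf = PmfProfile(r, np.zeros_like(r), np.zeros_like(r), 300.0)
        assert pmf_to_I_star(pmf, (5.0, 15.0), 18.0) == pytest.approx(10.0, rel=1e-6)

    def test_gaussian_well_closed_form(self):
        """W = (1/2)(r-r0)^2 integrates to sqrt(2 pi kT) ~ 1.935 A."""
        r = np.linspace(10, 30, 4001)
        w = 0.5 * (r - 20.0) ** 2
        pmf = PmfProfile(r, w, np.zeros_like(r), 300.0)
        val = pmf_to_I_star(pmf, (12.0, 28.0), 20.0)
        assert val == pytest.approx(math.sqrt(2 * math.pi * KT300), rel=1e-4)
        assert val == pytest.approx(1.935, abs=0.001)

    def test_grid_refinement_converged(self):
        vals = []
        for n in (1001, 2001):
            r = np.linspace(10, 30, n)
            w = 0.5 * (r - 20.0) ** 2
            pmf = PmfProfile(r, w, np.zeros_like(r), 300.0)
            vals.append(pmf_to_I_star(pmf, (12.0, 28.0), 20.0))
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-3

    def test_monotone_in_site_width(self):
        r = np.linspace(10, 30, 2001)
        w = 0.5 * (r - 20.0) ** 2
        pmf = PmfProfile(r, w, np.zeros_like(r), 300.0)
        widths = [(18, 22), (16, 24), (14, 26), (12, 28)]
        vals = [pmf_to_I_star(pmf, s, 20.0) for s in widths]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_range_outside_profile_raises(self):
        r = np.linspace(10, 30, 101)
        pmf = PmfProfile(r, np.zeros_like(r), np.zeros_like(r), 300.0)
        with pytest.raises(ValueError):
            pmf_to_I_star(pmf, (5.0, 15.0), 20.0)


class TestExponentialAveraging:
    def test_zero_work_gives_zero(self):
        assert exponential_averaging(np.zeros(100)).value == 0.0

    def test_gaussian_identity(self):
        rng = np.random.default_rng(12)
        mu, sig = 1.5, 0.4
        u = rng.normal(mu, sig, 100_000)
        est = exponential_averaging(u, 300.0)
        exact = mu - sig**2 / (2 * KT300)
        assert abs(est.value - exact) < 3 * est.stderr
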