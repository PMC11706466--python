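"""Pairwise statistics: enumeration counts, oracles, symmetry, and bounds."""

import functools

import numpy as np
import pytest

from dynsig import build_pair_index, compute_coupling_tensor, compute_spi
from dynsig.spis import (
    DIRECTED_SPIS,
    SPI_NAMES,
    UNDIRECTED_SPIS,
    dtw_distance,
    spi_distance,
    spi_infotheory,
    spi_model,
    spi_pearson,
    spi_spectral,
)


class TestPairIndex:
    @pytest.mark.parametrize(
        "r,directed,expected",
        [(82, True, 6642), (48, True, 2256), (48, False, 1128), (3, False, 3)],
    )
    def test_pair_counts(self, r, directed, expected):
        assert build_pair_index(r, directed).n_pairs == expected

    def test_small_undirected_enumeration(self):
        assert build_pair_index(3, False).pairs == ((0, 1), (0, 2), (1, 2))

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            build_pair_index(1, True)


class TestPearson:
    def test_self_and_sign(self, rng):
        x = rng.standard_normal(100)
        assert spi_pearson(x, x) == pytest.approx(1.0)
        assert spi_pearson(x, -x) == pytest.approx(-1.0)

    def test_population_value(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(100_000)
        e = rng.standard_normal(100_000)
        y = 0.6 * x + e
        assert spi_pearson(x, y) == pytest.approx(0.6 / np.sqrt(1.36), abs=0.01)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spi_pearson(np.ones(10), np.arange(10.0))


def _dtw_brute(x, y):
    """Exhaustive minimum over all monotone alignments (lengths <= 6)."""

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        c = (x[i] - y[j]) ** 2
        if i == 0 and j == 0:
            return c
        opts = []
        if i > 0:
            opts.append(best(i - 1, j))
        if j > 0:
            opts.append(best(i, j - 1))
        if i > 0 and j > 0:
            opts.append(best(i - 1, j - 1))
        return c + min(opts)

    return np.sqrt(best(len(x) - 1, len(y) - 1))


class TestDTW:
    def test_identical_series_zero(self, rng):
        x = rng.standard_normal(50)
        assert dtw_distance(x, x) == 0.0

    def test_repetition_absorbed(self):
        assert dtw_distance(np.array([0.0, 1, 2]), np.array([0.0, 0, 1, 2])) == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 7, size=2)
            x = tuple(rng.standard_normal(n))
            y = tuple(rng.standard_normal(m))
            assert dtw_distance(np.array(x), np.array(y)) == pytest.approx(
                _dtw_brute(x, y), rel=1e-12
            )

    def test_two_point_case(self):
        x, y = np.array([0.0, 3.0]), np.array([1.0, 1.0])
        assert dtw_distance(x, y) == pytest.approx(_dtw_brute(tuple(x), tuple(y)))

    def test_barycenter_of_identical_pair_is_the_series(self, rng):
        x = rng.standard_normal(40)
        z = (x - x.mean()) / x.std()
        assert spi_distance(x, x, "barycenter_DTW") == pytest.approx(z.mean(), abs=1e-9)


class TestSpectral:
    def test_coherence_of_identical_series(self, rng):
        x = rng.standard_normal(152)
        assert spi_spectral(x, x, "coherence_magnitude") == pytest.approx(1.0)

    def test_pli_quarter_cycle_and_zero_lag(self, rng):
        t = np.arange(200)
        assert spi_spectral(
            np.cos(0.3 * t), np.cos(0.3 * t - np.pi / 2), "PLI"
        ) == pytest.approx(1.0)
        x = rng.standard_normal(200)
        assert spi_spectral(x, x, "PLI") == 0.0  # sign(sin 0) = 0

    def test_psi_antisymmetry(self, rng):
        x, y = rng.standard_normal(152), rng.standard_normal(152)
        for which in ("PSI_frequency", "PSI_time_frequency"):
            assert spi_spectral(x, y, which) == pytest.approx(
                -spi_spectral(y, x, which), rel=1e-9
            )

    def test_psi_sign_identifies_leader(self):
        # y lags x: information flows x -> y, PSI(x, y) > 0
        rng = np.random.default_rng(5)
        drive = rng.standard_normal(3000)
        x = np.convolve(drive, np.ones(3) / 3, mode="same")
        y = np.roll(x, 2) + 0.05 * rng.standard_normal(3000)
        assert spi_spectral(x, y, "PSI_frequency") > 0

    def test_power_envelope_corr_of_comodulated_pair(self):
        rng = np.random.default_rng(6)
        t = np.arange(400)
        env = 1.5 + np.sin(2 * np.pi * t / 200)
        x = env * np.cos(0.9 * t) + 0.01 * rng.standard_normal(400)
        y = env * np.cos(0.9 * t + 2.0) + 0.01 * rng.standard_normal(400)
        assert spi_spectral(x, y, "power_envelope_corr") > 0.8


class TestInfoTheory:
    def test_te_near_zero_for_independent_noise(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert spi_infotheory(x, y, "transfer_entropy") < 0.005

    def test_te_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(8)
        T = 10_000
        x = rng.standard_normal(T)
        y = np.zeros(T)
        eps = rng.standard_normal(T)
        for t in range(1, T):
            y[t] = 0.5 * x[t - 1] + eps[t]
        te = spi_infotheory(x, y, "transfer_entropy")
        assert te == pytest.approx(0.5 * np.log(1.25), rel=0.10)

    def test_te_matches_independent_regression_path(self):
        # same Gaussian TE via an explicit least-squares residual-variance route
        rng = np.random.default_rng(9)
        T = 2000
        x = rng.standard_normal(T)
        y = np.zeros(T)
        for t in range(1, T):
            y[t] = 0.4 * y[t - 1] + 0.3 * x[t - 1] + rng.standard_normal()
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        yt, y1, x1 = zy[1:], zy[:-1], zx[:-1]

        def rss(design, target):
            beta, *_ = np.linalg.lstsq(design, target, rcond=None)
            r = target - design @ beta
            return (r @ r) / len(target)

        v_hist = rss(np.column_stack([np.ones_like(y1), y1]), yt)
        v_full = rss(np.column_stack([np.ones_like(y1), y1, x1]), yt)
        expected = 0.5 * np.log(v_hist / v_full)
        assert spi_infotheory(x, y, "transfer_entropy") == pytest.approx(
            expected, abs=1e-3
        )

    def test_di_uses_contemporaneous_source(self):
        rng = np.random.default_rng(10)
        T = 5000
        x = rng.standard_normal(T)
        y = 0.8 * x + 0.3 * rng.standard_normal(T)  # zero-lag coupling
        di = spi_infotheory(x, y, "DI")
        te = spi_infotheory(x, y, "transfer_entropy")
        assert di > 0.3
        assert te < 0.05  # no lagged information beyond y's own history

    def test_phi_star_zero_for_independent_pair(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert abs(spi_infotheory(x, y, "phi_star")) < 0.005

    def test_phi_star_positive_for_coupled_pair(self):
        rng = np.random.default_rng(12)
        T = 5000
        x, y = np.zeros(T), np.zeros(T)
        for t in range(1, T):
            x[t] = 0.4 * x[t - 1] + 0.4 * y[t - 1] + rng.standard_normal()
            y[t] = 0.4 * y[t - 1] + 0.4 * x[t - 1] + rng.standard_normal()
        assert spi_infotheory(x, y, "phi_star") > 0.05


class TestModelBased:
    def test_spectral_gc_matches_parametric_var(self):
        rng = np.random.default_rng(13)
        T = 10_000
        x = rng.standard_normal(T)
        y = np.zeros(T)
        eps = rng.standard_normal(T)
        for t in range(1, T):
            y[t] = 0.8 * x[t - 1] + eps[t]
        # parametric Geweke GC x->y: ln(var reduced / var full) = ln(1.64)
        assert spi_model(x, y, "spectral_GC") == pytest.approx(
            np.log(1.64), rel=0.15
        )
        assert spi_model(y, x, "spectral_GC") < 0.05

    def test_cointegration_detects_shared_trend(self):
        rng = np.random.default_rng(14)
        T = 400
        walk = np.cumsum(rng.standard_normal(T))
        y = walk + 0.5 * rng.standard_normal(T)
        coupled = spi_model(walk, y, "cointegration")
        w1 = np.cumsum(rng.standard_normal(T))
        w2 = np.cumsum(rng.standard_normal(T))
        independent = spi_model(w1, w2, "cointegration")
        assert coupled < 0  # strongly negative ADF statistic
        assert abs(coupled) > abs(independent)

    def test_anm_identifies_causal_direction(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(-2, 2, 400)
        y = x**2 + 0.1 * rng.standard_normal(400)
        assert spi_model(x, y, "ANM") < spi_model(y, x, "ANM")


class TestProperties:
    @pytest.mark.parametrize("name", UNDIRECTED_SPIS)
    def test_undirected_symmetry(self, name, rng):
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert compute_spi(x, y, name) == pytest.approx(
            compute_spi(y, x, name), rel=1e-7, abs=1e-9
        )

    def test_bounds(self, rng):
        x, y = rng.standard_normal(120), rng.standard_normal(120)
        assert -1 <= compute_spi(x, y, "Pearson") <= 1
        assert 0 <= compute_spi(x, y, "PLI") <= 1
        assert 0 <= compute_spi(x, y, "coherence_magnitude") <= 1
        for name in ("DTW", "transfer_entropy", "DI", "phi_star"):
            assert compute_spi(x, y, name) >= -1e-9

    def test_directed_flows_concentrate_near_zero_under_independence(self):
        rng = np.random.default_rng(16)
        vals = {n: [] for n in ("transfer_entropy", "DI", "PSI_frequency")}
        for _ in range(8):
            x, y = rng.standard_normal(400), rng.standard_normal(400)
            for n in vals:
                vals[n].append(abs(compute_spi(x, y, n)))
        assert np.median(vals["transfer_entropy"]) < 0.02
        assert np.median(vals["DI"]) < 0.02
        assert np.median(vals["PSI_frequency"]) < 0.5


class TestCouplingTensor:
    def test_pair_counts_by_directedness(self, null_cohort):
        tensors = compute_coupling_tensor(null_cohort, ["Pearson", "transfer_entropy"])
        by_name = {t.spi_name: t for t in tensors}
        r = null_cohort.n_regions
        assert by_name["Pearson"].values.shape[1] == r * (r - 1) // 2
        assert by_name["transfer_entropy"].values.shape[1] == r * (r - 1)
        assert not by_name["Pearson"].directed
        assert by_name["transfer_entropy"].directed

    def test_unknown_spi_lists_valid_names(self, null_cohort):
        with pytest.raises(ValueError, match="Pearson"):
            compute_coupling_tensor(null_cohort, ["nope"])

    def test_all_names_resolve(self):
        assert len(SPI_NAMES) == 14
        assert set(DIRECTED_SPIS) | set(UNDIRECTED_SPIS) == set(SPI_NAMES)

    def test_parallel_matches_serial(self, null_cohort):
        a = compute_coupling_tensor(null_cohort, ["Pearson"], n_jobs=1)[0]
        b = compute_coupling_tensor(null_cohort, ["Pearson"], n_jobs=2)[0]
        np.testing.assert_array_equal(a.values, b.values)
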