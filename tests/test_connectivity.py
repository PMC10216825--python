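import numpy as np
import pytest
from scipy import stats

from gcq import (
    CollinearityError,
    CouplingSpec,
    ZeroDynamicRangeError,
    connectivity_matrix,
    granger_f,
    normalize,
    simulate_var,
)


def brute_force_granger_f(x, y, p):
    """Independent oracle: explicit lag stacking and normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    rows_y, rows_x, resp = [], [], []
    for t in range(p, n):
        resp.append(y[t])
        rows_y.append([y[t - i] for i in range(1, p + 1)])
        rows_x.append([x[t - j] for j in range(1, p + 1)])
    resp = np.array(resp)

    def rss(design):
        design = np.asarray(design, float)
        beta = np.linalg.solve(design.T @ design, design.T @ resp)
        resid = resp - design @ beta
        return float(resid @ resid)

    ones = [[1.0]] * len(resp)
    rss_r = rss(np.hstack([ones, rows_y]))
    rss_u = rss(np.hstack([ones, rows_y, rows_x]))
    n_eff = n - p
    return ((rss_r - rss_u) / p) / (rss_u / (n_eff - 2 * p - 1))


class TestNormalize:
    def test_three_point_example(self):
        np.testing.assert_allclose(
            normalize([0.0, 5.0, 10.0]).values, [-1.0, 0.0, 1.0]
        )

    def test_two_valued_example(self):
        np.testing.assert_allclose(
            normalize([-3.0, -3.0, 3.0]).values, [-1.0, -1.0, 1.0]
        )

    def test_extremes_attained_exactly(self, rng):
        for _ in range(20):
            sig = rng.standard_normal(rng.integers(2, 200))
            if sig.min() == sig.max():
                continue
            out = normalize(sig)
            assert out.values.min() == -1.0
            assert out.values.max() == 1.0

    def test_metadata_retains_extrema(self):
        out = normalize([2.0, 4.0, 8.0])
        assert (out.e_min, out.e_max) == (2.0, 8.0)

    def test_constant_signal_zero_dynamic_range(self):
        with pytest.raises(ZeroDynamicRangeError, match="zero dynamic range"):
            normalize(np.full(10, 1.3))


class TestGrangerF:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = int(rng.integers(1, 4))
            spec = CouplingSpec.from_links(2, [(0, 1, float(rng.uniform(0, 0.8)))])
            nodes = simulate_var(spec, 256, rng)
            res = granger_f(nodes[0], nodes[1], lags=p)
            expected = brute_force_granger_f(nodes[0], nodes[1], p)
            assert res.f_stat == pytest.approx(expected, rel=1e-6)

    def test_matches_statsmodels(self, rng):
        from statsmodels.tsa.stattools import grangercausalitytests

        spec = CouplingSpec.from_links(2, [(0, 1, 0.6)])
        nodes = simulate_var(spec, 512, rng)
        for p in (1, 2, 5):
            ours = granger_f(nodes[0], nodes[1], lags=p).f_stat
            ref = grangercausalitytests(
                np.column_stack([nodes[1], nodes[0]]), maxlag=[p]
            )[p][0]["ssr_ftest"][0]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_rss_monotone_and_f_nonnegative(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 200))
            res = granger_f(x, y, lags=int(rng.integers(1, 6)))
            assert res.rss_unrestricted <= res.rss_restricted
            assert res.f_stat >= 0

    def test_scale_offset_invariance(self, rng):
        spec = CouplingSpec.from_links(2, [(0, 1, 0.5)])
        nodes = simulate_var(spec, 300, rng)
        base = granger_f(nodes[0], nodes[1], lags=2).f_stat
        scaled = granger_f(3.2 * nodes[0] - 7, -0.5 * nodes[1] + 2, lags=2).f_stat
        assert scaled == pytest.approx(base, rel=1e-8)

    def test_identical_signals_collinear(self, rng):
        x = rng.standard_normal(200)
        with pytest.raises(CollinearityError, match="collinear"):
            granger_f(x, x, lags=1)

    def test_strong_unidirectional_coupling(self, rng):
        n = 1024
        x = rng.standard_normal(n + 1)
        y = 0.9 * x[:-1] + 0.05 * rng.standard_normal(n)
        x = x[1:]
        fwd = granger_f(x, y, lags=1)
        rev = granger_f(y, x, lags=1)
        assert fwd.f_stat > 60
        assert rev.f_stat < 60
        assert fwd.causal and not rev.causal

    def test_time_reversal_flips_dominant_direction(self):
        """Reversing time swaps which direction of a unidirectional pair
        carries the larger F (median over seeds)."""
        spec = CouplingSpec.from_links(2, [(0, 1, 0.8)])
        fwd_minus_rev, rev_after_flip = [], []
        for s in range(15):
            nodes = simulate_var(spec, 512, np.random.default_rng([3, s]))
            x, y = nodes
            fwd_minus_rev.append(
                granger_f(x, y, lags=1).f_stat - granger_f(y, x, lags=1).f_stat
            )
            xr, yr = x[::-1], y[::-1]
            rev_after_flip.append(
                granger_f(yr, xr, lags=1).f_stat - granger_f(xr, yr, lags=1).f_stat
            )
        assert np.median(fwd_minus_rev) > 0
        assert np.median(rev_after_flip) > 0

    def test_bic_lag_recovers_true_order(self):
        """With a pure VAR(1) pair, BIC picks a small order (no overfit)."""
        spec = CouplingSpec.from_links(2, [(0, 1, 0.7)])
        nodes = simulate_var(spec, 1024, np.random.default_rng(4))
        res = granger_f(nodes[0], nodes[1], lags="bic", max_lag=10)
        assert res.p_lags <= 2

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            granger_f(np.arange(10.0), np.arange(10.0) ** 2, lags=4)


class TestConnectivityMatrix:
    def test_count_and_diagonal(self, rng):
        signals = list(rng.standard_normal((6, 300)))
        cm = connectivity_matrix(signals, lags=1)
        assert cm.values.shape == (6, 6)
        np.testing.assert_array_equal(np.diag(cm.values), 0.0)
        assert np.count_nonzero(cm.values) == 30  # F > 0 a.s. off-diagonal
        assert np.all(cm.values >= 0)

    def test_orientation_row_target_column_source(self, rng):
        spec = CouplingSpec.from_links(2, [(0, 1, 0.9)])
        nodes = simulate_var(spec, 1024, rng)
        cm = connectivity_matrix(list(nodes), ["a", "b"], lags=1)
        # node 0 drives node 1 → large F at (target=1, source=0)
        assert cm.values[1, 0] > 10 * cm.values[0, 1]

    def test_permutation_equivariance(self, rng):
        signals = rng.standard_normal((4, 300))
        cm = connectivity_matrix(list(signals), lags=1)
        perm = [2, 0, 3, 1]
        cm_p = connectivity_matrix(list(signals[perm]), lags=1)
        np.testing.assert_allclose(
            cm_p.values, cm.values[np.ix_(perm, perm)], atol=1e-10
        )

    def test_white_noise_rarely_crosses_threshold(self, rng):
        """P(F > 60) for independent noise at p=1, n≈8000 is negligible."""
        signals = list(rng.standard_normal((6, 8000)))
        cm = connectivity_matrix(signals, lags=1)
        assert np.all(cm.values <= 60.0)
        # analytic sanity: the F(1, ~8000) tail beyond 60 is ~1e-14
        assert stats.f.sf(60, 1, 7995) < 1e-12

    def test_constant_signal_cells_zero_with_warning(self, rng, caplog):
        signals = [rng.standard_normal(300), np.full(300, 2.0),
                   rng.standard_normal(300)]
        with caplog.at_level("WARNING"):
            cm = connectivity_matrix(signals, ["a", "b", "c"], lags=1)
        assert cm.n_failed == 4  # all cells touching signal b
        assert np.all(cm.values[1, :] == 0) and np.all(cm.values[:, 1] == 0)
        assert cm.values[2, 0] > 0 or cm.values[0, 2] > 0

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            connectivity_matrix([rng.standard_normal(100),
                                 rng.standard_normal(101)])

    def test_csv_roundtrip(self, rng, tmp_path):
        import pandas as pd

        cm = connectivity_matrix(list(rng.standard_normal((3, 200))),
                                 ["x", "y", "z"], lags=1)
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        frame = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(frame.to_numpy(), cm.values)
        assert list(frame.columns) == ["x", "y", "z"]
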