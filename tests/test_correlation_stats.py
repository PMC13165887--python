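import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vhitdrift as vd
from vhitdrift.errors import InputError, UndefinedCorrelationError


def tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair count with tie corrections."""
    n = len(x)
    C = D = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0:
            tx += 1
        if dy == 0:
            ty += 1
        if dx * dy > 0:
            C += 1
        elif dx * dy < 0:
            D += 1
    n0 = n * (n - 1) // 2
    return (C - D) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTauB:
    def test_perfect_concordance_and_discordance(self):
        tau, _ = vd.kendall_tau_b([1, 2, 3, 4], [2, 4, 6, 8])
        assert tau == pytest.approx(1.0)
        tau, _ = vd.kendall_tau_b([1, 2, 3, 4], [8, 6, 4, 2])
        assert tau == pytest.approx(-1.0)

    def test_tied_example_matches_pair_count_oracle(self):
        x = np.array([1.0, 1, 2, 3])
        y = np.array([1.0, 2, 2, 3])
        tau, _ = vd.kendall_tau_b(x, y)
        assert tau == pytest.approx(tau_b_oracle(x, y), rel=1e-12)

    def test_matches_oracle_on_random_vectors(self, rng):
        """tau-b equals the explicit pair-count oracle, with and without ties."""
        for k in range(500):
            n = int(rng.integers(3, 25))
            if k % 2:
                x = rng.integers(0, 5, n).astype(float)  # heavy ties
                y = rng.integers(0, 5, n).astype(float)
            else:
                x = rng.normal(size=n)
                y = rng.normal(size=n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, p = vd.kendall_tau_b(x, y)
            assert tau == pytest.approx(tau_b_oracle(x, y), rel=1e-10, abs=1e-12)
            assert -1.0 <= tau <= 1.0
            assert 0.0 <= p <= 1.0

    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        tau, _ = vd.kendall_tau_b(x, y)
        tau2, _ = vd.kendall_tau_b(np.exp(x), y**3)  # strictly monotone maps
        assert tau2 == pytest.approx(tau, rel=1e-12, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            vd.kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKendallMatrix:
    def test_matrix_shape_symmetry_diagonal(self, default_features):
        res = vd.kendall_matrix(default_features)
        assert res.tau.shape == (11, 11)
        assert np.allclose(res.tau, res.tau.T)
        assert np.allclose(np.diag(res.tau), 1.0)
        assert np.allclose(np.diag(res.pvals), 0.0)
        assert ((res.tau.to_numpy() >= -1) & (res.tau.to_numpy() <= 1)).all()

    def test_matrix_consistent_with_pairwise_calls(self, default_features):
        res = vd.kendall_matrix(default_features)
        x = default_features["d_e"].to_numpy()
        y = default_features["v_max"].to_numpy()
        tau, p = vd.kendall_tau_b(x, y)
        assert res.tau.loc["d_e", "v_max"] == pytest.approx(tau)
        assert res.pvals.loc["d_e", "v_max"] == pytest.approx(p)

    def test_constant_column_flagged_undefined(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "c": np.ones(10)}
        )
        res = vd.kendall_matrix(df)
        assert np.isnan(res.tau.loc["c", "a"])
        assert not np.isnan(res.tau.loc["a", "b"])


class TestFisherCI:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.68, 19, (0.33, 0.87)), (0.72, 19, (0.39, 0.88)), (0.75, 19, (0.45, 0.90))],
    )
    def test_printed_intervals_recovered(self, r, n, expected):
        lo, hi = vd.fisher_ci_from_r(r, n)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_r_interval_symmetric(self):
        lo, hi = vd.fisher_ci_from_r(0.0, 30)
        assert lo == pytest.approx(-hi)

    def test_width_shrinks_with_n(self):
        w19 = np.diff(vd.fisher_ci_from_r(0.7, 19))[0]
        w103 = np.diff(vd.fisher_ci_from_r(0.7, 103))[0]
        assert w103 < w19

    def test_boundary_r_rejected(self):
        with pytest.raises(InputError):
            vd.fisher_ci_from_r(1.0, 19)
        with pytest.raises(InputError):
            vd.fisher_ci_from_r(0.5, 3)

    def test_report_contains_r_inside_open_interval(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rep = vd.pearson_with_fisher_ci(x, y)
        assert rep.r_ci_low < rep.r < rep.r_ci_high
        assert -1 < rep.r_ci_low and rep.r_ci_high < 1
        assert rep.r_squared == pytest.approx(rep.r**2)


class TestGroupSummary:
    @staticmethod
    def _df(drifts, protocol="Lateral"):
        return pd.DataFrame(
            {
                "protocol": protocol,
                "d_e": drifts,
                "v_max": np.full(len(drifts), 150.0),
            }
        )

    def test_normal_approximation_interval(self, rng):
        drifts = rng.normal(-3.0, 2.0, 24)
        gs = vd.group_summary(self._df(drifts), "Lateral")
        se = drifts.std(ddof=1) / np.sqrt(24)
        assert gs.mean_drift == pytest.approx(drifts.mean())
        assert gs.ci_low == pytest.approx(drifts.mean() - 1.959964 * se, rel=1e-6)
        assert gs.ci_high == pytest.approx(drifts.mean() + 1.959964 * se, rel=1e-6)
        assert gs.ci_low <= gs.mean_drift <= gs.ci_high

    def test_printed_table_intervals(self):
        # normal-approximation CI from the printed (mean, SD, n) triples
        cases = [
            (-3.23, 3.30, 24, (-4.55, -1.91)),
            (-3.08, 4.21, 16, (-5.14, -1.02)),
            (-7.41, 3.06, 17, (-8.86, -5.96)),
        ]
        for mean, sd, n, expected in cases:
            lo, hi = vd.normal_ci(mean, sd, n)
            assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_sd_collapses_interval(self):
        gs = vd.group_summary(self._df(np.full(5, -2.0)), "Lateral")
        assert gs.ci_low == gs.ci_high == gs.mean_drift == -2.0

    def test_ci_width_scales_inverse_sqrt_n(self, rng):
        drifts = rng.normal(-3.0, 2.0, 400)
        w_small = np.ptp(vd.normal_ci(0, drifts.std(ddof=1), 25))
        w_large = np.ptp(vd.normal_ci(0, drifts.std(ddof=1), 400))
        assert w_small / w_large == pytest.approx(4.0, rel=1e-9)

    def test_empty_group_rejected(self, default_features):
        with pytest.raises(InputError):
            vd.group_summary(default_features[default_features.protocol == "x"], "x")


class TestGroupComparisons:
    def test_kruskal_hand_computed_h(self):
        H, p = vd.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert H == pytest.approx(32 / 7)
        assert 0 < p < 1

    def test_kruskal_invariant_to_group_order(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, 10), rng.normal(2, 1, 9)]
        H1, _ = vd.kruskal_wallis(groups)
        H2, _ = vd.kruskal_wallis(groups[::-1])
        assert H1 == pytest.approx(H2)
        assert H1 >= 0

    def test_kruskal_identical_values_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            vd.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])

    def test_mann_whitney_u_matches_exhaustive_count(self):
        table = vd.pairwise_mann_whitney({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        # every (a, b) pair has a < b: U for 'a' is 0 (two-sided statistic is
        # reported for the first group by scipy convention, max-U = 9)
        assert table.loc[0, "U"] in (0.0, 9.0)
        assert table.loc[0, "alpha_corrected"] == pytest.approx(0.05)

    def test_three_group_bonferroni_threshold(self, rng):
        groups = {k: rng.normal(size=10) for k in ("Lateral", "LARP", "RALP")}
        table = vd.pairwise_mann_whitney(groups)
        assert len(table) == 3
        assert table["alpha_corrected"].unique() == pytest.approx([0.05 / 3])
        assert round(table.loc[0, "alpha_corrected"], 4) == 0.0167

    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        table = vd.pairwise_mann_whitney({"a": x, "b": x.copy()})
        assert table.loc[0, "p"] > 0.9
        assert not table.loc[0, "significant"]


class TestDriftVelocityCorrelation:
    def test_magnitude_convention_flips_sign(self, default_features):
        rep_abs = vd.drift_velocity_correlation(default_features, "RALP")
        rep_signed = vd.drift_velocity_correlation(
            default_features, "RALP", signed=True
        )
        # drifts are negative: |d_e| grows when signed d_e falls
        assert np.sign(rep_abs.r) == -np.sign(rep_signed.r)

    def test_unknown_protocol_rejected(self, default_features):
        with pytest.raises(InputError):
            vd.drift_velocity_correlation(default_features, "Vertical")
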