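"""Partial correlations, BH-FDR, ANCOVA, Fisher z, hierarchical regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubnet import (
    bh_adjust,
    ancova_group_effect,
    fisher_z_compare,
    hierarchical_regression,
    partial_correlation,
    screen_hubs,
)
from hubnet.connectome import NodalStrengthTable


def inverse_correlation_oracle(x, y, covs):
    """Partial correlation via the inverse-correlation-matrix identity."""
    data = np.column_stack([x, y, covs])
    prec = np.linalg.inv(np.corrcoef(data, rowvar=False))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 30))
        res = partial_correlation(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1])
        assert res.df == 28

    def test_perfect_association(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        cov = rng.standard_normal(20)
        res = partial_correlation(x, x.copy(), cov)
        assert res.r == pytest.approx(1.0)
        assert res.p_raw == 0.0

    @pytest.mark.parametrize("seed", [2, 3, 4, 5])
    def test_matches_inverse_correlation_matrix_oracle(self, seed):
        """Residualization route equals the precision-matrix identity, 1e-10."""
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 12))
        covs = rng.standard_normal((12, 3))
        res = partial_correlation(x, y, covs)
        assert res.r == pytest.approx(
            inverse_correlation_oracle(x, y, covs), abs=1e-10
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        frame = pd.DataFrame(
            rng.standard_normal((40, 4)), columns=["x", "y", "c1", "c2"]
        )
        res = partial_correlation(
            frame.x, frame.y, frame[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_raw == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 25))
        covs = rng.standard_normal((25, 2))
        base = partial_correlation(x, y, covs).r
        scaled = partial_correlation(
            3.2 * x - 1.0, -0.5 * y + 7.0, 2.0 * covs + 5.0
        ).r
        assert abs(scaled) == pytest.approx(abs(base), abs=1e-12)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 15))
        c = rng.standard_normal(15)
        with pytest.raises(ValueError):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestBHAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_smallest_of_90(self):
        """3e-6 among 90 larger p-values adjusts to 3e-6 * 90 = 2.7e-4."""
        p = np.concatenate([[3e-6], np.linspace(0.01, 0.9, 89)])
        assert bh_adjust(p)[0] == pytest.approx(2.7e-4)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.uniform(size=60)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    def test_dominates_raw_monotone_decision_consistent(self, p):
        """Adjusted p's dominate raw p's, are monotone in the sorted order,
        and thresholding them reproduces the classic step-up rejection set."""
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        for q in (0.01, 0.05, 0.2):
            # Ignore entries within float rounding of the decision boundary.
            clear = np.abs(adj - q) > 1e-9
            assert np.array_equal(
                (adj <= q)[clear], self._step_up_rejections(p, q)[clear]
            )

    @staticmethod
    def _step_up_rejections(p, q):
        """Independent step-up oracle: reject the k smallest p's where k is
        the largest rank with p_(k) <= q*k/m."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        below = np.flatnonzero(ranked <= q * np.arange(1, m + 1) / m)
        reject = np.zeros(m, dtype=bool)
        if below.size:
            reject[order[: below.max() + 1]] = True
        return reject

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


def _table(values, labels=None):
    n, m = values.shape
    labels = labels or [f"R{j:03d}" for j in range(m)]
    return NodalStrengthTable(
        subject_ids=[f"s{i}" for i in range(n)],
        values=values,
        region_labels=labels,
    )


class TestScreenHubs:
    def test_planted_region_ranks_first(self):
        rng = np.random.default_rng(10)
        n, m = 65, 30
        trait = rng.standard_normal(n)
        values = np.abs(rng.standard_normal((n, m)) + 5)
        values[:, 4] += 1.5 * trait
        covs = rng.standard_normal((n, 3))
        res = screen_hubs(_table(values), trait, covs)
        best = min(res, key=lambda r: r.p_raw)
        assert best.region == "R004"
        assert best.p_adjusted < 0.05
        assert all(r.p_adjusted >= r.p_raw for r in res)
        assert all(r.df == n - 2 - 3 for r in res)

    def test_agrees_with_scalar_partial_correlation(self):
        rng = np.random.default_rng(12)
        values = np.abs(rng.standard_normal((20, 5)) + 4)
        trait = rng.standard_normal(20)
        covs = rng.standard_normal((20, 2))
        res = screen_hubs(_table(values), trait, covs)
        for j, r in enumerate(res):
            scalar = partial_correlation(values[:, j], trait, covs)
            assert r.r == pytest.approx(scalar.r, abs=1e-12)
            assert r.p_raw == pytest.approx(scalar.p_raw, abs=1e-12)


class TestAncova:
    def test_recovers_known_adjusted_offset(self):
        """Noiseless group offset on a covariate trend is recovered exactly."""
        group = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        cov = np.arange(10.0)
        delta = 0.7
        values = (2.0 + 0.3 * cov + delta * group)[:, None] + np.zeros((10, 3))
        res = ancova_group_effect(_table(values), group, cov[:, None])
        for r in res:
            assert r.group_effect == pytest.approx(delta, abs=1e-10)

    def test_identical_groups_flat(self):
        rng = np.random.default_rng(13)
        base = np.abs(rng.standard_normal((30, 8)) + 4)
        values = np.vstack([base, base])  # two identical groups
        group = np.r_[np.zeros(30), np.ones(30)]
        res = ancova_group_effect(_table(values), group)
        for r in res:
            assert r.group_effect == pytest.approx(0.0, abs=1e-10)
            assert r.p_adjusted == pytest.approx(1.0)

    def test_f_is_t_squared(self):
        rng = np.random.default_rng(14)
        values = np.abs(rng.standard_normal((24, 4)) + 4)
        group = rng.integers(0, 2, 24)
        res = ancova_group_effect(_table(values), group)
        for r in res:
            assert r.f == pytest.approx(r.t**2)

    def test_no_covariates_matches_pooled_t(self):
        """With only the group indicator the ANCOVA t is the pooled t."""
        from hubnet import group_compare

        rng = np.random.default_rng(15)
        values = np.abs(rng.standard_normal((40, 1)) + 4)
        group = np.r_[np.zeros(22), np.ones(18)]
        res = ancova_group_effect(_table(values), group)[0]
        t, df, p = group_compare(
            (values[group == 1, 0], values[group == 0, 0]), "t_pooled"
        )
        assert res.t == pytest.approx(t)
        assert res.p_raw == pytest.approx(p)


class TestFisherZ:
    def test_equal_correlations(self):
        res = fisher_z_compare(0.4, 30, 0.4, 25, k=2)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_closed_form_hand_evaluation(self):
        """r=0.5 vs 0.3 at n=40 each with k=3 partialled covariates."""
        res = fisher_z_compare(0.5, 40, 0.3, 40, k=3)
        se = np.sqrt(1 / (40 - 3 - 3) + 1 / (40 - 3 - 3))
        expected = (np.arctanh(0.5) - np.arctanh(0.3)) / se
        assert res.z == pytest.approx(expected, abs=1e-12)
        from scipy import stats

        assert res.p == pytest.approx(2 * stats.norm.sf(abs(expected)), abs=1e-12)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 6, 0.3, 40, k=3)


def normal_equations_r2(x_blocks, y):
    """Brute-force R^2 by solving the normal equations directly."""
    x = np.column_stack([np.ones(len(y))] + x_blocks)
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestHierarchicalRegression:
    def _toy(self):
        import pandas as pd

        rng = np.random.default_rng(16)
        n = 8
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        c = rng.standard_normal(n)
        y = 1.0 + 0.8 * a - 0.5 * b + 0.3 * c + 0.1 * rng.standard_normal(n)
        return (
            y,
            [pd.DataFrame({"a": a}), pd.DataFrame({"b": b, "c": c})],
            [a, b, c],
        )

    def test_matches_normal_equations_oracle(self):
        y, blocks, (a, b, c) = self._toy()
        res = hierarchical_regression(y, blocks)
        r2_1 = normal_equations_r2([a], y)
        r2_2 = normal_equations_r2([a, b, c], y)
        assert res.steps[0].r2 == pytest.approx(r2_1, abs=1e-10)
        assert res.steps[1].r2 == pytest.approx(r2_2, abs=1e-10)
        assert res.steps[1].delta_r2 == pytest.approx(r2_2 - r2_1, abs=1e-10)

    def test_delta_r2_nonnegative_and_r2_nondecreasing(self):
        y, blocks, _ = self._toy()
        res = hierarchical_regression(y, blocks)
        r2s = [s.r2 for s in res.steps]
        assert np.all(np.diff(r2s) >= -1e-12)
        assert all(s.delta_r2 >= -1e-12 for s in res.steps)

    def test_orthogonal_predictor_vif_one(self):
        import pandas as pd

        n = 40
        rng = np.random.default_rng(17)
        x1 = rng.standard_normal(n)
        # orthogonalize x2 against x1 and the intercept
        x2 = rng.standard_normal(n)
        x2 -= x2.mean() + x1 * (x1 @ (x2 - x2.mean())) / (x1 @ x1)
        y = x1 + 0.01 * rng.standard_normal(n)
        res = hierarchical_regression(
            y, [pd.DataFrame({"x1": x1}), pd.DataFrame({"x2": x2})]
        )
        x2_est = [p for p in res.predictors if p.name == "x2"][0]
        assert x2_est.vif == pytest.approx(1.0, abs=1e-6)
        assert res.steps[1].delta_r2 == pytest.approx(0.0, abs=1e-3)

    def test_tolerance_is_reciprocal_vif(self):
        y, blocks, _ = self._toy()
        res = hierarchical_regression(y, blocks)
        for p in res.predictors:
            assert p.tolerance == pytest.approx(1 / p.vif, abs=1e-12)
            assert p.vif >= 1.0

    def test_standardized_beta_matches_zscored_fit(self):
        import pandas as pd

        y, blocks, (a, b, c) = self._toy()
        res = hierarchical_regression(y, blocks)
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        zres = hierarchical_regression(
            z(y), [pd.DataFrame({"a": z(a), "b": z(b), "c": z(c)})]
        )
        for p, zp in zip(res.predictors, zres.predictors):
            assert p.beta == pytest.approx(zp.b, abs=1e-10)

    def test_rank_deficiency_rejected(self):
        import pandas as pd

        rng = np.random.default_rng(18)
        a = rng.standard_normal(12)
        y = rng.standard_normal(12)
        with pytest.raises(ValueError):
            hierarchical_regression(
                y, [pd.DataFrame({"a": a}), pd.DataFrame({"a2": 2 * a})]
            )
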