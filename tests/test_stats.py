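"""Rank-sum tests, bootstrap KS, multiplicity control, correlation, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tcrrep.stats import (
    PCA_COLUMNS,
    adjust_pvalues,
    bootstrap_ks,
    correlate,
    exact_wilcoxon,
    group_mean_table,
    pca_summary,
)


def wilcoxon_enumeration_oracle(x, y):
    """Two-sided exact p by full enumeration over all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = sum(1 for xi in xs for yi in ys if xi > yi)
        us.append(u)
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestExactWilcoxon:
    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(21)
        for nx in range(1, 7):
            for ny in range(1, 7):
                if nx + ny > 10:
                    continue
                x = rng.normal(size=nx)
                y = rng.normal(size=ny)
                res = exact_wilcoxon(x, y)
                assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_identical_tied_samples_give_p_one(self):
        res = exact_wilcoxon([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == 1.0
        assert "asymptotic" in res.test

    def test_one_sided_direction(self):
        res = exact_wilcoxon([10, 11, 12], [1, 2, 3], sidedness="greater")
        assert res.p_value <= 0.05
        res2 = exact_wilcoxon([10, 11, 12], [1, 2, 3], sidedness="less")
        assert res2.p_value > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            exact_wilcoxon([], [1.0])


class TestBootstrapKs:
    def test_identical_multisets_d_zero_p_one(self):
        res = bootstrap_ks([1, 2, 3, 4], [1, 2, 3, 4], n_boot=199, seed=1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports_d_one(self):
        res = bootstrap_ks([1, 2, 3], [10, 11, 12], n_boot=199, seed=1)
        assert res.statistic == 1.0

    def test_bitwise_reproducible(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = bootstrap_ks(x, y, n_boot=499, seed=9)
        b = bootstrap_ks(x, y, n_boot=499, seed=9)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(5, 40)))
            y = rng.normal(size=int(rng.integers(5, 40)))
            two = bootstrap_ks(x, y, n_boot=199, seed=0).statistic
            one = bootstrap_ks(x, y, "greater", n_boot=199, seed=0).statistic
            assert two == pytest.approx(sps.ks_2samp(x, y).statistic, abs=1e-12)
            assert one == pytest.approx(
                sps.ks_2samp(x, y, alternative="greater").statistic, abs=1e-12
            )

    def test_minimum_boot_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ks([1.0], [2.0], n_boot=10, seed=0)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            assert adjust_pvalues([0.04], method) == [pytest.approx(0.04)]

    def test_bonferroni_multiplies_by_m(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx([0.03, 0.06, 0.09])

    def test_bh_step_up(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "benjamini_hochberg") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_bh_preserves_significance_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        adj = np.array(adjust_pvalues(list(p), "benjamini_hochberg"))
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")


class TestCorrelate:
    def test_monotone_is_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert correlate(x, [v**3 for v in x])[0] == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert correlate(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _metric_frame(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, 6)), columns=list(PCA_COLUMNS))


class TestPca:
    def test_variance_fractions_sum_to_one_nonincreasing(self):
        out = pca_summary(_metric_frame())
        assert out.variance_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(out.variance_fractions) <= 1e-12).all()

    def test_projection_invariant_to_row_order_up_to_sign(self):
        df = _metric_frame()
        a = pca_summary(df).projections.to_numpy()
        perm = np.random.default_rng(1).permutation(len(df))
        b = pca_summary(df.iloc[perm]).projections.to_numpy()
        assert np.allclose(np.abs(a[perm]), np.abs(b), atol=1e-9)

    def test_zero_variance_column_named(self):
        df = _metric_frame()
        df["gini_vj"] = 1.0
        with pytest.raises(ValueError, match="gini_vj"):
            pca_summary(df)

    def test_wrong_columns_rejected(self):
        df = _metric_frame().rename(columns={"gini_vj": "oops"})
        with pytest.raises(ValueError):
            pca_summary(df)

    def test_group_separation_positive_for_separated_presets(self, germline):
        from tcrrep.metrics import compute_sample_metrics
        from tcrrep.simulate import preset_config, simulate_repertoire

        rows, groups = [], []
        for grp, n in (("AT", 5), ("control", 7)):
            for i in range(n):
                s, _ = simulate_repertoire(
                    preset_config(grp, germline, seed=100 + i, n_clones=1200, n_reads=12000),
                    f"{grp}{i}", grp,
                )
                m = compute_sample_metrics(s, 6000, seed=1)
                rows.append({k: getattr(m, k) for k in PCA_COLUMNS})
                groups.append(grp)
        out = pca_summary(pd.DataFrame(rows), groups)
        assert out.silhouette is not None and out.silhouette > 0


class TestGroupMeans:
    def test_unknown_group_rejected(self, clinical):
        with pytest.raises(ValueError):
            group_mean_table(clinical, "X")

    def test_at_group_means(self, clinical):
        means = group_mean_table(clinical, "AT")
        assert means == {
            "lymphocytes": 1663, "t_cells": 1295, "cd4": 723, "cd8": 512, "b_cells": 135,
        }
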