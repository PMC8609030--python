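"""GC/MC/MDC/GDC statistics, permutation significance, DCG ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexdyn as cd
from coexdyn.connectivity import (
    connectivity_rank_correlation,
    gene_connectivity,
    gene_differential_connectivity,
    mdc,
    mdc_significance,
    mdc_timecourse,
    module_connectivity,
    rank_dhg,
)
from coexdyn.cohort import WindowAssignment
from conftest import exact_correlation_data, one_factor_groups


def _adj_frame(a, genes):
    return pd.DataFrame(a, index=genes, columns=genes)


def _random_expr(rng, g, n, prefix):
    return pd.DataFrame(
        rng.normal(size=(g, n)),
        index=[f"g{i}" for i in range(g)],
        columns=[f"{prefix}{j}" for j in range(n)],
    )


class TestGeneConnectivity:
    def test_two_gene_module(self):
        a = _adj_frame(np.array([[0.0, 0.2], [0.2, 0.0]]), ["x", "y"])
        gc = gene_connectivity(a)
        assert gc["x"] == gc["y"] == 0.2

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        expr = _random_expr(rng, 6, 12, "s")
        a = cd.adjacency(expr, power=8)
        frame = _adj_frame(a, list(expr.index))
        gc = gene_connectivity(frame, list(expr.index))
        for i, g in enumerate(expr.index):
            oracle = sum(a[i, j] for j in range(6) if j != i)
            assert abs(gc[g] - oracle) < 1e-12

    def test_uncorrelated_module_near_zero(self):
        rng = np.random.default_rng(2)
        expr = _random_expr(rng, 10, 200, "s")
        a = cd.adjacency(expr, power=8)
        gc = gene_connectivity(_adj_frame(a, list(expr.index)))
        assert gc.max() < 0.05


class TestModuleConnectivity:
    def test_two_gene_closed_form(self):
        t = _adj_frame(np.array([[1.0, 0.3], [0.3, 1.0]]), ["x", "y"])
        assert module_connectivity(t) == pytest.approx(0.3)

    def test_perfectly_correlated_module(self):
        n = 7
        t = _adj_frame(np.ones((n, n)), [f"g{i}" for i in range(n)])
        assert module_connectivity(t) == n * (n - 1) / 2

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        expr = _random_expr(rng, 5, 10, "s")
        t = cd.tom(cd.adjacency(expr, power=8))
        frame = _adj_frame(t, list(expr.index))
        oracle = sum(t[i, j] for i in range(4) for j in range(i + 1, 5))
        assert abs(module_connectivity(frame) - oracle) < 1e-12

    def test_singleton_module_rejected(self):
        t = _adj_frame(np.ones((1, 1)), ["x"])
        with pytest.raises(ValueError):
            module_connectivity(t)


class TestMDC:
    def test_identity_is_exactly_one(self):
        rng = np.random.default_rng(0)
        expr = _random_expr(rng, 10, 20, "s")
        res = mdc(expr, [expr])
        assert res.mdc == 1.0
        assert res.log_mdc == 0.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        expr = _random_expr(rng, 8, 15, "s")
        shuffled = expr[rng.permutation(expr.columns)]
        res = mdc(expr, [shuffled])
        assert res.mdc == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry_with_single_control_set(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = _random_expr(rng, 9, 14, "x")
            y = _random_expr(rng, 9, 14, "y")
            assert mdc(x, [y]).mdc * mdc(y, [x]).mdc == pytest.approx(1.0, abs=1e-12)

    def test_planted_gain_matches_independent_reimplementation(self):
        ec, et = one_factor_groups(5, 50, 100, r_case=0.6, r_ctrl=0.3)
        res = mdc(ec, [et])
        assert res.mdc > 1

        def mc_scratch(frame):
            r = np.corrcoef(frame.to_numpy())
            a = np.abs(r) ** 8
            np.fill_diagonal(a, 0.0)
            k = a.sum(1)
            g = a.shape[0]
            total = 0.0
            for i in range(g):
                for j in range(i + 1, g):
                    l = a[i] @ a[:, j] - a[i, i] * a[i, j] - a[i, j] * a[j, j]
                    total += (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            return total

        expected = mc_scratch(ec) / mc_scratch(et)
        assert res.mdc == pytest.approx(expected, abs=1e-10)

    def test_zero_control_connectivity_flagged(self):
        cases = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
                             index=["a", "b"], columns=["s1", "s2", "s3"])
        ctrl = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                            index=["a", "b"], columns=["t1", "t2", "t3"])
        res = mdc(cases, [ctrl])
        assert not res.defined

    def test_model_exact_data_reproduces_analytic_ratio(self):
        """Data realizing the one-factor population correlations exactly
        must reproduce MDC = (0.6/0.3)^8 = 256: for a uniform module the
        TOM entry collapses to the adjacency, so MC = C(g,2) * r^8."""
        g, n = 50, 100
        genes = [f"g{i}" for i in range(g)]
        corr_case = np.full((g, g), 0.6); np.fill_diagonal(corr_case, 1.0)
        corr_ctrl = np.full((g, g), 0.3); np.fill_diagonal(corr_ctrl, 1.0)
        xc = exact_correlation_data(corr_case, n, seed=1)
        xt = exact_correlation_data(corr_ctrl, n, seed=2)
        ec = pd.DataFrame(xc.T, index=genes, columns=[f"c{j}" for j in range(n)])
        et = pd.DataFrame(xt.T, index=genes, columns=[f"t{j}" for j in range(n)])
        res = mdc(ec, [et])
        assert res.mdc == pytest.approx((0.6 / 0.3) ** 8, rel=1e-8)


class TestMDCSignificance:
    def test_duplicated_groups_give_half_half(self):
        rng = np.random.default_rng(3)
        x = _random_expr(rng, 10, 30, "x")
        y = x.copy()
        y.columns = [f"y{j}" for j in range(30)]
        res = mdc_significance(x, [y], M=400, seed=5)
        assert res.observed.mdc == pytest.approx(1.0, abs=1e-12)
        se = np.sqrt(0.25 / 400)
        assert abs(res.p_gain - 0.5) < 3 * se
        assert abs(res.p_loss - 0.5) < 3 * se

    def test_p_tails_are_complementary(self):
        rng = np.random.default_rng(9)
        x = _random_expr(rng, 6, 12, "x")
        y = _random_expr(rng, 6, 12, "y")
        res = mdc_significance(x, [y], M=200, seed=0)
        assert 0 <= res.p_gain <= 1 and 0 <= res.p_loss <= 1
        assert res.p_gain + res.p_loss <= 1 + 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = _random_expr(rng, 6, 12, "x")
        y = _random_expr(rng, 6, 12, "y")
        r1 = mdc_significance(x, [y], M=150, seed=10)
        r2 = mdc_significance(x, [y], M=150, seed=10)
        assert (r1.p_gain, r1.p_loss) == (r2.p_gain, r2.p_loss)

    def test_small_m_warns(self, caplog):
        rng = np.random.default_rng(4)
        x = _random_expr(rng, 5, 10, "x")
        y = _random_expr(rng, 5, 10, "y")
        with caplog.at_level("WARNING"):
            mdc_significance(x, [y], M=50, seed=0)
        assert any("unstable" in r.message for r in caplog.records)

    def test_null_pvalues_approximately_uniform(self):
        """Kolmogorov-Smirnov distance of null permutation p-values from
        U(0,1) stays small under an exchangeable null."""
        ps = []
        for i in range(120):
            rng = np.random.default_rng(3000 + i)
            x = _random_expr(rng, 6, 12, "x")
            y = _random_expr(rng, 6, 12, "y")
            ps.append(mdc_significance(x, [y], M=200, seed=i).p_gain)
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.1


class TestMDCTimecourse:
    def _window(self, day, expr):
        cols = list(expr.columns)
        return WindowAssignment(
            window_day=day,
            case_samples=cols[:12],
            control_sets=[cols[12:24], cols[24:36]],
        )

    def test_single_window_q_equals_p(self):
        rng = np.random.default_rng(6)
        expr = _random_expr(rng, 8, 36, "s")
        tc = mdc_timecourse(expr, [self._window(100, expr)], list(expr.index),
                            M=100, seed=1)
        assert len(tc) == 1
        assert tc.loc[0, "q_gain"] == tc.loc[0, "p_gain"]
        assert tc.loc[0, "q_loss"] == tc.loc[0, "p_loss"]

    def test_underpowered_windows_skipped_not_zero(self):
        rng = np.random.default_rng(8)
        expr = _random_expr(rng, 8, 36, "s")
        small = WindowAssignment(window_day=50,
                                 case_samples=list(expr.columns[:5]),
                                 control_sets=[list(expr.columns[5:10])])
        tc = mdc_timecourse(expr, [small], list(expr.index), M=100, seed=1,
                            min_samples_per_group=10)
        assert tc.loc[0, "skipped"]
        assert np.isnan(tc.loc[0, "mdc"])


class TestGeneDifferentialConnectivity:
    def test_identical_groups(self):
        rng = np.random.default_rng(12)
        x = _random_expr(rng, 6, 15, "x")
        y = x.copy()
        y.columns = [f"y{j}" for j in range(15)]
        out = gene_differential_connectivity(x, [y], list(x.index), M=100, seed=0)
        assert np.allclose(out["gdc"], 1.0)
        assert np.allclose(out["delta_h"], 0.0)

    def test_observed_matches_loop_oracle(self):
        rng = np.random.default_rng(13)
        x = _random_expr(rng, 4, 10, "x")
        y = _random_expr(rng, 4, 10, "y")
        out = gene_differential_connectivity(x, [y], list(x.index), M=100, seed=0)
        ax = cd.adjacency(x, power=8)
        ay = cd.adjacency(y, power=8)
        for i, g in enumerate(x.index):
            gcx = sum(ax[i, j] for j in range(4) if j != i)
            gcy = sum(ay[i, j] for j in range(4) if j != i)
            row = out.set_index("gene").loc[g]
            assert abs(row["gc_cases"] - gcx) < 1e-12
            assert abs(row["gc_controls"] - gcy) < 1e-12
            assert row["gdc"] == pytest.approx(gcx / gcy, rel=1e-9)
            assert abs(row["delta_h"] - (gcx - gcy)) < 1e-12

    def test_gdc_and_delta_h_agree_in_sign(self):
        rng = np.random.default_rng(14)
        x = _random_expr(rng, 10, 25, "x")
        y = _random_expr(rng, 10, 25, "y")
        out = gene_differential_connectivity(x, [y], list(x.index), M=100, seed=0)
        pos = out["gc_controls"] > 0
        assert ((out.loc[pos, "gdc"] > 1) == (out.loc[pos, "delta_h"] > 0)).all()

    def test_planted_hubs_take_top_ranks(self):
        hits = 0
        for seed in range(10):
            lam = cd.loading_for_correlation(0.4)
            loadings = np.full(50, lam)
            loadings[:5] *= 2  # doubled case loadings for 5 hub genes
            ec, et = one_factor_groups(seed, 50, 150, r_case=0.4, r_ctrl=0.4,
                                       case_loadings=loadings)
            out = gene_differential_connectivity(ec, [et], list(ec.index),
                                                 M=100, seed=seed)
            top5 = set(out.nlargest(5, "delta_h")["gene"])
            hits += top5 == {f"g{i:03d}" for i in range(5)}
        assert hits >= 9


class TestRankDHG:
    @staticmethod
    def _frame(genes, dh):
        return pd.DataFrame({
            "gene": genes,
            "gc_cases": np.abs(dh) + 1,
            "gc_controls": np.ones(len(genes)),
            "gdc": np.abs(dh) + 1,
            "delta_h": dh,
            "p_gain": np.zeros(len(genes)),
            "p_loss": np.zeros(len(genes)),
        })

    def test_double_top_gene_wins_overall(self):
        genes = ["a", "b", "c"]
        f = self._frame(genes, np.array([5.0, 1.0, 0.5]))
        m = self._frame(genes, np.array([4.0, 0.2, 0.7]))
        out = rank_dhg(f, m)
        assert out.iloc[0]["gene"] == "a"
        assert out.iloc[0]["final_rank"] == 2

    def test_ties_resolved_deterministically(self):
        genes = ["a", "b"]
        f = self._frame(genes, np.array([2.0, 1.0]))
        m = self._frame(genes, np.array([1.0, 2.0]))
        o1 = rank_dhg(f, m)
        o2 = rank_dhg(f, m)
        assert o1["gene"].tolist() == o2["gene"].tolist()
        # equal rank sums: larger per-sex maximum first (tie here), then ID
        assert o1.iloc[0]["final_rank"] == o1.iloc[1]["final_rank"] == 3

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i:03d}" for i in range(100)]
        dh_f = rng.normal(size=100)
        dh_m = rng.normal(size=100)
        out = rank_dhg(self._frame(genes, dh_f), self._frame(genes, dh_m))
        rf = pd.Series(stats.rankdata(-dh_f, method="ordinal"), index=genes)
        rm = pd.Series(stats.rankdata(-dh_m, method="ordinal"), index=genes)
        oracle = (rf + rm).sort_values(kind="mergesort")
        assert out["final_rank"].tolist() == oracle.values.tolist()

    def test_universe_mismatch_is_an_error(self):
        f = self._frame(["a", "b"], np.array([1.0, 2.0]))
        m = self._frame(["a", "c"], np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="universes differ"):
            rank_dhg(f, m)


class TestRankCorrelation:
    def test_identical_and_reversed(self):
        gc = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rho, _ = connectivity_rank_correlation(gc, gc)
        assert rho == pytest.approx(1.0)
        rho, _ = connectivity_rank_correlation(gc, gc.iloc[::-1].set_axis(list("abcd")))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(16)
        idx = [f"g{i}" for i in range(10)]
        a = pd.Series(rng.normal(size=10), index=idx)
        b = pd.Series(rng.normal(size=10), index=idx)
        rho, _ = connectivity_rank_correlation(a, b)
        oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        assert abs(rho - oracle) < 1e-12

    def test_too_few_genes_error(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            connectivity_rank_correlation(a, a)
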