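"""Normalization and the negative-binomial differential-expression test."""

import numpy as np
import pandas as pd
import pytest

from divergene import expression, synthetic


def _random_counts(seed, n_genes=100, n_samples=4, mean=50.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.poisson(mean, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestUpperQuartile:
    def test_identical_samples_get_unit_factors(self):
        c = _random_counts(0, n_samples=1)
        mat = pd.concat([c["s0"], c["s0"]], axis=1, keys=["x", "y"])
        assert np.allclose(expression.upper_quartile_factors(mat), [1.0, 1.0])

    def test_proportional_columns(self):
        c = _random_counts(1, n_samples=1)
        mat = pd.concat([c["s0"], 3 * c["s0"]], axis=1, keys=["x", "y"])
        f = expression.upper_quartile_factors(mat)
        assert np.allclose(f, [1 / np.sqrt(3), np.sqrt(3)])

    def test_matches_naive_percentile_computation(self):
        mat = _random_counts(2)
        f = expression.upper_quartile_factors(mat)
        # independent naive quantile: sort nonzero values, interpolate
        naive = {}
        for s in mat.columns:
            v = np.sort(mat[s][mat[s] > 0].to_numpy(dtype=float))
            h = (len(v) - 1) * 0.75
            lo = int(np.floor(h))
            naive[s] = v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])
        naive = pd.Series(naive)
        naive /= np.exp(np.log(naive).mean())
        assert np.allclose(f, naive, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        mat = _random_counts(3)
        mat["s0"] = 0
        with pytest.raises(ValueError, match="s0"):
            expression.upper_quartile_factors(mat)

    @pytest.mark.parametrize("method", ["uq", "median_ratio"])
    def test_scale_equivariance(self, method):
        """Multiplying one sample's counts by c multiplies its factor,
        relative to the others, by c (both normalization methods)."""
        mat = _random_counts(4) + 1
        fn = (expression.upper_quartile_factors if method == "uq"
              else expression.size_factors_median_ratio)
        f0 = fn(mat)
        mat2 = mat.copy()
        mat2["s1"] = mat2["s1"] * 5
        f1 = fn(mat2)
        assert np.isclose((f1["s1"] / f1["s0"]) / (f0["s1"] / f0["s0"]), 5.0)


class TestGcCorrect:
    def test_flat_trend_is_near_identity(self):
        rng = np.random.default_rng(0)
        mat = _random_counts(5, n_genes=300, mean=200.0)
        gc = pd.Series(rng.uniform(0.3, 0.7, 300), index=mat.index)
        out = expression.gc_correct(mat, gc)
        rel = np.abs(out.to_numpy() - mat.to_numpy()) / np.maximum(mat.to_numpy(), 1)
        assert np.median(rel) < 0.05

    def test_removes_planted_monotone_bias(self):
        rng = np.random.default_rng(1)
        gc = pd.Series(rng.uniform(0.3, 0.7, 400))
        mu = 200.0 * 2 ** (4 * (gc - 0.5))
        mat = pd.DataFrame({"s0": rng.poisson(mu), "s1": rng.poisson(mu)})
        out = expression.gc_correct(mat, gc)
        slope = np.polyfit(gc, np.log2(out["s0"] + 0.5), 1)[0]
        raw_slope = np.polyfit(gc, np.log2(mat["s0"] + 0.5), 1)[0]
        assert abs(raw_slope) > 3  # sanity: bias was there
        assert abs(slope) < 0.3

    def test_column_totals_preserved(self):
        rng = np.random.default_rng(2)
        gc = pd.Series(rng.uniform(0.3, 0.7, 200))
        mat = pd.DataFrame({"s0": rng.poisson(200.0 * 2 ** (2 * (gc - 0.5)))})
        out = expression.gc_correct(mat, gc)
        assert np.isclose(out["s0"].sum(), mat["s0"].sum(), rtol=1e-9)

    def test_constant_gc_warns_and_returns_input(self):
        mat = _random_counts(6)
        gc = pd.Series(0.5, index=mat.index)
        with pytest.warns(UserWarning):
            out = expression.gc_correct(mat, gc)
        assert out.equals(mat)

    def test_single_gene_warns_identity(self):
        mat = _random_counts(7, n_genes=1)
        gc = pd.Series([0.4], index=mat.index)
        with pytest.warns(UserWarning):
            assert expression.gc_correct(mat, gc).equals(mat)


class TestSizeFactors:
    def test_doubled_sample(self):
        c = _random_counts(8, n_samples=1, mean=100.0) + 1
        mat = pd.concat([c["s0"], 2 * c["s0"]], axis=1, keys=["x", "y"])
        f = expression.size_factors_median_ratio(mat)
        assert np.isclose(f["y"] / f["x"], 2.0)

    def test_identical_samples_equal_factors(self):
        c = _random_counts(9, n_samples=1) + 1
        mat = pd.concat([c["s0"]] * 3, axis=1, keys=["x", "y", "z"])
        f = expression.size_factors_median_ratio(mat)
        assert np.allclose(f, f.iloc[0])

    def test_matches_brute_force(self):
        mat = _random_counts(10) + 1
        f = expression.size_factors_median_ratio(mat)
        geo = np.exp(np.log(mat.to_numpy(dtype=float)).mean(axis=1))
        brute = [np.median(mat[s].to_numpy() / geo) for s in mat.columns]
        assert np.allclose(f, brute, atol=1e-12)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert np.isclose(expression.bh_adjust([0.03])[0], 0.03)

    def test_step_up_hand_example(self):
        # hand-applied: p_(i) * 4/i, cummin from the top -> all 0.04
        assert np.allclose(expression.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(expression.bh_adjust([1.0, 1.0, 1.0]), 1.0)


class TestNbTest:
    def test_planted_fold_change_recovered(self):
        cfg = synthetic.SimConfig(
            n_genes=200, strains_per_population=(3, 3), nb_dispersion=0.01,
            regulon_definitions=[("r", ("g0000",))], planted_log2fc={"r": 3.0},
            seed=21,
        )
        cm = synthetic.simulate_counts(cfg)
        cols = list(cm.counts.columns)
        de = expression.nb_test(cm.counts, cols[:3], cols[3:])
        assert 2.5 <= de.loc["g0000", "log2FoldChange"] <= 3.5
        assert de.loc["g0000", "padj"] < 0.05

    def test_all_zero_gene_flagged(self):
        mat = _random_counts(11) + 1
        mat.loc["g0"] = 0
        de = expression.nb_test(mat, ["s0", "s1"], ["s2", "s3"])
        assert de.loc["g0", "pvalue"] == 1.0
        assert de.loc["g0", "log2FoldChange"] == 0.0
        assert de.loc["g0", "flag"] == "all_zero"

    def test_group_swap_negates_log2fc_and_keeps_p(self):
        mat = _random_counts(12)
        d1 = expression.nb_test(mat, ["s0", "s1"], ["s2", "s3"])
        d2 = expression.nb_test(mat, ["s2", "s3"], ["s0", "s1"])
        ok = d1["flag"] == ""
        assert np.allclose(d1.loc[ok, "log2FoldChange"], -d2.loc[ok, "log2FoldChange"])
        assert np.allclose(d1["pvalue"], d2["pvalue"], atol=1e-9)

    def test_single_sample_group_rejected(self):
        mat = _random_counts(13)
        with pytest.raises(ValueError):
            expression.nb_test(mat, [], ["s0", "s1"])

    def test_null_type_one_error_is_calibrated(self):
        fracs = []
        for seed in range(30):
            cfg = synthetic.SimConfig(
                n_genes=300, strains_per_population=(3, 3),
                planted_log2fc={}, regulon_definitions=[], seed=seed,
            )
            cm = synthetic.simulate_counts(cfg)
            cols = list(cm.counts.columns)
            de = expression.nb_test(cm.counts, cols[:3], cols[3:])
            fracs.append((de["pvalue"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07
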