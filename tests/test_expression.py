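"""Expressed-gene calling: the z-score rule, its degenerate cases and the
median-of-ratios bulk normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesiclink import io as vio
from vesiclink.errors import VesiclinkError
from vesiclink.expression import (call_expressed, call_expressed_bulk,
                                  contexts_from_matrix, mean_by_group,
                                  normalize_bulk, restrict_shared_genes,
                                  size_factors)


def oracle_call(values: dict, z_cutoff=-3.0) -> dict:
    """Independent loop implementation of the z rule (population SD)."""
    nz = {g: v for g, v in values.items() if v > 0}
    logs = {g: np.log2(v) for g, v in nz.items()}
    mu = sum(logs.values()) / len(logs)
    sd = (sum((x - mu) ** 2 for x in logs.values()) / len(logs)) ** 0.5
    out = {}
    for g, v in values.items():
        if v <= 0:
            out[g] = False
        elif sd == 0:
            out[g] = True
        else:
            out[g] = logs[g] >= mu + z_cutoff * sd
    return out


class TestMeanByGroup:
    def _matrix(self):
        values = pd.DataFrame(
            [[0, 2, 4, 7], [1, 1, 1, 9]], index=["g1", "g2"],
            columns=["c1", "c2", "c3", "c4"]).astype(float)
        labels = pd.DataFrame(
            {"cell_type": ["mono", "mono", "mono", "dc"],
             "condition": ["h", "h", "h", "h"]},
            index=pd.Index(values.columns, name="cell_id"))
        return vio.ExpressionMatrix(values, labels)

    def test_mean_includes_zeros(self):
        means = mean_by_group(self._matrix())
        assert means[("mono", "h")]["g1"] == pytest.approx(2.0)

    def test_single_cell_group_is_identity(self):
        means = mean_by_group(self._matrix())
        assert means[("dc", "h")]["g2"] == 9

    def test_cell_order_invariance(self):
        m = self._matrix()
        shuffled = vio.ExpressionMatrix(m.values[["c3", "c1", "c4", "c2"]],
                                        m.labels.loc[["c3", "c1", "c4", "c2"]])
        a, b = mean_by_group(m), mean_by_group(shuffled)
        for k in a:
            pd.testing.assert_series_equal(a[k], b[k])


class TestCallExpressed:
    def test_zero_sd_all_nonzero_expressed(self):
        ctx = call_expressed({"g1": 8.0, "g2": 8.0, "g3": 8.0})
        assert ctx.expressed.all()

    def test_zero_mean_gene_not_expressed_and_excluded_from_stats(self):
        ctx = call_expressed({"g1": 0.0, "g2": 4.0, "g3": 4.0})
        assert not ctx.expressed["g1"]
        assert ctx.expressed["g2"] and ctx.expressed["g3"]
        assert np.isnan(ctx.mean_log2["g1"])

    def test_seven_high_one_low_boundary_arithmetic(self):
        # log2 values {10.0 x7, 1.0}: mean 8.875, population sd 2.97647,
        # boundary -0.0544 -> every gene expressed (frozen from the oracle)
        values = {f"g{i}": 2.0 ** 10 for i in range(7)}
        values["low"] = 2.0
        ctx = call_expressed(values)
        assert ctx.expressed.all()
        nz = ctx.mean_log2.dropna()
        assert nz.mean() == pytest.approx(8.875)
        assert nz.std(ddof=0) == pytest.approx(2.97647, abs=1e-4)

    def test_single_outlier_cannot_exceed_sqrt_n_minus_one_sds(self):
        # with population SD, one outlier among n genes sits at most
        # sqrt(n-1) SDs from the mean; sqrt(7) < 3, so even a 2^-10 gene
        # stays "expressed" among seven high genes
        values = {f"g{i}": 2.0 ** 10 for i in range(7)}
        values["low"] = 2.0 ** -10
        ctx = call_expressed(values)
        assert ctx.expressed.all()
        assert ctx.z["low"] == pytest.approx(-np.sqrt(7), abs=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(VesiclinkError, match="no expressed genes"):
            call_expressed({"g1": 0.0, "g2": 0.0})

    def test_boundary_equality_counts_as_expressed(self):
        # engineer a gene sitting exactly at mean - 3 sd via root finding,
        # then check the >= boundary policy
        from scipy.optimize import brentq
        base = {f"g{i}": float(v) for i, v in
                enumerate([512, 600, 700, 800, 512, 600, 700, 800, 650, 700,
                           640, 660])}

        def gap(log2v):
            vals = dict(base, boundary=2.0 ** log2v)
            logs = np.log2(np.array(list(vals.values())))
            return log2v - (logs.mean() - 3 * logs.std(ddof=0))

        root = brentq(gap, -40.0, 9.0, xtol=1e-14)
        ctx = call_expressed(dict(base, boundary=2.0 ** root))
        assert ctx.z["boundary"] == pytest.approx(-3.0, abs=1e-6)
        assert ctx.expressed["boundary"]
        ctx_below = call_expressed(dict(base, boundary=2.0 ** (root - 0.01)))
        assert not ctx_below.expressed["boundary"]

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(5, 60))
            vals = np.round(rng.gamma(0.5, 200, size=n), 3)
            vals[rng.random(n) < 0.2] = 0.0
            if (vals > 0).sum() < 2:
                continue
            values = {f"g{i}": float(v) for i, v in enumerate(vals)}
            ctx = call_expressed(values)
            assert ctx.expressed.to_dict() == oracle_call(values)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e5), min_size=3,
                    max_size=30),
           st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, vals, c):
        values = {f"g{i}": v for i, v in enumerate(vals)}
        scaled = {g: v * c for g, v in values.items()}
        a = call_expressed(values).expressed
        b = call_expressed(scaled).expressed
        assert a.equals(b)

    def test_monotonicity_raising_one_gene_never_unexpresses_it(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            vals = rng.gamma(1.0, 100, size=12)
            values = {f"g{i}": float(v) for i, v in enumerate(vals)}
            target = "g0"
            before = call_expressed(values).expressed[target]
            values[target] *= 10
            after = call_expressed(values).expressed[target]
            assert after or not before


class TestBulk:
    def test_identical_samples_have_unit_size_factors(self):
        counts = pd.DataFrame({"s1": [10, 100, 4], "s2": [10, 100, 4]})
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)
        assert np.allclose(normalize_bulk(counts), counts)

    def test_scale_equivariance(self):
        a = pd.DataFrame({"s1": [10, 100, 4]})
        counts = pd.concat([a["s1"], 2 * a["s1"]], axis=1)
        counts.columns = ["s1", "s2"]
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        normed = normalize_bulk(counts)
        assert np.allclose(normed["s1"], normed["s2"])

    def test_hand_computed_example(self):
        counts = pd.DataFrame([[10, 20], [100, 200], [4, 8]],
                              columns=["a", "b"])
        sf = size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_matches_pydeseq2_size_factors(self):
        from pydeseq2.preprocessing import deseq2_norm
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 5)) + 1,
                              columns=[f"s{i}" for i in range(5)])
        _, sf_ref = deseq2_norm(counts.T)  # pydeseq2 wants samples x genes
        sf = size_factors(counts)
        assert np.allclose(sf.to_numpy(), np.asarray(sf_ref).ravel())

    def test_no_common_nonzero_gene_raises(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(VesiclinkError, match="pseudo-reference"):
            size_factors(counts)

    def test_gene_intersection_across_datasets(self):
        d1 = pd.DataFrame({"s1": [1, 2, 3]}, index=["a", "b", "c"])
        d2 = pd.DataFrame({"t1": [4, 5, 6]}, index=["b", "c", "d"])
        r1, r2 = restrict_shared_genes(d1, d2)
        assert list(r1.index) == list(r2.index) == ["b", "c"]

    def test_constant_gene_expressed_in_all_groups(self):
        rng = np.random.default_rng(0)
        normalized = pd.DataFrame(
            rng.uniform(50, 500, size=(30, 4)),
            columns=["h1", "h2", "d1", "d2"],
            index=[f"g{i}" for i in range(30)])
        normalized.loc["const"] = 100.0
        groups = {"h1": ("thp1", "healthy"), "h2": ("thp1", "healthy"),
                  "d1": ("thp1", "uc"), "d2": ("thp1", "uc")}
        ctxs = call_expressed_bulk(normalized, groups)
        assert set(ctxs) == {("thp1", "healthy"), ("thp1", "uc")}
        assert all(c.expressed["const"] for c in ctxs.values())


class TestPlantedRecovery:
    def test_generated_groups_recover_planted_partition(self, fixture_dir):
        fx = fixture_dir
        matrix = vio.read_expression(
            fx.root / "expression.mtx", fx.root / "expression.labels.tsv",
            genes_path=fx.root / "expression.genes.tsv",
            cells_path=fx.root / "expression.cells.tsv")
        ctxs = contexts_from_matrix(matrix)
        for group, ctx in ctxs.items():
            assert ctx.expressed_genes == fx.expr.truth_expressed[group]
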