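import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lysiphen.deg import ExpressionMatrix, bh_adjust, differential_call, expression_filter
from lysiphen.errors import DesignError, DomainError
from lysiphen.simulate import simulate_fpkm


def _matrix(rows: dict) -> ExpressionMatrix:
    cols = ["c1_r1", "c1_r2", "c1_r3", "c2_r1", "c2_r2", "c2_r3"]
    fpkm = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    cond = {c: ("c1" if c.startswith("c1") else "c2") for c in cols}
    return ExpressionMatrix(fpkm=fpkm, conditions=cond)


class TestBhAdjust:
    def test_stepup_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(p) / len(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_domain_enforced(self):
        with pytest.raises(DomainError):
            bh_adjust([0.1, 1.2])


class TestExpressionFilter:
    def test_worked_example_kept(self):
        # 3 samples >= 1; expressed condition CV = 0.1/1.2 ≈ 0.083 < 0.2
        em = _matrix({"g": [1.2, 1.3, 1.1, 0.4, 0.5, 0.45]})
        assert "g" in expression_filter(em)

    def test_all_zero_gene_dropped(self):
        em = _matrix({"g": [0, 0, 0, 0, 0, 0]})
        assert len(expression_filter(em)) == 0

    def test_constant_expressed_gene_kept(self):
        em = _matrix({"g": [5.0] * 6})
        assert "g" in expression_filter(em)

    def test_noisy_replicates_rejected_by_cv(self):
        em = _matrix({"g": [1.0, 3.0, 8.0, 2.0, 2.1, 1.9]})  # condition-1 CV >> 0.2
        assert len(expression_filter(em)) == 0

    def test_floor_requires_three_of_six(self):
        em = _matrix({"g": [1.5, 0.2, 0.3, 0.4, 0.5, 0.6]})
        assert len(expression_filter(em)) == 0

    def test_column_order_invariance_within_conditions(self):
        rows = {"g1": [1.2, 1.3, 1.1, 0.4, 0.5, 0.45], "g2": [2, 8, 5, 1, 1.1, 0.9]}
        em = _matrix(rows)
        shuffled = _matrix({k: [v[2], v[0], v[1], v[5], v[4], v[3]] for k, v in rows.items()})
        assert list(expression_filter(em)) == list(expression_filter(shuffled))

    def test_cv_scope_all_flag(self):
        # tight within conditions but wide across them: 'within' keeps, 'all' drops
        em = _matrix({"g": [10.0, 10.1, 9.9, 2.0, 2.05, 1.95]})
        assert "g" in expression_filter(em, cv_scope="within")
        assert len(expression_filter(em, cv_scope="all")) == 0

    def test_wrong_design_rejected(self):
        cols = ["a", "b", "c", "d"]
        fpkm = pd.DataFrame([[1.0, 1, 1, 1]], index=["g"], columns=cols)
        with pytest.raises(DesignError):
            ExpressionMatrix(fpkm=fpkm, conditions={c: "x" for c in cols})


class TestDifferentialCall:
    def test_null_gene_not_called(self):
        em = _matrix({"g": [5.0, 5.2, 4.8, 5.1, 4.9, 5.0]})
        rec = differential_call(em).loc["g"]
        assert abs(rec["log2fc"]) < 0.1
        assert not rec["is_deg"]

    def test_fourfold_gene_called(self):
        em = _matrix({
            "g_de": [8.0, 8.1, 7.9, 2.0, 2.05, 1.95],
            **{f"null{i}": [3.0 + 0.01 * i, 3.05, 2.95, 3.0, 3.02, 2.98] for i in range(10)},
        })
        rec = differential_call(em).loc["g_de"]
        assert rec["log2fc"] == pytest.approx(np.log2(8.05 / 2.1), abs=0.05)
        assert rec["is_deg"] and rec["direction"] == "up"

    def test_zero_variance_equal_means_p_one(self):
        em = _matrix({"g": [2.0] * 6})
        assert differential_call(em).loc["g", "p"] == 1.0

    def test_q_never_below_p(self):
        em, _ = simulate_fpkm(n_genes=300, de_fraction=0.1, seed=3)
        calls = differential_call(em)
        ok = calls["passed_expression_filter"]
        assert np.all(calls.loc[ok, "q"] + 1e-12 >= calls.loc[ok, "p"])


class TestSimulateFpkm:
    def test_pure_null_truth_labels(self):
        _, truth = simulate_fpkm(n_genes=100, de_fraction=0.0, seed=1)
        assert not truth["is_de"].any()

    def test_seeded_determinism(self):
        m1, t1 = simulate_fpkm(n_genes=50, seed=9)
        m2, t2 = simulate_fpkm(n_genes=50, seed=9)
        pd.testing.assert_frame_equal(m1.fpkm, m2.fpkm)
        pd.testing.assert_frame_equal(t1, t2)

    def test_called_set_close_to_truth_at_fourfold(self):
        em, truth = simulate_fpkm(n_genes=2000, de_fraction=0.10, fold=4.0, seed=7)
        calls = differential_call(em)
        called = set(calls.index[calls["is_deg"]])
        true = set(truth.index[truth["is_de"]])
        jaccard = len(called & true) / len(called | true)
        assert jaccard >= 0.8

    def test_fdr_and_sensitivity_at_stated_noise(self):
        em, truth = simulate_fpkm(n_genes=2000, de_fraction=0.10, fold=4.0, seed=11)
        calls = differential_call(em)
        called = calls["is_deg"]
        is_de = truth["is_de"]
        fdr = float((called & ~is_de).sum()) / max(int(called.sum()), 1)
        sens = float((called & is_de).sum()) / int(is_de.sum())
        assert fdr <= 0.10
        assert sens >= 0.8
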