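"""Median-of-ratios normalization, geometric-mean scoring, group effects and
hypergeometric enrichment (with exhaustive-enumeration oracle)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from icbtox import (
    SimConfig,
    gen_cohort,
    gen_expression,
    group_effect,
    hypergeometric_enrichment,
    normalize,
    signature_score,
    size_factors,
)
from icbtox.expression import NormalizationError


def matrix(data, genes=None, samples=None):
    data = np.asarray(data)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        m = matrix([[10, 10], [3, 3], [7, 7]])
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_proportional_columns_closed_form(self):
        # column B = 2 x column A -> factors (1/sqrt(2), sqrt(2))
        m = matrix([[10, 20], [3, 6], [7, 14], [100, 200]])
        sf = size_factors(m)
        assert sf["s0"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert sf["s1"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_general_proportional_closed_form(self):
        # c_j / geometric-mean(c) for arbitrary positive scalings
        scal = np.array([0.5, 1.0, 2.5, 4.0])
        base = np.array([11, 3, 40, 7, 90], dtype=float)
        m = matrix(np.outer(base, scal))
        expected = scal / np.exp(np.mean(np.log(scal)))
        assert np.allclose(size_factors(m), expected, atol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.integers(1, 100, size=(30, 4)))
        perm = m.sample(frac=1, random_state=0)
        assert np.allclose(size_factors(m), size_factors(perm))

    def test_zero_genes_excluded_and_error_when_none_left(self):
        m = matrix([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError):
            size_factors(m)

    def test_matches_independent_median_of_ratios_oracle(self):
        # independent route through pydeseq2's size-factor fitting
        try:
            from pydeseq2.dds import DeseqDataSet
        except Exception:
            pytest.skip("pydeseq2 unavailable")
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.1, size=(60, 8)) + 1
        m = matrix(counts)
        meta = pd.DataFrame({"condition": ["a"] * 4 + ["b"] * 4}, index=m.columns)
        dds = DeseqDataSet(counts=m.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        assert np.allclose(size_factors(m), dds.obs["size_factors"], rtol=1e-8)


class TestNormalize:
    def test_unit_factors_identity(self):
        m = matrix([[4, 9], [1, 2]])
        pd.testing.assert_frame_equal(normalize(m, pd.Series([1.0, 1.0], index=m.columns)),
                                      m.astype(float))

    def test_proportional_columns_equalized(self):
        m = matrix([[10, 20], [3, 6], [7, 14]])
        norm = normalize(m, size_factors(m))
        assert np.allclose(norm["s0"], norm["s1"])

    def test_renormalizing_removes_between_sample_scaling(self):
        # re-estimated factors of a normalized matrix are a single constant
        # (the geometric mean of the original factors): idempotent up to scale
        rng = np.random.default_rng(2)
        m = matrix(rng.integers(1, 200, size=(40, 5)))
        sf = size_factors(m)
        again = size_factors(normalize(m, sf))
        assert np.ptp(again.to_numpy()) < 1e-12
        assert again.iloc[0] == pytest.approx(np.exp(np.mean(np.log(sf))), rel=1e-12)

    def test_nonpositive_factor_rejected(self):
        m = matrix([[1, 1]])
        with pytest.raises(NormalizationError):
            normalize(m, pd.Series([1.0, 0.0], index=m.columns))


class TestSignatureScore:
    def test_geometric_mean_toy(self):
        m = matrix([[1], [4], [16]], genes=["a", "b", "c"])
        assert signature_score(m, ["a", "b", "c"], pseudocount=0)["s0"] == pytest.approx(4.0)

    def test_constant_genes_give_constant(self):
        m = matrix(np.full((5, 3), 7.0))
        assert np.allclose(signature_score(m, list(m.index), pseudocount=0), 7.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(4)
        m = matrix(rng.uniform(1, 50, size=(10, 4)))
        s1 = signature_score(m, list(m.index), pseudocount=0)
        s2 = signature_score(m * 3.5, list(m.index), pseudocount=0)
        assert np.allclose(s2, 3.5 * s1)

    def test_monotone_in_member_gene(self):
        m = matrix([[2.0, 2.0], [8.0, 8.0]], genes=["a", "b"])
        lo = signature_score(m, ["a", "b"], pseudocount=0)
        m.loc["a", "s1"] = 5.0
        hi = signature_score(m, ["a", "b"], pseudocount=0)
        assert hi["s1"] > lo["s1"] and hi["s0"] == lo["s0"]

    def test_missing_genes_listed(self):
        m = matrix([[1.0]], genes=["a"])
        with pytest.raises(ValueError, match="missing"):
            signature_score(m, ["a", "x", "y", "z"])

    def test_zero_with_zero_pseudocount_rejected(self):
        m = matrix([[0.0]], genes=["a"])
        with pytest.raises(NormalizationError):
            signature_score(m, ["a"], pseudocount=0)


class TestGroupEffect:
    def test_identical_groups_zero_effect(self):
        m = matrix(np.tile([[8.0], [2.0]], (1, 6)), genes=["IL7", "x"])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=m.columns)
        assert group_effect(m, "IL7", groups).effect == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_shift_recovered_exactly(self):
        vals = np.array([[4.0] * 3 + [4.0 * 2**0.57] * 3])
        m = matrix(vals, genes=["IL7"])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=m.columns)
        eff = group_effect(m, "IL7", groups, pseudocount=0)
        assert eff.effect == pytest.approx(0.57, abs=1e-12)

    def test_simulation_recovery_of_eqtl_shift(self):
        # mean recovered carrier shift across seeds, oracle = group means
        effects = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, n_patients=300, carrier_log2_shift=0.57)
            cohort = gen_cohort(cfg)
            counts = gen_expression(cfg, cohort, n_genes=30)
            groups = pd.Series(
                np.where(cohort["carrier"], "carrier", "noncarrier").tolist(),
                index=cohort["patient_id"],
            )
            effects.append(
                group_effect(counts.astype(float), "IL7", groups, reference="noncarrier").effect
            )
        assert np.mean(effects) == pytest.approx(0.57, abs=0.05)

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(8)
        n = 200
        group = np.repeat([0, 1], n // 2)
        batch = rng.normal(size=n) + 0.8 * group  # confounded covariate
        y = 2.0 ** (5 + 1.0 * batch + 0.0 * group + rng.normal(0, 0.01, n))
        m = matrix(y[None, :], genes=["IL7"])
        groups = pd.Series(np.where(group == 1, "b", "a"), index=m.columns)
        raw = group_effect(m, "IL7", groups, pseudocount=0)
        adj = group_effect(m, "IL7", groups,
                           covariates=pd.DataFrame({"batch": batch}, index=m.columns),
                           pseudocount=0)
        assert abs(adj.effect) < abs(raw.effect)

    def test_degenerate_group_sizes_rejected(self):
        m = matrix([[1.0, 2.0, 3.0]], genes=["IL7"])
        groups = pd.Series(["a", "b", "b"], index=m.columns)
        with pytest.raises(ValueError):
            group_effect(m, "IL7", groups)


def enrichment_p_enumeration(universe, n_hits, n_ann, overlap):
    """Exhaustive oracle: sum C(n_ann, k) C(universe-n_ann, n_hits-k) / C(universe, n_hits)."""
    total = special.comb(universe, n_hits, exact=True)
    acc = 0
    for k in range(overlap, min(n_hits, n_ann) + 1):
        acc += special.comb(n_ann, k, exact=True) * special.comb(
            universe - n_ann, n_hits - k, exact=True
        )
    return acc / total


class TestEnrichment:
    def test_full_overlap_with_universe(self):
        genes = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(genes, genes, 20)
        assert res.p_value == pytest.approx(1.0) and res.fold_change == pytest.approx(1.0)

    def test_zero_overlap_p_is_one(self):
        res = hypergeometric_enrichment(["a", "b"], ["c", "d"], 10)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example_against_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:5]
        ann = universe[1:9]  # overlap = 4
        res = hypergeometric_enrichment(hits, ann, 20)
        assert res.overlap == 4
        assert res.p_value == pytest.approx(enrichment_p_enumeration(20, 5, 8, 4), rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_enumeration_on_random_instances(self, data):
        universe = data.draw(st.integers(min_value=2, max_value=25))
        n_hits = data.draw(st.integers(min_value=1, max_value=universe))
        n_ann = data.draw(st.integers(min_value=1, max_value=universe))
        genes = [f"g{i}" for i in range(universe)]
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        hits = list(rng.choice(genes, size=n_hits, replace=False))
        ann = list(rng.choice(genes, size=n_ann, replace=False))
        res = hypergeometric_enrichment(hits, ann, universe)
        expected = enrichment_p_enumeration(universe, n_hits, n_ann, res.overlap)
        assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["a", "b", "c"], ["a"], 2)
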