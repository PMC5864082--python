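from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from barfit.errors import ParameterError, ValidationError
from barfit.fitness import (
    bh_fdr,
    classify,
    estimate_dispersion,
    intersect_calls,
    run_contrast,
    size_factors,
)
from barfit.fitness import test_contrast as wald_contrast  # avoid pytest collection
from barfit.sim import SimConfig, simulate_count_matrix


def nb_counts(rng, mu, alpha, size):
    """NB draws parameterized by mean and dispersion Var = mu + alpha mu^2."""
    if alpha == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


class TestSizeFactors:
    def test_worked_example(self):
        counts = pd.DataFrame([[100, 200], [50, 100], [10, 20]], columns=["a", "b"])
        sf = size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [0.7071, 1.4142], atol=1e-4)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14]})
        np.testing.assert_allclose(size_factors(counts).to_numpy(), [1.0, 1.0])

    def test_doubling_one_column_doubles_its_factor_ratio(self, rng):
        # scale equivariance holds on factor ratios (the geometric means,
        # and with them the common normalization, shift when one column is
        # rescaled)
        counts = pd.DataFrame(rng.poisson(100, size=(50, 3)) + 1, columns=list("abc"))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 2
        sf2 = size_factors(scaled)
        assert sf2["b"] / sf2["a"] == pytest.approx(2 * sf["b"] / sf["a"])
        assert sf2["c"] / sf2["a"] == pytest.approx(sf["c"] / sf["a"])

    def test_matches_pydeseq2(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = pd.DataFrame(rng.poisson(200, size=(80, 4)) + 1, columns=list("abcd"))
        sf = size_factors(counts)
        _, sf_ref = pydeseq2.deseq2_norm(counts.T)  # samples × genes layout
        np.testing.assert_allclose(sf.to_numpy(), np.asarray(sf_ref), rtol=1e-10)

    def test_all_sparse_matrix_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValidationError, match="pseudocount"):
            size_factors(counts)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        counts = pd.DataFrame(rng.poisson(500, size=(1000, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        sf = size_factors(counts)
        est = estimate_dispersion(counts, sf, [["a1", "a2"], ["b1", "b2"]])
        assert est.alpha.mean() <= 0.05

    def test_zero_variance_falls_back_to_trend(self):
        counts = pd.DataFrame({"a1": [100, 200], "a2": [100, 200],
                               "b1": [100, 200], "b2": [100, 200]})
        est = estimate_dispersion(counts, size_factors(counts),
                                  [["a1", "a2"], ["b1", "b2"]])
        assert (est.raw == 0).all()
        np.testing.assert_allclose(
            est.alpha.to_numpy(), est.trend(est.base_mean.to_numpy()))

    def test_nb_dispersion_recovered(self, rng):
        mu, alpha = 500, 0.1
        counts = pd.DataFrame(nb_counts(rng, mu, alpha, (1000, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        est = estimate_dispersion(counts, size_factors(counts),
                                  [["a1", "a2"], ["b1", "b2"]])
        assert 0.05 < est.alpha.median() < 0.2

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2]})
        with pytest.raises(ParameterError, match="replicate"):
            estimate_dispersion(counts, pd.Series([1.0, 1.0], index=["a1", "b1"]),
                                [["a1"], ["b1"]])


class TestContrast:
    @pytest.fixture()
    def counts4(self, rng):
        return pd.DataFrame(nb_counts(rng, 800, 0.01, (300, 4)),
                            columns=["a1", "a2", "b1", "b2"],
                            index=[f"S{i:04d}" for i in range(300)])

    def test_identical_groups_are_null(self):
        counts = pd.DataFrame({"a1": [100, 50], "a2": [120, 60],
                               "b1": [100, 50], "b2": [120, 60]},
                              index=["S1", "S2"])
        sf = size_factors(counts)
        est = estimate_dispersion(counts, sf, [["a1", "a2"], ["b1", "b2"]])
        res = wald_contrast(counts, sf, est, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["p"] > 0.99).all()
        assert (classify(res)["call"] == "NS").all()

    def test_antisymmetry(self, counts4):
        sf = size_factors(counts4)
        est = estimate_dispersion(counts4, sf, [["a1", "a2"], ["b1", "b2"]])
        fwd = wald_contrast(counts4, sf, est, ["a1", "a2"], ["b1", "b2"])
        rev = wald_contrast(counts4, sf, est, ["b1", "b2"], ["a1", "a2"])
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-10)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_scale_invariance(self, counts4):
        base = run_contrast(counts4, ["a1", "a2"], ["b1", "b2"])
        scaled = counts4.copy()
        scaled["b1"] = scaled["b1"] * 7
        alt = run_contrast(scaled, ["a1", "a2"], ["b1", "b2"])
        # size factors absorb the rescaling up to the fixed pseudocount and
        # the Poisson part of the mean-variance relation (pre-scaled counts
        # of c*K have variance c^2*mu, not c*mu), so invariance is exact
        # only in the dispersion-dominated limit
        np.testing.assert_allclose(base["log2fc"], alt["log2fc"], atol=1e-3)
        np.testing.assert_allclose(base["p"], alt["p"], atol=0.02)

    def test_all_zero_strain_reported_ns(self, counts4):
        counts = counts4.copy()
        counts.iloc[0] = 0
        res = run_contrast(counts, ["a1", "a2"], ["b1", "b2"])
        assert res.iloc[0]["log2fc"] == 0.0
        assert res.iloc[0]["p"] == 1.0
        assert res.iloc[0]["call"] == "NS"

    def test_padj_dominates_p(self, counts4):
        res = run_contrast(counts4, ["a1", "a2"], ["b1", "b2"])
        assert (res["padj"] >= res["p"] - 1e-12).all()
        assert res["padj"].between(0, 1).all()

    def test_planted_effect_recovered(self):
        cfg = SimConfig(n_strains=400, depth=400_000, seed=21,
                        fraction_null=0.9, fraction_hi=0.05, fraction_hp=0.05)
        counts, truth = simulate_count_matrix(cfg, "Clim30", stages=("P", "B"))
        res = run_contrast(counts, ["Clim30_P_r1", "Clim30_P_r2"],
                           ["Clim30_B_r1", "Clim30_B_r2"])
        m = res.join(truth.set_index("strain_id"))
        affected = m[m["label"] != "null"]
        signed = (np.sign(affected["s"]) * affected["log2fc"]).mean()
        assert signed == pytest.approx(6 * 0.2, abs=0.3)


class TestClassify:
    @pytest.mark.parametrize("log2fc,p,expected", [
        (+1.0, 0.001, "HP"),
        (+0.5, 0.001, "NS"),  # below log2(1.5) ≈ 0.585
        (-2.0, 0.20, "NS"),  # fold passes, p fails
        (-0.6, 0.01, "HI"),
        (+0.59, 0.049, "HP"),
    ])
    def test_rule(self, log2fc, p, expected):
        res = pd.DataFrame({"baseMean": [1.0], "log2fc": [log2fc], "se": [0.1],
                            "p": [p], "padj": [p], "call": ["NS"]})
        assert classify(res)["call"].iloc[0] == expected

    def test_fold_below_one_rejected(self):
        res = pd.DataFrame({"log2fc": [0.0], "p": [1.0]})
        with pytest.raises(ParameterError, match="fold"):
            classify(res, fold=0.9)


class TestIntersectCalls:
    def test_disjoint_sets(self):
        tab = intersect_calls({"A": {"s1", "s2", "s3"}, "B": {"s4", "s5", "s6", "s7"}})
        got = dict(zip(tab["conditions"], tab["count"]))
        assert got == {"A": 3, "B": 4, "A+B": 0}

    def test_identical_sets(self):
        s = {"x", "y", "z", "w", "v"}
        tab = intersect_calls({"A": set(s), "B": set(s)})
        got = dict(zip(tab["conditions"], tab["count"]))
        assert got == {"A": 0, "B": 0, "A+B": 5}

    def test_matches_power_set_enumeration(self, rng):
        conds = list("ABCD")
        universe = [f"s{i}" for i in range(40)]
        sets = {c: {s for s in universe if rng.random() < 0.3} for c in conds}
        tab = intersect_calls(sets)
        got = dict(zip(tab["conditions"], tab["count"]))
        # brute-force oracle over the power set
        for size in range(1, 5):
            for subset in combinations(conds, size):
                expected = sum(
                    1 for s in universe
                    if {c for c in conds if s in sets[c]} == set(subset))
                assert got["+".join(subset)] == expected


class TestBhFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == 0.3

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(200)
        np.testing.assert_allclose(bh_fdr(p), sm.multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2])


class TestBhFdrProperties:
    """Contract properties of the step-up adjustment."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_output_in_unit_interval_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_monotone_on_sorted_inputs(self, pvals):
        p = np.sort(np.asarray(pvals))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
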