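import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coresort.differential import (
    DifferentialEnrichment,
    bh_fdr,
    two_sample_ttest,
    volcano_table,
)
from coresort.preprocess import impute_missing, log2_transform
from coresort.simulate import SimulationConfig, simulate_experiment

from conftest import make_design, make_table


def brute_force_bh(pvalues):
    """Direct step-up definition: q_i = min_{p_j >= p_i} m*p_j/rank_j, capped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_ttest_identical_vectors():
    res = two_sample_ttest([1, 2, 3], [1, 2, 3])
    assert res.tstat == 0.0 and res.pvalue == 1.0


def test_ttest_hand_computed_pooled_variance():
    # means 12 and 16, each sample variance 2.5 -> pooled SE = 1, t = 4, df = 8
    a = [10, 11, 12, 13, 14]
    b = [14, 15, 16, 17, 18]
    res = two_sample_ttest(a, b)
    assert res.tstat == pytest.approx(4.0)
    assert res.df == 8
    assert res.pvalue == pytest.approx(2 * stats.t.sf(4.0, 8), rel=1e-12)
    assert res.pvalue == pytest.approx(0.0039, abs=2e-4)


@pytest.mark.parametrize("flavor", ["student", "welch"])
def test_ttest_matches_scipy(rng, flavor):
    for _ in range(25):
        a = rng.normal(0, 1 + rng.random(), size=rng.integers(2, 9))
        b = rng.normal(rng.normal(), 1 + rng.random(), size=rng.integers(2, 9))
        ours = two_sample_ttest(a, b, flavor=flavor)
        ref = stats.ttest_ind(b, a, equal_var=(flavor == "student"))
        assert ours.tstat == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-10)


@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    st.lists(st.floats(-50, 50), min_size=2, max_size=8),
)
@settings(max_examples=50, deadline=None)
def test_ttest_swap_negates_t_keeps_p(a, b):
    fwd = two_sample_ttest(a, b)
    rev = two_sample_ttest(b, a)
    assert fwd.tstat == pytest.approx(-rev.tstat, rel=1e-9, abs=1e-12)
    assert fwd.pvalue == pytest.approx(rev.pvalue, rel=1e-9, abs=1e-12)


def test_ttest_degenerate_constant_vectors():
    equal = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
    assert (equal.tstat, equal.pvalue, equal.degenerate) == (0.0, 1.0, False)
    diff = two_sample_ttest([2.0, 2.0], [3.0, 3.0])
    assert diff.pvalue == 0.0 and diff.degenerate
    assert diff.tstat == np.inf


def test_ttest_input_validation():
    with pytest.raises(ValueError):
        two_sample_ttest([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_ttest([1, 2], [np.nan, 2])
    with pytest.raises(ValueError):
        two_sample_ttest([1, 2], [1, 2], flavor="paired")


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------

def test_bh_fdr_worked_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.5])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])


def test_bh_fdr_trivial_cases():
    assert bh_fdr([0.2]).tolist() == [0.2]
    assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_matches_brute_force_on_permutations(rng):
    base_sets = [
        [0.001, 0.008, 0.039, 0.041, 0.042, 0.6],
        [0.05, 0.05, 0.01, 0.9, 0.3, 0.2],
        list(rng.random(6)),
    ]
    for base in base_sets:
        for perm in itertools.permutations(base):
            assert np.allclose(bh_fdr(list(perm)), brute_force_bh(perm), atol=1e-12)


def test_bh_fdr_never_below_p(rng):
    p = rng.random(200)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# the full DE stage
# ---------------------------------------------------------------------------

def fit_simple(values, **fit_kw):
    table = make_table(values, scale="log2")
    model = DifferentialEnrichment(table, make_design())
    return model.fit(**fit_kw)


def test_log2fc_is_comparison_minus_reference():
    values = [[5.0] * 5 + [7.0] * 5]
    res = fit_simple(values)
    assert res.frame["log2fc"].iloc[0] == pytest.approx(2.0)
    assert res.frame["direction"].iloc[0] == "increased"


def test_direction_counts_partition_significance(rng):
    values = rng.normal(10, 1, size=(300, 10))
    values[:60, 5:] += rng.normal(1.0, 0.5, size=(60, 5))
    res = fit_simple(values)
    f = res.frame
    n_sig = int((f["pvalue"] < 0.05).sum())
    assert res.counts["n_increased"] + res.counts["n_decreased"] == n_sig
    assert (f["qvalue"] >= f["pvalue"] - 1e-12).all()
    assert (f.loc[f["fold2"], "direction"] != "unchanged").all()


def test_group_swap_negates_log2fc_keeps_p(rng):
    values = rng.normal(10, 1, size=(50, 10))
    table = make_table(values, scale="log2")
    design = make_design()
    fwd = DifferentialEnrichment(table, design).fit()
    rev = DifferentialEnrichment(table, design.swapped()).fit()
    assert np.allclose(fwd.frame["log2fc"], -rev.frame["log2fc"])
    assert np.allclose(fwd.frame["pvalue"], rev.frame["pvalue"])
    assert np.allclose(fwd.frame["qvalue"], rev.frame["qvalue"])


def test_null_simulation_type_one_error():
    """Full DE stage on null data: positive rate within 3 binomial SE of alpha."""
    config = SimulationConfig(n_proteins=1000, dropout_slope=0.0, seed=20240518).null()
    table, design, _, _ = simulate_experiment(config)
    logged = log2_transform(impute_missing(table))
    res = DifferentialEnrichment(logged, design).fit(alpha=0.05)
    rate = res.counts["n_significant"] / res.counts["n_proteins"]
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(rate - 0.05) <= 3 * se


def test_model_rejects_wrong_scale_and_design():
    table = make_table([[1.0] * 10], scale="raw")
    with pytest.raises(ValueError, match="log2"):
        DifferentialEnrichment(table, make_design())
    table = make_table([[1.0] * 8], scale="log2", samples=[f"X{i}" for i in range(8)])
    with pytest.raises(ValueError, match="assignment"):
        DifferentialEnrichment(table, make_design()).fit()


def test_volcano_table_columns_and_arithmetic(rng):
    values = rng.normal(10, 1, size=(40, 10))
    res = fit_simple(values)
    vol = res.volcano_table()
    assert len(vol) == 40
    assert np.allclose(vol["neg_log10_p"], -np.log10(res.frame["pvalue"]))
    # p = 0.05 -> 1.301 on the -log10 axis
    assert -np.log10(0.05) == pytest.approx(1.301, abs=1e-3)
    empty = volcano_table(res.frame.iloc[:0])
    assert len(empty) == 0


def test_summary_mentions_headline_counts(rng):
    values = rng.normal(10, 1, size=(30, 10))
    res = fit_simple(values)
    text = res.summary()
    assert "FACS vs MACS" in text
    assert str(res.counts["n_significant"]) in text
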