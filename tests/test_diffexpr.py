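"""Normalization, BH correction, dispersion estimation, QL F-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from evbiomark import (
    CountMatrix,
    DesignSpec,
    SampleTable,
    bh_adjust,
    call_significant,
    normalize_within_biotype,
    run_de,
)
from evbiomark.diffexpr import (
    DesignError,
    build_design_matrix,
    fit_dispersions,
    prefilter_features,
    ql_f_test,
)


def _cm(counts: dict, biotypes) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index.name = "feature_id"
    return CountMatrix(df, pd.Series(biotypes))


def _two_group_table(n_a: int, n_b: int, group_a="PreOp", group_b="HC") -> SampleTable:
    rows = [{"sample_id": f"a{i}", "subject": f"a{i}", "group": group_a} for i in range(n_a)]
    rows += [{"sample_id": f"b{i}", "subject": f"b{i}", "group": group_b} for i in range(n_b)]
    return SampleTable(pd.DataFrame(rows))


# --- normalization ----------------------------------------------------------


def test_biotype_cpm_arithmetic():
    cm = _cm({"s1": [10, 30]}, {0: "miRNA", 1: "miRNA"})
    norm, totals = normalize_within_biotype(cm)
    assert norm.loc[0, "s1"] == pytest.approx(250_000.0)
    assert totals.loc["miRNA", "s1"] == 40


def test_scaling_within_biotype_cancels():
    cm1 = _cm({"s1": [10, 30], "s2": [5, 15]}, {0: "miRNA", 1: "miRNA"})
    cm2 = _cm({"s1": [30, 90], "s2": [5, 15]}, {0: "miRNA", 1: "miRNA"})
    n1, _ = normalize_within_biotype(cm1)
    n2, _ = normalize_within_biotype(cm2)
    assert np.allclose(n1.to_numpy(), n2.to_numpy())


def test_biotypes_normalized_independently():
    base = _cm({"s1": [10, 30, 7]}, {0: "miRNA", 1: "miRNA", 2: "lncRNA"})
    changed = _cm({"s1": [10, 30, 700]}, {0: "miRNA", 1: "miRNA", 2: "lncRNA"})
    n1, _ = normalize_within_biotype(base)
    n2, _ = normalize_within_biotype(changed)
    assert np.allclose(n1.loc[[0, 1], "s1"], n2.loc[[0, 1], "s1"])


def test_zero_biotype_total_becomes_missing():
    cm = _cm({"s1": [0, 5], "s2": [3, 5]}, {0: "miRNA", 1: "lncRNA"})
    norm, _ = normalize_within_biotype(cm)
    assert np.isnan(norm.loc[0, "s1"])
    assert norm.loc[0, "s2"] == pytest.approx(1e6)


# --- BH ---------------------------------------------------------------------


def _bh_oracle(p):
    """Textbook step-up: sort, multiply by n/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = min(val, 1.0)
        prev = val
    return adj


def test_bh_hand_derived_case():
    assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_value_unchanged():
    assert bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_textbook_oracle_and_bounds(p):
    p = np.array(p)
    adj = bh_adjust(p)
    assert np.allclose(adj, _bh_oracle(p))
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


# --- dispersion estimation --------------------------------------------------


def _nb(rng, mean, phi):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean)).astype(float)


def test_dispersion_recovery_moderate_size():
    rng = np.random.default_rng(0)
    G, n = 300, 30
    mu = rng.lognormal(5.5, 0.8, G)[:, None] * np.ones(2 * n)
    Y = _nb(rng, mu, 0.3)
    X = np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])
    offset = np.zeros_like(Y)
    phi = fit_dispersions(Y, X, offset)
    assert 0.24 <= np.median(phi) <= 0.36


def test_poisson_data_estimates_near_zero():
    rng = np.random.default_rng(1)
    G, n = 200, 20
    mu = rng.lognormal(5.0, 0.5, G)[:, None] * np.ones(2 * n)
    Y = rng.poisson(mu).astype(float)
    X = np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])
    phi = fit_dispersions(Y, X, np.zeros_like(Y))
    assert np.median(phi) <= 0.02


def test_infinite_prior_shrinks_to_common_estimate():
    rng = np.random.default_rng(2)
    n = 20
    X = np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])
    mu = np.array([200.0, 220.0])[:, None] * np.ones(2 * n)
    Y = np.vstack([_nb(rng, mu[:1], 0.05), _nb(rng, mu[1:], 0.8)])
    phi = fit_dispersions(Y, X, np.zeros_like(Y), prior_df=1e9)
    assert phi[0] == pytest.approx(phi[1], rel=1e-3)


# --- QL F-test --------------------------------------------------------------


def test_large_effect_detected_with_correct_fold_change():
    rng = np.random.default_rng(3)
    G, n = 50, 30
    group = np.r_[np.zeros(n), np.ones(n)]
    mu = rng.lognormal(5.5, 0.5, G)[:, None] * np.exp(np.log(16.0) * group)[None, :]
    Y = _nb(rng, mu, 0.3)
    X = np.column_stack([np.ones(2 * n), group])
    offset = np.zeros_like(Y)
    phi = fit_dispersions(Y, X, offset)
    res = ql_f_test(Y, X, 1, offset, phi)
    assert (res["p"] < 1e-6).all()
    log2fc = res["coef"] / np.log(2)
    assert ((log2fc > 3.2) & (log2fc < 4.8)).all()


def test_p_values_invariant_to_sample_order(small_dataset):
    _, cm, samples, _ = small_dataset
    design = DesignSpec("PreOp_vs_HC", paired=False)
    res1 = run_de(cm, samples, design)
    shuffled = SampleTable(samples.table.sample(frac=1, random_state=0))
    res2 = run_de(cm, shuffled, design)
    common = res1.index
    assert np.allclose(res1.loc[common, "p"], res2.loc[common, "p"], rtol=1e-6)


def test_offset_absorbs_within_biotype_scaling(small_dataset):
    _, cm, samples, _ = small_dataset
    design = DesignSpec("PreOp_vs_HC", paired=False)
    res1 = run_de(cm, samples, design)
    scaled = cm.counts.copy()
    target = samples.samples_in_group("HC")[0]
    mirna = cm.biotypes[cm.biotypes == "miRNA"].index
    scaled.loc[mirna, target] = scaled.loc[mirna, target] * 3
    res2 = run_de(CountMatrix(scaled, cm.biotypes), samples, design)
    common = res1.index.intersection(res2.index)
    # fold changes are exactly invariant (normalization cancels the scale);
    # p-values shift only through the likelihood's weighting of the sample
    assert np.allclose(res1.loc[common, "log2FC"], res2.loc[common, "log2FC"])
    rho = stats.spearmanr(res1.loc[common, "p"], res2.loc[common, "p"]).statistic
    assert rho > 0.99


def test_prefilter_drops_sparse_features():
    counts = pd.DataFrame(
        {"s1": [0, 5, 1], "s2": [0, 4, 0], "s3": [0, 6, 1], "s4": [0, 3, 1]}
    )
    counts.index.name = "feature_id"
    cm = CountMatrix(counts, pd.Series({0: "miRNA", 1: "miRNA", 2: "miRNA"}))
    keep = prefilter_features(cm, ["s1", "s2", "s3", "s4"])
    assert list(keep) == [1, 2]


def test_paired_design_requires_shared_subjects():
    samples = _two_group_table(4, 4, group_a="PreOp", group_b="PostOp")
    with pytest.raises(DesignError, match="subject"):
        build_design_matrix(samples, DesignSpec("PreOp_vs_PostOp", paired=True))


def test_too_small_group_rejected():
    samples = _two_group_table(1, 5)
    with pytest.raises(DesignError, match=">=2"):
        build_design_matrix(samples, DesignSpec("PreOp_vs_HC", paired=False))


# --- significance calls -----------------------------------------------------


def test_significance_boundary_rules():
    res = pd.DataFrame(
        {
            "adj_p": [0.05, 0.04, 0.05, 0.06],
            "log2FC": [1.01, 1.00, -1.2, 2.0],
            "biotype": ["miRNA"] * 4,
        },
        index=["a", "b", "c", "d"],
    )
    out = call_significant(res)
    assert list(out.index) == ["a", "c"]  # b: |lfc| not > 1; d: adj_p > 0.05
    assert out.loc["a", "direction"] == "up"
    assert out.loc["c", "direction"] == "down"


def test_empty_input_empty_output():
    res = pd.DataFrame(columns=["adj_p", "log2FC", "biotype"])
    assert call_significant(res).empty
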