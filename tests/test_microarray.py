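"""Normalisation, moderated t, BH adjustment and fold-change selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from matreg.microarray import (
    ModeratedFitParams,
    adjust_bh,
    aggregate_probes,
    background_subtract,
    build_comparison_table,
    compute_fc,
    filter_flags,
    fit_moderated,
    loess_normalize,
    moderated_t,
    posterior_variance,
    select_de,
)


def _probe_frame(**cols):
    base = {
        "gene_id": "g", "array_id": "a", "genotype": "mat+", "replicate": 1,
        "probe": 1, "sample_fg": 1000.0, "sample_bg": 100.0,
        "ref_fg": 1000.0, "ref_bg": 100.0, "flag": 100,
    }
    n = max(len(v) for v in cols.values())
    data = {k: cols.get(k, [base[k]] * n) for k in base}
    data["probe"] = cols.get("probe", list(range(1, n + 1)))
    return pd.DataFrame(data)


def test_filter_flags_keeps_good_and_moderate():
    probes = _probe_frame(flag=[100, 0, -50, -100])
    kept = filter_flags(probes)
    assert len(kept) == 2
    assert set(kept.flag) == {100, 0}


def test_filter_flags_identity_when_all_good():
    probes = _probe_frame(flag=[100, 100, 100])
    assert len(filter_flags(probes)) == 3


def test_filter_flags_unknown_value_rejected():
    with pytest.raises(ValueError, match="unknown flag"):
        filter_flags(_probe_frame(flag=[100, 17]))


def test_background_subtraction_and_floor():
    probes = _probe_frame(sample_fg=[1000.0, 50.0], sample_bg=[100.0, 100.0])
    net = background_subtract(probes)
    assert net.sample_net.tolist() == [900.0, 0.5]
    assert net.low_signal.tolist() == [False, True]


def test_loess_constant_m_normalises_to_zero():
    rng = np.random.default_rng(0)
    a = rng.uniform(6, 14, 500)
    m = np.full(500, 0.7)
    out = loess_normalize(m, a)
    assert np.allclose(out, 0.0, atol=1e-8)


def test_loess_removes_planted_sinusoidal_dye_bias():
    rng = np.random.default_rng(1)
    a = rng.uniform(4, 16, 5000)
    true_m = rng.normal(0, 0.15, 5000)
    biased = true_m + 0.5 * np.sin(a)
    # the sinusoid's period (2 pi in A units) is short relative to the A
    # range, so a tighter span than the smooth-dye-bias default is needed
    out = loess_normalize(biased, a, span=0.1)
    residual = out - true_m
    # amplitude of the remaining intensity-dependent trend, reduced >= 10x
    amp_before = 0.5
    bins = np.digitize(a, np.linspace(4, 16, 25))
    trend = np.array([residual[bins == b].mean() for b in range(1, 25)])
    assert np.nanmax(np.abs(trend)) < amp_before / 10


def test_loess_pure_noise_nearly_identity():
    rng = np.random.default_rng(2)
    a = rng.uniform(4, 16, 3000)
    m = rng.normal(0, 0.2, 3000)
    out = loess_normalize(m, a)
    assert np.median(np.abs(out - m)) < 0.2 / 5


def test_loess_small_array_falls_back_to_median_centering(caplog):
    a = np.linspace(0, 1, 10)
    m = np.linspace(0, 1, 10) + 5
    with caplog.at_level("WARNING"):
        out = loess_normalize(m, a)
    assert "median-centering" in caplog.text
    assert np.median(out) == pytest.approx(0.0)


def test_probe_aggregation_is_median_and_robust():
    probes = _probe_frame(sample_fg=[0.0] * 4)
    probes["m_norm"] = [1.0, 1.1, 0.9, 5.0]
    probes["sample_net"] = [10.0, 20.0, 30.0, 40.0]
    probes["ref_net"] = 1.0
    agg = aggregate_probes(probes)
    assert agg.m.iloc[0] == pytest.approx(1.05)
    assert agg.sample_mean.iloc[0] == pytest.approx(25.0)


def test_probe_aggregation_matches_brute_force():
    rng = np.random.default_rng(3)
    rows = []
    for g in range(20):
        for arr in range(4):
            for p in range(rng.integers(1, 5)):
                rows.append(
                    {
                        "gene_id": f"g{g}", "array_id": f"a{arr}", "genotype": "mat+",
                        "replicate": arr, "m_norm": rng.normal(), "sample_net": 1.0,
                        "ref_net": 1.0,
                    }
                )
    df = pd.DataFrame(rows)
    agg = aggregate_probes(df).set_index(["gene_id", "array_id"]).m
    for (g, a), grp in df.groupby(["gene_id", "array_id"]):
        assert agg[(g, a)] == pytest.approx(np.median(grp.m_norm))


# ------------------------------------------------------------- moderated t


def test_variance_equal_to_prior_is_unchanged_regardless_of_d0():
    for d0 in (0.5, 4.0, 100.0):
        params = ModeratedFitParams(d0, 0.04)
        post = posterior_variance(np.full(5, 0.04), 12.0, params)
        assert np.allclose(post, 0.04, rtol=1e-12)


def test_homogeneous_variances_give_complete_shrinkage():
    var = np.full(50, 0.04)
    fit = fit_moderated(var, 12.0)
    assert np.isinf(fit.d0)
    post = posterior_variance(var, 12.0, fit)
    assert np.allclose(post, fit.s0_sq)


def test_infinite_d0_shrinks_to_prior():
    params = ModeratedFitParams(np.inf, 0.01)
    post = posterior_variance(np.array([0.5, 0.001]), 12.0, params)
    assert np.allclose(post, 0.01)


def test_posterior_variance_between_sample_and_prior():
    params = ModeratedFitParams(4.0, 0.02)
    var = np.array([0.001, 0.02, 0.5])
    post = posterior_variance(var, 12.0, params)
    lo = np.minimum(var, params.s0_sq)
    hi = np.maximum(var, params.s0_sq)
    assert np.all(post >= lo) and np.all(post <= hi)


def test_moderated_fit_recovers_planted_prior():
    """Variances from scaled inv-chi2(d0=4, s0^2=0.0225): d0 in [2.5, 6.5],
    s0^2 within 25%."""
    rng = np.random.default_rng(7)
    d0, s0_sq, dg = 4.0, 0.0225, 12
    sigma = s0_sq * d0 / rng.chisquare(d0, 5000)
    sample_var = sigma * rng.chisquare(dg, 5000) / dg
    fit = fit_moderated(sample_var, float(dg))
    assert 2.5 <= fit.d0 <= 6.5
    assert abs(fit.s0_sq - s0_sq) / s0_sq < 0.25


def test_all_zero_variances_give_infinite_d0(caplog):
    with caplog.at_level("WARNING"):
        fit = fit_moderated(np.zeros(20), 12.0)
    assert np.isinf(fit.d0) and fit.s0_sq == 0.0


def test_moderated_t_null_difference():
    params = ModeratedFitParams(4.0, 0.02)
    t, p = moderated_t([1.0, 1.2, 0.8], [1.2, 1.0, 0.8], params)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_moderated_t_with_zero_prior_df_equals_student_t():
    rng = np.random.default_rng(11)
    params = ModeratedFitParams(0.0, 1.0)
    for _ in range(100):
        g1 = rng.normal(0, 1, rng.integers(3, 8))
        g2 = rng.normal(0.5, 1, rng.integers(3, 8))
        t, p = moderated_t(g1, g2, params)
        ref = stats.ttest_ind(g1, g2, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_moderated_t_requires_two_arrays_per_group():
    with pytest.raises(ValueError, match=">= 2 arrays"):
        moderated_t([1.0], [1.0, 2.0], ModeratedFitParams(4.0, 0.02))


# ------------------------------------------------------------ BH adjustment


def test_bh_closed_forms():
    assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def _bh_brute_force(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_bh_matches_brute_force_and_is_valid(p):
    adj = adjust_bh(p)
    assert adj == pytest.approx(_bh_brute_force(p))
    assert np.all(adj >= np.asarray(p) - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


# -------------------------------------------------------------- fold change


def test_fold_change_closed_forms():
    assert compute_fc(1.0) == pytest.approx(2.0)
    assert compute_fc(-1.0) == pytest.approx(-2.0)
    assert compute_fc(0.0) == pytest.approx(1.0)
    assert compute_fc(np.log2(2.95)) == pytest.approx(2.95)


@given(
    st.floats(min_value=1e-9, max_value=20, allow_nan=False)
    | st.floats(min_value=-20, max_value=-1e-9, allow_nan=False)
)
@settings(deadline=None, derandomize=True)
def test_fold_change_antisymmetric_and_never_fractional(x):
    fc = compute_fc(x)
    assert abs(fc) >= 1.0
    assert compute_fc(-x) == pytest.approx(-fc, rel=1e-12)


def test_selection_boundaries():
    table = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "fc_matplus_vs_matminus": [2.0, 1.99],
            "p_matplus_vs_matminus": [0.004, 1e-9],
            "a_matplus_vs_matminus": [10.0, 10.0],
            "selected_matplus_vs_matminus": [False, False],
        }
    )
    out, summary = select_de(table)
    assert out.selected_matplus_vs_matminus.tolist() == [True, False]
    assert summary["matplus_vs_matminus"] == {"up": 1, "down": 0, "total": 1}


def test_table1_threshold_partition(table1):
    """The printed mating-type-specific gene list splits 13 up / 6 down at
    the inclusive 2-fold cut."""
    fc = table1.fc
    assert (fc >= 2).sum() == 13
    assert (fc <= -2).sum() == 6


# ------------------------------------------------------- end-to-end checks


def test_null_run_selects_fewer_than_alpha_fraction(null_run):
    n = null_run["design"].n_genes
    for comp, counts in null_run["summary"].items():
        assert counts["total"] <= 0.005 * n


def test_planted_de_genes_detected_with_high_power():
    """|log2 effect| = 1.5, s0 = 0.15, n = 4: >= 99% of planted regulator
    targets are selected in their diagnostic comparison and in mat+ vs mat-."""
    import matreg
    from matreg import SimulationDesign, simulate_expression

    design = SimulationDesign(
        n_genes=800, seed=5, class_proportions={"4": 0.1, "5": 0.1},
        nonexpressed_fraction=0.0,
    )
    probes, truth = simulate_expression(design)
    table = matreg.run_de(probes)["comparison_table"].merge(truth, on="gene_id")
    c4 = table[table.planted_class == "4"]
    c5 = table[table.planted_class == "5"]
    hits = (
        c4.selected_matplus_vs_fpr1.sum()
        + c5.selected_matminus_vs_fmr1.sum()
        + c4.selected_matplus_vs_matminus.sum()
        + c5.selected_matplus_vs_matminus.sum()
    )
    total = 2 * (len(c4) + len(c5))
    assert hits / total >= 0.99
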