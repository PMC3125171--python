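"""Regulator calls, class partition, rescue rules and specificity."""

import numpy as np
import pandas as pd
import pytest

import matreg
from matreg import SimulationDesign, simulate_expression
from matreg.classify import (
    RegulatorCall,
    assign_class,
    call_regulator,
    call_specific,
    class_counts,
    classify_table,
    classify_truth,
    composite_fc,
    compute_ssr,
    rescue_class8,
)


def _row(**kwargs):
    base = {"gene_id": "g"}
    base.update(kwargs)
    return pd.Series(base)


def _calls(fpr1="0", fmr1="0", snp="0", basis="primary"):
    def mk(factor, call):
        b = basis if call != "0" else "none"
        fc = {"A": 3.0, "R": -3.0}.get(call, np.nan)
        return RegulatorCall(factor, call, b, fc, 1e-4 if call != "0" else np.nan)

    return {"FPR1": mk("FPR1", fpr1), "FMR1": mk("FMR1", fmr1), "SNP": mk("SNP", snp)}


# ------------------------------------------------------------- call_regulator


def test_borderline_fc_call_repressed_by_fpr1():
    # Pa_4_5280: FC = -1.97, p = 0.00048 in mat+ vs fpr1-
    row = _row(fc_matplus_vs_fpr1=-1.97, p_matplus_vs_fpr1=0.00048)
    call = call_regulator(row, "FPR1")
    assert call.call == "R" and call.basis == "borderline_fc"


def test_borderline_fc_call_activated_by_fmr1():
    # Pa_1_3100: FC = 1.97, p = 0.00056 in mat- vs fmr1-
    row = _row(fc_matminus_vs_fmr1=1.97, p_matminus_vs_fmr1=0.00056)
    call = call_regulator(row, "FMR1")
    assert call.call == "A" and call.basis == "borderline_fc"


def test_insignificant_p_gates_the_call():
    row = _row(fc_matplus_vs_fpr1=3.0, p_matplus_vs_fpr1=0.5)
    call = call_regulator(row, "FPR1")
    assert call.call == "0" and call.basis == "none"


def test_missing_comparison_gives_null_call():
    call = call_regulator(_row(), "SNP")
    assert call.call == "0" and call.basis == "none"


# --------------------------------------------------------------- composite


def test_composite_fc_reproduces_printed_example():
    assert composite_fc(1.69, -1.75) == pytest.approx(2.9575)


def test_composite_fc_identity_and_magnitudes():
    assert composite_fc(1.0, 1.0) == pytest.approx(1.0)
    assert composite_fc(-2.0, 3.0) == pytest.approx(6.0)


def test_composite_fc_rejects_fractional_input():
    with pytest.raises(ValueError, match="magnitude"):
        composite_fc(0.5, 2.0)


def test_rescue_applies_to_printed_class8_gene():
    # Pa_7_9690: activated by FPR1 (1.69), repressed by FMR1 (-1.75),
    # combining to the observed 2.95-fold mat+ vs mat- change
    row = _row(
        fc_matplus_vs_fpr1=1.69,
        fc_matminus_vs_fmr1=-1.75,
        fc_matplus_vs_matminus=2.95,
        p_matplus_vs_fpr1=0.001,
        p_matminus_vs_fmr1=0.001,
    )
    calls, notes = rescue_class8(row, _calls())
    assert calls["FPR1"].call == "A" and calls["FPR1"].basis == "composite"
    assert calls["FMR1"].call == "R" and calls["FMR1"].basis == "composite"
    assert notes and notes[0].startswith("composite:A/R")


def test_rescue_rejects_weak_subthreshold_pair():
    row = _row(
        fc_matplus_vs_fpr1=1.1,
        fc_matminus_vs_fmr1=-1.1,
        fc_matplus_vs_matminus=2.9,
    )
    calls, notes = rescue_class8(row, _calls())
    assert calls["FPR1"].call == "0" and not notes


def test_rescue_allows_concordant_direction_pattern():
    row = _row(
        fc_matplus_vs_fpr1=1.6,
        fc_matminus_vs_fmr1=1.6,
        fc_matplus_vs_matminus=2.56,
    )
    calls, notes = rescue_class8(row, _calls())
    assert calls["FPR1"].call == "A" and calls["FMR1"].call == "A"


def test_rescue_never_fires_on_nonzero_primary_calls():
    row = _row(
        fc_matplus_vs_fpr1=1.6,
        fc_matminus_vs_fmr1=1.6,
        fc_matplus_vs_matminus=2.56,
    )
    calls, notes = rescue_class8(row, _calls(fpr1="A"))
    assert calls["FPR1"].basis == "primary" and not notes


# ------------------------------------------------------------- assign_class


@pytest.mark.parametrize(
    "fpr1,fmr1,snp,de,expected",
    [
        ("A", "0", "0", True, "4"),   # Pa_4_3858
        ("0", "R", "0", True, "5"),   # Pa_1_16335
        ("A", "R", "A", True, "2"),   # Pa_1_20510
        ("0", "0", "A", True, "1"),
        ("0", "0", "0", True, "8"),
        ("A", "R", "0", True, "3"),
        ("A", "0", "A", True, "6"),
        ("0", "R", "R", True, "7"),
        ("A", "A", "0", False, "9"),  # Pa_5_4645
        ("A", "R", "0", False, "unassigned"),
        ("0", "0", "0", False, "unassigned"),
    ],
)
def test_class_patterns(fpr1, fmr1, snp, de, expected):
    assert assign_class(_calls(fpr1, fmr1, snp), de) == expected


def test_nonprimary_bases_do_not_change_the_pattern():
    calls = _calls("A", "R")
    calls["FPR1"].basis = "borderline_fc"
    calls["FMR1"].basis = "composite"
    assert assign_class(calls, True) == "8"


def test_table2_concordant_class9_genes(table2):
    """The ten genes regulated to a similar level in both mating types are
    all class 9 with concordant calls; significance is taken from the
    published selection."""
    rows = pd.DataFrame(
        {
            "gene_id": table2.gene_id,
            "fc_matplus_vs_matminus": 1.0,
            "p_matplus_vs_matminus": 1.0,
            "fc_matplus_vs_fpr1": table2.fc_fpr1_side,
            "p_matplus_vs_fpr1": 1e-4,
            "fc_matminus_vs_fmr1": table2.fc_fmr1_side,
            "p_matminus_vs_fmr1": 1e-4,
            "fc_fpr1_vs_fmr1": 1.0,
            "p_fpr1_vs_fmr1": 1.0,
        }
    )
    out = classify_table(rows)
    assert (out.class_label == "9").sum() == 10
    assert out.fpr1_call.tolist() == table2.fpr1.tolist()
    assert out.fmr1_call.tolist() == table2.fmr1.tolist()


# ------------------------------------------------------------- truth level


def test_truth_mapping_covers_all_planted_patterns():
    assert classify_truth(0, 0, 1.5, 0) == "1"
    assert classify_truth(1.5, -1.5, 1.5, 0) == "2"
    assert classify_truth(1.5, -1.5, 0, 0) == "3"
    assert classify_truth(1.5, 0, 0, 0) == "4"
    assert classify_truth(0, 1.5, 0, 0) == "5"
    assert classify_truth(1.5, 0, 1.5, 0) == "6"
    assert classify_truth(0, 1.5, 0, 1.5) == "7"
    assert classify_truth(0.75, -0.75, 0, 0) == "8"
    assert classify_truth(1.5, 1.5, 0, 0) == "9"
    assert classify_truth(0, 0, 0, 0) == "none"


# ---------------------------------------------------------------- partition


def test_partition_is_exclusive_and_class_aware(default_run):
    asg = default_run["assignments"]
    assert asg.class_label.isin([str(k) for k in range(1, 10)] + ["unassigned"]).all()
    de = asg.de_matplus_vs_matminus
    in_18 = asg.class_label.isin([str(k) for k in range(1, 9)])
    assert (in_18 <= de).all()  # classes 1-8 only for DE genes
    assert (~de | in_18).all()  # every DE gene lands in 1-8
    assert ((asg.class_label == "9") <= ~de).all()
    counts = class_counts(asg)
    assert sum(counts.values()) == len(asg)


def test_default_design_class_recovery(default_run):
    merged = default_run["assignments"].merge(default_run["truth"], on="gene_id")
    truth_label = merged.planted_class.replace("none", "unassigned")
    assert (merged.class_label == truth_label).mean() >= 0.95


def test_recovery_degrades_monotonically_with_noise():
    rates = []
    for sigma0 in (0.15, 0.3, 0.6):
        design = SimulationDesign(n_genes=500, seed=9, sigma0_sq=sigma0**2)
        probes, truth = simulate_expression(design)
        table = matreg.run_de(probes)["comparison_table"]
        asg = classify_table(table).merge(truth, on="gene_id")
        planted = asg[asg.planted_class != "none"]
        rates.append((planted.class_label == planted.planted_class).mean())
    assert rates[0] >= rates[1] >= rates[2]


# ---------------------------------------------------------------- SSR calls


def test_ssr_extremes():
    signals = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g2"],
            "genotype": ["mat+", "mat-", "mat+", "mat-"],
            "mean_signal": [0.5, 0.5, 2000.0, 2000.0],
        }
    )
    ssr = compute_ssr(signals, {"mat+": 20.0, "mat-": 20.0})
    vals = ssr.set_index(["gene_id", "genotype"]).ssr
    assert vals[("g1", "mat+")] <= 3  # floored signal: not expressed
    assert vals[("g2", "mat+")] == pytest.approx(100.0)


def test_ssr_zero_background_sd_is_infinite():
    signals = pd.DataFrame(
        {"gene_id": ["g"], "genotype": ["mat+"], "mean_signal": [10.0]}
    )
    assert np.isinf(compute_ssr(signals, {"mat+": 0.0}).ssr.iloc[0])


def test_specificity_rule():
    ssr = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g2"],
            "genotype": ["mat+", "mat-", "mat+", "mat-"],
            "ssr": [50.0, 1.0, 40.0, 40.0],
        }
    )
    out = call_specific(ssr).set_index("gene_id").specific_to
    assert out["g1"] == "mat+"
    assert out["g2"] == "none"


def test_planted_specific_genes_recovered():
    """Twenty planted mat+-specific genes are recovered within one."""
    design = SimulationDesign(
        n_genes=600, seed=13, n_matplus_specific=20, nonexpressed_fraction=0.05
    )
    probes, truth = simulate_expression(design)
    de = matreg.run_de(probes)
    ssr = compute_ssr(de["signals"], de["background_sd"])
    table = de["comparison_table"]
    de_flags = table.set_index("gene_id").selected_matplus_vs_matminus
    specific = call_specific(ssr, de_flags)
    n_plus = (specific.specific_to == "mat+").sum()
    assert abs(n_plus - 20) <= 1
    # planted non-expressed genes are called not expressed in both types
    off = truth.gene_id[truth.expressed_in == "."]
    wide = ssr.pivot(index="gene_id", columns="genotype", values="ssr").loc[off]
    assert ((wide["mat+"] <= 3) & (wide["mat-"] <= 3)).mean() >= 0.95
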