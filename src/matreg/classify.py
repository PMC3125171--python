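"""Regulatory-class partitioning of mating-type target genes.

Each gene receives a call (A = activated, R = repressed, 0 = no control) for
the three candidate factors — FPR1 (diagnosed by the mat+ vs fpr1-
comparison), FMR1 (mat- vs fmr1-) and mating-type-linked SNPs (fpr1- vs
fmr1-) — and is placed into one of nine classes, or left unassigned:

======  ==========================  =====================================
class   (FPR1, FMR1, SNP) pattern   meaning
======  ==========================  =====================================
1       (0, 0, 1)                   SNP background only
2       (1, 1, 1)                   all three factors
3       (1, 1, 0)                   both regulators, opposed
4       (1, 0, 0)                   FPR1 only
5       (0, 1, 0)                   FMR1 only
6       (1, 0, 1)                   FPR1 + SNP
7       (0, 1, 1)                   FMR1 + SNP
8       (0, 0, 0)                   differential but sub-threshold control
9       --                          not differential, concordant control
======  ==========================  =====================================

Classes 1-8 apply to genes differentially transcribed between mat+ and mat-;
class 9 to genes regulated to the same level in both mating types.  Two
rescue annotations refine class 8 without moving genes out of it: a
borderline-fold-change call (1.8 <= |FC| < 2 at p < 0.005) and a composite
call where the product of the two sub-threshold wild-type-to-mutant fold
changes reproduces the observed mat+ vs mat- fold change.

Mating-type-specific expression is called from the signal-to-standard-
deviation ratio (SSR): a gene is taken as not expressed in a genotype when
its mean net signal is at most three background standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    DIAGNOSTIC_COMPARISON,
    GENOTYPES,
    MAT_MINUS,
    MAT_PLUS,
    fc_col,
    p_col,
    selected_col,
)

logger = logging.getLogger(__name__)

#: (FPR1 present, FMR1 present, SNP present) -> class label, for DE genes
DEFAULT_CLASS_MAP = {
    (0, 0, 1): "1",
    (1, 1, 1): "2",
    (1, 1, 0): "3",
    (1, 0, 0): "4",
    (0, 1, 0): "5",
    (1, 0, 1): "6",
    (0, 1, 1): "7",
    (0, 0, 0): "8",
}

FACTORS = ("FPR1", "FMR1", "SNP")


@dataclass
class RegulatorCall:
    factor: str
    call: str  # "A", "R" or "0"
    basis: str  # "primary", "borderline_fc", "composite" or "none"
    evidence_fc: float = float("nan")
    evidence_p: float = float("nan")

    def __post_init__(self):
        if (self.call == "0") != (self.basis == "none"):
            raise ValueError(f"call {self.call!r} inconsistent with basis {self.basis!r}")


def call_regulator(
    row: pd.Series,
    factor: str,
    fc_cut: float = 2.0,
    p_cut: float = 0.005,
    borderline_fc_low: float = 1.8,
) -> RegulatorCall:
    """Call one factor from a gene's row of the comparison table.

    Primary call at |FC| >= ``fc_cut`` and p < ``p_cut``; borderline call at
    ``borderline_fc_low`` <= |FC| < ``fc_cut`` with the same p gate.  The FC
    sign gives the direction: positive = activated, negative = repressed.
    """
    comp = DIAGNOSTIC_COMPARISON[factor]
    fc = row.get(fc_col(comp))
    p = row.get(p_col(comp))
    if fc is None or p is None or not np.isfinite(fc) or not np.isfinite(p):
        logger.debug("gene %s: %s comparison missing, call 0", row.get("gene_id"), factor)
        return RegulatorCall(factor, "0", "none")
    direction = "A" if fc > 0 else "R"
    if p < p_cut and abs(fc) >= fc_cut:
        return RegulatorCall(factor, direction, "primary", fc, p)
    if p < p_cut and borderline_fc_low <= abs(fc) < fc_cut:
        return RegulatorCall(factor, direction, "borderline_fc", fc, p)
    return RegulatorCall(factor, "0", "none", fc, p)


def composite_fc(fc_fpr1_side: float, fc_fmr1_side: float) -> float:
    """Predicted |FC(mat+ vs mat-)| from the two wild-type-to-mutant FCs.

    On the signed-fold-change convention magnitudes multiply: activation by
    one factor in one mating type and repression by the other in the opposite
    mating type combine multiplicatively in the between-mating-type ratio.
    """
    if abs(fc_fpr1_side) < 1 or abs(fc_fmr1_side) < 1:
        raise ValueError("signed fold changes must have magnitude >= 1")
    return abs(fc_fpr1_side) * abs(fc_fmr1_side)


def rescue_class8(
    row: pd.Series,
    calls: dict[str, RegulatorCall],
    tol: float = 0.10,
    subfc_floor: float = 1.25,
) -> tuple[dict[str, RegulatorCall], list[str]]:
    """Composite rescue for differential genes with both regulator calls 0.

    If both sub-threshold fold changes have magnitude >= ``subfc_floor`` and
    their product matches the observed mat+ vs mat- fold-change magnitude
    within relative tolerance ``tol``, both FPR1 and FMR1 receive calls with
    basis ``composite`` (signs taken from the sub-FCs).  Returns the possibly
    updated calls and a list of rescue notes.
    """
    if calls["FPR1"].call != "0" or calls["FMR1"].call != "0":
        return calls, []
    fc_f = row.get(fc_col(DIAGNOSTIC_COMPARISON["FPR1"]))
    fc_m = row.get(fc_col(DIAGNOSTIC_COMPARISON["FMR1"]))
    fc_mm = row.get(fc_col("matplus_vs_matminus"))
    if any(v is None or not np.isfinite(v) for v in (fc_f, fc_m, fc_mm)):
        return calls, []
    if abs(fc_f) < subfc_floor or abs(fc_m) < subfc_floor:
        return calls, []
    predicted = composite_fc(fc_f, fc_m)
    if abs(predicted - abs(fc_mm)) / abs(fc_mm) > tol:
        return calls, []
    updated = dict(calls)
    updated["FPR1"] = RegulatorCall(
        "FPR1", "A" if fc_f > 0 else "R", "composite", fc_f, row.get(p_col(DIAGNOSTIC_COMPARISON["FPR1"]))
    )
    updated["FMR1"] = RegulatorCall(
        "FMR1", "A" if fc_m > 0 else "R", "composite", fc_m, row.get(p_col(DIAGNOSTIC_COMPARISON["FMR1"]))
    )
    note = (
        f"composite:{updated['FPR1'].call}/{updated['FMR1'].call}"
        f":predicted={predicted:.4g}:observed={abs(fc_mm):.4g}"
    )
    return updated, [note]


def assign_class(
    calls: dict[str, RegulatorCall],
    de_in_matplus_vs_matminus: bool,
    class_map: dict | None = None,
) -> str:
    """Map primary calls and differential status to a class label.

    Only primary-basis calls define the pattern; borderline and composite
    bases annotate genes without moving them between classes.  Non-DE genes
    with concordant primary FPR1 and FMR1 calls form class 9; all other
    non-DE genes are unassigned.
    """
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    primary = {f: c.call if c.basis == "primary" else "0" for f, c in calls.items()}
    if de_in_matplus_vs_matminus:
        pattern = tuple(int(primary[f] != "0") for f in FACTORS)
        return cmap[pattern]
    if primary["FPR1"] != "0" and primary["FPR1"] == primary["FMR1"]:
        return "9"
    return "unassigned"


def classify_truth(
    beta_fpr1: float,
    beta_fmr1: float,
    beta_snp_plus: float,
    beta_snp_minus: float,
    threshold_log2: float = 1.0,
) -> str:
    """Noise-free class of a gene from its planted log2 effects.

    Mirrors :func:`assign_class` at the level of true effects: a factor is
    present when its log2 effect magnitude reaches ``threshold_log2`` (the
    2-fold cut), and the gene is differential when the combined mat+ vs mat-
    log2 difference does.
    """
    snp = beta_snp_plus - beta_snp_minus
    diff = beta_fpr1 - beta_fmr1 + snp
    de = abs(diff) >= threshold_log2 - 1e-12
    f = abs(beta_fpr1) >= threshold_log2 - 1e-12
    m = abs(beta_fmr1) >= threshold_log2 - 1e-12
    s = abs(snp) >= threshold_log2 - 1e-12
    if de:
        return DEFAULT_CLASS_MAP[(int(f), int(m), int(s))]
    if f and m and np.sign(beta_fpr1) == np.sign(beta_fmr1):
        return "9"
    return "none"


def classify_table(
    table: pd.DataFrame,
    fc_cut: float = 2.0,
    p_cut: float = 0.005,
    borderline_fc_low: float = 1.8,
    composite_tol: float = 0.10,
    subfc_floor: float = 1.25,
    class_map: dict | None = None,
) -> pd.DataFrame:
    """Classify every gene of a comparison table.

    Differential status in mat+ vs mat- is recomputed from the FC and p
    columns with the same thresholds used for the calls.  Returns one row per
    gene with per-factor calls and bases, the class label, rescue notes, and
    the borderline-p flag (a diagnostic comparison with |FC| >= ``fc_cut``
    whose adjusted p lies in [``p_cut``, 0.05)).
    """
    out = []
    for _, row in table.iterrows():
        fc_mm = row.get(fc_col("matplus_vs_matminus"))
        p_mm = row.get(p_col("matplus_vs_matminus"))
        de = (
            fc_mm is not None
            and p_mm is not None
            and np.isfinite(fc_mm)
            and np.isfinite(p_mm)
            and abs(fc_mm) >= fc_cut
            and p_mm < p_cut
        )
        calls = {
            f: call_regulator(row, f, fc_cut, p_cut, borderline_fc_low) for f in FACTORS
        }
        notes = [
            f"borderline_fc:{f}:{c.call}"
            for f, c in calls.items()
            if c.basis == "borderline_fc"
        ]
        label = assign_class(calls, de, class_map)
        if de and label == "8":
            calls, rescue_notes = rescue_class8(
                row, calls, composite_tol, subfc_floor
            )
            notes += rescue_notes
        borderline_p = False
        for f in FACTORS:
            comp = DIAGNOSTIC_COMPARISON[f]
            fc, p = row.get(fc_col(comp)), row.get(p_col(comp))
            if (
                fc is not None
                and p is not None
                and np.isfinite(fc)
                and np.isfinite(p)
                and abs(fc) >= fc_cut
                and p_cut <= p < 0.05
            ):
                borderline_p = True
        out.append(
            {
                "gene_id": row["gene_id"],
                "de_matplus_vs_matminus": bool(de),
                "fpr1_call": calls["FPR1"].call,
                "fpr1_basis": calls["FPR1"].basis,
                "fmr1_call": calls["FMR1"].call,
                "fmr1_basis": calls["FMR1"].basis,
                "snp_call": calls["SNP"].call,
                "snp_basis": calls["SNP"].basis,
                "class_label": label,
                "rescue_notes": ";".join(notes) if notes else ".",
                "borderline_p": borderline_p,
            }
        )
    return pd.DataFrame(out)


def class_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Per-class gene counts, including ``unassigned``."""
    labels = [str(k) for k in range(1, 10)] + ["unassigned"]
    vc = assignments.class_label.value_counts()
    return {lab: int(vc.get(lab, 0)) for lab in labels}


def compute_ssr(
    signals: pd.DataFrame,
    background_sd: dict[str, float] | pd.Series,
) -> pd.DataFrame:
    """Signal-to-standard-deviation ratio per gene and genotype.

    ``signals`` has columns ``gene_id, genotype, mean_signal`` (mean net
    sample-channel intensity over that genotype's arrays);
    ``background_sd`` maps genotype to the pooled standard deviation of the
    local-background measurements on those arrays.  A zero background SD
    yields an infinite SSR.
    """
    bsd = pd.Series(background_sd, dtype=float)
    ssr = signals.copy()
    denom = ssr.genotype.map(bsd)
    with np.errstate(divide="ignore"):
        ssr["ssr"] = np.where(
            denom.to_numpy() > 0,
            ssr.mean_signal.to_numpy() / np.where(denom.to_numpy() > 0, denom.to_numpy(), 1.0),
            np.inf,
        )
    return ssr[["gene_id", "genotype", "ssr"]]


def call_specific(
    ssr: pd.DataFrame,
    de_flags: pd.Series | None = None,
    ssr_cut: float = 3.0,
) -> pd.DataFrame:
    """Mating-type-specific expression calls from per-genotype SSRs.

    A gene is specific to mat+ when it is expressed there (SSR > cut) and not
    expressed in mat- (SSR <= cut); symmetrically for mat-.  ``de_flags``
    (indexed by gene id) optionally restricts candidates to genes
    differentially transcribed between the mating types, which suppresses
    spurious calls from weakly expressed genes hovering at the cut.
    """
    wide = ssr.pivot(index="gene_id", columns="genotype", values="ssr")
    plus = wide[MAT_PLUS]
    minus = wide[MAT_MINUS]
    specific = np.where(
        (plus > ssr_cut) & (minus <= ssr_cut),
        MAT_PLUS,
        np.where((minus > ssr_cut) & (plus <= ssr_cut), MAT_MINUS, "none"),
    )
    out = pd.DataFrame({"gene_id": wide.index, "specific_to": specific}).reset_index(
        drop=True
    )
    if de_flags is not None:
        de = out.gene_id.map(de_flags).fillna(False).astype(bool)
        out.loc[~de, "specific_to"] = "none"
    return out
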