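"""Shared vocabulary: genotypes, comparisons, flag levels, column names.

The experimental design is four genotypes of *Podospora anserina* — the two
wild-type mating types (``mat+`` carrying the FPR1 transcription factor,
``mat-`` carrying FMR1) and the loss-of-function mutants ``fpr1-`` and
``fmr1-`` — each hybridised in four biological replicates against a common
reference on two-color arrays.  All inference runs over four indirect
genotype contrasts.
"""

from __future__ import annotations

MAT_PLUS = "mat+"
MAT_MINUS = "mat-"
FPR1_MUT = "fpr1-"
FMR1_MUT = "fmr1-"

GENOTYPES = (MAT_PLUS, MAT_MINUS, FPR1_MUT, FMR1_MUT)

#: comparison key -> (numerator genotype, denominator genotype)
COMPARISONS = {
    "matplus_vs_matminus": (MAT_PLUS, MAT_MINUS),
    "fpr1_vs_fmr1": (FPR1_MUT, FMR1_MUT),
    "matplus_vs_fpr1": (MAT_PLUS, FPR1_MUT),
    "matminus_vs_fmr1": (MAT_MINUS, FMR1_MUT),
}

#: diagnostic comparison used to call each regulator
DIAGNOSTIC_COMPARISON = {
    "FPR1": "matplus_vs_fpr1",
    "FMR1": "matminus_vs_fmr1",
    "SNP": "fpr1_vs_fmr1",
}

# GenePix-style spot quality flags
FLAG_GOOD = 100
FLAG_MODERATE = 0
FLAG_NOT_FOUND = -50
FLAG_BAD = -100
FLAG_LEVELS = (FLAG_GOOD, FLAG_MODERATE, FLAG_NOT_FOUND, FLAG_BAD)
#: flags whose spots are kept for analysis
FLAG_KEEP = (FLAG_GOOD, FLAG_MODERATE)

PROBE_COLUMNS = (
    "gene_id",
    "array_id",
    "genotype",
    "replicate",
    "probe",
    "sample_fg",
    "sample_bg",
    "ref_fg",
    "ref_bg",
    "flag",
)


def fc_col(comparison: str) -> str:
    return f"fc_{comparison}"


def p_col(comparison: str) -> str:
    return f"p_{comparison}"


def a_col(comparison: str) -> str:
    return f"a_{comparison}"


def selected_col(comparison: str) -> str:
    return f"selected_{comparison}"


def comparison_columns() -> list[str]:
    """Canonical column order of a comparison table."""
    cols = ["gene_id"]
    for c in COMPARISONS:
        cols += [fc_col(c), p_col(c), a_col(c), selected_col(c)]
    return cols
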