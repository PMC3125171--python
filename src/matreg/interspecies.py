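"""Cross-species comparison of mating-type target-gene sets.

Tests whether two species' target-gene sets share more orthologous pairs
than expected given the genome size (Yates-corrected chi-square on a 2x2
contingency table) and whether the fold changes of the shared orthologs
correlate (Pearson on signed-log-transformed FCs, plus Spearman and
Kendall rank statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def build_contingency(
    n_pairs: int,
    n_targets_sp1: int,
    n_targets_sp2: int,
    genome_size: int = 10556,
    literal: bool = False,
) -> np.ndarray:
    """2x2 contingency table for the ortholog-overlap test.

    Default (disjoint-cell) construction::

        [[n_pairs,      n_targets_sp1 - n_pairs],
         [n_targets_sp2, genome_size - n_targets_sp2]]

    ``literal=True`` keeps the undecremented totals in the second column, the
    verbatim row description of the published methods; both constructions
    give the same qualitative answer on the published counts.
    """
    for name, val in (
        ("n_pairs", n_pairs),
        ("n_targets_sp1", n_targets_sp1),
        ("n_targets_sp2", n_targets_sp2),
        ("genome_size", genome_size),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if n_pairs > n_targets_sp1:
        raise ValueError("n_pairs cannot exceed n_targets_sp1")
    if literal:
        table = np.array([[n_pairs, n_targets_sp1], [n_targets_sp2, genome_size]])
    else:
        table = np.array(
            [
                [n_pairs, n_targets_sp1 - n_pairs],
                [n_targets_sp2, genome_size - n_targets_sp2],
            ]
        )
    if (table < 0).any():
        raise ValueError(f"negative derived cell in contingency table: {table.tolist()}")
    return table


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Chi-square with Yates continuity correction on a 2x2 table.

    chi2 = sum max(|O - E| - 0.5, 0)^2 / E, upper-tail p on 1 df.  The
    correction is clamped at zero so near-null tables cannot yield a
    negative contribution.
    """
    o = np.asarray(table, dtype=float)
    if o.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {o.shape}")
    rows = o.sum(axis=1)
    cols = o.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("zero row or column margin")
    e = np.outer(rows, cols) / o.sum()
    chi2 = float(np.sum(np.maximum(np.abs(o - e) - 0.5, 0.0) ** 2 / e))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class OverlapTest:
    n_pairs: int
    n_targets_sp1: int
    n_targets_sp2: int
    genome_size: int
    chi2: float
    p: float


def count_overlap(
    pairs: pd.DataFrame, targets1, targets2
) -> int:
    """Orthologous pairs whose members are targets in both species."""
    t1, t2 = set(targets1), set(targets2)
    return int((pairs.id_sp1.isin(t1) & pairs.id_sp2.isin(t2)).sum())


def overlap_test(
    targets1,
    targets2,
    pairs: pd.DataFrame,
    genome_size: int = 10556,
    literal: bool = False,
) -> OverlapTest:
    """Enrichment of shared orthologs between two target-gene sets."""
    n_pairs = count_overlap(pairs, targets1, targets2)
    table = build_contingency(
        n_pairs, len(set(targets1)), len(set(targets2)), genome_size, literal
    )
    chi2, p = yates_chi2(table)
    return OverlapTest(n_pairs, len(set(targets1)), len(set(targets2)), genome_size, chi2, p)


def transform_fc(fc: np.ndarray) -> np.ndarray:
    """Signed log transform of signed fold changes: sign(FC) * log2|FC|.

    Odd and monotone over the signed-FC convention (|FC| >= 1), mapping
    FC = +/-1 to 0.
    """
    fc = np.asarray(fc, dtype=float)
    if np.any(np.abs(fc) < 1):
        raise ValueError("signed fold changes must have magnitude >= 1")
    return np.sign(fc) * np.log2(np.abs(fc))


def fc_correlation(fc_sp1: np.ndarray, fc_sp2: np.ndarray) -> dict:
    """Correlation of orthologous fold changes on the signed-log scale.

    Pearson r with its two-sided t-test p, Spearman rho, and Kendall tau-b
    (exact p for n <= 10 in the absence of ties, normal approximation
    otherwise).  Degenerate inputs (zero variance on either side) report
    missing values.
    """
    x = transform_fc(fc_sp1)
    y = transform_fc(fc_sp2)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need >= 3 fold-change pairs of equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        return {
            "n": n,
            "pearson_r": np.nan,
            "pearson_p": np.nan,
            "spearman_rho": np.nan,
            "spearman_p": np.nan,
            "kendall_tau": np.nan,
            "kendall_p": np.nan,
        }
    r, rp = stats.pearsonr(x, y)
    rho, rhop = stats.spearmanr(x, y)
    method = "exact" if n <= 10 else "asymptotic"
    try:
        tau, taup = stats.kendalltau(x, y, variant="b", method=method)
    except ValueError:  # exact method rejects ties
        tau, taup = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return {
        "n": n,
        "pearson_r": float(r),
        "pearson_p": float(rp),
        "spearman_rho": float(rho),
        "spearman_p": float(rhop),
        "kendall_tau": float(tau),
        "kendall_p": float(taup),
    }
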