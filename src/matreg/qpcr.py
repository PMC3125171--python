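"""RT-qPCR quantification: efficiencies, geNorm and REST.

Three pieces of methodology:

* amplification efficiency from a 1/10 dilution series,
  ``E = 10^(-1/slope)`` of the Cq vs log10-input regression;
* geNorm reference-gene selection: the stability measure M (a gene's mean
  pairwise log-ratio standard deviation over all other candidates), stepwise
  elimination, and the pairwise variation V(n/n+1) between normalisation
  factors built from the n and n+1 most stable genes, with the V < 0.15 rule
  and the MIQE minimum of three reference genes;
* REST-style efficiency-corrected relative expression ratios with a
  fixed-reallocation randomisation test and a percentile-bootstrap interval.

All quantities work on relative quantities ``Q = E^(minCq - Cq)`` per gene;
any per-gene constant cancels in every downstream statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def efficiency_from_dilution(cq: np.ndarray, log10_input: np.ndarray) -> float:
    """Amplification efficiency from a standard curve.

    ``log10_input`` is the log10 of relative template input (e.g. 0, -1, -2
    for 1/10 serial dilutions).  E = 2 is perfect per-cycle doubling; the
    percent efficiency conventionally quoted is (E - 1) * 100.
    """
    cq = np.asarray(cq, dtype=float)
    x = np.asarray(log10_input, dtype=float)
    if len(cq) < 3:
        raise ValueError("need >= 3 dilution points")
    slope = np.polyfit(x, cq, 1)[0]
    if slope >= 0:
        raise ValueError(f"positive slope {slope:.3g}: dilution series inverted")
    return float(10.0 ** (-1.0 / slope))


def relative_quantities(cq_wide: pd.DataFrame, efficiencies: pd.Series) -> pd.DataFrame:
    """Q = E^(minCq - Cq) per gene (rows genes, columns samples)."""
    eff = efficiencies.reindex(cq_wide.index).to_numpy(dtype=float)[:, None]
    cq = cq_wide.to_numpy(dtype=float)
    return pd.DataFrame(
        eff ** (cq.min(axis=1, keepdims=True) - cq),
        index=cq_wide.index,
        columns=cq_wide.columns,
    )


def _pairwise_m(log_q: pd.DataFrame) -> pd.Series:
    """geNorm M: mean over partners of SD_s(log2 Qj/Qk)."""
    genes = log_q.index
    vals = log_q.to_numpy()
    m = {}
    for j, gj in enumerate(genes):
        sds = [
            np.std(vals[j] - vals[k], ddof=1)
            for k in range(len(genes))
            if k != j
        ]
        m[gj] = float(np.mean(sds))
    return pd.Series(m)


def genorm_m(quantities: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Stability values and stepwise elimination order.

    ``quantities`` has genes as rows and samples as columns.  Returns the
    full-panel M values and the elimination order (least stable first); the
    final two genes, which geNorm cannot rank, close the list in ascending
    final-M then name order.
    """
    if quantities.shape[0] < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    if quantities.shape[1] < 2:
        raise ValueError("geNorm needs >= 2 samples")
    q = quantities.astype(float)
    if (q <= 0).any().any():
        raise ValueError("quantities must be positive")
    log_q = np.log2(q)
    m_full = _pairwise_m(log_q)
    order: list[str] = []
    remaining = log_q.copy()
    while len(remaining) > 2:
        m = _pairwise_m(remaining)
        worst = m.sort_values(ascending=False, kind="stable").index
        # deterministic tie-break on name
        top = m[m == m.max()].index.sort_values()[0]
        order.append(top)
        remaining = remaining.drop(index=top)
    last = _pairwise_m(remaining).sort_values(kind="stable")
    order.extend(sorted(last.index, key=lambda g: (last[g], g), reverse=True))
    return m_full, order


def genorm_v(
    quantities: pd.DataFrame, elimination_order: list[str]
) -> dict[int, float]:
    """Pairwise variation V(n/n+1) between successive normalisation factors.

    NF_n is the per-sample geometric mean of the n most stable genes'
    quantities; V(n/n+1) is the SD over samples of log2(NF_n / NF_{n+1}).
    """
    ranking = list(reversed(elimination_order))  # most stable first
    log_q = np.log2(quantities.astype(float).loc[ranking])
    v = {}
    for n in range(2, len(ranking)):
        nf_n = log_q.iloc[:n].mean(axis=0)
        nf_n1 = log_q.iloc[: n + 1].mean(axis=0)
        v[n] = float(np.std(nf_n - nf_n1, ddof=1))
    return v


def select_references(
    v_series: dict[int, float],
    ranking: list[str],
    v_cut: float = 0.15,
    miqe_min: int = 3,
) -> list[str]:
    """Choose the reference-gene set from the V series.

    The smallest n with V(n/n+1) < ``v_cut`` is sufficient; if two genes
    suffice, a third is added per MIQE guidelines unless including it pushes
    V(3/4) above the cut.  When no n qualifies all candidates are returned
    with a warning.
    """
    qualifying = [n for n in sorted(v_series) if v_series[n] < v_cut]
    if not qualifying:
        logger.warning("no n reaches V < %.3g: returning all %d genes", v_cut, len(ranking))
        return list(ranking)
    n = qualifying[0]
    if n == 2 and miqe_min >= 3 and len(ranking) >= 3:
        if v_series.get(3, 0.0) > v_cut:
            logger.info("third reference would raise V above %.3g: keeping 2", v_cut)
        else:
            n = 3
    return list(ranking[:n])


@dataclass
class GeNormResult:
    m_values: pd.Series
    elimination_order: list[str]
    v_series: dict[int, float]
    selected_refs: list[str]


def run_genorm(
    cq: pd.DataFrame, v_cut: float = 0.15, miqe_min: int = 3
) -> GeNormResult:
    """geNorm screen of a long-format Cq table (all genes as candidates)."""
    cq_wide = cq.pivot_table(index="gene_id", columns="sample_id", values="cq")
    eff = cq.groupby("gene_id").efficiency.first()
    q = relative_quantities(cq_wide, eff)
    m, order = genorm_m(q)
    v = genorm_v(q, order)
    refs = select_references(v, list(reversed(order)), v_cut=v_cut, miqe_min=miqe_min)
    return GeNormResult(m, order, v, refs)


@dataclass
class RESTResult:
    ratio: float
    p_value: float
    n_permutations: int
    ci: tuple[float, float]
    log2_ratio: float


def _normalized_log2_expression(
    cq: pd.DataFrame, target: str, refs: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample reference-normalised log2 expression of the target.

    Technical replicates are averaged first.  Returns (y, condition) indexed
    by sample, with y = log2 E_t * (-Cq_t) + mean_r log2 E_r * Cq_r, whose
    treatment-minus-control mean difference is the log2 REST ratio.
    """
    mean_cq = cq.pivot_table(index="gene_id", columns="sample_id", values="cq")
    eff = cq.groupby("gene_id").efficiency.first()
    cond = cq.drop_duplicates("sample_id").set_index("sample_id").condition
    cond = cond.reindex(mean_cq.columns)
    for g in [target, *refs]:
        if g not in mean_cq.index:
            raise ValueError(f"gene {g!r} absent from Cq table")
    y = -np.log2(eff[target]) * mean_cq.loc[target]
    ref_part = sum(np.log2(eff[r]) * mean_cq.loc[r] for r in refs) / len(refs)
    return y + ref_part, cond


def rest_ratio(
    cq: pd.DataFrame,
    target: str,
    refs: list[str],
    control: str = "control",
    treatment: str = "treatment",
    n_permutations: int = 2000,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
) -> RESTResult:
    """Efficiency-corrected relative expression with a randomisation test.

    ratio = E_t^(meanCq_control - meanCq_treatment) normalised by the
    geometric mean of the reference genes' corresponding factors.  The p
    value comes from fixed-reallocation randomisation: condition labels are
    reshuffled over samples (whole samples, all genes moving together) and
    the two-sided tail of |log2 ratio| is counted with the add-one rule.
    The interval is a percentile bootstrap over samples within conditions.
    """
    y, cond = _normalized_log2_expression(cq, target, refs)
    ctrl = y[cond == control].to_numpy()
    trt = y[cond == treatment].to_numpy()
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per condition")
    obs = trt.mean() - ctrl.mean()

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ctrl, trt])
    n_c, n = len(ctrl), len(pooled)
    if math.comb(n, n_c) <= 1:
        logger.warning("fewer than 2 label arrangements: p = 1")
        p = 1.0
    else:
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        perm = pooled[idx]
        stat = perm[:, n_c:].mean(axis=1) - perm[:, :n_c].mean(axis=1)
        exceed = np.sum(np.abs(stat) >= abs(obs) - 1e-12)
        p = float((exceed + 1) / (n_permutations + 1))

    bi_c = rng.integers(0, len(ctrl), size=(n_bootstrap, len(ctrl)))
    bi_t = rng.integers(0, len(trt), size=(n_bootstrap, len(trt)))
    boot = trt[bi_t].mean(axis=1) - ctrl[bi_c].mean(axis=1)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return RESTResult(
        ratio=float(2.0**obs),
        p_value=p,
        n_permutations=n_permutations,
        ci=(float(2.0**lo), float(2.0**hi)),
        log2_ratio=float(obs),
    )


def mark_genomic_contamination(cq: pd.DataFrame, min_gap: float = 5.0) -> pd.DataFrame:
    """Flag measurements invalid when genomic contamination is too close.

    For intron-less genes assayed with non-discriminating primers, a
    no-reverse-transcription control (``row_type == 'nrt'``) must sit at
    least ``min_gap`` cycles above the cDNA signal for the measurement to
    count.  Genes without NRT rows are assumed to use exon-junction primers
    and stay valid.
    """
    out = cq.copy()
    if "row_type" not in out.columns:
        out["valid"] = True
        return out
    cdna = out[out.row_type == "cdna"]
    nrt = out[out.row_type == "nrt"]
    gap = (
        nrt.groupby(["gene_id", "sample_id"]).cq.mean()
        - cdna.groupby(["gene_id", "sample_id"]).cq.mean()
    )
    bad = set(gap[gap < min_gap].index)
    keys = list(zip(out.gene_id, out.sample_id))
    out["valid"] = [k not in bad for k in keys]
    return out
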