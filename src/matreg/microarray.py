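"""Two-color microarray differential transcription analysis.

From probe-level intensities to the per-gene comparison table: flag
filtering, local background subtraction, within-array loess normalisation of
the log-ratio M on the mean log-intensity A, median aggregation of probe
replicates, empirical-Bayes moderated t statistics on the four indirect
genotype contrasts, Benjamini-Hochberg adjustment, signed fold changes and
the FC >= 2 / p < 0.005 selection rule.

The moderated t shrinks each gene's pooled residual variance s_g^2 (d_g
degrees of freedom) towards a prior s_0^2 carrying d_0 prior degrees of
freedom::

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)
    t_g    = (mean_1 - mean_2) / (s~_g sqrt(1/n_1 + 1/n_2)),   df = d_0 + d_g

with (d_0, s_0^2) estimated by method-of-moments on the log sample variances
(Fisher-z/F-distribution moments, the standard empirical-Bayes fit).
Because every genotype is hybridised against a common reference, a contrast
between two genotypes is the difference of their mean M values, and the
residual variance is pooled across all four genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .schema import (
    COMPARISONS,
    FLAG_KEEP,
    FLAG_LEVELS,
    GENOTYPES,
    a_col,
    comparison_columns,
    fc_col,
    p_col,
    selected_col,
)

logger = logging.getLogger(__name__)

NET_FLOOR = 0.5  # fluorescence units; keeps logs defined after subtraction


def filter_flags(probes: pd.DataFrame) -> pd.DataFrame:
    """Drop bad and not-found spots; keep good and moderate ones."""
    flags = set(probes.flag.unique())
    unknown = flags - set(FLAG_LEVELS)
    if unknown:
        raise ValueError(f"unknown flag values: {sorted(unknown)}")
    kept = probes[probes.flag.isin(FLAG_KEEP)].reset_index(drop=True)
    logger.info("flag filter: kept %d of %d spots", len(kept), len(probes))
    return kept


def background_subtract(probes: pd.DataFrame, floor: float = NET_FLOOR) -> pd.DataFrame:
    """Add net intensities ``sample_net``/``ref_net`` = max(fg - bg, floor).

    Spots floored on the sample channel are marked ``low_signal`` for the
    downstream signal-to-SD expression calls.
    """
    out = probes.copy()
    s_net = out.sample_fg.to_numpy() - out.sample_bg.to_numpy()
    r_net = out.ref_fg.to_numpy() - out.ref_bg.to_numpy()
    out["low_signal"] = s_net < floor
    out["sample_net"] = np.maximum(s_net, floor)
    out["ref_net"] = np.maximum(r_net, floor)
    return out


def loess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
    min_probes: int = 50,
) -> np.ndarray:
    """Intensity-dependent normalisation: M minus a loess fit of M on A.

    Locally weighted first-degree regression with tricube weights and
    ``iterations`` robustness iterations.  With fewer than ``min_probes``
    points the fit is unreliable and the array falls back to
    median-centering.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if len(m) < min_probes:
        logger.warning(
            "only %d probes (< %d): falling back to median-centering", len(m), min_probes
        )
        return m - np.median(m)
    delta = 0.01 * (a.max() - a.min())
    fit = lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=False)
    return m - fit


def normalize_arrays(probes: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Per-array M/A computation and loess normalisation.

    Adds ``a_value`` (0.5 log2(sample*ref)) and ``m_norm`` (normalised log2
    sample/ref) columns.
    """
    out = probes.copy()
    s = out.sample_net.to_numpy()
    r = out.ref_net.to_numpy()
    out["m_raw"] = np.log2(s / r)
    out["a_value"] = 0.5 * np.log2(s * r)
    m_norm = np.empty(len(out))
    for _, idx in out.groupby("array_id", sort=False).indices.items():
        m_norm[idx] = loess_normalize(
            out.m_raw.to_numpy()[idx], out.a_value.to_numpy()[idx], span=span
        )
    out["m_norm"] = m_norm
    return out


def aggregate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe replicates: median M, mean net channel intensities.

    Returns one row per gene x array.  Genes with no surviving spot on an
    array are simply absent for that array (missing value downstream).
    """
    agg = (
        probes.groupby(["gene_id", "array_id", "genotype", "replicate"], sort=False)
        .agg(
            m=("m_norm", "median"),
            sample_mean=("sample_net", "mean"),
            ref_mean=("ref_net", "mean"),
            n_probes=("m_norm", "size"),
        )
        .reset_index()
    )
    return agg


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes prior of the per-gene variance distribution."""

    d0: float
    s0_sq: float


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        step = (tri - y) / polygamma(2, x)
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-10 * max(x, 1.0):
            break
    return float(x)


def fit_moderated(variances: np.ndarray, df_resid: np.ndarray | float) -> ModeratedFitParams:
    """Estimate (d0, s0^2) from the ensemble of per-gene sample variances.

    Method-of-moments on log variances: for s_g^2 ~ s0^2 F(d_g, d0), the
    statistic e_g = log s_g^2 - psi(d_g/2) + log(d_g/2) has mean
    log s0^2 + psi(d0/2) - log(d0/2) and excess variance psi'(d0/2) beyond
    psi'(d_g/2).  Homogeneous variances give d0 = inf (complete shrinkage).
    """
    var = np.asarray(variances, dtype=float)
    dg = np.broadcast_to(np.asarray(df_resid, dtype=float), var.shape)
    ok = np.isfinite(var) & (var > 0) & (dg >= 1)
    if np.all(~np.isfinite(var) | (var == 0)):
        logger.warning("all variances zero: d0 = inf, s0_sq = 0")
        return ModeratedFitParams(np.inf, 0.0)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 genes with positive variance and df >= 1, got {ok.sum()}")
    z = np.log(var[ok])
    d = dg[ok]
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _inv_trigamma(evar)
        s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return ModeratedFitParams(float(d0), s0)


def posterior_variance(
    variances: np.ndarray, df_resid: np.ndarray | float, params: ModeratedFitParams
) -> np.ndarray:
    """Shrunken variance s~^2 = (d0 s0^2 + dg s^2) / (d0 + dg)."""
    var = np.asarray(variances, dtype=float)
    dg = np.broadcast_to(np.asarray(df_resid, dtype=float), var.shape)
    if np.isinf(params.d0):
        return np.full(var.shape, params.s0_sq)
    return (params.d0 * params.s0_sq + dg * var) / (params.d0 + dg)


def moderated_t(
    group1: np.ndarray,
    group2: np.ndarray | None,
    params: ModeratedFitParams,
) -> tuple[float, float]:
    """Moderated t and two-sided raw p for one gene's contrast.

    ``group2=None`` tests the mean of ``group1`` against zero (one-sample
    contrast against the common reference).  With d0 = 0 this reduces to the
    ordinary (pooled) t-test.
    """
    g1 = np.asarray(group1, dtype=float)
    n1 = len(g1)
    if group2 is None:
        if n1 < 2:
            raise ValueError("one-sample contrast needs >= 2 arrays")
        diff = g1.mean()
        dg = n1 - 1
        s_sq = g1.var(ddof=1)
        factor = np.sqrt(1.0 / n1)
    else:
        g2 = np.asarray(group2, dtype=float)
        n2 = len(g2)
        if n1 < 2 or n2 < 2:
            raise ValueError("two-group contrast needs >= 2 arrays per group")
        diff = g1.mean() - g2.mean()
        dg = n1 + n2 - 2
        s_sq = (g1.var(ddof=1) * (n1 - 1) + g2.var(ddof=1) * (n2 - 1)) / dg
        factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    if dg == 0 and np.isfinite(params.d0):
        raise ValueError("zero residual df with finite d0")
    s_tilde = np.sqrt(posterior_variance(s_sq, dg, params))
    if s_tilde == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / (s_tilde * factor)
    df = params.d0 + dg
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(df) else 2.0 * stats.norm.sf(abs(t))
    return float(t), float(p)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compute_fc(mean_m_diff: np.ndarray | float) -> np.ndarray | float:
    """Signed linear fold change from a log2 ratio.

    r = 2^x reported as r when r >= 1 and -1/r otherwise, so FC never lies
    strictly between -1 and 1 and FC(0) = 1.
    """
    x = np.asarray(mean_m_diff, dtype=float)
    r = np.exp2(x)
    fc = np.where(r >= 1.0, r, -1.0 / r)
    return float(fc) if np.isscalar(mean_m_diff) else fc


def build_comparison_table(
    aggregated: pd.DataFrame,
    fc_cut: float = 2.0,
    p_cut: float = 0.005,
    min_arrays: int = 2,
    params: ModeratedFitParams | None = None,
) -> tuple[pd.DataFrame, ModeratedFitParams]:
    """Per-gene FC / adjusted p / A / selection for the four comparisons.

    The residual variance is pooled over all four genotypes per gene; a gene
    is testable in a comparison only when both genotypes retain at least
    ``min_arrays`` arrays.  ``params`` overrides the empirical-Bayes fit
    (useful for d0 = 0, the unmoderated t).
    """
    m_wide = aggregated.pivot(index="gene_id", columns="array_id", values="m")
    geno_of = aggregated.drop_duplicates("array_id").set_index("array_id").genotype
    genes = m_wide.index

    means, counts, ss = {}, {}, {}
    sample_means = {}
    sig = aggregated.pivot(index="gene_id", columns="array_id", values="sample_mean")
    for g in GENOTYPES:
        cols = [c for c in m_wide.columns if geno_of[c] == g]
        block = m_wide[cols]
        n = block.notna().sum(axis=1)
        mu = block.mean(axis=1)
        means[g], counts[g] = mu, n
        ss[g] = ((block.sub(mu, axis=0)) ** 2).sum(axis=1)
        sample_means[g] = sig[cols].mean(axis=1)

    dg = sum(np.maximum(counts[g] - 1, 0) for g in GENOTYPES).astype(float)
    pooled = sum(ss[g] for g in GENOTYPES) / dg.replace(0, np.nan)

    if params is None:
        params = fit_moderated(pooled.to_numpy(), dg.to_numpy())
    logger.info("moderated fit: d0 = %.3g, s0_sq = %.4g", params.d0, params.s0_sq)

    s_tilde_sq = posterior_variance(pooled.to_numpy(), dg.to_numpy(), params)
    table = pd.DataFrame({"gene_id": genes})
    n_untestable = 0
    for comp, (g1, g2) in COMPARISONS.items():
        n1, n2 = counts[g1].to_numpy().astype(float), counts[g2].to_numpy().astype(float)
        testable = (n1 >= min_arrays) & (n2 >= min_arrays) & np.isfinite(s_tilde_sq)
        diff = (means[g1] - means[g2]).to_numpy()
        se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        df = params.d0 + dg.to_numpy()
        if np.isfinite(params.d0):
            raw = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            raw = 2.0 * stats.norm.sf(np.abs(t))
        raw = np.where(testable, raw, np.nan)
        adj = adjust_bh(raw)
        a_val = np.log2((sample_means[g1].to_numpy() + sample_means[g2].to_numpy()) / 2.0)
        fc = compute_fc(diff)
        table[fc_col(comp)] = fc
        table[p_col(comp)] = adj
        table[a_col(comp)] = a_val
        with np.errstate(invalid="ignore"):
            table[selected_col(comp)] = (
                (np.abs(fc) >= fc_cut) & (adj < p_cut) & testable
            )
        table[f"praw_{comp}"] = raw  # pre-adjustment p, kept for calibration checks
        n_untestable += int((~testable).sum())
    if n_untestable:
        logger.info("untestable gene/comparison combinations: %d", n_untestable)
    cols = comparison_columns() + [f"praw_{c}" for c in COMPARISONS]
    return table[cols], params


def select_de(
    table: pd.DataFrame, fc_cut: float = 2.0, p_cut: float = 0.005
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Recompute selection flags and count up/down genes per comparison.

    The selection rule is inclusive on the fold-change cut (FC >= 2 or
    FC <= -2) and strict on the p cut (p < 0.005).
    """
    out = table.copy()
    summary: dict[str, dict[str, int]] = {}
    for comp in COMPARISONS:
        if fc_col(comp) not in out.columns or p_col(comp) not in out.columns:
            continue
        fc = out[fc_col(comp)].to_numpy(dtype=float)
        p = out[p_col(comp)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            sel = (np.abs(fc) >= fc_cut) & (p < p_cut)
        sel &= np.isfinite(fc) & np.isfinite(p)
        out[selected_col(comp)] = sel
        summary[comp] = {
            "up": int((sel & (fc > 0)).sum()),
            "down": int((sel & (fc < 0)).sum()),
            "total": int(sel.sum()),
        }
    return out, summary


def signal_summary(probes: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene per-genotype mean net sample signal and background SDs.

    Feeds the SSR expression calls: the signal is the mean background-
    subtracted sample-channel intensity over a genotype's arrays, the noise
    scale the pooled SD of that genotype's local-background measurements.
    """
    signals = (
        probes.groupby(["gene_id", "genotype"], sort=False)
        .agg(mean_signal=("sample_net", "mean"))
        .reset_index()
    )
    bg_sd = probes.groupby("genotype").sample_bg.std(ddof=1)
    return signals, bg_sd


def run_de(
    probes: pd.DataFrame,
    span: float = 0.3,
    fc_cut: float = 2.0,
    p_cut: float = 0.005,
    min_arrays: int = 2,
) -> dict:
    """Probe table to comparison table, end to end.

    Returns a dict with keys ``comparison_table``, ``params``, ``signals``,
    ``background_sd`` and ``summary`` (selection counts per comparison).
    """
    kept = filter_flags(probes)
    net = background_subtract(kept)
    norm = normalize_arrays(net, span=span)
    agg = aggregate_probes(norm)
    table, params = build_comparison_table(
        agg, fc_cut=fc_cut, p_cut=p_cut, min_arrays=min_arrays
    )
    table, summary = select_de(table, fc_cut=fc_cut, p_cut=p_cut)
    signals, bg_sd = signal_summary(net)
    return {
        "comparison_table": table,
        "params": params,
        "signals": signals,
        "background_sd": bg_sd,
        "summary": summary,
    }
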