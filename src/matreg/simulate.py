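"""Synthetic data with planted ground truth.

Three generators cover the three experimental layers of the study:

* :func:`simulate_expression` — probe-level two-color microarray intensities
  for the four-genotype design, with per-gene variance heterogeneity drawn
  from a scaled inverse-chi-square prior, planted FPR1/FMR1/SNP effects
  encoding a known regulatory class per gene, non-expressed genes emitting
  background-level signal, and GenePix-style quality flags.
* :func:`simulate_cq` — RT-qPCR quantification-cycle tables with designated
  stable reference genes, per-gene amplification efficiencies and planted
  condition effects.
* :func:`simulate_ortholog_sets` — two-species target-gene sets joined by an
  ortholog-pair list with a planted (or hypergeometric) overlap.

Every generator is a pure function of its design and seed: the same seed
reproduces bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .classify import classify_truth
from .schema import (
    FLAG_BAD,
    FLAG_GOOD,
    FLAG_MODERATE,
    FLAG_NOT_FOUND,
    FMR1_MUT,
    FPR1_MUT,
    GENOTYPES,
    MAT_MINUS,
    MAT_PLUS,
    PROBE_COLUMNS,
)

# Genome-scale class frequencies: 157 differentially transcribed genes out of
# 10,556, split 13 / 103 / 41 over the SNP-only class, the six regulator
# classes and the sub-threshold class, plus 10 concordantly regulated genes.
DEFAULT_CLASS_PROPORTIONS = {
    "1": 13 / 10556,
    "2": 8 / 10556,
    "3": 10 / 10556,
    "4": 45 / 10556,
    "5": 30 / 10556,
    "6": 5 / 10556,
    "7": 5 / 10556,
    "8": 41 / 10556,
    "9": 10 / 10556,
}

TRUTH_COLUMNS = (
    "gene_id",
    "beta_fpr1",
    "beta_fmr1",
    "beta_snp_plus",
    "beta_snp_minus",
    "planted_class",
    "expressed_in",
    "sigma_sq",
)


@dataclass
class SimulationDesign:
    """Parameters of the synthetic microarray experiment.

    Defaults emulate the study conditions: four biological replicates per
    genotype against a common reference, |log2 effect| = 1.5 (FC ~ 2.8),
    residual log2-scale noise with prior scale s0 = 0.15 and d0 = 4 prior
    degrees of freedom, and genome-like class frequencies.
    """

    n_genes: int = 1000
    n_replicates: int = 4
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size_log2: float = 1.5
    sigma0_sq: float = 0.0225  # s0 = 0.15 on the log2 scale
    d0: float = 4.0
    baseline_log2: float = 10.0
    baseline_sd: float = 2.0  # per-gene spread of expression level (log2)
    nonexpressed_fraction: float = 0.10
    background_mean: float = 80.0
    background_sd: float = 20.0
    n_probe_replicates: int = 4
    probe_noise_sd: float = 0.05
    ref_noise_sd: float = 0.10
    dye_bias_amplitude: float = 0.0
    frac_flag_bad: float = 0.02
    frac_flag_not_found: float = 0.01
    frac_flag_moderate: float = 0.05
    n_matplus_specific: int = 0
    n_matminus_specific: int = 0
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "n_genes",
            "n_replicates",
            "sigma0_sq",
            "d0",
            "background_sd",
            "n_probe_replicates",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        nonneg = (
            "baseline_sd",
            "effect_size_log2",
            "nonexpressed_fraction",
            "background_mean",
            "probe_noise_sd",
            "ref_noise_sd",
            "frac_flag_bad",
            "frac_flag_not_found",
            "frac_flag_moderate",
            "n_matplus_specific",
            "n_matminus_specific",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        planted = sum(self.class_proportions.get(str(k), 0.0) for k in range(1, 10))
        none_p = self.class_proportions.get("none", 1.0 - planted)
        if abs(planted + none_p - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")
        if planted > 1.0 + 1e-9:
            raise ValueError("class_proportions for classes 1-9 exceed 1")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def _class_counts(proportions: dict, n_genes: int) -> dict[str, int]:
    """Largest-remainder allocation of genes to classes 1..9."""
    labels = [str(k) for k in range(1, 10)]
    raw = {lab: proportions.get(lab, 0.0) * n_genes for lab in labels}
    counts = {lab: int(math.floor(v)) for lab, v in raw.items()}
    short = int(round(sum(raw.values()))) - sum(counts.values())
    # assign leftover genes to the largest fractional remainders
    remainders = sorted(labels, key=lambda k: raw[k] - counts[k], reverse=True)
    for lab in remainders[:max(short, 0)]:
        counts[lab] += 1
    return counts


def _plant_betas(rng: np.random.Generator, label: str, e: float) -> tuple[float, float, float, float]:
    """Signed (beta_fpr1, beta_fmr1, beta_snp_plus, beta_snp_minus) for a class."""
    s = float(rng.choice((-1.0, 1.0)))
    if label == "1":  # SNP only
        if rng.random() < 0.5:
            return 0.0, 0.0, s * e, 0.0
        return 0.0, 0.0, 0.0, s * e
    if label == "2":  # all three factors
        s2 = float(rng.choice((-1.0, 1.0)))
        s3 = float(rng.choice((-1.0, 1.0)))
        if rng.random() < 0.5:
            return s * e, s2 * e, s3 * e, 0.0
        return s * e, s2 * e, 0.0, s3 * e
    if label == "3":  # FPR1 and FMR1, discordant so the mat+ vs mat- contrast is non-null
        return s * e, -s * e, 0.0, 0.0
    if label == "4":
        return s * e, 0.0, 0.0, 0.0
    if label == "5":
        return 0.0, s * e, 0.0, 0.0
    if label == "6":  # FPR1 + SNP, reinforcing
        return s * e, 0.0, s * e, 0.0
    if label == "7":  # FMR1 + SNP, reinforcing
        return 0.0, s * e, 0.0, s * e
    if label == "8":  # sub-threshold opposite-sign pair whose combination is DE
        return s * e / 2.0, -s * e / 2.0, 0.0, 0.0
    if label == "9":  # concordant control, cancels in mat+ vs mat-
        return s * e, s * e, 0.0, 0.0
    return 0.0, 0.0, 0.0, 0.0


def simulate_truth(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene ground truth table for ``design``."""
    n = design.n_genes
    e = design.effect_size_log2
    counts = _class_counts(design.class_proportions, n)
    order = rng.permutation(n)

    betas = np.zeros((n, 4))
    labels = np.array(["none"] * n, dtype=object)
    expressed = np.array([f"{MAT_PLUS};{MAT_MINUS}"] * n, dtype=object)

    pos = 0
    for lab in [str(k) for k in range(1, 10)]:
        for _ in range(counts[lab]):
            g = order[pos]
            betas[g] = _plant_betas(rng, lab, e)
            labels[g] = lab
            pos += 1

    # mating-type-specific genes: expressed in a single mating type, driven by
    # the corresponding master regulator (classes 4 and 5)
    pool = order[pos:]
    need = design.n_matplus_specific + design.n_matminus_specific
    n_nonexp = int(round(design.nonexpressed_fraction * n))
    if len(pool) < need + n_nonexp:
        raise ValueError(
            "n_genes too small for the requested specific and non-expressed genes"
        )
    for g in pool[: design.n_matplus_specific]:
        betas[g] = (e, 0.0, 0.0, 0.0)
        labels[g] = "4"
        expressed[g] = MAT_PLUS
    off = design.n_matplus_specific
    for g in pool[off : off + design.n_matminus_specific]:
        betas[g] = (0.0, e, 0.0, 0.0)
        labels[g] = "5"
        expressed[g] = MAT_MINUS
    off += design.n_matminus_specific
    for g in pool[off : off + n_nonexp]:
        expressed[g] = "."

    sigma_sq = design.sigma0_sq * design.d0 / rng.chisquare(design.d0, size=n)

    width = len(str(n))
    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(n)],
            "beta_fpr1": betas[:, 0],
            "beta_fmr1": betas[:, 1],
            "beta_snp_plus": betas[:, 2],
            "beta_snp_minus": betas[:, 3],
            "planted_class": labels,
            "expressed_in": expressed,
            "sigma_sq": sigma_sq,
        }
    )
    # consistency guard: the planted label must be recomputable from the betas
    recomputed = truth.apply(
        lambda r: classify_truth(
            r.beta_fpr1, r.beta_fmr1, r.beta_snp_plus, r.beta_snp_minus
        ),
        axis=1,
    )
    mism = truth.planted_class[
        (recomputed != truth.planted_class) & (truth.planted_class != "none")
    ]
    if len(mism):
        raise AssertionError(f"planted classes inconsistent with betas: {list(mism.index)}")
    return truth


def _true_m(truth: pd.DataFrame) -> np.ndarray:
    """Expected log2 sample/reference ratio per gene x genotype.

    Functional FPR1 acts in mat+ only, functional FMR1 in mat- only; the
    mat+-linked SNP background is shared by mat+ and fpr1-, the mat--linked
    background by mat- and fmr1-.
    """
    bf = truth.beta_fpr1.to_numpy()
    bm = truth.beta_fmr1.to_numpy()
    sp = truth.beta_snp_plus.to_numpy()
    sm = truth.beta_snp_minus.to_numpy()
    m = np.zeros((len(truth), len(GENOTYPES)))
    for j, g in enumerate(GENOTYPES):
        m[:, j] = (
            bf * (g == MAT_PLUS)
            + bm * (g == MAT_MINUS)
            + sp * (g in (MAT_PLUS, FPR1_MUT))
            + sm * (g in (MAT_MINUS, FMR1_MUT))
        )
    return m


def _expressed_matrix(truth: pd.DataFrame) -> np.ndarray:
    """Boolean gene x genotype matrix of where the transcript is present.

    Mating-type-specific genes are on only in their own mating type (their
    activator is absent from both mutants); genes with ``expressed_in == '.'``
    are off everywhere and emit background-level signal.
    """
    on = np.ones((len(truth), len(GENOTYPES)), dtype=bool)
    expr = truth.expressed_in.to_numpy()
    for i, tag in enumerate(expr):
        if tag == ".":
            on[i, :] = False
        elif tag == MAT_PLUS:
            on[i, :] = [g == MAT_PLUS for g in GENOTYPES]
        elif tag == MAT_MINUS:
            on[i, :] = [g == MAT_MINUS for g in GENOTYPES]
    return on


def simulate_expression(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probe-level two-color table and its ground truth.

    Returns ``(probes, truth)``.  ``probes`` has one row per spot (gene x
    array x probe replicate) with foreground/background intensities for both
    channels and a quality flag.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    truth = simulate_truth(design, rng)

    n = design.n_genes
    reps = design.n_replicates
    n_arrays = reps * len(GENOTYPES)
    p = design.n_probe_replicates

    genotype_of_array = np.repeat(np.arange(len(GENOTYPES)), reps)
    rep_of_array = np.tile(np.arange(1, reps + 1), len(GENOTYPES))
    array_ids = [
        f"{GENOTYPES[g]}_r{r}" for g, r in zip(genotype_of_array, rep_of_array)
    ]

    m_true = _true_m(truth)[:, genotype_of_array]  # (n, arrays)
    on = _expressed_matrix(truth)[:, genotype_of_array]  # (n, arrays)
    ref_on = _expressed_matrix(truth).any(axis=1)[:, None]  # reference is a condition mix

    sigma = np.sqrt(truth.sigma_sq.to_numpy())[:, None]
    e_arr = rng.normal(0.0, 1.0, size=(n, n_arrays)) * sigma

    shape = (n, n_arrays, p)
    gene_baseline = design.baseline_log2 + rng.normal(0.0, design.baseline_sd, size=n)
    ref_log2 = gene_baseline[:, None, None] + rng.normal(
        0.0, design.ref_noise_sd, size=shape
    )
    ref_net_on = np.exp2(ref_log2)
    bsd = design.background_sd
    ref_net_off = np.abs(rng.normal(0.0, bsd, size=shape))
    ref_net = np.where(np.broadcast_to(ref_on[:, :, None], shape), ref_net_on, ref_net_off)

    m_spot = m_true[:, :, None] + e_arr[:, :, None] + rng.normal(
        0.0, design.probe_noise_sd, size=shape
    )
    sample_net_on = ref_net * np.exp2(m_spot)
    sample_net_off = np.abs(rng.normal(0.0, bsd, size=shape))
    sample_net = np.where(on[:, :, None], sample_net_on, sample_net_off)

    if design.dye_bias_amplitude:
        a_spot = 0.5 * np.log2(np.maximum(sample_net, 0.5) * np.maximum(ref_net, 0.5))
        sample_net = sample_net * np.exp2(design.dye_bias_amplitude * np.sin(a_spot))

    sample_bg = np.clip(rng.normal(design.background_mean, bsd, size=shape), 0.0, None)
    ref_bg = np.clip(rng.normal(design.background_mean, bsd, size=shape), 0.0, None)

    u = rng.random(size=shape)
    flags = np.full(shape, FLAG_GOOD, dtype=np.int64)
    b, nf, mod = design.frac_flag_bad, design.frac_flag_not_found, design.frac_flag_moderate
    flags[u < b + nf + mod] = FLAG_MODERATE
    flags[u < b + nf] = FLAG_NOT_FOUND
    flags[u < b] = FLAG_BAD

    gene_ids = truth.gene_id.to_numpy()
    probes = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_arrays * p),
            "array_id": np.tile(np.repeat(array_ids, p), n),
            "genotype": np.tile(
                np.repeat([GENOTYPES[g] for g in genotype_of_array], p), n
            ),
            "replicate": np.tile(np.repeat(rep_of_array, p), n),
            "probe": np.tile(np.arange(1, p + 1), n * n_arrays),
            "sample_fg": (sample_net + sample_bg).ravel(),
            "sample_bg": sample_bg.ravel(),
            "ref_fg": (ref_net + ref_bg).ravel(),
            "ref_bg": ref_bg.ravel(),
            "flag": flags.ravel(),
        },
        columns=list(PROBE_COLUMNS),
    )
    return probes, truth


def simulate_cq(
    n_genes: int,
    n_samples: int,
    stable_refs: int,
    efficiencies: float | np.ndarray = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 1,
    condition_effects: dict[str, float] | None = None,
    default_effect_log2: float = 1.0,
    unstable_noise_sd: float = 0.0,
    intercept: float = 35.0,
    sample_shift_sd: float = 0.2,
) -> pd.DataFrame:
    """Generate a long-format Cq table.

    The first ``stable_refs`` genes are perfectly stable housekeeping genes
    (no condition effect, no extra noise); remaining genes carry a log2
    ``condition_effects`` shift in treatment samples (defaulting to
    ``default_effect_log2`` with alternating sign) plus optional per-sample
    instability noise.  Samples split half control / half treatment.
    """
    if stable_refs < 2:
        raise ValueError(f"stable_refs must be >= 2, got {stable_refs}")
    if n_genes < stable_refs:
        raise ValueError("n_genes must be >= stable_refs")
    eff = np.broadcast_to(np.asarray(efficiencies, dtype=float), (n_genes,)).copy()
    if np.any(eff <= 1.0) or np.any(eff > 2.1):
        raise ValueError("efficiency must lie in (1, 2.1]")

    rng = np.random.default_rng(seed)
    genes = [f"q{i:02d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    condition = np.array(
        ["control" if j < n_samples // 2 else "treatment" for j in range(n_samples)]
    )

    effects = np.zeros(n_genes)
    for i in range(stable_refs, n_genes):
        effects[i] = default_effect_log2 * (1 if (i - stable_refs) % 2 == 0 else -1)
    if condition_effects:
        for gene, val in condition_effects.items():
            effects[genes.index(gene)] = val

    base = rng.uniform(6.0, 14.0, size=n_genes)
    shift = rng.normal(0.0, sample_shift_sd, size=n_samples)

    log2_expr = base[:, None] + shift[None, :]
    log2_expr += effects[:, None] * (condition == "treatment")[None, :]
    if unstable_noise_sd > 0:
        noise = rng.normal(0.0, unstable_noise_sd, size=(n_genes, n_samples))
        noise[:stable_refs, :] = 0.0
        log2_expr += noise

    cq = intercept - log2_expr / np.log2(eff)[:, None]
    rows = []
    for r in range(1, n_replicates + 1):
        obs = cq + (rng.normal(0.0, noise_sd, size=cq.shape) if noise_sd > 0 else 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat(genes, n_samples),
                    "sample_id": np.tile(samples, n_genes),
                    "condition": np.tile(condition, n_genes),
                    "replicate": r,
                    "cq": obs.ravel(),
                    "efficiency": np.repeat(eff, n_samples),
                    "is_reference": np.repeat(
                        np.arange(n_genes) < stable_refs, n_samples
                    ),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_ortholog_sets(
    genome1_size: int,
    genome2_size: int,
    n_targets1: int,
    n_targets2: int,
    planted_overlap: int | None,
    seed: int = 0,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Two species' target-gene sets joined by a 1-1 ortholog-pair list.

    Every species-1 target gene is given an ortholog in genome 2; with
    ``planted_overlap`` an exact number of those orthologs land inside the
    species-2 target set, with ``None`` the landing is uniform (hypergeometric
    overlap, the by-chance null).  Returns ``(targets1, targets2, pairs)``.
    """
    for name, val in (
        ("genome1_size", genome1_size),
        ("genome2_size", genome2_size),
        ("n_targets1", n_targets1),
        ("n_targets2", n_targets2),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if n_targets1 > genome1_size or n_targets2 > genome2_size:
        raise ValueError("target sets cannot exceed their genome size")
    if n_targets1 > genome2_size:
        raise ValueError("not enough genome-2 genes to give every target an ortholog")
    if planted_overlap is not None:
        if planted_overlap > min(n_targets1, n_targets2):
            raise ValueError(
                f"planted_overlap {planted_overlap} exceeds min target-set size"
            )
        if n_targets1 - planted_overlap > genome2_size - n_targets2:
            raise ValueError("not enough non-target genome-2 genes for the non-overlap pairs")

    rng = np.random.default_rng(seed)
    w1 = len(str(genome1_size))
    w2 = len(str(genome2_size))
    genome2 = np.array([f"pa_{i:0{w2}d}" for i in range(genome2_size)])
    targets1 = [f"sp1_{i:0{w1}d}" for i in rng.choice(genome1_size, n_targets1, replace=False)]
    t2_idx = rng.choice(genome2_size, n_targets2, replace=False)
    targets2 = list(genome2[t2_idx])
    in_t2 = np.zeros(genome2_size, dtype=bool)
    in_t2[t2_idx] = True

    if planted_overlap is None:
        partners = genome2[rng.choice(genome2_size, n_targets1, replace=False)]
    else:
        hit = genome2[rng.choice(t2_idx, planted_overlap, replace=False)]
        non_t2 = np.flatnonzero(~in_t2)
        miss = genome2[rng.choice(non_t2, n_targets1 - planted_overlap, replace=False)]
        partners = np.concatenate([hit, miss])
        partners = partners[rng.permutation(len(partners))]

    pairs = pd.DataFrame({"id_sp1": targets1, "id_sp2": partners})
    return targets1, targets2, pairs
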