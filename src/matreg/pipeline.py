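"""End-to-end workflow: simulate or load, normalise, test, classify, report."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import classify as cls
from . import interspecies as ispec
from . import microarray as ma
from .io import (
    PipelineConfig,
    read_comparison_table,
    read_gene_set,
    read_ortholog_pairs,
    read_probe_table,
    write_comparison_table,
    write_tsv,
)
from .simulate import SimulationDesign, simulate_expression

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``.

    Produces, under ``config.out_dir``: the comparison table, the
    classification table with per-class counts, the specificity calls, and
    (when ortholog inputs are given) the interspecies overlap report, plus a
    machine-readable ``summary.json``.  Returns the output bundle as a dict.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    summary: dict = {
        "thresholds": {
            "fc_cut": config.fc_cut,
            "p_cut": config.p_cut,
            "borderline_fc_low": config.borderline_fc_low,
            "ssr_cut": config.ssr_cut,
            "composite_tol": config.composite_tol,
        },
        "seed": config.seed,
    }

    signals = bg_sd = None
    if config.comparison_table:
        logger.info("stage load: comparison table %s", config.comparison_table)
        table = read_comparison_table(config.comparison_table)
        table, de_summary = ma.select_de(table, config.fc_cut, config.p_cut)
    else:
        if config.probe_table:
            logger.info("stage load: probe table %s", config.probe_table)
            probes = read_probe_table(config.probe_table)
        else:
            logger.info("stage simulate: %d genes, seed %d", config.n_genes, config.seed)
            design = SimulationDesign(n_genes=config.n_genes, seed=config.seed)
            probes, truth = simulate_expression(design)
            write_tsv(truth, out_dir / "truth.tsv")
            bundle["truth"] = truth
        try:
            de = ma.run_de(
                probes,
                span=config.span,
                fc_cut=config.fc_cut,
                p_cut=config.p_cut,
            )
        except Exception as err:
            raise RuntimeError(f"stage de failed: {err}") from err
        table = de["comparison_table"]
        de_summary = de["summary"]
        signals, bg_sd = de["signals"], de["background_sd"]
    write_comparison_table(table, out_dir / "comparison_table.tsv")
    bundle["comparison_table"] = table
    summary["selection"] = de_summary

    try:
        assignments = cls.classify_table(
            table,
            fc_cut=config.fc_cut,
            p_cut=config.p_cut,
            borderline_fc_low=config.borderline_fc_low,
            composite_tol=config.composite_tol,
        )
    except Exception as err:
        raise RuntimeError(f"stage classify failed: {err}") from err
    counts = cls.class_counts(assignments)
    summary["class_counts"] = counts

    if signals is not None:
        ssr = cls.compute_ssr(signals, bg_sd)
        de_flags = assignments.set_index("gene_id").de_matplus_vs_matminus
        specific = cls.call_specific(ssr, de_flags, ssr_cut=config.ssr_cut)
        assignments = assignments.merge(specific, on="gene_id", how="left")
        summary["specific"] = {
            lab: int((specific.specific_to == lab).sum()) for lab in ("mat+", "mat-")
        }
        bundle["specificity"] = specific
    write_tsv(assignments, out_dir / "classification.tsv")
    bundle["classification"] = assignments

    if config.targets_sp1 and config.ortholog_pairs:
        targets1 = read_gene_set(config.targets_sp1).gene_id.tolist()
        pairs = read_ortholog_pairs(config.ortholog_pairs)
        fcc = "fc_matplus_vs_matminus"
        own, _ = ma.select_de(table, config.overlap_fc_cut, config.p_cut)
        targets2 = own.gene_id[own["selected_matplus_vs_matminus"]].tolist()
        result = ispec.overlap_test(targets1, targets2, pairs, config.genome_size)
        summary["overlap"] = {
            "n_pairs": result.n_pairs,
            "n_targets_sp1": result.n_targets_sp1,
            "n_targets_sp2": result.n_targets_sp2,
            "chi2": result.chi2,
            "p": result.p,
        }
        bundle["overlap"] = result

    digest = hashlib.sha256()
    for name in sorted(p.name for p in out_dir.glob("*.tsv")):
        digest.update((out_dir / name).read_bytes())
    summary["output_sha256"] = digest.hexdigest()
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    bundle["summary"] = summary
    logger.info("pipeline done: outputs in %s (sha256 %s)", out_dir, summary["output_sha256"][:12])
    return bundle
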