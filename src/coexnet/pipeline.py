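"""End-to-end pipeline orchestration: filter -> network -> modules -> annotation.

Stages communicate through files written atomically (temp file + rename)
so a run is auditable and resumable; the motif-enrichment and orthology
stages are optional and gated by the config.  Identical config + seed
yields byte-identical outputs.  The run report records per-stage sizes,
thresholds, Table-style network statistics and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cismotif import motif_zscore, read_promoters_fasta, results_to_frame, significant_motifs
from .cpmod import clique_percolation, modules_to_frame
from .enrich import annotate_modules, read_gmt, refine_gene_annotations
from .exprfilter import compute_fpkm_threshold, filter_low_expression, read_expression_matrix
from .network import (
    calibrate_min_abs_pcc,
    compute_mutual_ranks,
    compute_pcc_pairs,
    network_statistics,
    select_edges,
)
from .rbhortho import (
    collapse_best_hsp,
    evalue_peak_threshold,
    pairs_to_frame,
    read_hits,
    reciprocal_top_hits,
    secondary_pairs,
)

logger = logging.getLogger("coexnet.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage




@dataclass
class PipelineConfig:
    """All stage inputs and parameters for one pipeline run."""

    expression: str
    gmt: str
    out_dir: str
    promoters: str | None = None
    motifs: str | None = None
    motif_gene_list: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    genome_size: int | None = None
    percentile: float = 5.0
    sigma: float = 3.0
    min_abs_pcc: float | str = 0.6  # a value in [0,1] or "auto" (permutation-calibrated)
    rank_cutoff: int = 3
    mr_cutoff: float = 30.0
    rule: str = "union"
    k: int = 5
    fdr_cutoff: float = 0.05
    z_cutoff: float = 4.0
    n_draws: int = 1000
    top_n: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.expression).exists():
            raise FileNotFoundError(f"expression matrix not found: {self.expression}")
        if not Path(self.gmt).exists():
            raise FileNotFoundError(f"GMT file not found: {self.gmt}")
        for name in ("promoters", "motifs", "motif_gene_list", "hits_ab", "hits_ba"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} not found: {path}")
        if isinstance(self.min_abs_pcc, str):
            if self.min_abs_pcc != "auto":
                raise ValueError("min_abs_pcc must be a number in [0, 1] or 'auto'")
        elif not 0 <= self.min_abs_pcc <= 1:
            raise ValueError("min_abs_pcc must be in [0, 1]")
        if self.rank_cutoff <= 0 or self.mr_cutoff <= 0 or self.k < 3:
            raise ValueError("cutoffs must be positive and k >= 3")
        if self.rule not in ("union", "intersection"):
            raise ValueError(f"unknown rule: {self.rule}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        _atomic_write(path, yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_frame(path, df, **kwargs) -> None:
    from io import StringIO

    buf = StringIO()
    df.to_csv(buf, sep="\t", index=False, **kwargs)
    _atomic_write(path, buf.getvalue())


def summarize_network(
    n_edges: int, n_nodes: int, module_sizes, genome_size: int | None = None
) -> dict:
    """Table-style network summary block.

    Mean edges per gene (2E/N) to one decimal, mean module nodes to one
    decimal, coverage percent to two decimals — half-up rounding.
    """
    from .network import _round_half_up

    block = {
        "coexpression_pairs": n_edges,
        "network_nodes": n_nodes,
        "mean_edges_per_gene": _round_half_up(2 * n_edges / n_nodes, 1) if n_nodes else 0.0,
        "module_number": len(module_sizes),
        "mean_module_nodes": (
            _round_half_up(sum(module_sizes) / len(module_sizes), 1) if module_sizes else 0.0
        ),
    }
    if genome_size:
        block["coverage_percent"] = _round_half_up(100.0 * n_nodes / genome_size, 2)
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute filter -> network -> modules -> enrichment -> refinement.

    Motif and orthology stages run only when their inputs are configured.
    Returns the run report (also written to ``out_dir/report.json``).
    A stage failure is re-raised as :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": config.config_hash(),
                    "config": config.to_dict(), "stages": {}}
    current = {"stage": "filter"}
    try:
        return _run_stages(config, out, report, current)
    except Exception as exc:
        raise StageError(current["stage"], exc) from exc


def _run_stages(config: PipelineConfig, out: Path, report: dict, current: dict) -> dict:
    # --- filter ---------------------------------------------------------
    matrix = read_expression_matrix(config.expression)
    threshold = compute_fpkm_threshold(matrix, config.percentile, config.sigma)
    filtered, removal = filter_low_expression(matrix, threshold)
    _atomic_write(out / "threshold.json", json.dumps(threshold.to_dict(), indent=1))
    _atomic_frame(out / "removal_report.tsv", removal.to_frame(matrix))
    filtered.to_tsv(out / "expression.filtered.tsv")
    report["stages"]["filter"] = {
        "genes_in": matrix.shape[0], "genes_out": filtered.shape[0],
        "samples": matrix.shape[1], "threshold": threshold.threshold,
        "removed": len(removal.removed),
    }
    logger.info("filter: %d -> %d genes (threshold %.4g)",
                matrix.shape[0], filtered.shape[0], threshold.threshold)

    current["stage"] = "network"
    # --- network --------------------------------------------------------
    min_abs_pcc = config.min_abs_pcc
    if min_abs_pcc == "auto":
        min_abs_pcc = calibrate_min_abs_pcc(filtered, seed=config.seed)
        logger.info("network: calibrated min_abs_pcc = %.3f", min_abs_pcc)
    pairs = compute_pcc_pairs(filtered, min_abs_pcc)
    ranked = compute_mutual_ranks(pairs)
    network = select_edges(ranked, config.rank_cutoff, config.mr_cutoff,
                           config.rule, genome_size=config.genome_size)
    network.to_tsv(out / "edges.tsv")
    genome_size = config.genome_size or matrix.shape[0]
    stats = network_statistics(network, genome_size=genome_size)
    _atomic_write(out / "network_stats.json", json.dumps(stats, indent=1))
    report["stages"]["network"] = {
        "candidate_pairs": len(pairs), "edges": network.n_edges,
        "min_abs_pcc": float(min_abs_pcc),
        "nodes": network.n_nodes,
        "constant_genes_dropped": pairs.attrs.get("n_constant_dropped", 0),
        **stats,
    }
    logger.info("network: %d pairs -> %d edges over %d nodes",
                len(pairs), network.n_edges, network.n_nodes)

    current["stage"] = "modules"
    # --- modules --------------------------------------------------------
    modules = clique_percolation(network, config.k)
    _atomic_frame(out / "modules.tsv", modules_to_frame(modules))
    module_sizes = [m.size for m in modules]
    report["stages"]["modules"] = {
        "k": config.k, "module_count": len(modules),
        "mean_module_size": (sum(module_sizes) / len(module_sizes)) if modules else 0.0,
    }
    logger.info("modules: %d at k=%d", len(modules), config.k)

    current["stage"] = "enrichment"
    # --- enrichment + refinement ---------------------------------------
    genesets = read_gmt(config.gmt, namespace="GO")
    genesets = genesets.restricted_to(set(filtered.gene_ids))
    annotations = annotate_modules(modules, genesets, config.fdr_cutoff)
    _atomic_frame(out / "module_annotations.tsv", annotations,
                  float_format="%.6g")
    refined = refine_gene_annotations(network, modules, annotations,
                                      genesets, config.fdr_cutoff)
    _atomic_frame(out / "refined_annotations.tsv", refined, float_format="%.6g")
    n_annotated_modules = annotations.loc[annotations["significant"], "subject"].nunique()
    report["stages"]["enrichment"] = {
        "terms": len(genesets.terms),
        "annotated_modules": int(n_annotated_modules),
        "unannotated_modules": len(modules) - int(n_annotated_modules),
        "percent_genes_annotated": refined.attrs.get("percent_genes_annotated", 0.0),
    }
    logger.info("enrichment: %d/%d modules annotated", n_annotated_modules, len(modules))

    current["stage"] = "motifs"
    # --- optional: motif enrichment ------------------------------------
    if config.promoters and config.motifs and config.motif_gene_list:
        promoters = read_promoters_fasta(config.promoters)
        with open(config.motif_gene_list) as fh:
            gene_list = [line.strip() for line in fh if line.strip()]
        motifs = []
        with open(config.motifs) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    name, consensus = line.split("\t")
                    motifs.append((name, consensus))
        results = [
            motif_zscore(promoters, gene_list, consensus,
                         n_draws=config.n_draws, seed=config.seed + i)
            for i, (name, consensus) in enumerate(motifs)
        ]
        _atomic_frame(out / "motif_results.tsv", results_to_frame(results),
                      float_format="%.6g")
        significant = significant_motifs(results)
        report["stages"]["motifs"] = {
            "motifs_tested": len(results),
            "significant": len(significant),
        }
        logger.info("motifs: %d/%d significant", len(significant), len(results))

    current["stage"] = "orthology"
    # --- optional: orthology -------------------------------------------
    if config.hits_ab and config.hits_ba:
        hits_ab = collapse_best_hsp(read_hits(config.hits_ab))
        hits_ba = collapse_best_hsp(read_hits(config.hits_ba))
        best = reciprocal_top_hits(hits_ab, hits_ba, config.top_n)
        try:
            peak = evalue_peak_threshold(best)
            secondary = secondary_pairs(hits_ab, hits_ba, peak, best)
        except ValueError:
            peak, secondary = None, []
        _atomic_frame(out / "orthologs.tsv", pairs_to_frame(best + secondary),
                      float_format="%.6g")
        report["stages"]["orthology"] = {
            "best_pairs": len(best), "secondary_pairs": len(secondary),
            "evalue_peak": peak,
        }
        logger.info("orthology: %d best, %d secondary", len(best), len(secondary))

    current["stage"] = "report"
    report["summary"] = summarize_network(
        network.n_edges, network.n_nodes, module_sizes, genome_size
    )
    _atomic_write(out / "report.json", json.dumps(report, indent=1, sort_keys=True))
    return report
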