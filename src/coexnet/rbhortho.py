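"""Reciprocal-best-hit orthology from tabular protein alignment hits.

Consumes 12-column tabular alignments (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore), one table per
direction.  Best-tier pairs are reciprocal top-N hits (default N = 3: b in
a's top three AND a in b's top three, by ascending E-value).  The peak of
the log10 E-value distribution of best pairs then sets a threshold below
which additional reciprocal pairs qualify as secondary-tier orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

EVALUE_FLOOR = 1e-180  # zero E-values mapped here before log transform


def read_hits(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed alignment table {path}: {exc}") from exc
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-values")
    return df


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def collapse_best_hsp(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per (query, subject): lowest E-value, ties by highest bitscore."""
    df = hits.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["qseqid", "sseqid", "evalue", "bitscore", "_order"],
                        ascending=[True, True, True, False, True], kind="mergesort")
    df = df.drop_duplicates(["qseqid", "sseqid"], keep="first")
    return df.drop(columns="_order").reset_index(drop=True)


def _rank_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-query subject ranks: E-value asc, bitscore desc, subject id asc."""
    df = hits.sort_values(["qseqid", "evalue", "bitscore", "sseqid"],
                          ascending=[True, True, False, True], kind="mergesort").copy()
    df["rank"] = df.groupby("qseqid", sort=False).cumcount() + 1
    return df


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    tier: str  # "best" | "secondary"
    rank_a: int  # b's rank in a's hit list
    rank_b: int
    min_e_value: float


def reciprocal_top_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, top_n: int = 3
) -> list[OrthologPair]:
    """Pairs (a, b) with b in a's top-N subjects and a in b's top-N subjects."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if hits_ab.empty or hits_ba.empty:
        return []
    ranked_ab = _rank_hits(hits_ab)
    ranked_ba = _rank_hits(hits_ba)
    ab = ranked_ab[ranked_ab["rank"] <= top_n]
    ba = ranked_ba[ranked_ba["rank"] <= top_n]
    ba_lookup = {(q, s): (r, e) for q, s, r, e in
                 zip(ba["qseqid"], ba["sseqid"], ba["rank"], ba["evalue"])}
    pairs = []
    for a, b, rank_a, e_ab in zip(ab["qseqid"], ab["sseqid"], ab["rank"], ab["evalue"]):
        hit = ba_lookup.get((b, a))
        if hit is None:
            continue
        rank_b, e_ba = hit
        pairs.append(OrthologPair(
            gene_a=a, gene_b=b, tier="best",
            rank_a=int(rank_a), rank_b=int(rank_b),
            min_e_value=float(min(e_ab, e_ba)),
        ))
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def evalue_peak_threshold(best_pairs) -> float:
    """E-value at the modal bin of the best pairs' log10 E-value histogram.

    Freedman-Diaconis bin width; ties between equally tall bins resolve
    toward the more significant (smaller E-value) bin.  Requires enough
    pairs (>= 20) for the histogram to carry mass.
    """
    evalues = np.array([max(p.min_e_value, EVALUE_FLOOR) for p in best_pairs])
    if evalues.size < 20:
        raise ValueError("need at least 20 best pairs for a peak estimate")
    log_e = np.log10(evalues)
    if np.ptp(log_e) == 0.0:
        return float(evalues[0])  # degenerate histogram
    counts, edges = np.histogram(log_e, bins="fd")
    modal = int(np.argmax(counts))  # argmax takes the first (smallest) tied bin
    center = (edges[modal] + edges[modal + 1]) / 2.0
    return float(10.0 ** center)


def secondary_pairs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    threshold: float,
    best_pairs,
    comparison: str = "min",
) -> list[OrthologPair]:
    """Reciprocal pairs (any rank) below the E-value threshold, best tier excluded.

    ``comparison="min"`` (default) compares the smaller of the two
    directional E-values with the threshold; ``"max"`` requires both
    directions below it.
    """
    if comparison not in ("min", "max"):
        raise ValueError(f"unknown comparison: {comparison}")
    ranked_ab = _rank_hits(hits_ab)
    ranked_ba = _rank_hits(hits_ba)
    ba_lookup = {(q, s): (r, e) for q, s, r, e in
                 zip(ranked_ba["qseqid"], ranked_ba["sseqid"],
                     ranked_ba["rank"], ranked_ba["evalue"])}
    best = {(p.gene_a, p.gene_b) for p in best_pairs}
    pairs = []
    for a, b, rank_a, e_ab in zip(ranked_ab["qseqid"], ranked_ab["sseqid"],
                                  ranked_ab["rank"], ranked_ab["evalue"]):
        if (a, b) in best:
            continue
        hit = ba_lookup.get((b, a))
        if hit is None:
            continue
        rank_b, e_ba = hit
        stat = min(e_ab, e_ba) if comparison == "min" else max(e_ab, e_ba)
        if stat < threshold:
            pairs.append(OrthologPair(
                gene_a=a, gene_b=b, tier="secondary",
                rank_a=int(rank_a), rank_b=int(rank_b),
                min_e_value=float(min(e_ab, e_ba)),
            ))
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "tier": [p.tier for p in pairs],
            "rank_a": [p.rank_a for p in pairs],
            "rank_b": [p.rank_b for p in pairs],
            "min_e_value": [p.min_e_value for p in pairs],
        }
    )
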