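"""Coexpression-network construction by Pearson correlation and mutual rank.

For every retained gene pair the Pearson correlation coefficient (PCC) is
computed across samples; each gene then ranks its partners, and a pair's
mutual rank MR(AB) = sqrt(Rank(A->B) * Rank(B->A)) is the geometric mean of
the two directional ranks.  Edges are selected by the rule
"unidirectional rank <= 3 OR MR <= 30" (both cutoffs configurable), after
which network statistics (nodes, edges, mean degree, genome coverage) are
reported.  An ROC sweep over MR cutoffs against a labelled gold standard
supports cutoff evaluation.

Ranks are computed within sign class by default: a gene ranks its positive
partners by descending PCC and, independently, its negative partners by
ascending PCC, so that negative coexpression can survive rank-based
selection.  A combined-|PCC| ranking mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "mr", "sign"]


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("at least 3 samples required")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        raise ValueError("undefined correlation: constant vector")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def calibrate_min_abs_pcc(
    matrix,
    quantile: float = 99.5,
    n_permutations: int = 3,
    seed: int = 0,
) -> float:
    """Data-driven weak-pair cutoff from a permutation null.

    Permuting each gene's samples independently destroys all coexpression
    while preserving every marginal; the requested upper quantile of the
    null |PCC| distribution is then a cutoff exceeded by almost no chance
    correlation at this sample size.  With few samples (the regime where
    chance correlations are large) this calibration matters far more than
    any fixed default.
    """
    if not 0 < quantile < 100:
        raise ValueError("quantile must be in (0, 100)")
    rng = np.random.default_rng(seed)
    values = matrix.values
    values = values[values.std(axis=1) > 0]
    if len(values) < 3:
        raise ValueError("need at least 3 non-constant genes to calibrate")
    iu = np.triu_indices(len(values), k=1)
    levels = []
    for _ in range(n_permutations):
        permuted = np.array([rng.permutation(row) for row in values])
        null_pcc = np.corrcoef(permuted)[iu]
        levels.append(np.percentile(np.abs(null_pcc), quantile))
    return float(np.mean(levels))


def compute_pcc_pairs(matrix, min_abs_pcc: float = 0.6) -> pd.DataFrame:
    """All unordered gene pairs with |PCC| >= min_abs_pcc.

    Genes with constant expression are excluded (their correlation is
    undefined); the number dropped is recorded in ``df.attrs``.
    Pairs are canonical: gene_a < gene_b, sorted for reproducible diffs.
    """
    if not 0.0 <= min_abs_pcc <= 1.0:
        raise ValueError("min_abs_pcc must be in [0, 1]")
    values = matrix.values
    genes = np.asarray(matrix.gene_ids)
    constant = values.std(axis=1) == 0.0
    n_constant = int(constant.sum())
    values = values[~constant]
    genes = genes[~constant]
    n = len(genes)
    if n < 2:
        out = pd.DataFrame(columns=["gene_a", "gene_b", "pcc"])
        out.attrs["n_constant_dropped"] = n_constant
        return out
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    pcc = corr[iu, ju]
    keep = np.abs(pcc) >= min_abs_pcc
    ga, gb = genes[iu[keep]], genes[ju[keep]]
    swap = ga > gb
    ga2 = np.where(swap, gb, ga)
    gb2 = np.where(swap, ga, gb)
    out = pd.DataFrame({"gene_a": ga2, "gene_b": gb2, "pcc": pcc[keep]})
    out = out.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_constant_dropped"] = n_constant
    return out


def compute_mutual_ranks(
    pairs: pd.DataFrame,
    universe: set[str] | None = None,
    ranking: str = "signed",
) -> pd.DataFrame:
    """Directional PCC ranks and mutual ranks for a pair table.

    Under ``ranking="signed"`` each gene keeps two independent partner
    lists: positive partners ranked 1,2,... by descending PCC and negative
    partners by ascending PCC (most negative first).  Under
    ``ranking="abs"`` a single list ranked by descending |PCC| is used.
    Ties are broken by lexicographic partner id.  MR = sqrt(rank_ab*rank_ba).
    """
    if ranking not in ("signed", "abs"):
        raise ValueError(f"unknown ranking mode: {ranking}")
    if pairs.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    if universe is not None:
        referenced = set(pairs["gene_a"]) | set(pairs["gene_b"])
        outside = referenced - set(universe)
        if outside:
            raise ValueError(f"pairs reference genes outside universe: {sorted(outside)[:5]}")

    # view each unordered pair from both endpoints
    fwd = pairs[["gene_a", "gene_b", "pcc"]].rename(
        columns={"gene_a": "source", "gene_b": "partner"}
    )
    rev = pairs[["gene_b", "gene_a", "pcc"]].rename(
        columns={"gene_b": "source", "gene_a": "partner"}
    )
    directed = pd.concat([fwd, rev], ignore_index=True)
    if ranking == "signed":
        directed["sign_neg"] = directed["pcc"] < 0
        # positive: descending pcc; negative: ascending pcc; ties by partner id
        directed["key"] = np.where(directed["sign_neg"], directed["pcc"], -directed["pcc"])
        group_cols = ["source", "sign_neg"]
    else:
        directed["key"] = -directed["pcc"].abs()
        group_cols = ["source"]
    directed = directed.sort_values(group_cols + ["key", "partner"], kind="mergesort")
    directed["rank"] = directed.groupby(group_cols, sort=False).cumcount() + 1

    rank_lookup = dict(
        zip(zip(directed["source"], directed["partner"]), directed["rank"])
    )
    out = pairs.copy()
    out["rank_ab"] = [rank_lookup[(a, b)] for a, b in zip(out["gene_a"], out["gene_b"])]
    out["rank_ba"] = [rank_lookup[(b, a)] for a, b in zip(out["gene_a"], out["gene_b"])]
    out["mr"] = np.sqrt(out["rank_ab"].to_numpy(float) * out["rank_ba"].to_numpy(float))
    out["sign"] = np.where(out["pcc"] < 0, "negative", "positive")
    out = out[PAIR_COLUMNS].sort_values(["gene_a", "gene_b"], kind="mergesort")
    out.attrs = dict(pairs.attrs)
    return out.reset_index(drop=True)


@dataclass
class CoexpressionNetwork:
    """Selected coexpression edges plus derived statistics."""

    edges: pd.DataFrame
    genome_size: int | None = None
    nodes: set[str] = field(init=False)

    def __post_init__(self) -> None:
        if (self.edges["gene_a"] == self.edges["gene_b"]).any():
            raise ValueError("self-edges are not allowed")
        key = list(zip(self.edges["gene_a"], self.edges["gene_b"]))
        if len(key) != len(set(key)):
            raise ValueError("duplicate edges")
        self.nodes = set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.nodes}
        for a, b in zip(self.edges["gene_a"], self.edges["gene_b"]):
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_tsv(self, path) -> None:
        out = self.edges.copy()
        out["pcc"] = out["pcc"].map(lambda v: f"{v:.6f}")
        out["mr"] = out["mr"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> CoexpressionNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return CoexpressionNetwork(edges=df)


def select_edges(
    ranked: pd.DataFrame,
    rank_cutoff: int = 3,
    mr_cutoff: float = 30.0,
    rule: str = "union",
    strict: bool = False,
    genome_size: int | None = None,
) -> CoexpressionNetwork:
    """Select network edges by directional rank and mutual rank.

    ``union`` (default) keeps a pair iff min(rank_ab, rank_ba) <= rank_cutoff
    OR mr <= mr_cutoff; ``intersection`` requires both.  ``strict=True``
    switches both comparisons to strict inequality.
    """
    if rank_cutoff <= 0 or mr_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown rule: {rule}")
    min_rank = np.minimum(ranked["rank_ab"], ranked["rank_ba"])
    if strict:
        rank_ok = min_rank < rank_cutoff
        mr_ok = ranked["mr"] < mr_cutoff
    else:
        rank_ok = min_rank <= rank_cutoff
        mr_ok = ranked["mr"] <= mr_cutoff
    keep = (rank_ok | mr_ok) if rule == "union" else (rank_ok & mr_ok)
    edges = ranked.loc[keep].reset_index(drop=True)
    return CoexpressionNetwork(edges=edges, genome_size=genome_size)


def _round_half_up(value: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def network_statistics(network: CoexpressionNetwork, genome_size: int | None = None) -> dict:
    """Edge/node counts, mean edges per gene (2E/N) and genome coverage.

    Reported values follow the conventional summary-table rounding: mean
    degree to one decimal, coverage percent to two decimals (half-up).
    """
    genome_size = genome_size if genome_size is not None else network.genome_size
    n, e = network.n_nodes, network.n_edges
    if n == 0:
        return {
            "n_edges": 0,
            "n_nodes": 0,
            "mean_edges_per_gene": 0.0,
            "coverage_percent": 0.0,
            "warning": "empty network",
        }
    stats = {
        "n_edges": e,
        "n_nodes": n,
        "mean_edges_per_gene": _round_half_up(2 * e / n, 1),
    }
    if genome_size:
        if genome_size < n:
            raise ValueError("genome_size smaller than node count")
        stats["coverage_percent"] = _round_half_up(100.0 * n / genome_size, 2)
    return stats


def degree_distribution(network: CoexpressionNetwork) -> tuple[pd.DataFrame, float | None]:
    """Exact degree histogram plus a log-log linear-fit slope.

    The slope is a descriptive scale-free diagnostic only (fit of
    log(count) against log(degree) over degrees >= 1).
    """
    degrees = pd.concat([network.edges["gene_a"], network.edges["gene_b"]]).value_counts()
    hist = degrees.value_counts().sort_index()
    table = pd.DataFrame({"degree": hist.index.astype(int), "gene_count": hist.to_numpy()})
    slope = None
    mask = table["degree"] >= 1
    if mask.sum() >= 2:
        slope = float(
            np.polyfit(np.log(table.loc[mask, "degree"]), np.log(table.loc[mask, "gene_count"]), 1)[0]
        )
    return table, slope


def evaluate_cutoffs_roc(
    ranked: pd.DataFrame,
    positives: set[tuple[str, str]],
    negatives: set[tuple[str, str]],
) -> tuple[pd.DataFrame, float]:
    """ROC over MR thresholds against labelled gold-standard pairs.

    A pair scores by -MR (lower MR = stronger edge); labelled pairs absent
    from the ranked table score as non-edges (-inf).  Returns the ROC
    points (mr_cutoff, fpr, tpr) and the trapezoidal AUC.
    """
    if not positives or not negatives:
        raise ValueError("both label sets must be non-empty")
    positives = {tuple(sorted(p)) for p in positives}
    negatives = {tuple(sorted(p)) for p in negatives}
    if positives & negatives:
        raise ValueError("label sets must be disjoint")
    mr_lookup = dict(zip(zip(ranked["gene_a"], ranked["gene_b"]), ranked["mr"]))
    labels, scores, mrs = [], [], []
    for label, pairs in ((1, positives), (0, negatives)):
        for pair in sorted(pairs):
            mr = mr_lookup.get(pair, math.inf)
            labels.append(label)
            scores.append(-min(mr, 1e12))  # finite sentinel for non-edges
            mrs.append(mr)
    from sklearn.metrics import roc_curve

    if len(set(scores)) == 1:  # all tied: chance-level by convention
        points = pd.DataFrame({"mr_cutoff": [mrs[0]], "fpr": [1.0], "tpr": [1.0]})
        return points, 0.5
    fpr, tpr, thresh = roc_curve(labels, scores, drop_intermediate=False)
    points = pd.DataFrame({"mr_cutoff": -thresh, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc
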