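"""Gene-set over-representation analysis and annotation refinement.

Module annotation uses the one-sided Fisher exact test (the hypergeometric
upper tail P(X >= overlap)) per (module, term), Benjamini-Hochberg FDR
within each term namespace, and a significance cutoff of FDR < 0.05.
Annotation refinement is two-step: genes first inherit their modules'
significant terms, then every network gene is tested against its direct
coexpression neighborhood and terms passing FDR are appended.  Every
refined record carries a provenance tag (module-inherited vs
neighbor-derived).

An optional Z-score flag re-scores a term's overlap against random
same-size gene draws, marking very strong terms (Z > 4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

RESULT_COLUMNS = [
    "subject",
    "term",
    "namespace",
    "overlap",
    "subject_size",
    "term_size",
    "background_size",
    "p_value",
    "fdr",
    "significant",
]


@dataclass
class GeneSetCollection:
    """Term -> gene-set mapping over a background universe (GMT-style)."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]
    namespaces: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"empty term: {term}")
            outside = genes - self.background
            if outside:
                raise ValueError(
                    f"term {term} has genes outside background: {sorted(outside)[:5]}"
                )
        for term in self.terms:
            self.namespaces.setdefault(term, "other")

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every term and the background with ``universe``; drop emptied terms."""
        terms = {
            t: frozenset(g & universe) for t, g in self.terms.items() if g & universe
        }
        return GeneSetCollection(
            terms=terms,
            background=frozenset(self.background & universe),
            namespaces={t: self.namespaces[t] for t in terms},
            descriptions={t: self.descriptions.get(t, "") for t in terms},
        )


def read_gmt(path, background: set[str] | None = None, namespace: str = "other") -> GeneSetCollection:
    """Strict GMT reader: term TAB description TAB gene TAB gene ..."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in terms:
                raise ValueError(f"GMT line {lineno}: duplicate term {term}")
            terms[term] = frozenset(genes)
            descriptions[term] = desc
    if background is None:
        background = set().union(*terms.values()) if terms else set()
    return GeneSetCollection(
        terms=terms,
        background=frozenset(background),
        namespaces={t: namespace for t in terms},
        descriptions=descriptions,
    )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.terms):
            genes = "\t".join(sorted(collection.terms[term]))
            fh.write(f"{term}\t{collection.descriptions.get(term, '')}\t{genes}\n")


def fisher_enrichment(
    subject_genes: set[str], term_genes: set[str], background: set[str]
) -> dict:
    """One-sided over-representation p-value: P(X >= overlap), hypergeometric.

    X counts term genes in a random subject-size draw from the background.
    """
    subject_genes, term_genes, background = set(subject_genes), set(term_genes), set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    offenders = (subject_genes | term_genes) - background
    if offenders:
        raise ValueError(f"genes outside background: {sorted(offenders)[:5]}")
    overlap = len(subject_genes & term_genes)
    n_bg, n_term, n_subj = len(background), len(term_genes), len(subject_genes)
    p = float(hypergeom.sf(overlap - 1, n_bg, n_term, n_subj))
    return {
        "overlap": overlap,
        "subject_size": n_subj,
        "term_size": n_term,
        "background_size": n_bg,
        "p_value": min(p, 1.0),
    }


def bh_fdr(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Bonferroni via method=)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method=method)[1]


def annotate_modules(
    modules,
    genesets: GeneSetCollection,
    fdr_cutoff: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Fisher test per (module, term); FDR within each namespace.

    Module genes outside the background are dropped (with a count in
    ``df.attrs``); modules with no significant term are left unannotated.
    """
    if not genesets.terms:
        raise ValueError("empty gene-set collection")
    background = set(genesets.background)
    rows = []
    n_dropped = 0
    for module in modules:
        genes = set(module.genes) & background
        n_dropped += len(module.genes) - len(genes)
        if not genes:
            continue
        for term, term_genes in genesets.terms.items():
            res = fisher_enrichment(genes, term_genes, background)
            rows.append(
                {
                    "subject": module.module_id,
                    "term": term,
                    "namespace": genesets.namespaces[term],
                    **res,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
        df.attrs["n_genes_outside_background"] = n_dropped
        return df
    df["fdr"] = np.nan
    for _, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "p_value"], method=method)
    df["significant"] = df["fdr"] < fdr_cutoff
    df = df.sort_values(["subject", "fdr", "term"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_genes_outside_background"] = n_dropped
    return df[RESULT_COLUMNS]


def refine_gene_annotations(
    network,
    modules,
    module_annotations: pd.DataFrame,
    genesets: GeneSetCollection,
    fdr_cutoff: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-step per-gene annotation refinement.

    Step 1: each gene inherits its modules' significant terms.  Step 2: for
    every network gene, Fisher enrichment of each term against the gene's
    direct-neighbor set, FDR across terms per gene; passing terms are
    appended as neighbor-derived.  Inherited records are never removed.
    """
    sig = module_annotations[module_annotations["significant"]]
    sig_terms_by_module: dict[str, list[str]] = {}
    for row in sig.itertuples():
        sig_terms_by_module.setdefault(row.subject, []).append(row.term)

    records: list[dict] = []
    seen: set[tuple[str, str]] = set()
    for module in modules:
        for term in sig_terms_by_module.get(module.module_id, []):
            for gene in sorted(module.genes):
                if (gene, term) not in seen:
                    seen.add((gene, term))
                    records.append(
                        {"gene_id": gene, "term": term,
                         "namespace": genesets.namespaces.get(term, "other"),
                         "provenance": "module", "fdr": np.nan}
                    )

    background = set(genesets.background)
    term_items = sorted(genesets.terms.items())
    for gene, neighbors in sorted(network.neighbors().items()):
        subject = neighbors & background
        if not subject:
            continue
        p_values, terms = [], []
        for term, term_genes in term_items:
            res = fisher_enrichment(subject, term_genes, background)
            p_values.append(res["p_value"])
            terms.append(term)
        fdrs = bh_fdr(p_values, method=method)
        for term, fdr in zip(terms, fdrs):
            if fdr < fdr_cutoff and (gene, term) not in seen:
                seen.add((gene, term))
                records.append(
                    {"gene_id": gene, "term": term,
                     "namespace": genesets.namespaces[term],
                     "provenance": "neighbors", "fdr": float(fdr)}
                )
    df = pd.DataFrame(records, columns=["gene_id", "term", "namespace", "provenance", "fdr"])
    df = df.sort_values(["gene_id", "term"], kind="mergesort").reset_index(drop=True)
    n_annotated = df["gene_id"].nunique()
    df.attrs["percent_genes_annotated"] = (
        100.0 * n_annotated / network.n_nodes if network.n_nodes else 0.0
    )
    return df


def term_zscore(
    subject_genes: set[str],
    term_genes: set[str],
    background: set[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Z of the observed overlap vs random same-size gene draws."""
    rng = np.random.default_rng(seed)
    background_arr = np.array(sorted(background))
    term = set(term_genes)
    observed = len(set(subject_genes) & term)
    size = len(set(subject_genes) & set(background))
    draws = np.empty(n_draws)
    for i in range(n_draws):
        sample = rng.choice(background_arr, size=size, replace=False)
        draws[i] = len(term.intersection(sample))
    mean, sd = float(draws.mean()), float(draws.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else np.nan
    return {"observed": observed, "null_mean": mean, "null_sd": sd,
            "z": z, "degenerate_null": sd == 0.0}


def term_zscore_flag(
    results: pd.DataFrame,
    subjects: dict[str, frozenset[str] | set[str]],
    genesets: GeneSetCollection,
    z_cutoff: float = 4.0,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag enrichment results whose overlap Z-score exceeds ``z_cutoff``.

    ``subjects`` maps each result's subject id to its gene set (needed to
    rebuild the randomized null).  Degenerate nulls (sd = 0) are reported
    with z = NaN and never flagged.
    """
    out = results.copy()
    zs, flags = [], []
    for i, row in enumerate(out.itertuples()):
        res = term_zscore(
            set(subjects[row.subject]) & set(genesets.background),
            genesets.terms[row.term],
            set(genesets.background),
            n_draws=n_draws,
            seed=seed + i,
        )
        zs.append(res["z"])
        flags.append((not res["degenerate_null"]) and res["z"] > z_cutoff)
    out["z"] = zs
    out["z_flagged"] = flags
    return out[out["z_flagged"]].reset_index(drop=True)
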