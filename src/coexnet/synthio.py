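"""Seeded synthetic inputs with recorded ground truth.

Every pipeline stage can be exercised without any external download: this
module generates an FPKM-like expression matrix with planted co-regulated
gene blocks, gene-set collections aligned to those blocks, promoter
sequences with a motif planted at an elevated rate in a target list, and
reciprocal alignment-hit tables with a known ortholog map.  All randomness
flows from one explicit integer seed through `numpy.random.default_rng`;
regeneration with the same seed reproduces identical artifacts
byte-for-byte.

The expression model is a latent-factor block design: genes of a block
share a per-sample Gaussian factor mixed with independent noise
(latent correlation ~ rho), and the latent value is exponentiated onto a
per-gene lognormal baseline, giving non-negative heavy-tailed marginals.
A small fraction of genes is "unexpressed" (uniform below a low ceiling in
every sample) so the 3-sigma filter has a non-trivial target population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cismotif import IUPAC, PromoterSet
from .enrich import GeneSetCollection
from .exprfilter import ExpressionMatrix
from .rbhortho import HIT_COLUMNS


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated artifact set."""

    seed: int
    planted_blocks: dict[str, frozenset[str]] = field(default_factory=dict)
    unexpressed_genes: frozenset[str] = frozenset()
    aligned_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    motif_target_genes: frozenset[str] = frozenset()
    motif_insertions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    ortholog_map: frozenset[tuple[str, str]] = frozenset()

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "planted_blocks": {k: sorted(v) for k, v in sorted(self.planted_blocks.items())},
            "unexpressed_genes": sorted(self.unexpressed_genes),
            "aligned_terms": {k: sorted(v) for k, v in sorted(self.aligned_terms.items())},
            "motif_target_genes": sorted(self.motif_target_genes),
            "motif_insertions": {k: v for k, v in sorted(self.motif_insertions.items())},
            "ortholog_map": sorted(list(p) for p in self.ortholog_map),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            planted_blocks={k: frozenset(v) for k, v in payload["planted_blocks"].items()},
            unexpressed_genes=frozenset(payload["unexpressed_genes"]),
            aligned_terms={k: frozenset(v) for k, v in payload["aligned_terms"].items()},
            motif_target_genes=frozenset(payload["motif_target_genes"]),
            motif_insertions={
                k: [(int(p), s) for p, s in v]
                for k, v in payload["motif_insertions"].items()
            },
            ortholog_map=frozenset(tuple(p) for p in payload["ortholog_map"]),
        )


def _block_factors(n_blocks: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Per-block latent sample profiles, mutually orthogonal where possible.

    Ten independent Gaussian draws in a 12-sample space carry chance
    pairwise correlations large enough to confound distinct blocks, so the
    first min(n_blocks, n_samples) factors are an orthonormal random frame
    (QR of a Gaussian matrix) scaled to unit per-sample variance; any
    factors beyond the space's dimension are plain Gaussian draws.
    """
    n_orth = min(n_blocks, n_samples)
    q, _ = np.linalg.qr(rng.standard_normal((n_samples, n_orth)))
    factors = (q * np.sqrt(n_samples)).T
    if n_blocks > n_orth:
        extra = rng.standard_normal((n_blocks - n_orth, n_samples))
        factors = np.vstack([factors, extra])
    return factors


def generate_expression(
    n_genes: int = 500,
    n_samples: int = 12,
    n_blocks: int = 10,
    block_size: int = 20,
    rho: float = 0.95,
    noise_sd: float = 1.0,
    seed: int = 0,
    unexpressed_fraction: float = 0.04,
    unexpressed_ceiling: float = 0.01,
    base_log_mean: float = 1.0,
    base_log_sd: float = 1.0,
    latent_sd: float = 0.6,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted co-regulated blocks.

    Block genes share a per-sample latent factor: the latent value is
    sqrt(rho) * factor + sqrt(1 - rho) * noise_sd * eps, so with
    noise_sd = 1 the latent pairwise correlation is exactly rho (rho = 1
    with noise_sd = 0 gives perfectly proportional FPKM profiles).  FPKM
    is exp(base + latent_sd * latent): ``latent_sd`` sets the within-gene
    log-scale variation across samples (default 0.6, about a 1.8-fold sd
    — typical of a developmental series), keeping the realized FPKM-scale
    correlation close to rho; the per-gene baseline is lognormal (clipped
    below so expressed genes stay clear of the low-expression threshold).
    ``unexpressed_fraction`` of genes are instead uniform in
    [0, unexpressed_ceiling] in every sample.
    """
    if n_genes <= 0 or n_samples < 3 or n_blocks < 0 or block_size <= 0:
        raise ValueError("non-positive dimensions")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_block_genes = n_blocks * block_size
    n_unexpressed = int(round(unexpressed_fraction * n_genes))
    if n_block_genes + n_unexpressed > n_genes:
        raise ValueError("blocks plus unexpressed genes exceed n_genes")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]

    latent = rng.standard_normal((n_genes, n_samples)) * noise_sd
    factors = _block_factors(n_blocks, n_samples, rng) if n_blocks else None
    blocks: dict[str, frozenset[str]] = {}
    cursor = 0
    for b in range(n_blocks):
        members = list(range(cursor, cursor + block_size))
        cursor += block_size
        latent[members] = (
            np.sqrt(rho) * factors[b]
            + np.sqrt(1.0 - rho) * latent[members]
        )
        blocks[f"B{b + 1:02d}"] = frozenset(gene_ids[i] for i in members)

    base = base_log_mean + base_log_sd * rng.standard_normal(n_genes)
    base = np.maximum(base, -0.5)  # keep expressed genes clear of the filter
    fpkm = np.exp(base[:, None] + latent_sd * latent)

    unexpressed_idx = rng.choice(
        np.arange(n_block_genes, n_genes), size=n_unexpressed, replace=False
    ) if n_unexpressed else np.array([], dtype=int)
    fpkm[unexpressed_idx] = rng.uniform(
        0.0, unexpressed_ceiling, size=(n_unexpressed, n_samples)
    )

    df = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = SyntheticTruth(
        seed=seed,
        planted_blocks=blocks,
        unexpressed_genes=frozenset(gene_ids[i] for i in unexpressed_idx),
    )
    return ExpressionMatrix(df), truth


def generate_genesets(
    truth: SyntheticTruth,
    n_noise_terms: int = 20,
    jitter: float = 0.1,
    seed: int = 0,
    universe: list[str] | None = None,
    noise_term_sizes: tuple[int, int] = (5, 30),
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Gene sets aligned to planted blocks plus random noise terms.

    One term per planted block with round(jitter * size) members swapped
    for random off-block genes, plus ``n_noise_terms`` random sets.  The
    universe defaults to all genes referenced in the truth ledger.
    """
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = sorted(set().union(*truth.planted_blocks.values(), truth.unexpressed_genes))
    universe = sorted(universe)
    terms: dict[str, frozenset[str]] = {}
    namespaces: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    aligned: dict[str, frozenset[str]] = {}
    for block_id in sorted(truth.planted_blocks):
        members = sorted(truth.planted_blocks[block_id])
        n_swap = int(round(jitter * len(members)))
        term_id = f"TERM_{block_id}"
        kept = members
        if n_swap:
            drop = set(rng.choice(members, size=n_swap, replace=False))
            kept = [g for g in members if g not in drop]
            pool = [g for g in universe if g not in truth.planted_blocks[block_id] and g not in kept]
            kept = kept + list(rng.choice(pool, size=n_swap, replace=False))
        terms[term_id] = frozenset(kept)
        namespaces[term_id] = "GO"
        descriptions[term_id] = f"aligned to planted block {block_id}"
        aligned[term_id] = frozenset(kept)
    for t in range(n_noise_terms):
        size = int(rng.integers(noise_term_sizes[0], noise_term_sizes[1] + 1))
        term_id = f"NOISE_{t + 1:03d}"
        terms[term_id] = frozenset(rng.choice(universe, size=size, replace=False))
        namespaces[term_id] = "GO"
        descriptions[term_id] = "random noise term"
    collection = GeneSetCollection(
        terms=terms,
        background=frozenset(universe),
        namespaces=namespaces,
        descriptions=descriptions,
    )
    out_truth = SyntheticTruth(
        seed=truth.seed,
        planted_blocks=dict(truth.planted_blocks),
        unexpressed_genes=truth.unexpressed_genes,
        aligned_terms=aligned,
        motif_target_genes=truth.motif_target_genes,
        motif_insertions=dict(truth.motif_insertions),
        ortholog_map=truth.ortholog_map,
    )
    return collection, out_truth


def _instantiate_consensus(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        ch if len(IUPAC[ch]) == 1 else IUPAC[ch][rng.integers(len(IUPAC[ch]))]
        for ch in motif.upper()
    )


def generate_promoters(
    gene_ids,
    length: int = 3000,
    motif: str = "CAACGG",
    target_genes=(),
    planted_rate: float = 3.0,
    background_rate: float = 0.3,
    seed: int = 0,
) -> tuple[PromoterSet, SyntheticTruth]:
    """Uniform-random promoters with non-overlapping motif insertions.

    The motif's consensus is instantiated (degenerate codes resolved at
    random per insertion) Poisson(planted_rate) times in each target
    promoter and Poisson(background_rate) times elsewhere.  Insertion
    positions never overlap or straddle ends and are recorded for audit.
    """
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code in motif: {ch!r}")
    if length < len(motif):
        raise ValueError("motif longer than promoter")
    if planted_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    target = set(target_genes)
    missing = target - set(gene_ids)
    if missing:
        raise ValueError(f"target genes not in gene_ids: {sorted(missing)[:5]}")
    alphabet = np.array(list("ACGT"))
    m = len(motif)
    sequences: dict[str, str] = {}
    insertions: dict[str, list[tuple[int, str]]] = {}
    for gene in gene_ids:
        seq = list(rng.choice(alphabet, size=length))
        rate = planted_rate if gene in target else background_rate
        n_insert = int(rng.poisson(rate))
        placed: list[tuple[int, str]] = []
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_insert and attempts < 200 * max(n_insert, 1):
            attempts += 1
            pos = int(rng.integers(0, length - m + 1))
            if any(pos < end and pos + m > start for start, end in occupied):
                continue
            instance = _instantiate_consensus(motif, rng)
            seq[pos:pos + m] = list(instance)
            occupied.append((pos, pos + m))
            placed.append((pos, instance))
        sequences[gene] = "".join(seq)
        if placed:
            insertions[gene] = sorted(placed)
    promoters = PromoterSet(sequences=sequences, nominal_length=length)
    truth = SyntheticTruth(
        seed=seed,
        motif_target_genes=frozenset(target),
        motif_insertions=insertions,
    )
    return promoters, truth


def generate_alignment_hits(
    n_a: int = 200,
    n_b: int = 200,
    n_orthologs: int = 150,
    decoy_hits_per_query: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Reciprocal alignment-hit tables with a known ortholog map.

    Each true ortholog pair receives mutually best (lowest-E-value)
    reciprocal hits; decoy hits are strictly worse.  Returns the A->B
    table, the B->A table and the truth ledger.
    """
    if min(n_a, n_b, n_orthologs, decoy_hits_per_query) < 0:
        raise ValueError("negative counts")
    if n_orthologs > min(n_a, n_b):
        raise ValueError("n_orthologs exceeds proteome size")
    rng = np.random.default_rng(seed)
    genes_a = [f"A{i + 1:04d}" for i in range(n_a)]
    genes_b = [f"B{i + 1:04d}" for i in range(n_b)]
    partners = rng.permutation(n_b)[:n_orthologs]
    ortho = [(genes_a[i], genes_b[partners[i]]) for i in range(n_orthologs)]

    def hit_row(q, s, evalue):
        length = int(rng.integers(120, 480))
        pident = float(np.round(rng.uniform(35, 99), 1))
        mismatch = int(round(length * (1 - pident / 100)))
        bitscore = float(np.round(60 - 1.8 * np.log10(max(evalue, 1e-300)), 1))
        return [q, s, pident, length, mismatch, int(rng.integers(0, 4)),
                1, length, 1, length, evalue, bitscore]

    rows_ab, rows_ba = [], []
    for a, b in ortho:
        e_true = float(10.0 ** -rng.uniform(60, 140))
        rows_ab.append(hit_row(a, b, e_true))
        rows_ba.append(hit_row(b, a, e_true))
    ortho_partner_of_a = {a: b for a, b in ortho}
    ortho_partner_of_b = {b: a for a, b in ortho}
    # decoy hits are one-directional: a pair hit as a decoy in A->B is never
    # also emitted in B->A, so decoys can never form reciprocal pairs
    decoy_pairs: set[tuple[str, str]] = set()
    for q, pool, partner_of, rows, forward in (
        (genes_a, genes_b, ortho_partner_of_a, rows_ab, True),
        (genes_b, genes_a, ortho_partner_of_b, rows_ba, False),
    ):
        for query in q:
            partner = partner_of.get(query)
            decoy_pool = [
                s for s in pool
                if s != partner
                and ((query, s) if forward else (s, query)) not in decoy_pairs
            ]
            k = min(decoy_hits_per_query, len(decoy_pool))
            if k == 0:
                continue
            subjects = rng.choice(decoy_pool, size=k, replace=False)
            for s in subjects:
                decoy_pairs.add((query, s) if forward else (s, query))
                e_decoy = float(10.0 ** -rng.uniform(2, 40))  # strictly worse than 1e-60
                rows.append(hit_row(query, s, e_decoy))
    hits_ab = pd.DataFrame(rows_ab, columns=HIT_COLUMNS)
    hits_ba = pd.DataFrame(rows_ba, columns=HIT_COLUMNS)
    truth = SyntheticTruth(seed=seed, ortholog_map=frozenset(ortho))
    return hits_ab, hits_ba, truth
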