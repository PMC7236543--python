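"""Promoter cis-element scanning and Z-score enrichment.

Motifs are IUPAC consensus strings matched exactly (no PWM scoring) on
both strands with overlaps counted; `N` in a promoter matches nothing.
Enrichment of a motif in a gene list is scored against a randomized null:
the total occurrence count over the list's promoters is compared with the
totals of ``n_draws`` random same-size gene sets, giving

    Z = (observed_sum - null_mean) / null_sd

(plain standardization by default; the literal standard-error form
dividing by null_sd/sqrt(n_draws) is available via ``n_effective``) and an
empirical p-value with a +1 pseudocount so p is never 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _motif_regex(motif: str) -> re.Pattern:
    motif = motif.upper()
    parts = []
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code in motif: {ch!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all counted
    return re.compile(f"(?={''.join(parts)})")


@dataclass
class PromoterSet:
    """Gene id -> promoter sequence (A/C/G/T/N upstream regions)."""

    sequences: dict[str, str]
    nominal_length: int = 3000

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty promoter set")
        valid = set("ACGTN")
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty promoter for {gene}")
            bad = set(seq.upper()) - valid
            if bad:
                raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in promoter {gene}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in sorted(self.sequences.items())
        ]
        seqio_write(records, path, "fasta")


def read_promoters_fasta(path, nominal_length: int = 3000) -> PromoterSet:
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return PromoterSet(sequences=sequences, nominal_length=nominal_length)


def scan_promoter(sequence: str, motif: str) -> int:
    """Count motif occurrences on both strands, overlaps included.

    The motif is matched against the sequence and against its reverse
    complement; `N` bases in the sequence never match (N is not in any
    consensus code's allowed set here because the motif pattern only
    admits A/C/G/T at each position).
    """
    sequence = sequence.upper()
    if len(motif) > len(sequence):
        raise ValueError("motif longer than sequence")
    pattern = _motif_regex(motif)
    forward = len(pattern.findall(sequence))
    reverse = len(pattern.findall(reverse_complement(sequence)))
    return forward + reverse


def motif_counts(promoters: PromoterSet, motif: str) -> pd.Series:
    """Per-gene occurrence counts for one motif over the whole promoter set."""
    return pd.Series(
        {gene: scan_promoter(seq, motif) for gene, seq in promoters.sequences.items()},
        dtype=int,
    )


@dataclass
class MotifZResult:
    motif: str
    gene_list_size: int
    observed_sum: int
    null_mean: float
    null_sd: float
    n_draws: int
    z: float
    empirical_p: float
    seed: int
    degenerate_null: bool = False

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "gene_list_size": self.gene_list_size,
            "observed_sum": self.observed_sum,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_draws": self.n_draws,
            "z": self.z,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "degenerate_null": self.degenerate_null,
        }


def motif_zscore(
    promoters: PromoterSet,
    gene_list,
    motif: str,
    n_draws: int = 1000,
    seed: int = 0,
    n_effective: int = 1,
    counts: pd.Series | None = None,
) -> MotifZResult:
    """Observed motif load in a gene list vs random same-size gene sets.

    Each of the ``n_draws`` null draws picks, without replacement, as many
    genes as the list holds from all promoter-bearing genes and records the
    total motif count.  ``counts`` can carry precomputed per-gene counts to
    amortize scanning across calls.
    """
    gene_list = sorted(set(gene_list))
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    missing = set(gene_list) - set(promoters.sequences)
    if missing:
        raise ValueError(f"gene list outside promoter set: {sorted(missing)[:5]}")
    if counts is None:
        counts = motif_counts(promoters, motif)
    counts = counts.reindex(sorted(promoters.sequences))
    values = counts.to_numpy(dtype=float)
    observed = int(counts[gene_list].sum())
    rng = np.random.default_rng(seed)
    size = len(gene_list)
    sums = np.empty(n_draws)
    n_genes = len(values)
    for i in range(n_draws):
        idx = rng.choice(n_genes, size=size, replace=False)
        sums[i] = values[idx].sum()
    null_mean = float(sums.mean())
    null_sd = float(sums.std(ddof=1))
    degenerate = null_sd == 0.0
    if degenerate:
        z = float("nan")
    else:
        z = (observed - null_mean) / (null_sd / np.sqrt(n_effective))
    empirical_p = float((1 + np.sum(sums >= observed)) / (1 + n_draws))
    return MotifZResult(
        motif=motif.upper(),
        gene_list_size=size,
        observed_sum=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        n_draws=n_draws,
        z=float(z),
        empirical_p=empirical_p,
        seed=seed,
        degenerate_null=degenerate,
    )


def significant_motifs(results, p_cutoff: float = 0.05) -> list[MotifZResult]:
    """Results with empirical p < cutoff, strongest (highest Z) first."""
    kept = [r for r in results if r.empirical_p < p_cutoff]
    return sorted(kept, key=lambda r: (-(r.z if np.isfinite(r.z) else -np.inf), r.motif))


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
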