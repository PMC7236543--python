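# coexnet

Gene **coexpression-network analysis** for bulk transcriptomes: from an
FPKM expression matrix to functional modules and refined gene
annotations. The package implements the network-first annotation
strategy used for non-model plant genomes, where most genes lack
experimental annotation and "guilt by association" through coexpression
is the main source of functional hypotheses.

It is aimed at computational biologists who have a genes × samples
expression table (plus, optionally, gene-set collections, promoter
sequences and protein alignment hits) and want a tested, scriptable
version of the classic pipeline rather than a web platform.

## The method

1. **Low-expression filtering (3σ rule).** For each sample take the 5th
   percentile of its FPKM distribution; with mean *μ* and unbiased SD
   *σ* of those percentiles across samples, the threshold is
   *t = μ + 3σ*. Genes with FPKM < *t* in **every** sample are removed
   (their correlations are uninformative).
2. **Network construction (PCC + mutual rank).** For every retained
   gene pair the Pearson correlation
   *r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)* is computed; weak pairs
   are discarded (fixed cutoff, or a permutation-null calibration via
   `calibrate_min_abs_pcc`). Each gene ranks its partners by |r| within
   sign class, and a pair's **mutual rank** is
   *MR(AB) = √(Rank(A→B) · Rank(B→A))*. Edges are kept when
   min(Rank(A→B), Rank(B→A)) ≤ 3 **or** MR ≤ 30 (cutoffs and rule
   configurable).
3. **Module detection (k-clique percolation).** Communities are unions
   of k-cliques connected through shared (k−1)-node overlaps; modules
   have ≥ k genes and may overlap. A from-scratch CPM implementation is
   provided, brute-force-verified, with a k-scan helper.
4. **Annotation (Fisher + FDR) and refinement.** Modules are tested for
   gene-set over-representation with the one-sided Fisher exact test
   (hypergeometric upper tail) and Benjamini–Hochberg FDR (< 0.05).
   Genes then inherit their modules' significant terms, and every
   network gene is additionally tested against its direct coexpression
   neighborhood.
5. **Cis-element enrichment (Z-score).** IUPAC consensus motifs are
   counted in promoters on both strands; a gene list's total motif load
   is standardized against 1,000 random same-size gene lists:
   *Z = (X̄ − u)/σ*, with an empirical p-value alongside.
6. **Orthology (reciprocal best hits).** From two directional 12-column
   alignment tables: reciprocal top-3 pairs form the best tier; the
   peak of the best tier's E-value distribution sets the threshold for
   the secondary tier.

A seeded synthetic-data generator (`coexnet.synthio`) produces all
pipeline inputs with recorded ground truth — planted co-regulated
blocks, block-aligned gene sets, promoters with planted motifs, and
alignment tables with a known ortholog map — so every stage is testable
end to end without external data.

## Worked example

`examples/01_filter_and_network.py` builds a 500-gene, 12-sample
synthetic transcriptome with 10 planted blocks of 20 co-regulated genes
and runs filtering + network construction:

```
expression matrix: 500 genes x 12 samples
3-sigma FPKM threshold: 0.390 (mean of per-sample 5th percentiles 0.281 + 3 x SD)
removed 20 low-expression genes (the generator planted 20)
permutation-calibrated |PCC| cutoff: 0.772 (the 99.5th percentile of chance correlation at this sample size)
network: 2368 edges over 406 nodes, mean 11.7 edges/gene, 81.2% genome coverage
```

The threshold removes exactly the generator's planted "unexpressed"
genes; the calibrated cutoff keeps pairs stronger than almost all
chance correlation at 12 samples. `examples/02_modules_and_annotation.py`
continues to modules and annotation:

```
11 CPM modules at k=6 (sizes [6, 21, 21, 21, 21, 22, 22, 22, 23, 23, 25])
10/11 modules carry a term at FDR < 0.05
  M0001: TERM_B01 (overlap 18/20, FDR 7.96e-26)
  ...
224 genes annotated (55.2% of network genes); 221 module-inherited, 5 neighborhood-derived records
```

Each planted block resurfaces as one module annotated with its aligned
term. `examples/03_motif_enrichment.py` and `examples/04_orthologs.py`
demonstrate the cis-element Z-score (planted motif: Z = 9.34,
empirical p = 0.001; absent control: Z = −0.61, p = 1.0) and RBH
orthology (150/150 true pairs recovered at mutual rank 1).

## Command line

A thin CLI mirrors the library:

```bash
coexnet simulate --n-genes 500 --seed 7 --out-dir data/
coexnet filter --expression data/expression.tsv --out filtered.tsv
coexnet build --expression filtered.tsv --min-abs-pcc 0.8 --out edges.tsv
coexnet modules --edges edges.tsv --k 6 --out modules.tsv
coexnet run --config config.yaml     # whole pipeline from one YAML config
```

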