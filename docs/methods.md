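# Methods

This note documents the models, parameter choices and numerical
conventions behind `coexnet`, and what the synthetic benchmark does and
does not establish about real data.

## Low-expression filtering

The threshold is `mean(p) + sigma * sd(p)` where `p` collects each
sample's 5th-percentile FPKM. Conventions, all configurable:

- the percentile is taken over **all** genes of a sample, zeros
  included, with linear interpolation between order statistics;
- the SD across samples is the unbiased (n−1) form; a single sample is
  accepted only with `sigma=0`;
- removal requires strict `FPKM < threshold` in **every** sample — one
  sample at or above the threshold retains the gene;
- an optional grouping argument computes per-group thresholds when the
  samples fall into experimental groups.

Filtering is idempotent and monotone (raising the threshold never
rescues a gene), and never touches the sample set.

## Correlation, mutual rank and edge selection

Pearson correlation is computed on FPKM values as given (no log
transform), per the standard product-moment formula; constant-expression
genes are excluded with a logged count rather than silently.

Ranks are computed **within sign class**: each gene ranks its retained
positive partners by descending r and, independently, its negative
partners by ascending r, so negative coexpression can survive
rank-based selection. Ties break by lexicographic partner id, making
the whole computation permutation-auditable. `ranking="abs"` provides
the combined-|r| alternative. MR is the geometric mean of the two
directional ranks; selection defaults to the union rule
`min(rank) <= 3 OR MR <= 30` with an intersection variant and
strict-inequality flags.

**Sample-size caveat.** Fixed cutoffs inherit their meaning from the
partner-list length: MR ≤ 30 is the top ~0.06% of partners in a
30k-node network but the top ~6% in a 500-gene benchmark, and at 12
samples chance |r| routinely exceeds 0.6. The package therefore ships
`calibrate_min_abs_pcc`: each gene's samples are permuted independently
(destroying all coexpression, preserving every marginal) and the
weak-pair cutoff is set to an upper quantile (default 99.5%) of the
null |r| distribution, averaged over a few permutations. The pipeline
accepts `min_abs_pcc: "auto"` to apply it. This mirrors the practice of
calibrating the weak-pair cutoff on the data rather than importing a
fixed value across scales.

The ROC helper sweeps MR cutoffs against labelled pair sets (TPR/FPR
per cutoff, trapezoidal AUC); labelled pairs absent from the ranked
table score as non-edges. With identical scores everywhere the AUC is
0.5 by convention.

## Clique percolation

`clique_percolation` is a from-scratch CPM: k-cliques are derived from
maximal cliques (networkx `find_cliques`) but the output contract is
the brute-force definition — every fully connected k-set, once, in
canonical order. Two distinct k-cliques can share at most k−1 nodes, so
indexing cliques by their (k−1)-subsets finds exactly the adjacent
pairs; union–find over those links yields the communities. Modules may
overlap in genes; module ids are deterministic (sorted member lists).
Edge sign is ignored by default, with a positive-only mode.

`scan_k` reports module count and coverage per k and recommends the k
maximizing (coverage, module count) lexicographically. Because
k-clique coverage is monotone non-increasing in k, this composite
essentially recommends `k_min`; it is deliberately advisory only. For
the benchmark analyses the pipeline uses k = 6 (k = 5 by library
default), the values used in practice for networks of this kind; at
k = 6 noise triangles cannot seed modules and the planted blocks
separate cleanly.

## Enrichment and annotation refinement

`fisher_enrichment` is the one-sided hypergeometric upper tail
P(X ≥ overlap) (scipy `hypergeom.sf`, exact — no normal approximation),
cross-checked in the tests against an exact rational-arithmetic sum.
Multiple testing uses Benjamini–Hochberg by default (Bonferroni by
flag); the FDR family is all tests within one namespace for module
annotation and all terms per gene for the refinement step. The
background defaults to the genes present after filtering, not the whole
genome — enrichment then asks "is this term over-represented among the
expressed genes", the question the network can answer.

Refinement is two-step: module members inherit their modules'
significant terms (provenance `module`), then each gene's direct
neighbor set is tested per term and passing terms are appended
(provenance `neighbors`). Inherited annotations are never removed.

The optional term Z-score re-scores an enrichment result's overlap
against `n_draws` random same-size gene draws, flagging terms with
Z > 4; a degenerate null (SD = 0) yields NaN and is never flagged.

## Cis-element Z-score

Motifs are IUPAC consensus strings matched exactly, both strands,
overlaps counted; `N` in a promoter matches nothing; PWM scoring is out
of scope. The enrichment null redraws `n_draws` (default 1,000) random
gene lists of the same size and records each list's total motif count.
The Z statistic standardizes the observed total against that null:
`Z = (observed − mean)/sd` with the unbiased SD. A literal
standard-error form (dividing by sd/√n_draws) exists behind
`n_effective`, but it inflates Z by ~√1000 for what is a single
observation, so plain standardization is the default and the empirical
p-value `(1 + #{draws ≥ observed})/(1 + n_draws)` — never exactly 0 —
is always reported as the robust criterion.

## RBH orthology

Hit tables are collapsed to the best HSP per (query, subject) — lowest
E-value, ties by bitscore then input order. Ranking is E-value
ascending, bitscore descending, subject id. "Top three hits" is read as
reciprocal top-3 membership (b in a's top 3 AND a in b's top 3), with
`top_n=1` giving strict RBH. The secondary threshold is the center of
the modal bin of the best pairs' log10 E-value histogram
(Freedman–Diaconis widths; ties resolve to the more significant bin;
zero E-values floored at 1e−180); secondary pairs are reciprocal pairs
below it (comparing the smaller directional E-value by default,
max-based by flag), never duplicating best-tier pairs.

## Synthetic data: what it emulates, what it does not

`generate_expression` plants `n_blocks` blocks of co-regulated genes:
each block shares a latent per-sample factor, each gene mixes it with
independent noise (`latent = √rho·factor + √(1−rho)·noise`), and FPKM
is `exp(base + latent_sd·latent)` with a lognormal per-gene baseline —
non-negative, heavy-tailed marginals with within-gene log-variation set
by `latent_sd` (default 0.6, ≈1.8-fold SD across samples, typical of a
developmental series; this also keeps the realized FPKM-scale
correlation close to `rho`). The block factors are an orthonormal
random frame rather than iid draws: ten iid Gaussian factors in a
12-sample space carry chance correlations up to ±0.7, which would make
"distinct" planted blocks genuinely cross-correlated and the ground
truth ill-defined. A small fraction of genes (default 4%) is
"unexpressed" — uniform below 0.01 in every sample — giving the 3σ
filter a non-trivial target; the expressed baseline is clipped below so
that the threshold (≈0.2–0.4 at the defaults) cleanly separates the two
populations. Defaults (500 genes, 10 blocks × 20, rho = 0.95, 12
samples) are desk-scale study conditions, not the ~50k-gene scale of a
real genome.

Gene sets, promoters and alignment tables follow the same pattern:
aligned terms are planted blocks with a `jitter` fraction of members
swapped; promoters are uniform-random sequences with non-overlapping,
position-recorded consensus insertions at Poisson rates; alignment
tables give true ortholog pairs mutually-best reciprocal hits with
strictly worse, one-directional decoys (a decoy pair is never emitted
in both directions, so decoys cannot form reciprocal pairs by chance).
All randomness flows from one integer seed through a single
`numpy` generator; identical seeds give byte-identical artifacts.

What passing the benchmark does **not** show: robustness to batch
effects, count noise at low expression, correlated (non-block)
co-regulation structure, unbalanced block sizes, promoter base
composition bias, or paralog-rich proteomes — none of which the
generator models.

### Residual stochasticity of block recovery

At 12 samples a background gene has a few-percent chance of correlating
above any reasonable cutoff with a block's factor; recovered modules
therefore usually carry a handful of genuinely chance-correlated extra
genes. Across seeds, ≥ 9 of 10 planted blocks are recovered at
Jaccard ≥ 0.8 in ~90% of runs, with failures being complete blocks plus
6–8 extras — a property of the sample size, not of the implementation.

## Numerical conventions

- Report rounding is half-up: mean degree and mean module size to one
  decimal, coverage percent to two (matching the usual summary-table
  precision).
- Edge lists, module tables and enrichment tables are sorted on stable
  keys so repeated runs diff cleanly; pipeline outputs are written
  atomically (temp file + rename), and two runs with identical config
  and seed are byte-identical.
- Desk-scale problem sizes used by the test suite and the acceptance
  script (20 oracle matrices ≤ 60 genes; 50 oracle graphs ≤ 30 nodes;
  100 null motifs at 400 draws on 200 × 1-kb promoters; 1,000 draws for
  the planted-motif Z; 200-protein proteomes) are the package's chosen
  benchmark sizes — small enough to brute-force, large enough for the
  Monte-Carlo bands used.
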