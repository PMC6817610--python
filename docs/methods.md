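# Methods and design notes

This note records the models implemented, the defaults that matter, the
numerical choices, and what the synthetic-data tests do and do not show.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Co-expression networks

Expression is transformed to log2(FPKM + 1) before correlation by default
(`transform="log2p1"`); FPKM distributions are heavy-tailed and the log
stabilizes variance, while `transform="none"` reproduces correlations on
the raw scale. Genes with zero variance under the chosen transform have
no defined correlation; they are dropped and reported rather than
imputed. Missing expression values are rejected outright — correlation
semantics with silent imputation are ambiguous.

Mutual rank combines the two reciprocal ranks by geometric mean by
default. A plain-product mode is provided (`mode="product"`), but the
magnitude of the conventional cutoffs (MR ≤ 55 on networks of tens of
thousands of genes) and the mutual-rank literature both correspond to the
geometric mean, so that is the default. Rank ties are broken by
lexicographic gene id: average ranks would make MR non-integer in
undocumented ways, and ordinal ranks with a fixed tie-break make results
identical across platforms. Negative edges rank partners on the
ascending-correlation tail, separately from positive ranks — a single
descending ranking would assign negative partners meaninglessly large
ranks. The negative-edge mutual-rank cutoff is applied symmetrically to
the positive one.

Thresholds: positive edges require PCC ≥ 0.8 *and* MR ≤ 55 (global
preset) or MR ≤ 50 (conditional preset); negative edges use
PCC ∈ (−1, −0.3). The looser (0.5, 1) interval sometimes quoted for
"positively correlated" pairs is treated as sign vocabulary only; the
stricter 0.8 bound is the edge criterion.

Sample QC flags a sample when its mean correlation with all other samples
falls below a cutoff (default 0.5) and reports the hierarchical-clustering
leaf order of the sample correlation matrix for visual inspection,
mirroring heatmap-based outlier screening.

## Threshold tuning by AUROC

Positive pairs are those co-annotated to at least one GO term whose size,
*after* restriction to measured genes, lies in [4, 20] — small enough to
be specific, large enough to contribute pairs. The negative class is not
canonically defined; here it is a seeded uniform sample of
non-co-annotated pairs, by default as many as there are positives, which
keeps AUROC interpretable and cheap. Each (PCC, MR) grid cell is scored
as a binary classifier (a pair passes the cell's filter or not), because
the object being evaluated is the thresholded network, not the raw
correlation. AUROC uses the Mann–Whitney rank formulation (ties count
half). Argmax ties resolve toward the sparser network, then the stricter
cuts, reflecting a preference for high-credibility edges.

## Clique-percolation modules

Communities are connected components of the relation joining k-cliques
sharing k − 1 nodes. The implementation percolates *maximal* cliques
(size ≥ k, pairwise intersection ≥ k − 1), which yields identical
communities while enumerating far fewer objects; maximal cliques come
from networkx's Bron–Kerbosch. The test suite checks exact equivalence
against a direct k-clique enumeration oracle on random graphs. Only
positively-signed edges enter by default: negative correlation has no
clique semantics for co-expression modules. Module ids are assigned by
descending size, then lexicographically smallest member, so ids are
stable across runs. Defaults k = 6 and minimum module size 6 follow
common database practice for dense co-expression graphs.

## Enrichment statistics

Gene-set enrichment is the one-sided upper-tail hypergeometric test
(enrichment only, not depletion), with Benjamini–Hochberg FDR at 0.05.
The universe is the caller's choice; for module annotation the natural
universe is all genes in the expression matrix. A term enters the tested
family only when it overlaps the query and has at least two members in
the universe; zero-overlap terms are reported with p = 1 but excluded
from the BH family so that untestable terms do not dilute the correction.

## Promoter motif enrichment

Promoters are the 3,000 bp immediately upstream of the TSS, reverse
complemented for minus-strand genes so every sequence reads 5'→3' toward
the gene, truncated (and flagged) at chromosome edges. Motifs are IUPAC
consensus strings matched exactly (degenerate codes expand to character
classes); overlapping occurrences all count; an N in the *sequence*
matches nothing. Matching is on the promoter strand only by default —
promoters are already strand-resolved, and single-strand counting avoids
double-counting palindromes — with a both-strands option for unstranded
motif semantics.

The background for a query of m genes is 1,000 independent draws of m
genes without replacement from the promoter universe. Background
dispersion uses the population standard deviation (ddof = 0); at 1,000
draws the difference from the sample estimator is negligible but the
definition must be fixed for bit-reproducibility. A motif absent from
every draw (stdev 0) is reported as NA rather than an infinite Z.

## Chromatin-state model

Binarization calls a mark present in a bin when the Poisson upper tail of
its rounded count, at the genome-wide mean rate for that mark, is ≤ 1e-4
(e.g. λ = 1 ⇒ present iff count ≥ 7). The background is global — no
control track and no local rate — which is the standard default when no
input/control experiment exists.

The HMM has independent Bernoulli emissions per mark given the state.
Training is Baum–Welch EM over chromosomes as independent sequences, with
scaled (per-position normalized) forward–backward; parameters are floored
at 1e-6 to avoid log(0) and absorbing zeros. Initialization draws
emissions uniformly from (0.1, 0.9) and biases transitions toward
self-transition (0.5 on the diagonal) because chromatin states are
spatially coherent; the best of 3 seeded restarts by final log-likelihood
is kept, and every restart's log-likelihood trace is retained (EM
guarantees monotonicity; the tests assert it). Convergence: absolute
log-likelihood change < 1e-4 or 200 iterations. Decoding defaults to
maximum-posterior per bin, with Viterbi available. Returned states are
sorted by descending total emission mass so state ids are stable.

Model comparison reports, per candidate state, the maximum Pearson
correlation of its emission vector across a reference model's states.
For choosing the number of states, an absolute similarity cutoff turned
out to be a poor rule: an undersized model's blended emission vectors can
still *correlate* > 0.95 with reference states, because correlation is
blind to emission magnitude. The recommendation rule is therefore
saturation — the smallest model whose median per-state similarity to the
largest swept model improves by less than 0.01 when one more state is
allowed. This is explicitly a heuristic; the full comparison table is
returned so users can apply their own criterion.

Fold enrichment rasterizes features to bins (≥ 1 bp overlap counts the
bin) and computes (overlap/state bins)/(feature bins/total bins); states
with no bins give NA. Binarized marks can be profiled as additional
columns with the same formula.

## Synthetic data

The generators define the default study conditions used throughout the
tests.

*Expression*: 200 genes × 200 samples, 10 planted modules of 8 genes.
Each module shares a latent per-sample Gaussian profile; a member gene is
√ρ·latent + √(1−ρ)·noise with ρ = 0.9, so the expected within-module
correlation on the log scale is exactly ρ. Log values are shifted +5 and
exponentiated base 2, giving lognormal-like FPKM in roughly the 4–250
range whose log2(FPKM+1) transform is essentially the generating
Gaussian — so the pipeline's default transform sees the planted
correlation structure undistorted. Latent factors, not copulas: simple,
and pairwise correlation is controlled exactly in expectation.

*Gene sets*: one term per planted module plus 20 random decoy terms with
sizes uniform in [4, 20].

*Promoters*: 500 genes, 3,000 bp, GC 0.40 (typical for plant promoter
regions), motif TGACGTCA (a bZIP/ACGT-class element) planted twice,
non-overlapping, in each of 50 foreground promoters.

*Chromatin*: 20,000 bins × 4 marks from a 3-state chain (active /
repressed / quiescent) with a sticky quiescent state (self-transition
0.95) so that, as in real genomes, most bins are mark-poor and
genome-wide presence per mark stays near 15%. Counts are
Poisson(λ_high = 30) in present bins and Poisson(λ_low = 0.1) in absent
bins. λ_high = 30 is deliberate: with ~15% presence the binarization
background (global mean ≈ 4.7) induces a cutoff of ~15 counts, and
Poisson(30) clears that cutoff with probability ≈ 0.998, so the
binarize→learn pipeline sees essentially the generating binary matrix. A
weaker signal (e.g. λ_high = 10) would put the cutoff inside the signal
distribution and censor a third of truly present bins — a regime that
tests binarization robustness, not parameter recovery. The ratio 30:0.1
corresponds to a strongly enriched mark over a clean background.

## What the simulations do and do not show

The generators produce idealized data: modules with homogeneous
correlation and independent background genes, i.i.d. promoter bases, and
marks that are conditionally independent given the state with a single
genome-wide signal rate. Passing the recovery tests shows the estimators
are correct and well-calibrated under their own model assumptions; it
does not show robustness to unmodeled features of real data —
between-module correlation, batch effects, promoter sequence composition
structure (CpG islands, repeats), copy-number-driven signal, or
mark-specific background rates. Headline numbers from full-scale resources
(tens of thousands of genes, hundreds of thousands of edges and segments)
depend on corpus-scale data and are out of desk-scale reach; the test
suite instead verifies every statistic against independent oracles at
small size and every pipeline against planted truth at moderate size
(200-gene networks, 20,000-bin genomes — sizes chosen so the full suite
runs in well under a minute apiece).

## Known limitations

- Correlation ranks (hence MR) are O(n²) memory; the implementation
  targets up to a few thousand genes, not 45k-gene transcriptomes, which
  would need a blocked/out-of-core rank computation.
- The clique enumeration underlying CPM is exponential in the worst case;
  dense graphs at loose thresholds may be infeasible (as with any CPM
  tool).
- Binarization has no control-track adjustment and no local background.
- PWM/log-odds motif scanning is out of scope; motifs are consensus
  strings.
- The HMM assumes marks independent given the state and a single emission
  vocabulary genome-wide; no stacked multi-sample or tied-variance
  designs.
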