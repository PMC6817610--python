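# omicsforge

Analytical engine for multi-dimensional omics gene-function resources:
gene co-expression networks with mutual-rank filtering and GO-prior AUROC
threshold tuning, overlapping functional-module detection by clique
percolation, gene-set and promoter-motif enrichment statistics, and
chromatin-state segmentation of binarized epigenomic marks with a
multivariate hidden Markov model.

It is written for computational biologists who assemble co-expression /
chromatin-state databases from bulk RNA-seq and epigenomic tracks and want
the statistics behind such resources as a reproducible, testable library
rather than a pile of one-off scripts.

## The methods

**Co-expression.** For genes $x, y$ measured across $n$ samples the
Pearson correlation is

$$\mathrm{PCC}(x,y)=\frac{\sum_i (x_i-\bar x)(y_i-\bar y)}
{\sqrt{\sum_i (x_i-\bar x)^2}\sqrt{\sum_i (y_i-\bar y)^2}},$$

computed by default on $\log_2(\mathrm{FPKM}+1)$. Correlation alone is
hub-biased, so edges are additionally filtered by **mutual rank**: if
$\mathrm{Rank}(A{\to}B)$ is the position of $B$ in $A$'s PCC-sorted
partner list, then

$$\mathrm{MR}(A,B)=\sqrt{\mathrm{Rank}(A{\to}B)\cdot\mathrm{Rank}(B{\to}A)}.$$

Preset cutoffs mirror published database practice: a *global* network at
PCC ≥ 0.8 and MR ≤ 55, a *conditional* (tissue-preferential) network at
PCC ≥ 0.8 and MR ≤ 50, and negative edges in the PCC interval (−1, −0.3).
Candidate cutoffs can be tuned by the AUROC of the thresholded network
against pair labels derived from GO terms of size 4–20.

**Modules.** Overlapping modules are the $k$-clique percolation
communities of the network ($k=6$, ≥ 6 genes per module), annotated by
one-sided hypergeometric (Fisher) enrichment with Benjamini–Hochberg FDR
(≤ 0.05).

**Motifs.** Promoters are the 3,000 bp upstream of the TSS,
strand-resolved. A consensus motif's count $N_\mathrm{motif}$ in $m$
query promoters is standardized against 1,000 random draws of $m$ genes:
$Z=(N_\mathrm{motif}-\mathrm{mean}_\mathrm{motif})/\mathrm{stdev}_\mathrm{motif}$,
$P=1-\Phi(Z)$.

**Chromatin states.** Each mark is binarized per 200-bp bin against a
genome-wide Poisson background ($P(X\ge c;\lambda)\le 10^{-4}$); a hidden
Markov model with independent Bernoulli emissions per mark is trained by
Baum–Welch EM with random restarts, bins get their maximum-posterior
state, and states are interpreted via emission similarity between models
and fold enrichment over genomic feature classes,
$\mathrm{fold}(s,f)=\frac{|s\cap f|/|s|}{|f|/\text{total bins}}$.

A seeded `synthetic` module generates every input with planted ground
truth (latent-factor co-expression modules, motif-spiked promoters,
HMM-emitted signal tracks), so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/coexpression_network.py
```

```
genes: 200   samples: 200
global network edges (PCC>=0.8, MR<=55): 280
conditional network edges (MR<=50):      280
edge Jaccard between the two:            1.000
```

The simulation plants 10 modules of 8 genes (pairwise correlation 0.9);
10 × C(8,2) = 280 within-module pairs are both highly correlated and
mutually top-ranked, so they survive the global cutoffs while background
pairs do not, and the stricter conditional mutual-rank cutoff changes
nothing (Jaccard 1.0). Continuing with `examples/module_detection.py`:

```
10 modules with >= 6 genes (planted: 10)
module M1 (8 genes) top term: TERM_MOD1
  overlap 8/8, p = 1.81e-14, FDR = 1.81e-13, significant: True
```

Clique percolation returns exactly the planted modules, and the first
module's hypergeometric annotation finds its generating term. The other
examples (`threshold_tuning.py`, `motif_enrichment.py`,
`chromatin_states.py`) walk the AUROC grid search, the motif Z-scores
(planted TGACGTCA: Z ≈ 17.6 vs ≤ 1.5 for decoys) and the chromatin HMM
(emission mean absolute error vs truth ≈ 0.005; promoter fold enrichment
≈ 6 for the active state).

A thin CLI mirrors the library for shell use: `omicsforge network
build|tune|compare`, `omicsforge modules`, `omicsforge enrich`,
`omicsforge motif`, `omicsforge chromatin learn|enrich`, `omicsforge
simulate ...` (see `--help`).

## Layout

```
src/omicsforge/   io, coexpression, network_eval, modules, enrichment,
                  motifs, chromatin, synthetic, cli
examples/         one narrative script per capability
tests/            pytest suite with independent oracles
docs/methods.md   modelling assumptions, defaults and limitations
```
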