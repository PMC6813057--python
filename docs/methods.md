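# Methods

## Model

The classifier is a qualitative, rank-only decision rule over a fixed list
of oriented gene pairs. For a pair (gene1, gene2) the MSI-associated
pattern is a strict within-sample inequality `E_gene1 > E_gene2`; a sample
is called MSI when at least `k` of the signature's pairs show their
pattern. Because every quantity the rule consumes is a within-sample
comparison, the call is invariant under any strictly increasing transform
applied to a sample's expression vector. This is the central robustness
property of the approach and is enforced by tests (classification before
and after per-sample monotone distortion must be identical).

Discovery assumes two labeled classes (MSI, with MSI-L grouped into MSS)
and proceeds in a fixed order:

1. *DE screen.* Two-sided Student's t-test (equal variance, as classically
   defined) per gene, BH FDR < `de_fdr` (default 0.01). Genes with zero
   variance in both classes get p = 1 rather than an error. An optional
   `max_de_genes` cap (top genes by p) keeps the quadratic pair screen
   desk-scale.
2. *Pair screen.* For each unordered pair of DE genes both orientations
   are considered and the one with the larger frequency difference is
   kept, so FD ≥ 0 after orientation; ties between orientations break to
   lexicographic gene order. Ties in expression (`E_i = E_j`) never count
   as the pattern — the conservative choice, which can only withhold a
   vote, never manufacture one. The one-sided Fisher exact p-value (upper
   hypergeometric tail: pattern more frequent in MSI) is BH-adjusted over
   all tested pairs as a single family, FDR < `pair_fdr` (default 0.01).
3. *FD statistic.* `FD = p1 - p2` with `p_c` the within-class frequency of
   the oriented pattern.
4. *Redundancy removal.* Greedy pass over pairs sorted by FD descending
   (ties: Fisher p ascending, then gene names); a pair is kept iff neither
   of its genes occurs in an already-kept pair. This is the *iterative*
   greedy reading of "keep only the pair with the largest FD per gene": a
   pair discarded because one gene is taken does not block its other gene
   from appearing in a later pair. The stricter per-gene-best-only variant
   would discard more pairs; the iterative form is deterministic, keeps
   more of the signal, and its per-gene uniqueness invariant is tested on
   random pair sets.
5. *Selection.* Pairs with FD ≥ `fd_min` (0.8 by default; 0.9 is the
   configuration used for left-sided tumors) form the signature. The vote
   threshold k is chosen by evaluating every k from 1 to the number of
   pairs and maximising the F-score, defined throughout as the harmonic
   mean of sensitivity and specificity (not the precision/recall F1).
   F-score ties break toward the larger k — the more specific classifier.

The pipeline contains no randomness; fitting twice on the same inputs
yields byte-identical signatures.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `de_fdr` | 0.01 | BH FDR for the per-gene t-test screen |
| `pair_fdr` | 0.01 | BH FDR for the one-sided Fisher pair screen |
| `fd_min` | 0.8 | minimum frequency difference for signature membership (0.9 for the left-sided configuration) |
| `max_de_genes` | none | optional cap on genes entering the pair screen |
| `missing_policy` | error | how prediction treats absent signature genes |

When a fixed signature is applied to a platform lacking some of its genes
(`missing_policy="drop"`), the vote threshold is rescaled to
`ceil(k * pairs_used / n_pairs)` (minimum 1), preserving the vote fraction
(7/10 for the built-in signature). The rescaling rule is this package's
design choice for a use case the discovery procedure does not address.

## Evaluation choices

- AUC uses vote counts as the score and the Mann-Whitney formulation with
  midrank tie handling, equal to the trapezoidal area under the empirical
  ROC; an all-pairs brute-force count is the test oracle.
- Reported metrics are rounded half-up to 4 decimals.
- The clustering assessment of signature-disconfirmed samples computes DE
  genes between signature-confirmed MSI and MSS samples, takes the top 100
  by ascending q (ties: p, then symbol), clusters all samples by
  complete-linkage/Euclidean hierarchical clustering cut at two clusters,
  labels each cluster by the majority class of its confirmed members
  ("unassigned" on ties), and reports the cluster class each query joins.
  Majority labeling is an operational stand-in for reading a dendrogram by
  eye.

## Synthetic cohorts

`simulate_dataset` generates the conditions the discovery procedure
assumes: `n_msi`/`n_mss` samples (default 60/60), `n_genes` total genes
(default 300, log-normal background: per-gene log2 baseline uniform on
[3, 9] with Gaussian noise, `noise_sd` = 1, exponentiated to a positive
measurement scale), and `n_planted_pairs` pairs (default 10) whose pattern
holds with probability `p_pattern_msi` (0.95) in MSI and `p_pattern_mss`
(0.05) in MSS samples — true FD 0.9, matching the effect size the FD ≥ 0.8
filter targets.

Planted pairs are built by drawing both gene values iid from the pair's
class-shifted distribution and assigning (max, min) to (gene1, gene2) with
the class's pattern probability, so the pattern probability is hit
exactly. That assignment hands gene2 the smaller draw in MSI and the
larger in MSS, eroding its between-class mean shift by
`2 (p_msi - p_mss) / sqrt(pi)` noise SDs; the pair-level class shift is
raised by exactly that amount so the disadvantaged gene still shifts by
`de_shift` SDs (default 2) and planted genes clear the DE screen as
intended.

Two perturbation operators support robustness measurement:
`apply_monotone_distortion` (per-sample increasing cubic `a + b·x + c·x³`,
b, c > 0 — rank-preserving by construction) and `apply_degradation`
(multiplicative attenuation of a random gene subset per sample — *not*
rank-preserving; under mild settings, 10% of genes attenuated to 70–95%,
over 90% of signature-pair orderings survive).

What the simulator does not emulate: probe-level microarray noise, GC
bias, tumor-purity mixtures, correlated gene modules, or realistic
library-size variation. Passing tests on these cohorts demonstrate that
the pipeline recovers planted rank structure at the stated effect sizes
and calibrates its FDR on null data — not that it reproduces any specific
clinical cohort's accuracy.

## Problem sizes

Tests and the acceptance script run the discovery pipeline on cohorts of
120 samples × 300 genes (20 replicate seeds), the null calibration on 100
genes × 120 samples, oracle comparisons on all 2×2 tables with class sizes
≤ 12, 1000 random p-vectors and 500 random score vectors, and clustering
on 33-sample blob cohorts — sizes at which every stage's exact behavior
can be checked in seconds on a laptop.

## Known limitations

- The exact published discovery counts (thousands of DE genes, ~1.65M
  candidate pairs) arise from specific public cohorts and are not
  reproduced here; the pipeline is validated on synthetic ground truth
  instead, and the published 10-pair signature itself is shipped verbatim.
- The strict-inequality tie rule means a platform that reports many tied
  values (e.g. heavily censored counts) loses votes; `pairs_used`
  accounting makes this visible but cannot recover the information.
- Redundancy removal is greedy, not optimal: a maximum-weight matching on
  the pair graph could retain a larger total FD, but would depart from the
  published procedure.
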