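# Methods

## Scope and model

`cernet` implements a three-step construction of subtype-specific competing
endogenous RNA (ceRNA) networks from bulk expression cohorts, followed by
network-topology and gene-set analyses:

1. **Differential expression.** For each tumor subtype, every gene (mRNA,
   lncRNA, miRNA) is compared with the shared normal cohort by a two-sided
   Wilcoxon rank-sum test on log2 expression. P-values are Bonferroni
   adjusted within the RNA class (`adjusted = min(1, p·m)` with `m` the
   number of genes tested in that class); a gene is called differentially
   expressed (DE) when the adjusted p is below 0.05 and the absolute log2
   fold change (difference of group means on the log2 scale) is at least 1.
2. **miRNA dys-regulatory network.** A directed bipartite graph per subtype:
   an edge miRNA→target is kept when the pair is sequence-predicted (input
   target map), both endpoints are DE in that subtype, and their Pearson
   correlation across the subtype's tumor samples is negative with raw
   two-sided p < 0.01. The raw (uncorrected) threshold is deliberate: it is
   the network's defining filter, not an inference statement.
3. **ceRNA network.** For every pair of targets sharing at least one
   regulator miRNA in the dys-regulatory network, two criteria must hold:
   the shared-regulator count is significant under an upper-tail
   hypergeometric test (universe = the miRNA nodes of that subtype's
   dys-regulatory network; Bonferroni over the candidate pairs; adjusted
   p < 0.01), and the targets are positively co-expressed with Pearson
   r ≥ 0.5 and Bonferroni-adjusted correlation p < 0.01. Surviving pairs
   form an undirected network with all edge weights set to 1.

Downstream: hubs are the top decile of nodes by degree with boundary ties
included (cutoff count `c = ceil(0.10·|V|)`; every node whose degree reaches
the c-th largest degree is a hub, making the call independent of node
order). Hubs present in ≥ 3 subtype networks are *common*, in exactly one
*specific*, otherwise *intermediate*; the strict variant of "specific"
(absent from every other network even as a non-hub) is available behind a
flag. K-core indices come from iterative peeling and are normalized by each
network's own maximal core so layers are comparable across subtypes. The
degree distribution is checked against a power law by least squares on
log10(frequency) vs log10(degree) — transparent, though not a
maximum-likelihood exponent estimate. Gene-set enrichment of hub
sub-network genes uses the same hypergeometric kernel over a configurable
universe (default: all mRNA genes in the expression input; only
protein-coding queries are submitted since the gene-set collections are
gene-symbol based), Bonferroni corrected within each collection category.
The mutation overlay relates a per-subtype mutated-gene list to the ceRNA
network by (i) a one-sided rank-sum test of mutated vs non-mutated node
degrees, (ii) hypergeometric enrichment of mutated genes among hubs and
(iii) mean normalized k-core layer of mutated vs other nodes.

## Numerical and procedural choices

- **Rank-sum test.** Exact enumeration of the null distribution when both
  groups have ≤ `exact_limit` (default 10) samples and the pooled values are
  tie-free; otherwise the tie-corrected normal approximation *without*
  continuity correction, so symmetric inputs give p = 1 exactly. Genes with
  zero variance across both groups get p = 1 by convention and are flagged.
- **Correlation p-values** use the t transform `t = r·sqrt((n−2)/(1−r²))`
  with n−2 degrees of freedom, two-sided. Zero-variance genes are skipped
  and logged rather than propagating NaNs.
- **Hypergeometric tail** probabilities are computed once in a shared kernel
  (scipy's stable tail sum) used by the shared-miRNA test, the enrichment
  test and the mutated-hub test alike.
- **"FDR" label.** Adjusted p-values are Bonferroni but reported under the
  column name `fdr`, the label this literature conventionally prints for the
  thresholded quantity.
- **Multiplicity scopes.** DE: within RNA class and subtype. ceRNA: the
  Bonferroni factor is the number of candidate pairs actually tested in that
  subtype, applied independently to the sharing and the correlation tests.
  Enrichment: within collection category.
- **Ties and boundaries.** `r ≥ 0.5` is inclusive ("no less than"); hub
  decile boundary ties are included; a star graph on 11 nodes therefore
  yields all nodes as hubs (the second-ranked degree is a leaf degree) —
  a documented pathology of the inclusive rule, not a bug.
- **Preprocessing.** Genes with zero expression in every sample are dropped,
  then values become `log2(x + pseudocount)` with pseudocount 1 (keeps zeros
  at zero and is monotone). Matrices are genes × samples. mRNA/lncRNA
  matrices are treated as already comparable across samples; no
  re-normalization is applied.
- **Determinism.** All serialization canonicalizes undirected edges
  (lexicographically smaller endpoint first) and sorts rows; the pipeline
  manifest records every threshold and an SHA-256 checksum of every input,
  and contains no timestamps, so identical inputs give byte-identical
  output directories.

## The synthetic cohort generator

`synthetic.simulate_cohort` emulates the statistical structure the pipeline
assumes, with ground truth emitted alongside. On the log2 scale, for sample
s and target gene g:

    x_gs = mu_g + delta_g·[DE in s's subtype] + beta·S_p(s)·[g in couple p]
           + c_p(s)·[g in couple p] + eps,   eps ~ N(0, noise_sd²)

miRNA values are drawn first. The miRNAs of one couple share a per-sample
latent factor (`mirna_cluster_sd`), mimicking co-transcribed miRNA clusters
(e.g. the miR-17-92 family), and `S_p` is the baseline-centered sum of the
couple's miRNA values, so the repression slope `beta < 0` couples each
endpoint negatively to every one of its regulators and — because both
endpoints integrate the same `S_p` — positively to its partner; the couple
driver `c_p` adds further co-expression. Normal samples carry baselines and
noise only. Key defaults (chosen once as the generator's study conditions):

| parameter | default | units / meaning |
|---|---|---|
| subtypes × tumors, normals | 2 × 50, 50 | samples |
| mRNA / lncRNA / miRNA | 500 / 100 / 100 | genes |
| `de_fraction` | 0.10 | background DE genes per class per subtype |
| `de_lfc` | 1.5 | log2 shift of background DE |
| `noise_sd` | 0.5 | log2 units |
| couples × shared miRNAs | 30 × 5 | planted ceRNA pairs |
| `couple_mirna_pool` | 60 | DE miRNAs couples draw regulators from |
| `repression` | −0.5 | log2 target per unit summed centered miRNA |
| `mirna_cluster_sd`, `couple_driver_sd` | 0.7, 0.5 | latent-factor sd |
| `couple_mirna_lfc` | 2.5 | planted up-shift of pool miRNAs |
| decoy edges | 5 × planted | predicted pairs with no coupling |

Rationale for the non-obvious ones. With k independent shared miRNAs a
single miRNA can explain at most 1/k of an endpoint's variance, capping the
per-edge |r| at 1/√5 ≈ 0.45, too weak for reliable edge recovery at n = 50
and p < 0.01; the within-couple miRNA cluster factor lifts per-edge |r| to
≈ 0.65 while preserving the negative sign, which is also the realistic
regime (clustered miRNAs are strongly co-expressed). The couple-pool miRNAs
carry a stronger planted shift (2.5) because their cluster-driver variance
would otherwise make the |LFC| ≥ 1 call marginal, and one missed miRNA
removes five planted edges at once. Couple endpoints draw baselines from
the well-expressed range (12–16 log2 units) because the simulated log2
scale floors at 0 (raw expression is non-negative) and strong repression
would otherwise censor them. Couple machinery (endpoints, pool miRNAs) is
planted DE in every subtype on top of the background fraction — endpoints
down, miRNAs up, the concordant pattern bulk tumor cohorts show — because
the couple regulators must be DE for the dys-regulatory network to contain
them, and a 10%-of-100 miRNA DE pool cannot supply 30 couples × 5 miRNAs
without collapsing the hypergeometric universe to M ≈ 10, where the
sharing test is powerless by construction.

What the generator does *not* emulate: count-level (negative binomial)
noise, isoform structure, batch effects, correlated background genes, or
overlapping couples — the planted ceRNA graph is a disjoint union of edges,
so its degree distribution is flat and hub/power-law/mutation analyses are
only informative on real or designed networks (they are validated against
hand-peeled and enumerated oracles in the test suite). Passing recovery
tests therefore show that the pipeline's filters find exactly the planted
covariance structure at the stated sizes; they do not certify performance
on real cohorts with heavier tails and confounding.

## Problem sizes used in validation

Unit and property tests run on the generator's defaults (10 replicate
cohorts for recovery; 20 pure-noise cohorts for calibration), 100 random
graphs of up to 50 nodes for the k-core oracle, full enumeration of all
hypergeometric configurations with universe ≤ 15, and 200 random rank-sum
inputs with group sizes ≤ 6 against exhaustive permutation. The acceptance
script re-runs the recovery and calibration studies (10 cohorts each) plus
a 3-subtype cohort for cross-subtype hub quantities; end to end it completes
in well under a minute on one CPU.

## Known limitations

- Bonferroni control is conservative; with very large candidate-pair counts
  the ceRNA call becomes stringent (the real cohorts this design targets
  have 10³–10⁵ candidate pairs per subtype).
- The power-law check is a least-squares diagnostic, not a model test;
  exponents from sparse degree tables are noisy and flagged with a warning
  below 10 distinct degrees.
- The asymptotic rank-sum path is vectorized per gene but recomputes tie
  corrections row-wise; cohorts far larger than ~10⁴ genes × 10³ samples
  would benefit from a blocked implementation.
- Whether the sharing/correlation "P < 0.01" filters should be one- or
  two-sided is ambiguous in this literature; two-sided p-values with an
  explicit sign constraint (r < 0, or r ≥ 0.5) are used, configurable at
  the call sites.
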