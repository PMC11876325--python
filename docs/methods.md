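# Methods

This note records the models implemented in `ratecov`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and the
numerical edge cases. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Relative evolutionary rates (RER)

The substrate is a genes × branches matrix of branch lengths
(substitutions/site) on a common branch index. Branch identity is the clade —
the set of descendant leaf taxa — which makes the index stable across gene
trees with missing taxa: a gene-tree branch maps to the master branch whose
clade, restricted to the gene's taxa, is identical; when pruning makes two
master branches restrict to the same clade, neither receives a value
(ambiguous), and they stay missing for that gene. This is the standard
bipartition-matching convention; it is order-independent and testable, at the
cost of discarding length information on merged branch paths rather than
attributing their sum to one of the branches.

The rate model is multiplicative: the expected length of branch *b* in gene
*g* is `s_g * m_b`, where

* `m_b` — the reference length of branch *b*: the trimmed mean
  (`trim_frac = 0.1` per tail) of its non-missing lengths across genes.
  Trimming keeps single runaway genes from inflating a branch's reference;
  0.1 discards clear outliers while keeping the estimator efficient.
  Branches observed in fewer than `min_genes_per_branch = 3` genes, or with a
  non-positive trimmed mean, are dropped — their reference is not estimable.
* `s_g` — the gene's overall rate scale:
  `sum_b l[g,b] / sum_b m_b` over the gene's observed, retained branches.
  This is the ratio-of-sums estimator, exact under the multiplicative model
  and insensitive to which branches a gene happens to have.

RER is the log-ratio residual `log((l + eps) / (s_g * m_b + eps))` with
`eps = 1e-6` guarding zero-length branches (exactly zero lengths occur in real
gene trees; `eps` is far below any biologically meaningful length at the
substitutions/site scale). Log-ratio residuals are symmetric about 0,
scale-free, and make "twice as fast as expected" equal `log 2` on every
branch. A regression-based residual (rates regressed on the master vector) is
the main published alternative; the log-ratio form was chosen because its
invariances (global rescaling, per-gene rescaling with a fixed reference) are
exact and directly testable.

## The ERC statistic

For genes A and B: restrict both RER vectors to the n branches observed in
both; Winsorize each restricted vector with `k = 3` (the k largest values set
to the (k+1)-th largest, the k smallest to the (k+1)-th smallest); Pearson-
correlate; clamp r to ±(1 − 1e-6); report

    erc = atanh(r) * sqrt(n - 3)

Decisions behind this:

* **Winsorization is two-tailed and per-pair.** "Most extreme" is read as
  both tails, since outliers in either direction drive spurious correlation.
  It is applied to the pair-restricted vectors so each pair's statistic is
  self-contained (with no missing data this equals one global per-gene
  Winsorization, which the vectorized all-pairs path exploits; the test suite
  checks the two paths agree). If n ≤ 2k + 1 the order statistics collapse
  and the vector becomes constant — such pairs are invalid anyway under the
  default `min_branches = 10`.
* **Fisher scaling.** `atanh(r) * sqrt(n - 3)` is the variance-stabilized
  z-score: it spreads (−1, 1) onto the real line and normalizes pairs with
  different branch counts onto one comparable, approximately standard-normal
  null scale. The clamp keeps the transform finite for numerically perfect
  correlations; `atanh(1 - 1e-6) ≈ 7.25`, well outside any plausible null
  value, so clamping never masks signal.
* **Validity.** A pair is valid when n ≥ `min_branches` (default 10, and the
  transform itself needs n > 3) and neither Winsorized vector is constant.
  Invalid pairs carry NaN and are skipped by set-level means.

## The complex permutation test

The set-level statistic is the mean erc over all unordered between-set pairs
(shared members are paired once and never with themselves). The null keeps
the query set fixed and replaces the other set with `|b|` genes drawn
uniformly without replacement from the universe — all genes in the matrix
except the query set's members; whether the target's own members should also
be excluded is genuinely ambiguous, so the universe is an explicit argument.
The empirical p-value is one-sided (enrichment) with the +1 correction,
`p = (1 + #{null >= observed}) / (1 + N)`, which is never 0 and is exact under
exchangeability. An `exhaustive=True` mode enumerates every subset instead of
sampling; because the true target set is itself one of the enumerated draws
and ties with the observed statistic, the smallest exhaustive p is
2/(1 + #subsets), not 1/(1 + #subsets).

Null summaries use the finite null values only; `null_sd` is the sample
standard deviation (ddof = 1).

**Known bias at small gene counts.** The reference `m_b` is fitted from all
genes, so any two genes' residuals share its estimation error — the familiar
−1/(G−1) correlation of mean-centered residuals. At G = 200 genes this puts
the null erc mean near atanh(−1/199)·√(n−3) ≈ −0.04 (the acceptance script
computes the realized value); at a genome-wide matrix of ~12,000 genes it is
negligible. The permutation test is immune: observed and null statistics are
computed from the same matrix, so the offset cancels.

## Overlap enrichment

Intervals are 0-based half-open everywhere (BED native; GFF3's 1-based closed
coordinates become `(start−1, end)` on read; strand is ignored). The overlap
predicate is ≥ 1 shared base — no minimum-fraction threshold — and abutting
half-open intervals do not overlap. Counting merges the subject into disjoint
runs and binary-searches each query (O((n+m) log m)), verified against the
all-pairs count.

One "random genome" re-places each query interval independently and uniformly
on its own chromosome (`start ~ U[0, chrom_len − len]`), preserving lengths,
chromosome assignment and count; shuffled intervals may overlap each other,
as real peak sets may after merging. The peak set is shuffled and the
features stay fixed, because features such as replication origins are
positionally constrained biology while peaks are the measured quantity. A
`circular` mode (one common offset per chromosome, modulo its length, with
end-spilling intervals kept intact at the chromosome edge) preserves
inter-peak spacing for users who consider peak clustering part of the null;
`uniform` is the default as the simplest null consistent with independent
random placement. The empirical p-value is one-sided with the +1 correction
(depletion via a flag); a normal fit to the null counts supplies the z-score
and `p_normal` reported alongside, matching how such nulls are usually
plotted. When the null is degenerate (sd = 0), z and `p_normal` are NaN and
the empirical p stands alone.

## Synthetic generators

**Correlated rates.** `l[g,b] = s_g * m_b * exp(e[g,b])` with
`e = sigma * (rho * f_cb + sqrt(1 - rho^2) * eps_gb)` for members of a
planted complex (one shared standard-normal factor `f` per complex per
branch) and `e = sigma * eps` for background genes. `rho` is thus the latent
correlation of log-rate deviations within a complex — the direct target of
parameter recovery — and `rho = 0` gives exchangeable background genes for
null calibration. Defaults (the package's study conditions): 40 species
(78 branches), 200 genes, `sigma = 0.4`, gene scales log-uniform on
[0.5, 2], 5% missing cells re-drawn so every gene keeps ≥ 1 observation,
branch lengths Exponential(0.1 substitutions/site) on a random-join rooted
binary topology. Power checks plant one 10-gene module at `rho = 0.8` and
test a 4-member query subset against the other 6 — the shape of a
4-subunit complex screened against a 6-subunit complex.

What this emulates: rate covariation as a branch-wise shared multiplicative
factor. What it does not: phylogenetic covariance among branches (branch
noise is i.i.d. given the factor), non-stationary rates, gene-tree topology
error, alignment/estimation noise in branch lengths, or missingness that is
biased toward fast-evolving taxa. Passing tests therefore show the statistic
recovers planted covariation under clean conditions, not that real gene
trees meet these assumptions.

**Planted-enrichment genome.** Defaults follow the budding-yeast ChIP-seq
setting the analyses target: 16 chromosomes × 750 kb (12 Mb), 350
non-overlapping origin-like features of 500 bp, 605 peaks of 400 bp. Each
peak is, with probability `pi`, centered uniformly inside a uniformly chosen
feature (clipped to the chromosome; with peak ≤ feature the overlap is
guaranteed), otherwise placed uniformly on the genome (chromosome chosen
proportional to the number of valid start positions, so placement is uniform
over the genome). Features are rejection-sampled to be non-overlapping, with
a hard attempt cap (1000 × n_features) that raises with advice to lower the
density. Not emulated: the real yeast karyotype (uneven chromosome sizes,
centromeres/telomeres), peak-width variation, and spatial clustering of
peaks beyond the planted feature association.

**Determinism.** Every generator is a pure function of (config, seed); seeds
feed named `SeedSequence` spawn streams so the tree, the rate matrix and the
genome draws are independent even under the same seed. All writers stamp the
tool version and seed in a comment header; pipeline runs write a manifest
with parameter values and SHA-256 digests of inputs and outputs. Data
outputs are byte-identical across re-runs with the same config and seed (the
manifest itself records wall time and so differs).

## Problem sizes used in validation

Calibration and power suites run at the study conditions above: 200
replicate null datasets for p-value uniformity (500-permutation ERC tests,
1000-permutation overlap tests), 10 seeds for ERC recovery at
1000 permutations, 50 seeds for overlap power, 1000 random instances for the
sweep/brute-force oracle, and exhaustive-vs-sampled permutation comparison
on a 12-gene universe. The discreteness of the overlap count (null sd ≈ 3–4
at these scales) makes the empirical test slightly conservative near
p = 0.05; this is intrinsic to count-valued permutation statistics, not an
implementation artifact.

## Known limitations

* The RER reference is estimated from the input matrix itself; with few
  genes (tens) the shared-reference bias above becomes visible in raw erc
  values. Use the permutation test, not raw erc thresholds, for inference.
* Branch lengths are taken as given; no correction for their estimation
  variance or for phylogenetic non-independence of branches.
* The overlap test treats query intervals as independent under the null;
  if real peaks cluster for reasons unrelated to the subject features, the
  uniform null overstates significance (the circular mode is the provided
  alternative).
* GFF3 attribute parsing extracts `ID`/`Name` only; other attributes are
  ignored.
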