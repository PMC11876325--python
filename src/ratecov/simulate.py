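"""Synthetic data with the statistical structure the two analyses assume.

Correlated-rate model
---------------------
Gene branch lengths are generated as a gene-scale x branch-reference product
perturbed by lognormal noise,

    l[g,b] = s[g] * m[b] * exp(e[g,b]),

where for background genes e = sigma * eps with eps ~ N(0,1) i.i.d., and for
members of a designated "complex" the noise shares a per-complex, per-branch
factor f:

    e[g,b] = sigma * (rho * f[c(g),b] + sqrt(1 - rho^2) * eps[g,b]).

rho in [0,1] is then the latent pairwise correlation of log-rate deviations
within the complex — the quantity the ERC statistic is designed to detect —
and rho = 0 recovers exchangeable background genes, which calibrates the null.

Genome model
------------
A multi-chromosome genome with fixed-length, mutually non-overlapping features
(replication-origin-like) and a peak set in which each peak is, with
probability pi, centered uniformly inside a random feature (planted
enrichment) and otherwise placed uniformly on the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (BranchLengthMatrix, ComplexSet, Genome, Interval,
                 IntervalSet, SpeciesTree)

__all__ = [
    "ComplexSpec", "TreeSimConfig", "GenomeSimConfig",
    "simulate_species_tree", "simulate_branch_lengths",
    "simulate_genome_with_peaks",
]

_REJECTION_CAP_PER_FEATURE = 1000


@dataclass(frozen=True)
class ComplexSpec:
    """A planted complex: name, member gene indices, correlation strength."""

    name: str
    members: tuple[int, ...]
    rho: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass(frozen=True)
class TreeSimConfig:
    """Conditions for the correlated branch-length generator.

    Defaults describe a desk-scale study: 40 species, 200 genes, lognormal
    noise sd 0.4, gene scales log-uniform on [0.5, 2], 5% missing cells.
    """

    n_species: int = 40
    branch_length_mean: float = 0.1  # substitutions/site, exponential scale
    n_genes: int = 200
    complexes: tuple[ComplexSpec, ...] = ()
    sigma: float = 0.4
    gene_scale_range: tuple[float, float] = (0.5, 2.0)
    missing_frac: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        used: set[int] = set()
        for c in self.complexes:
            if used & set(c.members):
                raise ValueError("complex member sets must be disjoint")
            used |= set(c.members)
            if any(i < 0 or i >= self.n_genes for i in c.members):
                raise ValueError(f"complex {c.name!r} references a gene index "
                                 f"outside [0, {self.n_genes})")


@dataclass(frozen=True)
class GenomeSimConfig:
    """Conditions for the planted-enrichment genome generator.

    Defaults emulate the budding-yeast ChIP-seq setting: a 12 Mb genome in
    16 chromosomes, 350 origin-like features of 500 bp, and 605 peaks of
    400 bp (typical narrow-peak widths).
    """

    n_chrom: int = 16
    chrom_lengths: int | tuple[int, ...] = 750_000
    n_features: int = 350
    feature_length: int = 500
    n_peaks: int = 605
    peak_length: int = 400
    pi: float = 0.6  # probability a peak is placed at a feature
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.feature_length < 1 or self.peak_length < 1:
            raise ValueError("feature and peak lengths must be >= 1")
        lens = self.lengths()
        if max(self.feature_length, self.peak_length) > min(lens):
            raise ValueError("feature/peak length exceeds a chromosome")
        if self.n_features * self.feature_length > sum(lens):
            raise ValueError("features do not fit in the genome")

    def lengths(self) -> tuple[int, ...]:
        if isinstance(self.chrom_lengths, int):
            return (self.chrom_lengths,) * self.n_chrom
        if len(self.chrom_lengths) != self.n_chrom:
            raise ValueError("chrom_lengths must have n_chrom entries")
        return tuple(self.chrom_lengths)


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of a config seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def simulate_species_tree(cfg: TreeSimConfig) -> SpeciesTree:
    """Random rooted binary topology (sequential random join) with
    Exponential(branch_length_mean) branch lengths.  2n - 2 branches."""
    if cfg.n_species < 3:
        raise ValueError("need at least 3 species")
    rng = _rng(cfg.seed, 0)
    width = len(str(cfg.n_species))
    taxa = tuple(f"sp{i + 1:0{width}d}" for i in range(cfg.n_species))
    clades = [frozenset((t,)) for t in taxa]
    lengths: dict[frozenset, float] = {}
    pool = list(clades)
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        merged = pool[i] | pool[j]
        pool[i] = merged
        pool.pop(j)
        if len(pool) > 1:  # the final merge is the (unlengthed) root
            clades.append(merged)
    for clade in clades:
        lengths[clade] = float(rng.exponential(cfg.branch_length_mean))
    return SpeciesTree(taxa=taxa, lengths=lengths)


def simulate_branch_lengths(tree: SpeciesTree,
                            cfg: TreeSimConfig) -> BranchLengthMatrix:
    """Correlated lognormal branch-length matrix over the tree's branches."""
    rng = _rng(cfg.seed, 1)
    branch_ids = tree.branch_ids
    m = np.array([tree.lengths[frozenset(b.split("|"))] for b in branch_ids])
    B = len(branch_ids)
    G = cfg.n_genes
    width = len(str(G))
    genes = [f"g{i + 1:0{width}d}" for i in range(G)]

    lo, hi = cfg.gene_scale_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    e = cfg.sigma * rng.standard_normal((G, B))
    for c in cfg.complexes:
        f = rng.standard_normal(B)  # shared per complex, per branch
        idx = np.array(c.members, dtype=int)
        eps = rng.standard_normal((len(idx), B))
        e[idx] = cfg.sigma * (c.rho * f +
                              np.sqrt(1.0 - c.rho ** 2) * eps)
    lengths = s[:, None] * m[None, :] * np.exp(e)

    if cfg.missing_frac > 0:
        mask = rng.random((G, B)) < cfg.missing_frac
        all_gone = mask.all(axis=1)
        while all_gone.any():  # every gene keeps >= 1 observed branch
            mask[all_gone] = rng.random((int(all_gone.sum()), B)) < cfg.missing_frac
            all_gone = mask.all(axis=1)
        lengths = np.where(mask, np.nan, lengths)

    df = pd.DataFrame(lengths, index=genes, columns=branch_ids)
    return BranchLengthMatrix(df)


def complex_gene_names(cfg: TreeSimConfig, spec: ComplexSpec) -> tuple[str, ...]:
    """Gene ids of a planted complex's members under this config's naming."""
    width = len(str(cfg.n_genes))
    return tuple(f"g{i + 1:0{width}d}" for i in spec.members)


def planted_complex_sets(cfg: TreeSimConfig) -> list[ComplexSet]:
    return [ComplexSet(c.name, complex_gene_names(cfg, c))
            for c in cfg.complexes]


def simulate_genome_with_peaks(cfg: GenomeSimConfig,
                               ) -> tuple[Genome, IntervalSet, IntervalSet]:
    """Genome + non-overlapping features + peaks with planted enrichment pi."""
    rng = _rng(cfg.seed, 2)
    lens = cfg.lengths()
    names = tuple(f"chr{i + 1}" for i in range(cfg.n_chrom))
    genome = Genome(dict(zip(names, lens)))

    # uniform-over-genome chromosome weights for a placement of length L
    def chrom_weights(L: int) -> np.ndarray:
        w = np.array([ln - L + 1 for ln in lens], dtype=float)
        return w / w.sum()

    # features: rejection-sample non-overlapping placements
    feats: list[Interval] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    wf = chrom_weights(cfg.feature_length)
    attempts = 0
    cap = _REJECTION_CAP_PER_FEATURE * cfg.n_features
    while len(feats) < cfg.n_features:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                "could not place non-overlapping features after "
                f"{cap} attempts; lower the feature density")
        ci = int(rng.choice(cfg.n_chrom, p=wf))
        start = int(rng.integers(0, lens[ci] - cfg.feature_length + 1))
        end = start + cfg.feature_length
        if any(s < end and start < e for s, e in occupied[names[ci]]):
            continue
        occupied[names[ci]].append((start, end))
        feats.append(Interval(names[ci], start, end,
                              name=f"feat{len(feats) + 1}"))
    features = IntervalSet(feats, label="features")

    # peaks: with probability pi, centered uniformly within a random feature
    peaks: list[Interval] = []
    wp = chrom_weights(cfg.peak_length)
    L = cfg.peak_length
    for i in range(cfg.n_peaks):
        if rng.random() < cfg.pi:
            f = feats[int(rng.integers(0, len(feats)))]
            center = int(rng.integers(f.start, f.end))
            start = center - L // 2
            clen = genome.chromosomes[f.chrom]
            start = min(max(start, 0), clen - L)
            peaks.append(Interval(f.chrom, start, start + L,
                                  name=f"peak{i + 1}"))
        else:
            ci = int(rng.choice(cfg.n_chrom, p=wp))
            start = int(rng.integers(0, lens[ci] - L + 1))
            peaks.append(Interval(names[ci], start, start + L,
                                  name=f"peak{i + 1}"))
    return genome, features, IntervalSet(peaks, label="peaks")
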