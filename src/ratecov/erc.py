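"""Evolutionary rate covariation (ERC).

The pipeline is: per-gene branch lengths -> relative evolutionary rates (RER)
-> per-pair Winsorized Pearson correlation -> Fisher z scaled by branch count
-> complex-vs-complex permutation test against random gene sets.

Model
-----
For gene g and master branch b with observed length ``l[g,b]``, the reference
length ``m[b]`` is a trimmed mean of the branch's non-missing lengths across
genes, and the gene scale ``s[g]`` makes each gene's lengths comparable to the
reference over the branches the gene actually has:

    s[g] = sum_b l[g,b] / sum_b m[b]        (over the gene's present branches)

The relative evolutionary rate is the log-ratio residual

    RER[g,b] = log((l[g,b] + eps) / (s[g] * m[b] + eps))

which is 0 when the gene evolves at its expected rate on that branch, positive
on accelerated branches and negative on decelerated ones.  For two genes the
ERC statistic is the Pearson correlation r of their RER vectors over the n
branches both genes have, after Winsorizing each vector (the k most extreme
values in each tail are condensed to the (k+1)-th), mapped to an unbounded
scale by the variance-stabilizing Fisher transform

    erc = atanh(r) * sqrt(n - 3)

so that values from pairs with different branch counts are comparable and
approximately standard normal under independence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BranchLengthMatrix, ComplexSet

__all__ = [
    "RERModel", "RERMatrix", "ERCResult", "ERCMatrix", "ComplexTestResult",
    "fit_rer_model", "compute_rer", "winsorize", "erc_pair", "erc_matrix",
    "between_set_values", "complex_permutation_test",
]

DEFAULT_WINSOR_K = 3
DEFAULT_MIN_BRANCHES = 10
DEFAULT_MIN_GENES_PER_BRANCH = 3
DEFAULT_TRIM_FRAC = 0.1
DEFAULT_EPSILON = 1e-6
DEFAULT_R_CLAMP = 1e-6


@dataclass
class RERModel:
    """Reference branch lengths and per-gene scales fitted from a matrix."""

    master_lengths: pd.Series  # index: retained branch ids; all > 0
    gene_scales: pd.Series     # index: gene ids; all > 0
    epsilon: float


@dataclass
class RERMatrix:
    """Genes x branches relative evolutionary rates; NaN where unobserved."""

    df: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def branches(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class ERCResult:
    gene_a: str
    gene_b: str
    r: float      # Pearson correlation over shared branches (NaN if undefined)
    n: int        # number of shared branches
    erc: float    # Fisher-scaled value; NaN when not valid
    valid: bool


@dataclass
class ERCMatrix:
    """Symmetric gene x gene Fisher-scaled covariation with branch counts."""

    values: pd.DataFrame     # erc, diagonal NaN
    n_branches: pd.DataFrame  # shared-branch counts, int

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ComplexTestResult:
    complex_a: str
    complex_b: str
    n_pairs: int
    observed_stat: float
    null_mean: float
    null_sd: float
    p_empirical: float
    n_permutations: int
    seed: int | None


def fit_rer_model(blm: BranchLengthMatrix,
                  trim_frac: float = DEFAULT_TRIM_FRAC,
                  min_genes_per_branch: int = DEFAULT_MIN_GENES_PER_BRANCH,
                  epsilon: float = DEFAULT_EPSILON) -> RERModel:
    """Fit reference branch lengths (trimmed column means) and gene scales.

    Branches observed in fewer than ``min_genes_per_branch`` genes, or whose
    trimmed mean is not positive, are dropped from the model.
    """
    df = blm.df
    empty = df.isna().all(axis=1)
    if empty.any():
        raise ValueError(f"gene {empty.idxmax()!r} has all-missing lengths")
    counts = df.notna().sum(axis=0)
    master = pd.Series({
        b: stats.trim_mean(df[b].dropna().to_numpy(), trim_frac)
        for b in df.columns
    }, dtype=float)
    keep = (counts >= min_genes_per_branch) & (master > 0)
    master = master[keep[keep].index]
    if master.empty:
        raise ValueError("no branch satisfies min_genes_per_branch; "
                         "lower the threshold or provide more genes")
    sub = df[master.index]
    present = sub.notna()
    num = sub.sum(axis=1)  # skips NaN
    den = present.mul(master, axis=1).sum(axis=1)
    if (den <= 0).any():
        bad = den.index[den <= 0][0]
        raise ValueError(f"gene {bad!r} has no retained branches; "
                         "cannot fit a gene scale")
    scales = num / den
    return RERModel(master_lengths=master, gene_scales=scales, epsilon=epsilon)


def compute_rer(blm: BranchLengthMatrix, model: RERModel) -> RERMatrix:
    """Log-ratio relative rates: log((l + eps) / (s_g * m_b + eps))."""
    df = blm.df[model.master_lengths.index]
    expected = np.outer(model.gene_scales.reindex(df.index).to_numpy(),
                        model.master_lengths.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN propagation
        rer = np.log((df.to_numpy() + model.epsilon) /
                     (expected + model.epsilon))
    return RERMatrix(pd.DataFrame(rer, index=df.index, columns=df.columns))


def winsorize(v: np.ndarray, k: int) -> np.ndarray:
    """Condense the k most extreme values in each tail to the (k+1)-th.

    If the vector has no more than 2k + 1 entries the order statistics
    collapse and every value becomes the median.  Input order is preserved.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    v = np.asarray(v, dtype=float).copy()
    n = len(v)
    if k == 0 or n == 0:
        return v
    if n <= 2 * k + 1:
        v[:] = np.median(v)
        return v
    s = np.sort(v)
    return np.clip(v, s[k], s[n - k - 1])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def erc_pair(rer: RERMatrix, gene_a: str, gene_b: str,
             k: int = DEFAULT_WINSOR_K,
             min_branches: int = DEFAULT_MIN_BRANCHES,
             r_clamp: float = DEFAULT_R_CLAMP) -> ERCResult:
    """ERC between two genes over their shared (both-observed) branches."""
    for g in (gene_a, gene_b):
        if g not in rer.df.index:
            raise KeyError(f"gene {g!r} not in RER matrix")
    xa = rer.df.loc[gene_a].to_numpy()
    xb = rer.df.loc[gene_b].to_numpy()
    mask = ~(np.isnan(xa) | np.isnan(xb))
    n = int(mask.sum())
    r = float("nan")
    valid = False
    if n >= 2:
        wa = winsorize(xa[mask], k)
        wb = winsorize(xb[mask], k)
        r = _pearson(wa, wb)
        if not math.isnan(r):
            r = float(np.clip(r, -1.0 + r_clamp, 1.0 - r_clamp))
            valid = n >= min_branches and n > 3
    erc = math.atanh(r) * math.sqrt(n - 3) if valid else float("nan")
    return ERCResult(gene_a, gene_b, r, n, erc, valid)


def erc_matrix(rer: RERMatrix, genes: list[str] | None = None,
               k: int = DEFAULT_WINSOR_K,
               min_branches: int = DEFAULT_MIN_BRANCHES,
               r_clamp: float = DEFAULT_R_CLAMP) -> ERCMatrix:
    """All-pairs ERC.  Symmetric; the diagonal is undefined (NaN).

    When the matrix has no missing values every pair shares all branches, so
    per-pair Winsorization equals one Winsorization of each gene's full row
    and the correlation matrix is computed in a single vectorized pass; the
    general case falls back to a pairwise loop.  Both paths evaluate the same
    formula (checked against each other in the test suite).
    """
    df = rer.df if genes is None else rer.df.loc[list(genes)]
    gene_list = list(df.index)
    G = len(gene_list)
    X = df.to_numpy(dtype=float)
    if not np.isnan(X).any():
        n = X.shape[1]
        W = np.apply_along_axis(winsorize, 1, X, k)
        C = W - W.mean(axis=1, keepdims=True)
        norms = np.sqrt((C * C).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (C @ C.T) / np.outer(norms, norms)
        R = np.clip(R, -1.0 + r_clamp, 1.0 - r_clamp)
        if n >= min_branches and n > 3:
            Z = np.arctanh(R) * math.sqrt(n - 3)
        else:
            Z = np.full_like(R, np.nan)
        Z[~np.isfinite(R)] = np.nan
        np.fill_diagonal(Z, np.nan)
        counts = np.full((G, G), n, dtype=int)
    else:
        Z = np.full((G, G), np.nan)
        counts = np.zeros((G, G), dtype=int)
        present = ~np.isnan(X)
        for i, j in itertools.combinations(range(G), 2):
            mask = present[i] & present[j]
            n = int(mask.sum())
            counts[i, j] = counts[j, i] = n
            if n < 2 or n <= 3 or n < min_branches:
                continue
            wa = winsorize(X[i, mask], k)
            wb = winsorize(X[j, mask], k)
            r = _pearson(wa, wb)
            if math.isnan(r):
                continue
            r = float(np.clip(r, -1.0 + r_clamp, 1.0 - r_clamp))
            Z[i, j] = Z[j, i] = math.atanh(r) * math.sqrt(n - 3)
    values = pd.DataFrame(Z, index=gene_list, columns=gene_list)
    n_branches = pd.DataFrame(counts, index=gene_list, columns=gene_list)
    return ERCMatrix(values=values, n_branches=n_branches)


def between_set_values(m: ERCMatrix, a: ComplexSet, b: ComplexSet,
                       ) -> list[tuple[tuple[str, str], float]]:
    """ERC for every unordered pair (x in a, y in b, x != y), de-duplicated.

    Members absent from the matrix are dropped with a warning.  Values may be
    NaN when the underlying pair was not valid; callers average over the
    finite ones.
    """
    genes = set(m.genes)
    a_mem = [g for g in a.members if g in genes]
    b_mem = [g for g in b.members if g in genes]
    for cs, mem in ((a, a_mem), (b, b_mem)):
        dropped = set(cs.members) - set(mem)
        if dropped:
            warnings.warn(f"complex {cs.name!r}: members absent from ERC "
                          f"matrix dropped: {sorted(dropped)}")
    out: list[tuple[tuple[str, str], float]] = []
    seen: set[frozenset] = set()
    for x in a_mem:
        for y in b_mem:
            if x == y:
                continue
            key = frozenset((x, y))
            if key in seen:
                continue
            seen.add(key)
            out.append(((x, y), float(m.values.at[x, y])))
    if not out:
        raise ValueError(f"no pairs between complexes {a.name!r} and {b.name!r}")
    return out


def _mean_block(values: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> float:
    block = values[np.ix_(a_idx, b_idx)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(block))


def complex_permutation_test(m: ERCMatrix, a: ComplexSet, b: ComplexSet,
                             n_perm: int = 1000, seed: int | None = None,
                             universe: list[str] | None = None,
                             exhaustive: bool = False) -> ComplexTestResult:
    """Test whether mean ERC between complexes a and b exceeds chance.

    The observed statistic is the mean of the between-set ERC values.  Each
    permutation keeps a fixed and replaces b with ``|b|`` genes drawn
    uniformly without replacement from the universe (by default: all genes in
    the matrix except members of a).  The one-sided upper-tail empirical
    p-value uses the +1 correction: (1 + #{null >= obs}) / (1 + n_perm).

    With ``exhaustive=True`` every size-``|b|`` subset of the universe is
    enumerated instead of sampled (small universes only).
    """
    pairs = between_set_values(m, a, b)
    vals = np.array([v for _, v in pairs], dtype=float)
    if not np.isfinite(vals).any():
        raise ValueError("no valid (finite) between-set ERC values")
    observed = float(np.nanmean(vals))
    n_pairs = len(pairs)

    genes = m.genes
    a_set = set(a.members)
    if universe is None:
        universe = [g for g in genes if g not in a_set]
    pos = {g: i for i, g in enumerate(genes)}
    uni_idx = np.array([pos[g] for g in universe], dtype=int)
    a_idx = np.array([pos[g] for g in a.members if g in pos], dtype=int)
    b_size = len([g for g in b.members if g in pos])
    if len(uni_idx) < b_size:
        raise ValueError("universe smaller than the replacement set size")
    V = m.values.to_numpy()

    if exhaustive:
        null = np.array([
            _mean_block(V, a_idx, np.array(comb, dtype=int))
            for comb in itertools.combinations(uni_idx, b_size)
        ])
        n_draws = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(uni_idx, size=b_size, replace=False)
            null[i] = _mean_block(V, a_idx, draw)
        n_draws = n_perm
    finite = null[np.isfinite(null)]
    p = (1 + int((finite >= observed).sum())) / (1 + n_draws)
    return ComplexTestResult(
        complex_a=a.name, complex_b=b.name, n_pairs=n_pairs,
        observed_stat=observed,
        null_mean=float(finite.mean()) if finite.size else float("nan"),
        null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        p_empirical=p, n_permutations=n_draws, seed=seed)


def pairs_table(m: ERCMatrix, rer: RERMatrix | None = None) -> pd.DataFrame:
    """Long-format per-pair table (gene_a, gene_b, n, erc) from a matrix."""
    rows = []
    genes = m.genes
    for i, j in itertools.combinations(range(len(genes)), 2):
        rows.append((genes[i], genes[j],
                     int(m.n_branches.iat[i, j]), float(m.values.iat[i, j])))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n", "erc"])
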