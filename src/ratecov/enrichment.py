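"""Interval overlap counting and the random-genome permutation test.

The question: do ChIP-seq peaks (the query) fall on a class of genomic
features (the subject — e.g. replication origins) more often than expected by
chance?  The null model re-places each query interval uniformly at random on
its own chromosome, preserving interval lengths, chromosome assignment and
count ("one random genome" per permutation), and recounts the overlap.  The
empirical p-value uses the +1 correction; a normal approximation fitted to the
null counts is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Genome, Interval, IntervalSet

__all__ = [
    "OverlapResult", "EnrichmentTestResult", "count_overlapping",
    "overlap_mask", "joint_peaks", "shuffle_intervals",
    "overlap_permutation_test",
]


@dataclass
class OverlapResult:
    n_query: int
    n_overlapping: int  # query intervals sharing >= 1 base with any subject

    @property
    def percent(self) -> float:
        return 100.0 * self.n_overlapping / self.n_query if self.n_query else 0.0


@dataclass
class EnrichmentTestResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float            # (observed - null_mean) / null_sd; NaN if sd == 0
    p_empirical: float  # +1-corrected permutation p
    p_normal: float     # tail probability under a normal fitted to the null
    n_permutations: int
    seed: int | None
    alternative: str = "enrichment"


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted-by-start intervals into disjoint runs."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _subject_index(subject: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: _merge(np.array([s for s, _ in ivs], dtype=np.int64),
                      np.array([e for _, e in ivs], dtype=np.int64))
        for chrom, ivs in by_chrom.items()
    }


def _mask_against_index(chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
                        index: dict[str, tuple[np.ndarray, np.ndarray]],
                        ) -> np.ndarray:
    """Boolean per query interval: overlaps >= 1 base of the merged subject.

    Sorted sweep via binary search: with merged, disjoint subject runs, a
    query [s, e) overlaps some run iff the last run starting before e ends
    after s.
    """
    hit = np.zeros(len(start), dtype=bool)
    for c in np.unique(chrom):
        if c not in index:
            continue
        ms, me = index[c]
        sel = chrom == c
        qs, qe = start[sel], end[sel]
        idx = np.searchsorted(ms, qe, side="left") - 1
        ok = idx >= 0
        ok[ok] = me[idx[ok]] > qs[ok]
        hit[sel] = ok
    return hit


def overlap_mask(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query boolean overlap indicator, in query order."""
    chrom, start, end = query.arrays()
    return _mask_against_index(chrom, start, end, _subject_index(subject))


def count_overlapping(query: IntervalSet, subject: IntervalSet) -> OverlapResult:
    """Count query intervals touching (>= 1 shared base) any subject interval."""
    mask = overlap_mask(query, subject)
    return OverlapResult(n_query=len(query), n_overlapping=int(mask.sum()))


def joint_peaks(a: IntervalSet, b: IntervalSet, label: str | None = None,
                ) -> IntervalSet:
    """The subset of a's intervals overlapping >= 1 interval of b.

    Coordinates of a are preserved; the label records both parents.
    """
    mask = overlap_mask(a, b)
    kept = [iv for iv, m in zip(a.intervals, mask) if m]
    return IntervalSet(kept, label or f"{a.label}&{b.label}")


def shuffle_intervals(s: IntervalSet, genome: Genome,
                      rng: np.random.Generator,
                      mode: str = "uniform") -> IntervalSet:
    """Produce one "random genome": re-place every interval at random.

    mode="uniform" (default): each interval is independently re-placed on its
    own chromosome with start ~ uniform integer in [0, chrom_len - length];
    lengths, chromosome assignment and count are preserved, and shuffled
    intervals may overlap each other.

    mode="circular": all intervals on a chromosome are shifted by one common
    uniform offset modulo the chromosome length (inter-peak spacing preserved
    up to the wrap seam); an interval whose end would run past the chromosome
    is wrapped back to the start intact.
    """
    s.validate_against(genome)
    out: list[Interval] = []
    if mode == "uniform":
        for iv in s:
            clen = genome.chromosomes[iv.chrom]
            if iv.length > clen:
                raise ValueError(
                    f"interval of length {iv.length} exceeds {iv.chrom}")
            start = int(rng.integers(0, clen - iv.length + 1))
            out.append(Interval(iv.chrom, start, start + iv.length, iv.name))
    elif mode == "circular":
        offsets = {c: int(rng.integers(0, ln))
                   for c, ln in genome.chromosomes.items()}
        for iv in s:
            clen = genome.chromosomes[iv.chrom]
            if iv.length > clen:
                raise ValueError(
                    f"interval of length {iv.length} exceeds {iv.chrom}")
            start = (iv.start + offsets[iv.chrom]) % clen
            if start + iv.length > clen:
                start = clen - iv.length  # keep the wrapped interval intact
            out.append(Interval(iv.chrom, start, start + iv.length, iv.name))
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return IntervalSet(out, label=f"{s.label}|shuffled")


def overlap_permutation_test(query: IntervalSet, subject: IntervalSet,
                             genome: Genome, n_perm: int = 10000,
                             seed: int | None = None,
                             alternative: str = "enrichment",
                             mode: str = "uniform") -> EnrichmentTestResult:
    """Permutation test of query/subject overlap against random genomes.

    The observed statistic is the number of query intervals overlapping the
    subject; each permutation shuffles the query (features stay fixed) and
    recounts.  ``alternative`` is "enrichment" (upper tail, default) or
    "depletion" (lower tail).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("enrichment", "depletion"):
        raise ValueError(f"unknown alternative {alternative!r}")
    query.validate_against(genome)
    index = _subject_index(subject)
    chrom, start, end = query.arrays()
    lengths = end - start
    observed = int(_mask_against_index(chrom, start, end, index).sum())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    chrom_len = np.array([genome.chromosomes[c] for c in chrom], dtype=np.int64)
    if (lengths > chrom_len).any():
        raise ValueError("an interval is longer than its chromosome")
    if mode == "uniform":
        high = chrom_len - lengths + 1
        for i in range(n_perm):
            ns = rng.integers(0, high)
            null[i] = int(_mask_against_index(chrom, ns, ns + lengths,
                                              index).sum())
    elif mode == "circular":
        chrom_names = list(genome.chromosomes)
        cpos = np.array([chrom_names.index(c) for c in chrom])
        clens = np.array([genome.chromosomes[c] for c in chrom_names],
                         dtype=np.int64)
        for i in range(n_perm):
            offs = rng.integers(0, clens)
            ns = (start + offs[cpos]) % chrom_len
            over = ns + lengths > chrom_len
            ns[over] = chrom_len[over] - lengths[over]
            null[i] = int(_mask_against_index(chrom, ns, ns + lengths,
                                              index).sum())
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    if null_sd and math.isfinite(null_sd) and null_sd > 0:
        z = (observed - null_mean) / null_sd
        p_normal = float(stats.norm.sf(z)) if alternative == "enrichment" \
            else float(stats.norm.cdf(z))
    else:
        z = float("nan")
        p_normal = float("nan")
    if alternative == "enrichment":
        exceed = int((null >= observed).sum())
    else:
        exceed = int((null <= observed).sum())
    p_emp = (1 + exceed) / (1 + n_perm)
    return EnrichmentTestResult(
        observed=observed, null_mean=null_mean, null_sd=null_sd, z=z,
        p_empirical=p_emp, p_normal=p_normal, n_permutations=n_perm,
        seed=seed, alternative=alternative)
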