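"""Mining maximal irreducible regions of coverage.

An interval of a coverage vector is *irreducible* at threshold mu when every
split into two parts leaves both parts with mean value >= mu (for a single
position: value >= mu).  Irreducible intervals tolerate short interior dips
below mu — an exon whose coverage sags over a GC-poor stretch is still one
region — while provably starting and ending with a value >= mu, so region
boundaries sit only where expression is genuinely high.  The quantity mined
is usually raw or smoothed coverage, but any non-negative per-nucleotide
signal (region-based coverage, |splicing index|) works the same way.

Mining returns the *maximal* irreducible intervals: those contained in no
longer irreducible interval.  Overlapping or touching irreducible intervals
always merge into a larger irreducible interval, so the maximal ones are
pairwise disjoint.  A minimum-width filter (``minsup``) is applied after
maximality — setting it above the read length suppresses single-stack
artifacts such as PCR over-amplification towers.

Implementation notes
--------------------
Let ``w = values - mu`` and ``S`` its prefix-sum array (``S[0] = 0``).  The
interval ``[a, b)`` is irreducible iff ``S[a] = min S[a..b]`` and
``S[b] = max S[a..b]``: the prefix condition says no prefix mean falls below
mu, the suffix condition the same for suffixes.  For every start ``a`` the
longest irreducible interval is ``[a, B(a))`` where ``B(a)`` is the rightmost
argmax of ``S`` strictly between ``a`` and the first position where ``S``
drops below ``S[a]``.  Because overlapping/touching irreducible intervals
merge, the maximal intervals are exactly the connected runs of the union of
all ``[a, B(a))`` — computed here with a monotone stack for the "next
smaller" positions and a sparse table for range argmax, O(n log n) overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .coverage import CoverageTrack, TrackKind
from .errors import ConfigurationError, DomainError
from .intervals import GenomicInterval

#: conventional detection threshold for "expressed" coverage
DEFAULT_MU = 5.0


def default_minsup(read_length: int) -> int:
    """Minimum region width that suppresses a single stack of duplicated
    reads: one nucleotide more than the read length."""
    return read_length + 1


@dataclass(frozen=True)
class MiningParams:
    """Tuning knobs of the region miner.

    ``mu``     — coverage threshold defining "expressed" (>= 0).
    ``minsup`` — minimum region width in nucleotides (>= 1).
    ``strict`` — if True, prefix/suffix means must exceed mu strictly.
                 The default is non-strict (>=): on integer coverage,
                 equality with mu is common and the single-position base
                 case (value >= mu) forces >= for consistency.
    """

    mu: float = DEFAULT_MU
    minsup: int = 51
    strict: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ConfigurationError(f"mu must be >= 0, got {self.mu}")
        if self.minsup < 1:
            raise ConfigurationError(f"minsup must be >= 1, got {self.minsup}")


@dataclass(frozen=True)
class IrreducibleRegion:
    """A mined interval, its mean signal, and the parameters that found it."""

    interval: GenomicInterval
    mean_value: float
    params: MiningParams

    def length(self) -> int:
        return self.interval.length()


def _check_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise DomainError("values must be a non-empty 1-D vector")
    if np.any(values < 0):
        raise DomainError("mining operates on non-negative signals")
    return values


def is_irreducible(values: Sequence[float], mu: float, strict: bool = False) -> bool:
    """Does every split of ``values`` leave both halves with mean >= mu?

    Equivalent formulation (the one computed): every prefix mean and every
    suffix mean is >= mu.  A single value is irreducible iff it is >= mu.
    Strict mode replaces >= by >.
    """
    v = _check_values(values)
    S = np.concatenate(([0.0], np.cumsum(v - mu)))
    prefixes = S[1:] - S[0]
    suffixes = S[-1] - S[:-1]
    if strict:
        return bool(np.all(prefixes > 0) and np.all(suffixes > 0))
    return bool(np.all(prefixes >= 0) and np.all(suffixes >= 0))


# ---------------------------------------------------------------------------
# fast maximal-interval computation


def _next_smaller(S: np.ndarray, strict: bool) -> np.ndarray:
    """f[a] = smallest k > a with S[k] < S[a] (<= in strict mode), else len(S).

    Positions b of irreducible intervals starting at a must satisfy
    a < b < f[a].
    """
    n = len(S)
    f = np.full(n, n, dtype=np.int64)
    stack: list[int] = []  # indices with S values forming the active frontier
    Sl = S.tolist()  # list indexing is much faster in the Python loop
    if strict:
        for k in range(n):
            sk = Sl[k]
            while stack and sk <= Sl[stack[-1]]:
                f[stack.pop()] = k
            stack.append(k)
    else:
        for k in range(n):
            sk = Sl[k]
            while stack and sk < Sl[stack[-1]]:
                f[stack.pop()] = k
            stack.append(k)
    return f


def _sparse_argmax_table(S: np.ndarray, prefer_right: bool) -> list[np.ndarray]:
    """Sparse table of range-argmax indices; ties resolved rightmost
    (non-strict mode) or leftmost (strict mode)."""
    n = len(S)
    table = [np.arange(n, dtype=np.int64)]
    j = 1
    while (1 << j) <= n:
        prev = table[-1]
        half = 1 << (j - 1)
        m = n - (1 << j) + 1
        left = prev[:m]
        right = prev[half : half + m]
        if prefer_right:
            take_right = S[right] >= S[left]
        else:
            take_right = S[right] > S[left]
        table.append(np.where(take_right, right, left))
        j += 1
    return table


def _range_argmax(
    table: list[np.ndarray],
    S: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    prefer_right: bool,
) -> np.ndarray:
    """Vectorised argmax of S over the half-open index ranges [lo, hi)."""
    length = hi - lo
    out = np.empty(len(lo), dtype=np.int64)
    k = np.int64(np.floor(np.log2(length)))  # length >= 1 guaranteed by caller
    for kk in np.unique(k):
        mask = k == kk
        l = table[kk][lo[mask]]
        r = table[kk][hi[mask] - (1 << int(kk))]
        if prefer_right:
            take_right = S[r] >= S[l]
        else:
            take_right = S[r] > S[l]
        out[mask] = np.where(take_right, r, l)
    return out


def maximal_irreducible_intervals(
    values: Sequence[float], mu: float, strict: bool = False
) -> list[tuple[int, int]]:
    """All maximal irreducible intervals of a vector, as local (start, end).

    No width filter is applied here; ``minsup`` is a post-filter on the
    maximal intervals (sub-intervals of a long region are never re-reported
    just to satisfy the width condition).
    """
    v = _check_values(values)
    n = v.size
    S = np.empty(n + 1)
    S[0] = 0.0
    np.cumsum(v - mu, out=S[1:])

    f = _next_smaller(S, strict)
    # candidate starts: an irreducible interval starting at a needs
    # S[a+1] >= S[a] (first value >= mu), i.e. a non-empty (a, f[a]) range
    starts = np.nonzero(f[:n] > np.arange(1, n + 1))[0]
    if len(starts) == 0:
        return []
    table = _sparse_argmax_table(S, prefer_right=not strict)
    best_end = _range_argmax(
        table, S, starts + 1, f[starts], prefer_right=not strict
    )

    # union of [a, best_end(a)) -> connected runs = maximal intervals
    reach = np.arange(n + 1, dtype=np.int64)  # default: no interval starts here
    reach[starts] = best_end
    running = np.maximum.accumulate(reach[:n])
    covered = running > np.arange(n)
    if not covered.any():
        return []
    edges = np.diff(covered.astype(np.int8))
    run_starts = np.nonzero(edges == 1)[0] + 1
    run_ends = np.nonzero(edges == -1)[0] + 1
    if covered[0]:
        run_starts = np.concatenate(([0], run_starts))
    if covered[-1]:
        run_ends = np.concatenate((run_ends, [n]))
    return list(zip(run_starts.tolist(), run_ends.tolist()))


def _to_regions(
    intervals: Iterable[tuple[int, int]],
    values: np.ndarray,
    params: MiningParams,
    region: GenomicInterval | None,
) -> list[IrreducibleRegion]:
    chrom = region.chrom if region is not None else "region"
    strand = region.strand if region is not None else "."
    offset = region.start if region is not None else 0
    out = []
    for s, e in intervals:
        if e - s < params.minsup:
            continue
        out.append(
            IrreducibleRegion(
                GenomicInterval(chrom, offset + s, offset + e, strand),
                float(np.mean(values[s:e])),
                params,
            )
        )
    return out


def find_irreducible_regions(
    track: CoverageTrack, sample: str, params: MiningParams
) -> list[IrreducibleRegion]:
    """Maximal irreducible regions of one sample's signal, width-filtered.

    Returned regions are sorted, pairwise disjoint, carry genome coordinates
    (the track's origin applied) and their mean signal value.
    """
    values = track.sample_values(sample)
    intervals = maximal_irreducible_intervals(values, params.mu, params.strict)
    return _to_regions(intervals, np.asarray(values, dtype=float), params, track.region)


# ---------------------------------------------------------------------------
# brute-force oracle

BRUTE_FORCE_GUARD = 10_000


def brute_force_regions(
    values: Sequence[float],
    params: MiningParams,
    region: GenomicInterval | None = None,
) -> list[IrreducibleRegion]:
    """Exhaustive-enumeration reference for the mining contract.

    Enumerates every interval, tests irreducibility from the prefix-sum
    characterisation, keeps the intervals contained in no longer irreducible
    interval, then applies the width filter.  Refuses vectors longer than
    ``BRUTE_FORCE_GUARD`` — it exists as a test oracle, not for analysis.
    """
    v = _check_values(values)
    n = v.size
    if n > BRUTE_FORCE_GUARD:
        raise ConfigurationError(
            f"brute-force oracle refuses n={n} > {BRUTE_FORCE_GUARD}"
        )
    S = np.concatenate(([0.0], np.cumsum(v - params.mu)))
    # running min/max of S from every start: run_min[a, k] = min S[a..a+k]
    offs = np.minimum(np.arange(n + 1)[None, :] + np.arange(n + 1)[:, None], n)
    shifted = S[offs]  # shifted[a, k] = S[min(a+k, n)]
    run_min = np.minimum.accumulate(shifted, axis=1)
    run_max = np.maximum.accumulate(shifted, axis=1)
    covered = np.zeros(n, dtype=bool)
    for a in range(n):
        ks = np.arange(1, n - a + 1)
        ends = S[a + ks]
        if params.strict:
            # S[a] strictly below S[a+1..b]; S[b] strictly above S[a..b-1]
            ok = (run_min[a + 1][ks - 1] > S[a]) & (ends > run_max[a][ks - 1])
        else:
            ok = (run_min[a][ks] >= S[a]) & (ends >= run_max[a][ks])
        if ok.any():
            # union over irreducible [a, b) at this start = [a, largest b)
            covered[a : a + int(ks[ok][-1])] = True
    # maximal irreducible intervals = connected runs of covered positions
    intervals: list[tuple[int, int]] = []
    p = 0
    while p < n:
        if covered[p]:
            q = p
            while q < n and covered[q]:
                q += 1
            intervals.append((p, q))
            p = q
        else:
            p += 1
    return _to_regions(intervals, v, params, region)


# ---------------------------------------------------------------------------
# region-based coverage and cross-sample support


def region_based_coverage(
    track: CoverageTrack,
    sample: str,
    mu_ladder: Sequence[float],
    minsup: int,
    strict: bool = False,
) -> CoverageTrack:
    """Discretised coverage: each position gets the largest mu of a ladder at
    which it lies inside a mined region, else 0.

    Mining at several thresholds and keeping the highest supported one makes
    the coverage profile 'human readable' and erases over-amplification
    peaks and shallow local minima in one pass.
    """
    ladder = [float(m) for m in mu_ladder]
    if not ladder:
        raise ConfigurationError("mu ladder must be non-empty")
    if any(m <= 0 for m in ladder) or any(
        b <= a for a, b in zip(ladder, ladder[1:])
    ):
        raise ConfigurationError(
            f"mu ladder must be strictly increasing and positive: {ladder}"
        )
    values = track.sample_values(sample)
    out = np.zeros(len(values))
    for mu in ladder:  # ascending: later (higher) levels overwrite
        params = MiningParams(mu=mu, minsup=minsup, strict=strict)
        for s, e in maximal_irreducible_intervals(values, mu, strict):
            if e - s >= minsup:
                out[s:e] = mu
    return CoverageTrack(track.region, [sample], out[None, :], TrackKind.REGION_BASED)


def support_filter(
    per_sample_regions: Mapping[str, Sequence[IrreducibleRegion]],
    gene: GenomicInterval,
    min_samples: int,
) -> bool:
    """Does a gene contain mined regions in at least ``min_samples`` samples?"""
    if min_samples < 1:
        raise ConfigurationError("min_samples must be >= 1")
    return support_count(per_sample_regions, gene) >= min_samples


def support_count(
    per_sample_regions: Mapping[str, Sequence[IrreducibleRegion]],
    gene: GenomicInterval,
) -> int:
    """Number of samples with >= 1 mined region overlapping the gene.

    A gene counts once per sample no matter how many regions it contains.
    """
    return sum(
        any(r.interval.overlaps(gene) for r in regions)
        for regions in per_sample_regions.values()
    )


# ---------------------------------------------------------------------------
# mu resolvers: adaptive threshold strategies

MuResolver = Callable[[np.ndarray], float]


def fixed_mu(value: float = DEFAULT_MU) -> MuResolver:
    """The simple strategy: one detection threshold for everything."""
    return lambda values: float(value)


def fraction_of_max(fraction: float) -> MuResolver:
    """mu = fraction * max(coverage) of the current slice."""
    if not 0 < fraction <= 1:
        raise ConfigurationError(f"fraction must be in (0, 1]: {fraction}")
    return lambda values: float(fraction * np.max(values))


def fraction_of_min(fraction: float) -> MuResolver:
    """mu = fraction * min(coverage) of the current slice."""
    if fraction <= 0:
        raise ConfigurationError(f"fraction must be positive: {fraction}")
    return lambda values: float(fraction * np.min(values))
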