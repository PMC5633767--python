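"""Read-depth segmentation and copy-number classification.

Pipeline stages mirror the standard resequencing workflow for segmental
deletion/duplication discovery in a reference-aligned genome:

1. median depth over 1000-bp bins (``bin_median``);
2. circular binary segmentation (CBS) into constant-mean segments
   (``segment_track``): recursive search for the arc [i, j) maximizing the
   two-sample t-statistic between arc and complement, accepted by a
   permutation test;
3. merging of adjacent >=50-kb segments with the same mean unless separated
   by a gap larger than 50 kb, and dissolution of sub-50-kb segments
   (``merge_filter_segments``);
4. classification against per-chromosome depth statistics: segments more
   than one standard deviation above the chromosome mean are duplications,
   more than one below are deletions (``classify_segments``).

Coordinates are 0-based half-open bp; bins are contiguous from position 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CoverageTrack",
    "CoverageSegment",
    "ChromStats",
    "bin_median",
    "chrom_stats",
    "segment_track",
    "merge_filter_segments",
    "classify_segments",
    "segment_and_classify",
]


class InputError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Binned depth for one chromosome: contiguous bins from position 0,
    ``gap`` flags bins with no aligned data (excluded from all statistics)."""

    chrom: str
    bin_size: int
    values: np.ndarray
    gap: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gap is None:
            self.gap = np.zeros(self.values.size, dtype=bool)
        self.gap = np.asarray(self.gap, dtype=bool)
        if self.gap.size != self.values.size:
            raise InputError("gap mask and values must have equal length")
        if np.any(self.values[~self.gap] < 0):
            raise InputError("negative depth values")

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CoverageSegment:
    chrom: str
    start: int          # bp, half-open
    end: int
    mean_cov: float
    n_bins: int
    cls: str | None = None   # "deletion" | "normal" | "duplication"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromStats:
    chrom: str
    mean_cov: float
    sd_cov: float


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    half = cw[-1] / 2.0
    idx = int(np.searchsorted(cw, half, side="left"))
    if cw[idx] == half and idx + 1 < v.size:
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


def bin_median(
    intervals,
    chrom: str = "",
    bin_size: int = 1000,
    chrom_length: int | None = None,
) -> CoverageTrack:
    """Median depth over fixed-size bins from a per-bp (or finer-bin) track.

    ``intervals`` is an (N, 3) array-like or DataFrame of sorted,
    non-overlapping half-open rows (start, end, depth) as read from a
    bedGraph.  Each bin's value is the median over its *covered* positions;
    bins with no data become gap bins; a final partial bin keeps its own
    median.
    """
    arr = np.asarray(intervals, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise InputError("expected rows of (start, end, depth)")
    starts, ends, depths = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(depths < 0):
        raise InputError("negative depth values")
    if np.any(ends <= starts):
        raise InputError("empty or inverted intervals")
    if np.any(starts[1:] < ends[:-1]):
        bad = int(np.argmax(starts[1:] < ends[:-1])) + 1
        raise InputError(f"intervals unsorted or overlapping at row {bad}")
    total = int(chrom_length if chrom_length is not None else ends[-1])
    n_bins = -(-total // bin_size)
    values = np.zeros(n_bins)
    gap = np.ones(n_bins, dtype=bool)
    k = 0  # index of first interval possibly overlapping current bin
    for b in range(n_bins):
        lo, hi = b * bin_size, min((b + 1) * bin_size, total)
        while k < len(starts) and ends[k] <= lo:
            k += 1
        vs, ws = [], []
        j = k
        while j < len(starts) and starts[j] < hi:
            ov = min(ends[j], hi) - max(starts[j], lo)
            if ov > 0:
                vs.append(depths[j])
                ws.append(ov)
            j += 1
        if vs:
            values[b] = _weighted_median(np.asarray(vs), np.asarray(ws, dtype=float))
            gap[b] = False
    return CoverageTrack(chrom=chrom, bin_size=bin_size, values=values, gap=gap)


def chrom_stats(track: CoverageTrack) -> ChromStats:
    """Arithmetic mean and population SD of depth over non-gap bins."""
    v = track.values[~track.gap]
    if v.size == 0:
        raise InputError(f"no data bins on {track.chrom}")
    return ChromStats(track.chrom, float(v.mean()), float(v.std(ddof=0)))


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _best_arc(x: np.ndarray, minw: int) -> tuple[float, int, int]:
    """Maximal between-group sum of squares over all arcs [i, j) with both the
    arc and its (circular) complement at least ``minw`` bins.  The two-sample
    t-statistic is a monotone function of this quantity at fixed total SS, so
    the argmax and the permutation test are equivalent to max-|t| search."""
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    mu = S[-1] / n
    best, bi, bj = -1.0, 0, n
    for k in range(minw, n - minw + 1):
        A = S[k:] - S[:-k]
        B = (A - k * mu) ** 2 * (n / (k * (n - k)))
        i = int(np.argmax(B))
        if B[i] > best:
            best, bi, bj = float(B[i]), i, i + k
    return best, bi, bj


def _perm_batch_max(x: np.ndarray, rng: np.random.Generator, batch: int, minw: int) -> np.ndarray:
    """Max between-group SS for ``batch`` random permutations of x."""
    n = x.size
    X = rng.permuted(np.tile(x, (batch, 1)), axis=1)
    S = np.concatenate([np.zeros((batch, 1)), np.cumsum(X, axis=1)], axis=1)
    mu = S[:, -1:] / n
    best = np.zeros(batch)
    for k in range(minw, n - minw + 1):
        A = S[:, k:] - S[:, : n + 1 - k]
        B = (A - k * mu) ** 2 * (n / (k * (n - k)))
        np.maximum(best, B.max(axis=1), out=best)
    return best


def _arc_significant(
    x: np.ndarray,
    b_obs: float,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
    minw: int,
    batch: int = 50,
) -> bool:
    """Sequential permutation test on the max-arc statistic.

    Permutations run in batches with two early exits: the split is rejected
    as soon as enough permuted maxima exceed the observed one that the final
    p-value is certain to land above alpha, and accepted as soon as the
    running estimate (1+e)/(1+m) is at or below alpha with at least
    ceil(1/alpha) permutations drawn (the smallest count that can certify
    the level).
    """
    e, m = 0, 0
    m_accept = max(1, int(np.ceil(1.0 / alpha)))
    # small first batch rejects clear nulls cheaply; second lands exactly on
    # the earliest possible acceptance count
    schedule = [batch // 2, m_accept - batch // 2] if m_accept > batch // 2 else [batch]
    step = 0
    while m < n_permutations:
        nb = schedule[step] if step < len(schedule) else batch
        step += 1
        nb = max(1, min(nb, n_permutations - m))
        maxima = _perm_batch_max(x, rng, nb, minw)
        e += int(np.sum(maxima >= b_obs))
        m += nb
        if (1 + e) / (1 + n_permutations) > alpha:
            return False
        if m >= m_accept and (1 + e) / (1 + m) <= alpha:
            return True
    return (1 + e) / (1 + m) <= alpha


def _cbs_recurse(
    x: np.ndarray,
    offset: int,
    alpha: float,
    minw: int,
    n_permutations: int,
    rng: np.random.Generator,
    breakpoints: list[int],
) -> None:
    n = x.size
    if n < 2 * minw:
        return
    sstot = float(np.sum((x - x.mean()) ** 2))
    if sstot <= 0:
        return
    b_obs, i, j = _best_arc(x, minw)
    if b_obs <= 0:
        return
    if not _arc_significant(x, b_obs, alpha, n_permutations, rng, minw):
        return
    cuts = [c for c in (i, j) if 0 < c < n]
    breakpoints.extend(offset + c for c in cuts)
    edges = [0, *cuts, n]
    for lo, hi in zip(edges[:-1], edges[1:]):
        _cbs_recurse(x[lo:hi], offset + lo, alpha, minw, n_permutations, rng, breakpoints)


def segment_track(
    track: CoverageTrack,
    alpha: float = 0.01,
    min_width_bins: int = 3,
    seed: int = 0,
    n_permutations: int = 1000,
) -> list[CoverageSegment]:
    """Partition a binned track into constant-mean raw segments by CBS.

    Gap bins carry no data: they are excluded from all statistics and break
    the track into independently segmented stretches.  Each accepted
    breakpoint's permutation p-value is at most ``alpha``.  Returns raw
    (unclassified) segments in coordinate order.
    """
    rng = np.random.default_rng(seed)
    good = ~track.gap
    if not good.any():
        warnings.warn(f"all-gap track {track.chrom}; nothing to segment")
        return []
    segments: list[CoverageSegment] = []
    # contiguous non-gap stretches
    idx = np.flatnonzero(good)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for chunk in np.split(idx, splits):
        x = track.values[chunk]
        breakpoints: list[int] = []
        if x.size >= 2:
            _cbs_recurse(x, 0, alpha, min_width_bins, n_permutations, rng, breakpoints)
        edges = [0, *sorted(breakpoints), x.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            b0, b1 = int(chunk[lo]), int(chunk[hi - 1]) + 1
            segments.append(
                CoverageSegment(
                    chrom=track.chrom,
                    start=b0 * track.bin_size,
                    end=b1 * track.bin_size,
                    mean_cov=float(x[lo:hi].mean()),
                    n_bins=hi - lo,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# merging / filtering / classification
# ---------------------------------------------------------------------------

def _merge_pair(a: CoverageSegment, b: CoverageSegment) -> CoverageSegment:
    n = a.n_bins + b.n_bins
    mean = (a.mean_cov * a.n_bins + b.mean_cov * b.n_bins) / n
    return CoverageSegment(a.chrom, a.start, b.end, mean, n, None)


def merge_filter_segments(
    segments: list[CoverageSegment],
    min_length: int = 50_000,
    gap_limit: int = 50_000,
    mean_tol: float = 0.10,
    ref_mean: float | None = None,
) -> list[CoverageSegment]:
    """Merge adjacent same-mean segments and dissolve sub-minimum segments.

    Adjacent segments merge when their means differ by at most
    ``mean_tol * ref_mean`` (a relative stand-in for "the same mean coverage
    value") and the intervening coordinate gap is at most ``gap_limit``.
    Segments shorter than ``min_length`` are absorbed into the nearest
    mean-compatible neighbour, or dropped; all output segments are at least
    ``min_length`` long.
    """
    if not segments:
        return []
    segs = sorted(segments, key=lambda s: s.start)
    if ref_mean is None:
        tot = sum(s.n_bins for s in segs)
        ref_mean = sum(s.mean_cov * s.n_bins for s in segs) / tot
    tol = mean_tol * ref_mean

    def compatible(a: CoverageSegment, b: CoverageSegment) -> bool:
        return b.start - a.end <= gap_limit and abs(a.mean_cov - b.mean_cov) <= tol

    changed = True
    while changed:
        changed = False
        # merge pass
        merged: list[CoverageSegment] = [segs[0]]
        for s in segs[1:]:
            if compatible(merged[-1], s):
                merged[-1] = _merge_pair(merged[-1], s)
                changed = True
            else:
                merged.append(s)
        segs = merged
        # dissolve one short segment per sweep (then re-merge)
        for i, s in enumerate(segs):
            if s.length >= min_length:
                continue
            neighbours = []
            if i > 0 and compatible(segs[i - 1], s):
                neighbours.append((abs(segs[i - 1].mean_cov - s.mean_cov), i - 1))
            if i + 1 < len(segs) and compatible(s, segs[i + 1]):
                neighbours.append((abs(segs[i + 1].mean_cov - s.mean_cov), i + 1))
            if neighbours:
                _, j = min(neighbours)
                lo, hi = min(i, j), max(i, j)
                segs[lo:hi + 1] = [_merge_pair(segs[lo], segs[hi])]
            else:
                del segs[i]
            changed = True
            break
    return [s for s in segs if s.length >= min_length]


def refine_boundaries(
    track: CoverageTrack,
    segments: list[CoverageSegment],
    window_bins: int = 25,
) -> list[CoverageSegment]:
    """Re-fit each boundary between coordinate-adjacent segments by exact
    maximum likelihood: the cut position minimizing the residual sum of
    squares of the two flanking stretches.  Merging can drag a boundary a
    few bins when a short transition segment is absorbed; this local
    re-optimization restores the best single-changepoint estimate.  The cut
    may move at most ``window_bins`` and never past a segment midpoint.
    """
    if len(segments) < 2:
        return segments
    segs = sorted(segments, key=lambda s: s.start)
    bs = track.bin_size
    out = [segs[0]]
    for b in segs[1:]:
        a = out[-1]
        if a.end != b.start or a.chrom != b.chrom:
            out.append(b)
            continue
        a0, cut, b1 = a.start // bs, a.end // bs, -(-b.end // bs)
        lo = max(a0 + 1, cut - window_bins, (a0 + cut) // 2)
        hi = min(b1 - 1, cut + window_bins, -(-(cut + b1) // 2))
        x = track.values[a0:b1]
        S = np.concatenate(([0.0], np.cumsum(x)))
        S2 = np.concatenate(([0.0], np.cumsum(x**2)))
        cands = np.arange(lo, hi + 1) - a0
        n1 = cands.astype(float)
        n2 = (b1 - a0) - n1
        s1, s2 = S[cands], S[-1] - S[cands]
        sse = (S2[-1] - s1**2 / n1 - s2**2 / n2)
        best = int(cands[np.argmin(sse)]) + a0
        k1, k2 = best - a0, b1 - best
        out[-1] = replace(a, end=best * bs, mean_cov=float(S[best - a0] / k1),
                          n_bins=k1)
        out.append(replace(b, start=best * bs,
                           mean_cov=float((S[-1] - S[best - a0]) / k2), n_bins=k2))
    return out


def classify_segments(
    segments: list[CoverageSegment],
    stats: ChromStats,
    k: float = 1.0,
) -> list[CoverageSegment]:
    """Classify each segment against chromosome depth statistics: mean above
    mu + k*sd -> duplication, below mu - k*sd -> deletion, else normal."""
    if stats.sd_cov == 0 and any(s.mean_cov != stats.mean_cov for s in segments):
        warnings.warn(f"degenerate stats (sd=0) on {stats.chrom}; strict inequality applies")
    out = []
    for s in segments:
        if s.mean_cov > stats.mean_cov + k * stats.sd_cov:
            cls = "duplication"
        elif s.mean_cov < stats.mean_cov - k * stats.sd_cov:
            cls = "deletion"
        else:
            cls = "normal"
        out.append(replace(s, cls=cls))
    return out


def segment_and_classify(
    track: CoverageTrack,
    alpha: float = 0.01,
    min_width_bins: int = 3,
    min_length: int = 50_000,
    gap_limit: int = 50_000,
    mean_tol: float = 0.10,
    k: float = 1.0,
    seed: int = 0,
    n_permutations: int = 1000,
) -> list[CoverageSegment]:
    """Full per-chromosome pipeline: CBS -> merge/filter -> boundary
    refinement -> 1-SD classification."""
    stats = chrom_stats(track)
    raw = segment_track(track, alpha=alpha, min_width_bins=min_width_bins,
                        seed=seed, n_permutations=n_permutations)
    merged = merge_filter_segments(raw, min_length=min_length, gap_limit=gap_limit,
                                   mean_tol=mean_tol, ref_mean=stats.mean_cov)
    refined = refine_boundaries(track, merged)
    return classify_segments(refined, stats, k=k)
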