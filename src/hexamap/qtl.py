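"""QTL interval mapping on DH linkage maps.

Composite interval mapping is approximated by Haley-Knott regression: at
each grid position the (standardized) phenotype is regressed on the
expected parental dosage imputed from flanking markers under Haldane
recombination probabilities, plus forward-selected marker cofactors, with
cofactors within +/-10 cM of the tested position excluded.  LOD is the
(n/2) log10 RSS ratio of the cofactor-only null against the full model;
R-squared at the peak is 1 - RSS_full/RSS_null.  QTL are reported above a
LOD threshold (default 5) with 1-LOD support intervals and, when an
interval overlaps the genetic span of a called rearrangement event, the
colocalized event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .hecall import RearrangementEvent
from .linkmap import LinkageMap, haldane_r
from .markers import MISSING

__all__ = [
    "LODProfile",
    "QTLResult",
    "expected_genotype",
    "select_cofactors",
    "scan",
    "genome_scan",
    "report_qtl",
    "max_lod",
]


@dataclass
class LODProfile:
    group: str
    grid: np.ndarray
    lod: np.ndarray
    r2: np.ndarray
    cofactors: list[int]        # indices into the map's bin list


@dataclass
class QTLResult:
    trait: str
    group: str
    peak_cm: float
    ci_lo: float
    ci_hi: float
    lod: float
    r2: float
    event_id: str | None


def expected_genotype(cm: np.ndarray, scores: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Expected P2 dosage for every line at every grid position.

    ``cm``: marker positions on the group (non-decreasing); ``scores``:
    (markers x lines) parental origins {0, 1, -1 missing}; ``positions``:
    grid (cM).  Returns (len(positions) x n_lines) posterior probabilities
    of P2 origin given the nearest informative flanking markers, using
    Haldane transition probabilities.  At a fully informative marker the
    dosage is exactly the marker's origin; with no informative flank it is
    0.5 (flagged by construction: both transitions uninformative).
    """
    cm = np.asarray(cm, dtype=float)
    grid = np.asarray(positions, dtype=float)
    n_pos, n_lines = grid.size, scores.shape[1]
    out = np.full((n_pos, n_lines), 0.5)
    for l in range(n_lines):
        inf = scores[:, l] != MISSING
        if not inf.any():
            continue
        c = cm[inf]
        g = scores[inf, l].astype(float)
        idx = np.searchsorted(c, grid, side="right")
        li = idx - 1
        ri = np.clip(idx, 0, c.size - 1)
        has_l = li >= 0
        has_r = idx <= c.size - 1
        li = np.clip(li, 0, c.size - 1)
        rL = haldane_r(np.abs(grid - c[li]))
        rR = haldane_r(np.abs(c[ri] - grid))
        # P(x=1 | left flank), P(right flank | x)
        a1 = np.where(g[li] == 1, 1 - rL, rL)
        a0 = 1 - a1
        b1 = np.where(g[ri] == 1, 1 - rR, rR)
        b0 = 1 - b1
        a1, a0 = np.where(has_l, a1, 0.5), np.where(has_l, a0, 0.5)
        b1, b0 = np.where(has_r, b1, 0.5), np.where(has_r, b0, 0.5)
        w1, w0 = a1 * b1, a0 * b0
        out[:, l] = w1 / (w1 + w0)
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def select_cofactors(
    dosages: np.ndarray,
    y: np.ndarray,
    max_cofactors: int = 5,
    p_entry: float = 1e-3,
) -> list[int]:
    """Forward selection of marker cofactors (rows of ``dosages``): at each
    round add the marker with the smallest partial-F p-value, stopping at
    ``max_cofactors`` or when no candidate enters below ``p_entry``."""
    n = y.size
    selected: list[int] = []
    X = np.ones((n, 1))
    rss0 = _rss(X, y)
    for _ in range(max_cofactors):
        best_p, best_i, best_rss = 1.0, None, None
        for i in range(dosages.shape[0]):
            if i in selected:
                continue
            Xc = np.column_stack([X, dosages[i]])
            rss1 = _rss(Xc, y)
            df2 = n - Xc.shape[1]
            if df2 <= 0 or rss1 <= 0:
                continue
            F = (rss0 - rss1) / (rss1 / df2)
            p = float(sstats.f.sf(F, 1, df2))
            if p < best_p:
                best_p, best_i, best_rss = p, i, rss1
        if best_i is None or best_p >= p_entry:
            break
        selected.append(best_i)
        X = np.column_stack([X, dosages[best_i]])
        rss0 = best_rss
    return selected


def scan(
    group: str,
    cm: np.ndarray,
    scores: np.ndarray,
    phenotype: np.ndarray,
    cofactor_dosages: np.ndarray | None = None,
    cofactor_meta: list[tuple[str, float]] | None = None,
    cofactor_idx: list[int] | None = None,
    step: float = 1.0,
    window_cm: float = 10.0,
) -> LODProfile:
    """Haley-Knott scan of one linkage group.

    ``cofactor_dosages`` rows are cofactor genotype vectors with metadata
    (group name, cM position) used for the +/-``window_cm`` exclusion around
    the tested position.  The phenotype is standardized to unit variance
    (LOD and R-squared are invariant to this).
    """
    y = np.asarray(phenotype, dtype=float)
    sd = y.std()
    grid = np.arange(cm.min(), cm.max() + step / 2, step)
    if sd == 0:
        warnings.warn("constant phenotype; returning an all-zero profile")
        return LODProfile(group, grid, np.zeros(grid.size), np.zeros(grid.size),
                          list(cofactor_idx or []))
    y = (y - y.mean()) / sd
    n = y.size
    dos = expected_genotype(cm, scores, grid)
    lod = np.zeros(grid.size)
    r2 = np.zeros(grid.size)
    meta = cofactor_meta or []
    for k, pos in enumerate(grid):
        keep = [
            j for j in range(len(meta))
            if not (meta[j][0] == group and abs(meta[j][1] - pos) <= window_cm)
        ]
        cols = [np.ones(n)]
        if cofactor_dosages is not None and keep:
            cols.extend(cofactor_dosages[j] for j in keep)
        X0 = np.column_stack(cols)
        X1 = np.column_stack(cols + [dos[k]])
        rss0, rss1 = _rss(X0, y), _rss(X1, y)
        if rss1 <= 0:
            rss1 = np.finfo(float).tiny
        lod[k] = (n / 2.0) * np.log10(rss0 / rss1)
        r2[k] = 1.0 - rss1 / rss0
    return LODProfile(group, grid, lod, r2, list(cofactor_idx or []))


def genome_scan(
    linkage_map: LinkageMap,
    phenotype: np.ndarray,
    step: float = 1.0,
    max_cofactors: int = 5,
    p_entry: float = 1e-3,
    window_cm: float = 10.0,
) -> list[LODProfile]:
    """Cofactor selection over all mapped bins, then a scan of every group."""
    reps = linkage_map.bins
    all_dos = np.stack([
        np.where(b[0].scores == MISSING, 0.5, b[0].scores).astype(float) for b in reps
    ])
    y = np.asarray(phenotype, dtype=float)
    if y.std() > 0:
        cof_idx = select_cofactors(all_dos, (y - y.mean()) / y.std(),
                                   max_cofactors=max_cofactors, p_entry=p_entry)
    else:
        cof_idx = []
    bin_pos: dict[int, tuple[str, float]] = {}
    for lg in linkage_map.groups:
        for idx, cmv in zip(lg.order, lg.cm):
            bin_pos[idx] = (lg.name, float(cmv))
    cof_dos = all_dos[cof_idx] if cof_idx else None
    cof_meta = [bin_pos[i] for i in cof_idx]
    profiles = []
    for lg in linkage_map.groups:
        if len(lg.order) < 2:
            continue
        scores = np.stack([reps[i][0].scores for i in lg.order])
        profiles.append(scan(lg.name, lg.cm, scores, y, cof_dos, cof_meta,
                             cof_idx, step=step, window_cm=window_cm))
    return profiles


def _peaks(lod: np.ndarray, threshold: float, valley_drop: float = 2.0) -> list[int]:
    """Indices of QTL peaks: local maxima above threshold, with two maxima
    counted separately only when separated by a valley more than
    ``valley_drop`` LOD below the lower of the two."""
    above = lod > threshold
    if not above.any():
        return []
    cand = [i for i in range(lod.size)
            if above[i]
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == lod.size - 1 or lod[i] >= lod[i + 1])]
    peaks: list[int] = []
    for i in cand:
        if not peaks:
            peaks.append(i)
            continue
        j = peaks[-1]
        valley = lod[j:i + 1].min()
        if valley < min(lod[i], lod[j]) - valley_drop:
            peaks.append(i)
        elif lod[i] > lod[j]:
            peaks[-1] = i
    return peaks


def report_qtl(
    profiles: list[LODProfile],
    events: list[RearrangementEvent] | None = None,
    threshold: float = 5.0,
    trait: str = "trait",
) -> list[QTLResult]:
    """QTL above the LOD threshold with 1-LOD support intervals, annotated
    with any rearrangement event whose genetic span overlaps the interval."""
    events = events or []
    results: list[QTLResult] = []
    for prof in profiles:
        for pk in _peaks(prof.lod, threshold):
            target = prof.lod[pk] - 1.0
            lo = pk
            while lo > 0 and prof.lod[lo - 1] >= target:
                lo -= 1
            hi = pk
            while hi < prof.lod.size - 1 and prof.lod[hi + 1] >= target:
                hi += 1
            ci = (float(prof.grid[lo]), float(prof.grid[hi]))
            best_ev, best_ov = None, 0.0
            for ev in events:
                if ev.group != prof.group or ev.cm_span is None:
                    continue
                ov = min(ci[1], ev.cm_span[1]) - max(ci[0], ev.cm_span[0])
                if ov >= 0 and ov >= best_ov:
                    best_ev, best_ov = ev.event_id, ov
            results.append(QTLResult(
                trait=trait, group=prof.group, peak_cm=float(prof.grid[pk]),
                ci_lo=ci[0], ci_hi=ci[1], lod=float(prof.lod[pk]),
                r2=float(prof.r2[pk]), event_id=best_ev,
            ))
    return results


def max_lod(profiles: list[LODProfile]) -> float:
    """Genome-wide maximum LOD, e.g. for permutation thresholds."""
    return max((float(p.lod.max()) for p in profiles), default=0.0)
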