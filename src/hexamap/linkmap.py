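"""DH linkage-map construction.

Recombination fractions between marker bins are estimated directly from
parental-origin vectors (in a DH population every marker class, including
the dominant PA recoding, is fully informative because lines are
homozygous).  Markers are grouped as connected components at a
recombination-fraction cut-off (default 0.2), ordered within groups by
travelling-salesman-path seriation (greedy nearest-neighbour construction
plus 2-opt refinement; exhaustive search for small groups), and placed on a
centiMorgan scale with the Haldane mapping function, consistent with the
no-interference crossover model of the simulator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .markers import MISSING, MarkerRecord

__all__ = [
    "RFMatrix",
    "LinkageGroup",
    "LinkageMap",
    "pairwise_rf",
    "group_markers",
    "order_group",
    "map_distances",
    "haldane_cm",
    "haldane_r",
    "build_map",
]


class MapError(RuntimeError):
    pass


@dataclass
class RFMatrix:
    """Pairwise recombination fractions (symmetric, diagonal 0) with the
    count of lines informative for each pair."""

    r: np.ndarray
    informative: np.ndarray
    min_informative: int = 20

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def usable(self) -> np.ndarray:
        """Mask of pairs with enough jointly informative lines."""
        return self.informative >= self.min_informative


@dataclass
class LinkageGroup:
    name: str
    chrom: str                  # majority-vote anchor chromosome
    order: list[int]            # indices into the bin list
    cm: np.ndarray              # non-decreasing positions


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    bins: list[list[MarkerRecord]]   # bin -> member markers (rep first)

    def group_of_chrom(self, chrom: str) -> list[LinkageGroup]:
        return [g for g in self.groups if g.chrom == chrom]


def pairwise_rf(scores: np.ndarray, min_informative: int = 20) -> RFMatrix:
    """Recombination fractions from an (n_bins x n_lines) origin matrix
    with entries {0, 1, -1=missing}: r = discordant / jointly informative,
    truncated at 0.5."""
    S = np.asarray(scores, dtype=np.int8)
    known = (S != MISSING).astype(np.int32)
    informative = known @ known.T
    p1 = ((S == 0) & (S != MISSING)).astype(np.int32)
    p2 = (S == 1).astype(np.int32)
    concord = p1 @ p1.T + p2 @ p2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(informative > 0, (informative - concord) / informative, np.nan)
    r = np.minimum(r, 0.5)
    np.fill_diagonal(r, 0.0)
    return RFMatrix(r=r, informative=informative, min_informative=min_informative)


def group_markers(rf: RFMatrix, cutoff: float = 0.2) -> list[list[int]]:
    """Linkage groups = connected components of the graph whose edges join
    pairs with r < cutoff; pairs with too few informative lines are
    non-edges."""
    adj = (rf.r < cutoff) & rf.usable()
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _path_cost(order: list[int], d: np.ndarray) -> float:
    return float(sum(d[a, b] for a, b in zip(order[:-1], order[1:])))


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    improved = True
    n = len(order)
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                new = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                if _path_cost(new, d) < _path_cost(order, d) - 1e-12:
                    order = new
                    improved = True
    return order


def order_group(
    group: list[int],
    rf: RFMatrix,
    seed: int = 0,
    exhaustive_limit: int = 8,
    n_starts: int = 8,
) -> list[int]:
    """Order the bins of one linkage group to minimize the sum of adjacent
    recombination fractions (TSP-path objective).

    Groups of up to ``exhaustive_limit`` bins are solved exactly by
    enumeration; larger groups by greedy nearest-neighbour construction from
    several seeded starts followed by 2-opt refinement.
    """
    if len(group) <= 2:
        return list(group)
    d = rf.r[np.ix_(group, group)].copy()
    d[~rf.usable()[np.ix_(group, group)]] = 0.5
    d[np.isnan(d)] = 0.5
    n = len(group)
    if n <= exhaustive_limit:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:   # skip mirror-image orders
                continue
            c = _path_cost(list(perm), d)
            if c < best_cost:
                best, best_cost = list(perm), c
        return [group[i] for i in best]
    rng = np.random.default_rng(seed)
    starts = list(rng.choice(n, size=min(n_starts, n), replace=False))
    best, best_cost = None, np.inf
    for s in starts:
        order = [int(s)]
        left = set(range(n)) - {int(s)}
        while left:
            last = order[-1]
            nxt = min(left, key=lambda x: d[last, x])
            order.append(nxt)
            left.remove(nxt)
        order = _two_opt(order, d)
        c = _path_cost(order, d)
        if c < best_cost:
            best, best_cost = order, c
    return [group[i] for i in best]


def haldane_cm(r: float) -> float:
    """Haldane map distance (cM) from a recombination fraction."""
    if r >= 0.5:
        raise MapError("adjacent recombination fraction >= 0.5; split the group")
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_r(d_cm: float) -> float:
    """Recombination fraction from a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def map_distances(order: list[int], rf: RFMatrix) -> np.ndarray:
    """Cumulative Haldane cM positions along an ordered group."""
    cm = [0.0]
    for a, b in zip(order[:-1], order[1:]):
        r = rf.r[a, b]
        if np.isnan(r):
            r = 0.49  # uninformative adjacency: near-unlinked placeholder
        cm.append(cm[-1] + haldane_cm(float(r)))
    return np.asarray(cm)


def build_map(
    bins: list[list[MarkerRecord]],
    cutoff: float = 0.2,
    min_informative: int = 20,
    seed: int = 0,
    require_seg_ok: bool = True,
) -> tuple[LinkageMap, RFMatrix]:
    """Assemble a full linkage map from cosegregation bins.

    Bins whose representative fails the 1:1 segregation test are excluded
    (``require_seg_ok``), mirroring the requirement that every scoring class
    fit DH segregation before mapping.  Groups are named after the
    majority-vote chromosome of their members' anchors, with ``_1``, ``_2``
    suffixes when one chromosome yields several groups; each group is
    oriented so that anchor bp positions run forward.
    """
    usable = [b for b in bins if (b[0].seg_ok or not require_seg_ok)]
    if not usable:
        return LinkageMap(groups=[], bins=[]), None
    scores = np.stack([b[0].scores for b in usable])
    rf = pairwise_rf(scores, min_informative=min_informative)
    groups = group_markers(rf, cutoff=cutoff)
    lgs: list[LinkageGroup] = []
    name_counts: dict[str, int] = {}
    for g in groups:
        order = order_group(g, rf, seed=seed)
        # canonical orientation: majority-chromosome anchors ascending
        chroms = [m.chrom for i in order for m in usable[i]]
        vals, cnts = np.unique(chroms, return_counts=True)
        top = vals[cnts == cnts.max()]
        chrom = sorted(
            top, key=lambda c: min(m.pos for i in order for m in usable[i] if m.chrom == c)
        )[0]
        anchor_pos = [usable[i][0].pos for i in order if usable[i][0].chrom == chrom]
        if len(anchor_pos) >= 2 and anchor_pos[0] > anchor_pos[-1]:
            order = order[::-1]
        cm = map_distances(order, rf)
        name_counts[chrom] = name_counts.get(chrom, 0) + 1
        lgs.append(LinkageGroup(name=chrom, chrom=chrom, order=order, cm=cm))
    for chrom, k in name_counts.items():
        if k > 1:
            i = 1
            for lg in lgs:
                if lg.chrom == chrom:
                    lg.name = f"{chrom}_{i}"
                    i += 1
    return LinkageMap(groups=lgs, bins=usable), rf
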