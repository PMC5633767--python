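"""SNP-array marker classification for two-parent DH populations.

Markers from a polyploid Infinium-style array are sorted into three usable
scoring classes before mapping:

* **simple** — codominant biallelic SNP: parents AA vs BB, lines AA or BB;
* **het** — hemi-SNP: the probe hybridizes to two homoeologous (or
  duplicated) loci of which only one is polymorphic, so one parent and the
  carrier lines read heterozygous-appearing AB despite being fully
  homozygous; scored codominantly with AB assigned to the hemi-SNP parent;
* **PA** — presence-absence: the probe site is deleted on one parental
  haplotype, so that parent and the carrier lines give no call (NC); scored
  dominantly with NC assigned to the null-allele parent.

Mapped marker names carry the class suffix ('-het', '-PA') so rearranged
regions remain visible on the genetic map.  All classes must fit the 1:1
segregation expected in a DH population (chi-square test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "AnchorHit",
    "MarkerRecord",
    "ClassifyConfig",
    "filter_anchors",
    "classify_marker",
    "classify_matrix",
    "segregation_test",
    "bin_cosegregating",
    "records_to_frame",
]

MISSING = -1  # scored-vector code; 0 = P1 origin, 1 = P2 origin


@dataclass(frozen=True)
class AnchorHit:
    """Physical anchor of a marker's flanking sequence on the reference."""

    marker: str
    chrom: str
    pos: int
    overlap_length: int = 60
    identity: float = 100.0
    has_gaps: bool = False
    n_hits: int = 1


@dataclass
class MarkerRecord:
    marker: str
    chrom: str
    pos: int
    cls: str                       # simple | het | PA | monomorphic | rejected
    scores: np.ndarray | None      # per-line {0: P1, 1: P2, -1: missing}
    count_p1: int = 0
    count_p2: int = 0
    chi2: float = float("nan")
    p_value: float = float("nan")
    seg_ok: bool = False
    reason: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def name_suffix(self) -> str:
        return {"het": "-het", "PA": "-PA"}.get(self.cls, "")

    @property
    def name(self) -> str:
        return self.marker + self.name_suffix


@dataclass(frozen=True)
class ClassifyConfig:
    min_lines: int = 20          # minimum non-missing line calls
    sporadic_nc: float = 0.10    # NC fraction treated as technical missingness
    off_pattern_tol: float = 0.05  # tolerated fraction of calls outside the class pattern
    pa_balance: tuple[float, float] = (0.3, 0.7)  # NC fraction window suggesting PA
    # 1:1 gate level: at n ~ 164 segregation drift is regionally correlated,
    # so a 0.05 gate discards whole chromosome stretches and fragments maps;
    # 0.01 keeps drift while still rejecting genuinely distorted markers
    alpha: float = 0.01


def filter_anchors(
    hits: list[AnchorHit],
    min_overlap: int = 50,
    min_identity: float = 95.0,
    require_unique: bool = True,
) -> list[str]:
    """Keep markers whose anchor hit passes the physical-anchoring filter:
    overlap >= 50 bp, identity >= 95%, no alignment gaps, and (by default)
    a unique hit on the reference."""
    kept = []
    for h in hits:
        if h.overlap_length < min_overlap or h.identity < min_identity or h.has_gaps:
            continue
        if require_unique and h.n_hits != 1:
            continue
        kept.append(h.marker)
    return kept


def segregation_test(count_p1: int, count_p2: int, alpha: float = 0.05):
    """Chi-square goodness-of-fit against the 1:1 DH segregation ratio.

    chi2 = (c1 - c2)^2 / (c1 + c2) on 1 df; a marker passes when p >= alpha.
    """
    n = count_p1 + count_p2
    if n < 1:
        raise ValueError("need at least one scored line")
    chi2 = (count_p1 - count_p2) ** 2 / n
    p = float(sstats.chi2.sf(chi2, df=1))
    return float(chi2), p, p >= alpha


_HOM = ("AA", "BB")


def _counts(calls: np.ndarray) -> dict[str, int]:
    u, c = np.unique(calls, return_counts=True)
    return dict(zip(u.tolist(), c.tolist()))


def classify_marker(
    marker: str,
    chrom: str,
    pos: int,
    parent1: str,
    parent2: str,
    line_calls: np.ndarray,
    config: ClassifyConfig = ClassifyConfig(),
) -> MarkerRecord:
    """Classify one marker from its parental and DH-line calls and score the
    lines to parental origin.

    Decision rules (small fractions of off-pattern calls, up to
    ``off_pattern_tol``, are treated as technical errors and set missing):

    a. parents AA vs BB, lines in {AA, BB} (+ sporadic NC)  -> simple;
    b. one parent AB, other homozygous, lines in {AB, hom}  -> het
       (AB scored as the hemi-SNP parent's allele);
    c. one parent NC, other called; called lines uniform and equal to the
       called parent; NC fraction near 1:1                   -> PA
       (NC scored as the null-allele parent);
    d. parents identical and lines uniform                   -> monomorphic;
    otherwise rejected with a reason code.

    When one parent is NC but the lines segregate two homozygous alleles
    near 1:1 with only sporadic NC, the parental call is imputed and the
    marker is kept as simple (flag ``imputed_parent``).
    """
    calls = np.asarray(line_calls, dtype=object)
    n = calls.size
    rec = MarkerRecord(marker, chrom, pos, "rejected", None)

    def reject(reason: str) -> MarkerRecord:
        rec.reason = reason
        return rec

    def finish(cls: str, scores: np.ndarray, flags: list[str] | None = None) -> MarkerRecord:
        rec.cls = cls
        rec.scores = scores
        rec.flags = flags or []
        rec.count_p1 = int(np.sum(scores == 0))
        rec.count_p2 = int(np.sum(scores == 1))
        rec.chi2, rec.p_value, rec.seg_ok = segregation_test(
            rec.count_p1, rec.count_p2, alpha=config.alpha
        )
        return rec

    cnt = _counts(calls)
    n_nc = cnt.get("NC", 0)
    if n - n_nc < config.min_lines and not (parent1 == "NC") ^ (parent2 == "NC"):
        return reject("insufficient_data")

    if parent1 == "NC" and parent2 == "NC":
        return reject("parents_uncalled")

    if (parent1 == "NC") ^ (parent2 == "NC"):
        null_is_p1 = parent1 == "NC"
        called_parent = parent2 if null_is_p1 else parent1
        called = calls[calls != "NC"]
        ccnt = _counts(called)
        nc_frac = n_nc / n
        # PA pattern: called lines all show the present parent's allele
        off = called.size - ccnt.get(called_parent, 0)
        if (called.size and off <= config.off_pattern_tol * n
                and config.pa_balance[0] <= nc_frac <= config.pa_balance[1]):
            scores = np.full(n, MISSING, dtype=np.int8)
            scores[calls == "NC"] = 0 if null_is_p1 else 1
            scores[calls == called_parent] = 1 if null_is_p1 else 0
            return finish("PA", scores)
        # rescue: biallelic segregation with a technically failed parent call
        hom = {k: v for k, v in ccnt.items() if k in _HOM}
        if (len(hom) == 2 and nc_frac <= config.sporadic_nc
                and ccnt.get("AB", 0) <= config.off_pattern_tol * n):
            if called_parent not in _HOM:
                return reject("parent_missing_pattern")
            other = "BB" if called_parent == "AA" else "AA"
            scores = np.full(n, MISSING, dtype=np.int8)
            scores[calls == called_parent] = 0 if not null_is_p1 else 1
            scores[calls == other] = 1 if not null_is_p1 else 0
            if int(np.sum(scores >= 0)) < config.min_lines:
                return reject("insufficient_data")
            return finish("simple", scores, flags=["imputed_parent"])
        return reject("parent_missing_pattern")

    if n - n_nc < config.min_lines:
        return reject("insufficient_data")

    if parent1 == parent2:
        # monomorphic if the lines agree with the parents (sporadic noise aside)
        off = n - n_nc - cnt.get(parent1, 0)
        if off <= config.off_pattern_tol * n:
            rec.cls = "monomorphic"
            return rec
        return reject("identical_parents_segregating")

    if parent1 in _HOM and parent2 in _HOM:
        off = n - cnt.get("AA", 0) - cnt.get("BB", 0) - n_nc
        if off > config.off_pattern_tol * n:
            return reject("excess_off_pattern")
        if n_nc / n > config.sporadic_nc:
            return reject("excess_missing")
        scores = np.full(n, MISSING, dtype=np.int8)
        scores[calls == parent1] = 0
        scores[calls == parent2] = 1
        return finish("simple", scores)

    if "AB" in (parent1, parent2):
        hemi_is_p1 = parent1 == "AB"
        hom_parent = parent2 if hemi_is_p1 else parent1
        if hom_parent not in _HOM:
            return reject("uninformative_parents")
        off = n - cnt.get("AB", 0) - cnt.get(hom_parent, 0) - n_nc
        if off > config.off_pattern_tol * n:
            return reject("excess_off_pattern")
        if n_nc / n > config.sporadic_nc:
            return reject("excess_missing")
        scores = np.full(n, MISSING, dtype=np.int8)
        scores[calls == "AB"] = 0 if hemi_is_p1 else 1
        scores[calls == hom_parent] = 1 if hemi_is_p1 else 0
        return finish("het", scores)

    return reject("unrecognized_pattern")


def classify_matrix(
    calls: pd.DataFrame,
    anchors: list[AnchorHit] | None = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> list[MarkerRecord]:
    """Classify every marker of a call matrix (columns: marker, chrom, pos,
    P1, P2, then line columns).  If ``anchors`` is given, markers failing the
    anchoring filter are rejected up front (reason ``anchor_filtered``)."""
    line_cols = [c for c in calls.columns if c not in ("marker", "chrom", "pos", "P1", "P2")]
    kept = None
    if anchors is not None:
        kept = set(filter_anchors(anchors))
    records = []
    mat = calls[line_cols].to_numpy(dtype=object)
    for i, row in enumerate(calls.itertuples(index=False)):
        if kept is not None and row.marker not in kept:
            records.append(MarkerRecord(row.marker, row.chrom, int(row.pos),
                                        "rejected", None, reason="anchor_filtered"))
            continue
        records.append(
            classify_marker(row.marker, row.chrom, int(row.pos),
                            row.P1, row.P2, mat[i], config=config)
        )
    return records


def bin_cosegregating(
    records: list[MarkerRecord],
    missing_wildcard: bool = False,
) -> list[list[MarkerRecord]]:
    """Group markers with identical scored vectors into bins to reduce the
    locus count before map construction.

    By default missing calls must match exactly (strict equality keeps the
    relation transitive).  With ``missing_wildcard`` a missing call matches
    either origin; bins are then grown greedily in genome order against the
    bin representative, and the choice is recorded on each member's flags.
    The representative of a bin is its first marker in genome order.
    """
    scored = [r for r in records if r.scores is not None]
    scored.sort(key=lambda r: (r.chrom, r.pos))
    bins: list[list[MarkerRecord]] = []
    if not missing_wildcard:
        seen: dict[bytes, int] = {}
        for r in scored:
            key = r.scores.tobytes()
            if key in seen:
                bins[seen[key]].append(r)
            else:
                seen[key] = len(bins)
                bins.append([r])
        return bins
    for r in scored:
        for b in bins:
            rep = b[0].scores
            both = (rep != MISSING) & (r.scores != MISSING)
            if np.all(rep[both] == r.scores[both]):
                b.append(r)
                r.flags.append("wildcard_bin")
                break
        else:
            bins.append([r])
    return bins


def records_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    """Tabular view of classified markers (one row per marker)."""
    rows = []
    for r in records:
        rows.append({
            "marker": r.marker, "name": r.name, "chrom": r.chrom, "pos": r.pos,
            "class": r.cls, "count_P1": r.count_p1, "count_P2": r.count_p2,
            "chi2": r.chi2, "p_value": r.p_value, "seg_ok": r.seg_ok,
            "reason": r.reason, "flags": ",".join(r.flags),
        })
    return pd.DataFrame(rows)
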