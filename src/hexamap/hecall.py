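"""Rearrangement calling: reconcile genetic-map and read-depth evidence.

A homoeologous exchange (HE) leaves a characteristic double signature: a
segmental deletion on one subgenome chromosome together with a duplication
of the homoeologous segment on its partner.  On the genetic map the
deletion appears as a run of presence-absence ('PA') markers and the
duplication as a run of hemi-SNP ('het') markers (or of translocated
markers mapping away from their anchor chromosome); in parental read depth
they appear as deletion / duplication coverage segments.

This module finds marker runs (three or more adjacent same-class markers
form a confident block; shorter runs are kept at single-marker confidence),
pairs loss evidence with homoeologous gain evidence through the homoeology
table, and tiers each called event by whether both evidence kinds agree.
This stage is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coverage import CoverageSegment
from .genome import HomoeologyBlock
from .linkmap import LinkageMap

__all__ = [
    "MarkerBlock",
    "RearrangementEvent",
    "find_blocks",
    "pair_homoeologues",
    "reconcile_evidence",
    "events_to_frame",
    "call_rearrangements",
]


@dataclass
class MarkerBlock:
    group: str
    cm_start: float
    cm_end: float
    markers: list[str]
    block_class: str            # "PA-run" | "het-run" | "translocated-run"
    chrom: str                  # physical footprint
    start: int
    end: int

    @property
    def run_length(self) -> int:
        return len(self.markers)


@dataclass
class RearrangementEvent:
    event_id: str
    cls: str                                  # deletion | duplication | HE | conflict
    lost: tuple[str, int, int] | None
    gained: tuple[str, int, int] | None
    group: str | None = None
    cm_span: tuple[float, float] | None = None
    blocks: list[MarkerBlock] = field(default_factory=list)
    segments: list[CoverageSegment] = field(default_factory=list)
    tier: str = ""


# ---------------------------------------------------------------------------
# marker blocks
# ---------------------------------------------------------------------------

def find_blocks(linkage_map: LinkageMap, min_run: int = 3) -> list[MarkerBlock]:
    """Maximal runs of adjacent PA / het / translocated markers on the map.

    A marker is *translocated* when it segregates normally but its physical
    anchor lies on a different chromosome than the linkage group's: in a
    parent carrying a duplicative translocation such markers map to the new
    (homoeologous) position of the duplicated copy.  Runs shorter than
    ``min_run`` are still emitted; ``reconcile_evidence`` downgrades them to
    single-marker confidence rather than discarding them.
    """
    blocks: list[MarkerBlock] = []
    for lg in linkage_map.groups:
        seq = []  # (label, marker record, cm)
        for idx, cm in zip(lg.order, lg.cm):
            for rec in linkage_map.bins[idx]:
                if rec.cls == "PA":
                    label = "PA-run"
                elif rec.cls == "het":
                    label = "het-run"
                elif rec.cls == "simple" and rec.chrom != lg.chrom:
                    label = "translocated-run"
                else:
                    label = None
                seq.append((label, rec, float(cm)))
        i = 0
        while i < len(seq):
            label = seq[i][0]
            if label is None:
                i += 1
                continue
            j = i
            while j + 1 < len(seq) and seq[j + 1][0] == label:
                j += 1
            members = [s[1] for s in seq[i:j + 1]]
            chroms = [m.chrom for m in members]
            chrom = max(set(chroms), key=chroms.count)
            anchored = [m for m in members if m.chrom == chrom]
            blocks.append(MarkerBlock(
                group=lg.name,
                cm_start=seq[i][2],
                cm_end=seq[j][2],
                markers=[m.name for m in members],
                block_class=label,
                chrom=chrom,
                start=min(m.pos for m in anchored),
                end=max(m.pos for m in anchored) + 1,
            ))
            i = j + 1
    return blocks


# ---------------------------------------------------------------------------
# homoeology projection over a block table
# ---------------------------------------------------------------------------

def _project_interval(
    blocks: list[HomoeologyBlock], chrom: str, start: int, end: int
) -> tuple[str, int, int] | None:
    """Project an interval through the homoeology table (piecewise linear per
    block; a reversed block, end < start on the C side, encodes an
    inversion).  Block-by-block images on the same partner chromosome are
    merged to their envelope."""
    pieces: dict[str, list[int]] = {}
    for blk in blocks:
        for (c, s, e, pc, ps, pe) in (
            (blk.chrom_a, blk.start_a, blk.end_a, blk.chrom_c, blk.start_c, blk.end_c),
            (blk.chrom_c, blk.start_c, blk.end_c, blk.chrom_a, blk.start_a, blk.end_a),
        ):
            lo, hi = max(start, s), min(end, e)
            if c != chrom or lo >= hi:
                continue
            f0 = (lo - s) / (e - s)
            f1 = (hi - s) / (e - s)
            q0 = ps + f0 * (pe - ps)
            q1 = ps + f1 * (pe - ps)
            a, b = sorted((int(round(q0)), int(round(q1))))
            pieces.setdefault(pc, []).extend([a, b])
    if not pieces:
        return None
    # keep the partner chromosome receiving the largest share
    best = max(pieces, key=lambda c: max(pieces[c]) - min(pieces[c]))
    return best, min(pieces[best]), max(pieces[best])


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# pairing and reconciliation
# ---------------------------------------------------------------------------

@dataclass
class _Locus:
    role: str                   # "loss" | "gain"
    chrom: str
    start: int
    end: int
    blocks: list[MarkerBlock] = field(default_factory=list)
    segments: list[CoverageSegment] = field(default_factory=list)

    def absorb(self, other: "_Locus") -> None:
        self.start = min(self.start, other.start)
        self.end = max(self.end, other.end)
        self.blocks.extend(other.blocks)
        self.segments.extend(other.segments)


def _cluster(items: list[_Locus]) -> list[_Locus]:
    """Merge overlapping same-chromosome evidence into loci."""
    out: list[_Locus] = []
    for it in sorted(items, key=lambda x: (x.chrom, x.start)):
        if out and out[-1].chrom == it.chrom and it.start < out[-1].end:
            out[-1].absorb(it)
        else:
            out.append(it)
    return out


def pair_homoeologues(
    blocks: list[MarkerBlock],
    segments: list[CoverageSegment],
    homoeology: list[HomoeologyBlock],
    min_jaccard: float = 0.25,
) -> list[RearrangementEvent]:
    """Pair deletion evidence with homoeologous duplication evidence.

    Loss evidence: PA-runs and deletion coverage segments.  Gain evidence:
    het-runs, translocated-runs, and duplication coverage segments.
    A loss locus whose homoeologous image overlaps a gain locus with an
    interval Jaccard of at least ``min_jaccard`` becomes an HE; unmatched
    losses are deletions, unmatched gains duplications.  A loss locus that
    physically overlaps a gain locus on the *same* chromosome is flagged as
    a conflict rather than silently resolved.
    """
    loci: list[_Locus] = []
    for b in blocks:
        role = "loss" if b.block_class == "PA-run" else "gain"
        loci.append(_Locus(role, b.chrom, b.start, b.end, blocks=[b]))
    for s in segments:
        if s.cls == "deletion":
            loci.append(_Locus("loss", s.chrom, s.start, s.end, segments=[s]))
        elif s.cls == "duplication":
            loci.append(_Locus("gain", s.chrom, s.start, s.end, segments=[s]))
    losses = _cluster([l for l in loci if l.role == "loss"])
    gains = _cluster([l for l in loci if l.role == "gain"])

    events: list[RearrangementEvent] = []
    used_gains: set[int] = set()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"RE{counter:03d}"

    def placement(all_blocks: list[MarkerBlock]):
        if not all_blocks:
            return None, None
        g = all_blocks[0].group
        cms = [b.cm_start for b in all_blocks if b.group == g] + \
              [b.cm_end for b in all_blocks if b.group == g]
        return g, (min(cms), max(cms))

    for loss in losses:
        conflict = next(
            (g for g in gains
             if g.chrom == loss.chrom and _jaccard((loss.start, loss.end),
                                                   (g.start, g.end)) > 0),
            None,
        )
        if conflict is not None:
            grp, span = placement(loss.blocks + conflict.blocks)
            events.append(RearrangementEvent(
                new_id(), "conflict", (loss.chrom, loss.start, loss.end),
                (conflict.chrom, conflict.start, conflict.end), grp, span,
                loss.blocks + conflict.blocks, loss.segments + conflict.segments))
            used_gains.add(id(conflict))
            continue
        image = _project_interval(homoeology, loss.chrom, loss.start, loss.end)
        match = None
        if image is not None:
            cands = [
                (i, g) for i, g in enumerate(gains)
                if id(g) not in used_gains and g.chrom == image[0]
                and _jaccard(image[1:], (g.start, g.end)) >= min_jaccard
            ]
            if cands:
                match = max(cands, key=lambda ig: _jaccard(image[1:], (ig[1].start, ig[1].end)))[1]
        if match is not None:
            used_gains.add(id(match))
            grp, span = placement(loss.blocks + match.blocks)
            events.append(RearrangementEvent(
                new_id(), "HE", (loss.chrom, loss.start, loss.end),
                (match.chrom, match.start, match.end), grp, span,
                loss.blocks + match.blocks, loss.segments + match.segments))
        else:
            grp, span = placement(loss.blocks)
            events.append(RearrangementEvent(
                new_id(), "deletion", (loss.chrom, loss.start, loss.end), None,
                grp, span, loss.blocks, loss.segments))
    for g in gains:
        if id(g) in used_gains:
            continue
        grp, span = placement(g.blocks)
        events.append(RearrangementEvent(
            new_id(), "duplication", None, (g.chrom, g.start, g.end),
            grp, span, g.blocks, g.segments))
    return events


def reconcile_evidence(
    events: list[RearrangementEvent],
    min_run: int = 3,
    min_seg_length: int = 50_000,
) -> list[RearrangementEvent]:
    """Assign confidence tiers in place and return the events.

    validated     — at least one marker block and one coverage segment agree;
    putative      — one evidence kind only, but a run of >= min_run markers
                    or a segment of >= min_seg_length;
    single-marker — everything weaker.
    """
    for ev in events:
        has_block = bool(ev.blocks)
        has_seg = bool(ev.segments)
        if has_block and has_seg:
            ev.tier = "validated"
        elif (has_block and max(b.run_length for b in ev.blocks) >= min_run) or \
             (has_seg and max(s.length for s in ev.segments) >= min_seg_length):
            ev.tier = "putative"
        else:
            ev.tier = "single-marker"
    return events


def events_to_frame(events: list[RearrangementEvent]) -> pd.DataFrame:
    """Tabular report: one row per event with genetic and physical extents."""
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id,
            "class": ev.cls,
            "lost_chrom": ev.lost[0] if ev.lost else "",
            "lost_start": ev.lost[1] if ev.lost else "",
            "lost_end": ev.lost[2] if ev.lost else "",
            "gained_chrom": ev.gained[0] if ev.gained else "",
            "gained_start": ev.gained[1] if ev.gained else "",
            "gained_end": ev.gained[2] if ev.gained else "",
            "group": ev.group or "",
            "cm_start": ev.cm_span[0] if ev.cm_span else "",
            "cm_end": ev.cm_span[1] if ev.cm_span else "",
            "tier": ev.tier,
            "n_blocks": len(ev.blocks),
            "n_segments": len(ev.segments),
            "evidence": ";".join(
                [f"block:{b.block_class}@{b.group}" for b in ev.blocks]
                + [f"segment:{s.cls}@{s.chrom}:{s.start}-{s.end}" for s in ev.segments]
            ),
        })
    return pd.DataFrame(rows)


def call_rearrangements(
    linkage_map: LinkageMap,
    segments: list[CoverageSegment],
    homoeology: list[HomoeologyBlock],
    min_run: int = 3,
    min_jaccard: float = 0.25,
    min_seg_length: int = 50_000,
) -> list[RearrangementEvent]:
    """find_blocks -> pair_homoeologues -> reconcile_evidence in one call."""
    blocks = find_blocks(linkage_map, min_run=min_run)
    events = pair_homoeologues(blocks, segments, homoeology, min_jaccard=min_jaccard)
    return reconcile_evidence(events, min_run=min_run, min_seg_length=min_seg_length)
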