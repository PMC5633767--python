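"""Readers and writers for the text formats used across the pipeline.

Conventions: bedGraph / BED / BEDPE are UCSC-style 0-based half-open; all
tabular outputs are TSV with a fixed column registry.  Every file written
here starts with comment lines naming the producing stage, its parameters
and the seed, so any artifact can be traced to its run; readers skip
``#`` comments and ``track`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageSegment, CoverageTrack
from .genome import HomoeologyBlock
from .hecall import RearrangementEvent, events_to_frame
from .linkmap import LinkageGroup, LinkageMap
from .markers import MISSING, MarkerRecord

__all__ = [
    "read_bedgraph", "write_bedgraph",
    "read_segments_bed", "write_segments_bed",
    "read_calls", "write_calls",
    "read_anchors", "write_anchors",
    "read_homoeology", "write_homoeology",
    "read_phenotypes", "write_phenotypes",
    "write_markers", "read_markers",
    "write_map", "read_map",
    "write_events", "write_events_bedpe",
    "write_truth", "header_lines",
]


class FormatError(ValueError):
    pass


def header_lines(stage: str, params: dict | None = None, seed: int | None = None) -> str:
    items = dict(params or {})
    if seed is not None:
        items["seed"] = seed
    kv = " ".join(f"{k}={v}" for k, v in items.items())
    return f"# hexamap stage={stage} {kv}".rstrip() + "\n"


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into chrom -> (N, 3) arrays of
    (start, end, depth).  Intervals must be sorted and non-overlapping per
    chromosome; violations are reported with their line number."""
    out: dict[str, list[list[float]]] = {}
    last_end: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"line {ln}: expected 4 columns")
            chrom, s, e, d = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
            if d < 0:
                raise FormatError(f"line {ln}: negative depth")
            if e <= s:
                raise FormatError(f"line {ln}: empty interval")
            if chrom in last_end and s < last_end[chrom]:
                raise FormatError(f"line {ln}: unsorted or overlapping interval on {chrom}")
            last_end[chrom] = e
            out.setdefault(chrom, []).append([s, e, d])
    return {c: np.asarray(rows) for c, rows in out.items()}


def write_bedgraph(path, tracks: dict[str, CoverageTrack] | dict[str, np.ndarray],
                   bin_size: int | None = None, stage: str = "simulate",
                   params: dict | None = None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines(stage, params, seed))
        for chrom in sorted(tracks):
            tr = tracks[chrom]
            if isinstance(tr, CoverageTrack):
                values, bs, gap = tr.values, tr.bin_size, tr.gap
            else:
                values, bs, gap = np.asarray(tr), bin_size, None
                if bs is None:
                    raise FormatError("bin_size required for raw arrays")
            for i, v in enumerate(values):
                if gap is not None and gap[i]:
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:g}\n")


# ---------------------------------------------------------------------------
# segments BED6+
# ---------------------------------------------------------------------------

def write_segments_bed(path, segments: list[CoverageSegment],
                       params: dict | None = None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines("segment", params, seed))
        fh.write("# chrom\tstart\tend\tclass\tmean_cov\tstrand\tn_bins\n")
        for s in sorted(segments, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.cls or 'raw'}\t"
                     f"{s.mean_cov:.4f}\t.\t{s.n_bins}\n")


def read_segments_bed(path) -> list[CoverageSegment]:
    segs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            c, s, e, cls, mean, _strand, nb = line.rstrip("\n").split("\t")[:7]
            segs.append(CoverageSegment(c, int(s), int(e), float(mean), int(nb),
                                        None if cls == "raw" else cls))
    return segs


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _write_tsv(path, df: pd.DataFrame, stage: str, params=None, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines(stage, params, seed))
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_calls(path, calls: pd.DataFrame, params=None, seed=None) -> None:
    _write_tsv(path, calls, "simulate", params, seed)


def read_calls(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_homoeology(path, blocks: list[HomoeologyBlock], params=None, seed=None) -> None:
    df = pd.DataFrame(
        [(b.chrom_a, b.start_a, b.end_a, b.chrom_c, b.start_c, b.end_c) for b in blocks],
        columns=["chromA", "startA", "endA", "chromC", "startC", "endC"],
    )
    _write_tsv(path, df, "simulate", params, seed)


def read_homoeology(path) -> list[HomoeologyBlock]:
    df = _read_tsv(path)
    return [HomoeologyBlock(r.chromA, int(r.startA), int(r.endA),
                            r.chromC, int(r.startC), int(r.endC))
            for r in df.itertuples(index=False)]


def write_anchors(path, hits, params=None, seed=None) -> None:
    df = pd.DataFrame(
        [(h.marker, h.chrom, h.pos, h.overlap_length, h.identity,
          int(h.has_gaps), h.n_hits) for h in hits],
        columns=["marker", "chrom", "pos", "overlap_length", "identity",
                 "has_gaps", "n_hits"],
    )
    _write_tsv(path, df, "simulate", params, seed)


def read_anchors(path) -> list:
    from .markers import AnchorHit
    df = _read_tsv(path)
    return [AnchorHit(r.marker, r.chrom, int(r.pos), int(r.overlap_length),
                      float(r.identity), bool(r.has_gaps), int(r.n_hits))
            for r in df.itertuples(index=False)]


def write_phenotypes(path, phenotypes: pd.DataFrame | pd.Series, params=None, seed=None) -> None:
    df = phenotypes.to_frame() if isinstance(phenotypes, pd.Series) else phenotypes
    df = df.reset_index(names="line")
    _write_tsv(path, df, "simulate", params, seed)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_tsv(path).set_index("line")


# ---------------------------------------------------------------------------
# marker records (classification output), with scores for downstream stages
# ---------------------------------------------------------------------------

_SCORE_CHARS = {0: "0", 1: "1", MISSING: "-"}


def write_markers(path, records: list[MarkerRecord], params=None, seed=None) -> None:
    rows = []
    for r in records:
        scored = "".join(_SCORE_CHARS[int(v)] for v in r.scores) if r.scores is not None else ""
        rows.append({
            "marker": r.marker, "name": r.name, "chrom": r.chrom, "pos": r.pos,
            "class": r.cls, "count_P1": r.count_p1, "count_P2": r.count_p2,
            "chi2": round(r.chi2, 6) if r.chi2 == r.chi2 else "",
            "p_value": round(r.p_value, 8) if r.p_value == r.p_value else "",
            "seg_ok": int(r.seg_ok), "reason": r.reason,
            "flags": ",".join(r.flags), "scored": scored,
        })
    _write_tsv(path, pd.DataFrame(rows), "classify", params, seed)


def read_markers(path) -> list[MarkerRecord]:
    df = _read_tsv(path)
    recs = []
    inv = {"0": 0, "1": 1, "-": MISSING}
    for _, r in df.iterrows():
        scored = r["scored"] if isinstance(r["scored"], str) else ""
        scores = (np.array([inv[ch] for ch in scored], dtype=np.int8)
                  if scored else None)
        rec = MarkerRecord(r["marker"], r["chrom"], int(r["pos"]), r["class"], scores)
        rec.count_p1, rec.count_p2 = int(r["count_P1"]), int(r["count_P2"])
        rec.seg_ok = bool(r["seg_ok"])
        rec.reason = r["reason"] if isinstance(r["reason"], str) else ""
        rec.flags = r["flags"].split(",") if isinstance(r["flags"], str) and r["flags"] else []
        recs.append(rec)
    return recs


# ---------------------------------------------------------------------------
# linkage map
# ---------------------------------------------------------------------------

def write_map(path, linkage_map: LinkageMap, params=None, seed=None) -> None:
    rows = []
    for lg in linkage_map.groups:
        for order_idx, (bin_idx, cmv) in enumerate(zip(lg.order, lg.cm)):
            for rec in linkage_map.bins[bin_idx]:
                rows.append({
                    "group": lg.name, "group_chrom": lg.chrom, "order": order_idx,
                    "bin": bin_idx, "cM": round(float(cmv), 4),
                    "marker": rec.name, "class": rec.cls,
                    "chrom": rec.chrom, "pos": rec.pos,
                })
    _write_tsv(path, pd.DataFrame(rows), "map", params, seed)


def read_map(path, records: list[MarkerRecord]) -> LinkageMap:
    """Rebuild a LinkageMap from map.tsv plus the classified marker records
    (which carry the scored vectors)."""
    df = _read_tsv(path)
    by_name = {r.name: r for r in records}
    bins: list[list[MarkerRecord]] = []
    bin_ids: dict[int, int] = {}
    groups = []
    for gname, gdf in df.groupby("group", sort=False):
        gdf = gdf.sort_values(["order", "marker"])
        order, cm = [], []
        for (order_idx, bin_idx), bdf in gdf.groupby(["order", "bin"], sort=True):
            if bin_idx not in bin_ids:
                bin_ids[bin_idx] = len(bins)
                bins.append([by_name[m] for m in bdf["marker"]])
            order.append(bin_ids[bin_idx])
            cm.append(float(bdf["cM"].iloc[0]))
        groups.append(LinkageGroup(name=gname, chrom=gdf["group_chrom"].iloc[0],
                                   order=order, cm=np.asarray(cm)))
    return LinkageMap(groups=groups, bins=bins)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def write_events(path, events: list[RearrangementEvent], params=None, seed=None) -> None:
    _write_tsv(path, events_to_frame(events), "call-he", params, seed)


def write_events_bedpe(path, events: list[RearrangementEvent],
                       params=None, seed=None) -> None:
    """BEDPE of lost<->gained interval pairs for HE events."""
    with open(path, "w") as fh:
        fh.write(header_lines("call-he", params, seed))
        for ev in events:
            if ev.cls != "HE":
                continue
            l, g = ev.lost, ev.gained
            fh.write(f"{l[0]}\t{l[1]}\t{l[2]}\t{g[0]}\t{g[1]}\t{g[2]}\t"
                     f"{ev.event_id}\t{ev.tier}\t.\t.\n")


def write_truth(path, dataset, seed: int | None = None) -> None:
    """JSON ground-truth record of a simulated dataset."""
    d = {
        "seed": seed,
        "events": [
            {"event_id": e.event_id, "kind": e.kind, "lost": e.lost,
             "gained": e.gained, "carrier_parent": e.carrier_parent}
            for e in dataset.events
        ],
        "carriers": {c: dataset.carriers[c].astype(int).tolist()
                     for c in dataset.carriers.columns},
        "lines": list(dataset.carriers.index),
        "qtl": None,
    }
    if dataset.qtl is not None:
        d["qtl"] = {"trait": dataset.qtl.trait, "event_id": dataset.qtl.event_id,
                    "effect": dataset.qtl.effect, "sigma": dataset.qtl.sigma,
                    "heritability": dataset.qtl.heritability}
    Path(path).write_text(json.dumps(d, indent=1))
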