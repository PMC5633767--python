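"""End-to-end orchestration: simulate -> segment -> classify -> map ->
call-he -> qtl, with a manifest recording the resolved configuration,
input checksums and per-stage logs.  Deterministic given the seed."""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .coverage import CoverageTrack, segment_and_classify
from .genome import ConfigError
from .hecall import call_rearrangements, find_blocks
from .io import (write_bedgraph, write_calls, write_events, write_events_bedpe,
                 write_homoeology, write_map, write_markers, write_phenotypes,
                 write_segments_bed, write_truth)
from .linkmap import build_map
from .markers import ClassifyConfig, bin_cosegregating, classify_matrix
from .qtl import genome_scan, report_qtl
from .simulate import simulate_dataset

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage, writing artifacts into ``outdir``.

    Returns the manifest (also written as manifest.json).  Any stage
    failure aborts with the stage name; artifacts of completed stages are
    preserved.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config.to_dict(), "stages": {}, "checksums": {}}
    log: dict = {}
    stage = "simulate"
    try:
        sim = config.sim
        if any(e.kind == "HE" for e in (sim.events or [])) and not sim.genome.n_pairs:
            raise ConfigError("HE simulation requires a homoeology table")
        ds = simulate_dataset(sim, seed=seed)
        params = {"n_lines": sim.n_lines, "spacing": sim.marker_spacing}
        for parent, tracks in ds.coverage.items():
            write_bedgraph(out / f"coverage_{parent}.bedgraph", tracks,
                           bin_size=ds.genome.bin_size, params=params, seed=seed)
        write_calls(out / "calls.tsv", ds.calls, params, seed)
        from .io import write_anchors
        from .simulate import anchor_hits
        write_anchors(out / "anchors.tsv", anchor_hits(ds.calls), seed=seed)
        write_homoeology(out / "homoeology.tsv", ds.genome.homoeology_blocks, seed=seed)
        if ds.phenotype is not None:
            write_phenotypes(out / "phenotypes.tsv", ds.phenotype, seed=seed)
        write_truth(out / "truth.json", ds, seed=seed)
        log[stage] = {"n_events": len(ds.events), "n_markers": len(ds.calls)}

        stage = "segment"
        all_segments = []
        for parent, tracks in ds.coverage.items():
            for chrom, depth in tracks.items():
                track = CoverageTrack(chrom, ds.genome.bin_size, depth)
                segs = segment_and_classify(
                    track, alpha=config.cbs_alpha, min_width_bins=config.min_width_bins,
                    min_length=config.min_segment_length, gap_limit=config.gap_limit,
                    mean_tol=config.mean_tol, k=config.k_sd, seed=seed,
                    n_permutations=config.n_permutations,
                )
                all_segments.extend(segs)
        write_segments_bed(out / "segs.bed",
                           all_segments,
                           params={"alpha": config.cbs_alpha, "k": config.k_sd},
                           seed=seed)
        aberrant = [s for s in all_segments if s.cls in ("deletion", "duplication")]
        log[stage] = {"n_segments": len(all_segments), "n_aberrant": len(aberrant)}

        stage = "classify"
        records = classify_matrix(
            ds.calls, config=ClassifyConfig(min_lines=config.min_lines,
                                            alpha=config.seg_alpha))
        write_markers(out / "markers.tsv", records,
                      params={"alpha": config.seg_alpha}, seed=seed)
        log[stage] = {
            "n_markers": len(records),
            "by_class": {c: sum(r.cls == c for r in records)
                         for c in ("simple", "het", "PA", "monomorphic", "rejected")},
        }

        stage = "map"
        bins = bin_cosegregating(records)
        linkage_map, rf = build_map(bins, cutoff=config.rf_cutoff,
                                    min_informative=config.min_informative, seed=seed)
        write_map(out / "map.tsv", linkage_map,
                  params={"rf_cutoff": config.rf_cutoff}, seed=seed)
        log[stage] = {"n_groups": len(linkage_map.groups),
                      "n_bins": len(linkage_map.bins)}

        stage = "call-he"
        events = call_rearrangements(
            linkage_map, aberrant, ds.genome.homoeology_blocks,
            min_run=config.min_run, min_jaccard=config.min_jaccard,
            min_seg_length=config.min_segment_length,
        )
        write_events(out / "events.tsv", events,
                     params={"min_run": config.min_run}, seed=seed)
        write_events_bedpe(out / "events.bedpe", events, seed=seed)
        log[stage] = {"n_events": len(events),
                      "by_class": {c: sum(e.cls == c for e in events)
                                   for c in ("deletion", "duplication", "HE", "conflict")}}

        stage = "qtl"
        if ds.phenotype is not None and linkage_map.groups:
            profiles = genome_scan(
                linkage_map, ds.phenotype.to_numpy(), step=config.qtl_step_cm,
                max_cofactors=config.max_cofactors, p_entry=config.cofactor_p_entry,
                window_cm=config.window_cm,
            )
            qtls = report_qtl(profiles, events, threshold=config.lod_threshold,
                              trait=ds.qtl.trait if ds.qtl else "trait")
            import pandas as pd
            qdf = pd.DataFrame([vars(q) for q in qtls])
            with open(out / "qtl.tsv", "w") as fh:
                fh.write(f"# hexamap stage=qtl lod_threshold={config.lod_threshold} "
                         f"seed={seed}\n")
                qdf.to_csv(fh, sep="\t", index=False)
            log[stage] = {"n_qtl": len(qtls),
                          "max_lod": float(np.max([q.lod for q in qtls])) if qtls else 0.0}
        else:
            log[stage] = {"n_qtl": 0, "skipped": True}
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        manifest["stages"] = log
        manifest["error"] = {"stage": stage, "message": str(exc),
                             "trace": traceback.format_exc()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, exc) from exc

    manifest["stages"] = log
    for p in sorted(out.glob("*")):
        if p.name != "manifest.json":
            manifest["checksums"][p.name] = _md5(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
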