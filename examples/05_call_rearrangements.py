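"""Call rearrangements by reconciling marker runs with coverage segments.

A deletion paired with a duplication of the homoeologous segment is called
as a homoeologous exchange (HE); a deletion with no compensating
duplication stays a deletion.  Events supported by both evidence kinds are
tier 'validated'.
"""

from hexamap import (CoverageTrack, simulate_dataset, classify_matrix,
                     bin_cosegregating, build_map, call_rearrangements,
                     segment_and_classify, GenomeConfig, SimConfig, TrueEvent)
from hexamap.hecall import events_to_frame

config = SimConfig(
    genome=GenomeConfig(n_pairs=2, chrom_length=3_000_000),
    events=[
        TrueEvent("he1", "HE", lost=("A01", 1_000_000, 1_600_000),
                  gained=("C01", 1_000_000, 1_600_000)),
        TrueEvent("del1", "deletion", lost=("C02", 500_000, 1_100_000)),
    ],
    n_lines=164, qtl_event=None,
)
ds = simulate_dataset(config, seed=5)

segments = []
for chrom, depth in ds.coverage["P2"].items():
    segments += [s for s in segment_and_classify(
        CoverageTrack(chrom, 1000, depth), seed=5)
        if s.cls in ("deletion", "duplication")]

linkage_map, _ = build_map(bin_cosegregating(classify_matrix(ds.calls)))
events = call_rearrangements(linkage_map, segments, ds.genome.homoeology_blocks)

cols = ["event_id", "class", "lost_chrom", "lost_start", "lost_end",
        "gained_chrom", "tier"]
print(events_to_frame(events)[cols].to_string(index=False))
# Expect one validated HE (A01 loss + homoeologous C01 gain) and one
# validated deletion on C02, matching the simulated truth.
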