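"""Classify SNP-array calls into simple / hemi-SNP / presence-absence markers.

Each class is scored to parental origin and tested against the 1:1
segregation expected in a DH population.
"""

from hexamap import simulate_dataset, classify_matrix, GenomeConfig, SimConfig, TrueEvent
from hexamap.markers import records_to_frame

config = SimConfig(
    genome=GenomeConfig(n_pairs=1, chrom_length=3_000_000),
    events=[TrueEvent("he", "HE", lost=("A01", 1_000_000, 1_600_000),
                      gained=("C01", 1_000_000, 1_600_000))],
    n_lines=164, qtl_event=None,
)
ds = simulate_dataset(config, seed=3)
records = classify_matrix(ds.calls)
df = records_to_frame(records)

print(df["class"].value_counts().to_string())
print("\nexample markers (suffix marks rearrangement-tracing classes):")
cols = ["name", "class", "count_P1", "count_P2", "chi2", "seg_ok"]
print(df[df["class"] == "PA"].head(3)[cols].to_string(index=False))
print(df[df["class"] == "het"].head(3)[cols].to_string(index=False))
# 'PA' markers are no-calls on the deleted haplotype (dominant scoring);
# 'het' markers read AB in carriers of the duplicated segment. Both fit
# 1:1 segregation, so they can be mapped like ordinary markers.
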