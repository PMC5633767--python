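"""Simulate a toy allopolyploid DH mapping experiment with known truth.

Two homoeologous chromosome pairs (A01/C01, A02/C02), one parent carrying a
homoeologous exchange (HE) and a pure deletion, 164 doubled-haploid lines.
"""

from hexamap import GenomeConfig, SimConfig, TrueEvent, simulate_dataset

config = SimConfig(
    genome=GenomeConfig(n_pairs=2, chrom_length=3_000_000),
    events=[
        TrueEvent("he1", "HE", lost=("A01", 1_000_000, 1_600_000),
                  gained=("C01", 1_000_000, 1_600_000)),
        TrueEvent("del1", "deletion", lost=("C02", 500_000, 1_100_000)),
    ],
    n_lines=164,
    qtl_event=0,          # the HE drives the phenotype
)
ds = simulate_dataset(config, seed=1)

print(f"{len(ds.events)} true events, {len(ds.calls)} array markers, "
      f"{ds.carriers.shape[0]} DH lines")
print("carrier fraction per event (expected ~0.5 under 1:1 DH segregation):")
print(ds.carriers.mean().round(3).to_string())
print("marker truth classes:")
print(ds.truth.true_class.value_counts().to_string())
print(f"QTL heritability of the HE carrier effect: {ds.qtl.heritability:.2f}")
# Each PA marker sits in the lost interval (no-call in carriers); each het
# marker sits in the gained interval (heterozygous-appearing in carriers).
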