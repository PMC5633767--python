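# hexamap

Detection and genetic mapping of **homoeologous exchanges (HEs)**,
segmental deletions and duplications in allopolyploid crops, and their
colocalization with QTL — for geneticists and breeders working with
doubled-haploid (DH) populations of species such as *Brassica napus*,
where exchanges between the A and C subgenomes are a major source of trait
variation that standard mapping pipelines silently discard.

## What it does

An HE replaces a chromosome segment with its counterpart from the other
subgenome, producing a linked deletion + duplication.  `hexamap` calls
such events by reconciling two evidence streams:

1. **Read depth.**  Parental WGS depth is summarized as median coverage
   over 1000-bp bins and segmented by circular binary segmentation
   (recursive max-|t| arc search with sequential permutation acceptance).
   Adjacent ≥ 50-kb segments with the same mean merge unless separated by
   a > 50-kb gap; a segment is a duplication if its mean exceeds the
   chromosome mean μc by one standard deviation sc, a deletion if it falls
   below μc − sc.
2. **Rearrangement-aware markers.**  SNP-array calls in a two-parent DH
   population are classified as simple (AA × BB), hemi-SNP `-het` (one
   parent AB because a duplicated variant copy co-hybridizes) or
   presence–absence `-PA` (one parent null because the probe site is
   deleted); each class is scored to parental origin, tested against the
   1:1 DH segregation ratio, χ² = (c₁−c₂)²/(c₁+c₂), and mapped like any
   other marker (grouping at recombination fraction r < 0.2, TSP-path
   ordering, Haldane distances d = −50·ln(1−2r) cM).

Runs of ≥ 3 adjacent `-PA` or `-het` markers form blocks; a deletion
signal whose homoeologous image overlaps a duplication signal becomes an
HE, and events supported by both marker and coverage evidence are tier
`validated`.  Interval mapping (Haley–Knott regression with forward-
selected cofactors, LOD = (n/2)·log₁₀(RSS₀/RSS₁), reporting threshold
LOD > 5) then links called events to quantitative traits.

A bundled synthetic-data generator simulates the complete experiment —
two-subgenome genome, parental events, DH meiosis, Infinium-style calls,
negative-binomial depth, additive QTL — with known ground truth, so every
stage is testable end to end without external data.  See
`docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Simulate one HE (A01 segment replaced by its C01 homoeologue) and one pure
deletion in a 164-line DH population, then call events from the combined
evidence (`examples/05_call_rearrangements.py`):

```
event_id    class lost_chrom  lost_start  lost_end gained_chrom      tier
   RE001       HE        A01     1000000   1600000          C01 validated
   RE002 deletion        C02      500000   1100000              validated
```

Both simulated events are recovered with exact boundaries and the correct
class: the A01 loss is paired with its homoeologous C01 gain into a single
HE, while the C02 deletion, lacking any compensating duplication, stays a
deletion; `validated` means marker blocks and coverage segments agree.

Scanning a phenotype driven by the HE carrier status
(`examples/06_qtl_colocalization.py`):

```
QTL on A01: peak 70.0 cM (1-LOD interval 63.0-73.0), LOD 12.7, R2 0.30, colocalized event: RE001
QTL on A01: peak 79.0 cM (1-LOD interval 79.0-79.0), LOD 13.0, R2 0.31, colocalized event: RE001
called HE spans 69.4-91.2 cM on A01
```

The LOD peaks sit far above the reporting threshold of 5 and inside the
called HE's genetic span — the QTL is explained by the rearrangement
itself, which is the package's central use case.

The other `examples/` scripts walk through each capability: simulation,
coverage segmentation, marker classification, and linkage-map
construction.

## Command line

Each stage is also a subcommand, chained by `run`:

```bash
hexamap simulate --seed 1 --out sim/
hexamap segment  --bedgraph sim/coverage_P2.bedgraph --out segs.bed
hexamap classify --calls sim/calls.tsv --anchors sim/anchors.tsv --out markers.tsv
hexamap map      --markers markers.tsv --out map.tsv
hexamap call-he  --map map.tsv --markers markers.tsv --segments segs.bed \
                 --homoeology sim/homoeology.tsv --out events.tsv
hexamap qtl      --map map.tsv --markers markers.tsv --pheno sim/phenotypes.tsv \
                 --events events.tsv --out qtl.tsv
hexamap run      --seed 1 --out run/        # the whole pipeline + manifest
```

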