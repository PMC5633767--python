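import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hexamap.genome import GenomeConfig, simulate_genome
from hexamap.simulate import SimConfig, TrueEvent


@pytest.fixture
def small_genome():
    """Two homoeologous pairs of 3-Mb chromosomes, 1-kb bins."""
    return simulate_genome(GenomeConfig(n_pairs=2, chrom_length=3_000_000))


def five_event_layout() -> list[TrueEvent]:
    """Three HEs plus two pure deletions (500-600 kb), spread so no
    chromosome is more than ~40% rearranged."""
    return [
        TrueEvent("he1", "HE", lost=("A01", 1_000_000, 1_600_000),
                  gained=("C01", 1_000_000, 1_600_000)),
        TrueEvent("he2", "HE", lost=("A02", 400_000, 900_000),
                  gained=("C02", 400_000, 900_000)),
        TrueEvent("he3", "HE", lost=("A02", 1_800_000, 2_300_000),
                  gained=("C02", 1_800_000, 2_300_000)),
        TrueEvent("del1", "deletion", lost=("C01", 2_200_000, 2_800_000)),
        TrueEvent("del2", "deletion", lost=("A01", 2_300_000, 2_900_000)),
    ]


def toy_config(events=None, **kw) -> SimConfig:
    """Desk-scale study conditions: 2 pairs x 3 Mb, 164 DH lines, 50-kb
    marker spacing, 20x depth."""
    defaults = dict(
        genome=GenomeConfig(n_pairs=2, chrom_length=3_000_000),
        n_lines=164,
        events=events if events is not None else five_event_layout(),
        qtl_event=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)
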