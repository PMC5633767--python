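"""Toy allopolyploid genome model with homoeologous block structure.

The model mirrors an A/C two-subgenome allotetraploid: every A chromosome is
fully tiled by homoeology blocks that map co-linearly onto its C-subgenome
partner.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeConfig", "HomoeologyBlock", "GenomeModel", "simulate_genome"]


class ConfigError(ValueError):
    """Raised for invalid simulation / pipeline configuration."""


@dataclass(frozen=True)
class HomoeologyBlock:
    """Co-linear correspondence between an A-subgenome and a C-subgenome interval."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_c: str
    start_c: int
    end_c: int

    def __post_init__(self) -> None:
        if self.end_a <= self.start_a or self.end_c <= self.start_c:
            raise ConfigError("homoeology block intervals must be non-empty")


@dataclass(frozen=True)
class GenomeConfig:
    n_pairs: int = 2
    chrom_length: int = 20_000_000
    bin_size: int = 1000
    blocks_per_pair: int = 1

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("need at least one homoeologous chromosome pair")
        if self.chrom_length < self.bin_size:
            raise ConfigError("block/bin size exceeds chromosome length")
        if self.blocks_per_pair < 1:
            raise ConfigError("blocks_per_pair must be >= 1")


@dataclass
class GenomeModel:
    """Chromosome lengths plus the homoeology table pairing A and C blocks."""

    chromosomes: list[tuple[str, int]]
    homoeology_blocks: list[HomoeologyBlock]
    bin_size: int = 1000

    _lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name} has non-positive length")
        for blk in self.homoeology_blocks:
            for chrom, s, e in ((blk.chrom_a, blk.start_a, blk.end_a),
                                (blk.chrom_c, blk.start_c, blk.end_c)):
                if chrom not in self._lengths:
                    raise ConfigError(f"block references unknown chromosome {chrom}")
                if s < 0 or e > self._lengths[chrom]:
                    raise ConfigError(f"block interval out of bounds on {chrom}")

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def n_bins(self, chrom: str) -> int:
        return -(-self._lengths[chrom] // self.bin_size)

    # -- homoeology projection --------------------------------------------

    def _block_at(self, chrom: str, pos: int) -> tuple[HomoeologyBlock, bool] | None:
        for blk in self.homoeology_blocks:
            if blk.chrom_a == chrom and blk.start_a <= pos < blk.end_a:
                return blk, True
            if blk.chrom_c == chrom and blk.start_c <= pos < blk.end_c:
                return blk, False
        return None

    def project(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map a position onto its homoeologous partner (piecewise-linear per block)."""
        hit = self._block_at(chrom, pos)
        if hit is None:
            return None
        blk, on_a = hit
        if on_a:
            frac = (pos - blk.start_a) / (blk.end_a - blk.start_a)
            return blk.chrom_c, int(round(blk.start_c + frac * (blk.end_c - blk.start_c)))
        frac = (pos - blk.start_c) / (blk.end_c - blk.start_c)
        return blk.chrom_a, int(round(blk.start_a + frac * (blk.end_a - blk.start_a)))

    def project_interval(self, chrom: str, start: int, end: int) -> tuple[str, int, int] | None:
        """Project a half-open interval; both ends must fall in the same block."""
        a = self.project(chrom, start)
        b = self.project(chrom, end - 1)
        if a is None or b is None or a[0] != b[0]:
            return None
        lo, hi = sorted((a[1], b[1] + 1))
        return a[0], lo, hi

    def partner(self, chrom: str) -> str | None:
        for blk in self.homoeology_blocks:
            if blk.chrom_a == chrom:
                return blk.chrom_c
            if blk.chrom_c == chrom:
                return blk.chrom_a
        return None


def simulate_genome(config: GenomeConfig, seed: int = 0) -> GenomeModel:
    """Build a deterministic toy genome: n pairs of equal-length A/C chromosomes,
    each A chromosome fully tiled by co-linear homoeology blocks onto its partner.

    The seed is accepted for interface symmetry with the stochastic simulators;
    the default construction is deterministic.
    """
    del seed  # construction is deterministic
    chroms: list[tuple[str, int]] = []
    blocks: list[HomoeologyBlock] = []
    for i in range(1, config.n_pairs + 1):
        ca, cc = f"A{i:02d}", f"C{i:02d}"
        chroms.append((ca, config.chrom_length))
        chroms.append((cc, config.chrom_length))
        edges = np.linspace(0, config.chrom_length, config.blocks_per_pair + 1).astype(int)
        for lo, hi in zip(edges[:-1], edges[1:]):
            blocks.append(HomoeologyBlock(ca, int(lo), int(hi), cc, int(lo), int(hi)))
    return GenomeModel(chromosomes=chroms, homoeology_blocks=blocks, bin_size=config.bin_size)
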