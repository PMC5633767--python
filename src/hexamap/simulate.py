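"""Synthetic data generator for an allopolyploid DH mapping experiment.

Generates, with known ground truth: parental rearrangement events (segmental
deletions, duplications, and homoeologous exchanges), a doubled-haploid (DH)
population segregating 1:1, Infinium-style array calls (simple SNP, hemi-SNP
'het', presence-absence 'PA'), negative-binomial read-depth tracks
proportional to copy number, and an additive phenotype controlled by the
carrier status of one event.

Biological conventions
----------------------
* Parents and DH lines are fully homozygous.  A parent carrying a deletion
  has lost both copies of the segment (copy number 0) unless configured
  otherwise; a duplicated segment is present in two extra copies.
* An HE replaces a segment of one subgenome by the homoeologous segment of
  the other: markers inside the lost interval become presence-absence ('PA')
  markers, markers anchored inside the gained interval read as
  heterozygous-appearing hemi-SNPs ('het') in carriers because the extra
  (variant) copy hybridizes alongside the resident copies.
* Meiosis: crossover count per chromosome is Poisson, positions uniform, no
  interference — consistent with downstream Haldane map distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigError, GenomeConfig, GenomeModel, simulate_genome

__all__ = [
    "TrueEvent",
    "Inheritance",
    "QTLTruth",
    "SimConfig",
    "SimDataset",
    "simulate_parent_events",
    "simulate_dh_population",
    "simulate_array_calls",
    "simulate_coverage",
    "simulate_phenotype",
    "simulate_dataset",
]

PARENTS = ("P1", "P2")


class PlacementError(RuntimeError):
    """Requested events could not be placed without overlap."""


@dataclass(frozen=True)
class TrueEvent:
    """A parental rearrangement: deletion (lost only), duplication (gained only)
    or HE (lost interval plus its homoeologous image, gained)."""

    event_id: str
    kind: str                                     # "deletion" | "duplication" | "HE"
    lost: tuple[str, int, int] | None = None       # (chrom, start, end), half-open
    gained: tuple[str, int, int] | None = None
    carrier_parent: str = "P2"

    def __post_init__(self) -> None:
        if self.kind == "deletion" and not (self.lost and self.gained is None):
            raise ConfigError("deletion must have exactly a lost interval")
        if self.kind == "duplication" and not (self.gained and self.lost is None):
            raise ConfigError("duplication must have exactly a gained interval")
        if self.kind == "HE" and not (self.lost and self.gained):
            raise ConfigError("HE needs both lost and gained intervals")
        if self.carrier_parent not in PARENTS:
            raise ConfigError("carrier_parent must be P1 or P2")

    @property
    def anchor(self) -> tuple[str, int]:
        """Locus whose inheritance decides carrier status: the rearranged
        haplotype physically resides where the loss (or tandem gain) sits."""
        chrom, start, end = self.lost if self.lost else self.gained
        return chrom, (start + end) // 2

    def intervals(self):
        if self.lost:
            yield ("lost", *self.lost)
        if self.gained:
            yield ("gained", *self.gained)


@dataclass
class Inheritance:
    """Parental-origin mosaic of one DH line: per chromosome, crossover
    breakpoints (bp, ascending) and origin labels (0 = P1, 1 = P2) for the
    k+1 resulting intervals."""

    chrom_breaks: dict[str, np.ndarray]
    chrom_origins: dict[str, np.ndarray]

    def origin_at(self, chrom: str, pos) -> np.ndarray:
        idx = np.searchsorted(self.chrom_breaks[chrom], np.atleast_1d(pos), side="right")
        return self.chrom_origins[chrom][idx]


@dataclass(frozen=True)
class QTLTruth:
    trait: str
    event_id: str
    effect: float          # additive effect a, trait units (carrier - non-carrier)
    sigma: float           # residual SD, trait units
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("residual SD must be non-negative")

    @property
    def heritability(self) -> float:
        # carrier indicator has variance 1/4 in a balanced DH population
        a2 = self.effect**2
        return a2 / (a2 + 4 * self.sigma**2)


# ---------------------------------------------------------------------------
# parental events
# ---------------------------------------------------------------------------

def _overlaps(occupied: dict[str, list[tuple[int, int]]], chrom: str, s: int, e: int) -> bool:
    return any(s < e0 and s0 < e for s0, e0 in occupied.get(chrom, ()))


def simulate_parent_events(
    genome: GenomeModel,
    n_events: int,
    kind_mix: tuple[float, float, float] = (0.3, 0.3, 0.4),
    size_range: tuple[int, int] = (100_000, 1_000_000),
    seed: int = 0,
    carrier_parent: str = "P2",
    max_tries: int = 500,
) -> list[TrueEvent]:
    """Place non-overlapping rearrangement events on the genome.

    kind_mix gives (deletion, duplication, HE) proportions.  HE losses are
    drawn on A chromosomes and their gains are the homoeologous images.
    """
    if size_range[0] < genome.bin_size:
        raise ConfigError("minimum event size must be at least one bin")
    rng = np.random.default_rng(seed)
    mix = np.asarray(kind_mix, dtype=float)
    mix = mix / mix.sum()
    kinds = ["deletion", "duplication", "HE"]
    a_chroms = [c for c in genome.chrom_names if c.startswith("A")]
    occupied: dict[str, list[tuple[int, int]]] = {}
    events: list[TrueEvent] = []
    for i in range(n_events):
        kind = kinds[rng.choice(3, p=mix)]
        placed = False
        for _ in range(max_tries):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            size = max(genome.bin_size, (size // genome.bin_size) * genome.bin_size)
            if kind == "HE":
                chrom = a_chroms[rng.integers(len(a_chroms))]
            else:
                chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            if size >= genome.length(chrom):
                continue
            start = int(rng.integers(0, genome.length(chrom) - size))
            start = (start // genome.bin_size) * genome.bin_size
            end = start + size
            if _overlaps(occupied, chrom, start, end):
                continue
            if kind == "HE":
                image = genome.project_interval(chrom, start, end)
                if image is None or _overlaps(occupied, image[0], image[1], image[2]):
                    continue
                ev = TrueEvent(f"ev{i}", "HE", lost=(chrom, start, end),
                               gained=image, carrier_parent=carrier_parent)
            elif kind == "deletion":
                ev = TrueEvent(f"ev{i}", "deletion", lost=(chrom, start, end),
                               carrier_parent=carrier_parent)
            else:
                ev = TrueEvent(f"ev{i}", "duplication", gained=(chrom, start, end),
                               carrier_parent=carrier_parent)
            for _, c, s, e in ev.intervals():
                occupied.setdefault(c, []).append((s, e))
            events.append(ev)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place event {i} without overlap")
    return events


# ---------------------------------------------------------------------------
# DH meiosis
# ---------------------------------------------------------------------------

def simulate_dh_population(
    genome: GenomeModel,
    events: list[TrueEvent],
    n_lines: int,
    crossovers_per_chrom_mean: float = 1.5,
    seed: int = 0,
    decouple_at: dict[str, int] | None = None,
) -> tuple[list[Inheritance], pd.DataFrame]:
    """Simulate DH lines from a two-parent cross.

    Each chromosome of each line is a mosaic of the two parental haplotypes:
    Poisson(c) crossovers at uniform positions, starting origin Bernoulli(1/2),
    then chromosome doubling (so lines are fully homozygous).

    ``decouple_at`` maps chromosome -> position at which pairing is disrupted
    (e.g. by a large parent-specific rearrangement): the two sides then
    segregate independently, which severs linkage across the boundary.

    Returns the inheritance mosaics and the carrier matrix (lines x events):
    True where the line inherited the rearranged haplotype.
    """
    if n_lines < 2:
        raise ConfigError("need at least 2 DH lines")
    rng = np.random.default_rng(seed)
    decouple_at = decouple_at or {}
    lines: list[Inheritance] = []
    for _ in range(n_lines):
        breaks: dict[str, np.ndarray] = {}
        origins: dict[str, np.ndarray] = {}
        for chrom, length in genome.chromosomes:
            k = rng.poisson(crossovers_per_chrom_mean)
            bp = np.sort(rng.integers(0, length, size=k)).astype(float)
            start = rng.integers(2)
            orig = (start + np.arange(k + 1)) % 2
            if chrom in decouple_at:
                # independent segregation of the two arms
                cut = float(decouple_at[chrom])
                j = int(np.searchsorted(bp, cut, side="right"))
                right_start = rng.integers(2)
                right = (right_start + np.arange(k - j + 1)) % 2
                bp = np.insert(bp, j, cut)
                orig = np.concatenate([orig[: j + 1], right])
            breaks[chrom] = bp
            origins[chrom] = orig.astype(np.int8)
        lines.append(Inheritance(breaks, origins))
    carriers = carrier_matrix(lines, events)
    return lines, carriers


def carrier_matrix(lines: list[Inheritance], events: list[TrueEvent]) -> pd.DataFrame:
    data = {}
    for ev in events:
        chrom, pos = ev.anchor
        want = PARENTS.index(ev.carrier_parent)
        data[ev.event_id] = [int(line.origin_at(chrom, pos)[0]) == want for line in lines]
    return pd.DataFrame(data, index=[f"DH{i:04d}" for i in range(len(lines))], dtype=bool)


# ---------------------------------------------------------------------------
# array calls
# ---------------------------------------------------------------------------

_CALLS = np.array(["AA", "BB", "AB", "NC"])


def _which_interval(events: list[TrueEvent], chrom: str, pos: int) -> tuple[str, TrueEvent] | None:
    for ev in events:
        for role, c, s, e in ev.intervals():
            if c == chrom and s <= pos < e:
                return role, ev
    return None


def simulate_array_calls(
    genome: GenomeModel,
    events: list[TrueEvent],
    inheritance: list[Inheritance],
    marker_spacing: int = 50_000,
    missing_rate: float = 0.02,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit an Infinium-style call matrix plus per-marker truth labels.

    Markers are placed every ``marker_spacing`` bp.  Truth classes:

    * inside a lost interval  -> 'PA'  (no-call in carriers: probe site deleted)
    * inside a gained interval -> 'het' (AB in carriers: variant extra copy)
    * elsewhere               -> 'simple' (codominant AA/BB)

    Returns (calls, truth).  ``calls`` rows are markers with columns
    marker, chrom, pos, P1, P2, then one column per DH line; values in
    {AA, BB, AB, NC}.  ``truth`` carries marker, chrom, pos, true_class,
    event_id.
    """
    if not (0 <= missing_rate <= 1 and 0 <= error_rate <= 1):
        raise ConfigError("rates must lie in [0, 1]")
    if marker_spacing < 1:
        raise ConfigError("marker spacing must be >= 1 bp")
    rng = np.random.default_rng(seed)
    n_lines = len(inheritance)
    line_names = [f"DH{i:04d}" for i in range(n_lines)]

    rows = []
    truth_rows = []
    for chrom, length in genome.chromosomes:
        positions = np.arange(marker_spacing // 2, length, marker_spacing)
        # parental origin of every line at every marker of this chromosome
        orig = np.stack([line.origin_at(chrom, positions) for line in inheritance])
        for j, pos in enumerate(positions):
            pos = int(pos)
            mid = f"{chrom}_{pos}"
            hit = _which_interval(events, chrom, pos)
            if hit is None:
                klass, ev = "simple", None
                p1, p2 = "AA", "BB"
                calls = np.where(orig[:, j] == 0, "AA", "BB")
            else:
                role, ev = hit
                want = PARENTS.index(ev.carrier_parent)
                # the rearranged haplotype travels as one unit (pairing is
                # disturbed inside the interval), so every marker in either
                # of the event's intervals reads the anchor locus' origin
                anchor_chrom, anchor_pos = ev.anchor
                carrier = np.array(
                    [line.origin_at(anchor_chrom, anchor_pos)[0] == want
                     for line in inheritance]
                )
                if role == "lost":
                    klass = "PA"
                    p1, p2 = ("NC", "AA") if ev.carrier_parent == "P1" else ("AA", "NC")
                    calls = np.where(carrier, "NC", "AA")
                else:
                    klass = "het"
                    p1, p2 = ("AB", "AA") if ev.carrier_parent == "P1" else ("AA", "AB")
                    calls = np.where(carrier, "AB", "AA")
            calls = calls.astype(object)
            # technical noise: miscalls then missingness (parents included)
            pcalls = [p1, p2]
            for pi in range(2):
                if pcalls[pi] != "NC" and rng.random() < error_rate:
                    pcalls[pi] = str(rng.choice(_CALLS[:3]))
                if rng.random() < missing_rate:
                    pcalls[pi] = "NC"
            err = rng.random(n_lines) < error_rate
            if err.any():
                calls[err] = rng.choice(_CALLS[:3], size=int(err.sum()))
            miss = rng.random(n_lines) < missing_rate
            calls[miss] = "NC"
            rows.append([mid, chrom, pos, pcalls[0], pcalls[1], *calls])
            truth_rows.append([mid, chrom, pos, klass, ev.event_id if ev else ""])

    calls_df = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "P1", "P2", *line_names])
    truth_df = pd.DataFrame(truth_rows, columns=["marker", "chrom", "pos", "true_class", "event_id"])
    return calls_df, truth_df


def anchor_hits(calls: pd.DataFrame):
    """Clean physical anchors for every simulated marker (unique hit, long
    overlap, high identity): the simulator models post-anchoring markers,
    so the anchoring filter is a pass-through unless the user perturbs it."""
    from .markers import AnchorHit
    return [AnchorHit(r.marker, r.chrom, int(r.pos)) for r in
            calls[["marker", "chrom", "pos"]].itertuples(index=False)]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def copy_number_profile(
    genome: GenomeModel,
    events: list[TrueEvent],
    carrier,
    loss: int = 2,
    gain: int = 2,
) -> dict[str, np.ndarray]:
    """Per-bin copy number (baseline 2) for a parent id or an
    event_id->bool carrier mapping."""
    profiles = {c: np.full(genome.n_bins(c), 2, dtype=float) for c in genome.chrom_names}
    for ev in events:
        if isinstance(carrier, str):
            applies = ev.carrier_parent == carrier
        else:
            applies = bool(carrier.get(ev.event_id, False))
        if not applies:
            continue
        for role, chrom, s, e in ev.intervals():
            b0, b1 = s // genome.bin_size, -(-e // genome.bin_size)
            if role == "lost":
                profiles[chrom][b0:b1] -= loss
            else:
                profiles[chrom][b0:b1] += gain
    for arr in profiles.values():
        np.clip(arr, 0, None, out=arr)
    return profiles


def simulate_coverage(
    genome: GenomeModel,
    events: list[TrueEvent],
    carrier="P2",
    mean_depth: float = 200.0,
    dispersion: float = 200.0,
    seed: int = 0,
    loss: int = 2,
    gain: int = 2,
) -> dict[str, "np.ndarray"]:
    """Negative-binomial per-bin read counts, mean = mean_depth * copy_number / 2.

    ``mean_depth`` is in reads per bin: 20x coverage with 100-bp reads puts
    about 200 reads in a 1-kb bin.

    ``dispersion`` is the NB size parameter (variance = m + m^2/dispersion);
    ``dispersion=inf`` gives Poisson counts.  Returns chrom -> per-bin depth.
    """
    if mean_depth <= 0:
        raise ConfigError("mean depth must be positive")
    rng = np.random.default_rng(seed)
    cn = copy_number_profile(genome, events, carrier, loss=loss, gain=gain)
    out: dict[str, np.ndarray] = {}
    for chrom, profile in cn.items():
        m = mean_depth * profile / 2.0
        depth = np.zeros_like(m)
        pos = m > 0
        if np.isinf(dispersion):
            depth[pos] = rng.poisson(m[pos])
        else:
            p = dispersion / (dispersion + m[pos])
            depth[pos] = rng.negative_binomial(dispersion, p)
        out[chrom] = depth
    return out


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(carriers: pd.DataFrame, qtl: QTLTruth, seed: int = 0) -> pd.Series:
    """Additive single-QTL phenotype: y_i = mu + a * carrier_i + N(0, sigma^2)."""
    if qtl.event_id not in carriers.columns:
        raise ConfigError(f"causal event {qtl.event_id} not in carrier matrix")
    rng = np.random.default_rng(seed)
    x = carriers[qtl.event_id].to_numpy(dtype=float)
    y = qtl.mu + qtl.effect * x + rng.normal(0.0, qtl.sigma, size=len(x))
    return pd.Series(y, index=carriers.index, name=qtl.trait)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions of the default toy experiment: two homoeologous
    chromosome pairs, a 164-line DH population, 50-kb marker spacing and
    20x parental sequencing depth."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_events: int = 5
    kind_mix: tuple[float, float, float] = (0.3, 0.3, 0.4)
    event_size_range: tuple[int, int] = (500_000, 1_000_000)
    n_lines: int = 164
    crossovers_per_chrom_mean: float = 1.5
    marker_spacing: int = 50_000
    missing_rate: float = 0.02
    error_rate: float = 0.005
    # 20x sequencing coverage with ~100-bp reads puts ~200 reads in a 1-kb
    # bin; NB size = mean gives variance ~ 2x mean, a typical WGS figure
    mean_depth: float = 200.0
    dispersion: float = 200.0
    copy_loss: int = 2
    copy_gain: int = 2
    qtl_event: int | None = 0        # index into events; None disables phenotype
    qtl_effect: float = 2.0
    qtl_sigma: float = 1.0
    trait: str = "trait1"
    events: list[TrueEvent] | None = None   # explicit events override placement


@dataclass
class SimDataset:
    config: SimConfig
    genome: GenomeModel
    events: list[TrueEvent]
    inheritance: list[Inheritance]
    carriers: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    coverage: dict[str, dict[str, np.ndarray]]   # parent -> chrom -> per-bin depth
    phenotype: pd.Series | None
    qtl: QTLTruth | None


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimDataset:
    """Run every simulator stage with seeds derived from one master seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_ev, s_pop, s_calls, s_cov1, s_cov2, s_phen = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)
    ]
    genome = simulate_genome(config.genome, seed=seed)
    if config.events is not None:
        events = config.events
    else:
        events = simulate_parent_events(
            genome, config.n_events, config.kind_mix, config.event_size_range, seed=s_ev
        )
    inheritance, carriers = simulate_dh_population(
        genome, events, config.n_lines, config.crossovers_per_chrom_mean, seed=s_pop
    )
    calls, truth = simulate_array_calls(
        genome, events, inheritance, config.marker_spacing,
        config.missing_rate, config.error_rate, seed=s_calls,
    )
    coverage = {
        "P1": simulate_coverage(genome, events, "P1", config.mean_depth,
                                config.dispersion, seed=s_cov1,
                                loss=config.copy_loss, gain=config.copy_gain),
        "P2": simulate_coverage(genome, events, "P2", config.mean_depth,
                                config.dispersion, seed=s_cov2,
                                loss=config.copy_loss, gain=config.copy_gain),
    }
    phenotype = qtl = None
    if config.qtl_event is not None and events:
        qtl = QTLTruth(config.trait, events[config.qtl_event].event_id,
                       config.qtl_effect, config.qtl_sigma)
        phenotype = simulate_phenotype(carriers, qtl, seed=s_phen)
    return SimDataset(config, genome, events, inheritance, carriers, calls, truth,
                      coverage, phenotype, qtl)
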