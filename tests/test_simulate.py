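import numpy as np
import pandas as pd
import pytest

from hexamap.genome import ConfigError, GenomeConfig, simulate_genome
from hexamap.simulate import (QTLTruth, SimConfig, TrueEvent, simulate_array_calls,
                              simulate_coverage, simulate_dataset,
                              simulate_dh_population, simulate_parent_events,
                              simulate_phenotype)

from conftest import five_event_layout, toy_config
from oracles import overlap_oracle


# -- parental events ---------------------------------------------------------

def test_no_events_requested(small_genome):
    assert simulate_parent_events(small_genome, 0) == []


def test_he_gain_is_homoeologous_image(small_genome):
    evs = simulate_parent_events(small_genome, 1, kind_mix=(0, 0, 1),
                                 size_range=(1_000_000, 1_000_000), seed=3)
    ev = evs[0]
    assert ev.kind == "HE"
    image = small_genome.project_interval(*ev.lost)
    assert image == ev.gained


def test_many_events_pairwise_disjoint():
    g = simulate_genome(GenomeConfig(n_pairs=2, chrom_length=20_000_000))
    evs = simulate_parent_events(g, 50, size_range=(50_000, 50_000), seed=1)
    intervals = [(c, s, e) for ev in evs for _, c, s, e in ev.intervals()]
    assert len(evs) == 50
    assert not overlap_oracle(intervals)


def test_event_kind_interval_contract():
    with pytest.raises(ConfigError):
        TrueEvent("x", "deletion", gained=("A01", 0, 1000))
    with pytest.raises(ConfigError):
        TrueEvent("x", "HE", lost=("A01", 0, 1000))


# -- DH meiosis --------------------------------------------------------------

def test_zero_crossovers_whole_chromosome_single_origin(small_genome):
    lines, _ = simulate_dh_population(small_genome, [], 20,
                                      crossovers_per_chrom_mean=0.0, seed=0)
    for line in lines:
        for chrom in small_genome.chrom_names:
            assert line.chrom_breaks[chrom].size == 0
            assert line.chrom_origins[chrom].size == 1


def test_carrier_fraction_near_half():
    g = simulate_genome(GenomeConfig(n_pairs=1, chrom_length=2_000_000))
    ev = [TrueEvent("e", "deletion", lost=("A01", 500_000, 700_000))]
    n = 10_000
    _, carriers = simulate_dh_population(g, ev, n, seed=5)
    frac = carriers["e"].mean()
    assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)


def test_population_deterministic(small_genome):
    ev = five_event_layout()
    l1, c1 = simulate_dh_population(small_genome, ev, 30, seed=11)
    l2, c2 = simulate_dh_population(small_genome, ev, 30, seed=11)
    pd.testing.assert_frame_equal(c1, c2)
    for a, b in zip(l1, l2):
        for chrom in small_genome.chrom_names:
            np.testing.assert_array_equal(a.chrom_breaks[chrom], b.chrom_breaks[chrom])


def test_he_lost_and_gained_cosegregate(small_genome):
    """Carrier status of an HE's two intervals travels together: PA markers
    in the lost interval and het markers in the gained interval show the
    same carrier indicator in every line."""
    ev = [TrueEvent("he", "HE", lost=("A01", 1_000_000, 1_500_000),
                    gained=("C01", 1_000_000, 1_500_000))]
    lines, carriers = simulate_dh_population(small_genome, ev, 60, seed=2)
    calls, truth = simulate_array_calls(small_genome, ev, lines,
                                        missing_rate=0, error_rate=0, seed=0)
    line_cols = [c for c in calls.columns if c.startswith("DH")]
    pa = truth.loc[truth.true_class == "PA", "marker"]
    het = truth.loc[truth.true_class == "het", "marker"]
    assert len(pa) and len(het)
    carrier = carriers["he"].to_numpy()
    for m in pa:
        row = calls.loc[calls.marker == m, line_cols].iloc[0].to_numpy()
        np.testing.assert_array_equal(row == "NC", carrier)
    for m in het:
        row = calls.loc[calls.marker == m, line_cols].iloc[0].to_numpy()
        np.testing.assert_array_equal(row == "AB", carrier)


# -- array calls -------------------------------------------------------------

def test_noiseless_deletion_markers_nc_iff_carrier(small_genome):
    ev = [TrueEvent("d", "deletion", lost=("A01", 600_000, 1_100_000))]
    lines, carriers = simulate_dh_population(small_genome, ev, 50, seed=1)
    calls, truth = simulate_array_calls(small_genome, ev, lines,
                                        missing_rate=0, error_rate=0, seed=0)
    line_cols = [c for c in calls.columns if c.startswith("DH")]
    carrier = carriers["d"].to_numpy()
    inside = truth.true_class == "PA"
    assert inside.sum() == 10  # 500 kb / 50 kb spacing
    for m in truth.loc[inside, "marker"]:
        row = calls.loc[calls.marker == m, line_cols].iloc[0].to_numpy()
        np.testing.assert_array_equal(row == "NC", carrier)


def test_no_events_no_pa_or_het_labels(small_genome):
    lines, _ = simulate_dh_population(small_genome, [], 30, seed=4)
    _, truth = simulate_array_calls(small_genome, [], lines, seed=0)
    assert set(truth.true_class) == {"simple"}


def test_nc_fraction_matches_missing_rate(small_genome):
    rate = 0.02
    lines, _ = simulate_dh_population(small_genome, [], 164, seed=9)
    calls, truth = simulate_array_calls(small_genome, [], lines,
                                        missing_rate=rate, error_rate=0, seed=9)
    line_cols = [c for c in calls.columns if c.startswith("DH")]
    vals = calls[line_cols].to_numpy()
    frac = float((vals == "NC").mean())
    n = vals.size
    assert abs(frac - rate) <= 3 * np.sqrt(rate * (1 - rate) / n)


def test_bad_rates_rejected(small_genome):
    lines, _ = simulate_dh_population(small_genome, [], 25, seed=0)
    with pytest.raises(ConfigError):
        simulate_array_calls(small_genome, [], lines, missing_rate=1.5)


# -- coverage ----------------------------------------------------------------

def test_poisson_limit_mean(small_genome):
    cov = simulate_coverage(small_genome, [], "P2", mean_depth=20,
                            dispersion=np.inf, seed=0)
    v = cov["A01"]
    assert abs(v.mean() - 20) < 3 * np.sqrt(20 / v.size)
    assert abs(v.var() - 20) < 2  # Poisson variance == mean


def test_homozygous_deletion_bins_zero(small_genome):
    ev = [TrueEvent("d", "deletion", lost=("A01", 1_000_000, 1_200_000))]
    cov = simulate_coverage(small_genome, ev, "P2", seed=1, loss=2)
    assert np.all(cov["A01"][1000:1200] == 0)


def test_single_copy_duplication_ratio():
    g = simulate_genome(GenomeConfig(n_pairs=1, chrom_length=20_000_000))
    ev = [TrueEvent("u", "duplication", gained=("A01", 0, 10_000_000))]
    cov = simulate_coverage(g, ev, "P2", mean_depth=20, dispersion=20,
                            seed=3, gain=1)
    dup = cov["A01"][:10_000].mean()
    flank = cov["A01"][10_000:].mean()
    assert abs(dup / flank - 1.5) < 0.03  # 10,000 bins each: LLN bound


def test_non_carrier_parent_flat(small_genome):
    cov = simulate_coverage(small_genome, five_event_layout(), "P1", seed=0)
    for chrom, v in cov.items():
        assert abs(v.mean() - 200) < 5.0


# -- phenotype ---------------------------------------------------------------

def test_sigma_zero_two_values():
    carriers = pd.DataFrame({"e": [True, False, True, False]},
                            index=[f"DH{i}" for i in range(4)])
    y = simulate_phenotype(carriers, QTLTruth("t", "e", effect=3.0, sigma=0.0), seed=0)
    assert set(np.round(y.unique(), 9)) == {0.0, 3.0}


def test_null_effect_mean_difference_small():
    rng = np.random.default_rng(0)
    n = 2000
    carriers = pd.DataFrame({"e": rng.random(n) < 0.5},
                            index=[f"DH{i}" for i in range(n)])
    y = simulate_phenotype(carriers, QTLTruth("t", "e", effect=0.0, sigma=1.0), seed=1)
    diff = y[carriers.e].mean() - y[~carriers.e].mean()
    se = np.sqrt(1 / carriers.e.sum() + 1 / (~carriers.e).sum())
    assert abs(diff) <= 3 * se


def test_phenotype_deterministic():
    carriers = pd.DataFrame({"e": [True] * 5 + [False] * 5},
                            index=[f"DH{i}" for i in range(10)])
    q = QTLTruth("t", "e", 1.0, 0.5)
    pd.testing.assert_series_equal(simulate_phenotype(carriers, q, seed=3),
                                   simulate_phenotype(carriers, q, seed=3))
    assert 0 < q.heritability < 1


# -- bundle ------------------------------------------------------------------

def test_dataset_reproducible_bit_exact():
    cfg = toy_config(n_lines=40)
    a = simulate_dataset(cfg, seed=42)
    b = simulate_dataset(cfg, seed=42)
    pd.testing.assert_frame_equal(a.calls, b.calls)
    pd.testing.assert_frame_equal(a.carriers, b.carriers)
    for parent in ("P1", "P2"):
        for chrom in a.coverage[parent]:
            np.testing.assert_array_equal(a.coverage[parent][chrom],
                                          b.coverage[parent][chrom])
    pd.testing.assert_series_equal(a.phenotype, b.phenotype)
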