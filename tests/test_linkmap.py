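import numpy as np
import pytest
from scipy.stats import spearmanr

from hexamap import simulate_dataset
from hexamap.linkmap import (MapError, build_map, group_markers, haldane_cm,
                             map_distances, order_group, pairwise_rf)
from hexamap.markers import bin_cosegregating, classify_matrix

from conftest import toy_config
from oracles import best_order_oracle


# -- recombination fractions -------------------------------------------------

def test_identical_vectors_zero_rf():
    s = np.array([[0, 1, 0, 1] * 10, [0, 1, 0, 1] * 10], dtype=np.int8)
    rf = pairwise_rf(s)
    assert rf.r[0, 1] == 0.0
    assert rf.informative[0, 1] == 40


def test_two_discordant_of_hundred():
    a = np.zeros(100, dtype=np.int8)
    b = np.zeros(100, dtype=np.int8)
    b[:2] = 1
    rf = pairwise_rf(np.stack([a, b]))
    assert rf.r[0, 1] == pytest.approx(0.02)


def test_missing_excluded_from_denominator():
    a = np.array([0, 0, 1, 1, -1], dtype=np.int8)
    b = np.array([0, 1, 1, -1, 0], dtype=np.int8)
    rf = pairwise_rf(np.stack([a, b]))
    assert rf.informative[0, 1] == 3
    assert rf.r[0, 1] == pytest.approx(1 / 3)


def test_independent_vectors_rf_near_half():
    rng = np.random.default_rng(0)
    n_pairs, n = 1000, 164
    s = rng.integers(0, 2, size=(2 * n_pairs, n)).astype(np.int8)
    rf = pairwise_rf(s)
    vals = [rf.r[2 * i, 2 * i + 1] for i in range(n_pairs)]
    # truncation at 0.5 halves the upper tail; mean of min(X, .5) for
    # X ~ Bin(164, .5)/164 is about 0.5 - E|X-.5|/2 = 0.5 - sd/sqrt(2pi)
    sd = np.sqrt(0.25 / n)
    expect = 0.5 - sd / np.sqrt(2 * np.pi)
    assert abs(np.mean(vals) - expect) <= 3 * sd / np.sqrt(n_pairs)


# -- grouping ----------------------------------------------------------------

def test_two_chromosomes_two_groups():
    ds = simulate_dataset(toy_config(events=[], qtl_event=None,
                                     genome=__import__("hexamap").GenomeConfig(
                                         n_pairs=1, chrom_length=3_000_000)),
                          seed=4)
    records = classify_matrix(ds.calls)
    bins = bin_cosegregating(records)
    reps = [b for b in bins if b[0].seg_ok]
    scores = np.stack([b[0].scores for b in reps])
    rf = pairwise_rf(scores)
    groups = group_markers(rf, cutoff=0.2)
    big = [g for g in groups if len(g) > 2]
    assert len(big) == 2
    for g in big:
        chroms = {reps[i][0].chrom for i in g}
        assert len(chroms) == 1


def test_unlinked_markers_singleton_groups():
    rng = np.random.default_rng(1)
    s = rng.integers(0, 2, size=(10, 200)).astype(np.int8)
    rf = pairwise_rf(s)
    groups = group_markers(rf, cutoff=0.2)
    assert all(len(g) == 1 for g in groups)


def test_grouping_monotone_in_cutoff():
    """Groups at a tighter cutoff refine the groups at a looser one."""
    ds = simulate_dataset(toy_config(events=[], qtl_event=None), seed=8)
    bins = bin_cosegregating(classify_matrix(ds.calls))
    reps = [b for b in bins if b[0].seg_ok]
    rf = pairwise_rf(np.stack([b[0].scores for b in reps]))
    loose = group_markers(rf, cutoff=0.2)
    tight = group_markers(rf, cutoff=0.15)
    loose_of = {}
    for gi, g in enumerate(loose):
        for m in g:
            loose_of[m] = gi
    for g in tight:
        assert len({loose_of[m] for m in g}) == 1


# -- ordering ----------------------------------------------------------------

def chain_rf(n, r_adj=0.05):
    """Perfect chain: r grows with distance via Haldane composition."""
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist = abs(i - j) * (-50 * np.log(1 - 2 * r_adj))
            d[i, j] = 0.5 * (1 - np.exp(-2 * dist / 100))
    from hexamap.linkmap import RFMatrix
    return RFMatrix(r=d, informative=np.full((n, n), 100))


def test_three_bin_chain_recovered():
    rf = chain_rf(3)
    assert order_group([0, 1, 2], rf) in ([0, 1, 2], [2, 1, 0])


def test_eight_loci_match_exhaustive_oracle():
    rng = np.random.default_rng(5)
    rf = chain_rf(8, r_adj=0.08)
    perm = list(rng.permutation(8))
    sub = rf.r[np.ix_(perm, perm)]
    from hexamap.linkmap import RFMatrix
    rfp = RFMatrix(r=sub, informative=np.full((8, 8), 100))
    got = order_group(list(range(8)), rfp)
    want = best_order_oracle(sub)
    assert got == want or got == want[::-1]


def test_reversal_canonicalized_by_anchor():
    ds = simulate_dataset(toy_config(events=[], qtl_event=None,
                                     genome=__import__("hexamap").GenomeConfig(
                                         n_pairs=1, chrom_length=2_000_000)),
                          seed=2)
    lm, _ = build_map(bin_cosegregating(classify_matrix(ds.calls)))
    for lg in lm.groups:
        pos = [lm.bins[i][0].pos for i in lg.order]
        assert pos[0] <= pos[-1]


# -- distances ---------------------------------------------------------------

def test_haldane_closed_forms():
    assert haldane_cm(0.0) == 0.0
    assert haldane_cm(0.2) == pytest.approx(-50 * np.log(0.6), abs=1e-9)
    assert haldane_cm(0.2) == pytest.approx(25.541, abs=1e-3)
    with pytest.raises(MapError):
        haldane_cm(0.5)


def test_cumulative_distances():
    from hexamap.linkmap import RFMatrix
    r = np.array([[0, 0.1, 0], [0.1, 0, 0.1], [0, 0.1, 0]])
    rf = RFMatrix(r=r, informative=np.full((3, 3), 100))
    cm = map_distances([0, 1, 2], rf)
    step = -50 * np.log(0.8)
    np.testing.assert_allclose(cm, [0, step, 2 * step])
    assert step == pytest.approx(11.157, abs=1e-3)


# -- full map recovery -------------------------------------------------------

def test_map_recovers_marker_order_and_length():
    """Control (no rearrangements): one group per chromosome, marker order
    matching physical order (|Spearman| >= 0.99), and map length near the
    100 * crossover-mean expectation."""
    lengths = []
    for seed in (1, 2, 3):
        ds = simulate_dataset(toy_config(events=[], qtl_event=None), seed=seed)
        lm, _ = build_map(bin_cosegregating(classify_matrix(ds.calls)))
        big = [g for g in lm.groups if len(g.order) > 3]
        assert len(big) == 4  # 2 homoeologous pairs
        for lg in big:
            pos = [lm.bins[i][0].pos for i in lg.order]
            rho = spearmanr(pos, np.arange(len(pos))).statistic
            assert abs(rho) >= 0.99
            lengths.append(lg.cm[-1])
    # Poisson mean 1.5 crossovers -> 150 cM expected per chromosome
    assert abs(np.mean(lengths) - 150) / 150 < 0.15


def test_rearrangement_splits_linkage_group():
    """Disrupted pairing across a parent-specific rearrangement severs
    linkage and yields two groups for one chromosome."""
    from hexamap.genome import GenomeConfig, simulate_genome
    from hexamap.simulate import simulate_array_calls, simulate_dh_population
    genome = simulate_genome(GenomeConfig(n_pairs=1, chrom_length=3_000_000))
    lines, _ = simulate_dh_population(genome, [], 164, seed=3,
                                      decouple_at={"A01": 1_500_000})
    calls, _ = simulate_array_calls(genome, [], lines, seed=3)
    lm, _ = build_map(bin_cosegregating(classify_matrix(calls)))
    a_groups = [g for g in lm.groups if g.chrom == "A01" and len(g.order) > 3]
    assert len(a_groups) == 2
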