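import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtclust import (
    GenomeGeneOrder,
    HGTCandidateSet,
    SpatialConfig,
    ValidationError,
    count_neighbour_pairs,
    expected_neighbour_pairs,
    observed_pairs_for_genome,
    spatial_analysis,
)
from hgtclust.spatial import _null_counts_for_genome, _genome_rng

from oracles import enumerate_expected_pairs


@pytest.mark.parametrize(
    "flags,want",
    [
        ([1, 1, 0, 0, 0], 1),
        ([1, 0, 0, 1, 0, 1, 0, 0, 0, 1], 2),
        ([0, 0, 0, 0], 0),
        ([0, 1, 0, 0, 0], 0),
        ([1, 1, 1, 1], 3),
        ([], 0),
    ],
)
def test_count_neighbour_pairs_window3(flags, want):
    assert count_neighbour_pairs(flags, window=3) == want


def test_count_neighbour_pairs_circular_wraps():
    # the trailing candidate sees the leading one through the wrap (the
    # window only looks rightward, so the leading one still sees nothing)
    assert count_neighbour_pairs([1, 0, 0, 0, 0, 1], window=3, topology="linear") == 0
    assert count_neighbour_pairs([1, 0, 0, 0, 0, 1], window=3, topology="circular") == 1
    assert count_neighbour_pairs([1, 0, 0, 1, 0, 0], window=3, topology="circular") == 2


def test_count_neighbour_pairs_rejects_non_binary():
    with pytest.raises(ValidationError):
        count_neighbour_pairs([0, 2, 1])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), max_size=40), st.integers(1, 4))
def test_count_reversal_invariance(flags, window):
    """Each qualifying right-window neighbour maps to a qualifying
    left-window neighbour of the reversed sequence."""
    assert count_neighbour_pairs(flags, window) == count_neighbour_pairs(
        flags[::-1], window
    )


@pytest.mark.parametrize(
    "n,c,want",
    [(4, 4, 3.0), (10, 3, 17 / 12), (10, 1, 0.0), (7, 0, 0.0)],
)
def test_expected_neighbour_pairs_values(n, c, want):
    assert expected_neighbour_pairs(n, c, window=3) == pytest.approx(want, rel=1e-12)


def test_expected_neighbour_pairs_expands_to_three_term_form():
    n, c = 50, 7
    three_term = (
        (n - 1) * (c / n) * (c - 1) / (n - 1)
        + (n - 2) * (c / n) * ((n - c) / (n - 1)) * (c - 1) / (n - 2)
        + (n - 3) * (c / n) * ((n - c) / (n - 1)) * ((n - c - 1) / (n - 2)) * (c - 1) / (n - 3)
    )
    assert expected_neighbour_pairs(n, c, window=3) == pytest.approx(three_term, rel=1e-14)


def test_expected_neighbour_pairs_rejects_c_above_n():
    with pytest.raises(ValidationError):
        expected_neighbour_pairs(5, 6)


@pytest.mark.parametrize("topology", ["linear", "circular"])
@pytest.mark.parametrize("n,c,w", [(6, 3, 3), (8, 5, 2), (5, 5, 3), (9, 2, 1), (4, 3, 3)])
def test_expected_matches_enumeration_spot_checks(n, c, w, topology):
    """Exhaustive-placement oracle agreement (full grid runs in acceptance)."""
    exact = enumerate_expected_pairs(n, c, w, circular=(topology == "circular"))
    assert expected_neighbour_pairs(n, c, w, topology) == pytest.approx(
        float(exact), rel=1e-12
    )


def test_observed_pairs_singletons_occupy_positions():
    config = SpatialConfig()
    order = GenomeGeneOrder(
        "G1", "chr", genes=("g1", "s", "g2"), examined=(True, False, True)
    )
    assert observed_pairs_for_genome(order, {"g1", "g2"}, config) == 1
    wide = GenomeGeneOrder(
        "G1", "chr", genes=("g1", "s1", "s2", "s3", "g2"),
        examined=(True, False, False, False, True),
    )
    assert observed_pairs_for_genome(wide, {"g1", "g2"}, config) == 0


def test_observed_pairs_unexamined_candidate_rejected():
    order = GenomeGeneOrder("G1", "chr", genes=("g1", "s"), examined=(True, False))
    with pytest.raises(ValidationError, match="not examined"):
        observed_pairs_for_genome(order, {"s"}, SpatialConfig())


def test_observed_pairs_empty_candidates(simple_order):
    assert observed_pairs_for_genome(simple_order, set(), SpatialConfig()) == 0


def test_spatial_analysis_all_candidates_is_exactly_null(simple_order):
    cset = HGTCandidateSet("all", {"G1": frozenset(simple_order.genes)})
    res = spatial_analysis([simple_order], cset, SpatialConfig(n_randomizations=99))
    assert res.cc == pytest.approx(1.0)
    assert res.p_value == 1.0  # only one arrangement exists


def test_spatial_analysis_min_p_is_forced_by_formula():
    # a tight planted block that no random arrangement can beat
    genes = tuple(f"g{i}" for i in range(200))
    order = GenomeGeneOrder("G1", "chr", genes=genes)
    cset = HGTCandidateSet("block", {"G1": frozenset(genes[:4])})
    res = spatial_analysis([order], cset, SpatialConfig(n_randomizations=999, seed=3))
    assert res.observed == 3
    assert res.p_value >= 1 / 1000
    assert res.p_value <= 0.01


def test_spatial_analysis_missing_genome_raises(simple_order):
    cset = HGTCandidateSet("x", {"G2": frozenset({"g1"})})
    with pytest.raises(ValidationError, match="G2"):
        spatial_analysis([simple_order], cset, SpatialConfig(n_randomizations=9))


def test_null_counts_conserve_candidate_number(simple_order):
    """Every randomization redistributes exactly c candidates."""
    config = SpatialConfig(n_randomizations=50, gap_mode="exact", seed=0)
    order = GenomeGeneOrder(
        "G1", "chr", genes=tuple(f"g{i}" for i in range(30)),
        examined=tuple(i % 3 != 0 for i in range(30)),
    )
    rng = _genome_rng(0, "G1")
    c = 5
    # re-derive placements through the public path: exact-mode nulls can
    # never exceed what c candidates can produce
    counts = _null_counts_for_genome([order], c, config, rng)
    assert counts.shape == (50,)
    assert counts.max() <= c
    assert counts.min() >= 0


def test_spatial_analysis_seed_determinism_and_order_invariance():
    rng = np.random.default_rng(0)
    orders = []
    cands = {}
    for g in ("G1", "G2", "G3"):
        genes = tuple(f"{g}|g{i}" for i in range(100))
        orders.append(GenomeGeneOrder(g, "chr", genes=genes))
        cands[g] = frozenset(rng.choice(genes, size=8, replace=False))
    cset = HGTCandidateSet("s", cands)
    config = SpatialConfig(n_randomizations=99, seed=42)
    res1 = spatial_analysis(orders, cset, config)
    res2 = spatial_analysis(list(reversed(orders)), cset, config)
    assert (res1.observed, res1.expected, res1.p_value) == (
        res2.observed, res2.expected, res2.p_value
    )


def test_gap_modes_agree_without_gaps():
    """With no singletons the conservative and the exact convention target
    the same null, so expectations agree up to permutation noise."""
    genes = tuple(f"g{i}" for i in range(300))
    order = GenomeGeneOrder("G1", "chr", genes=genes)
    cands = HGTCandidateSet(
        "s", {"G1": frozenset(np.random.default_rng(1).choice(genes, 20, replace=False))}
    )
    cons = spatial_analysis([order], cands, SpatialConfig(gap_mode="conservative",
                                                          n_randomizations=2999, seed=0))
    exact = spatial_analysis([order], cands, SpatialConfig(gap_mode="exact",
                                                           n_randomizations=2999, seed=0))
    assert cons.observed == exact.observed
    assert exact.expected == pytest.approx(cons.expected, rel=0.15)
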