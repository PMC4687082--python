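import itertools

import numpy as np
import pandas as pd
import pytest

from hgtclust import (
    ParsimonyConfig,
    PhyleticMatrix,
    Phylogeny,
    ValidationError,
    compare_candidate_sets,
    reconstruct_deltran,
    sankoff_min_cost,
    terminal_hgt_candidates,
)
from hgtclust.model import GenomeGeneOrder, HGTCandidateSet

from oracles import all_rooted_binary_trees, brute_force_min_costs, tree_to_newick


@pytest.mark.parametrize(
    "pattern,pg,pl,want",
    [
        ({"A": 1, "B": 1, "C": 1, "D": 1}, 1, 1, 0.0),
        ({"A": 1, "B": 0, "C": 0, "D": 0}, 1, 1, 1.0),
        ({"A": 1, "B": 0, "C": 0, "D": 0}, 2, 1, 2.0),
        ({"A": 0, "B": 0, "C": 0, "D": 0}, 2, 1, 0.0),
    ],
)
def test_sankoff_quartet_examples(quartet_tree, pattern, pg, pl, want):
    config = ParsimonyConfig(gain_penalty=pg, loss_penalty=pl)
    assert sankoff_min_cost(quartet_tree, pattern, config) == want


def test_sankoff_missing_tip_raises(quartet_tree, equal_penalties):
    with pytest.raises(ValidationError, match="missing"):
        sankoff_min_cost(quartet_tree, {"A": 1, "B": 0, "C": 0}, equal_penalties)


def test_deltran_single_tip_gain(quartet_tree, equal_penalties):
    recon = reconstruct_deltran(
        quartet_tree, {"A": 1, "B": 0, "C": 0, "D": 0}, equal_penalties
    )
    assert recon.gains_on_tips == {"A"}
    assert (recon.n_gains, recon.n_losses) == (1, 0)


def test_deltran_cherry_gain_is_internal(quartet_tree, equal_penalties):
    recon = reconstruct_deltran(
        quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0}, equal_penalties
    )
    assert recon.gains_on_tips == frozenset()
    assert (recon.n_gains, recon.n_losses) == (1, 0)


def test_deltran_ratio2_tie_resolves_to_terminal_gain(quartet_tree, strict_penalties):
    # gain-on-tip (cost 2) ties a root-presence scenario with two losses;
    # delaying the change tipward picks the terminal gain
    recon = reconstruct_deltran(
        quartet_tree, {"A": 1, "B": 0, "C": 0, "D": 0}, strict_penalties
    )
    assert recon.gains_on_tips == {"A"}
    assert recon.total_cost == 2.0


def test_deltran_all_absent_no_events(quartet_tree, equal_penalties):
    recon = reconstruct_deltran(
        quartet_tree, {"A": 0, "B": 0, "C": 0, "D": 0}, equal_penalties
    )
    assert recon.branch_events == {}
    assert recon.total_cost == 0.0


def test_deltran_cost_matches_sankoff_on_random_instances():
    rng = np.random.default_rng(11)
    labels = ["A", "B", "C", "D", "E"]
    trees = list(all_rooted_binary_trees(labels))
    for _ in range(100):
        tree = Phylogeny.from_newick(
            tree_to_newick(trees[rng.integers(len(trees))])
        )
        pattern = {l: int(rng.integers(2)) for l in labels}
        for ratio in (1.0, 2.0, 0.5):
            config = ParsimonyConfig(gain_penalty=ratio, loss_penalty=1.0)
            recon = reconstruct_deltran(tree, pattern, config)
            assert recon.total_cost == pytest.approx(
                sankoff_min_cost(tree, pattern, config)
            )
            assert recon.total_cost == pytest.approx(
                recon.n_gains * ratio + recon.n_losses
            )


def test_sankoff_matches_brute_force_on_5_tip_sample():
    """Spot-check against exhaustive enumeration (the full sweep up to six
    tips runs in the acceptance suite)."""
    labels = ["A", "B", "C", "D", "E"]
    trees = list(all_rooted_binary_trees(labels))[::7]
    for tuple_tree in trees:
        for pg in (1.0, 2.0):
            config = ParsimonyConfig(gain_penalty=pg, loss_penalty=1.0)
            expected, order = brute_force_min_costs(tuple_tree, pg, 1.0)
            tree = Phylogeny.from_newick(tree_to_newick(tuple_tree))
            for states, want in expected.items():
                pattern = dict(zip(order, states))
                assert sankoff_min_cost(tree, pattern, config) == want


def test_sankoff_on_multifurcating_tree():
    tree = Phylogeny.from_newick("(A,B,C,D);")
    config = ParsimonyConfig(1.0, 1.0)
    assert sankoff_min_cost(tree, {"A": 1, "B": 0, "C": 0, "D": 0}, config) == 1.0
    assert sankoff_min_cost(tree, {"A": 1, "B": 1, "C": 1, "D": 0}, config) == 1.0


def test_unrooted_tree_rejected():
    with pytest.raises(ValidationError, match="unrooted"):
        Phylogeny.from_newick("[&U] ((A,B),(C,D));")


def test_automorphism_symmetry(quartet_tree, equal_penalties):
    # swapping the two cherries is a tree automorphism: events must follow
    perm = {"A": "C", "B": "D", "C": "A", "D": "B"}
    for bits in itertools.product((0, 1), repeat=4):
        pattern = dict(zip("ABCD", bits))
        permuted = {perm[k]: v for k, v in pattern.items()}
        r1 = reconstruct_deltran(quartet_tree, pattern, equal_penalties)
        r2 = reconstruct_deltran(quartet_tree, permuted, equal_penalties)
        assert r2.gains_on_tips == frozenset(perm[t] for t in r1.gains_on_tips)
        assert r2.total_cost == r1.total_cost


def _matrix(patterns: dict[str, dict[str, int]], singletons=()):
    df = pd.DataFrame(patterns).T.astype(int)
    mapping = {
        (fam, genome): f"{genome}|{fam}"
        for fam, row in patterns.items()
        for genome, present in row.items()
        if present
    }
    return PhyleticMatrix(df, mapping, singleton_families=singletons)


def test_terminal_candidates_single_tip_family(quartet_tree, equal_penalties):
    matrix = _matrix({"f1": {"A": 1, "B": 0, "C": 0, "D": 0}})
    cset = terminal_hgt_candidates(matrix, quartet_tree, equal_penalties)
    assert cset.candidates["A"] == {"A|f1"}
    assert all(not cset.candidates[g] for g in "BCD")


def test_terminal_candidates_core_family_contributes_nothing(
    quartet_tree, equal_penalties
):
    matrix = _matrix({"f1": {"A": 1, "B": 1, "C": 1, "D": 1}})
    cset = terminal_hgt_candidates(matrix, quartet_tree, equal_penalties)
    assert cset.size() == 0


def test_terminal_candidates_skip_singletons(quartet_tree, equal_penalties):
    matrix = _matrix({"f1": {"A": 1, "B": 0, "C": 0, "D": 0}}, singletons={"f1"})
    cset = terminal_hgt_candidates(matrix, quartet_tree, equal_penalties)
    assert cset.size() == 0


def test_terminal_candidates_skip_plasmid_genes(quartet_tree, equal_penalties):
    matrix = _matrix({"f1": {"A": 1, "B": 0, "C": 0, "D": 0}})
    plasmid = GenomeGeneOrder("A", "pOne", genes=("A|f1",), is_plasmid=True)
    cset = terminal_hgt_candidates(
        matrix, quartet_tree, equal_penalties, orders=[plasmid]
    )
    assert cset.size() == 0


def test_terminal_candidates_missing_gene_mapping_raises(
    quartet_tree, equal_penalties
):
    df = pd.DataFrame({"A": [1], "B": [1], "C": [0], "D": [0]}, index=["f1"])
    df.loc["f2"] = [1, 0, 0, 0]
    matrix = PhyleticMatrix(df)  # no gene map at all
    with pytest.raises(ValidationError, match="no gene mapping"):
        terminal_hgt_candidates(matrix, quartet_tree, equal_penalties)


def test_gain_count_non_increasing_in_penalty_ratio(quartet_tree):
    """Raising the gain penalty can only shrink the candidate set: the
    stricter convention re-explains marginal gains as losses."""
    rng = np.random.default_rng(5)
    patterns = {
        f"f{i}": dict(zip("ABCD", (rng.random(4) < 0.5).astype(int)))
        for i in range(200)
    }
    matrix = _matrix(patterns)
    sizes = []
    for ratio in (1.0, 2.0):
        config = ParsimonyConfig(gain_penalty=ratio, loss_penalty=1.0)
        sizes.append(terminal_hgt_candidates(matrix, quartet_tree, config).size())
    assert sizes[0] >= sizes[1]
    assert sizes[0] > 0


def test_compare_candidate_sets():
    a = HGTCandidateSet("a", {"G1": frozenset({"g1", "g2", "g3"})})
    b = HGTCandidateSet("b", {"G1": frozenset({"g2"})})
    summary = compare_candidate_sets(a, b)
    assert summary["total"] == {
        "a": 3, "b": 1, "intersection": 1, "a_only": 2, "b_only": 0, "union": 3,
    }
    same = compare_candidate_sets(a, a)
    assert same["total"]["intersection"] == 3
    with pytest.raises(ValidationError, match="universe"):
        compare_candidate_sets(a, HGTCandidateSet("c", {"G2": frozenset()}))
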