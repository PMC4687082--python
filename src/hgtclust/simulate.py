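"""Synthetic genomes, phyletic matrices and coupling networks with known truth.

The generator emulates the data regime of a comparative study of ~21 closely
related enterobacterial genomes: a few thousand genes per genome with a
minority of singletons, gene families born at the ancestral root and lost
stochastically along branches, recent transfers appearing as gains on
terminal branches — optionally in operon-like contiguous blocks — and a
flux-coupling network of a few thousand genes with several hundred coupled
pairs.  All randomness flows from one seed through named substreams, so
every artifact is reproducible and insensitive to call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .model import (
    CouplingNetwork,
    GenomeGeneOrder,
    PhyleticMatrix,
    Phylogeny,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "random_tree",
    "simulate_genome_blocks",
    "simulate_family_evolution",
    "simulate_coupling_network",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study-regime parameters for all three simulators.

    Defaults mirror the empirical regime the statistics were designed for:
    ~2,000 genes per genome across 21 tips (~42,000 genes overall), ~2,977
    root-born families, ~96 terminal gains per tip (~2,000 recent transfers
    in total), and a coupling network of 4,242 genes with 701 fully coupled
    pairs.  ``block_length_distribution`` is degenerate at length 1
    (independent insertions — the spatial null); operon-like co-transfer is
    simulated by putting mass on lengths 2-4.
    """

    n_genes: int = 2000
    n_candidates: int = 96
    block_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0}
    )
    singleton_fraction: float = 0.15
    tree: Phylogeny | None = None
    n_tips: int = 21
    family_birth_at_root: int = 2977
    loss_rate: float = 0.05
    terminal_gain_count: int = 96
    internal_gain_count: int = 0
    network_n: int = 4242
    network_L1: int = 701
    coupling_module_size: int = 3
    enrichment_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.block_length_distribution.values())
        if not probs or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValidationError("block length probabilities must sum to 1")
        if any(l < 1 for l in self.block_length_distribution):
            raise ValidationError("block lengths must be >= 1")
        if not (0 <= self.singleton_fraction < 1):
            raise ValidationError("singleton_fraction must be in [0, 1)")
        if not (0 <= self.enrichment_fraction <= 1):
            raise ValidationError("enrichment_fraction must be in [0, 1]")
        if self.n_candidates > self.n_genes:
            raise ValidationError("n_candidates exceeds n_genes")
        if self.network_L1 > self.network_n * (self.network_n - 1) // 2:
            raise ValidationError("network_L1 exceeds the possible pair count")
        if not (0 <= self.loss_rate < 1):
            raise ValidationError("loss_rate must be in [0, 1)")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


def random_tree(n_tips: int, rng: np.random.Generator, prefix: str = "G") -> Phylogeny:
    """A random rooted binary tree built by uniform sequential attachment.

    Tips are labelled ``G01..``; internal nodes ``N1..`` so every branch has
    a stable identifier for event logs.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    width = max(2, len(str(n_tips)))
    labels = [f"{prefix}{i + 1:0{width}d}" for i in range(n_tips)]
    # nested-tuple topology, then serialize to newick
    tree = labels[0]
    for label in labels[1:]:
        positions = _subtree_positions(tree)
        pick = positions[int(rng.integers(len(positions)))]
        tree = _attach_at(tree, pick, label)
    counter = [0]

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        counter[0] += 1
        mine = counter[0]
        return f"({to_newick(node[0])},{to_newick(node[1])})N{mine}"

    return Phylogeny.from_newick(to_newick(tree) + ";")


def _subtree_positions(tree, path=()) -> list[tuple]:
    positions = [path]
    if isinstance(tree, tuple):
        positions += _subtree_positions(tree[0], path + (0,))
        positions += _subtree_positions(tree[1], path + (1,))
    return positions


def _attach_at(tree, path: tuple, label: str):
    if not path:
        return (tree, label)
    head, rest = path[0], path[1:]
    children = list(tree)
    children[head] = _attach_at(children[head], rest, label)
    return tuple(children)


def _sample_block_lengths(
    dist: Mapping[int, float], total: int, rng: np.random.Generator
) -> list[int]:
    """Block lengths from ``dist`` whose sum is exactly ``total`` (the final
    block is clipped if needed, conserving the candidate count)."""
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    out: list[int] = []
    remaining = total
    while remaining > 0:
        length = int(rng.choice(lengths, p=probs))
        length = min(length, remaining)
        out.append(length)
        remaining -= length
    return out


def _place_blocks(
    n: int, block_lengths: list[int], rng: np.random.Generator, max_tries: int = 2000
) -> list[int]:
    """Non-overlapping uniform placement by rejection sampling; returns the
    occupied positions."""
    occupied = np.zeros(n, dtype=bool)
    positions: list[int] = []
    for length in sorted(block_lengths, reverse=True):
        for _ in range(max_tries):
            start = int(rng.integers(0, n - length + 1))
            if not occupied[start : start + length].any():
                occupied[start : start + length] = True
                positions.extend(range(start, start + length))
                break
        else:
            raise ValidationError(
                f"could not place a block of length {length}: candidate load too high"
            )
    return positions


def simulate_genome_blocks(
    params: SimulationParams, genome_id: str = "G01", replicon_id: str = "chr"
) -> tuple[GenomeGeneOrder, frozenset[str]]:
    """One linear genome with planted candidate blocks.

    Exactly ``n_candidates`` candidate genes are placed in non-overlapping
    blocks whose lengths follow ``block_length_distribution``; a
    ``singleton_fraction`` share of the non-candidate genes is marked
    unexamined (singletons), creating gaps between examined genes.
    """
    rng = _substream(params.seed, f"genome:{genome_id}:{replicon_id}")
    n, c = params.n_genes, params.n_candidates
    lengths = _sample_block_lengths(params.block_length_distribution, c, rng)
    cand_positions = set(_place_blocks(n, lengths, rng))
    genes = tuple(f"{genome_id}|g{i:05d}" for i in range(n))
    non_cand = [i for i in range(n) if i not in cand_positions]
    n_singletons = int(round(params.singleton_fraction * len(non_cand)))
    singleton_positions = set(
        rng.choice(non_cand, size=n_singletons, replace=False).tolist()
    ) if n_singletons else set()
    examined = tuple(i not in singleton_positions for i in range(n))
    order = GenomeGeneOrder(
        genome_id=genome_id, replicon_id=replicon_id, genes=genes, examined=examined
    )
    candidates = frozenset(genes[i] for i in cand_positions)
    return order, candidates


def simulate_family_evolution(
    params: SimulationParams,
) -> tuple[PhyleticMatrix, list[dict], dict[str, GenomeGeneOrder]]:
    """Gene-family birth/loss/gain on a tree, with full ground truth.

    Every root-born family starts present at the root and is lost along each
    branch independently with probability ``loss_rate``.  Each terminal
    branch additionally gains ``terminal_gain_count`` brand-new families
    (absent everywhere else); with ``internal_gain_count`` > 0, internal
    branches gain families too (inherited by the subtree), exercising the
    terminal-only candidate filter.  Gained families are laid out in the
    recipient's gene order in blocks drawn from
    ``block_length_distribution``.

    Returns the phyletic matrix, an event log of dicts
    ``{family, branch, event}`` (branch = label of the child node of the
    edge), and one GenomeGeneOrder per tip including unexamined singleton
    genes at a ``singleton_fraction`` share of each genome.
    """
    tree = params.tree or random_tree(params.n_tips, _substream(params.seed, "tree"))
    rng = _substream(params.seed, "families")

    nodes = list(tree.preorder())
    node_label = {}
    for i, node in enumerate(nodes):
        label = Phylogeny.node_label(node) or getattr(node, "label", None) or f"node{i}"
        node_label[id(node)] = label
    tips = [n for n in nodes if n.is_leaf()]

    events: list[dict] = []
    n_fam = params.family_birth_at_root
    fam_ids = [f"F{i:05d}" for i in range(n_fam)]
    # presence of root-born families at every node, simulated top-down
    presence: dict[int, np.ndarray] = {id(tree.root): np.ones(n_fam, dtype=bool)}
    for node in nodes:
        if node is tree.root:
            continue
        parent = presence[id(node.parent_node)]
        losses = parent & (rng.random(n_fam) < params.loss_rate)
        presence[id(node)] = parent & ~losses
        for f in np.flatnonzero(losses):
            events.append(
                {"family": fam_ids[f], "branch": node_label[id(node)], "event": "loss"}
            )

    # gained families: new columns appended per branch
    gained_by_node: dict[int, list[str]] = {id(n): [] for n in nodes}
    counter = n_fam
    for node in nodes:
        if node is tree.root:
            continue
        k = params.terminal_gain_count if node.is_leaf() else params.internal_gain_count
        for _ in range(k):
            fam = f"F{counter:05d}"
            counter += 1
            gained_by_node[id(node)].append(fam)
            events.append(
                {"family": fam, "branch": node_label[id(node)], "event": "gain"}
            )

    def inherited_gains(node) -> list[str]:
        out = []
        cur = node
        while cur is not None:
            out.extend(gained_by_node.get(id(cur), []))
            cur = cur.parent_node
        return out

    tip_labels = [node_label[id(t)] for t in tips]
    all_fams = fam_ids + [f"F{i:05d}" for i in range(n_fam, counter)]
    matrix = pd.DataFrame(0, index=all_fams, columns=tip_labels, dtype="int8")
    family_to_gene: dict[tuple[str, str], str] = {}
    orders: dict[str, GenomeGeneOrder] = {}
    base_order = list(range(n_fam))  # shared ancestral gene order

    for tip in tips:
        label = node_label[id(tip)]
        core = [fam_ids[i] for i in base_order if presence[id(tip)][i]]
        gains = inherited_gains(tip)
        matrix.loc[core, label] = 1
        matrix.loc[gains, label] = 1
        genes_seq = [(fam, True) for fam in core]
        tip_rng = _substream(params.seed, f"order:{label}")
        # insert gained families in contiguous blocks at random positions
        gains_left = list(gains)
        while gains_left:
            length = _sample_block_lengths(
                params.block_length_distribution, len(gains_left), tip_rng
            )[0]
            block, gains_left = gains_left[:length], gains_left[length:]
            pos = int(tip_rng.integers(0, len(genes_seq) + 1))
            genes_seq[pos:pos] = [(fam, True) for fam in block]
        # singleton genes: unexamined, occupy positions
        f = params.singleton_fraction
        n_singletons = int(round(f / (1 - f) * len(genes_seq))) if f else 0
        for s in range(n_singletons):
            pos = int(tip_rng.integers(0, len(genes_seq) + 1))
            genes_seq[pos:pos] = [(f"orfan{s:05d}", False)]
        gene_names = []
        examined_flags = []
        for fam, is_exam in genes_seq:
            gene = f"{label}|{fam}"
            gene_names.append(gene)
            examined_flags.append(is_exam)
            if is_exam:
                family_to_gene[(fam, label)] = gene
        orders[label] = GenomeGeneOrder(
            genome_id=label, replicon_id="chr",
            genes=tuple(gene_names), examined=tuple(examined_flags),
        )

    matrix = matrix.loc[matrix.sum(axis=1) > 0]  # families lost everywhere drop out
    phyletic = PhyleticMatrix(matrix, family_to_gene)
    return phyletic, events, orders


def simulate_coupling_network(
    params: SimulationParams,
    node_names: list[str] | None = None,
) -> tuple[CouplingNetwork, frozenset[str]]:
    """A coupling network plus a candidate set of ``n_candidates`` genes.

    With ``enrichment_fraction`` = 0 the candidates are a uniform draw from
    the node universe (the null).  Otherwise that fraction of candidates is
    taken from coupled modules (cliques of ``coupling_module_size`` genes,
    filled whole), guaranteeing excess coupled pairs among candidates; the
    rest are drawn uniformly from the remaining genes.

    ``node_names`` grafts the network onto existing gene identifiers (e.g.
    one simulated genome's examined genes, the way a real coupling network
    is tied to one reference strain); it overrides ``network_n``.
    """
    rng = _substream(params.seed, "network")
    L1, n2 = params.network_L1, params.n_candidates
    if node_names is not None:
        nodes = list(node_names)
        n = len(nodes)
        if L1 > n * (n - 1) // 2:
            raise ValidationError("network_L1 exceeds the possible pair count")
    else:
        n = params.network_n
        nodes = [f"m{i:05d}" for i in range(n)]
    if n2 > n:
        raise ValidationError("n_candidates exceeds the node universe size")
    m = params.coupling_module_size
    n_enriched = int(round(params.enrichment_fraction * n2))
    pairs: set[tuple[int, int]] = set()
    module_nodes: list[int] = []
    if n_enriched:
        if m < 2:
            raise ValidationError("coupling_module_size must be >= 2 for enrichment")
        n_modules = -(-n_enriched // m)
        clique_pairs = n_modules * m * (m - 1) // 2
        if clique_pairs > L1 or n_modules * m > n:
            raise ValidationError(
                "enrichment infeasible: modules need more pairs or nodes than available"
            )
        module_nodes = rng.choice(n, size=n_modules * m, replace=False).tolist()
        for k in range(n_modules):
            clique = module_nodes[k * m : (k + 1) * m]
            for i in range(m):
                for j in range(i + 1, m):
                    pairs.add(tuple(sorted((clique[i], clique[j]))))
    while len(pairs) < L1:
        a, b = rng.integers(0, n, size=2)
        if a != b:
            pairs.add(tuple(sorted((int(a), int(b)))))
    network = CouplingNetwork(nodes, [(nodes[a], nodes[b]) for a, b in pairs])
    chosen = module_nodes[:n_enriched]
    rest_pool = [i for i in range(n) if i not in set(chosen)]
    extra = rng.choice(len(rest_pool), size=n2 - len(chosen), replace=False)
    chosen = chosen + [rest_pool[i] for i in extra]
    candidates = frozenset(nodes[i] for i in chosen)
    return network, candidates
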