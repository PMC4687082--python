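"""Generalized parsimony for gene gain/loss on a rooted phylogeny.

Each gene family's phyletic pattern (presence/absence at the tips) is
explained by ancestral presence states minimizing the total event cost,
where a gain (0 -> 1 along a branch) costs ``P_g`` and a loss (1 -> 0)
costs ``P_l``.  Ambiguity among equally parsimonious reconstructions is
resolved DELTRAN-style: state changes are delayed toward the tips.  A gene
is called an HGT candidate when its family's reconstruction places a gain
on the terminal branch leading to that genome.

Conventions where the literature leaves freedom (documented in the methods
note): both root states are free of charge; when the two root states tie in
total cost the absent state (0) is chosen, pushing gains tipward; when a
non-root node is ambiguous it takes its parent's state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .model import (
    GenomeGeneOrder,
    HGTCandidateSet,
    PhyleticMatrix,
    Phylogeny,
    ValidationError,
)

__all__ = [
    "ParsimonyConfig",
    "EventReconstruction",
    "sankoff_min_cost",
    "reconstruct_deltran",
    "terminal_hgt_candidates",
    "compare_candidate_sets",
]

_INF = float("inf")


@dataclass(frozen=True)
class ParsimonyConfig:
    """Gain/loss penalties.  The ratio P_g/P_l is what matters; the two
    standard settings are ratio 1 (balanced genomes) and ratio 2 (gains
    doubly penalized, a stricter candidate set)."""

    gain_penalty: float = 1.0
    loss_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_penalty <= 0 or self.loss_penalty <= 0:
            raise ValidationError("penalties must be positive")

    @property
    def ratio(self) -> float:
        return self.gain_penalty / self.loss_penalty

    def transition_cost(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return self.gain_penalty if child_state == 1 else self.loss_penalty


@dataclass
class EventReconstruction:
    """One minimum-cost gain/loss scenario for a single family."""

    family_id: str
    branch_events: dict[int, str]  # node id -> "gain" | "loss" (edge above node)
    total_cost: float
    ancestral_states: dict[int, int]  # node id -> 0/1
    gains_on_tips: frozenset[str] = field(default_factory=frozenset)
    n_gains: int = 0
    n_losses: int = 0


def _tip_costs(node: dendropy.Node, pattern: Mapping[str, int]) -> tuple[float, float]:
    label = node.taxon.label
    if label not in pattern:
        raise ValidationError(f"tip {label!r} missing from the phyletic pattern")
    state = pattern[label]
    if state not in (0, 1):
        raise ValidationError(f"tip state for {label!r} must be 0/1, got {state!r}")
    return (0.0, _INF) if state == 0 else (_INF, 0.0)


def _sankoff_tables(
    tree: Phylogeny, pattern: Mapping[str, int], config: ParsimonyConfig
) -> dict[int, tuple[float, float]]:
    """Bottom-up cost tables: cost[node][s] = min cost of the subtree below
    node given that node has state s."""
    costs: dict[int, tuple[float, float]] = {}
    pg, pl = config.gain_penalty, config.loss_penalty
    for node in tree.postorder():
        if node.is_leaf():
            costs[id(node)] = _tip_costs(node, pattern)
            continue
        c0 = c1 = 0.0
        for child in node.child_nodes():
            k0, k1 = costs[id(child)]
            c0 += min(k0, k1 + pg)  # parent 0: child 1 is a gain
            c1 += min(k1, k0 + pl)  # parent 1: child 0 is a loss
        costs[id(node)] = (c0, c1)
    return costs


def sankoff_min_cost(
    tree: Phylogeny, pattern: Mapping[str, int], config: ParsimonyConfig
) -> float:
    """Minimum total event cost over all ancestral-state assignments.

    Both root states are available at zero cost (no gain is charged for
    presence at the root).
    """
    costs = _sankoff_tables(tree, pattern, config)
    return min(costs[id(tree.root)])


def reconstruct_deltran(
    tree: Phylogeny, pattern: Mapping[str, int], config: ParsimonyConfig,
    family_id: str = "",
) -> EventReconstruction:
    """A minimum-cost reconstruction with changes delayed toward the tips.

    Top-down pass over the Sankoff tables: the root takes its cheaper state
    (ties -> absent, so presence is explained by tipward gains); every other
    node takes the state minimizing its own table cost plus the transition
    from its (already fixed) parent, with ties resolved to the parent's state.
    """
    costs = _sankoff_tables(tree, pattern, config)
    states: dict[int, int] = {}
    events: dict[int, str] = {}
    root = tree.root
    r0, r1 = costs[id(root)]
    states[id(root)] = 0 if r0 <= r1 else 1
    for node in tree.preorder():
        if node is root:
            continue
        parent_state = states[id(node.parent_node)]
        k0, k1 = costs[id(node)]
        cost_if_0 = k0 + config.transition_cost(parent_state, 0)
        cost_if_1 = k1 + config.transition_cost(parent_state, 1)
        if cost_if_0 < cost_if_1:
            state = 0
        elif cost_if_1 < cost_if_0:
            state = 1
        else:
            state = parent_state  # delay the change tipward
        states[id(node)] = state
        if state != parent_state:
            events[id(node)] = "gain" if state == 1 else "loss"
    n_gains = sum(1 for e in events.values() if e == "gain")
    n_losses = len(events) - n_gains
    total = n_gains * config.gain_penalty + n_losses * config.loss_penalty
    gains_on_tips = frozenset(
        node.taxon.label
        for node in tree.tree.leaf_node_iter()
        if events.get(id(node)) == "gain"
    )
    return EventReconstruction(
        family_id=family_id,
        branch_events=events,
        total_cost=total,
        ancestral_states=states,
        gains_on_tips=gains_on_tips,
        n_gains=n_gains,
        n_losses=n_losses,
    )


def terminal_hgt_candidates(
    matrix: PhyleticMatrix,
    tree: Phylogeny,
    config: ParsimonyConfig,
    name: str | None = None,
    orders: list[GenomeGeneOrder] | None = None,
) -> HGTCandidateSet:
    """Label genes gained on terminal branches as HGT candidates.

    For every family the DELTRAN reconstruction is computed; a gain on the
    terminal branch of tip genome G adds the family's mapped gene in G to
    the candidate set.  Singleton families (present in exactly one genome,
    i.e. no orthologs elsewhere) are conservatively never candidates, and
    genes on plasmid replicons are excluded when gene orders are supplied.
    """
    missing = set(matrix.genomes) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"matrix genomes absent from the tree: {sorted(missing)}")
    excluded_genes: dict[str, set[str]] = {}
    if orders is not None:
        for order in orders:
            bucket = excluded_genes.setdefault(order.genome_id, set())
            if order.is_plasmid:
                bucket.update(order.genes)
            else:
                bucket.update(
                    g for g, e in zip(order.genes, order.examined) if not e
                )
    candidates: dict[str, set[str]] = {g: set() for g in matrix.genomes}
    full_pattern = {label: 0 for label in tree.tip_labels}
    for family in matrix.families:
        if matrix.is_singleton(family):
            continue
        pattern = dict(full_pattern)
        pattern.update(matrix.pattern(family))
        recon = reconstruct_deltran(tree, pattern, config, family_id=family)
        for genome in recon.gains_on_tips:
            if genome not in candidates:
                continue  # tip outside the matrix columns
            gene = matrix.gene_for(family, genome)
            if gene is None:
                raise ValidationError(
                    f"family {family!r} present in {genome!r} but has no gene mapping"
                )
            if gene in excluded_genes.get(genome, ()):
                continue
            candidates[genome].add(gene)
    ratio = config.ratio
    return HGTCandidateSet(
        name=name or f"terminal.pen{ratio:g}",
        candidates={g: frozenset(s) for g, s in candidates.items()},
        penalty_ratio=ratio,
    )


def compare_candidate_sets(a: HGTCandidateSet, b: HGTCandidateSet) -> dict:
    """Overlap summary between two candidate sets over the same genomes."""
    if a.genomes != b.genomes:
        raise ValidationError(
            "candidate sets cover different genome universes: "
            f"{sorted(a.genomes ^ b.genomes)}"
        )
    per_genome = {}
    for genome in sorted(a.genomes):
        sa, sb = a.candidates[genome], b.candidates[genome]
        per_genome[genome] = {
            "a": len(sa),
            "b": len(sb),
            "intersection": len(sa & sb),
            "a_only": len(sa - sb),
            "b_only": len(sb - sa),
        }
    totals = {
        key: sum(g[key] for g in per_genome.values())
        for key in ("a", "b", "intersection", "a_only", "b_only")
    }
    totals["union"] = totals["a"] + totals["b"] - totals["intersection"]
    return {"per_genome": per_genome, "total": totals}
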