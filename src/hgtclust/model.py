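"""Shared domain types for the HGT-clustering pipeline.

The pipeline connects four kinds of data: ordered gene lists per replicon,
a gene-family presence/absence matrix over the tips of a rooted phylogeny,
per-genome sets of HGT candidate genes, and a metabolic coupling network.
Each container validates its own invariants at construction time so that
downstream statistics can assume clean inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "ValidationError",
    "GenomeGeneOrder",
    "PhyleticMatrix",
    "Phylogeny",
    "HGTCandidateSet",
    "CouplingNetwork",
    "ClusteringResult",
    "clustering_score",
]


class ValidationError(ValueError):
    """An input violates a documented invariant of the pipeline."""


@dataclass(frozen=True)
class GenomeGeneOrder:
    """The ordered genes of one replicon of one genome.

    Positions are 0-based contiguous indices along the replicon.  ``examined``
    marks genes that belong to a cross-genome orthologous family; genes with
    no ortholog anywhere in the dataset ("singletons") carry ``False`` and are
    never HGT candidates, but they still occupy positions and therefore create
    gaps between examined genes.
    """

    genome_id: str
    replicon_id: str
    genes: tuple[str, ...]
    examined: tuple[bool, ...] = ()
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        if not self.examined:
            object.__setattr__(self, "examined", tuple(True for _ in self.genes))
        if len(self.examined) != len(self.genes):
            raise ValidationError(
                f"replicon {self.replicon_id!r}: examined flags ({len(self.examined)}) "
                f"do not match gene count ({len(self.genes)})"
            )
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValidationError(
                f"duplicate gene id {dup!r} on replicon {self.replicon_id!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_examined(self) -> int:
        return sum(self.examined)

    @property
    def examined_genes(self) -> frozenset[str]:
        return frozenset(g for g, e in zip(self.genes, self.examined) if e)

    def position_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ValidationError(
                f"gene {gene!r} not on replicon {self.replicon_id!r}"
            ) from None


class PhyleticMatrix:
    """Presence/absence (0/1) of gene families across genomes.

    Wraps a pandas DataFrame (families as rows, genomes as columns) plus an
    optional map from (family, genome) to the concrete gene identifier that
    represents the family in that genome's gene order.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        family_to_gene: Mapping[tuple[str, str], str] | None = None,
        singleton_families: Iterable[str] = (),
    ) -> None:
        values = presence.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            bad = values[(values != 0) & (values != 1)].flat[0]
            raise ValidationError(f"matrix entries must be 0/1, found {bad!r}")
        self.presence = presence.astype("int8")
        self.family_to_gene = dict(family_to_gene or {})
        self.singleton_families = frozenset(singleton_families)
        for (fam, genome), gene in self.family_to_gene.items():
            if fam in self.presence.index and genome in self.presence.columns:
                if self.presence.at[fam, genome] == 0:
                    raise ValidationError(
                        f"family {fam!r} mapped to gene {gene!r} in {genome!r} "
                        "but is marked absent there"
                    )

    @property
    def families(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.columns)

    def pattern(self, family: str) -> dict[str, int]:
        """Phyletic pattern of one family: genome -> 0/1."""
        return self.presence.loc[family].to_dict()

    def is_singleton(self, family: str) -> bool:
        """Whether the family is flagged as a singleton (a gene with no
        detected ortholog anywhere in the dataset).

        Singleton status is an explicit annotation, not inferred from the
        presence pattern: a family can legitimately be present in a single
        genome of the matrix yet have orthology support.
        """
        return family in self.singleton_families

    def gene_for(self, family: str, genome: str) -> str | None:
        return self.family_to_gene.get((family, genome))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyleticMatrix):
            return NotImplemented
        return (
            self.presence.equals(other.presence)
            and self.family_to_gene == other.family_to_gene
            and self.singleton_families == other.singleton_families
        )


class Phylogeny:
    """A rooted phylogeny whose tips are genome identifiers.

    Thin wrapper around a dendropy Tree providing the traversals and branch
    classification (terminal vs internal) the parsimony module needs.
    Unrooted trees are rejected: with asymmetric gain/loss penalties the
    position of the root is material to the reconstruction.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        if tree.is_rooted is False:
            raise ValidationError("tree is unrooted; gain/loss inference needs a root")
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValidationError(f"duplicate tip label {dup!r}")
        self.tree = tree
        self.tip_labels = labels

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="default-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Duplicate" in str(exc) or "duplicate" in str(exc):
                raise ValidationError(f"duplicate tip label in tree: {exc}") from None
            raise
        return cls(tree)

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def postorder(self) -> Iterable[dendropy.Node]:
        return self.tree.postorder_node_iter()

    def preorder(self) -> Iterable[dendropy.Node]:
        return self.tree.preorder_node_iter()

    @staticmethod
    def node_label(node: dendropy.Node) -> str | None:
        return node.taxon.label if node.taxon is not None else None


@dataclass(frozen=True)
class HGTCandidateSet:
    """Per-genome sets of genes called as terminal-branch transfers."""

    name: str
    candidates: Mapping[str, frozenset[str]]
    penalty_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.penalty_ratio <= 0:
            raise ValidationError("penalty_ratio must be positive")
        object.__setattr__(
            self,
            "candidates",
            {g: frozenset(s) for g, s in self.candidates.items()},
        )

    def size(self, genome: str | None = None) -> int:
        if genome is not None:
            return len(self.candidates.get(genome, frozenset()))
        return sum(len(s) for s in self.candidates.values())

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(self.candidates)


class CouplingNetwork:
    """Gene node universe plus fully-coupled (undirected, simple) gene pairs.

    Stores ``n`` (universe size), ``L1`` (number of coupled pairs) and exposes
    p1 = L1 / (n*(n-1)/2), the a-priori probability that a random gene pair is
    coupled.
    """

    def __init__(self, node_universe: Iterable[str], coupled_pairs: Iterable[tuple[str, str]]) -> None:
        self.node_universe = frozenset(node_universe)
        pairs: set[frozenset[str]] = set()
        for a, b in coupled_pairs:
            if a == b:
                raise ValidationError(f"self-pair ({a!r}, {b!r}) not allowed")
            for gene in (a, b):
                if gene not in self.node_universe:
                    raise ValidationError(
                        f"gene {gene!r} in a coupled pair is not in the node universe"
                    )
            pairs.add(frozenset((a, b)))
        self.coupled_pairs = frozenset(pairs)

    @property
    def n(self) -> int:
        return len(self.node_universe)

    @property
    def L1(self) -> int:
        return len(self.coupled_pairs)

    @property
    def p1(self) -> float:
        total = self.n * (self.n - 1) / 2
        if total == 0:
            raise ValidationError("node universe must contain at least 2 genes")
        return self.L1 / total


@dataclass(frozen=True)
class ClusteringResult:
    """Observed count, null expectation, clustering score CC and permutation p.

    CC = observed / expected; CC >> 1 indicates clustering.  The permutation
    p-value is (r+1)/(R+1), so its smallest attainable value is 1/(R+1).
    ``cc`` is NaN when both observed and expected are 0 and +inf when a
    positive count meets a zero expectation.
    """

    name: str
    statistic: str
    observed: int
    expected: float
    cc: float
    p_value: float
    n_randomizations: int
    seed: int
    n_candidates: int = 0

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValidationError("counts and expectations are non-negative")
        if self.n_randomizations < 1:
            raise ValidationError("n_randomizations must be >= 1")
        lo = 1.0 / (self.n_randomizations + 1)
        if not (lo - 1e-12 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(
                f"p-value {self.p_value} outside [{lo}, 1] for R={self.n_randomizations}"
            )
        if self.expected > 0:
            ratio = self.observed / self.expected
            if not math.isclose(ratio, self.cc, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError("cc must equal observed/expected when expected > 0")


def clustering_score(observed: float, expected: float) -> float:
    """CC = observed / expected, with the degenerate cases made explicit.

    Returns NaN when observed and expected are both zero (no information) and
    +inf when observed > 0 but expected == 0.
    """
    if expected > 0:
        return observed / expected
    return math.nan if observed == 0 else math.inf
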