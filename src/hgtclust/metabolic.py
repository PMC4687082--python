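"""Metabolic (flux-coupling) clustering of HGT candidates.

Two genes are metabolic neighbours when their reactions are fully coupled:
any flux through one enforces a proportional flux through the other.  The
coupled-pair list is consumed as a precomputed undirected simple graph whose
topology stays fixed throughout.  With n genes in the node universe and L1
coupled pairs, a random pair is coupled with probability
p1 = L1 / (n(n-1)/2); a candidate set of n2 genes therefore contains
p1 * n2(n2-1)/2 coupled pairs in expectation under the null that coupling
and HGT status are unrelated.  Permutations redraw n2 genes uniformly from
the node universe and recount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model import (
    ClusteringResult,
    CouplingNetwork,
    ValidationError,
    clustering_score,
)

__all__ = [
    "MetabolicConfig",
    "observed_coupled_pairs",
    "expected_coupled_pairs",
    "metabolic_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetabolicConfig:
    n_randomizations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValidationError("n_randomizations must be >= 1")


def observed_coupled_pairs(network: CouplingNetwork, candidates: Iterable[str]) -> int:
    """Number of coupled pairs with both endpoints in the candidate set.

    Candidates outside the node universe are dropped (with a logged count):
    the null model only redistributes HGT status within the network.
    """
    cand = set(candidates)
    outside = cand - network.node_universe
    if outside:
        logger.info(
            "%d candidate genes outside the coupling node universe were dropped",
            len(outside),
        )
        cand -= outside
    return sum(1 for pair in network.coupled_pairs if pair <= cand)


def expected_coupled_pairs(n: int, L1: int, n2: int) -> float:
    """Null expectation p1 * n2(n2-1)/2 with p1 = L1 / (n(n-1)/2)."""
    if n < 2:
        raise ValidationError("node universe must contain at least 2 genes")
    if not (0 <= n2 <= n):
        raise ValidationError(f"n2 = {n2} outside [0, {n}]")
    max_pairs = n * (n - 1) // 2
    if not (0 <= L1 <= max_pairs):
        raise ValidationError(f"L1 = {L1} outside [0, {max_pairs}]")
    if n2 <= 1:
        return 0.0
    return (L1 / (n * (n - 1) / 2)) * (n2 * (n2 - 1) / 2)


def metabolic_analysis(
    network: CouplingNetwork,
    candidates: Iterable[str],
    config: MetabolicConfig | None = None,
    name: str = "candidates",
) -> ClusteringResult:
    """Observed vs expected coupled pairs among candidates, with a one-sided
    permutation p-value (network edges fixed, candidate count conserved)."""
    config = config or MetabolicConfig()
    if network.n == 0:
        raise ValidationError("empty coupling network")
    cand = set(candidates) & network.node_universe
    n2 = len(cand)
    observed = observed_coupled_pairs(network, cand)
    expected = expected_coupled_pairs(network.n, network.L1, n2)

    nodes = sorted(network.node_universe)
    index = {g: i for i, g in enumerate(nodes)}
    pairs = np.array(
        [[index[a], index[b]] for a, b in (tuple(p) for p in network.coupled_pairs)],
        dtype=np.int64,
    ).reshape(-1, 2)

    R = config.n_randomizations
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, len(nodes), n2]))
    member = np.zeros((R, len(nodes)), dtype=bool)
    if n2:
        picks = rng.random((R, len(nodes))).argsort(axis=1)[:, :n2]
        np.put_along_axis(member, picks, True, axis=1)
    if pairs.size:
        null_counts = (member[:, pairs[:, 0]] & member[:, pairs[:, 1]]).sum(axis=1)
    else:
        null_counts = np.zeros(R, dtype=np.int64)
    r = int((null_counts >= observed).sum())
    p_value = (r + 1) / (R + 1)
    return ClusteringResult(
        name=name,
        statistic="metabolic",
        observed=observed,
        expected=expected,
        cc=clustering_score(observed, expected),
        p_value=p_value,
        n_randomizations=R,
        seed=config.seed,
        n_candidates=n2,
    )
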