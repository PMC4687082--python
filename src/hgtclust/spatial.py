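"""Spatial (genome-neighbourhood) clustering of HGT candidates.

The statistic is Count_G: the number of genes that are HGT candidates and
have at least one further candidate among their next ``w`` right-hand
neighbours along the replicon (default w = 3, i.e. at most two intervening
genes — within the length of most E. coli operons).  Under the null of no
spatial association the expectation has a closed form; significance comes
from permutations that redistribute each genome's candidate count uniformly
over its gene positions.

Two gap conventions are provided.  ``gap_mode="conservative"`` computes the
expectation (and the permutation null) as if the examined genes were
arranged contiguously, ignoring the gaps that singletons introduce; because
observed counts *are* affected by those gaps, this convention biases the
expectation upward and understates clustering.  ``gap_mode="exact"`` places
permuted candidates on the true examined positions within the full gene
order and takes the simulation mean as the expectation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    ClusteringResult,
    GenomeGeneOrder,
    HGTCandidateSet,
    ValidationError,
    clustering_score,
)

__all__ = [
    "SpatialConfig",
    "count_neighbour_pairs",
    "expected_neighbour_pairs",
    "observed_pairs_for_genome",
    "spatial_analysis",
]


@dataclass(frozen=True)
class SpatialConfig:
    """Knobs of the spatial statistic.

    window
        How far right a neighbouring candidate may sit (w = 3 means at most
        2 intervening genes).
    topology
        "linear" matches the closed-form expectation; "circular" wraps the
        window around the replicon end.
    gap_mode
        "conservative" (closed-form expectation on contiguous
        examined genes, understates clustering) or "exact" (simulation-based,
        gaps respected).
    """

    window: int = 3
    topology: str = "linear"
    gap_mode: str = "conservative"
    n_randomizations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if self.gap_mode not in ("conservative", "exact"):
            raise ValidationError(f"unknown gap_mode {self.gap_mode!r}")
        if self.n_randomizations < 1:
            raise ValidationError("n_randomizations must be >= 1")


def _count_rows(flags: np.ndarray, w: int, circular: bool) -> np.ndarray:
    """Count_G for each row of a (R, n) 0/1 matrix, vectorized."""
    R, n = flags.shape
    if n == 0:
        return np.zeros(R, dtype=np.int64)
    boolean = flags.astype(bool)
    if circular:
        reps = 1 + -(-w // n)  # enough copies for a window that wraps w positions
        ext = np.tile(boolean, reps)[:, : n + w]
    else:
        ext = np.pad(boolean, ((0, 0), (0, w)))
    neighbour = np.zeros_like(boolean)
    for d in range(1, w + 1):
        neighbour |= ext[:, d : d + n]
    return (boolean & neighbour).sum(axis=1).astype(np.int64)


def count_neighbour_pairs(
    flags: Sequence[int], window: int = 3, topology: str = "linear"
) -> int:
    """Count genes with flag 1 whose next ``window`` right-hand neighbours
    include another flag-1 gene.

    In linear topology, positions beyond the sequence end contribute
    nothing; in circular topology the window wraps around.
    """
    arr = np.asarray(list(flags))
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][0]
        raise ValidationError(f"flags must be 0/1, found {bad!r}")
    return int(_count_rows(arr.reshape(1, -1), window, topology == "circular")[0])


def expected_neighbour_pairs(
    n: int, c: int, window: int = 3, topology: str = "linear"
) -> float:
    """Closed-form E(Count_G) when c of n positions are candidates uniformly
    at random (without replacement).

    Summing over the distance d to the nearest right-hand candidate,

        E = sum_{d=1..w} (#positions with a window reaching >= d)
            * P(gene is a candidate)
            * P(next d-1 genes are not) * P(gene at distance d is)

    which for w = 3 in linear topology is the three-term expression

        (n-1) c/n (c-1)/(n-1)
        + (n-2) c/n (n-c)/(n-1) (c-1)/(n-2)
        + (n-3) c/n (n-c)/(n-1) (n-c-1)/(n-2) (c-1)/(n-3).

    Circular topology replaces the position counts (n-d) by n.  Returns 0
    when c <= 1; for n <= window the sum truncates at d = n-1.
    """
    if c > n:
        raise ValidationError(f"c = {c} exceeds n = {n}")
    if c < 0 or n < 0:
        raise ValidationError("n and c must be non-negative")
    if c <= 1 or n <= 1:
        return 0.0
    total = 0.0
    for d in range(1, min(window, n - 1) + 1):
        prod = 1.0
        for j in range(1, d):
            prod *= (n - c - j + 1) / (n - j)
        if prod <= 0.0:
            break  # no non-candidate left to intervene
        positions = n if topology == "circular" else (n - d)
        total += positions * (c / n) * prod * (c - 1) / (n - d)
    return total


def observed_pairs_for_genome(
    order: GenomeGeneOrder, candidates: Iterable[str], config: SpatialConfig
) -> int:
    """Count_G on one replicon's full gene order.

    Non-candidate genes — including singletons and other unexamined genes —
    carry flag 0 but occupy positions, so they act as intervening genes.
    """
    cand = set(candidates)
    examined = order.examined_genes
    on_replicon = cand & set(order.genes)
    not_examined = on_replicon - examined
    if not_examined:
        raise ValidationError(
            f"candidates {sorted(not_examined)} on replicon {order.replicon_id!r} "
            "are not examined genes"
        )
    flags = [1 if g in cand else 0 for g in order.genes]
    return count_neighbour_pairs(flags, config.window, config.topology)


def _genome_rng(seed: int, genome_id: str) -> np.random.Generator:
    """Deterministic per-genome substream, invariant to genome ordering."""
    key = zlib.crc32(genome_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _random_placements(rng: np.random.Generator, R: int, n_slots: int, c: int) -> np.ndarray:
    """(R, n_slots) boolean matrix, each row with exactly c True slots."""
    out = np.zeros((R, n_slots), dtype=bool)
    if c == 0 or n_slots == 0:
        return out
    picks = rng.random((R, n_slots)).argsort(axis=1)[:, :c]
    np.put_along_axis(out, picks, True, axis=1)
    return out


def _null_counts_for_genome(
    replicons: Sequence[GenomeGeneOrder], c: int, config: SpatialConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """R permutation-null totals of Count_G for one genome, candidate count
    conserved exactly in every randomization."""
    R = config.n_randomizations
    circular = config.topology == "circular"
    w = config.window
    if config.gap_mode == "conservative":
        # contiguous arrangement of the examined genes only
        n_slots = sum(o.n_examined for o in replicons)
        flags = _random_placements(rng, R, n_slots, c)
        return _count_rows(flags, w, circular)
    # exact: scatter over true examined positions, count with gaps
    lengths = [len(o) for o in replicons]
    offsets = np.cumsum([0] + lengths)
    slot_positions = np.concatenate(
        [
            off + np.flatnonzero(o.examined)
            for off, o in zip(offsets, replicons)
        ]
        or [np.empty(0, dtype=np.int64)]
    ).astype(np.int64)
    slots = _random_placements(rng, R, slot_positions.size, c)
    full = np.zeros((R, int(offsets[-1])), dtype=bool)
    if slot_positions.size:
        full[:, slot_positions] = slots
    totals = np.zeros(R, dtype=np.int64)
    for off, length in zip(offsets, lengths):
        totals += _count_rows(full[:, off : off + length], w, circular)
    return totals


def spatial_analysis(
    orders: Iterable[GenomeGeneOrder],
    candidates: HGTCandidateSet,
    config: SpatialConfig | None = None,
) -> ClusteringResult:
    """Aggregate observed/expected neighbour-pair counts over genomes and
    attach a one-sided permutation p-value.

    Permutations redistribute exactly each genome's candidate count within
    that genome (over the genomes present in the candidate set's universe);
    p = (r+1)/(R+1) where r counts randomizations with a total at least the
    observed total.
    """
    config = config or SpatialConfig()
    by_genome: dict[str, list[GenomeGeneOrder]] = {}
    for order in orders:
        if order.is_plasmid:
            continue
        by_genome.setdefault(order.genome_id, []).append(order)
    missing = [g for g in candidates.candidates if g not in by_genome]
    if missing:
        raise ValidationError(f"no gene orders for candidate genomes {sorted(missing)}")

    observed = 0
    expected = 0.0
    R = config.n_randomizations
    null_totals = np.zeros(R, dtype=np.int64)
    for genome in sorted(candidates.candidates):
        replicons = by_genome[genome]
        cand = candidates.candidates[genome]
        placed = set()
        for rep in replicons:
            placed |= cand & set(rep.genes)
            observed += observed_pairs_for_genome(rep, cand, config)
        lost = cand - placed
        if lost:
            raise ValidationError(
                f"candidates {sorted(lost)} not found in genome {genome!r}"
            )
        c_g = len(cand)
        rng = _genome_rng(config.seed, genome)
        nulls = _null_counts_for_genome(replicons, c_g, config, rng)
        null_totals += nulls
        if config.gap_mode == "conservative":
            n_g = sum(o.n_examined for o in replicons)
            expected += expected_neighbour_pairs(n_g, c_g, config.window, config.topology)
        else:
            expected += float(nulls.mean())

    r = int((null_totals >= observed).sum())
    p_value = (r + 1) / (R + 1)
    return ClusteringResult(
        name=candidates.name,
        statistic="spatial",
        observed=observed,
        expected=expected,
        cc=clustering_score(observed, expected),
        p_value=p_value,
        n_randomizations=R,
        seed=config.seed,
        n_candidates=candidates.size(),
    )
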