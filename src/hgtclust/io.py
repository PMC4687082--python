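"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* gene order TSV — columns ``genome_id``, ``replicon_id``, ``gene_id``,
  optional ``position``, ``is_examined`` (0/1, default 1), ``is_plasmid``
  (0/1, default 0); one row per gene, file order = gene order unless
  ``position`` is given;
* GFF3 — gene features ordered by 1-based start coordinate (ties broken by
  end, then feature id);
* phyletic matrix TSV — families as rows, genomes as columns, 0/1 entries,
  with an optional sidecar mapping (family, genome) -> gene id;
* Newick trees;
* coupled-pairs TSV plus a one-gene-per-line node-universe file;
* clustering report TSV/JSON.
"""

from __future__ import annotations

import csv
import io as _io
import json
import os
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .model import (
    ClusteringResult,
    CouplingNetwork,
    GenomeGeneOrder,
    HGTCandidateSet,
    PhyleticMatrix,
    Phylogeny,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_gene_order",
    "write_gene_order",
    "read_phyletic_matrix",
    "write_phyletic_matrix",
    "read_tree",
    "read_coupling_network",
    "write_coupling_network",
    "read_candidate_sets",
    "write_candidate_set",
    "write_report",
    "read_report",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# gene orders


def _read_gene_order_tsv(path: str) -> list[GenomeGeneOrder]:
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = {"genome_id", "replicon_id", "gene_id"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(k) in (None, "") for k in required):
                raise ParseError(f"{path}:{lineno}: incomplete gene-order row")
            try:
                rows.append(
                    {
                        "genome_id": row["genome_id"],
                        "replicon_id": row["replicon_id"],
                        "gene_id": row["gene_id"],
                        "position": float(row["position"]) if row.get("position") else None,
                        "is_examined": bool(int(row.get("is_examined") or 1)),
                        "is_plasmid": bool(int(row.get("is_plasmid") or 0)),
                    }
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    orders: list[GenomeGeneOrder] = []
    df = pd.DataFrame(rows)
    if df.empty:
        return []
    for (genome, replicon), grp in df.groupby(["genome_id", "replicon_id"], sort=False):
        if grp["position"].notna().all():
            grp = grp.sort_values("position", kind="stable")
        orders.append(
            GenomeGeneOrder(
                genome_id=genome,
                replicon_id=replicon,
                genes=tuple(grp["gene_id"]),
                examined=tuple(grp["is_examined"]),
                is_plasmid=bool(grp["is_plasmid"].any()),
            )
        )
    return orders


def _read_gene_order_gff3(path: str) -> list[GenomeGeneOrder]:
    import gffutils

    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils reports the offending line itself
        raise ParseError(f"{path}: {exc}") from exc
    per_replicon: dict[str, list[tuple[int, int, str]]] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        per_replicon.setdefault(feat.seqid, []).append((feat.start, feat.end, gene_id))
    genome = os.path.splitext(os.path.basename(path))[0]
    orders = []
    for replicon, feats in sorted(per_replicon.items()):
        feats.sort()  # by start, then end, then id: deterministic
        orders.append(
            GenomeGeneOrder(
                genome_id=genome,
                replicon_id=replicon,
                genes=tuple(g for _, _, g in feats),
            )
        )
    return orders


def read_gene_order(
    path: str, format_name: str = "tsv", exclude_plasmids: bool = False
) -> list[GenomeGeneOrder]:
    """Read per-replicon gene orders from a TSV table or a GFF3 file.

    Within a replicon, genes are ordered by start coordinate (GFF3) or by the
    optional ``position`` column / file order (TSV).  With ``exclude_plasmids``
    set, replicons flagged as plasmids are dropped.
    """
    if format_name == "tsv":
        orders = _read_gene_order_tsv(path)
    elif format_name == "gff3":
        orders = _read_gene_order_gff3(path)
    else:
        raise ValidationError(f"unknown gene-order format {format_name!r}")
    if exclude_plasmids:
        orders = [o for o in orders if not o.is_plasmid]
    return orders


def write_gene_order(orders: Iterable[GenomeGeneOrder], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["genome_id", "replicon_id", "gene_id", "position", "is_examined", "is_plasmid"]
        )
        for order in orders:
            for pos, (gene, exam) in enumerate(zip(order.genes, order.examined)):
                writer.writerow(
                    [order.genome_id, order.replicon_id, gene, pos,
                     int(exam), int(order.is_plasmid)]
                )


# ---------------------------------------------------------------------------
# phyletic matrix


def read_phyletic_matrix(path: str, family_to_gene_path: str | None = None) -> PhyleticMatrix:
    """Read a families-by-genomes 0/1 TSV, with an optional gene-map sidecar."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_cols:
                raise ParseError(f"{path}:{lineno}: ragged row ({n_cols} columns expected)")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.astype("int64")
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric matrix entry ({exc})") from None
    mapping = {}
    if family_to_gene_path is not None:
        side = pd.read_csv(family_to_gene_path, sep="\t", dtype=str)
        for col in ("family_id", "genome_id", "gene_id"):
            if col not in side.columns:
                raise ParseError(f"{family_to_gene_path}: missing column {col!r}")
        mapping = {
            (r.family_id, r.genome_id): r.gene_id for r in side.itertuples()
        }
    return PhyleticMatrix(df, mapping)


def write_phyletic_matrix(matrix: PhyleticMatrix, path: str,
                          family_to_gene_path: str | None = None) -> None:
    matrix.presence.to_csv(path, sep="\t", index_label="family_id")
    if family_to_gene_path is not None:
        with open(family_to_gene_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["family_id", "genome_id", "gene_id"])
            for (fam, genome), gene in sorted(matrix.family_to_gene.items()):
                writer.writerow([fam, genome, gene])


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str) -> Phylogeny:
    """Read a rooted Newick tree; tip labels are preserved verbatim."""
    try:
        tree = dendropy.Tree.get(
            path=path, schema="newick", rooting="default-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "uplicate" in str(exc):
            raise ValidationError(f"{path}: duplicate tip label ({exc})") from None
        raise ParseError(f"{path}: {exc}") from exc
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# coupling network


def read_coupling_network(pairs_path: str, universe_path: str) -> CouplingNetwork:
    """Read coupled gene pairs (TSV: gene_a, gene_b) and the node universe.

    Pairs are deduplicated as unordered; self-pairs and pairs naming genes
    outside the universe raise a validation error.
    """
    with open(universe_path) as fh:
        universe = [line.strip() for line in fh if line.strip()]
    pairs: list[tuple[str, str]] = []
    with open(pairs_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0] in ("gene_a", "gene_id_a")):
                continue
            if len(row) < 2:
                raise ParseError(f"{pairs_path}:{lineno}: expected two gene columns")
            pairs.append((row[0], row[1]))
    return CouplingNetwork(universe, pairs)


def write_coupling_network(network: CouplingNetwork, pairs_path: str, universe_path: str) -> None:
    with open(universe_path, "w") as fh:
        for gene in sorted(network.node_universe):
            fh.write(gene + "\n")
    with open(pairs_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_a", "gene_b"])
        for pair in sorted(tuple(sorted(p)) for p in network.coupled_pairs):
            writer.writerow(pair)


# ---------------------------------------------------------------------------
# candidate sets


def read_candidate_sets(path: str) -> list[HGTCandidateSet]:
    """Read candidate sets (TSV: set_name, genome_id, gene_id, penalty_ratio)."""
    df = pd.read_csv(path, sep="\t", dtype={"set_name": str, "genome_id": str, "gene_id": str})
    for col in ("set_name", "genome_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    sets = []
    for name, grp in df.groupby("set_name", sort=False):
        ratio = float(grp["penalty_ratio"].iloc[0]) if "penalty_ratio" in grp else 1.0
        cands = {
            genome: frozenset(sub["gene_id"])
            for genome, sub in grp.groupby("genome_id", sort=False)
        }
        sets.append(HGTCandidateSet(name=str(name), candidates=cands, penalty_ratio=ratio))
    return sets


def write_candidate_set(cset: HGTCandidateSet, path: str, append: bool = False) -> None:
    mode = "a" if append else "w"
    write_header = not (append and os.path.exists(path) and os.path.getsize(path) > 0)
    with open(path, mode, newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        if write_header:
            writer.writerow(["set_name", "genome_id", "gene_id", "penalty_ratio"])
        for genome in sorted(cset.candidates):
            for gene in sorted(cset.candidates[genome]):
                writer.writerow([cset.name, genome, gene, cset.penalty_ratio])


# ---------------------------------------------------------------------------
# reports

_REPORT_FIELDS = [
    "name", "statistic", "n_candidates", "observed", "expected",
    "cc", "p_value", "n_randomizations", "seed",
]


def write_report(results: Sequence[ClusteringResult], path: str, format_name: str = "tsv") -> None:
    """Write one record per clustering result, numbers at full precision."""
    if format_name == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(_REPORT_FIELDS)
            for res in results:
                writer.writerow([repr(v) if isinstance(v, float) else v
                                 for v in (getattr(res, f) for f in _REPORT_FIELDS)])
    elif format_name == "json":
        payload = [{f: getattr(res, f) for f in _REPORT_FIELDS} for res in results]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {format_name!r}")


def read_report(path: str, format_name: str = "tsv") -> list[ClusteringResult]:
    if format_name == "json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh, delimiter="\t"))
    results = []
    for rec in records:
        results.append(
            ClusteringResult(
                name=str(rec["name"]),
                statistic=str(rec["statistic"]),
                n_candidates=int(rec["n_candidates"]),
                observed=int(rec["observed"]),
                expected=float(rec["expected"]),
                cc=float(rec["cc"]),
                p_value=float(rec["p_value"]),
                n_randomizations=int(rec["n_randomizations"]),
                seed=int(rec["seed"]),
            )
        )
    return results
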