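"""Readers and writers for the pipeline's external formats.

Expression matrices, hit tables and annotation tables travel as
tab-separated UTF-8 text ("." marks an empty optional field), gene
models as GFF3, the gene ontology as OBO (``is_a`` edges only), and
merge maps / planted truth / manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import obonet
import pandas as pd

from .core import (
    TIME_POINTS,
    DomainHit,
    FormatError,
    LocusRecord,
)
from .enrichment import GoDag

# ---------------------------------------------------------------------------
# expression matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a loci x time-point FPKM matrix from TSV.

    The first column holds locus identifiers; the header names the time
    points. Columns are reordered to the canonical time-point order.

    Raises
    ------
    FormatError
        on negative values, duplicate locus ids, or a missing canonical
        column; the message names the offending cell or column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    missing = [tp for tp in TIME_POINTS if tp not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing canonical time-point column(s) {missing}")
    df = df[list(TIME_POINTS)]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate locus id {dup[0]!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value at locus {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative value {values[r, c]} at locus {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    df.index.name = "locus_id"
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    # %.17g preserves float64 exactly across the write/read round trip
    matrix.to_csv(path, sep="\t", index_label="locus_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# gene models (GFF3)


def read_gene_models(path: str | Path) -> dict[str, LocusRecord]:
    """Read gene features from GFF3 into coordinate-only locus records.

    Scaffold lengths are taken from ``##sequence-region`` pragmas; a gene
    extending past its declared scaffold length is a format error.
    """
    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    scaffold_lengths: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            fields = directive.split()
            if len(fields) != 4:
                raise FormatError(f"{path}: malformed pragma '##{directive}'")
            scaffold_lengths[fields[1]] = int(fields[3])
    records: dict[str, LocusRecord] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.seqid not in scaffold_lengths:
            raise FormatError(
                f"{path}: gene {feat.id!r} on undeclared scaffold {feat.seqid!r}"
            )
        length = scaffold_lengths[feat.seqid]
        if feat.end > length:
            raise FormatError(
                f"{path}: gene {feat.id!r} ends at {feat.end} beyond scaffold "
                f"{feat.seqid!r} length {length}"
            )
        records[feat.id] = LocusRecord(
            locus_id=feat.id,
            scaffold_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            scaffold_length=length,
            strand=feat.strand or "+",
        )
    return records


def _prevalidate_gff3(path: Path) -> None:
    """Cheap structural check so errors can name the offending line."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end < start or start < 1:
                raise FormatError(
                    f"{path}: line {lineno}: invalid coordinates {start}..{end}"
                )


def write_gene_models(
    records: dict[str, LocusRecord], path: str | Path
) -> None:
    """Write coordinate records as GFF3 with ``##sequence-region`` pragmas."""
    scaffolds: dict[str, int] = {}
    for rec in records.values():
        scaffolds.setdefault(rec.scaffold_id, rec.scaffold_length)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for sid in sorted(scaffolds):
            fh.write(f"##sequence-region {sid} 1 {scaffolds[sid]}\n")
        for rec in sorted(records.values(), key=lambda r: (r.scaffold_id, r.start)):
            fh.write(
                "\t".join(
                    [
                        rec.scaffold_id,
                        "fragtx",
                        "gene",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        f"ID={rec.locus_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# annotation table

_ANN_COLUMNS = (
    "locus_id",
    "defline",
    "go_ids",
    "domain_id",
    "truncation",
    "has_start_codon",
    "localization",
)


def read_annotations(path: str | Path) -> dict[str, LocusRecord]:
    """Read the per-locus annotation table.

    One row per (locus, domain hit); loci without domains use "." in the
    domain columns. Returns annotation-only records (coordinates default;
    combine with gene models via :func:`combine_records`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    records: dict[str, LocusRecord] = {}
    hits: dict[str, list[DomainHit]] = {}
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        locus = row.locus_id
        go_ids = frozenset(
            g for g in row.go_ids.split(";") if g and g != "."
        )
        if row.has_start_codon not in ("0", "1"):
            raise FormatError(
                f"{path}: line {row_idx}: has_start_codon must be 0 or 1, "
                f"got {row.has_start_codon!r}"
            )
        if locus not in records:
            records[locus] = LocusRecord(
                locus_id=locus,
                defline="" if row.defline == "." else row.defline,
                go_ids=go_ids,
                has_start_codon=row.has_start_codon == "1",
                localization=row.localization,
            )
            hits[locus] = []
        if row.domain_id and row.domain_id != ".":
            try:
                hits[locus].append(DomainHit(row.domain_id, row.truncation))
            except FormatError as exc:
                raise FormatError(f"{path}: line {row_idx}: {exc}") from exc
    for locus, rec in records.items():
        rec.domain_hits = tuple(hits[locus])
    return records


def write_annotations(records: dict[str, LocusRecord], path: str | Path) -> None:
    rows = []
    for rec in sorted(records.values(), key=lambda r: r.locus_id):
        domain_rows = rec.domain_hits or (DomainHit(".", "none"),)
        for hit in domain_rows:
            rows.append(
                {
                    "locus_id": rec.locus_id,
                    "defline": rec.defline or ".",
                    "go_ids": ";".join(sorted(rec.go_ids)) or ".",
                    "domain_id": hit.domain_id,
                    "truncation": hit.truncation,
                    "has_start_codon": int(rec.has_start_codon),
                    "localization": rec.localization,
                }
            )
    pd.DataFrame(rows, columns=list(_ANN_COLUMNS)).to_csv(path, sep="\t", index=False)


def combine_records(
    gene_models: dict[str, LocusRecord], annotations: dict[str, LocusRecord]
) -> dict[str, LocusRecord]:
    """Merge coordinate records with annotation records per locus."""
    combined: dict[str, LocusRecord] = {}
    for locus, coords in gene_models.items():
        ann = annotations.get(locus)
        combined[locus] = LocusRecord(
            locus_id=locus,
            scaffold_id=coords.scaffold_id,
            start=coords.start,
            end=coords.end,
            scaffold_length=coords.scaffold_length,
            strand=coords.strand,
            has_start_codon=ann.has_start_codon if ann else True,
            defline=ann.defline if ann else "",
            go_ids=ann.go_ids if ann else frozenset(),
            domain_hits=ann.domain_hits if ann else (),
            localization=ann.localization if ann else "NA",
        )
    return combined


# ---------------------------------------------------------------------------
# gene ontology (OBO)


def read_obo(path: str | Path) -> GoDag:
    """Read an OBO ontology keeping only ``is_a`` edges.

    Raises
    ------
    FormatError
        if an ``is_a`` parent is undefined or the ``is_a`` graph is cyclic.
    """
    graph = obonet.read_obo(str(path))
    terms: dict[str, tuple[str, str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for node, data in graph.nodes(data=True):
        for parent in data.get("is_a", []):
            parent_id = parent.split("!")[0].strip()
            if parent_id not in terms:
                raise FormatError(
                    f"{path}: term {node} has undefined is_a parent {parent_id}"
                )
            parents[node].add(parent_id)
    try:
        return GoDag(terms=terms, parents=parents)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_obo(dag: GoDag, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: fragtx-synthetic\n\n")
        for term_id in sorted(dag.terms):
            name, namespace = dag.terms[term_id]
            fh.write("[Term]\n")
            fh.write(f"id: {term_id}\n")
            fh.write(f"name: {name}\n")
            if namespace:
                fh.write(f"namespace: {namespace}\n")
            for parent in sorted(dag.parents[term_id]):
                fh.write(f"is_a: {parent} ! {dag.terms[parent][0]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# homology hit tables

_HIT_COLUMNS = ("qseqid", "sseqid", "evalue", "bitscore")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a tabular (outfmt-6 style) homology hit table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"qseqid": str, "sseqid": str}, float_precision="round_trip"
    )
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing hit-table column(s) {missing}")
    if (df["evalue"] < 0).any():
        raise FormatError(f"{path}: negative e-value")
    return df[list(_HIT_COLUMNS)].astype({"evalue": float, "bitscore": float})


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(_HIT_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# JSON payloads


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
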