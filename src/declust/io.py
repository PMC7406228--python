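"""Readers and writers for the standard formats the pipeline touches.

All readers reject malformed files rather than silently coercing, and all
reader/writer pairs round-trip losslessly. External coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    ExpressionRecord,
    GeneAnnotation,
    GeneSet,
    GenomeSequence,
    MotifMatch,
    OperonTable,
    TSSRecord,
)

__all__ = [
    "read_gff3",
    "annotations_from_locus_tags",
    "read_genome_fasta",
    "read_expression_table",
    "write_expression_table",
    "read_operons",
    "write_operons",
    "read_tss",
    "write_tss",
    "read_gmt",
    "write_gmt",
    "read_tomtom",
    "read_statuses",
]


class FormatError(ValueError):
    """A file violates its format contract."""


def _validate_gff3_lines(path: str | Path) -> None:
    # gffutils reports parse failures without positions; do a cheap
    # column-count pass first so errors carry a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise FormatError(
                    f"{path}: malformed GFF3 line {lineno}: "
                    f"expected 9 tab-separated columns"
                )


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneAnnotation]:
    """Read gene annotations from a GFF3 file.

    One :class:`GeneAnnotation` per feature carrying a ``locus_tag``
    attribute; ordinals are assigned by ascending start position.
    Duplicate locus tags are an error.
    """
    _validate_gff3_lines(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    raw: list[tuple[str, int, int, str, str | None]] = []
    seen: set[str] = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            tags = feat.attributes.get("locus_tag")
            if not tags:
                continue
            locus = tags[0]
            if locus in seen:
                raise FormatError(f"{path}: duplicate locus_tag {locus}")
            seen.add(locus)
            product = feat.attributes.get("product", [None])[0]
            if feat.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: feature {locus} has no usable strand"
                )
            raw.append((locus, feat.start, feat.end, feat.strand, product))
    raw.sort(key=lambda r: (r[1], r[2], r[0]))
    return [
        GeneAnnotation(locus_tag=locus, start=start, end=end, strand=strand,
                       ordinal=i, product=product)
        for i, (locus, start, end, strand, product) in enumerate(raw)
    ]


_LOCUS_NUM = re.compile(r"^([A-Za-z]+)(\d+)$")


def annotations_from_locus_tags(loci: list[str]) -> list[GeneAnnotation]:
    """Fallback ordering when no GFF3 is available.

    PAO1-style locus tags (``PA0001`` ...) are numbered along the
    chromosome, so a lexicographic sort of prefix+zero-padded-number tags
    recovers chromosome order. Coordinates are synthesized as unit-width
    placeholders; strand is reported as ``+`` and must not be relied on.
    """
    parsed = []
    for locus in loci:
        m = _LOCUS_NUM.match(locus)
        if not m:
            raise FormatError(
                f"locus tag {locus!r} is not prefix+number; cannot derive order"
            )
        parsed.append((m.group(1), int(m.group(2)), locus))
    parsed.sort()
    return [
        GeneAnnotation(locus_tag=locus, start=i + 1, end=i + 1, strand="+",
                       ordinal=i)
        for i, (_, _, locus) in enumerate(parsed)
    ]


def read_genome_fasta(path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read a single-contig genome FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"{path}: expected exactly one sequence, found {len(records)}"
        )
    return GenomeSequence(sequence=str(records[0].seq).upper(), circular=circular)


def _read_table(path: str | Path) -> pd.DataFrame:
    # Accept both TSV and CSV: sniff the header line.
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, comment=None)


def read_expression_table(
    path: str | Path,
    locus_column: str | None = None,
    log2fc_column: str = "log2FoldChange",
    padj_column: str = "padj",
) -> list[ExpressionRecord]:
    """Read a DESeq2-dialect results table (TSV or CSV).

    ``locus_column=None`` takes the first column. ``NA`` adjusted-P cells
    become missing values.
    """
    df = _read_table(path)
    if locus_column is None:
        locus_column = df.columns[0]
    for col in (locus_column, log2fc_column, padj_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for idx, row in df.iterrows():
        raw_fc = row[log2fc_column]
        try:
            log2fc = float(raw_fc)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric log2 fold change {raw_fc!r} "
                f"in data row {idx + 1}"
            ) from None
        raw_p = row[padj_column]
        if pd.isna(raw_p) or str(raw_p).strip().upper() == "NA":
            p_adj = None
        else:
            try:
                p_adj = float(raw_p)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric adjusted P {raw_p!r} "
                    f"in data row {idx + 1}"
                ) from None
        records.append(ExpressionRecord(str(row[locus_column]), log2fc, p_adj))
    return records


def write_expression_table(records: list[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus_tag": [r.locus_tag for r in records],
            "log2FoldChange": [r.log2fc for r in records],
            "padj": ["NA" if r.p_adj is None else r.p_adj for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_operons(path: str | Path) -> OperonTable:
    """Read an operon table: TSV with ``operon_id`` and comma-separated
    ``members`` in transcription order (most-upstream first)."""
    df = _read_table(path)
    for col in ("operon_id", "members"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    operons = {
        str(row["operon_id"]): [m for m in str(row["members"]).split(",") if m]
        for _, row in df.iterrows()
    }
    return OperonTable(operons)


def write_operons(table: OperonTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tmembers\n")
        for op_id, members in table.operons.items():
            fh.write(f"{op_id}\t{','.join(members)}\n")


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table: TSV with locus_tag, tss_position, strand, tss_type."""
    df = _read_table(path)
    for col in ("locus_tag", "tss_position", "strand", "tss_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        TSSRecord(
            locus_tag=str(row["locus_tag"]),
            tss_position=int(row["tss_position"]),
            strand=str(row["strand"]),
            tss_type=str(row["tss_type"]),
        )
        for _, row in df.iterrows()
    ]


def write_tss(records: list[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_tag\ttss_position\tstrand\ttss_type\n")
        for r in records:
            fh.write(f"{r.locus_tag}\t{r.tss_position}\t{r.strand}\t{r.tss_type}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets: name, description, then tab-separated members.

    Duplicate members within a line are dropped with a warning; lines with
    fewer than three fields (i.e. no members) are an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line {lineno} has fewer than 3 fields"
                )
            name, source, *members = fields
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                warnings.warn(
                    f"{path}: duplicate members in set {name} deduplicated",
                    stacklevel=2,
                )
            if not unique:
                raise FormatError(
                    f"{path}: GMT line {lineno} ({name}) has no members"
                )
            sets.append(GeneSet(name=name, members=set(unique), source=source))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\t{s.source}\t{members}\n")


_TOMTOM_QUERY = ("Query_ID", "#Query ID", "Query ID", "query_id")
_TOMTOM_TARGET = ("Target_ID", "Target ID", "target_id")
_TOMTOM_Q = ("q-value", "q_value", "qvalue")


def read_tomtom(path: str | Path, q_max: float = 0.5) -> list[MotifMatch]:
    """Read TomTom output, keeping matches with q <= ``q_max`` (inclusive).

    Handles the common TomTom TSV dialects; trailing ``#`` comment lines
    are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")

    def pick(candidates: tuple[str, ...], what: str) -> str:
        for c in candidates:
            if c in df.columns:
                return c
        raise FormatError(f"{path}: missing {what} column (looked for {candidates})")

    qcol = pick(_TOMTOM_Q, "q-value")
    querycol = pick(_TOMTOM_QUERY, "query")
    targetcol = pick(_TOMTOM_TARGET, "target")
    matches = []
    for _, row in df.dropna(subset=[qcol]).iterrows():
        q = float(row[qcol])
        if q <= q_max:
            matches.append(
                MotifMatch(
                    query_motif_id=str(row[querycol]),
                    target_regulator=str(row[targetcol]),
                    q_value=q,
                )
            )
    return matches


def read_statuses(path: str | Path) -> pd.DataFrame:
    """Read a classified-status TSV (locus_tag, log2fc, p_adj, status)."""
    df = _read_table(path)
    for col in ("locus_tag", "status"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df
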