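"""Operon-aware promoter extraction.

The motif-discovery front end reduces the DE gene list to one
representative per operon (the most upstream DE member in transcription
order — operon members share a promoter, so testing each would count the
same upstream region repeatedly), resolves each representative's
transcription start (mapped TSS where available, with the antisense
strand-switch rule; start codon otherwise) and extracts a fixed-length
upstream window from the circular genome for submission to a motif finder
such as MEME.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .model import (
    GeneAnnotation,
    GeneSet,
    GenomeSequence,
    MotifMatch,
    OperonTable,
    PromoterRegion,
    TSSRecord,
    ThresholdConfig,
)

__all__ = [
    "first_in_operon_filter",
    "resolve_start",
    "extract_upstream",
    "build_promoter_regions",
    "emit_promoter_fasta",
    "candidate_regulators",
]


def first_in_operon_filter(
    de_loci: list[str],
    operons: OperonTable,
    annotations: dict[str, GeneAnnotation],
) -> list[str]:
    """Reduce a DE gene list to one representative per operon.

    For each operon containing at least one DE gene, the most upstream DE
    gene in transcription order is kept; DE genes outside any operon pass
    through. Output is deduplicated and ordered by chromosome ordinal.
    """
    de_set = set()
    for locus in de_loci:
        if locus not in annotations:
            raise ValueError(f"DE locus {locus} is not annotated")
        de_set.add(locus)

    kept: set[str] = set()
    seen_operons: set[str] = set()
    for locus in de_set:
        op_id = operons.operon_of(locus)
        if op_id is None:
            kept.add(locus)
            continue
        if op_id in seen_operons:
            continue
        seen_operons.add(op_id)
        members = operons.operons[op_id]
        for m in members:
            if m not in annotations:
                raise ValueError(
                    f"operon {op_id} member {m} missing from annotation"
                )
        kept.add(next(m for m in members if m in de_set))
    return sorted(kept, key=lambda l: annotations[l].ordinal)


def _pick_tss(
    candidates: list[TSSRecord], annotation: GeneAnnotation
) -> TSSRecord:
    # a primary TSS wins; otherwise the one nearest the annotated start
    primaries = [t for t in candidates if t.tss_type.lower() == "primary"]
    if primaries:
        candidates = primaries
    anchor = annotation.translational_start
    return min(candidates, key=lambda t: (abs(t.tss_position - anchor), t.tss_position))


def resolve_start(
    locus: str,
    tss_table: dict[str, list[TSSRecord]],
    annotations: dict[str, GeneAnnotation],
) -> tuple[int, str, str, bool]:
    """Resolve a gene's transcription start.

    Returns ``(position, strand, source, flipped)``. A mapped TSS is used
    at its own position; a TSS typed ``antisense`` switches the gene's
    strand (``flipped=True``). With no TSS on file the start codon from
    the annotation is used (left coordinate on +, right on -).
    """
    ann = annotations[locus]
    candidates = tss_table.get(locus, [])
    if candidates:
        tss = _pick_tss(candidates, ann)
        if tss.tss_type.lower() == "antisense":
            flipped_strand = "-" if ann.strand == "+" else "+"
            return tss.tss_position, flipped_strand, "tss", True
        return tss.tss_position, tss.strand, "tss", False
    return ann.translational_start, ann.strand, "start_codon", False


def extract_upstream(
    genome: GenomeSequence, position: int, strand: str, length: int
) -> str:
    """Extract ``length`` bp upstream of a 1-based start position.

    On the + strand this is positions ``[position-length, position-1]`` in
    genome orientation; on the - strand, positions
    ``[position+1, position+length]`` reverse-complemented, so the result
    always reads 5'->3' toward the start. Coordinates wrap around the
    origin on a circular genome; on a linear genome an out-of-range
    window is an error (never a silent truncation).
    """
    L = genome.length
    if not (1 <= position <= L):
        raise ValueError(f"position {position} outside genome of length {L}")
    if length >= L:
        raise ValueError(f"window of {length} bp >= genome length {L}")
    if strand == "+":
        lo, hi = position - length, position - 1  # 1-based inclusive
    elif strand == "-":
        lo, hi = position + 1, position + length
    else:
        raise ValueError(f"bad strand {strand!r}")

    if not genome.circular and (lo < 1 or hi > L):
        missing = max(1 - lo, hi - L)
        raise ValueError(
            f"upstream window [{lo}, {hi}] leaves the linear genome "
            f"(would truncate {missing} bp)"
        )
    seq = "".join(genome.sequence[(i - 1) % L] for i in range(lo, hi + 1))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def build_promoter_regions(
    loci: list[str],
    genome: GenomeSequence,
    tss_table: dict[str, list[TSSRecord]],
    annotations: dict[str, GeneAnnotation],
    cfg: ThresholdConfig,
) -> list[PromoterRegion]:
    """Resolve starts and extract upstream windows for a list of genes."""
    regions = []
    for locus in loci:
        pos, strand, source, flipped = resolve_start(locus, tss_table, annotations)
        seq = extract_upstream(genome, pos, strand, cfg.upstream_len)
        regions.append(
            PromoterRegion(
                locus_tag=locus,
                resolved_position=pos,
                resolved_strand=strand,
                source=source,
                flipped=flipped,
                sequence=seq,
            )
        )
    return regions


def emit_promoter_fasta(
    regions: list[PromoterRegion],
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write promoter regions as FASTA for external motif discovery.

    Headers carry the locus tag plus provenance (start source, strand,
    flip flag, resolved coordinate). Refuses to write an empty file.
    An optional JSON manifest records the downstream motif-search
    settings used in the original analysis (MEME: up to 5 motifs at
    E <= 0.05; TomTom: q <= 0.5) so a rerun is self-documenting.
    """
    if not regions:
        raise ValueError("no promoter regions to write")
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.locus_tag,
            description=(
                f"source={r.source} strand={r.resolved_strand} "
                f"flipped={str(r.flipped).lower()} position={r.resolved_position}"
            ),
        )
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")
    if manifest_path is not None:
        manifest = {
            "n_promoters": len(regions),
            "upstream_len": len(regions[0].sequence),
            "meme": {"max_motifs": 5, "evalue_max": 0.05},
            "tomtom": {"q_max": 0.5},
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")


def candidate_regulators(
    matches: list[MotifMatch], regulons: list[GeneSet]
) -> tuple[list[GeneSet], list[str]]:
    """Map motif matches to regulon gene sets.

    Regulator names are matched case-insensitively and deduplicated;
    matches with no regulon on file are returned in the second element
    rather than raising.
    """
    by_name = {s.name.lower(): s for s in regulons}
    mapped: list[GeneSet] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for m in matches:
        key = m.target_regulator.lower()
        if key in seen:
            continue
        seen.add(key)
        if key in by_name:
            mapped.append(by_name[key])
        else:
            unmapped.append(m.target_regulator)
    return mapped, unmapped
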