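"""Circos text-track export.

Writes the plain-text karyotype and log2-fold-change data track a Circos
installation renders into the familiar circular expression plot:
significant upregulated genes red, significant downregulated genes
green, everything else grey. Only the text tracks are produced; the
drawing itself is Circos's job.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from .model import DEStatus, ExpressionRecord, GeneAnnotation

__all__ = ["write_circos_tracks", "status_color"]

_COLORS = {
    DEStatus.UP: "red",
    DEStatus.DOWN: "green",
    DEStatus.NOT_SIGNIFICANT: "grey",
}


def status_color(status: DEStatus) -> str:
    return _COLORS[status]


def write_circos_tracks(
    annotations: list[GeneAnnotation],
    expression: list[ExpressionRecord],
    statuses: dict[str, DEStatus],
    out_dir: str | Path,
    chromosome_id: str = "chr1",
    chromosome_label: str = "chromosome",
    genome_length: int | None = None,
) -> dict[str, int]:
    """Write ``karyotype.txt`` and ``log2fc.track.txt``.

    Expression rows whose locus is absent from the annotation are skipped
    with a warning. Returns per-color row counts plus the skip count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_locus = {a.locus_tag: a for a in annotations}
    length = genome_length or (max(a.end for a in annotations) if annotations else 0)

    with open(out / "karyotype.txt", "w") as fh:
        fh.write(f"chr - {chromosome_id} {chromosome_label} 0 {length} grey\n")

    counts = {"red": 0, "green": 0, "grey": 0, "skipped": 0}
    with open(out / "log2fc.track.txt", "w") as fh:
        for rec in expression:
            ann = by_locus.get(rec.locus_tag)
            if ann is None:
                counts["skipped"] += 1
                continue
            color = _COLORS[statuses[rec.locus_tag]]
            counts[color] += 1
            fh.write(
                f"{chromosome_id} {ann.start} {ann.end} "
                f"{rec.log2fc:.6g} color={color}\n"
            )
    if counts["skipped"]:
        warnings.warn(
            f"{counts['skipped']} expression rows had no annotation and "
            "were skipped",
            stacklevel=2,
        )
    return counts
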