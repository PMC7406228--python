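"""Seeded generator of a toy bacterial transcriptome study.

Produces everything the pipeline consumes — a circular genome with tiled
gene annotations, DOOR2-style operon predictions, a TSS table with
primary and antisense sites, regulon and curated gene sets, and a
DESeq2-dialect differential-expression table — together with the ground
truth of what was planted: same-direction runs of DE genes at chosen
ordinals, and regulons whose members are DE at an elevated rate.

Determinism contract: one :class:`numpy.random.Generator` seeded from
``cfg.seed`` is threaded through the sub-generators in a fixed order
(genome, operons, TSS, regulons, curated lists, expression), so the same
config yields byte-identical output files.

Planted runs are flanked by one gene forced non-DE on each side, so each
planted run is exactly a maximal run and cluster recovery can be judged
on exact membership rather than superset membership.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .model import (
    DEStatus,
    ExpressionRecord,
    GeneAnnotation,
    GeneSet,
    GenomeSequence,
    OperonTable,
    TSSRecord,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_genome",
    "generate_operons",
    "generate_tss",
    "generate_gene_sets",
    "generate_expression",
    "generate_study",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale bacterial study: a 1,000-gene circular
    chromosome of 900-bp genes with 100-bp intergenic gaps, 40% of genes
    on the minus strand, roughly half the genome organised in operons of
    geometric mean size 3, TSS mapped for 70% of genes (10% of those
    antisense), ten regulons of 10-50 genes, and a 10% background DE
    rate. Planted runs and planted regulons default to none.
    """

    seed: int = 0
    n_genes: int = 1000
    gene_length: int = 900
    intergenic_gap: int = 100
    p_minus_strand: float = 0.4
    operon_fraction: float = 0.5
    operon_size_mean: float = 3.0
    tss_coverage: float = 0.7
    antisense_tss_fraction: float = 0.1
    n_regulons: int = 10
    regulon_size_range: tuple[int, int] = (10, 50)
    n_curated: int = 5
    curated_size_range: tuple[int, int] = (10, 50)
    background_de_rate: float = 0.1
    planted_runs: tuple[tuple[int, int, str], ...] = ()  # (start_ordinal, length, "up"/"down")
    planted_regulons: tuple[tuple[int, float], ...] = ()  # (regulon index, de_rate)
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.6
    de_log2fc_margin: float = 0.1  # |log2fc| floor above log2(1.5)

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.gene_length < 1 or self.intergenic_gap < 0:
            raise ValueError("gene geometry does not fit on the chromosome")
        for name in (
            "p_minus_strand", "operon_fraction", "tss_coverage",
            "antisense_tss_fraction", "background_de_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        # planted runs (plus a one-gene buffer each side) must fit disjointly
        occupied: set[int] = set()
        for start, length, direction in self.planted_runs:
            if direction not in ("up", "down"):
                raise ValueError(f"planted run direction {direction!r}")
            if length < 1 or length > self.n_genes - 2:
                raise ValueError("planted run does not fit on the circle")
            span = {(start + k) % self.n_genes for k in range(-1, length + 1)}
            if span & occupied:
                raise ValueError("planted runs (with buffers) overlap")
            occupied |= span
        for idx, rate in self.planted_regulons:
            if not (0 <= idx < self.n_regulons):
                raise ValueError(f"planted regulon index {idx} out of range")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"planted regulon de_rate {rate} outside [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.n_genes * (self.gene_length + self.intergenic_gap)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    true_status: dict[str, str]
    planted_clusters: list[dict]
    planted_regulon_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_status": self.true_status,
                "planted_clusters": self.planted_clusters,
                "planted_regulon_names": self.planted_regulon_names,
            },
            indent=2,
            sort_keys=True,
        )


def _locus(i: int) -> str:
    return f"SG{i + 1:04d}"


def generate_genome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Random circular sequence with genes tiled at fixed spacing."""
    seq = "".join(rng.choice(_NUCS, size=cfg.genome_length))
    strands = np.where(rng.random(cfg.n_genes) < cfg.p_minus_strand, "-", "+")
    step = cfg.gene_length + cfg.intergenic_gap
    annotations = [
        GeneAnnotation(
            locus_tag=_locus(i),
            start=i * step + 1,
            end=i * step + cfg.gene_length,
            strand=str(strands[i]),
            ordinal=i,
            product="hypothetical protein",
        )
        for i in range(cfg.n_genes)
    ]
    return GenomeSequence(sequence=seq, circular=True), annotations


def generate_operons(
    cfg: SimulationConfig,
    annotations: list[GeneAnnotation],
    rng: np.random.Generator,
) -> OperonTable:
    """Group contiguous same-strand stretches into operons.

    Walking the chromosome, each unassigned gene seeds an operon with
    probability ``operon_fraction``; the intended size is geometric with
    the configured mean, truncated at the next strand switch.
    """
    operons: dict[str, list[str]] = {}
    i = 0
    n = len(annotations)
    while i < n:
        if rng.random() >= cfg.operon_fraction:
            i += 1
            continue
        size = int(rng.geometric(1.0 / cfg.operon_size_mean))
        members = [annotations[i].locus_tag]
        j = i + 1
        while (
            j < n
            and len(members) < size
            and annotations[j].strand == annotations[i].strand
        ):
            members.append(annotations[j].locus_tag)
            j += 1
        if len(members) >= 2:
            # most-upstream first: reverse for minus-strand operons
            if annotations[i].strand == "-":
                members = members[::-1]
            operons[f"OP{len(operons) + 1:03d}"] = members
        i = j
    return OperonTable(operons)


def generate_tss(
    cfg: SimulationConfig,
    annotations: list[GeneAnnotation],
    genome: GenomeSequence,
    rng: np.random.Generator,
) -> list[TSSRecord]:
    """Assign a TSS 10-80 bp upstream to a fraction of genes.

    A sub-fraction is typed ``antisense`` and sits on the strand opposite
    the gene; the rest are ``primary`` on the gene's own strand.
    """
    records = []
    L = genome.length
    for ann in annotations:
        if rng.random() >= cfg.tss_coverage:
            continue
        offset = int(rng.integers(10, 81))
        if ann.strand == "+":
            pos = (ann.start - 1 - offset) % L + 1
        else:
            pos = (ann.end - 1 + offset) % L + 1
        antisense = rng.random() < cfg.antisense_tss_fraction
        strand = (
            ("-" if ann.strand == "+" else "+") if antisense else ann.strand
        )
        records.append(
            TSSRecord(
                locus_tag=ann.locus_tag,
                tss_position=pos,
                strand=strand,
                tss_type="antisense" if antisense else "primary",
            )
        )
    return records


def generate_gene_sets(
    cfg: SimulationConfig,
    annotations: list[GeneAnnotation],
    rng: np.random.Generator,
    n_sets: int,
    size_range: tuple[int, int],
    prefix: str,
    source: str,
) -> list[GeneSet]:
    loci = [a.locus_tag for a in annotations]
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(loci, size=min(size, len(loci)), replace=False)
        sets.append(
            GeneSet(
                name=f"{prefix}{k + 1:02d}",
                members=set(str(m) for m in members),
                source=source,
            )
        )
    return sets


def generate_expression(
    cfg: SimulationConfig,
    annotations: list[GeneAnnotation],
    regulons: list[GeneSet],
    rng: np.random.Generator,
) -> tuple[list[ExpressionRecord], GroundTruth]:
    """DESeq2-dialect results with planted runs and enriched regulons.

    Background genes are DE with probability ``background_de_rate``
    (fair-coin direction); planted-regulon members are DE at their
    elevated rate; planted-run genes are DE in the planted direction with
    probability 1, and the single gene flanking each run end is forced
    non-DE. DE genes draw |log2fc| >= log2(1.5) + margin and adjusted P
    below 0.05; non-DE genes draw adjusted P above 0.05.
    """
    n = cfg.n_genes
    ordinal_of = {a.locus_tag: a.ordinal for a in annotations}
    log2_floor = math.log2(1.5) + cfg.de_log2fc_margin

    # draw order is fixed: background, regulon planting, run planting
    direction = np.where(rng.random(n) < 0.5, 1, -1)
    status = np.where(rng.random(n) < cfg.background_de_rate, direction, 0)

    planted_regulon_names = []
    for idx, rate in cfg.planted_regulons:
        reg = regulons[idx]
        planted_regulon_names.append(reg.name)
        for locus in sorted(reg.members):
            o = ordinal_of[locus]
            status[o] = direction[o] if rng.random() < rate else 0

    planted_clusters = []
    for start, length, run_dir in cfg.planted_runs:
        sign = 1 if run_dir == "up" else -1
        members = []
        for k in range(length):
            o = (start + k) % n
            status[o] = sign
            members.append(annotations[o].locus_tag)
        status[(start - 1) % n] = 0  # flanking buffers keep the run maximal
        status[(start + length) % n] = 0
        planted_clusters.append(
            {
                "start_ordinal": int(start),
                "length": int(length),
                "direction": run_dir,
                "members": members,
            }
        )

    magnitudes = np.clip(
        rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, size=n),
        log2_floor,
        None,
    )
    null_fc = rng.normal(0.0, 0.25, size=n)
    p_de = rng.uniform(1e-8, 0.05, size=n)
    p_null = rng.uniform(0.05 + 1e-9, 1.0, size=n)

    records = []
    true_status = {}
    for a in annotations:
        o = a.ordinal
        if status[o] != 0:
            log2fc = float(status[o] * magnitudes[o])
            p_adj = float(p_de[o])
            true_status[a.locus_tag] = "up" if status[o] > 0 else "down"
        else:
            log2fc = float(null_fc[o])
            p_adj = float(p_null[o])
            true_status[a.locus_tag] = "not_significant"
        records.append(ExpressionRecord(a.locus_tag, log2fc, p_adj))

    return records, GroundTruth(
        true_status=true_status,
        planted_clusters=planted_clusters,
        planted_regulon_names=planted_regulon_names,
    )


def _write_fasta(genome: GenomeSequence, path: Path, name: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} circular={str(genome.circular).lower()}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def _write_gff3(
    annotations: list[GeneAnnotation], genome_length: int, path: Path,
    name: str = "chr1",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {genome_length}\n")
        for a in annotations:
            attrs = f"ID=gene-{a.locus_tag};locus_tag={a.locus_tag}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write(
                f"{name}\tdeclust_sim\tgene\t{a.start}\t{a.end}\t.\t"
                f"{a.strand}\t.\t{attrs}\n"
            )


def generate_study(cfg: SimulationConfig, out_dir: str | Path | None = None):
    """Generate a full synthetic study; optionally write it to disk.

    Returns ``(genome, annotations, operons, tss, regulons, curated,
    expression, truth)``. When ``out_dir`` is given, writes
    ``genome.fasta``, ``genes.gff3``, ``operons.tsv``, ``tss.tsv``,
    ``regulons.gmt``, ``curated.gmt``, ``de_results.tsv`` and
    ``truth.json`` there.
    """
    rng = np.random.default_rng(cfg.seed)
    genome, annotations = generate_genome(cfg, rng)
    operons = generate_operons(cfg, annotations, rng)
    tss = generate_tss(cfg, annotations, genome, rng)
    regulons = generate_gene_sets(
        cfg, annotations, rng, cfg.n_regulons, cfg.regulon_size_range,
        "Reg", "simulated regulon",
    )
    curated = generate_gene_sets(
        cfg, annotations, rng, cfg.n_curated, cfg.curated_size_range,
        "List", "simulated curated list",
    )
    expression, truth = generate_expression(cfg, annotations, regulons, rng)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(genome, out / "genome.fasta")
        _write_gff3(annotations, genome.length, out / "genes.gff3")
        dio.write_operons(operons, out / "operons.tsv")
        dio.write_tss(tss, out / "tss.tsv")
        dio.write_gmt(regulons, out / "regulons.gmt")
        dio.write_gmt(curated, out / "curated.gmt")
        dio.write_expression_table(expression, out / "de_results.tsv")
        (out / "truth.json").write_text(truth.to_json() + "\n")

    return genome, annotations, operons, tss, regulons, curated, expression, truth
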