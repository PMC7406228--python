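"""Domain types shared across the pipeline.

The pipeline operates on a single circular bacterial chromosome. Genes are
identified by locus tag (e.g. ``PA1249``) and carry an *ordinal* — their
0-based index in chromosome order — which is the coordinate system the
cluster scan works in. External files use 1-based inclusive coordinates
(the GFF3 convention); any shift to 0-based half-open happens inside the
readers and sequence-extraction code, never here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class DEStatus(enum.Enum):
    """Per-gene differential-expression call under the study thresholds."""

    UP = "up"
    DOWN = "down"
    NOT_SIGNIFICANT = "not_significant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's position on the chromosome.

    ``ordinal`` is the gene's 0-based rank when all genes are sorted by
    ascending start position; ordinals over a genome form a permutation of
    ``0..n-1``.
    """

    locus_tag: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    ordinal: int
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")

    @property
    def translational_start(self) -> int:
        """Start-codon coordinate: left end on +, right end on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomeSequence:
    """A (by default circular) nucleotide sequence."""

    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in genome: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OperonTable:
    """Operon id -> ordered member locus tags, most-upstream first.

    A gene belongs to at most one operon; ``operon_of`` inverts the map.
    """

    operons: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for op_id, members in self.operons.items():
            if not members:
                raise ValueError(f"operon {op_id} has no members")
            for locus in members:
                if locus in seen:
                    raise ValueError(
                        f"{locus} appears in operons {seen[locus]} and {op_id}"
                    )
                seen[locus] = op_id
        self._operon_of = seen

    def operon_of(self, locus: str) -> str | None:
        return self._operon_of.get(locus)

    def __len__(self) -> int:
        return len(self.operons)


@dataclass(frozen=True)
class TSSRecord:
    """A transcriptional start site mapped to a gene.

    ``tss_type`` follows the source table's vocabulary (primary, secondary,
    internal, antisense, ...). Only ``antisense`` receives special
    treatment downstream: the gene's strand is switched before upstream
    extraction.
    """

    locus_tag: str
    tss_position: int  # 1-based
    strand: str
    tss_type: str = "primary"

    def __post_init__(self) -> None:
        if self.tss_position < 1:
            raise ValueError(f"{self.locus_tag}: TSS position < 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """One row of a DESeq2-style results table.

    ``p_adj`` is the BH-adjusted P value; ``None`` models the NA cells
    DESeq2 emits for independently filtered genes.
    """

    locus_tag: str
    log2fc: float
    p_adj: float | None

    def __post_init__(self) -> None:
        if self.p_adj is not None and not (0.0 <= self.p_adj <= 1.0):
            raise ValueError(
                f"{self.locus_tag}: p_adj {self.p_adj} outside [0, 1]"
            )


@dataclass
class GeneSet:
    """A named gene set: a regulon or a curated functional list."""

    name: str
    members: set[str]
    regulator_locus: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MotifMatch:
    """A TomTom match of a discovered motif to a known regulator's motif."""

    query_motif_id: str
    target_regulator: str
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class ThresholdConfig:
    """All analysis cutoffs in one place.

    Defaults are the study's printed settings: |fold change| >= 1.5 at
    BH-adjusted P <= 0.05 for the DE call; runs of at least five
    consecutive same-direction DE genes; 250 bp of upstream sequence;
    TomTom matches kept at q <= 0.5 (inclusive); enrichment called at
    BH <= 0.05. ``log2(fc_min)`` is computed at run time — 0.585 is a
    rounded display value, not the threshold.
    """

    fc_min: float = 1.5
    padj_max: float = 0.05
    min_run: int = 5
    upstream_len: int = 250
    tomtom_q_max: float = 0.5
    enrich_alpha: float = 0.05
    circular: bool = True
    fisher_alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        for name in ("padj_max", "tomtom_q_max", "enrich_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.upstream_len < 1:
            raise ValueError("upstream_len must be >= 1")
        if self.fisher_alternative not in ("two-sided", "greater"):
            raise ValueError(
                f"unsupported fisher alternative {self.fisher_alternative!r}"
            )

    @property
    def log2fc_min(self) -> float:
        return math.log2(self.fc_min)


@dataclass(frozen=True)
class DESummary:
    """Counts over one classified expression table."""

    n_measured: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if min(self.n_measured, self.n_up, self.n_down) < 0:
            raise ValueError("negative count")
        if self.n_de > self.n_measured:
            raise ValueError("n_de exceeds n_measured")

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class Cluster:
    """A maximal run of >= min_run consecutive same-direction DE genes.

    ``start_ordinal`` is the ordinal of the first member; on a circular
    chromosome the member ordinals may wrap through 0.
    """

    cluster_id: str
    direction: DEStatus
    member_loci: tuple[str, ...]
    start_ordinal: int

    def __post_init__(self) -> None:
        if self.direction not in (DEStatus.UP, DEStatus.DOWN):
            raise ValueError("cluster direction must be up or down")

    @property
    def length(self) -> int:
        return len(self.member_loci)


@dataclass(frozen=True)
class ClusterSummary:
    n_clusters: int
    n_cluster_genes: int
    fraction_of_de_genes: float


@dataclass(frozen=True)
class PromoterRegion:
    """A resolved transcription start plus its extracted upstream window."""

    locus_tag: str
    resolved_position: int  # 1-based
    resolved_strand: str
    source: str  # "tss" or "start_codon"
    flipped: bool
    sequence: str

    def __post_init__(self) -> None:
        if self.source not in ("tss", "start_codon"):
            raise ValueError(f"bad source {self.source!r}")
        if self.flipped and self.source != "tss":
            raise ValueError("strand flip only applies to TSS-derived starts")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts over a stated gene universe.

    a = DE genes inside the set, b = DE genes outside it,
    c = non-DE set members, d = everything else.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    n_de_in_set: int
    n_up: int
    n_down: int
    fraction_dysregulated: float
    p_value: float
    p_adjusted: float
    significant: bool
    alternative: str = "two-sided"
    testable: bool = True


@dataclass(frozen=True)
class OverlapReport:
    set_a_name: str
    set_b_name: str
    n_common_members: int
    fraction_dysregulated_a: float
    fraction_dysregulated_b: float
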