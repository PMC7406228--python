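"""End-to-end pipeline: classify -> clusters -> promoters -> enrichment.

A single YAML config names the input files and thresholds; stages run in
a fixed order, write plain-text outputs into one directory and record
their counts in a machine-readable run manifest. A missing operon table
degrades gracefully (no operon filtering, flagged in the manifest); any
other stage failure aborts, leaving a manifest that marks the failed
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import io as dio
from .circos import write_circos_tracks
from .classify import classify_table
from .clusters import find_clusters, sensitivity_sweep, summarize_clusters
from .enrichment import enrich_gene_sets, results_frame
from .model import DEStatus, ThresholdConfig
from .promoters import (
    build_promoter_regions,
    candidate_regulators,
    emit_promoter_fasta,
    first_in_operon_filter,
)

logger = logging.getLogger("declust")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_THRESHOLD_KEYS = {f.name for f in dataclasses.fields(ThresholdConfig)}


@dataclasses.dataclass
class PipelineConfig:
    """Paths plus thresholds for one pipeline run."""

    expression: str
    gff3: str | None = None
    genome_fasta: str | None = None
    operons: str | None = None
    tss: str | None = None
    regulons: str | None = None
    curated: str | None = None
    tomtom: str | None = None
    out_dir: str = "declust_out"
    sweep_k: tuple[int, ...] = (4, 5, 6)
    universe: str = "measured"  # or "annotated"
    thresholds: ThresholdConfig = dataclasses.field(default_factory=ThresholdConfig)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    thresholds = ThresholdConfig(
        **{k: v for k, v in raw.items() if k in _THRESHOLD_KEYS}
    )
    kwargs = {
        k: v
        for k, v in raw.items()
        if k in {f.name for f in dataclasses.fields(PipelineConfig)}
        and k != "thresholds"
    }
    if "sweep_k" in kwargs:
        kwargs["sweep_k"] = tuple(int(k) for k in kwargs["sweep_k"])
    return PipelineConfig(thresholds=thresholds, **kwargs)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run all stages; returns (and writes) the run manifest dict.

    Raises on stage failure after writing a manifest that marks the
    failed stage.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    cfg = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "declust 0.1.0",
        "thresholds": dataclasses.asdict(cfg),
        "inputs": {},
        "counts": {},
        "warnings": [],
        "stages": {},
        "failed_stage": None,
    }

    required = {"expression": config.expression}
    missing = [
        f"{name}: {path}"
        for name, path in required.items()
        if path is None or not Path(path).exists()
    ]
    for name in ("gff3", "genome_fasta", "operons", "tss", "regulons",
                 "curated", "tomtom"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            missing.append(f"{name}: {path}")
    if missing:
        raise FileNotFoundError(
            "missing input files:\n  " + "\n  ".join(missing)
        )
    for name in ("expression", "gff3", "genome_fasta", "operons", "tss",
                 "regulons", "curated", "tomtom"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256_16": _checksum(path)}

    def finish(stage: str, err: Exception) -> None:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise err

    # --- annotation ---------------------------------------------------
    stage = "annotation"
    try:
        records = dio.read_expression_table(config.expression)
        if config.gff3:
            annotations = dio.read_gff3(config.gff3)
        else:
            logger.warning("[annotation] no GFF3; deriving order from locus tags")
            manifest["warnings"].append("annotation order derived from locus tags")
            annotations = dio.annotations_from_locus_tags(
                [r.locus_tag for r in records]
            )
        ann_by_locus = {a.locus_tag: a for a in annotations}
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001 - manifest must record the stage
        finish(stage, err)

    # --- classify ------------------------------------------------------
    stage = "classify"
    try:
        statuses, summary = classify_table(records, cfg)
        with open(out / "statuses.tsv", "w") as fh:
            fh.write("locus_tag\tlog2fc\tp_adj\tstatus\n")
            for r in records:
                p = "NA" if r.p_adj is None else r.p_adj
                fh.write(f"{r.locus_tag}\t{r.log2fc}\t{p}\t{statuses[r.locus_tag]}\n")
        manifest["counts"].update(
            n_measured=summary.n_measured, n_up=summary.n_up,
            n_down=summary.n_down, n_de=summary.n_de,
        )
        logger.info("[classify] %d measured, %d DE", summary.n_measured, summary.n_de)
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001
        finish(stage, err)

    # --- clusters ------------------------------------------------------
    stage = "clusters"
    try:
        ordered = sorted(ann_by_locus.values(), key=lambda a: a.ordinal)
        n_unmeasured = sum(1 for a in ordered if a.locus_tag not in statuses)
        if n_unmeasured:
            manifest["warnings"].append(
                f"{n_unmeasured} annotated genes unmeasured; treated as "
                "not significant in the cluster scan"
            )
        status_vec = [
            statuses.get(a.locus_tag, DEStatus.NOT_SIGNIFICANT) for a in ordered
        ]
        loci = [a.locus_tag for a in ordered]
        clusters = find_clusters(status_vec, cfg, loci)
        csum = summarize_clusters(clusters, summary)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\tdirection\tlength\tstart_ordinal\t"
                     "first_locus\tlast_locus\tmembers\n")
            for c in clusters:
                fh.write(
                    f"{c.cluster_id}\t{c.direction}\t{c.length}\t"
                    f"{c.start_ordinal}\t{c.member_loci[0]}\t"
                    f"{c.member_loci[-1]}\t{','.join(c.member_loci)}\n"
                )
        sweep = sensitivity_sweep(status_vec, list(config.sweep_k), cfg, loci)
        sweep.to_csv(out / "cluster_sweep.tsv", sep="\t", index=False)
        manifest["counts"].update(
            n_clusters=csum.n_clusters,
            n_cluster_genes=csum.n_cluster_genes,
            fraction_of_de_in_clusters=csum.fraction_of_de_genes,
            circular=cfg.circular,
        )
        logger.info("[clusters] %d clusters / %d genes", csum.n_clusters,
                    csum.n_cluster_genes)
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001
        finish(stage, err)

    # --- promoters -----------------------------------------------------
    stage = "promoters"
    de_loci = [l for l, s in statuses.items()
               if s in (DEStatus.UP, DEStatus.DOWN) and l in ann_by_locus]
    if config.genome_fasta:
        try:
            genome = dio.read_genome_fasta(
                config.genome_fasta, circular=cfg.circular
            )
            if config.operons:
                operons = dio.read_operons(config.operons)
                reduced = first_in_operon_filter(de_loci, operons, ann_by_locus)
            else:
                manifest["warnings"].append(
                    "no operon table: operon filtering skipped"
                )
                reduced = sorted(
                    set(de_loci), key=lambda l: ann_by_locus[l].ordinal
                )
            tss_records: dict[str, list] = {}
            if config.tss:
                for t in dio.read_tss(config.tss):
                    tss_records.setdefault(t.locus_tag, []).append(t)
            else:
                manifest["warnings"].append(
                    "no TSS table: all starts fall back to the start codon"
                )
            regions = build_promoter_regions(
                reduced, genome, tss_records, ann_by_locus, cfg
            )
            if regions:
                emit_promoter_fasta(
                    regions, out / "promoters.fasta", out / "promoters.manifest.json"
                )
            manifest["counts"].update(
                n_de_after_operon_filter=len(reduced),
                n_promoters=len(regions),
            )
            manifest["stages"][stage] = "ok"
        except Exception as err:  # noqa: BLE001
            finish(stage, err)
    else:
        manifest["stages"][stage] = "skipped (no genome FASTA)"

    # --- regulators + enrichment ----------------------------------------
    stage = "enrichment"
    try:
        universe = (
            set(statuses)
            if config.universe == "measured"
            else set(ann_by_locus)
        )
        status_on_universe = {
            g: statuses.get(g, DEStatus.NOT_SIGNIFICANT) for g in universe
        }
        n_sets, n_sig = 0, 0
        for label, path in (("regulons", config.regulons),
                            ("curated", config.curated)):
            if not path:
                continue
            sets = dio.read_gmt(path)
            if label == "regulons" and config.tomtom:
                matches = dio.read_tomtom(config.tomtom, cfg.tomtom_q_max)
                sets, unmapped = candidate_regulators(matches, sets)
                if unmapped:
                    manifest["warnings"].append(
                        f"regulators without regulons on file: {unmapped}"
                    )
                manifest["counts"]["n_motif_matched_regulators"] = len(sets)
            if not sets:
                continue
            res = enrich_gene_sets(sets, status_on_universe, universe, cfg)
            results_frame(res).to_csv(
                out / f"enrichment_{label}.tsv", sep="\t", index=False
            )
            n_sets += len(res)
            n_sig += int(sum(r.significant for r in res))
        manifest["counts"].update(n_sets_tested=n_sets, n_significant=n_sig)
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001
        finish(stage, err)

    # --- circos export ---------------------------------------------------
    stage = "circos"
    try:
        counts = write_circos_tracks(
            list(ann_by_locus.values()), records, statuses, out / "circos"
        )
        manifest["counts"]["circos"] = counts
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001
        finish(stage, err)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
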