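"""Per-gene differential-expression calls.

A gene is called *up* when its log2 fold change reaches ``log2(fc_min)``
with adjusted P at or below ``padj_max``, *down* for the mirrored
condition, and *not significant* otherwise — including when the adjusted
P is missing (DESeq2's independent filtering emits NA there). Thresholds
are inclusive; ``log2(1.5)`` is evaluated exactly rather than using the
rounded 0.585 seen on plot legends.
"""

from __future__ import annotations

import math

from .model import DESummary, DEStatus, ExpressionRecord, ThresholdConfig

__all__ = [
    "classify_gene",
    "classify_table",
    "signed_fold",
    "log2_of_signed_fold",
]


def classify_gene(record: ExpressionRecord, cfg: ThresholdConfig) -> DEStatus:
    """Classify one gene as up / down / not significant."""
    if record.p_adj is None or record.p_adj > cfg.padj_max:
        return DEStatus.NOT_SIGNIFICANT
    if record.log2fc >= cfg.log2fc_min:
        return DEStatus.UP
    if record.log2fc <= -cfg.log2fc_min:
        return DEStatus.DOWN
    return DEStatus.NOT_SIGNIFICANT


def classify_table(
    records: list[ExpressionRecord], cfg: ThresholdConfig
) -> tuple[dict[str, DEStatus], DESummary]:
    """Classify a whole table; returns the status map and its summary.

    Locus tags must be unique across the table.
    """
    statuses: dict[str, DEStatus] = {}
    for rec in records:
        if rec.locus_tag in statuses:
            raise ValueError(f"duplicate locus tag {rec.locus_tag}")
        statuses[rec.locus_tag] = classify_gene(rec, cfg)
    n_up = sum(1 for s in statuses.values() if s is DEStatus.UP)
    n_down = sum(1 for s in statuses.values() if s is DEStatus.DOWN)
    return statuses, DESummary(n_measured=len(statuses), n_up=n_up, n_down=n_down)


def signed_fold(log2fc: float) -> float:
    """Convert a log2 fold change to the signed linear fold convention.

    Positive log2fc maps to ``2**log2fc``; negative maps to
    ``-2**(-log2fc)``, so a 9.6-fold repression prints as -9.6 rather
    than 0.104.
    """
    if log2fc >= 0:
        return 2.0 ** log2fc
    return -(2.0 ** (-log2fc))


def log2_of_signed_fold(fold: float) -> float:
    """Inverse of :func:`signed_fold`; folds in (-1, 1) have no preimage."""
    if -1.0 < fold < 1.0:
        raise ValueError(f"signed linear fold {fold} lies in (-1, 1)")
    if fold >= 1.0:
        return math.log2(fold)
    return -math.log2(-fold)
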