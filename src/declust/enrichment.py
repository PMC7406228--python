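"""Gene-set enrichment by Fisher's exact test with BH correction.

Each gene set (a transcription-factor regulon or a curated functional
list) is tested for over-representation of DE genes against a stated
universe — by default the measured genes. One BH family spans the sets
submitted together in a single call, mirroring separately reported
regulon and curated-list analyses.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    ContingencyTable,
    DEStatus,
    EnrichmentResult,
    GeneSet,
    OverlapReport,
    ThresholdConfig,
)

__all__ = [
    "contingency",
    "fisher_exact",
    "bh_adjust",
    "enrich_gene_sets",
    "compare_regulons",
    "results_frame",
]


def contingency(
    members: set[str], de_genes: set[str], universe: set[str]
) -> ContingencyTable:
    """2x2 table of (in set) x (DE) over the universe.

    Members and DE genes are restricted to the universe before counting.
    """
    m = members & universe
    de = de_genes & universe
    a = len(m & de)
    return ContingencyTable(
        a=a, b=len(de) - a, c=len(m) - a, d=len(universe) - len(m) - len(de) + a
    )


def fisher_exact(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact P for a 2x2 table.

    ``two-sided`` sums all tables with the same margins whose point
    probability does not exceed the observed one (the conventional
    definition); ``greater`` is the upper hypergeometric tail.
    An all-zero table carries no information and returns P = 1.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    if table.n == 0:
        warnings.warn("all-zero contingency table; P set to 1", stacklevel=2)
        return 1.0
    res = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_sets(
    sets: list[GeneSet],
    statuses: dict[str, DEStatus],
    universe: set[str],
    cfg: ThresholdConfig,
) -> list[EnrichmentResult]:
    """Test each gene set for enrichment of DE genes.

    Sets are restricted to the universe before counting; a set with no
    members in the universe is returned flagged untestable (P = NaN) and
    excluded from the BH family. ``significant`` means BH-adjusted
    P <= ``cfg.enrich_alpha``.
    """
    missing = {g for g in statuses if g not in universe}
    if missing:
        raise ValueError(
            f"{len(missing)} status genes outside the universe (e.g. "
            f"{sorted(missing)[:3]})"
        )
    de_genes = {
        g for g, s in statuses.items() if s in (DEStatus.UP, DEStatus.DOWN)
    }
    results: list[EnrichmentResult] = []
    testable_idx: list[int] = []
    pvals: list[float] = []
    for s in sets:
        in_universe = s.members & universe
        if len(in_universe) < len(s.members):
            warnings.warn(
                f"set {s.name}: {len(s.members) - len(in_universe)} members "
                "outside universe dropped before counting",
                stacklevel=2,
            )
        n_up = sum(1 for g in in_universe if statuses.get(g) is DEStatus.UP)
        n_down = sum(1 for g in in_universe if statuses.get(g) is DEStatus.DOWN)
        n_de = n_up + n_down
        size = len(in_universe)
        result = EnrichmentResult(
            set_name=s.name,
            set_size=size,
            n_de_in_set=n_de,
            n_up=n_up,
            n_down=n_down,
            fraction_dysregulated=(n_de / size) if size else 0.0,
            p_value=math.nan,
            p_adjusted=math.nan,
            significant=False,
            alternative=cfg.fisher_alternative,
            testable=size > 0,
        )
        if size > 0:
            table = contingency(s.members, de_genes, universe)
            result.p_value = fisher_exact(table, cfg.fisher_alternative)
            testable_idx.append(len(results))
            pvals.append(result.p_value)
        results.append(result)
    if pvals:
        adjusted = bh_adjust(pvals)
        for idx, padj in zip(testable_idx, adjusted):
            results[idx].p_adjusted = float(padj)
            results[idx].significant = bool(padj <= cfg.enrich_alpha)
    return results


def compare_regulons(
    set_a: GeneSet, set_b: GeneSet, statuses: dict[str, DEStatus]
) -> OverlapReport:
    """Overlap of two regulons plus each one's dysregulated fraction.

    Used to compare a database regulon against a ChIP-seq-derived one for
    the same regulator.
    """

    def frac(members: set[str]) -> float:
        de = sum(
            1
            for g in members
            if statuses.get(g) in (DEStatus.UP, DEStatus.DOWN)
        )
        return de / len(members)

    return OverlapReport(
        set_a_name=set_a.name,
        set_b_name=set_b.name,
        n_common_members=len(set_a.members & set_b.members),
        fraction_dysregulated_a=frac(set_a.members),
        fraction_dysregulated_b=frac(set_b.members),
    )


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV export."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "set_size": r.set_size,
                "n_de_in_set": r.n_de_in_set,
                "n_up": r.n_up,
                "n_down": r.n_down,
                "fraction_dysregulated": r.fraction_dysregulated,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "alternative": r.alternative,
                "testable": r.testable,
            }
            for r in results
        ]
    )
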