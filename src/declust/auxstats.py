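"""Small statistics outside the RNA-seq core.

Percent coefficient of variation for single-cell fluorescence samples,
comparative-threshold-cycle (2^-ddCt) relative expression for qRT-PCR,
earliest-significant-timepoint detection for promoter-reporter growth
curves, and the RNA-seq vs qPCR fold-change correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "percent_cv",
    "ddct_fold",
    "first_significant_timepoint",
    "fold_correlation",
]


def percent_cv(intensities) -> float:
    """Percent coefficient of variation: sd / mean x 100.

    Uses the sample (n-1) standard deviation; a high percent CV indicates
    spot-like fluorescence within cells, a low one a uniform signal.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two intensity measurements")
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    return float(x.std(ddof=1) / mean * 100.0)


def ddct_fold(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ddCt with a reference-gene normalizer.

    dCt = Ct(target) - Ct(reference) per condition, ddCt = dCt(test) -
    dCt(control). Assumes the classical doubling-per-cycle efficiency.
    """
    for ct in (ct_target_test, ct_ref_test, ct_target_control, ct_ref_control):
        if not np.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def first_significant_timepoint(series, alpha: float = 0.05) -> int | None:
    """Earliest timepoint with significantly higher signal than the start.

    ``series`` is a replicates x timepoints array. Each later timepoint
    is compared to timepoint 0 by a paired one-sided (greater) t test;
    returns the 0-based index of the first timepoint with p < ``alpha``,
    or ``None`` if no timepoint qualifies.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a replicates x timepoints array with >= 2 replicates")
    baseline = x[:, 0]
    for t in range(1, x.shape[1]):
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(x[:, t], baseline, alternative="greater")
        p = res.pvalue
        if np.isnan(p):
            # zero-variance differences: fall back on the sign of the mean shift
            p = 0.0 if (x[:, t] - baseline).mean() > 0 else 1.0
        if p < alpha:
            return t
    return None


def fold_correlation(rnaseq_log2fc, qpcr_log2fc) -> float:
    """Squared Pearson correlation of two fold-change vectors.

    Defaults to log2 folds (symmetric in up/down changes); callers
    preferring signed linear folds can transform before calling.
    """
    x = np.asarray(rnaseq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 aligned fold-change pairs")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
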