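"""The small statistics around the transcriptome core.

Percent CV quantifies whether single-cell fluorescence is spot-like
(high CV) or uniform (low CV); 2^-ddCt converts qPCR threshold cycles to
relative expression; the timepoint test finds when a promoter-reporter
first rises above its baseline; and R^2 summarizes RNA-seq vs qPCR
fold-change agreement.
"""

import numpy as np

from declust.auxstats import (
    ddct_fold,
    first_significant_timepoint,
    fold_correlation,
    percent_cv,
)

rng = np.random.default_rng(1)

spots = rng.gamma(shape=1.2, scale=50, size=800)      # spotty signal
uniform = rng.normal(60, 6, size=800).clip(min=0)     # even signal
print(f"percent CV, spot-like cells:  {percent_cv(spots):6.1f}%")
print(f"percent CV, uniform cells:    {percent_cv(uniform):6.1f}%")

# target amplifies 2 cycles earlier in the test condition, reference unchanged
fold = ddct_fold(ct_target_test=20, ct_ref_test=10,
                 ct_target_control=22, ct_ref_control=10)
print(f"2^-ddCt relative expression:  {fold:.1f}x")

# reporter activity flat for 4 timepoints, then induced
series = np.zeros((6, 10)) + rng.normal(0, 0.05, size=(6, 10))
series[:, 4:] += 2.0
t = first_significant_timepoint(series, alpha=0.05)
print(f"promoter activity first significant at timepoint index {t}")

rnaseq = rng.normal(0, 2, size=15)
qpcr = rnaseq + rng.normal(0, 1.2, size=15)           # noisy validation
print(f"RNA-seq vs qPCR R^2:          {fold_correlation(rnaseq, qpcr):.2f}")
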