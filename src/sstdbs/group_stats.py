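"""Paired within-subject condition comparisons (ON vs OFF).

Two-sided paired t-tests and Wilcoxon signed-rank tests on per-subject
measures; p-values are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = ["PairedResult", "paired_compare"]


@dataclass
class PairedResult:
    measure: str
    n: int
    mean_on: float
    mean_off: float
    statistic: float
    p_value: float
    test: str  # "paired_t" or "wilcoxon_signed_rank"
    undefined: bool = False  # statistic degenerate (e.g. zero-variance differences)


def paired_compare(
    values_on: Sequence[float],
    values_off: Sequence[float],
    test: str = "paired_t",
    measure: str = "",
) -> PairedResult:
    """Two-sided paired comparison of per-subject values.

    ``paired_t`` uses the t distribution with n-1 df on the differences.
    ``wilcoxon_signed_rank`` uses the exact null distribution for n <= 25
    (when no zero differences force the approximation) and the normal
    approximation above.  Zero-variance differences leave the t statistic
    undefined; the result is flagged rather than given a p-value.
    """
    on = np.asarray(values_on, dtype=float)
    off = np.asarray(values_off, dtype=float)
    if on.shape != off.shape or on.ndim != 1:
        raise ValueError("values_on and values_off must be 1-D and equal length")
    if on.size < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    if not (np.isfinite(on).all() and np.isfinite(off).all()):
        raise ValueError("missing pairs are not allowed")
    d = on - off

    if test == "paired_t":
        if np.std(d, ddof=1) == 0.0:
            # all differences identical: t undefined (0/0 at zero mean)
            stat = 0.0 if d[0] == 0.0 else float(np.sign(d[0]) * np.inf)
            return PairedResult(
                measure, on.size, float(on.mean()), float(off.mean()),
                stat, float("nan"), test, undefined=True,
            )
        res = scipy.stats.ttest_rel(on, off)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon_signed_rank":
        method = "exact" if on.size <= 25 and not np.any(d == 0.0) else "approx"
        res = scipy.stats.wilcoxon(on, off, method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return PairedResult(
        measure, on.size, float(on.mean()), float(off.mean()), stat, p, test
    )
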