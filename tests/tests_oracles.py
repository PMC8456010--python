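"""Independent brute-force oracles used by the acceptance tests."""

import numpy as np


def brute_force_anova(values: np.ndarray, groups: np.ndarray):
    """One-way ANOVA from sums of squares: (SSB/SST, F)."""
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    ssb = 0.0
    for g in np.unique(groups):
        sub = values[groups == g]
        ssb += len(sub) * (sub.mean() - grand) ** 2
    ssw = sst - ssb
    g = len(np.unique(groups))
    n = len(values)
    F = (ssb / (g - 1)) / (ssw / (n - g))
    return ssb / sst, F
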