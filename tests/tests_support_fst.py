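"""Independently coded F_ST oracles used by the test suite.

These deliberately re-derive the estimators through a different algebraic
route than the package implementation: the Hudson oracle evaluates the
plug-in expression term by term, and the Weir-Cockerham oracle runs the
nested allele-copy ANOVA (sums of squares -> mean squares -> variance
components) rather than the closed-form a/b/c expressions.
"""

import numpy as np


def hudson_plugin_oracle(p1, n1, p2, n2):
    within1 = p1 * (1 - p1) / (2 * n1 - 1)
    within2 = p2 * (1 - p2) / (2 * n2 - 1)
    num = (p1 - p2) * (p1 - p2) - within1 - within2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.nan if den == 0 else num / den


def wc_anova_oracle(counts1, counts2):
    counts = np.asarray([counts1, counts2], float)
    n_i = counts.sum(axis=1)
    r = 2
    N = n_i.sum()
    p_i = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_i)
    xbar = (n_i * p_i).sum() / N
    # sums of squares over allele copies x_ijc in {0, 1}
    ssw = (counts[:, 1] / 2).sum()  # heterozygote copies differ from own mean
    ssb = 0.0
    for i in range(2):
        for dosage in range(3):
            ssb += 2 * counts[i, dosage] * (dosage / 2 - p_i[i]) ** 2
    ssa = (2 * n_i * (p_i - xbar) ** 2).sum()
    if N <= r:
        return np.nan
    msw = ssw / N
    msb = ssb / (N - r)
    msa = ssa / (r - 1)
    nc = (N - (n_i**2).sum() / N) / (r - 1)
    s2_w = msw
    s2_b = (msb - msw) / 2
    s2_a = (msa - msb) / (2 * nc)
    den = s2_a + s2_b + s2_w
    return np.nan if den == 0 else s2_a / den
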