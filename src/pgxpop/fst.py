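"""Per-locus fixation-index estimators for two populations.

Hudson's estimator (with the finite-sample correction of the numerator) is
the headline statistic; the Weir–Cockerham theta from the a/b/c variance
components is computed alongside as a cross-check.  Negative estimates are
reported as computed — truncating at zero would bias multi-locus averages —
and multi-locus summaries should combine loci as the ratio of summed
numerators to summed denominators rather than averaging per-locus ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes
from .popstats import genotype_counts


class FstError(ValueError):
    pass


@dataclass
class FstEstimate:
    estimate: float  # nan marks undefined (both populations monomorphic)
    numerator: float
    denominator: float
    negative: bool = False


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> FstEstimate:
    """Hudson F_ST from allele frequencies and diploid sample sizes.

    numerator   = (p1-p2)^2 - p1(1-p1)/(2n1-1) - p2(1-p2)/(2n2-1)
    denominator = p1(1-p2) + p2(1-p1)
    """
    if n1 < 2 or n2 < 2:
        raise FstError("need at least 2 diploids per population")
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise FstError(f"frequency {p} outside [0, 1]")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (2 * n1 - 1)
        - p2 * (1 - p2) / (2 * n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        return FstEstimate(np.nan, num, den)  # co-monomorphic: undefined
    est = num / den
    return FstEstimate(est, num, den, negative=est < 0)


def wc_fst(counts1, counts2) -> FstEstimate:
    """Weir–Cockerham theta for one biallelic locus, two populations.

    ``counts1``/``counts2`` are (hom1, het, hom2) genotype counts.  Returns
    theta = a / (a + b + c) from the among-population (a), among-individual
    (b) and within-individual (c) variance components.
    """
    counts = np.asarray([counts1, counts2], dtype=float)
    if (counts < 0).any():
        raise FstError("genotype counts must be non-negative")
    n_i = counts.sum(axis=1)
    if (n_i < 1).any():
        raise FstError("each population needs at least one genotype")
    r = 2.0
    p_i = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_i)
    h_i = counts[:, 1] / n_i
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if pbar in (0.0, 1.0):
        return FstEstimate(np.nan, 0.0, 0.0)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    den = a + b + c
    if den == 0.0:
        return FstEstimate(np.nan, a, den)
    return FstEstimate(a / den, a, den, negative=(a / den) < 0)


def pairwise_fst_table(
    cohorts: dict[str, CohortGenotypes],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Loci x population-pair table of Hudson and WC estimates."""
    names = list(cohorts)
    if pairs is None:
        pairs = [(names[0], b) for b in names[1:]]
    panel = cohorts[names[0]].panel
    rows = []
    for a, b in pairs:
        ca, cb = cohorts[a], cohorts[b]
        for rsid in panel.rsids:
            g1 = genotype_counts(ca, rsid)
            g2 = genotype_counts(cb, rsid)
            n1, n2 = sum(g1), sum(g2)
            p1 = (g1[1] + 2 * g1[2]) / (2 * n1)
            p2 = (g2[1] + 2 * g2[2]) / (2 * n2)
            hud = hudson_fst(p1, n1, p2, n2)
            wc = wc_fst(g1, g2)
            rows.append(
                (
                    rsid,
                    f"{a}-{b}",
                    hud.estimate,
                    wc.estimate,
                    hud.numerator,
                    hud.denominator,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["rsid", "pair", "hudson", "weir_cockerham", "num", "den"],
    )


def mean_hudson_fst(table: pd.DataFrame, pair: str | None = None) -> float:
    """Multi-locus Hudson F_ST as ratio of summed components (Bhatia-style)."""
    df = table if pair is None else table[table["pair"] == pair]
    den = df["den"].sum()
    if den == 0:
        raise FstError("no polymorphic loci to combine")
    return float(df["num"].sum() / den)
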