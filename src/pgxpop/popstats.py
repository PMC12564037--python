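"""Frequency estimation and interpopulation association testing.

Tests run on genotype counts (2 populations x 3 genotype classes) with
Pearson's chi-square; the exact test of independence takes over when any
expected cell is zero or when more than ``fallback_fraction`` (default
0.8) of expected cells are below five.  That 80% threshold is deliberately
looser than the conventional 20% rule and is configurable.  Family-wise
error is controlled with the stepwise Holm–Bonferroni adjustment; the
default family is one population-pair column of tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import MISSING, CohortGenotypes
from .panel import FREQ_COLUMNS, FrequencyTable

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


class StatError(ValueError):
    pass


@dataclass
class TestResult:
    rsid: str
    pair: tuple[str, str]
    method: str  # "chi_square" | "fisher_exact"
    statistic: float | None
    df: int | None
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    mc_se: float | None = None

    def finalize(self, p_adj: float, alpha: float = DEFAULT_ALPHA) -> None:
        self.p_adjusted = p_adj
        self.significant = bool(p_adj < alpha)


def estimate_frequencies(
    cohort: CohortGenotypes, population: str | None = None
) -> tuple[FrequencyTable, pd.DataFrame]:
    """Allele frequencies and genotype counts from non-missing calls.

    Fully missing loci are omitted with a warning.  Returns the frequency
    table (denominator = 2 x called samples) and a per-locus genotype-count
    frame (hom1/het/hom2).
    """
    label = population or (
        str(cohort.populations[0]) if cohort.populations is not None else "cohort"
    )
    dos = cohort.dosage_matrix().values
    freq_rows, count_rows = [], []
    for j, v in enumerate(cohort.panel.variants):
        col = dos[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            log.warning("locus %s fully missing; omitted", v.rsid)
            continue
        n = called.size
        hom1 = int((called == 0).sum())
        het = int((called == 1).sum())
        hom2 = int((called == 2).sum())
        p2 = (het + 2 * hom2) / (2 * n)
        freq_rows.append((label, v.rsid, v.allele_1, 1.0 - p2, v.allele_2, p2, n))
        count_rows.append((label, v.rsid, hom1, het, hom2, n))
    freqs = FrequencyTable(pd.DataFrame(freq_rows, columns=FREQ_COLUMNS))
    counts = pd.DataFrame(
        count_rows, columns=["population", "rsid", "hom1", "het", "hom2", "n"]
    )
    return freqs, counts


def genotype_counts(cohort: CohortGenotypes, rsid: str) -> tuple[int, int, int]:
    j = cohort.panel.index_of(rsid)
    col = cohort.dosage_matrix().values[:, j]
    called = col[col != MISSING]
    return (
        int((called == 0).sum()),
        int((called == 1).sum()),
        int((called == 2).sum()),
    )


def _expected(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows * cols / table.sum()


def genotype_association_test(
    counts_pop1,
    counts_pop2,
    rsid: str = "",
    pair: tuple[str, str] = ("pop1", "pop2"),
    fallback_fraction: float = 0.8,
    enumeration_bound: int = 200_000,
    seed: int | None = None,
    n_mc: int = 100_000,
) -> TestResult:
    """2x3 genotype-frequency homogeneity test with exact-test fallback."""
    table = np.asarray([counts_pop1, counts_pop2], dtype=np.int64)
    if (table < 0).any():
        raise StatError("genotype counts must be non-negative")
    if table.sum(axis=1).min() == 0:
        raise StatError("each population needs at least one genotype")
    table = table[:, table.sum(axis=0) > 0]  # drop all-zero genotype columns
    if table.shape[1] < 2:
        # only one genotype class left: distributions are identical
        return TestResult(rsid, pair, "chi_square", 0.0, 0, 1.0)
    expected = _expected(table)
    use_fisher = (expected == 0).any() or (expected < 5).mean() > fallback_fraction
    if use_fisher:
        res = fisher_exact(
            table, enumeration_bound=enumeration_bound, seed=seed, n_mc=n_mc
        )
        return TestResult(
            rsid, pair, "fisher_exact", None, None, res.p, mc_se=res.mc_se
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(rsid, pair, "chi_square", float(chi2), int(dof), float(p))


@dataclass
class FisherResult:
    p: float
    method: str  # "enumeration" | "monte_carlo"
    mc_se: float | None = None
    n_tables: int | None = None


def _log_table_prob(table: np.ndarray, lognorm: float) -> float:
    # hypergeometric probability of an r x c table given fixed margins
    return (
        lognorm
        + gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(table.sum() + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_margins)

    def rec(i, remaining_cols, acc):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield acc + [list(last)]
            return
        target = row_margins[i]

        def fill(j, left, row):
            if j == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for x in range(0, min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - x, row + [x])

        for row in fill(0, target, []):
            rest = [remaining_cols[j] - row[j] for j in range(len(row))]
            yield from rec(i + 1, rest, acc + [row])

    yield from rec(0, list(col_margins), [])


def fisher_exact(
    table,
    enumeration_bound: int = 200_000,
    seed: int | None = None,
    n_mc: int = 100_000,
) -> FisherResult:
    """Two-sided exact test of independence for an r x c count table.

    Exact enumeration over all tables with the observed margins (two-sided
    by probability ordering) while the enumeration stays within
    ``enumeration_bound`` tables; beyond that a seeded Monte-Carlo
    permutation p-value is returned with its standard error.
    """
    table = np.asarray(table, dtype=np.int64)
    if (table < 0).any():
        raise StatError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return FisherResult(p=1.0, method="enumeration", n_tables=1)

    # lognorm folds the constant margin terms out of per-table probabilities
    lognorm = 0.0
    logp_obs = _log_table_prob(table, lognorm)
    tol = 1e-9 * abs(logp_obs) + 1e-12

    total = 0.0
    count = 0
    for t in _enumerate_tables(list(rows), list(cols)):
        count += 1
        if count > enumeration_bound:
            break
        lp = _log_table_prob(np.asarray(t), lognorm)
        if lp <= logp_obs + tol:
            total += np.exp(lp)
    else:
        return FisherResult(p=min(total, 1.0), method="enumeration", n_tables=count)

    if seed is None:
        raise StatError(
            f"enumeration bound ({enumeration_bound} tables) exceeded; "
            "supply a seed for the Monte-Carlo permutation p-value"
        )
    rng = np.random.default_rng(seed)
    # permutation draw: shuffle column labels of the flattened observations
    col_labels = np.repeat(np.arange(table.shape[1]), cols)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(col_labels)
        perm = np.zeros_like(table)
        start = 0
        for i, nri in enumerate(rows):
            seg = col_labels[start : start + nri]
            perm[i] = np.bincount(seg, minlength=table.shape[1])
            start += nri
        if _log_table_prob(perm, lognorm) <= logp_obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return FisherResult(p=p, method="monte_carlo", mc_se=se)


def holm_adjust(pvals) -> list[float]:
    """Stepwise Holm–Bonferroni adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = min((m - i) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj.tolist()


def pairwise_comparison_table(
    study: CohortGenotypes,
    references: dict[str, CohortGenotypes],
    alpha: float = DEFAULT_ALPHA,
    family: str = "per_pair",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Frequency table with per-locus tests against each reference cohort.

    ``family`` selects the Holm adjustment family: ``per_pair`` adjusts the
    loci of each study-vs-reference column together (24 tests per column);
    ``global`` pools every test into one family.
    """
    if family not in ("per_pair", "global"):
        raise StatError(f"unknown Holm family {family!r}")
    log.info("Holm family: %s (the analysis convention; set explicitly)", family)
    freqs, _ = estimate_frequencies(study)
    out = freqs.df.rename(columns={"n": "n_study"}).copy()
    results: dict[str, list[TestResult]] = {}
    for name, ref in references.items():
        col = []
        for rsid in study.panel.rsids:
            c1 = genotype_counts(study, rsid)
            c2 = genotype_counts(ref, rsid)
            col.append(
                genotype_association_test(
                    c1, c2, rsid=rsid, pair=("study", name), seed=seed
                )
            )
        results[name] = col
    if family == "global":
        flat = [t for col in results.values() for t in col]
        adj = holm_adjust([t.p_raw for t in flat])
        for t, a in zip(flat, adj):
            t.finalize(a, alpha)
    else:
        for col in results.values():
            adj = holm_adjust([t.p_raw for t in col])
            for t, a in zip(col, adj):
                t.finalize(a, alpha)
    for name, col in results.items():
        out[f"p_vs_{name}"] = [t.p_adjusted for t in col]
        out[f"sig_vs_{name}"] = [t.significant for t in col]
        out[f"method_vs_{name}"] = [t.method for t in col]
    return out
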