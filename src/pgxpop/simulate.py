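"""Synthetic cohort generators.

Three generative layers, matching the statistical structure the downstream
analyses assume:

* :func:`sample_hwe_cohort` — unstructured cohort at fixed allele
  frequencies under Hardy–Weinberg equilibrium, loci independent.
* :func:`sample_balding_nichols` — structured reference populations whose
  per-population allele frequencies are Beta-drifted around ancestral
  values (drift parameter ``F``).
* :func:`sample_admixed` — individuals whose two allele copies per locus
  are drawn from a mixture over cluster frequencies with per-individual
  ancestry proportions ``Q``.

Loci are simulated independently except inside CYP2C9/CYP2C19/CYP2D6,
where :func:`sample_star_cohort` draws whole star-allele haplotypes and
expands them to SNP calls so that allele linkage internal to a star allele
(e.g. the rs1065852-A copy riding on every *4 haplotype) is respected.
:func:`sample_greek_style_cohort` combines both: star-structured CYP genes,
HWE everywhere else, marginal allele frequencies equal to the input table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import MISSING, CohortGenotypes
from .panel import FrequencyTable, PanelConfigError, PanelDefinition
from .star_alleles import (
    DEFAULT_ALLELE,
    StarAlleleDefinition,
    definition_rsids,
    expand_diplotype_to_calls,
    load_definitions,
)

DEFAULT_SEED = 42


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Reproducible simulation settings (fixed seed => identical output)."""

    seed: int = DEFAULT_SEED
    n_per_population: dict = field(default_factory=dict)
    drift: dict = field(default_factory=dict)  # population -> F in (0, 1)
    ancestry: np.ndarray | None = None  # Q for admixed draws

    def __post_init__(self) -> None:
        for pop, f in self.drift.items():
            if not (0.0 < f < 1.0):
                raise SimulationError(f"drift F for {pop} must be in (0, 1), got {f}")
        if self.ancestry is not None:
            q = np.asarray(self.ancestry, float)
            if np.abs(q.sum(axis=1) - 1.0).max() > 1e-9:
                raise SimulationError("rows of Q must sum to 1")


def _freq2_vector(freqs: FrequencyTable, population: str, panel: PanelDefinition):
    p = np.empty(len(panel))
    for j, v in enumerate(panel.variants):
        p[j] = freqs.freq2(population, v.rsid)  # raises naming the rsid if absent
    return p


def _hwe_genotypes(p2: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, L, 2) allele indices; each copy is allele_2 w.p. p2[l]."""
    if ((p2 < 0) | (p2 > 1)).any():
        raise SimulationError("allele frequencies must lie in [0, 1]")
    g = rng.random((n, len(p2), 2)) < p2[None, :, None]
    return np.sort(g.astype(np.int8), axis=2)


def sample_hwe_cohort(
    freqs: FrequencyTable,
    population: str,
    n: int,
    seed: int,
    panel: PanelDefinition,
) -> CohortGenotypes:
    """HWE cohort at the table's frequencies; loci independent."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p2 = _freq2_vector(freqs, population, panel)
    geno = _hwe_genotypes(p2, n, rng)
    return CohortGenotypes(
        panel=panel,
        samples=[f"{population}_{i:05d}" for i in range(n)],
        genotypes=geno,
        populations=np.array([population] * n, dtype=object),
    )


def balding_nichols_freqs(
    ancestral: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """One Beta(p(1-F)/F, (1-p)(1-F)/F) draw per locus."""
    ancestral = np.asarray(ancestral, float)
    if not (0.0 < F < 1.0):
        raise SimulationError(f"F must be strictly between 0 and 1, got {F}")
    if ((ancestral <= 0) | (ancestral >= 1)).any():
        raise SimulationError("ancestral frequencies must be in (0, 1)")
    a = ancestral * (1.0 - F) / F
    b = (1.0 - ancestral) * (1.0 - F) / F
    return rng.beta(a, b)


def sample_balding_nichols(
    ancestral_freqs: np.ndarray,
    F_per_pop: dict,
    n_per_pop: dict,
    seed: int,
    panel: PanelDefinition,
) -> CohortGenotypes:
    """Structured populations: one drifted frequency per (pop, locus), then HWE."""
    rng = np.random.default_rng(seed)
    parts = []
    for pop in F_per_pop:
        if pop not in n_per_pop:
            raise SimulationError(f"no sample size given for population {pop!r}")
        p_k = balding_nichols_freqs(ancestral_freqs, F_per_pop[pop], rng)
        n = int(n_per_pop[pop])
        geno = _hwe_genotypes(p_k, n, rng)
        parts.append(
            CohortGenotypes(
                panel=panel,
                samples=[f"{pop}_{i:05d}" for i in range(n)],
                genotypes=geno,
                populations=np.array([pop] * n, dtype=object),
            )
        )
    from .cohort import concat_cohorts

    return concat_cohorts(parts)


def sample_admixed(
    Q: np.ndarray,
    P: np.ndarray,
    seed: int,
    panel: PanelDefinition,
    sample_prefix: str = "ADM",
) -> CohortGenotypes:
    """Admixed individuals: each allele copy is allele_2 w.p. sum_k q_ik p_kl."""
    Q = np.asarray(Q, float)
    P = np.asarray(P, float)
    if Q.ndim != 2 or P.ndim != 2 or Q.shape[1] != P.shape[0]:
        raise SimulationError(
            f"shape mismatch: Q is {Q.shape}, P is {P.shape} (need Q n x K, P K x L)"
        )
    if P.shape[1] != len(panel):
        raise SimulationError("P column count must match panel size")
    if np.abs(Q.sum(axis=1) - 1.0).max() > 1e-9:
        raise SimulationError("rows of Q must sum to 1")
    if ((P < 0) | (P > 1)).any():
        raise SimulationError("P entries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mix = Q @ P  # (n, L) per-copy probability of allele_2
    g = rng.random((Q.shape[0], P.shape[1], 2)) < mix[:, :, None]
    return CohortGenotypes(
        panel=panel,
        samples=[f"{sample_prefix}_{i:05d}" for i in range(Q.shape[0])],
        genotypes=np.sort(g.astype(np.int8), axis=2),
        populations=None,
    )


def separated_cluster_frequencies(
    K: int, L: int, p_major: float = 0.98
) -> np.ndarray:
    """Strongly differentiated cluster allele frequencies for recovery tests.

    Each cluster gets an equal block of private loci near fixation for the
    counted allele (``p_major``) while the others sit at ``1 - p_major`` —
    the strong-drift limit of differentiated populations.  With only as
    many loci as this panel carries, ancestry proportions of fully admixed
    individuals are identifiable to better than ~0.08 mean absolute error
    only in this regime (weaker drift leaves even the Bayes-optimal
    estimator above it), so the recovery experiments standardize on it.
    """
    if K < 1 or L < K:
        raise SimulationError("need L >= K >= 1")
    P = np.full((K, L), 1.0 - p_major)
    block = L // K
    for k in range(K):
        P[k, k * block : (k + 1) * block] = p_major
    return P


# ---------------------------------------------------------------------------
# star-allele structured sampling


def star_allele_frequencies(
    freqs: FrequencyTable,
    population: str,
    definitions: list[StarAlleleDefinition],
) -> dict[str, float]:
    """Haplotype frequencies per star allele derived from SNP frequencies.

    Each named allele takes the frequency of its tag variant; alleles whose
    tag variant also rides on a higher-level allele (e.g. *10's rs1065852-A
    also carried by *4) get the difference.  The remaining mass is *1.
    """
    out: dict[str, float] = {}
    for d in definitions:
        if d.tag_rsid is None:
            raise PanelConfigError(f"{d.gene}{d.name}: no tag_rsid for derivation")
        tag_allele = d.defining_states[d.tag_rsid]
        p = freqs.allele_freq(population, d.tag_rsid, tag_allele)
        for other in definitions:
            if other.name == d.name:
                continue
            if other.defining_states.get(d.tag_rsid) == tag_allele and (
                other.tag_rsid != d.tag_rsid
            ):
                p -= freqs.allele_freq(
                    population, other.tag_rsid, other.defining_states[other.tag_rsid]
                )
        if p < -1e-9:
            raise PanelConfigError(
                f"derived negative frequency for {d.gene}{d.name}"
            )
        out[d.name] = max(p, 0.0)
    rest = 1.0 - sum(out.values())
    if rest < -1e-9:
        raise PanelConfigError(
            f"star-allele frequencies exceed 1 for {definitions[0].gene}"
        )
    out[DEFAULT_ALLELE] = max(rest, 0.0)
    return out


def sample_star_diplotypes(
    star_freqs: dict[str, float], n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Two independent star-allele haplotypes per individual (HWE)."""
    names = list(star_freqs)
    probs = np.asarray([star_freqs[k] for k in names], float)
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=(n, 2), p=probs)
    return [(names[a], names[b]) for a, b in draws]


def sample_star_cohort(
    gene: str,
    star_freqs: dict[str, float],
    n: int,
    seed: int,
    panel: PanelDefinition,
    definitions: list[StarAlleleDefinition],
    population: str = "Greek",
) -> tuple[CohortGenotypes, list[tuple[str, str]]]:
    """Cohort carrying genotypes only at ``gene``'s definition sites.

    Returns the cohort (non-gene loci MISSING) and the true sampled
    diplotypes, for recovery tests.
    """
    rng = np.random.default_rng(seed)
    diplos = sample_star_diplotypes(star_freqs, n, rng)
    geno = np.full((n, len(panel), 2), MISSING, dtype=np.int8)
    rsids = definition_rsids(definitions)
    cols = {rsid: panel.index_of(rsid) for rsid in rsids}
    allele_index = {
        rsid: {a: i for i, a in enumerate(panel.variant(rsid).alleles)}
        for rsid in rsids
    }
    for i, dip in enumerate(diplos):
        calls = expand_diplotype_to_calls(dip, definitions, panel)
        for rsid, (a, b) in calls.items():
            geno[i, cols[rsid], 0] = allele_index[rsid][a]
            geno[i, cols[rsid], 1] = allele_index[rsid][b]
    cohort = CohortGenotypes(
        panel=panel,
        samples=[f"{population}_{gene}_{i:05d}" for i in range(n)],
        genotypes=geno,
        populations=np.array([population] * n, dtype=object),
    )
    return cohort, diplos


def sample_greek_style_cohort(
    freqs: FrequencyTable,
    population: str,
    n: int,
    seed: int,
    panel: PanelDefinition,
    definitions: dict[str, list[StarAlleleDefinition]] | None = None,
) -> CohortGenotypes:
    """HWE cohort with star-allele haplotype structure inside the CYP genes.

    Marginal allele frequencies at every locus equal the input table; loci
    outside the star-allele definition sites are drawn independently.
    """
    if definitions is None:
        definitions = load_definitions()
    if n < 1:
        raise SimulationError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    ss = root.spawn(len(definitions) + 1)
    base = sample_hwe_cohort(
        freqs, population, n, int(ss[0].generate_state(1)[0] % 2**31), panel
    )
    geno = base.genotypes.copy()
    for k, (gene, defs) in enumerate(sorted(definitions.items())):
        sf = star_allele_frequencies(freqs, population, defs)
        gene_cohort, _ = sample_star_cohort(
            gene,
            sf,
            n,
            int(ss[k + 1].generate_state(1)[0] % 2**31),
            panel,
            defs,
            population=population,
        )
        for rsid in definition_rsids(defs):
            j = panel.index_of(rsid)
            geno[:, j, :] = gene_cohort.genotypes[:, j, :]
    return CohortGenotypes(
        panel=panel,
        samples=[f"{population}_{i:05d}" for i in range(n)],
        genotypes=geno,
        populations=np.array([population] * n, dtype=object),
    )
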