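"""In-memory genotype containers.

``CohortGenotypes`` stores unphased diploid calls as an ``(n, L, 2)`` int8
array of allele indices (0 = panel allele_1, 1 = allele_2, -1 = missing),
canonically sorted within each call so that allele order never carries
information.  ``DosageMatrix`` is the derived ``(n, L)`` count of allele_2
copies with ``MISSING = -1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelDefinition, PanelConfigError

MISSING = -1


class GenotypeError(ValueError):
    pass


def _canonicalize(geno: np.ndarray) -> np.ndarray:
    """Sort allele pairs; a call is missing iff both slots are -1."""
    geno = np.asarray(geno, dtype=np.int8)
    if geno.ndim != 3 or geno.shape[2] != 2:
        raise GenotypeError(f"genotype array must be (n, L, 2), got {geno.shape}")
    half_missing = (geno == MISSING).sum(axis=2) == 1
    if half_missing.any():
        raise GenotypeError("half-missing calls are not supported")
    return np.sort(geno, axis=2)


@dataclass
class CohortGenotypes:
    """Samples x panel loci unphased diploid calls with optional labels."""

    panel: PanelDefinition
    samples: list[str]
    genotypes: np.ndarray  # (n, L, 2) int8
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("sample ids must be unique")
        self.genotypes = _canonicalize(self.genotypes)
        n, L, _ = self.genotypes.shape
        if n != len(self.samples):
            raise GenotypeError("sample count mismatch")
        if L != len(self.panel):
            raise GenotypeError("locus count does not match panel")
        valid = np.isin(self.genotypes, (MISSING, 0, 1))
        if not valid.all():
            raise GenotypeError("allele indices must be 0, 1 or MISSING")
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
            if len(self.populations) != n:
                raise GenotypeError("population label count mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosage_matrix(self) -> "DosageMatrix":
        g = self.genotypes
        d = g.sum(axis=2, dtype=np.int16)
        d[(g[:, :, 0] == MISSING)] = MISSING
        return DosageMatrix(values=d, rsids=list(self.panel.rsids))

    def calls_for_gene(self, sample_index: int, rsids: list[str]) -> dict:
        """Unphased allele-string pairs for the given rsids; None if missing."""
        out: dict[str, tuple[str, str] | None] = {}
        for rsid in rsids:
            j = self.panel.index_of(rsid)
            a, b = self.genotypes[sample_index, j]
            if a == MISSING:
                out[rsid] = None
            else:
                alleles = self.panel.variants[j].alleles
                out[rsid] = (alleles[a], alleles[b])
        return out

    def subset(self, indices: np.ndarray | list[int]) -> "CohortGenotypes":
        indices = np.asarray(indices, dtype=int)
        return CohortGenotypes(
            panel=self.panel,
            samples=[self.samples[i] for i in indices],
            genotypes=self.genotypes[indices].copy(),
            populations=None
            if self.populations is None
            else self.populations[indices].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame of allele-string calls (diagnostics/IO)."""
        rows = []
        for i, s in enumerate(self.samples):
            for j, v in enumerate(self.panel.variants):
                a, b = self.genotypes[i, j]
                call = "./." if a == MISSING else f"{v.alleles[a]}/{v.alleles[b]}"
                rows.append((s, v.rsid, call))
        return pd.DataFrame(rows, columns=["sample", "rsid", "call"])


@dataclass
class DosageMatrix:
    """allele_2 copy counts, ``values[i, l]`` in {0, 1, 2, MISSING}."""

    values: np.ndarray
    rsids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.rsids):
            raise GenotypeError("dosage matrix shape does not match rsids")
        ok = np.isin(self.values, (MISSING, 0, 1, 2))
        if not ok.all():
            raise GenotypeError("dosages must be 0, 1, 2 or MISSING")


def concat_cohorts(cohorts: list[CohortGenotypes]) -> CohortGenotypes:
    """Stack cohorts over samples (shared panel required)."""
    if not cohorts:
        raise GenotypeError("need at least one cohort")
    panel = cohorts[0].panel
    for c in cohorts[1:]:
        if c.panel.rsids != panel.rsids:
            raise PanelConfigError("cohorts use different panels")
    pops = [
        c.populations
        if c.populations is not None
        else np.array([""] * c.n_samples, dtype=object)
        for c in cohorts
    ]
    return CohortGenotypes(
        panel=panel,
        samples=[s for c in cohorts for s in c.samples],
        genotypes=np.concatenate([c.genotypes for c in cohorts], axis=0),
        populations=np.concatenate(pops),
    )
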