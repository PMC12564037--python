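"""Panel metadata and per-population allele-frequency tables.

The panel is a fixed set of 24 biallelic assay sites spanning 13 CNS
pharmacogenes.  Deletion alleles are carried symbolically as ``"del"``
everywhere inside the package and only anchored to REF/ALT strings at the
VCF boundary (:mod:`pgxpop.vcfio`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

DELETION = "del"

FREQ_COLUMNS = ["population", "rsid", "allele_1", "freq_1", "allele_2", "freq_2", "n"]


class PanelConfigError(ValueError):
    """Raised for malformed panel / frequency inputs."""


@dataclass(frozen=True)
class VariantDef:
    """One biallelic assay site of the panel."""

    rsid: str
    gene: str
    allele_1: str
    allele_2: str
    chrom: str = "1"
    pos: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not self.allele_1 or not self.allele_2:
            raise PanelConfigError(
                f"{self.rsid}: alleles must be non-empty strings "
                "(encode deletions explicitly as 'del')"
            )
        if self.allele_1 == self.allele_2:
            raise PanelConfigError(f"{self.rsid}: alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_1, self.allele_2)


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of :class:`VariantDef` with unique rsIDs."""

    variants: tuple[VariantDef, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise PanelConfigError(f"duplicate rsIDs in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for v in self.variants:
            if v.gene not in seen:
                seen.append(v.gene)
        return seen

    def variant(self, rsid: str) -> VariantDef:
        try:
            return self._index()[rsid]
        except KeyError:
            raise PanelConfigError(f"rsid {rsid!r} not in panel") from None

    def _index(self) -> dict[str, VariantDef]:
        # tiny panel: rebuild on demand, frozen dataclass keeps no cache
        return {v.rsid: v for v in self.variants}

    def index_of(self, rsid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.rsid == rsid:
                return i
        raise PanelConfigError(f"rsid {rsid!r} not in panel")

    def gene_rsids(self, gene: str) -> list[str]:
        return [v.rsid for v in self.variants if v.gene == gene]

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        with open(path) as fh:
            raw = json.load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "PanelDefinition":
        variants = tuple(
            VariantDef(
                rsid=v["rsid"],
                gene=v["gene"],
                allele_1=v["allele_1"],
                allele_2=v["allele_2"],
                chrom=v.get("chrom", "1"),
                pos=int(v.get("pos", 0)),
                note=v.get("note", ""),
            )
            for v in raw["variants"]
        )
        return cls(variants=variants, name=raw.get("name", "panel"))


def load_panel() -> PanelDefinition:
    """Load the bundled 24-variant CNS panel."""
    raw = json.loads(
        resources.files("pgxpop.data").joinpath("panel.json").read_text()
    )
    panel = PanelDefinition._from_dict(raw)
    if len(panel) != 24:
        raise PanelConfigError(
            f"bundled panel must contain 24 variants, found {len(panel)}"
        )
    return panel


class FrequencyTable:
    """Per-(population, rsid) allele frequencies with diploid sample sizes.

    Backed by a DataFrame with columns
    ``population, rsid, allele_1, freq_1, allele_2, freq_2, n``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FREQ_COLUMNS if c not in df.columns]
        if missing:
            raise PanelConfigError(f"frequency table missing columns: {missing}")
        df = df[FREQ_COLUMNS].copy()
        bad = df[(df["freq_1"] + df["freq_2"] - 1.0).abs() > 1e-9]
        if not bad.empty:
            raise PanelConfigError(
                "per-locus frequencies must sum to 1: "
                + ", ".join(bad["rsid"].astype(str))
            )
        if ((df["freq_1"] < 0) | (df["freq_1"] > 1)).any() or (
            (df["freq_2"] < 0) | (df["freq_2"] > 1)
        ).any():
            raise PanelConfigError("frequencies must lie in [0, 1]")
        if (df["n"] <= 0).any():
            raise PanelConfigError("sample sizes must be positive")
        self.df = df.reset_index(drop=True)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population"]))

    def row(self, population: str, rsid: str) -> pd.Series:
        sel = self.df[(self.df["population"] == population) & (self.df["rsid"] == rsid)]
        if sel.empty:
            raise PanelConfigError(
                f"no frequency for rsid {rsid!r} in population {population!r}"
            )
        return sel.iloc[0]

    def allele_freq(self, population: str, rsid: str, allele: str) -> float:
        row = self.row(population, rsid)
        if allele == row["allele_1"]:
            return float(row["freq_1"])
        if allele == row["allele_2"]:
            return float(row["freq_2"])
        raise PanelConfigError(f"allele {allele!r} unknown at {rsid}")

    def freq2(self, population: str, rsid: str) -> float:
        """Frequency of the panel's allele_2 (the dosage-counted allele)."""
        return float(self.row(population, rsid)["freq_2"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FrequencyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def load_greek_frequencies() -> FrequencyTable:
    """Bundled Greek-cohort allele frequencies (n = 3011 diploids)."""
    with resources.as_file(
        resources.files("pgxpop.data").joinpath("greek_frequencies.tsv")
    ) as p:
        return FrequencyTable.read_tsv(p)
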