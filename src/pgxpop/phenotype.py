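"""Diplotype-to-metabolizer-phenotype translation.

A :class:`PhenotypeRuleTable` carries per-allele activity values plus one
of two classification modes:

* ``score_interval`` — the activity score (sum of the two allele values)
  falls into ordered intervals mapping to PM/IM/NM/RM/UM;
* ``class_pair`` — the unordered pair of allele function classes maps
  directly to a phenotype (how CYP2C19 *1/*17 -> RM style rules are
  expressed).

Explicit diplotype overrides, when present, win over both modes.  The
tables are data, not code: the default ``bundled`` set reproduces the
population phenotype distributions the HWE model implies at the bundled
Greek frequencies, and a stricter activity-score variant (``cpic_strict``)
ships alongside for sensitivity runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .star_alleles import Diplotype

PHENOTYPE_ORDER = ("PM", "IM", "NM", "RM", "UM")


class RuleTableError(ValueError):
    pass


@dataclass
class PhenotypeRuleTable:
    gene: str
    activity: dict[str, float]
    mode: str  # "score_interval" | "class_pair"
    intervals: list[dict] = field(default_factory=list)
    classes: dict[str, str] = field(default_factory=dict)
    pairs: dict[str, str] = field(default_factory=dict)
    overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("score_interval", "class_pair"):
            raise RuleTableError(f"unknown rule mode {self.mode!r}")
        if self.mode == "score_interval":
            maxes = [iv["max"] for iv in self.intervals]
            if maxes != sorted(maxes):
                raise RuleTableError(f"{self.gene}: interval bounds must ascend")
            top = max(self.activity.values()) * 2
            if maxes and maxes[-1] < top - 1e-12:
                raise RuleTableError(
                    f"{self.gene}: intervals do not cover the top score {top}"
                )
        for ph in list(self.pairs.values()) + [
            iv["phenotype"] for iv in self.intervals
        ]:
            if ph not in PHENOTYPE_ORDER:
                raise RuleTableError(f"unknown phenotype {ph!r}")


def load_rule_tables(name: str = "bundled") -> dict[str, PhenotypeRuleTable]:
    raw = json.loads(
        resources.files("pgxpop.data").joinpath("phenotype_rules.json").read_text()
    )
    try:
        tables = raw["tables"][name]
    except KeyError:
        raise RuleTableError(
            f"no rule-table set named {name!r}; available: "
            f"{sorted(raw['tables'])}"
        ) from None
    out = {}
    for gene, t in tables.items():
        out[gene] = PhenotypeRuleTable(
            gene=gene,
            activity={k: float(v) for k, v in t["activity"].items()},
            mode=t["mode"],
            intervals=t.get("intervals", []),
            classes=t.get("classes", {}),
            pairs=t.get("pairs", {}),
            overrides=t.get("overrides", {}),
        )
    return out


def activity_score(diplotype: Diplotype, table: PhenotypeRuleTable) -> float:
    """Sum of the two alleles' activity values (symmetric in order)."""
    total = 0.0
    for allele in diplotype.alleles:
        if allele not in table.activity:
            raise RuleTableError(
                f"allele {allele!r} unknown to the {table.gene} rule table"
            )
        total += table.activity[allele]
    return total


def classify_phenotype(diplotype: Diplotype, table: PhenotypeRuleTable) -> str:
    """Phenotype label; overrides first, then the table's mode. Total."""
    key = diplotype.name
    if key in table.overrides:
        return table.overrides[key]
    if table.mode == "class_pair":
        try:
            cls = sorted(table.classes[a] for a in diplotype.alleles)
        except KeyError as e:
            raise RuleTableError(
                f"allele {e.args[0]!r} has no function class for {table.gene}"
            ) from None
        pair = "|".join(cls)
        if pair not in table.pairs:
            raise RuleTableError(f"{table.gene}: no rule for class pair {pair}")
        return table.pairs[pair]
    score = activity_score(diplotype, table)
    for iv in table.intervals:
        upper = iv["max"]
        if score < upper or (iv.get("inclusive", True) and score <= upper + 1e-12):
            return iv["phenotype"]
    raise RuleTableError(f"{table.gene}: score {score} exceeds all intervals")


def summarize_cohort_phenotypes(
    diplotypes: dict,
    tables: dict[str, PhenotypeRuleTable],
) -> pd.DataFrame:
    """Per-gene phenotype distribution over classified samples.

    ``diplotypes`` maps ``(sample, gene) -> Diplotype`` (as produced by
    :func:`pgxpop.star_alleles.call_cohort` via ``df.attrs``).  Percentages
    are over all classified samples per gene and sum to 100; the ambiguous
    count is carried per phenotype row for separate reporting.
    """
    if not diplotypes:
        raise RuleTableError("empty cohort: nothing to summarize")
    rows = []
    by_gene: dict[str, list[Diplotype]] = {}
    for (_, gene), dip in diplotypes.items():
        by_gene.setdefault(gene, []).append(dip)
    for gene, dips in sorted(by_gene.items()):
        table = tables[gene]
        counts = {ph: 0 for ph in PHENOTYPE_ORDER}
        ambiguous = 0
        for dip in dips:
            counts[classify_phenotype(dip, table)] += 1
            ambiguous += bool(dip.ambiguous)
        total = len(dips)
        for ph in PHENOTYPE_ORDER:
            rows.append(
                (
                    gene,
                    ph,
                    counts[ph],
                    100.0 * counts[ph] / total,
                    ambiguous,
                    total,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "phenotype", "count", "percent", "ambiguous_calls", "n"],
    )
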