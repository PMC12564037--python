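"""Diplotype caller: worked examples, exhaustive-oracle equivalence,
round-trip recovery of simulated haplotypes, and order invariance."""

import itertools

import numpy as np
import pytest

from pgxpop import call_star_diplotype, sample_star_cohort, star_allele_frequencies
from pgxpop.star_alleles import (
    DEFAULT_ALLELE,
    _CLASS_RANK,
    default_allele,
    definition_rsids,
    expand_diplotype_to_calls,
    reference_allele_map,
)


def genotype_options(variant):
    """The three unphased genotypes of a biallelic site."""
    a1, a2 = variant.alleles
    return [(a1, a1), (a1, a2), (a2, a2)]


def _reference_calls(gene, definitions, panel):
    """All definition sites homozygous for the reference allele."""
    ref = reference_allele_map(definitions, panel)
    return {rsid: (a, a) for rsid, a in ref.items()}


class TestWorkedExamples:
    def test_cyp2c9_compound_het(self, definitions):
        dip = call_star_diplotype(
            "CYP2C9",
            {"rs1799853": ("C", "T"), "rs1057910": ("A", "C")},
            definitions["CYP2C9"],
        )
        assert dip.name == "*2/*3" and not dip.ambiguous

    def test_cyp2d6_star4_star10_shared_variant(self, panel, definitions):
        # one rs1065852-A copy is consumed by *4; the leftover A without a
        # rs3892097-T partner is *10
        calls = _reference_calls("CYP2D6", definitions["CYP2D6"], panel)
        calls["rs3892097"] = ("C", "T")
        calls["rs1065852"] = ("A", "A")
        dip = call_star_diplotype("CYP2D6", calls, definitions["CYP2D6"])
        assert dip.name == "*4/*10" and not dip.ambiguous

    def test_all_reference_is_default_diplotype(self, panel, definitions):
        for gene in ("CYP2C9", "CYP2C19", "CYP2D6"):
            calls = _reference_calls(gene, definitions[gene], panel)
            dip = call_star_diplotype(gene, calls, definitions[gene])
            assert dip.name == "*1/*1" and not dip.ambiguous

    def test_cyp2c19_unassignable_star17_flagged(self, panel, definitions):
        # homozygous *2 leaves the *17 T copy without a haplotype to sit on
        calls = _reference_calls("CYP2C19", definitions["CYP2C19"], panel)
        calls["rs4244285"] = ("A", "A")
        calls["rs12248560"] = ("C", "T")
        dip = call_star_diplotype("CYP2C19", calls, definitions["CYP2C19"])
        assert dip.name == "*2/*2"
        assert dip.ambiguous
        assert "rs12248560" in dip.unresolved_variants

    def test_missing_defining_site_flags_ambiguity(self, panel, definitions):
        calls = _reference_calls("CYP2D6", definitions["CYP2D6"], panel)
        calls["rs1065852"] = None
        dip = call_star_diplotype("CYP2D6", calls, definitions["CYP2D6"])
        assert dip.ambiguous
        assert "rs1065852" in dip.unresolved_variants


def _oracle_call(gene, calls, definitions, panel):
    """Brute-force search over all unordered pairs of definitions.

    A pair is feasible when the variant copies it implies are contained in
    the observed genotypes site by site; among feasible pairs the winner
    minimizes the sorted (function-class rank, table order) key pair —
    i.e. strongest-precedence assignment first — mirroring no-function >
    decreased > default resolution.  Returns (sorted names, leftover rsids).
    """
    defs = list(definitions)
    variant_allele = {
        rsid: req for d in defs for rsid, req in d.defining_states.items()
    }
    observed = {
        rsid: sum(1 for x in calls[rsid] if x == variant_allele[rsid])
        for rsid in definition_rsids(defs)
    }
    cands = defs + [default_allele(gene)]
    rank = {}
    for i, d in enumerate(defs):
        rank[d.name] = (_CLASS_RANK[d.function_class], i)
    rank[DEFAULT_ALLELE] = (99, 99)
    best_key, best = None, None
    for a, b in itertools.combinations_with_replacement(cands, 2):
        implied: dict[str, int] = {}
        for d in (a, b):
            for rsid in d.defining_states:
                implied[rsid] = implied.get(rsid, 0) + 1
        if any(implied.get(r, 0) > observed[r] for r in observed):
            continue
        leftover = sorted(
            r for r in observed if observed[r] - implied.get(r, 0) > 0
        )
        key = tuple(sorted((rank[a.name], rank[b.name])))
        if best_key is None or key < best_key:
            best_key = key
            best = (tuple(sorted((a.name, b.name))), leftover)
    assert best is not None  # (*1, *1) is always feasible
    return best


@pytest.mark.parametrize("gene", ["CYP2C9", "CYP2C19", "CYP2D6"])
def test_greedy_equals_exhaustive_enumeration(gene, panel, definitions):
    """All 3^L genotype inputs per gene agree with the brute-force oracle."""
    defs = definitions[gene]
    rsids = definition_rsids(defs)
    options = [genotype_options(panel.variant(r)) for r in rsids]
    n_checked = 0
    for combo in itertools.product(*options):
        calls = dict(zip(rsids, combo))
        dip = call_star_diplotype(gene, calls, defs)
        names, leftover = _oracle_call(gene, calls, defs, panel)
        assert tuple(sorted(dip.alleles)) == tuple(sorted(names)), calls
        assert dip.unresolved_variants == leftover, calls
        assert dip.ambiguous == bool(leftover)
        n_checked += 1
    assert n_checked == 3 ** len(rsids)


@pytest.mark.parametrize("gene", ["CYP2C9", "CYP2C19", "CYP2D6"])
def test_round_trip_recovers_every_diplotype(gene, panel, definitions):
    """Expand each diplotype of the bundled catalog to genotypes, re-call,
    recover exactly; with these definitions every pair is identifiable."""
    defs = definitions[gene]
    names = [d.name for d in defs] + [DEFAULT_ALLELE]
    for pair in itertools.combinations_with_replacement(sorted(names), 2):
        calls = expand_diplotype_to_calls(pair, defs, panel)
        dip = call_star_diplotype(gene, calls, defs)
        assert tuple(sorted(dip.alleles)) == tuple(sorted(pair))
        assert not dip.ambiguous


def test_allele_order_within_call_is_irrelevant(panel, definitions, rng):
    gene = "CYP2D6"
    defs = definitions[gene]
    rsids = definition_rsids(defs)
    options = [genotype_options(panel.variant(r)) for r in rsids]
    for _ in range(200):
        combo = [opts[rng.integers(3)] for opts in options]
        calls = dict(zip(rsids, combo))
        flipped = {r: (b, a) for r, (a, b) in calls.items()}
        d1 = call_star_diplotype(gene, calls, defs)
        d2 = call_star_diplotype(gene, flipped, defs)
        assert d1.alleles == d2.alleles
        assert d1.unresolved_variants == d2.unresolved_variants


def test_sampled_cohort_recalls_true_diplotypes(panel, greek_freqs, definitions):
    gene = "CYP2D6"
    sf = star_allele_frequencies(greek_freqs, "Greek", definitions[gene])
    cohort, truth = sample_star_cohort(gene, sf, 500, 31, panel, definitions[gene])
    rsids = definition_rsids(definitions[gene])
    for i, true_pair in enumerate(truth):
        calls = cohort.calls_for_gene(i, rsids)
        dip = call_star_diplotype(gene, calls, definitions[gene])
        assert tuple(sorted(dip.alleles)) == tuple(sorted(true_pair))
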