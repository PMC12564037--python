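"""VCF v4.2 serialization of panel genotypes (pysam-backed).

Panel allele_1 maps to REF and allele_2 to ALT.  Symbolic deletion alleles
(``"del"``) are anchored per VCF convention: REF = anchor base + retained
allele, ALT = anchor base, so a T/del site becomes REF ``AT`` / ALT ``A``.
Unphased calls are written with ``/`` and missing calls as ``./.``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pysam

from .cohort import MISSING, CohortGenotypes
from .panel import DELETION, PanelDefinition

log = logging.getLogger(__name__)

_ANCHOR = "A"


class VcfFormatError(ValueError):
    pass


def _vcf_alleles(variant) -> tuple[str, str]:
    """(REF, ALT) strings for a panel variant, anchoring deletions."""
    a1, a2 = variant.allele_1, variant.allele_2
    if a1 == DELETION:
        return (_ANCHOR, _ANCHOR + a2)
    if a2 == DELETION:
        return (_ANCHOR + a1, _ANCHOR)
    return (a1, a2)


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as an uncompressed VCF v4.2 with GT fields."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    contigs = sorted({v.chrom for v in cohort.panel.variants})
    for c in contigs:
        header.add_line(f"##contig=<ID={c},length=10000000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in cohort.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(cohort.panel.variants):
            ref, alt = _vcf_alleles(v)
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(ref, alt), id=v.rsid
            )
            for i, s in enumerate(cohort.samples):
                a, b = cohort.genotypes[i, j]
                if a == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (int(a), int(b))
                rec.samples[s].phased = False
            out.write(rec)


def read_vcf(path: str | Path, panel: PanelDefinition) -> CohortGenotypes:
    """Read GT calls for panel loci; unknown rsIDs are skipped with a warning.

    Loci absent from the file come back MISSING for every sample.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n, L = len(samples), len(panel)
        geno = np.full((n, L, 2), MISSING, dtype=np.int8)
        panel_rsids = set(panel.rsids)
        for rec in vf:
            rsid = rec.id
            if rsid is None or rsid not in panel_rsids:
                msg = f"skipping record {rsid!r} at {rec.chrom}:{rec.pos}: not in panel"
                log.warning(msg)
                warnings.warn(msg)
                continue
            j = panel.index_of(rsid)
            expected = _vcf_alleles(panel.variant(rsid))
            if tuple(rec.alleles) != expected:
                raise VcfFormatError(
                    f"line for {rsid}: alleles {rec.alleles} do not match the "
                    f"panel encoding {expected}"
                )
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(x is None for x in gt):
                    continue  # stays MISSING
                if len(gt) != 2 or any(x not in (0, 1) for x in gt):
                    raise VcfFormatError(
                        f"malformed GT {gt!r} for sample {s} at {rsid}"
                    )
                geno[i, j, 0], geno[i, j, 1] = gt
    return CohortGenotypes(panel=panel, samples=samples, genotypes=geno)
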