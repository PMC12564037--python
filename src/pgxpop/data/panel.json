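{
  "name": "PGx-CNS-24",
  "coordinates": "synthetic",
  "comment": "24-SNP CNS pharmacogene panel. Gene labels follow the source panel's annotation. Chrom/pos are synthetic placeholder coordinates used only for VCF serialization; alleles are the panel's two assay alleles with deletions encoded symbolically as 'del'.",
  "variants": [
    {"rsid": "rs1799853",  "gene": "CYP2C9",  "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 1000},
    {"rsid": "rs28371725", "gene": "CYP2D6",  "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 2000},
    {"rsid": "rs2832407",  "gene": "GRIK1",   "allele_1": "A",     "allele_2": "C",   "chrom": "1", "pos": 3000},
    {"rsid": "rs1414334",  "gene": "CYP2D6",  "allele_1": "C",     "allele_2": "G",   "chrom": "1", "pos": 4000,
     "note": "gene label follows the panel annotation; this variant is conventionally assigned to HTR2C"},
    {"rsid": "rs1065852",  "gene": "CYP2D6",  "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 5000,
     "note": "panel lists A as allele_1 (20.0%); A is the *10/*4-linked variant allele, G the reference"},
    {"rsid": "rs35742686", "gene": "CYP2D6",  "allele_1": "T",     "allele_2": "del", "chrom": "1", "pos": 6000},
    {"rsid": "rs28399504", "gene": "CYP2C19", "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 7000},
    {"rsid": "rs4244285",  "gene": "CYP2C19", "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 8000,
     "note": "panel lists A as allele_1 (13.6%); A is the *2 no-function allele, G the reference"},
    {"rsid": "rs5030656",  "gene": "CYP2D6",  "allele_1": "CTTCT", "allele_2": "CT",  "chrom": "1", "pos": 9000},
    {"rsid": "rs1799978",  "gene": "DRD2",    "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 10000},
    {"rsid": "rs4713916",  "gene": "FKBP5",   "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 11000},
    {"rsid": "rs5030655",  "gene": "CYP2D6",  "allele_1": "A",     "allele_2": "del", "chrom": "1", "pos": 12000},
    {"rsid": "rs3892097",  "gene": "CYP2D6",  "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 13000},
    {"rsid": "rs4986893",  "gene": "CYP2C19", "allele_1": "G",     "allele_2": "A",   "chrom": "1", "pos": 14000},
    {"rsid": "rs2234922",  "gene": "EPHX1",   "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 15000},
    {"rsid": "rs1051740",  "gene": "EPHX1",   "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 16000},
    {"rsid": "rs489693",   "gene": "MC4R",    "allele_1": "A",     "allele_2": "C",   "chrom": "1", "pos": 17000},
    {"rsid": "rs12248560", "gene": "CYP2C19", "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 18000},
    {"rsid": "rs7668258",  "gene": "UGT2B7",  "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 19000},
    {"rsid": "rs3812718",  "gene": "SCN1A",   "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 20000},
    {"rsid": "rs1057910",  "gene": "CYP2C9",  "allele_1": "A",     "allele_2": "C",   "chrom": "1", "pos": 21000},
    {"rsid": "rs963468",   "gene": "DRD3",    "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 22000},
    {"rsid": "rs1800497",  "gene": "ANKK1",   "allele_1": "A",     "allele_2": "G",   "chrom": "1", "pos": 23000},
    {"rsid": "rs17782313", "gene": "MC4R",    "allele_1": "C",     "allele_2": "T",   "chrom": "1", "pos": 24000}
  ]
}
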