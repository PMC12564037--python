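# Methods

This note records the models implemented in `pgxpop`, the assumptions
behind the synthetic-data generators, the defaults that matter, and the
design choices made where more than one reasonable construction exists.

## Panel and data model

The unit of analysis is a fixed panel of 24 biallelic assay sites across
13 CNS-relevant pharmacogenes (`pgxpop/data/panel.json`).  Alleles are the
two assay alleles as strings; deletion alleles are symbolic (`"del"`)
everywhere in memory and are anchored to REF/ALT strings only at the VCF
boundary (REF = anchor base + retained allele).  Chromosome/position
fields are synthetic placeholders used solely to produce well-formed VCF;
they are not genomic coordinates.  One panel site (rs1414334) is labeled
CYP2D6 following the source panel's annotation although it is
conventionally an HTR2C variant; the label has no effect on calling
because the site defines no star allele.

Genotypes are unphased diploid calls stored as sorted allele-index pairs
(`(n, L, 2)` int8, −1 = missing); the derived dosage matrix counts copies
of the panel's `allele_2`.  Frequency tables are per-(population, rsid)
rows with both allele frequencies and the diploid sample size; the
bundled Greek table carries the cohort frequencies at n = 3011.

## Synthetic cohorts

Three generators produce the structures the analyses assume:

* **HWE cohort** — each of the 2n allele copies per locus is the counted
  allele independently with probability p; loci independent.
* **Balding–Nichols references** — per population k and locus l a single
  frequency is drawn from Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) around the
  ancestral p, then HWE genotypes are drawn at it.  E[p_kl] = p and
  Var[p_kl] = F_k·p(1−p), so F_k is the expected differentiation of that
  population from the ancestral pool.
* **Admixed individuals** — given ancestry proportions Q (rows sum to 1)
  and cluster frequencies P, each allele copy is the counted allele with
  probability Σ_k q_ik p_kl.

Inside CYP2C9, CYP2C19 and CYP2D6 loci are *not* independent: the cohort
generator draws two star-allele haplotypes per individual from haplotype
frequencies derived from the SNP table (each named allele takes its tag
variant's frequency; alleles whose tag also rides on a higher-precedence
allele take the difference — e.g. CYP2D6\*10 = f(rs1065852-A) − f(\*4) =
0.200 − 0.164 = 0.036) and expands them to SNP genotypes.  This preserves
the within-haplotype linkage that star-allele definitions require
(rs1065852-A always accompanies rs3892097-T on a \*4 haplotype) while
leaving every marginal SNP frequency equal to the input table.  Linkage
between genes, and any linkage not forced by a star-allele definition, is
not simulated.

Consequences for interpretation: passing tests demonstrate that the
algorithms are correct under HWE with star-allele haplotype structure and
Beta-drifted differentiation.  They do not demonstrate robustness to
features the generator omits — background LD, genotyping error,
Hardy–Weinberg departure, CYP2D6 copy-number variation, or X-linked
dosage (rs1414334 is treated as autosomal diploid).

## Star-allele calling

Definitions (`pgxpop/data/star_alleles.json`) are the standard catalog
restricted to the panel's sites: CYP2C9 \*2/\*3; CYP2C19 \*2/\*3/\*4/\*17;
CYP2D6 \*3/\*4/\*6/\*9/\*41/\*10, with \*4 carrying rs1065852-A as a
linked secondary state and \*10 defined by rs1065852-A alone.  The tables
are data, not code, and editable.

Calling is greedy: observed variant-allele copies are consumed by
definitions in function-class precedence order (no-function > decreased >
increased > default \*1), at most one named allele per haplotype slot.
The greedy order makes \*4-vs-\*10 resolution deterministic: one
rs3892097-T plus two rs1065852-A copies yields \*4/\*10.  The test suite
proves by exhaustive enumeration (all 3^L genotype inputs per gene) that
the greedy result coincides with brute-force search over all unordered
definition pairs, preferring strongest precedence.

Genotype configurations that no two-haplotype assignment explains (e.g.
a \*17 variant copy on a homozygous \*2 background) return the best
assignment with `ambiguous=True` and the unexplained rsids listed, rather
than raising — honest flagging was preferred over hard failure because
such patterns arise in real panel data through rare recombinant
haplotypes or genotyping error.  Missing defining sites likewise flag the
call; a missing site never vetoes an otherwise consistent assignment
(permissive interpretation), which keeps calls available at the cost of
marking them ambiguous.  Exceptions are reserved for malformed input
(alleles foreign to the panel).

## Phenotype translation

Rule tables (`pgxpop/data/phenotype_rules.json`) carry per-allele
activity values and one of two total classification modes: activity-score
intervals (CYP2D6: 0 → PM, (0, 1] → IM, (1, 2.25] → NM; no UM is
reachable without gene duplications, which the panel cannot see) or
function-class pair rules (CYP2C19: two no-function → PM, one no-function
→ IM, \*1/\*1 → NM, \*1/\*17 → RM, \*17/\*17 → UM; CYP2C9: \*1/\*1 → NM,
one reduced allele → IM, two → PM).  The default `bundled` CYP2C9 rule
treats \*2 and \*3 symmetrically as "reduced" because under HWE at the
bundled frequencies that rule reproduces the cohort's reported PM
fraction ((0.144 + 0.094)² ≈ 5.7%), where strict activity-score
classification would give ≈3.6%; the strict variant ships as
`cpic_strict` for sensitivity runs.  Classification is total over every
constructible diplotype (exhaustively tested), and monotone: substituting
a lower-activity allele never moves a score-interval phenotype toward
faster metabolism.

## Association testing

Interpopulation comparisons use the 2×3 genotype-count table per locus:
Pearson chi-square without continuity correction (all-zero genotype
columns dropped, df reduced accordingly), switching to the exact test of
independence when any expected cell is zero or more than 80% of expected
cells are below five.  The 80% threshold is deliberately looser than the
conventional 20% rule and is configurable (`fallback_fraction`).  The
exact test enumerates all tables with the observed margins (two-sided by
probability ordering) up to a configurable bound, beyond which a seeded
Monte-Carlo permutation p-value with standard error is substituted; an
unseeded request past the bound is an error, never a silent fallback.
Holm–Bonferroni adjustment is applied per study-vs-reference column of
loci by default (the table-column family); a pooled global family is
available, and the choice is logged because the family convention
materially changes adjusted values.  Significance is declared at adjusted
p < 0.01.

## Differentiation

Hudson's estimator with finite-sample numerator correction is the
headline statistic; Weir–Cockerham θ is computed alongside from the
a/b/c variance components and cross-checked in the tests against an
independently coded nested-ANOVA derivation to 1e-10.  Negative estimates
are reported as computed (flagged, not clipped) so that multi-locus
averages stay unbiased; multi-locus summaries combine loci as the ratio
of summed numerators to summed denominators.  A simulation oracle run
before the estimator tests were frozen showed that for two populations
each drifted F from a common ancestor this ratio-of-sums converges to F,
whereas the mean of per-locus ratios is biased low by roughly 10–15%
(Jensen's inequality); the invariant tests therefore pin the ratio-of-sums
to F within 20%.

## Structure analysis

Dosages are Patterson-scaled (mean-imputation of missing entries,
centering by 2p̂, division by √(p̂(1−p̂))); monomorphic loci are dropped
and recorded.  PCA is a deterministic SVD with a fixed sign convention
(largest-magnitude loading positive).  K-means (k-means++, 10 restarts,
seeded) and the silhouette/ARI/NMI evaluations run on the first two
components — consistent with the 2-D space in which the clusters are
reported — via scikit-learn; the NMI normalizer defaults to the
arithmetic mean of the entropies and is selectable.  Published
silhouette/ARI/NMI values for the real cohort are not reproducible from
synthetic data, so the suite tests the qualitative claim instead: on a
three-population Balding–Nichols simulation (drift 0.05/0.15/0.30,
~500 samples each, 24 loci) K = 3 clustering assigns ≥90% of the
high-drift population to a single cluster.

## Admixture inference

EM is the default backend: standard multiplicative updates, monotone in
the log-likelihood (asserted on every run), with responsibilities
computed separately for variant and reference copies, optional restarts,
and a supervised mode that pins labeled individuals' Q rows to anchor
cluster identities.  The Gibbs sampler augments with per-copy origins Z,
draws P | Z from Beta(1 + variant, 1 + reference) and Q | Z from
Dirichlet(α + counts) with α fixed at 1.0 (configurable; the sampler does
not infer it), and reports posterior means after burn-in.  Production
defaults are burn-in 10,000 / 50,000 sweeps; tests use a 1,000 / 5,000
profile.  Cluster labels are arbitrary, so estimates are aligned to a
reference by greedy correlation matching before any comparison; mean
per-cluster divergence is reported as expected heterozygosity
(1/L) Σ 2p(1−p).

The Q-recovery experiment (K = 3, n = 300, L = 24, Q ~ Dirichlet(1,1,1))
uses strongly separated cluster frequencies: each cluster owns an equal
block of private loci near fixation (0.98/0.02,
`simulate.separated_cluster_frequencies`).  An importance-sampling oracle
showed that with Beta-drifted P — even at F = 0.8 — the Bayes-optimal
posterior mean already exceeds 0.087 mean absolute error on Q, so no
estimator can do better there; with the separated design the information
floor drops to ≈0.066 and the EM/Gibbs fits reach ≈0.07.  A 24-locus
panel simply cannot resolve fine-grained ancestry of fully admixed
individuals; it can resolve strongly differentiated ancestry, and the
experiment tests exactly that regime.

## Pipeline

`run_pipeline` chains simulate → call → classify → compare → F_ST →
PCA/K-means → admixture and writes TSV artifacts plus a manifest
sufficient to reproduce the run (config echo, seed, version, artifact
list); reruns with the same config are byte-identical.  Defaults mirror
the study design: study cohort n = 3011, references 503/662/504, a
500-sample study subsample for the structure stages to match reference
volumes, K ∈ {3, 4}, α = 0.01.  Reference cohorts are Balding–Nichols
draws around the study frequencies with drifts EUR 0.01, EAS 0.10, AFR
0.15 — chosen once to mimic near-identity of the closest reference and
progressively stronger continental differentiation; real reference-panel
genotypes are deliberately out of scope.  All randomness flows from a
single root seed (default 42) through `numpy.random.SeedSequence` spawns.

## Numerical choices and degenerate inputs

* Frequencies validated to sum to 1 within 1e-9; Q rows to 1 within 1e-9
  (1e-6 on estimates).
* EM clamps P to [1e-9, 1−1e-9] to keep the likelihood finite; an empty
  cluster is reseeded from a random individual and logged.
* A mixture probability of exactly zero against a nonzero count makes the
  log-likelihood −inf (logged sentinel), not an exception.
* Co-monomorphic loci make both F_ST estimators undefined (NaN marker),
  never zero.
* The exact test returns p = 1 for tables with a zero margin (single
  attainable table).
* Silhouette uses the convention that singleton clusters score 0; a
  single-cluster partition is an error.
* PCA reports fewer components with a warning when rank falls short.

## Known limitations

Star-allele coverage is limited to panel-visible alleles, so phenotype
fractions are panel-relative (CYP2D6 UM is invisible without CNV data).
The generator's HWE and independence assumptions make the synthetic
cohort cleaner than real data; association-test and F_ST behavior under
genotyping artifacts is untested.  Printed per-locus p-values and
clustering-quality metrics of the original cohort depend on proprietary
genotypes and real reference panels and are checked only qualitatively.
Multi-run Gibbs alignment uses greedy correlation matching, not a full
label-switching posterior treatment.
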