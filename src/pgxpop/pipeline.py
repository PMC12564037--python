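"""End-to-end analysis pipeline.

One seeded run simulates the study cohort and structured reference
populations, then exercises every analysis stage and writes its artifacts
to an output directory:

* ``frequency_comparison.tsv`` — per-locus frequencies with Holm-adjusted
  interpopulation tests (one column per reference population);
* ``phenotypes_<gene>.tsv`` — predicted metabolizer distributions;
* ``fst_matrix.tsv`` — per-locus Hudson / Weir–Cockerham estimates per pair;
* ``pca_scores.tsv`` / ``pca_loadings.tsv`` — structure analysis exports;
* ``cluster_eval.tsv`` — K-means evaluation (silhouette/ARI/NMI) per K;
* ``admixture_Q.tsv`` — ancestry proportions with cluster divergences;
* ``manifest.json`` — config, seed and artifact list; sufficient to rerun.

Reference cohorts are simulated with Balding–Nichols drift around the
study frequencies (real continental reference genotypes are out of scope),
with per-population drift defaults chosen to mimic near-identity of the
European references and progressively stronger differentiation of the East
Asian and African ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import em_fit, gibbs_fit
from .cohort import CohortGenotypes, concat_cohorts
from .fst import pairwise_fst_table
from .panel import load_greek_frequencies, load_panel
from .phenotype import load_rule_tables, summarize_cohort_phenotypes
from .popstats import pairwise_comparison_table
from .simulate import (
    DEFAULT_SEED,
    SimulationError,
    sample_balding_nichols,
    sample_greek_style_cohort,
)
from .star_alleles import call_cohort
from .structure import evaluate_clustering, pca, scale_genotypes

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Defaults mirror the study design: a 3011-sample cohort, continental
    references of 503/662/504, a 500-sample subsample for structure
    analyses, K in {3, 4}, alpha = 0.01."""

    seed: int = DEFAULT_SEED
    n_study: int = 3011
    n_reference: dict = field(
        default_factory=lambda: {"EUR": 503, "AFR": 662, "EAS": 504}
    )
    drift: dict = field(
        default_factory=lambda: {"EUR": 0.01, "AFR": 0.15, "EAS": 0.10}
    )
    subsample: int = 500
    k_list: tuple = (3, 4)
    alpha: float = 0.01
    rules: str = "bundled"
    backend: str = "em"
    gibbs_burn_in: int = 10_000
    gibbs_iterations: int = 50_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_list"] = list(self.k_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "k_list" in d:
            d["k_list"] = tuple(d["k_list"])
        return cls(**d)


def subsample_cohort(cohort: CohortGenotypes, n: int, seed: int) -> CohortGenotypes:
    """Uniform subsample without replacement; deterministic under seed."""
    if n > cohort.n_samples:
        raise SimulationError(
            f"cannot subsample {n} from {cohort.n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cohort.n_samples, size=n, replace=False))
    return cohort.subset(idx)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel()
    freqs = load_greek_frequencies()
    root = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(6)]
    artifacts: list[str] = []

    log.info("stage: simulate (study n=%d)", config.n_study)
    study = sample_greek_style_cohort(freqs, "Greek", config.n_study, sub[0], panel)
    p_anc = np.array([freqs.freq2("Greek", r) for r in panel.rsids])
    p_anc = np.clip(p_anc, 1e-3, 1 - 1e-3)  # BN needs interior frequencies
    refs_all = sample_balding_nichols(
        p_anc, config.drift, config.n_reference, sub[1], panel
    )
    references = {
        pop: refs_all.subset(np.flatnonzero(refs_all.populations == pop))
        for pop in config.n_reference
    }

    log.info("stage: compare (chi-square/Fisher + Holm, alpha=%g)", config.alpha)
    comparison = pairwise_comparison_table(
        study, references, alpha=config.alpha, seed=sub[2]
    )
    _write(comparison, out / "frequency_comparison.tsv")
    artifacts.append("frequency_comparison.tsv")

    log.info("stage: call + phenotype (rules=%s)", config.rules)
    calls = call_cohort(study)
    tables = load_rule_tables(config.rules)
    summary = summarize_cohort_phenotypes(calls.attrs["diplotypes"], tables)
    for gene, gdf in summary.groupby("gene"):
        name = f"phenotypes_{gene}.tsv"
        _write(gdf, out / name)
        artifacts.append(name)

    log.info("stage: fst")
    fst = pairwise_fst_table({"Greek": subsample_cohort(study, config.subsample, sub[3]), **references})
    _write(fst, out / "fst_matrix.tsv")
    artifacts.append("fst_matrix.tsv")

    log.info("stage: structure (subsample=%d, K=%s)", config.subsample, config.k_list)
    struct_cohort = concat_cohorts(
        [subsample_cohort(study, config.subsample, sub[3])]
        + [references[p] for p in config.n_reference]
    )
    scaled = scale_genotypes(struct_cohort.dosage_matrix())
    pcares = pca(scaled, n_components=2)
    scores = pd.DataFrame(
        {
            "sample": struct_cohort.samples,
            "population": struct_cohort.populations,
            "PC1": pcares.scores[:, 0],
            "PC2": pcares.scores[:, 1],
        }
    )
    _write(scores, out / "pca_scores.tsv")
    loadings = pd.DataFrame(
        {
            "rsid": pcares.rsids,
            "PC1": pcares.loadings[:, 0],
            "PC2": pcares.loadings[:, 1],
        }
    )
    _write(loadings, out / "pca_loadings.tsv")
    artifacts += ["pca_scores.tsv", "pca_loadings.tsv"]

    eval_rows = []
    for K in config.k_list:
        ev = evaluate_clustering(
            pcares.scores, K, seed=sub[4], reference_labels=struct_cohort.populations
        )
        eval_rows.append((K, ev.silhouette, ev.ari, ev.nmi))
    _write(
        pd.DataFrame(eval_rows, columns=["K", "silhouette", "ari", "nmi"]),
        out / "cluster_eval.tsv",
    )
    artifacts.append("cluster_eval.tsv")

    log.info("stage: admixture (backend=%s, K=%d)", config.backend, config.k_list[0])
    K0 = config.k_list[0]
    dmat = struct_cohort.dosage_matrix()
    if config.backend == "em":
        adm = em_fit(dmat, K0, seed=sub[5], n_init=3)
    elif config.backend == "gibbs":
        adm = gibbs_fit(
            dmat,
            K0,
            burn_in=config.gibbs_burn_in,
            iterations=config.gibbs_iterations,
            seed=sub[5],
        )
    else:
        raise ValueError(f"unknown admixture backend {config.backend!r}")
    qdf = pd.DataFrame(adm.Q, columns=[f"Q{k+1}" for k in range(K0)])
    qdf.insert(0, "sample", struct_cohort.samples)
    qdf.insert(1, "population", struct_cohort.populations)
    _write(qdf, out / "admixture_Q.tsv")
    artifacts.append("admixture_Q.tsv")
    div = pd.DataFrame(
        {
            "cluster": [f"Q{k+1}" for k in range(K0)],
            "divergence": adm.divergence,
        }
    )
    _write(div, out / "admixture_divergence.tsv")
    artifacts.append("admixture_divergence.tsv")

    manifest = {
        "package": "pgxpop",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
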