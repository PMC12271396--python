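"""End-to-end pipeline: simulate -> harmonize -> ancestry -> screen -> report.

Every stage derives its randomness from a single master seed, records its
input/output counts in a structured filter log, and writes plain-text
outputs (VCF, TSV, JSON), so a fixed configuration reproduces bit-identical
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import annotate, enrichment, harmonize, simulate, vcfio
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """One synthetic source dataset: sample share, platform, site coverage."""

    id: str
    platform: str
    sample_fraction: float
    site_fraction: float
    missing_rate: float


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic run.

    The defaults are a desk-scale rendition of a multi-source admixed
    cohort: four datasets mixing array, exome, and whole-genome platforms,
    a five-cluster admixture structure whose expected cohort-mean ancestry
    is about 16.7/32.8/50.6% (AFR/AME/EUR), and a sparse annotation catalog
    with a handful of planted, strongly ancestry-divergent, pathogenic-
    annotated markers.
    """

    seed: int = 0
    n_samples: int = 600
    n_sites: int = 6000
    divergence: float = 0.15
    n_divergent_sites: int = 15
    concentration: float = simulate.DEFAULT_CONCENTRATION
    centroids: list = field(default_factory=lambda: simulate.DEFAULT_CENTROIDS.tolist())
    cluster_weights: list = field(default_factory=lambda: simulate.DEFAULT_CLUSTER_WEIGHTS.tolist())
    n_ref_per_pop: int = 60
    datasets: list = field(
        default_factory=lambda: [
            DatasetSpec("CHG", "WGG", 0.25, 0.55, 0.02),
            DatasetSpec("MCM", "WES", 0.25, 0.30, 0.05),
            DatasetSpec("MCA", "WGG", 0.30, 0.55, 0.02),
            DatasetSpec("PLQ", "WGS", 0.20, 1.00, 0.01),
        ]
    )
    # harmonization
    max_site_missing: float = 0.75
    min_maf: float = 0.05
    max_sample_missing: float = 0.99
    top_n_sites: int = 3000
    ld_window: int = 50
    ld_step: int = 25
    ld_r2_max: float = 0.5
    # ancestry
    n_components_pca: int = 10
    k_admixture: int = 3
    em_max_iter: int = 1000
    em_tol: float = 1e-3
    em_fix_p: bool = True
    kmeans_kmax: int = 8
    kmeans_restarts: int = 25
    # screening
    alpha: float = enrichment.GENOME_WIDE_ALPHA
    mc_cutoff: int = 3000
    mc_reps: int = 10_000

    def __post_init__(self) -> None:
        self.datasets = [
            ds if isinstance(ds, DatasetSpec) else DatasetSpec(**ds) for ds in self.datasets
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class FilterLog:
    """Input/output counts for each sample/site filter, in order."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, unit: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"filter {stage} output exceeds input ({n_out} > {n_in})")
        self.entries.append({"stage": stage, "unit": unit, "n_in": int(n_in), "n_out": int(n_out)})
        logger.info("%s: %d -> %d %s", stage, n_in, n_out, unit)


@dataclass
class SimulationOutput:
    panel: simulate.AncestralPanel
    truth: simulate.TrueQ
    cohort_genotypes: GenotypeMatrix
    datasets: list[harmonize.Dataset]
    reference: anc.ReferencePanel
    catalog: simulate.AnnotationCatalog
    divergent_sites: list


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_cohort(config: PipelineConfig) -> SimulationOutput:
    """Generate the full synthetic study: ancestral panel with planted
    divergent markers, admixed cohort, platform-split datasets, reference
    panel, and annotation catalog."""
    seeds = _child_seeds(config.seed, 8)
    panel = simulate.simulate_ancestral_freqs(
        m=config.n_sites, divergence=config.divergence, seed=seeds[0]
    )
    divergent_idx = simulate.plant_divergent_sites(
        panel, config.n_divergent_sites, seed=seeds[1]
    )
    spec = simulate.ClusterSpec(
        centroids=np.asarray(config.centroids),
        weights=np.asarray(config.cluster_weights),
        concentration=config.concentration,
        n_samples=config.n_samples,
    )
    truth = simulate.simulate_admixture_profiles(spec, seed=seeds[2])
    cohort = simulate.simulate_genotypes(panel, truth, seed=seeds[3])

    rng_sites = np.random.default_rng(seeds[4])
    groups: dict[str, tuple[list[str], simulate.PlatformMask]] = {}
    fracs = np.array([ds.sample_fraction for ds in config.datasets], dtype=float)
    bounds = np.concatenate([[0], np.cumsum(fracs / fracs.sum())])
    for i, ds in enumerate(config.datasets):
        lo, hi = int(round(bounds[i] * config.n_samples)), int(round(bounds[i + 1] * config.n_samples))
        members = cohort.samples[lo:hi]
        if ds.site_fraction >= 1.0:
            subset = np.arange(config.n_sites)
        else:
            n_take = int(round(ds.site_fraction * config.n_sites))
            subset = rng_sites.choice(config.n_sites, size=n_take, replace=False)
            # clinically genotyped markers are present on every platform
            subset = np.union1d(subset, divergent_idx)
        groups[ds.id] = (members, simulate.PlatformMask(
            platform=ds.platform, site_subset=np.sort(subset), missing_rate=ds.missing_rate
        ))
    split = simulate.split_cohort_into_datasets(cohort, groups, seed=seeds[5])
    datasets = [
        harmonize.Dataset(id=ds.id, platform=ds.platform, genotypes=g)
        for ds, g in zip(config.datasets, split)
    ]

    ref_geno, ref_labels = simulate.simulate_reference_genotypes(
        panel, n_per_pop=config.n_ref_per_pop, seed=seeds[6]
    )
    reference = anc.ReferencePanel(genotypes=ref_geno, pop_labels=ref_labels)

    catalog = simulate.simulate_annotations(panel.sites, seed=seeds[7])
    pharm_cycle = ["1A", "2A", "none"]
    for rank, j in enumerate(divergent_idx):
        catalog.set(
            panel.sites[int(j)],
            simulate.Annotation(
                clinvar_class="pathogenic_lp",
                pharm_level=pharm_cycle[rank % len(pharm_cycle)],
                label="ancestry_informative_marker",
            ),
        )
    return SimulationOutput(
        panel=panel,
        truth=truth,
        cohort_genotypes=cohort,
        datasets=datasets,
        reference=reference,
        catalog=catalog,
        divergent_sites=[panel.sites[int(j)] for j in divergent_idx],
    )


def harmonize_stage(
    datasets: list[harmonize.Dataset], config: PipelineConfig, log: FilterLog
) -> tuple[harmonize.MergedCohort, list]:
    """Union-merge and QC; returns the filtered cohort plus the
    occupancy-ranked, LD-pruned site list used for ancestry inference."""
    cohort = harmonize.union_merge(datasets)
    log.record("union_merge", "sites", sum(d.genotypes.n_sites for d in datasets),
               cohort.genotypes.n_sites)

    kept, _report = harmonize.kinship_filter(cohort.genotypes)
    n_before = cohort.genotypes.n_samples
    idx = [i for i, s in enumerate(cohort.samples) if s in set(kept)]
    cohort = cohort.subset_samples(idx)
    log.record("kinship_filter", "samples", n_before, cohort.genotypes.n_samples)

    n_before = cohort.genotypes.n_samples
    cohort = harmonize.filter_samples(cohort, config.max_sample_missing)
    log.record("filter_samples", "samples", n_before, cohort.genotypes.n_samples)

    n_before = cohort.genotypes.n_sites
    cohort = harmonize.filter_sites(cohort, config.max_site_missing, config.min_maf)
    log.record("filter_sites", "sites", n_before, cohort.genotypes.n_sites)

    top = harmonize.rank_sites_by_occupancy(cohort, config.top_n_sites)
    log.record("rank_sites_by_occupancy", "sites", cohort.genotypes.n_sites, len(top))

    pos = cohort.genotypes.site_index()
    top_matrix = cohort.genotypes.subset_sites([pos[k] for k in top])
    pruned = harmonize.ld_prune(
        top_matrix, window=config.ld_window, step=config.ld_step, r2_max=config.ld_r2_max
    )
    log.record("ld_prune", "sites", len(top), len(pruned))
    return cohort, pruned


def ancestry_stage(
    cohort: harmonize.MergedCohort,
    ancestry_sites: list,
    reference: anc.ReferencePanel,
    config: PipelineConfig,
    log: FilterLog,
) -> dict:
    """Reference PCA + projection, admixture EM, elbow clustering, naming."""
    seeds = _child_seeds(config.seed + 1, 3)
    ref_pos = reference.genotypes.site_index()
    shared = [k for k in ancestry_sites if k in ref_pos]
    log.record("ancestry_site_overlap", "sites", len(ancestry_sites), len(shared))
    ref_sub = reference.genotypes.subset_sites([ref_pos[k] for k in shared])
    ref_panel = anc.ReferencePanel(genotypes=ref_sub, pop_labels=list(reference.pop_labels))

    pca = anc.fit_reference_pca(ref_panel, n_components=config.n_components_pca)
    cohort_pos = cohort.genotypes.site_index()
    study = cohort.genotypes.subset_sites([cohort_pos[k] for k in shared])
    projections = anc.project_samples(pca, study)

    qm, p_hat, trace = anc.fit_admixture_em(
        study,
        K=config.k_admixture,
        max_iter=config.em_max_iter,
        tol=config.em_tol,
        seed=seeds[0],
        supervised_panel=ref_panel,
        fix_p=config.em_fix_p,
    )
    qm, p_hat = anc.align_components(qm, p_hat, ref_panel.population_frequencies())

    clusters = anc.kmeans_elbow(
        qm, k_min=1, k_max=config.kmeans_kmax,
        n_restarts=config.kmeans_restarts, seed=seeds[1],
    )
    clusters = anc.label_clusters(clusters, qm)
    return {
        "pca": pca,
        "projections": projections,
        "q": qm,
        "p_hat": p_hat,
        "loglik_trace": trace,
        "clusters": clusters,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write all outputs under ``outdir``.

    Returns the run report (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = FilterLog()

    sim = simulate_cohort(config)
    ds_dir = outdir / "datasets"
    ds_dir.mkdir(exist_ok=True)
    for ds in sim.datasets:
        vcfio.write_vcf(ds.genotypes, ds_dir / f"{ds.id}.vcf")
    vcfio.write_vcf(sim.reference.genotypes, ds_dir / "reference.vcf")
    pd.DataFrame({"sample": sim.reference.genotypes.samples,
                  "population": sim.reference.pop_labels}).to_csv(
        ds_dir / "reference_labels.tsv", sep="\t", index=False)
    vcfio.write_true_q_tsv(sim.truth, sim.cohort_genotypes.samples, outdir / "truth_q.tsv")
    vcfio.write_annotations_tsv(sim.catalog, outdir / "annotations.tsv")

    cohort, ancestry_sites = harmonize_stage(sim.datasets, config, log)
    _write_sites_tsv(cohort, outdir / "merged_sites.tsv")

    inference = ancestry_stage(cohort, ancestry_sites, sim.reference, config, log)
    qm: anc.QMatrix = inference["q"]
    clusters: anc.AncestryClusters = inference["clusters"]
    vcfio.write_q_tsv(qm.q, qm.samples, outdir / "q_matrix.tsv",
                      cluster=clusters.assignment, cluster_name=clusters.sample_names())
    _write_pcs_tsv(inference, qm.samples, outdir / "pc_coordinates.tsv")

    screen = enrichment.screen_genome(
        cohort, clusters, qm, sim.catalog,
        alpha=config.alpha, mc_cutoff=config.mc_cutoff, mc_reps=config.mc_reps,
        seed=_child_seeds(config.seed + 2, 1)[0],
    )
    log.record("screen_alpha", "sites", screen.n_sites_tested, len(screen.results))
    _write_screen_tsv(screen.results, outdir / "enriched_variants.tsv")
    _write_screen_tsv(screen.pharmacogenomic, outdir / "enriched_pharmacogenomic.tsv")
    _write_screen_tsv(screen.clinical, outdir / "enriched_clinical.tsv")

    ytab = annotate.diagnostic_yield(cohort, clusters, sim.catalog)
    ytab.to_frame().to_csv(outdir / "diagnostic_yield.tsv", sep="\t", index=False)
    annotate.summarize_frequencies(sim.datasets).to_csv(
        outdir / "frequency_summary.tsv", sep="\t", index=False, float_format="%.6f")

    report = _build_report(config, sim, cohort, inference, screen, ytab, log)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _build_report(config, sim, cohort, inference, screen, ytab, log) -> dict:
    qm: anc.QMatrix = inference["q"]
    clusters: anc.AncestryClusters = inference["clusters"]
    truth_by_sample = dict(zip(sim.cohort_genotypes.samples, sim.truth.q))
    q_true = np.array([truth_by_sample[s] for s in qm.samples])
    mae = float(np.abs(qm.q - q_true).mean())
    mean_q = qm.q.mean(axis=0)
    clinical_keys = {r.key for r in screen.clinical}
    divergent_pathogenic = [
        k for k in sim.divergent_sites
        if sim.catalog.get(k).clinvar_class == "pathogenic_lp"
    ]
    recovered = [str(k) for k in divergent_pathogenic if k in clinical_keys]
    return {
        "config": {"seed": config.seed, "n_samples": config.n_samples,
                   "n_sites": config.n_sites, "alpha": config.alpha},
        "filters": log.entries,
        "harmonized": {
            "n_samples": cohort.genotypes.n_samples,
            "n_sites": cohort.genotypes.n_sites,
        },
        "ancestry": {
            "mean_pct": {c: round(float(100 * mean_q[i]), 4)
                         for i, c in enumerate(qm.components)},
            "q_mae_vs_truth": round(mae, 6),
            "chosen_k": clusters.k,
            "cluster_counts": {n: int(c) for n, c in zip(clusters.names, clusters.counts)},
            "em_iterations": len(inference["loglik_trace"]),
            "pc1_pct_variance": round(float(inference["pca"].pct_variance[0]), 4),
        },
        "screen": {
            "n_sites_tested": screen.n_sites_tested,
            "n_enriched": len(screen.results),
            "n_pharmacogenomic": len(screen.pharmacogenomic),
            "n_clinical": len(screen.clinical),
            "n_divergent_pathogenic_planted": len(divergent_pathogenic),
            "n_divergent_pathogenic_recovered": len(recovered),
        },
        "diagnostic_yield_pct": {
            g: {c: round(float(ytab.percent[i, j]), 4)
                for j, c in enumerate(ytab.classes)}
            for i, g in enumerate(ytab.groups)
        },
    }


def _write_sites_tsv(cohort: harmonize.MergedCohort, path: Path) -> None:
    g = cohort.genotypes
    df = pd.DataFrame({
        "variant": [str(k) for k in g.sites],
        "occupancy": cohort.occupancy,
        "missing_fraction": g.site_missing_fraction(),
        "maf": g.minor_allele_frequency(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _write_pcs_tsv(inference: dict, samples: list[str], path: Path) -> None:
    proj = inference["projections"]
    df = pd.DataFrame(proj, columns=[f"PC{i+1}" for i in range(proj.shape[1])])
    df.insert(0, "sample", samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    scree = pd.DataFrame({
        "pc": [f"PC{i+1}" for i in range(len(inference["pca"].pct_variance))],
        "eigenvalue": inference["pca"].eigenvalues,
        "pct_variance": inference["pca"].pct_variance,
    })
    scree.to_csv(path.with_name("scree.tsv"), sep="\t", index=False, float_format="%.6f")


def _write_screen_tsv(results: list[enrichment.EnrichmentResult], path: Path) -> None:
    rows = []
    for r in results:
        rows.append({
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "variant": str(r.key),
            "association": r.annotation.label,
            "clinvar_class": r.annotation.clinvar_class,
            "pharm_level": r.annotation.pharm_level,
            "allele_count": r.table.grand_total,
            "fisher_p": f"{r.fisher.p:.6e}",
            "fisher_method": r.fisher.method,
            "fst": f"{r.fst.fst:.6f}",
            "enriched_cluster": r.enriched_cluster,
        })
    pd.DataFrame(rows, columns=[
        "chrom", "pos", "variant", "association", "clinvar_class", "pharm_level",
        "allele_count", "fisher_p", "fisher_method", "fst", "enriched_cluster",
    ]).to_csv(path, sep="\t", index=False)
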