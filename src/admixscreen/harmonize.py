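"""Merge heterogeneous per-dataset variant data into one non-redundant cohort.

The merge is a union keyed on the normalized ``chrom:pos:ref:alt`` identity:
every site found in any dataset is retained, and a sample's genotype at a
site its dataset never assayed is missing. Site "occupancy" (the number of
datasets carrying a site) drives the maximal-overlap site selection used for
ancestry inference. QC filters follow the order: kinship-based sample dedup,
sample missingness, site missingness + minor-allele frequency, occupancy
ranking, and finally LD pruning (for ancestry inference only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variants import MISSING, GenotypeMatrix, VariantKey, VariantRecordError

logger = logging.getLogger(__name__)

# Conventional kinship cut points at 2^(-3/2) (duplicates / monozygotic) and
# 2^(-5/2) (first-degree relatives).
DUPLICATE_KINSHIP = 0.354
FIRST_DEGREE_KINSHIP = 0.177


@dataclass
class Dataset:
    """One contributed source dataset: a short code, its platform, and its
    genotype matrix with normalized site keys."""

    id: str
    platform: str
    genotypes: GenotypeMatrix


@dataclass
class MergedCohort:
    """Union-merged cohort across datasets."""

    genotypes: GenotypeMatrix
    occupancy: np.ndarray  # per-site count of datasets carrying the site
    sample_to_dataset: dict[str, str] = field(default_factory=dict)

    @property
    def sites(self) -> list[VariantKey]:
        return self.genotypes.sites

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    def subset_sites(self, index) -> "MergedCohort":
        index = np.asarray(index, dtype=int)
        return MergedCohort(
            genotypes=self.genotypes.subset_sites(index),
            occupancy=self.occupancy[index].copy(),
            sample_to_dataset=dict(self.sample_to_dataset),
        )

    def subset_samples(self, index) -> "MergedCohort":
        index = np.asarray(index, dtype=int)
        g = self.genotypes.subset_samples(index)
        return MergedCohort(
            genotypes=g,
            occupancy=self.occupancy.copy(),
            sample_to_dataset={s: self.sample_to_dataset[s] for s in g.samples
                               if s in self.sample_to_dataset},
        )


def normalize_variant_ids(records) -> tuple[list[VariantKey], list[tuple[tuple, str]]]:
    """Normalize raw ``(chrom, pos, ref, alt)`` records to canonical keys.

    Returns (keys, rejected) where rejected pairs each bad record with its
    reason. Normalization strips any ``chr`` prefix and upper-cases alleles;
    it is idempotent.
    """
    keys: list[VariantKey] = []
    rejected: list[tuple[tuple, str]] = []
    for rec in records:
        chrom, pos, ref, alt = rec
        try:
            keys.append(VariantKey.from_record(chrom, pos, ref, alt))
        except (VariantRecordError, ValueError) as exc:
            rejected.append((tuple(rec), str(exc)))
    if rejected:
        logger.info("normalize_variant_ids: rejected %d records", len(rejected))
    return keys, rejected


def union_merge(datasets: list[Dataset]) -> MergedCohort:
    """Union-merge datasets on exact VariantKey.

    Records at the same chrom:pos with different alleles remain distinct
    sites. Duplicate sample ids across datasets are an error.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    all_samples: list[str] = []
    sample_to_dataset: dict[str, str] = {}
    for ds in datasets:
        for s in ds.genotypes.samples:
            if s in sample_to_dataset:
                raise ValueError(f"duplicate sample id {s!r} across datasets")
            sample_to_dataset[s] = ds.id
            all_samples.append(s)

    site_order: dict[VariantKey, int] = {}
    for ds in datasets:
        for key in ds.genotypes.sites:
            site_order.setdefault(key, len(site_order))
    sites = sorted(site_order, key=lambda k: k.sort_key)
    col = {k: j for j, k in enumerate(sites)}

    values = np.full((len(all_samples), len(sites)), MISSING, dtype=np.int8)
    occupancy = np.zeros(len(sites), dtype=int)
    row0 = 0
    for ds in datasets:
        g = ds.genotypes
        cols = np.array([col[k] for k in g.sites], dtype=int)
        if cols.size:
            values[row0: row0 + g.n_samples, cols] = g.values
            occupancy[cols] += 1
        row0 += g.n_samples

    merged = GenotypeMatrix(samples=all_samples, sites=sites, values=values)
    logger.info(
        "union_merge: %d datasets, %d samples, %d non-redundant sites",
        len(datasets), len(all_samples), len(sites),
    )
    return MergedCohort(genotypes=merged, occupancy=occupancy, sample_to_dataset=sample_to_dataset)


def rank_sites_by_occupancy(cohort: MergedCohort, n_keep: int) -> list[VariantKey]:
    """Select up to ``n_keep`` sites ranked by decreasing occupancy (the
    number of datasets carrying the site), ties broken by genomic
    coordinate ascending."""
    if n_keep < 0:
        raise ValueError("n_keep must be non-negative")
    order = sorted(
        range(len(cohort.sites)),
        key=lambda j: (-cohort.occupancy[j],) + cohort.sites[j].sort_key,
    )
    return [cohort.sites[j] for j in order[: min(n_keep, len(order))]]


def filter_sites(
    cohort: MergedCohort,
    max_missing_fraction: float = 0.75,
    min_maf: float = 0.05,
) -> MergedCohort:
    """Drop sites with missing fraction above ``max_missing_fraction`` or
    minor-allele frequency (over non-missing alleles) strictly below
    ``min_maf``. Sites with every genotype missing are dropped."""
    _check_fraction(max_missing_fraction, "max_missing_fraction")
    _check_fraction(min_maf, "min_maf")
    g = cohort.genotypes
    miss = g.site_missing_fraction()
    maf = g.minor_allele_frequency()
    keep = (miss <= max_missing_fraction) & ~np.isnan(maf) & (maf >= min_maf)
    logger.info("filter_sites: %d -> %d sites", g.n_sites, int(keep.sum()))
    return cohort.subset_sites(np.flatnonzero(keep))


def filter_samples(cohort: MergedCohort, max_missing_fraction: float = 0.99) -> MergedCohort:
    """Drop samples whose fraction of missing genotypes exceeds the
    threshold (strictly greater-than)."""
    _check_fraction(max_missing_fraction, "max_missing_fraction")
    frac = cohort.genotypes.sample_missing_fraction()
    keep = frac <= max_missing_fraction
    logger.info("filter_samples: %d -> %d samples", len(frac), int(keep.sum()))
    return cohort.subset_samples(np.flatnonzero(keep))


def _check_fraction(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 25,
    r2_max: float = 0.2,
) -> list[VariantKey]:
    """Greedy left-to-right LD pruning on genotype-dosage correlation.

    Within each sliding window, for any pair of retained sites with squared
    Pearson correlation above ``r2_max`` the later site is dropped. Missing
    genotypes are pairwise-excluded; a monomorphic site has undefined r**2
    and is treated as uncorrelated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0.0 <= r2_max <= 1.0:
        raise ValueError("r2_max must lie in [0, 1]")
    step = max(1, step)
    m = g.n_sites
    keep = np.ones(m, dtype=bool)
    vals = np.ma.masked_equal(g.values.astype(float), MISSING)
    start = 0
    while start < m:
        stop = min(start + window, m)
        idx = [j for j in range(start, stop) if keep[j]]
        if len(idx) > 1:
            sub = vals[:, idx]
            corr = np.ma.corrcoef(sub, rowvar=False)
            r2 = np.asarray(np.ma.filled(corr, 0.0)) ** 2
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > r2_max:
                        keep[idx[b]] = False
        if stop >= m:
            break
        start += step
    kept = [g.sites[j] for j in np.flatnonzero(keep)]
    logger.info("ld_prune: %d -> %d sites", m, len(kept))
    return kept


def kinship_matrix(g: GenotypeMatrix, min_shared_sites: int = 100) -> np.ndarray:
    """Pairwise kinship by a heterozygote-concordance estimator robust to
    population structure:

        phi_ij = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j))

    where counts are taken over sites non-missing in both samples: N_AaAa =
    shared heterozygote sites, N_AAaa = opposite-homozygote sites, and
    N_Aa(.) = each sample's heterozygote count. Duplicate samples score
    about 0.5, first-degree pairs about 0.25, unrelated pairs about 0.

    Pairs with fewer than ``min_shared_sites`` shared called sites get NaN
    with a warning.
    """
    v = g.values
    called = (v != MISSING).astype(np.float64)
    het = (v == 1).astype(np.float64)
    hom0 = (v == 0).astype(np.float64)
    hom2 = (v == 2).astype(np.float64)

    n_shared = called @ called.T
    n_het_het = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_i_shared = het @ called.T  # sample i het count over sites called in both

    denom = het_i_shared + het_i_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_het - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    low = n_shared < min_shared_sites
    if np.any(low[np.triu_indices_from(low, k=1)]):
        logger.warning(
            "kinship_matrix: %d pairs share fewer than %d called sites; skipped",
            int(low[np.triu_indices_from(low, k=1)].sum()), min_shared_sites,
        )
    phi[low] = np.nan
    np.fill_diagonal(phi, 0.5)
    return phi


def kinship_filter(
    g: GenotypeMatrix,
    dup_threshold: float = DUPLICATE_KINSHIP,
    first_degree_threshold: float = FIRST_DEGREE_KINSHIP,
    min_shared_sites: int = 100,
) -> tuple[list[str], list[dict]]:
    """Flag sample pairs with kinship above ``first_degree_threshold``
    (duplicates and first-degree relatives) and drop, from each flagged
    pair, the sample with the higher missing fraction.

    Returns (kept sample ids, report) where each report entry records the
    pair, its kinship, its relationship call, and the dropped sample.
    """
    if g.n_samples < 2:
        return list(g.samples), []
    phi = kinship_matrix(g, min_shared_sites=min_shared_sites)
    miss = g.sample_missing_fraction()
    flagged = []
    iu = np.triu_indices(g.n_samples, k=1)
    for i, j in zip(*iu):
        k = phi[i, j]
        if np.isnan(k) or k <= first_degree_threshold:
            continue
        relation = "duplicate" if k > dup_threshold else "first_degree"
        flagged.append((float(k), relation, int(i), int(j)))

    dropped: set[int] = set()
    report: list[dict] = []
    # Resolve the closest pairs first so a single bad sample absorbs drops.
    for k, relation, i, j in sorted(flagged, reverse=True):
        entry = {
            "sample_a": g.samples[i],
            "sample_b": g.samples[j],
            "kinship": k,
            "relationship": relation,
        }
        if i in dropped or j in dropped:
            entry["dropped"] = None
        else:
            victim = i if (miss[i], g.samples[i]) > (miss[j], g.samples[j]) else j
            dropped.add(victim)
            entry["dropped"] = g.samples[victim]
        report.append(entry)
    kept = [s for idx, s in enumerate(g.samples) if idx not in dropped]
    logger.info("kinship_filter: flagged %d pairs, dropped %d samples",
                len(flagged), len(dropped))
    return kept, report
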