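"""Synthetic admixed-cohort generator with known ground truth.

Emulates a multi-source Colombian-style cohort: three ancestral populations
(African, Indigenous American, European) diverged under the Balding-Nichols
model, samples drawn from a small number of admixture clusters on the
ancestry simplex, genotypes sampled under the standard admixture model, and
heterogeneous "platforms" (genotyping array, exome, whole genome) that each
observe only a subset of sites with some missingness. A sparse annotation
catalog stands in for clinical (ClinVar-style) and pharmacogenomic
(PharmGKB-style) databases.

Every step is seeded and reproducible, so downstream harmonization,
ancestry inference, and enrichment screening can be validated against the
simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import MISSING, GenotypeMatrix, VariantKey

ANCESTRY_COMPONENTS: tuple[str, str, str] = ("AFR", "AME", "EUR")

CLINVAR_CLASSES: tuple[str, ...] = ("none", "uncertain", "conflicting", "pathogenic_lp")
PHARM_LEVELS: tuple[str, ...] = ("none", "1A", "1B", "2A", "2B", "3", "4")
PLATFORMS: tuple[str, str, str] = ("WGG", "WES", "WGS")

# Five-cluster structure: three near-ancestral clusters plus two admixed
# clusters, one closer to the European pole and one closer to the Indigenous
# American pole with a minor African component. Mixing weights follow the
# relative cluster sizes 149/75/232/603/350 (n=1409); with these centroids the
# expected cohort-mean ancestry is (16.7, 32.7, 50.6)% (AFR, AME, EUR).
DEFAULT_CENTROIDS: np.ndarray = np.array(
    [
        [0.80, 0.08, 0.12],  # African-like
        [0.05, 0.90, 0.05],  # Indigenous American-like
        [0.05, 0.05, 0.90],  # European-like
        [0.08, 0.295, 0.625],  # Admixed, European-leaning
        [0.15, 0.55, 0.30],  # Admixed, Indigenous-leaning, minor African
    ]
)
DEFAULT_CLUSTER_WEIGHTS: np.ndarray = np.array([149, 75, 232, 603, 350]) / 1409.0
DEFAULT_CONCENTRATION: float = 60.0


@dataclass
class AncestralPanel:
    """Per-population alternate-allele frequencies at a common site set."""

    pop_labels: tuple[str, ...]
    freqs: np.ndarray  # K_anc x m
    sites: list[VariantKey]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.pop_labels), len(self.sites)):
            raise ValueError("ancestral frequency matrix shape mismatch")
        if self.freqs.size and (self.freqs.min() < 0 or self.freqs.max() > 1):
            raise ValueError("ancestral frequencies must lie in [0, 1]")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites in ancestral panel")

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class ClusterSpec:
    """Admixture-cluster mixture: centroids on the ancestry simplex,
    mixing weights, Dirichlet concentration, and cohort size."""

    centroids: np.ndarray = field(default_factory=lambda: DEFAULT_CENTROIDS.copy())
    weights: np.ndarray = field(default_factory=lambda: DEFAULT_CLUSTER_WEIGHTS.copy())
    concentration: float = DEFAULT_CONCENTRATION
    n_samples: int = 1409

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centroids.shape[0] == 0:
            raise ValueError("at least one cluster centroid required")
        if not np.allclose(self.centroids.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each centroid must sum to 1")
        if self.weights.shape != (self.centroids.shape[0],):
            raise ValueError("one mixing weight per centroid required")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixing weights must sum to 1")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_components(self) -> int:
        return self.centroids.shape[1]


@dataclass
class TrueQ:
    """Ground-truth ancestry fractions and cluster memberships."""

    q: np.ndarray  # n x K_anc
    true_cluster: np.ndarray  # n

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.true_cluster = np.asarray(self.true_cluster, dtype=int)
        if self.q.shape[0] != self.true_cluster.shape[0]:
            raise ValueError("one cluster index per sample required")
        if self.q.size:
            if self.q.min() < 0 or self.q.max() > 1:
                raise ValueError("ancestry fractions must lie in [0, 1]")
            if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("ancestry fractions must sum to 1 per sample")

    @property
    def n_samples(self) -> int:
        return self.q.shape[0]


@dataclass
class PlatformMask:
    """Which sites a platform observes, and its per-call missing rate.

    By convention a WGS mask covers every site.
    """

    platform: str
    site_subset: np.ndarray
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        self.site_subset = np.asarray(self.site_subset, dtype=int)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class Annotation:
    clinvar_class: str = "none"
    pharm_level: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        if self.clinvar_class not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar-style class {self.clinvar_class!r}")
        if self.pharm_level not in PHARM_LEVELS:
            raise ValueError(f"unknown pharmacogenomic evidence level {self.pharm_level!r}")


class AnnotationCatalog:
    """Mapping from VariantKey to its clinical/pharmacogenomic annotation."""

    def __init__(self, entries: dict[VariantKey, Annotation] | None = None) -> None:
        self.entries: dict[VariantKey, Annotation] = dict(entries or {})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def get(self, key: VariantKey) -> Annotation:
        return self.entries.get(key, Annotation())

    def set(self, key: VariantKey, annotation: Annotation) -> None:
        self.entries[key] = annotation


def _default_sites(m: int) -> list[VariantKey]:
    """Deterministic synthetic site grid: sites spread over 22 autosomes."""
    sites = []
    for j in range(m):
        chrom = str(j % 22 + 1)
        pos = 10_000 + (j // 22 + 1) * 1_000
        sites.append(VariantKey(chrom=chrom, pos=pos, ref="A", alt="G"))
    return sites


def simulate_ancestral_freqs(
    m: int,
    divergence: float | np.ndarray = 0.15,
    base_freq_sampler=None,
    pop_labels: tuple[str, ...] = ANCESTRY_COMPONENTS,
    seed: int | np.random.Generator | None = None,
) -> AncestralPanel:
    """Draw per-population allele frequencies under the Balding-Nichols model.

    Each site gets a shared ancestral frequency ``p`` from
    ``base_freq_sampler`` (default: Uniform(0.05, 0.95)); each population's
    frequency is then Beta-distributed with mean ``p`` and variance
    ``F * p * (1-p)``, via shapes ``p(1-F)/F`` and ``(1-p)(1-F)/F``.

    Parameters
    ----------
    divergence
        Per-population fixation index F in (0, 1); a scalar applies the same
        F to all populations.
    """
    if m < 0:
        raise ValueError("site count must be non-negative")
    rng = np.random.default_rng(seed)
    K = len(pop_labels)
    F = np.broadcast_to(np.asarray(divergence, dtype=float), (K,)).copy()
    if np.any(F <= 0) or np.any(F >= 1):
        raise ValueError("divergence F must lie strictly in (0, 1)")

    if base_freq_sampler is None:
        base = rng.uniform(0.05, 0.95, size=m)
    else:
        base = np.asarray(base_freq_sampler(rng, m), dtype=float)
    freqs = np.empty((K, m))
    for k in range(K):
        a = base * (1.0 - F[k]) / F[k]
        b = (1.0 - base) * (1.0 - F[k]) / F[k]
        freqs[k] = rng.beta(a, b) if m else np.empty(0)
    freqs = np.clip(freqs, 0.0, 1.0)
    return AncestralPanel(pop_labels=tuple(pop_labels), freqs=freqs, sites=_default_sites(m))


def plant_divergent_sites(
    panel: AncestralPanel,
    n_divergent: int,
    high_freq: float = 0.9,
    low_freq: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Overwrite ``n_divergent`` randomly chosen sites with strongly
    population-specific frequencies (one population near ``high_freq``, the
    rest near ``low_freq``), cycling through the ancestral populations.

    Emulates highly ancestry-informative markers such as the Duffy-null
    promoter variant. Returns the site indices modified (in place).
    """
    if n_divergent > panel.n_sites:
        raise ValueError("more divergent sites requested than sites in panel")
    rng = np.random.default_rng(seed)
    idx = rng.choice(panel.n_sites, size=n_divergent, replace=False)
    for rank, j in enumerate(sorted(idx)):
        hot = rank % panel.n_pops
        panel.freqs[:, j] = low_freq
        panel.freqs[hot, j] = high_freq
    return np.sort(idx)


def simulate_admixture_profiles(
    spec: ClusterSpec, seed: int | np.random.Generator | None = None
) -> TrueQ:
    """Assign each sample to a cluster by the mixing weights and draw its
    ancestry fractions from Dirichlet(concentration * centroid)."""
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    cluster = rng.choice(spec.n_clusters, size=n, p=spec.weights)
    q = np.empty((n, spec.n_components))
    for c in range(spec.n_clusters):
        members = np.flatnonzero(cluster == c)
        if members.size == 0:
            continue
        alpha = np.maximum(spec.concentration * spec.centroids[c], 1e-9)
        q[members] = rng.dirichlet(alpha, size=members.size)
    q = q / q.sum(axis=1, keepdims=True)
    return TrueQ(q=q, true_cluster=cluster)


def simulate_genotypes(
    panel: AncestralPanel,
    true_q: TrueQ,
    sample_prefix: str = "S",
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Sample diploid genotypes under the admixture model:
    ``g_ij ~ Binomial(2, sum_k q_ik * p_kj)``. No missingness yet."""
    if true_q.q.shape[1] != panel.n_pops:
        raise ValueError("ancestry fractions and ancestral panel disagree on K")
    rng = np.random.default_rng(seed)
    pi = true_q.q @ panel.freqs  # n x m expected alt-allele frequency
    g = rng.binomial(2, np.clip(pi, 0.0, 1.0)).astype(np.int8)
    samples = [f"{sample_prefix}{i:05d}" for i in range(true_q.n_samples)]
    return GenotypeMatrix(samples=samples, sites=list(panel.sites), values=g)


def simulate_reference_genotypes(
    panel: AncestralPanel,
    n_per_pop: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Draw unadmixed reference samples, ``n_per_pop`` per ancestral
    population, directly from the panel frequencies. Returns the genotype
    matrix and the per-sample population labels."""
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    rows = []
    samples = []
    for k, pop in enumerate(panel.pop_labels):
        g = rng.binomial(2, np.broadcast_to(panel.freqs[k], (n_per_pop, panel.n_sites)))
        rows.append(g.astype(np.int8))
        labels.extend([pop] * n_per_pop)
        samples.extend([f"REF_{pop}_{i:03d}" for i in range(n_per_pop)])
    values = np.vstack(rows) if rows else np.empty((0, panel.n_sites), dtype=np.int8)
    return GenotypeMatrix(samples=samples, sites=list(panel.sites), values=values), labels


def apply_platform_masks(
    g: GenotypeMatrix,
    assignment: dict[str, PlatformMask],
    seed: int | np.random.Generator | None = None,
) -> list[GenotypeMatrix]:
    """Split a cohort into per-dataset matrices, one per mask in
    ``assignment`` (dataset id -> mask), partitioning samples equally in
    cohort order. Use :func:`split_cohort_into_datasets` to control the
    sample groups explicitly."""
    groups = _equal_partition(g.samples, len(assignment))
    return split_cohort_into_datasets(
        g, {ds: (groups[i], mask) for i, (ds, mask) in enumerate(assignment.items())}, seed=seed
    )


def split_cohort_into_datasets(
    g: GenotypeMatrix,
    groups: dict[str, tuple[list[str], PlatformMask]],
    seed: int | np.random.Generator | None = None,
) -> list[GenotypeMatrix]:
    """Restrict each sample group to its platform's site subset and apply
    missing-completely-at-random dropout at the mask's missing rate.

    Every sample must appear in exactly one group.
    """
    rng = np.random.default_rng(seed)
    claimed: list[str] = []
    for _, (members, _) in groups.items():
        claimed.extend(members)
    if sorted(claimed) != sorted(g.samples):
        missing = set(g.samples) - set(claimed)
        extra = set(claimed) - set(g.samples)
        raise ValueError(
            f"sample partition invalid: unassigned={sorted(missing)[:5]}, unknown={sorted(extra)[:5]}"
        )
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    out: list[GenotypeMatrix] = []
    for _, (members, mask) in groups.items():
        if np.any(mask.site_subset >= g.n_sites) or np.any(mask.site_subset < 0):
            raise ValueError("platform mask site subset out of range")
        rows = np.array([sample_pos[s] for s in members], dtype=int)
        values = g.values[np.ix_(rows, mask.site_subset)].copy() if rows.size else np.empty(
            (0, mask.site_subset.size), dtype=np.int8
        )
        if mask.missing_rate > 0 and values.size:
            drop = rng.random(values.shape) < mask.missing_rate
            values[drop] = MISSING
        out.append(
            GenotypeMatrix(
                samples=list(members),
                sites=[g.sites[j] for j in mask.site_subset],
                values=values,
            )
        )
    return out


def _equal_partition(samples: list[str], k: int) -> list[list[str]]:
    bounds = np.linspace(0, len(samples), k + 1).astype(int)
    return [samples[bounds[i]: bounds[i + 1]] for i in range(k)]


def simulate_annotations(
    sites: list[VariantKey],
    class_probs: dict[str, float] | None = None,
    level_probs: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> AnnotationCatalog:
    """Independent categorical draws of a ClinVar-style class and a
    pharmacogenomic evidence level per site; unlisted mass goes to "none".

    Default class/level probabilities are sparse, mirroring how rare
    curated annotations are genome-wide.
    """
    if class_probs is None:
        class_probs = {"uncertain": 0.05, "conflicting": 0.02, "pathogenic_lp": 0.01}
    if level_probs is None:
        level_probs = {"1A": 0.002, "1B": 0.002, "2A": 0.003, "2B": 0.003, "3": 0.01, "4": 0.01}
    rng = np.random.default_rng(seed)
    catalog = AnnotationCatalog()
    classes, cp = _categorical(class_probs, CLINVAR_CLASSES)
    levels, lp = _categorical(level_probs, PHARM_LEVELS)
    drawn_class = rng.choice(len(classes), size=len(sites), p=cp)
    drawn_level = rng.choice(len(levels), size=len(sites), p=lp)
    for i, site in enumerate(sites):
        cls = classes[drawn_class[i]]
        lvl = levels[drawn_level[i]]
        label = ""
        if lvl != "none":
            label = f"drug_response_{lvl}"
        elif cls != "none":
            label = f"condition_{cls}"
        catalog.set(site, Annotation(clinvar_class=cls, pharm_level=lvl, label=label))
    return catalog


def _categorical(probs: dict[str, float], vocabulary: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
    for name, p in probs.items():
        if name not in vocabulary:
            raise ValueError(f"unknown category {name!r}")
        if p < 0:
            raise ValueError(f"negative probability for {name!r}")
    total = sum(probs.values())
    if total > 1 + 1e-12:
        raise ValueError("category probabilities sum to more than 1")
    names = [n for n in vocabulary if n != "none" and probs.get(n, 0.0) > 0]
    p = np.array([probs[n] for n in names], dtype=float)
    return ["none"] + names, np.concatenate([[1.0 - p.sum()], p])
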