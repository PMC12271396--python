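"""Continuous and categorical genetic-ancestry inference.

Three estimators, mirroring the standard population-genomics toolkit:

* reference-anchored PCA: eigenvectors are fit on labeled reference samples
  only and study samples are projected onto that PC space, so admixed cohort
  structure cannot distort the reference axes;
* three-way admixture fractions via an EM algorithm on the binomial
  admixture likelihood (K = 3: African, Indigenous American, European);
* categorical ancestry groups via K-means on the ancestry fractions with
  the elbow criterion (maximal discrete curvature of the inertia curve)
  choosing the number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .simulate import ANCESTRY_COMPONENTS
from .variants import MISSING, GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Labeled, unadmixed reference samples used to anchor inference."""

    genotypes: GenotypeMatrix
    pop_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.pop_labels) != self.genotypes.n_samples:
            raise ValueError("one population label per reference sample required")
        counts: dict[str, int] = {}
        for lab in self.pop_labels:
            counts[lab] = counts.get(lab, 0) + 1
        shallow = [lab for lab, c in counts.items() if c < 2]
        if shallow:
            raise ValueError(f"reference populations need >= 2 samples: {shallow}")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.pop_labels))

    def population_frequencies(self, order: tuple[str, ...] = ANCESTRY_COMPONENTS) -> np.ndarray:
        """Per-population alternate-allele frequencies (K x m), rows in the
        requested component order."""
        g = self.genotypes
        labels = np.asarray(self.pop_labels)
        freqs = np.empty((len(order), g.n_sites))
        for k, pop in enumerate(order):
            rows = labels == pop
            sub = g.values[rows]
            called = sub != MISSING
            alt = np.where(called, sub, 0).sum(axis=0).astype(float)
            tot = 2.0 * called.sum(axis=0)
            freqs[k] = np.divide(alt, tot, out=np.full(g.n_sites, np.nan), where=tot > 0)
        return freqs


@dataclass
class PCModel:
    """Reference PCA model: per-site standardization and orthonormal
    loadings so new samples can be projected into the reference PC space."""

    sites: list[VariantKey]
    alt_freq: np.ndarray  # reference alternate-allele frequency per site
    scale: np.ndarray  # sqrt(2 p (1-p)) per site
    loadings: np.ndarray  # m x n_components, orthonormal columns
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: np.ndarray  # reference-sample coordinates (n_ref x n_components)

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("PC loadings are not orthonormal")
        if np.any(np.diff(self.pct_variance) > 1e-9):
            raise ValueError("percent variance must be non-increasing")


@dataclass
class QMatrix:
    """Per-sample ancestry fractions on the probability simplex."""

    samples: list[str]
    q: np.ndarray  # n x K
    components: tuple[str, ...] = ANCESTRY_COMPONENTS

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if self.q.shape[0] != len(self.samples):
            raise ValueError("one Q row per sample required")
        if self.q.size and not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")


@dataclass
class AncestryClusters:
    """Categorical ancestry groups in Q space."""

    k: int
    assignment: np.ndarray  # per-sample cluster index
    centroids: np.ndarray  # k x K_anc
    names: list[str] = field(default_factory=list)
    inertia_curve: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.names and len(set(self.names)) != len(self.names):
            raise ValueError("cluster names must be unique")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def sample_names(self) -> list[str]:
        return [self.names[c] for c in self.assignment]


def fit_reference_pca(ref: ReferencePanel, n_components: int = 10) -> PCModel:
    """PCA on the reference panel with the usual allele-frequency
    standardization: each site is centered by ``2p`` and scaled by
    ``sqrt(2p(1-p))`` where ``p`` is the reference alternate-allele
    frequency. Missing genotypes are mean-imputed before decomposition;
    monomorphic sites are excluded."""
    g = ref.genotypes
    if g.n_samples < n_components + 1:
        raise ValueError("need at least n_components + 1 reference samples")
    called = g.values != MISSING
    alt = np.where(called, g.values, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    p = np.divide(alt, tot, out=np.zeros(g.n_sites), where=tot > 0)
    poly = (p > 0) & (p < 1)
    if int(poly.sum()) < n_components:
        raise ValueError("fewer polymorphic sites than requested components")
    idx = np.flatnonzero(poly)
    p = p[idx]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    x = np.where(called[:, idx], g.values[:, idx], 2.0 * p)
    x = (x - 2.0 * p) / scale

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, s.size)
    eigvals = s**2 / max(g.n_samples - 1, 1)
    pct = 100.0 * eigvals / eigvals.sum()
    return PCModel(
        sites=[g.sites[j] for j in idx],
        alt_freq=p,
        scale=scale,
        loadings=vt[:n_components].T,
        eigenvalues=eigvals[:n_components],
        pct_variance=pct[:n_components],
        scores=u[:, :n_components] * s[:n_components],
    )


def project_samples(model: PCModel, g: GenotypeMatrix) -> np.ndarray:
    """Project samples onto the reference PC space.

    Genotypes are standardized with the model's reference frequencies;
    missing entries are imputed to the reference mean (standardized zero).
    Samples observing fewer than half of the model sites are projected with
    a warning; a sample with no called model site is an error.
    """
    pos = g.site_index()
    overlap = [(i, pos[k]) for i, k in enumerate(model.sites) if k in pos]
    if not overlap:
        raise ValueError("no overlap between model sites and genotype matrix")
    model_idx = np.array([i for i, _ in overlap])
    g_idx = np.array([j for _, j in overlap])

    vals = g.values[:, g_idx]
    called = vals != MISSING
    n_called = called.sum(axis=1)
    if np.any(n_called == 0):
        bad = [g.samples[i] for i in np.flatnonzero(n_called == 0)]
        raise ValueError(f"samples with no called genotype at model sites: {bad[:5]}")
    if np.any(n_called < 0.5 * len(model.sites)):
        logger.warning(
            "project_samples: %d samples observe < 50%% of model sites",
            int((n_called < 0.5 * len(model.sites)).sum()),
        )
    p = model.alt_freq[model_idx]
    x = np.where(called, vals, 2.0 * p)
    x = (x - 2.0 * p) / model.scale[model_idx]
    x[~called] = 0.0
    return x @ model.loadings[model_idx]


def admixture_loglik(a: np.ndarray, b: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    pi = np.clip(q @ p, 1e-12, 1 - 1e-12)
    return float(np.sum(a * np.log(pi)) + np.sum(b * np.log1p(-pi)))


def fit_admixture_em(
    g: GenotypeMatrix,
    K: int = 3,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int | np.random.Generator | None = None,
    supervised_panel: ReferencePanel | None = None,
    fix_p: bool = False,
) -> tuple[QMatrix, np.ndarray, list[float]]:
    """Maximum-likelihood admixture fractions by EM.

    Maximizes the binomial admixture log-likelihood

        l = sum_ij [ g_ij log(pi_ij) + (2 - g_ij) log(1 - pi_ij) ],
        pi_ij = sum_k q_ik p_kj

    by alternating multiplicative (EM) updates of the ancestry fractions Q
    and component allele frequencies P. The updates are the standard
    complete-data expectations, so the log-likelihood is monotone
    non-decreasing. Missing genotypes contribute nothing to the likelihood.

    With ``supervised_panel``, P is initialized from the panel's population
    frequencies (optionally held fixed with ``fix_p``) and components are
    returned in the panel's (AFR, AME, EUR) order; unsupervised fits return
    components in arbitrary order (use :func:`align_components`).

    Returns (QMatrix, P, per-iteration log-likelihood trace).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    v = g.values.astype(float)
    called = g.values != MISSING
    a = np.where(called, v, 0.0)  # alt-allele counts
    b = np.where(called, 2.0 - v, 0.0)  # ref-allele counts
    n, m = a.shape

    q = rng.dirichlet(np.ones(K), size=n)
    if supervised_panel is not None:
        pops = supervised_panel.populations
        if len(pops) != K:
            raise ValueError(
                f"supervised panel has {len(pops)} populations but K={K}"
            )
        order = tuple(p for p in ANCESTRY_COMPONENTS if p in pops)
        order += tuple(p for p in pops if p not in order)
        p = supervised_panel.population_frequencies(order=order)
        if p.shape[1] != m:
            raise ValueError("supervised panel sites must match the genotype matrix")
        p = np.nan_to_num(p, nan=0.5)
    else:
        overall = np.divide(a.sum(axis=0), (a + b).sum(axis=0),
                            out=np.full(m, 0.5), where=(a + b).sum(axis=0) > 0)
        p = np.clip(overall + rng.normal(0, 0.08, size=(K, m)), 0.02, 0.98)
    p = np.clip(p, 1e-6, 1 - 1e-6)

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        pi = np.clip(q @ p, 1e-12, 1 - 1e-12)
        r1 = a / pi
        r0 = b / (1.0 - pi)
        # E-step expected allele assignments folded into multiplicative updates
        q_new = q * (r1 @ p.T + r0 @ (1.0 - p).T)
        q_new /= q_new.sum(axis=1, keepdims=True)
        if fix_p and supervised_panel is not None:
            p_new = p
        else:
            num = p * (q.T @ r1)
            den = num + (1.0 - p) * (q.T @ r0)
            with np.errstate(invalid="ignore"):
                p_new = np.where(den > 0, num / np.maximum(den, 1e-300), p)
            p_new = np.clip(p_new, 1e-6, 1 - 1e-6)
        q, p = q_new, p_new
        ll = admixture_loglik(a, b, q, p)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite admixture log-likelihood")
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    qm = QMatrix(samples=list(g.samples), q=q,
                 components=tuple(ANCESTRY_COMPONENTS[:K]) if K == 3 else tuple(
                     f"K{i+1}" for i in range(K)))
    return qm, p, trace


def align_components(
    q: QMatrix, p: np.ndarray, reference_freqs: np.ndarray,
    component_names: tuple[str, ...] = ANCESTRY_COMPONENTS,
) -> tuple[QMatrix, np.ndarray]:
    """Match inferred components to named ancestral populations by maximal
    correlation between inferred and reference allele frequencies
    (one-to-one, Hungarian assignment), and reorder Q columns and P rows
    accordingly."""
    K = p.shape[0]
    if reference_freqs.shape[0] != K:
        raise ValueError("need one reference frequency row per component")
    corr = np.empty((K, K))
    for k in range(K):
        for r in range(K):
            ok = np.isfinite(reference_freqs[r])
            c = np.corrcoef(p[k, ok], reference_freqs[r, ok])[0, 1]
            corr[k, r] = 0.0 if np.isnan(c) else c
    rows, cols = linear_sum_assignment(-corr)
    order = np.empty(K, dtype=int)
    order[cols] = rows  # component that maps to each reference population
    return (
        QMatrix(samples=list(q.samples), q=q.q[:, order],
                components=tuple(component_names[:K])),
        p[order],
    )


def kmeans_elbow(
    q: QMatrix,
    k_min: int = 1,
    k_max: int = 10,
    n_restarts: int = 25,
    seed: int | None = None,
) -> AncestryClusters:
    """K-means over a range of K with the elbow criterion.

    The chosen K is the knee of the log within-cluster sum of squares: the
    K whose log-inertia lies furthest below the secant from
    (k_min, log I(k_min)) to (k_max, log I(k_max)); ties break toward
    smaller K. Working on the log scale makes the criterion
    scale-invariant — on a K*-cluster mixture the inertia shrinks by a
    roughly constant factor per added cluster up to K* and flattens
    there, so the knee sits at K* rather than at the largest absolute
    drop (which always favors very small K). If the data are already
    perfectly explained at ``k_min`` (zero inertia), ``k_min`` is chosen.
    Data with no cluster structure have no elbow, and the chosen K is
    then arbitrary — as for any elbow-style rule.
    """
    n = q.q.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    if k_min < 1 or k_min > k_max:
        raise ValueError("require 1 <= k_min <= k_max")
    ss = np.random.SeedSequence(seed)
    fits: dict[int, KMeans] = {}
    inertia: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)))
        km.fit(q.q)
        fits[k] = km
        inertia[k] = float(km.inertia_)

    if inertia[k_min] <= 1e-12 or k_max == k_min:
        chosen = k_min
    else:
        ks = np.arange(k_min, k_max + 1)
        floor = 1e-12 * inertia[k_min]
        log_i = np.log([max(inertia[k], floor) for k in ks])
        t = (ks - ks[0]) / (ks[-1] - ks[0])
        secant = log_i[0] + t * (log_i[-1] - log_i[0])
        gap = secant - log_i
        best = np.flatnonzero(gap >= gap.max() - 1e-12)[0]
        chosen = int(ks[best])
    km = fits[chosen]
    logger.info("kmeans_elbow: chose K=%d (inertia %.4g)", chosen, inertia[chosen])
    return AncestryClusters(
        k=chosen,
        assignment=km.labels_,
        centroids=km.cluster_centers_,
        names=[],
        inertia_curve=inertia,
    )


def label_clusters(
    clusters: AncestryClusters,
    q: QMatrix,
    dominance_threshold: float = 0.65,
) -> AncestryClusters:
    """Name clusters from their centroids: a centroid whose largest ancestry
    component reaches ``dominance_threshold`` is named for that component
    (AFR/AME/EUR); the rest become ADX1, ADX2, ... ordered by decreasing
    European fraction (ADX1 sits closest to the European-like cluster).

    If two centroids claim the same ancestral name, the more dominant one
    keeps it and the other joins the admixed series.
    """
    cent = clusters.centroids
    comp = q.components
    eur_col = comp.index("EUR") if "EUR" in comp else cent.shape[1] - 1
    claims: dict[str, list[tuple[float, int]]] = {}
    for c in range(cent.shape[0]):
        top = int(np.argmax(cent[c]))
        if cent[c, top] >= dominance_threshold:
            claims.setdefault(comp[top], []).append((float(cent[c, top]), c))
    names: dict[int, str] = {}
    for pop, claimants in claims.items():
        claimants.sort(reverse=True)
        names[claimants[0][1]] = pop
    admixed = [c for c in range(cent.shape[0]) if c not in names]
    admixed.sort(key=lambda c: -cent[c, eur_col])
    for rank, c in enumerate(admixed, start=1):
        names[c] = f"ADX{rank}"
    return AncestryClusters(
        k=clusters.k,
        assignment=clusters.assignment.copy(),
        centroids=cent.copy(),
        names=[names[c] for c in range(cent.shape[0])],
        inertia_curve=dict(clusters.inertia_curve),
    )
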