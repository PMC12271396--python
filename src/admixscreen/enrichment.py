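"""Ancestry-enrichment screening.

For every variant the cohort is reduced to a 2 x k table of reference and
alternate allele counts across the k categorical ancestry groups. The
screen then computes:

* a two-sided Fisher exact p-value under the fixed-margins multivariate
  hypergeometric null, by probability-mass ordering: p is the total
  probability of all tables with the observed margins whose probability is
  at most that of the observed table. The sum is evaluated by a pruned
  depth-first enumeration over column compositions with exact upper and
  lower bounds on the attainable table probability of every subtree, so
  whole branches are either added in closed form (Vandermonde identity) or
  discarded. When the enumeration exceeds a node budget the p-value falls
  back to Monte-Carlo sampling of fixed-margin tables;
* a multi-group fixation index F_ST = 1 - H_S_bar / H_T, where H_T = 2pq
  from the pooled allele frequencies and H_S_bar is the within-group
  heterozygosity weighted by the proportion of individuals per group;
* per-ancestry Poisson regressions of genotype dosage on the continuous
  ancestry fraction (log link, fit by iteratively reweighted least squares).

Variants passing the genome-wide threshold are annotated and partitioned
into pharmacogenomic and clinical hit lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import norm

from .ancestry import AncestryClusters, QMatrix
from .harmonize import MergedCohort
from .simulate import Annotation, AnnotationCatalog
from .variants import MISSING, VariantKey

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8
# Relative tolerance when comparing a candidate table's probability with the
# observed table's (counts probability ties as "at most as probable").
TIE_RTOL = 1e-7


@dataclass
class ContingencyTable2xK:
    """Reference/alternate allele counts across k ancestry groups."""

    names: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if not (len(self.names) == self.ref_counts.size == self.alt_counts.size):
            raise ValueError("names, ref_counts, alt_counts must have equal length")
        if np.any(self.ref_counts < 0) or np.any(self.alt_counts < 0):
            raise ValueError("allele counts must be non-negative")

    @property
    def column_totals(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def grand_total(self) -> int:
        return int(self.column_totals.sum())

    def alt_frequencies(self) -> np.ndarray:
        tot = self.column_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.alt_counts / np.maximum(tot, 1), np.nan)

    def drop_empty_columns(self) -> "ContingencyTable2xK":
        keep = self.column_totals > 0
        return ContingencyTable2xK(
            names=[n for n, k in zip(self.names, keep) if k],
            ref_counts=self.ref_counts[keep],
            alt_counts=self.alt_counts[keep],
        )


@dataclass
class FisherResult:
    p: float
    method: str  # "exact" or "monte_carlo"
    se: float | None = None  # Monte-Carlo standard error
    nodes: int = 0


@dataclass
class FstComputation:
    p_i: np.ndarray
    q_i: np.ndarray
    f_i: np.ndarray
    h_t: float
    h_s_bar: float
    fst: float
    monomorphic: bool = False


@dataclass
class PoissonFit:
    ancestry: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    wald_p: float
    converged: bool


@dataclass
class EnrichmentResult:
    key: VariantKey
    table: ContingencyTable2xK
    fisher: FisherResult
    fst: FstComputation
    enriched_cluster: str
    annotation: Annotation
    poisson_fits: list[PoissonFit] = field(default_factory=list)


def build_allele_table(
    genotypes: np.ndarray, cluster_names_per_sample: list[str], cluster_order: list[str]
) -> ContingencyTable2xK:
    """Per-cluster allele counts at one site.

    ``genotypes`` is the per-sample dosage vector ({0,1,2} with -1 missing).
    For each cluster, alt = sum of dosages over non-missing samples and
    ref = 2 * n_nonmissing - alt; missing samples contribute nothing. A
    cluster with the site entirely missing keeps a (0, 0) column.
    """
    genotypes = np.asarray(genotypes)
    labels = np.asarray(cluster_names_per_sample)
    if genotypes.shape[0] != labels.shape[0]:
        raise ValueError("one cluster label per sample required")
    ref = np.zeros(len(cluster_order), dtype=np.int64)
    alt = np.zeros(len(cluster_order), dtype=np.int64)
    for c, name in enumerate(cluster_order):
        sub = genotypes[labels == name]
        called = sub != MISSING
        alt[c] = int(sub[called].sum())
        ref[c] = 2 * int(called.sum()) - alt[c]
    if np.any(ref + alt == 0):
        logger.debug("build_allele_table: empty column(s) retained")
    return ContingencyTable2xK(names=list(cluster_order), ref_counts=ref, alt_counts=alt)


class _WorkspaceExceeded(Exception):
    pass


def fisher_exact_2xk(
    table: ContingencyTable2xK,
    mc_cutoff: int = 500_000,
    mc_reps: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> FisherResult:
    """Two-sided Fisher exact test for a 2 x k allele-count table.

    Zero-total columns are dropped before testing. The exact path runs the
    pruned enumeration with a node budget of ``mc_cutoff``; past the budget
    the p-value is a Monte-Carlo estimate over ``mc_reps`` fixed-margin
    tables (reported with its standard error and the add-one estimator, so
    it is never exactly zero).
    """
    t = table.drop_empty_columns()
    if len(t.names) == 0:
        raise ValueError("all-zero contingency table")
    if len(t.names) == 1:
        return FisherResult(p=1.0, method="exact")
    cols = t.column_totals.astype(int)
    alts = t.alt_counts.astype(int)
    try:
        p, nodes = _exact_p(cols, alts, node_budget=mc_cutoff)
        return FisherResult(p=p, method="exact", nodes=nodes)
    except _WorkspaceExceeded:
        rng = np.random.default_rng(seed)
        p, se, hits = _monte_carlo_p(cols, alts, mc_reps, rng)
        if hits == 0:
            # No sampled table was as extreme as the observed one; a
            # Chernoff bound on the tail mass is then usually far sharper
            # than the add-one Monte-Carlo estimate and remains a valid
            # (deterministic) upper bound on the exact p-value.
            bound = _chernoff_upper_p(cols, alts)
            if bound < p:
                return FisherResult(p=bound, method="upper_bound")
        return FisherResult(p=p, method="monte_carlo", se=se)


def _log_choose_tables(cols: np.ndarray) -> list[np.ndarray]:
    """Per-column arrays of log C(c_i, a) for a = 0..c_i."""
    out = []
    for c in cols:
        a = np.arange(c + 1)
        out.append(gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1))
    return out


def _exact_p(cols: np.ndarray, alts: np.ndarray, node_budget: int) -> tuple[float, int]:
    k = cols.size
    A = int(alts.sum())
    N = int(cols.sum())
    lc = _log_choose_tables(cols)
    logw_obs = float(sum(lc[i][alts[i]] for i in range(k)))
    threshold = logw_obs + math.log1p(TIE_RTOL)

    # Suffix structures over columns i..k-1.
    suftot = np.concatenate([np.cumsum(cols[::-1])[::-1], [0]]).astype(int)
    cap = [min(A, int(suftot[i])) for i in range(k + 1)]

    # Upper bound: columns' log-binomial increments are decreasing (the
    # binomial row is log-concave), so the max over compositions with total
    # R is the sum of the R largest increments in the pooled suffix.
    lp_max: list[np.ndarray] = [None] * (k + 1)  # type: ignore[list-item]
    lp_max[k] = np.zeros(1)
    for i in range(k - 1, -1, -1):
        incs = np.concatenate(
            [lc[j][1:] - lc[j][:-1] for j in range(i, k)]
        ) if suftot[i] else np.empty(0)
        incs.sort()
        pref = np.concatenate([[0.0], np.cumsum(incs[::-1])])
        lp_max[i] = pref[: cap[i] + 1]

    # Lower bound: a concave-sum minimum over the box-with-simplex polytope
    # is attained at a vertex (all columns at 0 or capacity, at most one
    # fractional), enumerated exactly for these small k.
    lp_min: list[np.ndarray] = [None] * (k + 1)  # type: ignore[list-item]
    lp_min[k] = np.zeros(1)
    for i in range(k - 1, -1, -1):
        arr = np.full(cap[i] + 1, np.inf)
        suffix_cols = list(range(i, k))
        for mask in range(1 << len(suffix_cols)):
            cap_t = sum(int(cols[suffix_cols[b]]) for b in range(len(suffix_cols))
                        if mask >> b & 1)
            if cap_t > cap[i]:
                continue
            leftover = [suffix_cols[b] for b in range(len(suffix_cols))
                        if not (mask >> b & 1)]
            if not leftover:
                arr[cap_t] = min(arr[cap_t], 0.0)
                continue
            for j in leftover:
                hi = min(int(cols[j]), cap[i] - cap_t)
                if hi < 0:
                    continue
                seg = arr[cap_t: cap_t + hi + 1]
                np.minimum(seg, lc[j][: hi + 1], out=seg)
        lp_min[i] = arr

    lc_suf = [None] * (k + 1)
    for i in range(k + 1):
        if suftot[i] > 0:
            a = np.arange(cap[i] + 1)
            lc_suf[i] = gammaln(suftot[i] + 1) - gammaln(a + 1) - gammaln(suftot[i] - a + 1)
        else:
            lc_suf[i] = np.zeros(1)

    # Level-wise vectorized traversal: the frontier at column i is the set
    # of open prefixes (remaining count, partial log-weight); every child is
    # either added in closed form, pruned, or carried to the next level.
    acc: list[np.ndarray] = []
    nodes = 0
    front_r = np.array([A], dtype=np.int64)
    front_w = np.array([0.0])
    for i in range(k):
        if front_r.size == 0:
            break
        lo = np.maximum(0, front_r - int(suftot[i + 1]))
        hi = np.minimum(int(cols[i]), front_r)
        counts = hi - lo + 1
        total = int(counts.sum())
        node_idx = np.repeat(np.arange(front_r.size), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        a = np.arange(total) - np.repeat(starts, counts) + lo[node_idx]
        child_w = front_w[node_idx] + lc[i][a]
        r2 = front_r[node_idx] - a
        add = child_w + lp_max[i + 1][r2] <= threshold
        if add.any():
            acc.append(child_w[add] + lc_suf[i + 1][r2[add]])
        open_ = ~add & (child_w + lp_min[i + 1][r2] <= threshold)
        # bounds are tight at the last column, so nothing stays open past it
        front_r = r2[open_]
        front_w = child_w[open_]
        nodes += int(front_r.size)
        if nodes > node_budget:
            raise _WorkspaceExceeded
    log_total = gammaln(N + 1) - gammaln(A + 1) - gammaln(N - A + 1)
    flat = np.concatenate(acc) if acc else np.array([-np.inf])
    mx = float(flat.max())
    if not np.isfinite(mx):
        return 0.0, nodes
    p = float(np.exp(mx - log_total) * np.exp(flat - mx).sum())
    return min(p, 1.0), nodes


def _monte_carlo_p(
    cols: np.ndarray, alts: np.ndarray, reps: int, rng: np.random.Generator
) -> tuple[float, float, int]:
    lc = _log_choose_tables(cols)
    logw_obs = float(sum(lc[i][alts[i]] for i in range(cols.size)))
    threshold = logw_obs + math.log1p(TIE_RTOL)
    draws = rng.multivariate_hypergeometric(cols.tolist(), int(alts.sum()), size=reps)
    logw = np.zeros(reps)
    for i in range(cols.size):
        logw += lc[i][draws[:, i]]
    hits = int((logw <= threshold).sum())
    p = (hits + 1.0) / (reps + 1.0)
    se = math.sqrt(p * (1.0 - p) / reps)
    return p, se, hits


def _log_z(cols: np.ndarray, lc: list[np.ndarray], A: int, beta: float) -> float:
    """log sum over compositions a (sum a_i = A, 0 <= a_i <= c_i) of
    exp(beta * sum_i log C(c_i, a_i)), by log-space convolution over
    columns."""
    cur = np.zeros(1)
    for i in range(cols.size):
        c = int(cols[i])
        hi = min(A, cur.size - 1 + c)
        n_a = min(c, hi) + 1
        # log-space convolution: nxt[r] = LSE_a( beta*lc[a] + cur[r-a] ),
        # realized as a strided sliding-window view over a padded cur
        ext = np.concatenate([
            np.full(n_a - 1, -np.inf),
            cur,
            np.full(max(0, hi + 1 - cur.size), -np.inf),
        ])
        stride = ext.strides[0]
        win = np.lib.stride_tricks.as_strided(
            ext[n_a - 1:], shape=(hi + 1, n_a), strides=(stride, -stride)
        )
        m = win + beta * lc[i][:n_a]
        mx = m.max(axis=1)
        with np.errstate(invalid="ignore"):
            cur = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
        cur[~np.isfinite(mx)] = -np.inf
    return float(cur[A]) if A < cur.size else -np.inf


def _chernoff_upper_p(cols: np.ndarray, alts: np.ndarray) -> float:
    """Deterministic upper bound on the exact probability-mass p-value.

    With W the multivariate-hypergeometric probability weight of a random
    fixed-margins table, Markov's inequality on W^(-s) gives, for any s > 0,

        P(W <= w_obs) <= w_obs^s * E[W^(-s)]
                       = exp(s log w_obs + log Z(1 - s) - log C(N, A)),

    where Z(beta) sums the beta-th power of all table weights. The bound is
    taken as the minimum over a fixed grid of s values (the minimum over
    any subset of s remains a valid bound; the grid trades a little
    tightness for speed).
    """
    lc = _log_choose_tables(cols)
    A = int(alts.sum())
    N = int(cols.sum())
    logw_obs = float(sum(lc[i][alts[i]] for i in range(cols.size))) + math.log1p(TIE_RTOL)
    log_total = float(gammaln(N + 1) - gammaln(A + 1) - gammaln(N - A + 1))

    def log_bound(s: float) -> float:
        return s * logw_obs + _log_z(cols, lc, A, 1.0 - s) - log_total

    # ordered by typical tightness; stop once the bound is far below any
    # significance level in use (the partial minimum stays a valid bound)
    best = np.inf
    for s in (2.0, 4.0, 1.0, 8.0, 16.0, 0.5):
        best = min(best, log_bound(s))
        if best < math.log(1e-16):
            break
    return float(min(np.exp(best), 1.0))


def fst(table: ContingencyTable2xK, cluster_sizes: np.ndarray) -> FstComputation:
    """Multi-group fixation index F_ST = 1 - H_S_bar / H_T.

    H_T = 2pq from the pooled allele counts; H_S_bar = sum_i 2 p_i q_i f(i)
    with f(i) the proportion of individuals in group i. A monomorphic site
    (H_T = 0) returns F_ST = 0 with the ``monomorphic`` flag set; a group
    with zero allele total contributes zero heterozygosity with a warning.
    """
    sizes = np.asarray(cluster_sizes, dtype=float)
    if sizes.sum() <= 0:
        raise ValueError("cluster sizes must sum to a positive count")
    if table.grand_total <= 0:
        raise ValueError("overall allele total must be positive")
    tot = table.column_totals.astype(float)
    if np.any(tot == 0):
        logger.warning("fst: %d group(s) with zero allele total contribute H_i = 0",
                       int((tot == 0).sum()))
    q_i = np.divide(table.alt_counts, tot, out=np.zeros_like(tot), where=tot > 0)
    p_i = np.where(tot > 0, 1.0 - q_i, 0.0)
    f_i = sizes / sizes.sum()
    q = table.alt_counts.sum() / table.grand_total
    p = 1.0 - q
    h_t = 2.0 * p * q
    h_s_bar = float(np.sum(2.0 * p_i * q_i * f_i))
    if h_t == 0.0:
        return FstComputation(p_i=p_i, q_i=q_i, f_i=f_i, h_t=0.0, h_s_bar=h_s_bar,
                              fst=0.0, monomorphic=True)
    return FstComputation(p_i=p_i, q_i=q_i, f_i=f_i, h_t=h_t, h_s_bar=h_s_bar,
                          fst=1.0 - h_s_bar / h_t)


def poisson_ancestry_regression(
    genotypes: np.ndarray,
    ancestry_fraction: np.ndarray,
    ancestry_component: str,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PoissonFit:
    """Poisson log-link regression of genotype dosage on one continuous
    ancestry fraction, ``genotype ~ ancestry``, fit by IRLS with an
    intercept. Missing genotypes are excluded. If every genotype is zero
    the slope is unidentified (the likelihood increases toward -inf) and
    the fit is reported as not converged."""
    genotypes = np.asarray(genotypes, dtype=float)
    ancestry_fraction = np.asarray(ancestry_fraction, dtype=float)
    ok = genotypes != MISSING
    y = genotypes[ok]
    x = ancestry_fraction[ok]
    if y.size < 10:
        raise ValueError("need at least 10 non-missing samples")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("ancestry fractions must lie in [0, 1]")
    if np.all(y == 0):
        return PoissonFit(ancestry=ancestry_component, intercept=np.nan, slope=np.nan,
                          se_intercept=np.nan, se_slope=np.nan, wald_p=np.nan,
                          converged=False)
    exog = sm.add_constant(x, has_constant="add")
    try:
        res = sm.GLM(y, exog, family=sm.families.Poisson()).fit(
            maxiter=max_iter, tol=tol, scale=1.0
        )
    except Exception:  # perfect separation / numerical failure
        return PoissonFit(ancestry=ancestry_component, intercept=np.nan, slope=np.nan,
                          se_intercept=np.nan, se_slope=np.nan, wald_p=np.nan,
                          converged=False)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        return PoissonFit(ancestry=ancestry_component, intercept=float(params[0]),
                          slope=float(params[1]), se_intercept=np.nan, se_slope=np.nan,
                          wald_p=np.nan, converged=False)
    z = params[1] / bse[1] if bse[1] > 0 else 0.0
    wald_p = float(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny))
    return PoissonFit(
        ancestry=ancestry_component,
        intercept=float(params[0]),
        slope=float(params[1]),
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        wald_p=wald_p,
        converged=bool(getattr(res, "converged", True)),
    )


def designate_enriched_cluster(table: ContingencyTable2xK) -> str:
    """The ancestry group with the highest alternate-allele frequency;
    ties broken by larger allele total, then by name order."""
    tot = table.column_totals
    if np.all(tot == 0):
        raise ValueError("cannot designate enrichment for an all-empty table")
    freqs = table.alt_frequencies()
    best = np.nanmax(freqs)
    candidates = [
        i for i in range(len(table.names))
        if tot[i] > 0 and freqs[i] >= best - 1e-12
    ]
    candidates.sort(key=lambda i: (-tot[i], table.names[i]))
    return table.names[candidates[0]]


@dataclass
class ScreenResult:
    results: list[EnrichmentResult]
    n_sites_tested: int
    alpha: float

    @property
    def pharmacogenomic(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.annotation.pharm_level != "none"]

    @property
    def clinical(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.annotation.clinvar_class != "none"]


def screen_genome(
    cohort: MergedCohort,
    clusters: AncestryClusters,
    q: QMatrix,
    catalog: AnnotationCatalog | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    mc_cutoff: int = 500_000,
    mc_reps: int = 1_000_000,
    seed: int | None = None,
) -> ScreenResult:
    """Genome-wide screen for ancestry-enriched variants.

    For every site, build the 2 x k allele table across named ancestry
    groups and compute the Fisher exact p-value; sites with p < alpha are
    kept, and for those the screen computes F_ST, the enriched cluster,
    the three per-ancestry Poisson regressions, and attaches the catalog
    annotation. Results are sorted by ascending p.
    """
    if not clusters.names:
        raise ValueError("clusters must be named before screening")
    g = cohort.genotypes
    if g.n_sites == 0 or g.n_samples == 0:
        logger.warning("screen_genome: empty cohort")
        return ScreenResult(results=[], n_sites_tested=0, alpha=alpha)
    if q.samples != g.samples:
        raise ValueError("Q matrix and cohort sample order must match")
    sample_names = clusters.sample_names()
    order = sorted(set(sample_names), key=clusters.names.index)
    sizes = np.array([sum(1 for s in sample_names if s == name) for name in order])
    catalog = catalog or AnnotationCatalog()
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    n_tested = 0
    for j, key in enumerate(g.sites):
        geno = g.values[:, j]
        table = build_allele_table(geno, sample_names, order)
        if table.grand_total == 0:
            continue
        n_tested += 1
        fisher = fisher_exact_2xk(table, mc_cutoff=mc_cutoff, mc_reps=mc_reps, seed=rng)
        if fisher.p >= alpha:
            continue
        fits = []
        for k_comp, comp in enumerate(q.components):
            try:
                fits.append(poisson_ancestry_regression(geno, q.q[:, k_comp], comp))
            except ValueError:
                continue
        results.append(
            EnrichmentResult(
                key=key,
                table=table,
                fisher=fisher,
                fst=fst(table, sizes),
                enriched_cluster=designate_enriched_cluster(table),
                annotation=catalog.get(key),
                poisson_fits=fits,
            )
        )
    results.sort(key=lambda r: (r.fisher.p, r.key.sort_key))
    logger.info("screen_genome: %d/%d sites pass alpha=%.3g", len(results), n_tested, alpha)
    return ScreenResult(results=results, n_sites_tested=n_tested, alpha=alpha)
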