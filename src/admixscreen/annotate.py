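"""Diagnostic yield by ancestry group, evidence-level filtering, and
per-dataset allele-frequency summaries.

Diagnostic yield D_i^p is the percentage of the variants carried by
ancestry group i (at least one alternate allele among the group's
non-missing genotypes) that fall in pathogenicity class p (uncertain,
conflicting, pathogenic/likely pathogenic). The carried-variant denominator
makes yield comparable across groups of unequal size; an all-cohort-variant
denominator is available via ``denominator="all"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import AncestryClusters
from .enrichment import EnrichmentResult
from .harmonize import Dataset, MergedCohort
from .simulate import AnnotationCatalog
from .variants import MISSING

logger = logging.getLogger(__name__)

PATHOGENICITY_CLASSES = ("uncertain", "conflicting", "pathogenic_lp")
TOP_EVIDENCE_LEVELS = frozenset({"1A", "1B", "2A", "2B"})


@dataclass
class YieldTable:
    """Percent of each group's carried variants in each pathogenicity
    class, with the raw numerators and denominators alongside."""

    groups: list[str]
    classes: tuple[str, ...]
    percent: np.ndarray  # groups x classes
    numerators: np.ndarray
    denominators: np.ndarray  # per group

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups):
            for j, c in enumerate(self.classes):
                rows.append(
                    {
                        "group": g,
                        "class": c,
                        "numerator": int(self.numerators[i, j]),
                        "denominator": int(self.denominators[i]),
                        "percent": float(f"{self.percent[i, j]:.4g}"),
                    }
                )
        return pd.DataFrame(rows)


def diagnostic_yield(
    cohort: MergedCohort,
    clusters: AncestryClusters,
    catalog: AnnotationCatalog,
    denominator: str = "carried",
) -> YieldTable:
    """Compute D_i^p = 100 * (#class-p annotated variants carried by group
    i) / (#variants carried by group i) for each ancestry group and
    pathogenicity class."""
    if not clusters.names:
        raise ValueError("clusters must be named")
    if denominator not in {"carried", "all"}:
        raise ValueError("denominator must be 'carried' or 'all'")
    g = cohort.genotypes
    sample_names = np.asarray(clusters.sample_names())
    groups = sorted(set(sample_names.tolist()))
    site_class = np.array(
        [PATHOGENICITY_CLASSES.index(catalog.get(k).clinvar_class)
         if catalog.get(k).clinvar_class in PATHOGENICITY_CLASSES else -1
         for k in g.sites]
    )
    percent = np.zeros((len(groups), len(PATHOGENICITY_CLASSES)))
    nums = np.zeros_like(percent, dtype=int)
    denoms = np.zeros(len(groups), dtype=int)
    for i, grp in enumerate(groups):
        rows = sample_names == grp
        if not rows.any():
            logger.warning("diagnostic_yield: empty ancestry group %s", grp)
            continue
        sub = g.values[rows]
        carried = ((sub != MISSING) & (sub > 0)).any(axis=0)
        denom = int(carried.sum()) if denominator == "carried" else g.n_sites
        denoms[i] = denom
        for j in range(len(PATHOGENICITY_CLASSES)):
            nums[i, j] = int((carried & (site_class == j)).sum())
            if denom > 0:
                percent[i, j] = 100.0 * nums[i, j] / denom
    return YieldTable(
        groups=groups,
        classes=PATHOGENICITY_CLASSES,
        percent=percent,
        numerators=nums,
        denominators=denoms,
    )


def filter_by_evidence(
    results: list[EnrichmentResult],
    keep_levels: frozenset[str] | set[str] = TOP_EVIDENCE_LEVELS,
) -> list[EnrichmentResult]:
    """Retain results whose pharmacogenomic evidence level is in
    ``keep_levels``; ordering preserved."""
    return [r for r in results if r.annotation.pharm_level in keep_levels]


def summarize_frequencies(datasets: list[Dataset]) -> pd.DataFrame:
    """Per-dataset, per-variant allele counts and frequencies.

    Columns: dataset, variant, allele_count (2 x non-missing samples),
    ref_freq, alt_freq. A variant absent from a dataset produces no row.
    Variants with zero called genotypes in a dataset are likewise omitted
    (their frequencies are undefined).
    """
    rows = []
    for ds in datasets:
        g = ds.genotypes
        called = g.values != MISSING
        counts = 2 * called.sum(axis=0)
        alt = np.where(called, g.values, 0).sum(axis=0)
        for j, key in enumerate(g.sites):
            if counts[j] == 0:
                continue
            alt_freq = alt[j] / counts[j]
            rows.append(
                {
                    "dataset": ds.id,
                    "variant": str(key),
                    "allele_count": int(counts[j]),
                    "ref_freq": 1.0 - alt_freq,
                    "alt_freq": float(alt_freq),
                }
            )
    return pd.DataFrame(rows, columns=["dataset", "variant", "allele_count", "ref_freq", "alt_freq"])
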