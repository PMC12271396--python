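"""Core containers: normalized variant identities and genotype matrices.

Genotypes are stored as alternate-allele dosages for diploid, biallelic,
autosomal sites: values in {0, 1, 2}, with ``MISSING`` (-1) for no-calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


class VariantRecordError(ValueError):
    """Raised for a raw variant record that cannot form a valid key."""


@dataclass(frozen=True)
class VariantKey:
    """Normalized ``chrom:pos:ref:alt`` identity used to match variants
    across datasets regardless of the platform that produced them.

    ``chrom`` is stored without any ``chr`` prefix; ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantRecordError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantRecordError("empty ref or alt allele")
        if self.ref == self.alt:
            raise VariantRecordError(
                f"ref and alt alleles are identical ({self.ref}) at "
                f"{self.chrom}:{self.pos}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_record(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key from a raw record, stripping any ``chr`` prefix and
        upper-casing alleles. Idempotent on already-normalized input."""
        chrom = _CHR_PREFIX.sub("", str(chrom).strip())
        return cls(chrom=chrom, pos=int(pos), ref=str(ref).upper(), alt=str(alt).upper())

    @classmethod
    def from_string(cls, key: str) -> "VariantKey":
        parts = key.split(":")
        if len(parts) != 4:
            raise VariantRecordError(f"malformed variant key {key!r}")
        chrom, pos, ref, alt = parts
        return cls.from_record(chrom, int(pos), ref, alt)

    @property
    def sort_key(self) -> tuple:
        """Genomic ordering: numeric chromosomes first in numeric order,
        then other labels lexicographically, then position."""
        try:
            return (0, int(self.chrom), "", self.pos, self.ref, self.alt)
        except ValueError:
            return (1, 0, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """``n_samples x n_sites`` matrix of alternate-allele dosages.

    ``values`` uses int8 with -1 encoding a missing genotype.
    """

    samples: list[str]
    sites: list[VariantKey]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        allowed = {MISSING, 0, 1, 2}
        present = set(np.unique(self.values).tolist())
        if not present <= allowed:
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {present - allowed}")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate variant keys within one genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def site_missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return self.missing_mask().mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-site alternate allele frequency over non-missing alleles.

        Sites with no called genotypes get NaN.
        """
        called = ~self.missing_mask()
        alt = np.where(called, self.values, 0).sum(axis=0).astype(float)
        total = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / np.maximum(total, 1), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        aaf = self.alt_allele_frequency()
        return np.minimum(aaf, 1.0 - aaf)

    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in index],
            values=self.values[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            sites=list(self.sites),
            values=self.values[index, :].copy(),
        )

    def site_index(self) -> dict[VariantKey, int]:
        return {k: i for i, k in enumerate(self.sites)}


def unique_sites(keys: Iterable[VariantKey]) -> list[VariantKey]:
    """Deduplicate while preserving first-seen order."""
    seen: dict[VariantKey, None] = {}
    for k in keys:
        seen.setdefault(k)
    return list(seen)
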