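"""Core SNP data structures for sweep scanning.

The scanning unit is the *SNP vector*: an entire alignment column, i.e. one
binary allele state (0 = ancestral, 1 = derived) per sampled haplotype.
Distinct columns are deduplicated in a fixed-memory :class:`PatternPool`, and
each SNP is reduced to the triplet (pattern ID, bp location, derived-allele
count) stored column-wise in a :class:`SNPChunk`.  All window statistics run
on the triplets; the allele matrix itself is only touched once, at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

DEFAULT_POOL_BUDGET = 1_048_576  # bytes


class InputError(ValueError):
    """Malformed in-memory input (shape/length/value violations)."""


class ConfigurationError(ValueError):
    """Infeasible configuration (e.g. pattern pool too small for one window)."""


class PoolFullError(RuntimeError):
    """Raised when an unmatched SNP vector arrives at a full pattern pool.

    The caller is expected to flush (compute the pending chunk, relocate the
    window tail) and retry the insertion into the fresh pool.
    """


@dataclass
class SNPVector:
    """One alignment column: binary states for S haplotypes at one site."""

    alleles: np.ndarray
    location: int
    derived_count: int

    @classmethod
    def from_alleles(cls, alleles: Sequence[int] | np.ndarray, location: int) -> "SNPVector":
        arr = np.asarray(alleles, dtype=np.uint8)
        if arr.ndim != 1:
            raise InputError("allele vector must be one-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise InputError("allele states must be 0 (ancestral) or 1 (derived)")
        if location < 1:
            raise InputError(f"bp location must be >= 1, got {location}")
        return cls(alleles=arr, location=int(location), derived_count=int(arr.sum()))

    @property
    def sample_count(self) -> int:
        return self.alleles.shape[0]

    def is_polymorphic(self) -> bool:
        return 1 <= self.derived_count <= self.sample_count - 1


@dataclass
class Dataset:
    """An ordered set of SNP columns over a genomic region.

    ``genotypes`` is a (snp_count, sample_count) uint8 matrix; row *i* is the
    allele vector of the *i*-th SNP.  Locations are 1-based bp coordinates,
    non-decreasing, within [1, region_length].
    """

    genotypes: np.ndarray
    locations: np.ndarray
    region_length: int
    name: str = ""

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.uint8)
        self.locations = np.asarray(self.locations, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise InputError("genotypes must be a 2-D (snps x samples) matrix")
        if self.locations.shape != (self.genotypes.shape[0],):
            raise InputError("one location per SNP is required")
        if self.region_length <= 0:
            raise InputError("region_length must be positive")
        if self.locations.size:
            if (np.diff(self.locations) < 0).any():
                raise InputError("SNP locations must be non-decreasing")
            if self.locations[0] < 1 or self.locations[-1] > self.region_length:
                raise InputError("SNP locations must lie in [1, region_length]")

    @property
    def sample_count(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_count(self) -> int:
        return self.genotypes.shape[0]

    @property
    def derived_counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=1, dtype=np.int64)

    @property
    def snps(self) -> Iterator[SNPVector]:
        counts = self.derived_counts
        for i in range(self.snp_count):
            yield SNPVector(self.genotypes[i], int(self.locations[i]), int(counts[i]))


def filter_monomorphic(dataset: Dataset) -> tuple[Dataset, int]:
    """Drop columns with derived count 0 or S (the window factors are
    undefined on them); returns the filtered dataset and the removed count."""
    counts = dataset.derived_counts
    keep = (counts >= 1) & (counts <= dataset.sample_count - 1)
    removed = int((~keep).sum())
    if removed == 0:
        return dataset, 0
    filtered = Dataset(
        genotypes=dataset.genotypes[keep],
        locations=dataset.locations[keep],
        region_length=dataset.region_length,
        name=dataset.name,
    )
    return filtered, removed


def per_pattern_bytes(sample_count: int, packed: bool = True) -> int:
    """Storage accounting for one pattern: packed bits by default
    (ceil(S/8) bytes), or one byte per state with ``packed=False``."""
    if sample_count <= 0:
        raise ConfigurationError("sample count must be positive")
    return math.ceil(sample_count / 8) if packed else sample_count


def pool_capacity(
    memory_budget: int,
    sample_count: int,
    min_patterns: int = 1,
    packed: bool = True,
) -> int:
    """Maximum number of distinct patterns a budget of bytes can hold.

    Raises :class:`ConfigurationError` when fewer than ``min_patterns`` fit
    (callers pass the window size so one full window always fits).
    """
    if memory_budget <= 0:
        raise ConfigurationError("memory budget must be positive")
    cap = memory_budget // per_pattern_bytes(sample_count, packed=packed)
    if cap < max(min_patterns, 1):
        raise ConfigurationError(
            f"pool budget of {memory_budget} B holds {cap} patterns for "
            f"S={sample_count}; at least {max(min_patterns, 1)} required"
        )
    return cap


class PatternPool:
    """Deduplicated store of distinct SNP-vector patterns under a byte budget.

    Lookup is by exact content equality (hash of the raw column bytes); no
    complement/folded matching — input is assumed polarized.
    """

    def __init__(
        self,
        sample_count: int,
        memory_budget: int = DEFAULT_POOL_BUDGET,
        min_capacity: int = 1,
        packed: bool = True,
    ) -> None:
        self.sample_count = sample_count
        self.memory_budget = memory_budget
        self.capacity = pool_capacity(
            memory_budget, sample_count, min_patterns=min_capacity, packed=packed
        )
        self._index: dict[bytes, int] = {}
        self._patterns: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._patterns)

    @property
    def is_full(self) -> bool:
        return len(self._patterns) >= self.capacity

    def pattern(self, pattern_id: int) -> np.ndarray:
        return self._patterns[pattern_id]

    @property
    def patterns(self) -> list[np.ndarray]:
        return list(self._patterns)

    def match_or_insert(self, alleles: np.ndarray) -> tuple[int, bool]:
        """Return (pattern ID, is_new); raises :class:`PoolFullError` when the
        pool is at capacity and the vector matches no stored pattern."""
        v = np.ascontiguousarray(alleles, dtype=np.uint8)
        if v.shape != (self.sample_count,):
            raise InputError(
                f"allele vector length {v.shape} does not match S={self.sample_count}"
            )
        key = v.tobytes()
        hit = self._index.get(key)
        if hit is not None:
            return hit, False
        if self.is_full:
            raise PoolFullError(
                f"pattern pool at capacity ({self.capacity}); flush the chunk"
            )
        new_id = len(self._patterns)
        self._index[key] = new_id
        self._patterns.append(v.copy())
        return new_id, True


@dataclass
class SNPChunk:
    """Compact per-SNP triplets (pattern ID, bp location, derived count)."""

    pattern_ids: np.ndarray
    locations: np.ndarray
    derived_counts: np.ndarray

    def __post_init__(self) -> None:
        self.pattern_ids = np.asarray(self.pattern_ids, dtype=np.int64)
        self.locations = np.asarray(self.locations, dtype=np.int64)
        self.derived_counts = np.asarray(self.derived_counts, dtype=np.int64)
        n = self.pattern_ids.shape[0]
        if self.locations.shape[0] != n or self.derived_counts.shape[0] != n:
            raise InputError("chunk triplet vectors must have identical length")
        if n and (np.diff(self.locations) < 0).any():
            raise InputError("chunk locations must be non-decreasing")

    def __len__(self) -> int:
        return self.pattern_ids.shape[0]


def build_chunk(dataset: Dataset, pool: PatternPool) -> SNPChunk:
    """Load a whole (pre-filtered) dataset into one pool/chunk pair."""
    ids = np.empty(dataset.snp_count, dtype=np.int64)
    for i in range(dataset.snp_count):
        ids[i], _ = pool.match_or_insert(dataset.genotypes[i])
    return SNPChunk(ids, dataset.locations.copy(), dataset.derived_counts)
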