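"""The composite mu statistic for selective-sweep detection.

A window ``W`` of an even number ``W_sz`` of consecutive SNPs slides along the
chromosome with a step of one SNP, and is scored as

    mu = D_ln * mu_var * mu_sfs * mu_ld

where, for a region of ``D_ln`` bp,

* ``mu_var``  — (bp span of the window) / (D_ln * W_sz): a fixed SNP count
  spread over more base pairs means locally reduced diversity, the first
  sweep signature;
* ``mu_sfs``  — fraction of window SNPs whose derived-allele count is 1 or
  S - 1: the sweep-induced shift of the site frequency spectrum toward
  singletons and high-frequency derived variants;
* ``mu_ld``   — an occurrence-based proxy of the sweep LD layout (high LD
  within each flank, low LD across the selected site), computed from the
  distinct SNP-vector patterns of the two window halves L and R:

      (n_SL * n_PL + n_SR * n_PR) / (P_Lsz * P_Rsz)

  with n_SL the number of left-half SNPs (with multiplicity) whose pattern
  does not occur in the right half, n_PL the number of distinct left-half
  patterns absent from the right half, and symmetrically for the right side.

The weighted variant (mu_var)^k * mu_sfs * mu_ld (0 <= k <= 1) down-weights
the diversity factor where the mutation rate varies along the chromosome;
k = 1 is the plain product.

Each score is attributed to the bp midpoint between the first and the last
SNP of its window.  ``scan_naive`` recomputes every window from scratch and
serves as the oracle; ``scan_incremental`` maintains exact integer running
state so each one-SNP shift costs O(1), and reproduces the oracle bit for
bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .snp_core import (
    DEFAULT_POOL_BUDGET,
    Dataset,
    InputError,
    PatternPool,
    PoolFullError,
    SNPChunk,
)

__all__ = [
    "ScanConfig",
    "MuScore",
    "compute_mu_var",
    "compute_mu_sfs",
    "compute_mu_ld",
    "compute_mu",
    "window_location",
    "scan_naive",
    "scan_incremental",
    "relocate_tail",
    "ChunkedScanner",
]


@dataclass
class ScanConfig:
    """Scan parameters.

    window_size : even number of SNPs per window (default 50, i.e. halves of
        25 SNPs — large enough for stable pattern counts at S ~ 20).
    k : exponent on ``mu_var`` in [0, 1]; 1 gives the plain product.
    region_length : D_ln override (required for ms input, where positions
        are unit-interval fractions).
    mask : excluded bp intervals, 1-based inclusive (start, end) pairs;
        windows whose midpoint falls inside are flagged and left out of
        reports, but still counted in the raw score track.
    """

    window_size: int = 50
    k: float = 1.0
    region_length: int | None = None
    mask: Sequence[tuple[int, int]] = ()

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.window_size % 2 != 0:
            raise InputError("window_size must be an even integer >= 2")
        if not 0.0 <= self.k <= 1.0:
            raise InputError("k must lie in [0, 1]")


@dataclass
class MuScore:
    """One evaluated window position."""

    position: float
    mu_var: float
    mu_sfs: float
    mu_ld: float
    mu: float
    window_first_bp: int
    window_last_bp: int
    masked: bool = False


def compute_mu_var(first_bp: int, last_bp: int, region_length: int, window_size: int) -> float:
    """Diversity factor: window bp span normalised by region length and SNP count."""
    if region_length <= 0 or window_size <= 0:
        raise InputError("region_length and window_size must be positive")
    if last_bp < first_bp:
        raise InputError("window last bp precedes first bp")
    return (last_bp - first_bp) / (region_length * window_size)


def compute_mu_sfs(derived_counts: Sequence[int] | np.ndarray, sample_count: int) -> float:
    """SFS factor: fraction of window SNPs with derived count 1 or S - 1."""
    counts = np.asarray(derived_counts, dtype=np.int64)
    if counts.size == 0:
        raise InputError("empty window")
    if (counts < 1).any() or (counts > sample_count - 1).any():
        raise InputError("monomorphic site in window; filter the dataset first")
    hits = int(((counts == 1) | (counts == sample_count - 1)).sum())
    return hits / counts.size


def _ld_counts(
    left_ids: np.ndarray, right_ids: np.ndarray
) -> tuple[int, int, int, int, int, int]:
    left_set = set(left_ids.tolist())
    right_set = set(right_ids.tolist())
    n_sl = sum(1 for p in left_ids.tolist() if p not in right_set)
    n_pl = sum(1 for p in left_set if p not in right_set)
    n_sr = sum(1 for p in right_ids.tolist() if p not in left_set)
    n_pr = sum(1 for p in right_set if p not in left_set)
    return n_sl, n_pl, n_sr, n_pr, len(left_set), len(right_set)


def _mu_ld_from_counts(
    n_sl: int, n_pl: int, n_sr: int, n_pr: int, p_lsz: int, p_rsz: int
) -> float:
    return (n_sl * n_pl + n_sr * n_pr) / (p_lsz * p_rsz)


def compute_mu_ld(
    left_snp_ids: Sequence[int] | np.ndarray, right_snp_ids: Sequence[int] | np.ndarray
) -> float:
    """LD factor from the pattern IDs of the two window halves.

    SNPs are counted with multiplicity in the first term of each product;
    pattern-set membership drives the second term and the denominator.  When
    the halves share every pattern the numerator is 0, hence ``mu_ld`` = 0.
    """
    left = np.asarray(left_snp_ids, dtype=np.int64)
    right = np.asarray(right_snp_ids, dtype=np.int64)
    if left.size == 0 or right.size == 0:
        raise InputError("both window halves must be non-empty")
    return _mu_ld_from_counts(*_ld_counts(left, right))


def compute_mu(
    mu_var: float, mu_sfs: float, mu_ld: float, region_length: int, k: float = 1.0
) -> float:
    """Composite score D_ln * mu_var**k * mu_sfs * mu_ld (k = 1: plain product)."""
    if min(mu_var, mu_sfs, mu_ld) < 0:
        raise InputError("factors must be non-negative")
    if not 0.0 <= k <= 1.0:
        raise InputError("k must lie in [0, 1]")
    v = mu_var if k == 1.0 else mu_var**k
    return region_length * v * mu_sfs * mu_ld


def window_location(first_bp: int, last_bp: int) -> float:
    """Midpoint (real-valued, never rounded) between a window's end SNPs."""
    if last_bp < first_bp:
        raise InputError("window last bp precedes first bp")
    return (first_bp + last_bp) / 2


def _in_mask(position: float, mask: Sequence[tuple[int, int]]) -> bool:
    return any(start <= position <= end for start, end in mask)


def _emit(
    first_bp: int,
    last_bp: int,
    region_length: int,
    window_size: int,
    sfs_hits: int,
    n_sl: int,
    n_pl: int,
    n_sr: int,
    n_pr: int,
    p_lsz: int,
    p_rsz: int,
    k: float,
    mask: Sequence[tuple[int, int]],
) -> MuScore:
    # All window state is integer counters; divisions happen only here, so the
    # naive and incremental paths produce bitwise-identical floats.
    mu_var = compute_mu_var(first_bp, last_bp, region_length, window_size)
    mu_sfs = sfs_hits / window_size
    mu_ld = _mu_ld_from_counts(n_sl, n_pl, n_sr, n_pr, p_lsz, p_rsz)
    mu = compute_mu(mu_var, mu_sfs, mu_ld, region_length, k)
    pos = window_location(first_bp, last_bp)
    return MuScore(
        position=pos,
        mu_var=mu_var,
        mu_sfs=mu_sfs,
        mu_ld=mu_ld,
        mu=mu,
        window_first_bp=int(first_bp),
        window_last_bp=int(last_bp),
        masked=_in_mask(pos, mask),
    )


def _resolve_region_length(dataset: Dataset, config: ScanConfig) -> int:
    return config.region_length if config.region_length else dataset.region_length


def scan_naive(dataset: Dataset, config: ScanConfig | None = None) -> list[MuScore]:
    """Reference scan: every window recomputed from scratch.

    Emits exactly max(0, D_sz - W_sz + 1) scores in left-to-right order; a
    dataset with fewer SNPs than one window yields an empty track and a
    warning.
    """
    config = config or ScanConfig()
    w = config.window_size
    n = dataset.snp_count
    if n < w:
        warnings.warn(
            f"dataset has {n} SNPs, fewer than the window size {w}; no scores",
            stacklevel=2,
        )
        return []
    d_ln = _resolve_region_length(dataset, config)
    s = dataset.sample_count
    # Pattern identity by content over the whole dataset.
    index: dict[bytes, int] = {}
    ids = np.empty(n, dtype=np.int64)
    for i in range(n):
        ids[i] = index.setdefault(dataset.genotypes[i].tobytes(), len(index))
    counts = dataset.derived_counts
    if (counts < 1).any() or (counts > s - 1).any():
        raise InputError("monomorphic site present; apply filter_monomorphic first")
    locs = dataset.locations
    half = w // 2
    is_edge = (counts == 1) | (counts == s - 1)
    scores: list[MuScore] = []
    for t in range(n - w + 1):
        left = ids[t : t + half]
        right = ids[t + half : t + w]
        scores.append(
            _emit(
                int(locs[t]),
                int(locs[t + w - 1]),
                d_ln,
                w,
                int(is_edge[t : t + w].sum()),
                *_ld_counts(left, right),
                config.k,
                config.mask,
            )
        )
    return scores


class _WindowState:
    """Exact running counters for one sliding window.

    Tracks the left/right pattern multisets together with the four Eq-style
    exclusivity counters (exclusive SNPs and exclusive distinct patterns per
    side) and the singleton/high-frequency SNP count, all updated in O(1) per
    pattern arrival/departure.
    """

    __slots__ = ("cnt_l", "cnt_r", "excl_snps", "excl_pats", "sfs_hits")

    def __init__(self) -> None:
        self.cnt_l: dict[int, int] = {}
        self.cnt_r: dict[int, int] = {}
        self.excl_snps = [0, 0]  # [left, right]
        self.excl_pats = [0, 0]
        self.sfs_hits = 0

    def _add(self, side: int, p: int) -> None:
        own = self.cnt_l if side == 0 else self.cnt_r
        other = self.cnt_r if side == 0 else self.cnt_l
        c = own.get(p, 0)
        own[p] = c + 1
        oc = other.get(p, 0)
        if oc == 0:
            self.excl_snps[side] += 1
            if c == 0:
                self.excl_pats[side] += 1
        elif c == 0:
            # p becomes shared: the other side loses its exclusivity for p.
            self.excl_snps[1 - side] -= oc
            self.excl_pats[1 - side] -= 1

    def _remove(self, side: int, p: int) -> None:
        own = self.cnt_l if side == 0 else self.cnt_r
        other = self.cnt_r if side == 0 else self.cnt_l
        c = own[p]
        if c == 1:
            del own[p]
        else:
            own[p] = c - 1
        oc = other.get(p, 0)
        if oc == 0:
            self.excl_snps[side] -= 1
            if c == 1:
                self.excl_pats[side] -= 1
        elif c == 1:
            # p leaves this side entirely: the other side regains exclusivity.
            self.excl_snps[1 - side] += oc
            self.excl_pats[1 - side] += 1

    def add_left(self, p: int) -> None:
        self._add(0, p)

    def add_right(self, p: int) -> None:
        self._add(1, p)

    def remove_left(self, p: int) -> None:
        self._remove(0, p)

    def remove_right(self, p: int) -> None:
        self._remove(1, p)


def _scan_chunk(
    chunk: SNPChunk,
    sample_count: int,
    region_length: int,
    config: ScanConfig,
) -> Iterator[MuScore]:
    """Incremental scan of one chunk: initialise counters on the first window,
    then update them per one-SNP shift.  Windows needing SNPs beyond the chunk
    end are left to the next chunk (relocation carries the tail over)."""
    w = config.window_size
    n = len(chunk)
    if n < w:
        return
    ids = chunk.pattern_ids
    locs = chunk.locations
    counts = chunk.derived_counts
    if (counts < 1).any() or (counts > sample_count - 1).any():
        raise InputError("monomorphic site present; apply filter_monomorphic first")
    half = w // 2
    is_edge = (counts == 1) | (counts == sample_count - 1)
    state = _WindowState()
    for i in range(half):
        state.add_left(int(ids[i]))
    for i in range(half, w):
        state.add_right(int(ids[i]))
    state.sfs_hits = int(is_edge[:w].sum())
    for t in range(n - w + 1):
        yield _emit(
            int(locs[t]),
            int(locs[t + w - 1]),
            region_length,
            w,
            state.sfs_hits,
            state.excl_snps[0],
            state.excl_pats[0],
            state.excl_snps[1],
            state.excl_pats[1],
            len(state.cnt_l),
            len(state.cnt_r),
            config.k,
            config.mask,
        )
        if t + w < n:
            mid = int(ids[t + half])
            state.remove_left(int(ids[t]))
            state.remove_right(mid)
            state.add_left(mid)
            state.add_right(int(ids[t + w]))
            state.sfs_hits += int(is_edge[t + w]) - int(is_edge[t])


def relocate_tail(
    chunk: SNPChunk, pool: PatternPool, window_size: int
) -> tuple[SNPChunk, PatternPool]:
    """Carry the last ``window_size - 1`` SNPs into a fresh pool/chunk pair.

    Windows straddling a chunk boundary are thereby computed in the next
    chunk, exactly once.  Pattern IDs are re-mapped to the new pool; the new
    pool contains exactly the distinct patterns of the tail.
    """
    tail = window_size - 1
    new_pool = PatternPool(
        pool.sample_count, pool.memory_budget, min_capacity=window_size
    )
    if len(chunk) <= tail:  # nothing to drop: re-map everything
        tail = len(chunk)
    ids = np.empty(tail, dtype=np.int64)
    old_ids = chunk.pattern_ids[len(chunk) - tail :]
    for j, old in enumerate(old_ids):
        ids[j], _ = new_pool.match_or_insert(pool.pattern(int(old)))
    return (
        SNPChunk(
            ids,
            chunk.locations[len(chunk) - tail :].copy(),
            chunk.derived_counts[len(chunk) - tail :].copy(),
        ),
        new_pool,
    )


class ChunkedScanner:
    """Streaming scanner: SNPs arrive one by one, chunks are flushed when the
    pattern pool fills, and the W - 1 tail is relocated so every window is
    emitted exactly once.

    ``max_chunk_snps`` forces smaller chunks than the pool would allow (used
    to exercise boundary handling); it must be at least the window size.
    """

    def __init__(
        self,
        sample_count: int,
        region_length: int,
        config: ScanConfig | None = None,
        pool_budget: int = DEFAULT_POOL_BUDGET,
        max_chunk_snps: int | None = None,
    ) -> None:
        self.config = config or ScanConfig()
        if max_chunk_snps is not None and max_chunk_snps < self.config.window_size:
            raise InputError("max_chunk_snps must be >= window_size")
        self.sample_count = sample_count
        self.region_length = region_length
        self.max_chunk_snps = max_chunk_snps
        self.pool = PatternPool(
            sample_count, pool_budget, min_capacity=self.config.window_size
        )
        self._ids: list[int] = []
        self._locs: list[int] = []
        self._counts: list[int] = []
        self._total = 0
        self.chunks_flushed = 0
        # Instrumentation for the memory contract: peak SNPs resident at once.
        self.peak_resident_snps = 0

    def _current_chunk(self) -> SNPChunk:
        return SNPChunk(
            np.asarray(self._ids, dtype=np.int64),
            np.asarray(self._locs, dtype=np.int64),
            np.asarray(self._counts, dtype=np.int64),
        )

    def _flush(self) -> list[MuScore]:
        chunk = self._current_chunk()
        out = list(
            _scan_chunk(chunk, self.sample_count, self.region_length, self.config)
        )
        new_chunk, new_pool = relocate_tail(chunk, self.pool, self.config.window_size)
        self.pool = new_pool
        self._ids = new_chunk.pattern_ids.tolist()
        self._locs = new_chunk.locations.tolist()
        self._counts = new_chunk.derived_counts.tolist()
        self.chunks_flushed += 1
        return out

    def push(self, alleles: np.ndarray, location: int, derived_count: int) -> list[MuScore]:
        """Feed one SNP column; returns any scores that became computable."""
        out: list[MuScore] = []
        if (
            self.max_chunk_snps is not None
            and len(self._ids) >= self.max_chunk_snps
        ):
            out = self._flush()
        try:
            pid, _ = self.pool.match_or_insert(alleles)
        except PoolFullError:
            out = self._flush()
            pid, _ = self.pool.match_or_insert(alleles)
        self._ids.append(pid)
        self._locs.append(int(location))
        self._counts.append(int(derived_count))
        self._total += 1
        self.peak_resident_snps = max(self.peak_resident_snps, len(self._ids))
        return out

    def finish(self) -> list[MuScore]:
        """Flush the final chunk; warns when the whole stream held fewer SNPs
        than one window."""
        if self._total < self.config.window_size:
            warnings.warn(
                f"stream had {self._total} SNPs, fewer than the window size "
                f"{self.config.window_size}; no scores",
                stacklevel=2,
            )
            return []
        return list(
            _scan_chunk(
                self._current_chunk(),
                self.sample_count,
                self.region_length,
                self.config,
            )
        )


def scan_incremental(
    dataset: Dataset,
    config: ScanConfig | None = None,
    pool_budget: int = DEFAULT_POOL_BUDGET,
    max_chunk_snps: int | None = None,
) -> list[MuScore]:
    """Chunked incremental scan of a dataset; output equals :func:`scan_naive`."""
    config = config or ScanConfig()
    scanner = ChunkedScanner(
        dataset.sample_count,
        _resolve_region_length(dataset, config),
        config,
        pool_budget=pool_budget,
        max_chunk_snps=max_chunk_snps,
    )
    counts = dataset.derived_counts
    out: list[MuScore] = []
    for i in range(dataset.snp_count):
        out.extend(
            scanner.push(dataset.genotypes[i], int(dataset.locations[i]), int(counts[i]))
        )
    out.extend(scanner.finish())
    return out
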