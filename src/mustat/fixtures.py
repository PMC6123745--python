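"""Synthetic ms-format fixtures with controllable sweep-like structure.

This generator is deliberately *not* a coalescent simulator.  It manufactures
the three sweep signatures directly — a local SNP-density drop, an excess of
singletons and (S-1)-frequency derived variants, and homogeneous-but-disjoint
SNP patterns in the two flanks — so the expected value of every window factor
is analytically checkable.  Neutral columns draw their derived-allele count
from the standard neutral frequency spectrum (probability of count *i*
proportional to 1/i), with carriers chosen uniformly; positions are distinct
uniform draws over the region.

Geometry of a sweep fixture centred at ``center_bp`` for a region of L bp:

* core, ``center +- 0.025 L``: SNPs thinned by ``density_drop`` (keep
  probability 1/density_drop); surviving columns redrawn as singletons or
  (S-1)-count columns with probability ``sfs_skew``;
* flanks, the next ``0.15 L`` on each side: columns replaced, with
  probability ``flank_pattern_homogeneity``, by one of a few side-specific
  template patterns.  Templates carry S-1 derived alleles (distinct ancestral
  carrier per template, left and right sides disjoint), emulating hitchhiked
  high-frequency variants, so flank homogeneity feeds the SFS factor too;
  non-template flank columns are SFS-skewed at the same rate as the core;
* elsewhere: plain neutral columns.

Real data differ in ways this generator ignores: recombination makes flank
patterns decay gradually rather than switch at a boundary, signatures are
asymmetric, and demography perturbs the background spectrum.  Passing tests
therefore demonstrate correctness of the statistic and scanner, not power on
real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import ms_text
from .snp_core import Dataset, InputError

CORE_HALFWIDTH_FRACTION = 0.025
FLANK_WIDTH_FRACTION = 0.15


@dataclass
class SweepSpec:
    """Strength knobs for the embedded sweep signatures."""

    center_bp: Optional[int] = None  # default: region midpoint
    density_drop: float = 4.0  # core keep-probability is 1/density_drop
    sfs_skew: float = 0.7  # fraction of near-center columns redrawn as 1/(S-1)
    flank_pattern_homogeneity: float = 0.85  # fraction of flank columns templated
    flank_templates: int = 2  # template patterns per flank

    def __post_init__(self) -> None:
        if self.density_drop < 1:
            raise InputError("density_drop must be >= 1")
        for frac in (self.sfs_skew, self.flank_pattern_homogeneity):
            if not 0.0 <= frac <= 1.0:
                raise InputError("sweep fractions must lie in [0, 1]")
        if self.flank_templates < 1:
            raise InputError("at least one template pattern per flank")


@dataclass
class FixtureSpec:
    sample_count: int = 20
    snp_count: int = 1000
    region_length: int = 100_000
    seed: int = 0
    sweep: Optional[SweepSpec] = None

    def __post_init__(self) -> None:
        if self.sample_count < 2:
            raise InputError("need at least 2 haplotypes")
        if self.snp_count > self.region_length:
            raise InputError(
                "cannot place more distinct integer positions than base pairs"
            )


def _neutral_column(rng: np.random.Generator, s: int, weights: np.ndarray) -> np.ndarray:
    count = int(rng.choice(np.arange(1, s), p=weights))
    column = np.zeros(s, dtype=np.uint8)
    column[rng.permutation(s)[:count]] = 1
    return column


def _skewed_column(rng: np.random.Generator, s: int) -> np.ndarray:
    """A singleton or an (S-1)-count column, 50/50, random carrier."""
    column = np.zeros(s, dtype=np.uint8)
    carrier = int(rng.integers(s))
    if rng.random() < 0.5:
        column[carrier] = 1
    else:
        column[:] = 1
        column[carrier] = 0
    return column


def neutral_sfs_weights(sample_count: int) -> np.ndarray:
    """P(derived count = i) ~ 1/i for i in 1..S-1 (neutral expectation)."""
    w = 1.0 / np.arange(1, sample_count)
    return w / w.sum()


def _positions(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    pos = rng.choice(spec.region_length, size=spec.snp_count, replace=False) + 1
    pos.sort()
    return pos.astype(np.int64)


def generate_neutral(spec: FixtureSpec) -> tuple[Dataset, str]:
    """Neutral dataset: uniform positions, 1/i frequency spectrum; returns the
    in-memory dataset and its ms-format text (deterministic given seed)."""
    if spec.sweep is not None:
        raise InputError("spec carries a sweep block; use generate_sweep")
    rng = np.random.default_rng(spec.seed)
    positions = _positions(rng, spec)
    weights = neutral_sfs_weights(spec.sample_count)
    genotypes = np.vstack(
        [
            _neutral_column(rng, spec.sample_count, weights)
            for _ in range(spec.snp_count)
        ]
    )
    ds = Dataset(
        genotypes=genotypes,
        locations=positions,
        region_length=spec.region_length,
        name=f"neutral.seed{spec.seed}",
    )
    return ds, ms_text([ds])


def _flank_templates(
    rng: np.random.Generator, s: int, n_per_side: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """High-frequency-derived template patterns, disjoint between sides:
    template *j* is all-derived except one side-specific ancestral carrier."""
    if 2 * n_per_side > s:
        raise InputError("too many templates for the sample size")
    carriers = rng.permutation(s)[: 2 * n_per_side]
    left, right = [], []
    for j in range(n_per_side):
        for side, carrier in ((left, carriers[j]), (right, carriers[n_per_side + j])):
            column = np.ones(s, dtype=np.uint8)
            column[carrier] = 0
            side.append(column)
    return left, right


def generate_sweep(spec: FixtureSpec) -> tuple[Dataset, str]:
    """Dataset with the three sweep signatures embedded around the center.

    Core thinning removes SNPs, so the returned dataset holds slightly fewer
    than ``spec.snp_count`` columns.
    """
    if spec.sweep is None:
        raise InputError("spec lacks a sweep block; use generate_neutral")
    sw = spec.sweep
    rng = np.random.default_rng(spec.seed)
    s = spec.sample_count
    length = spec.region_length
    center = sw.center_bp if sw.center_bp is not None else length // 2
    core = CORE_HALFWIDTH_FRACTION * length
    flank = FLANK_WIDTH_FRACTION * length
    weights = neutral_sfs_weights(s)
    left_templates, right_templates = _flank_templates(rng, s, sw.flank_templates)

    positions = _positions(rng, spec)
    keep, columns = [], []
    for pos in positions:
        offset = pos - center
        in_core = abs(offset) <= core
        if in_core and rng.random() >= 1.0 / sw.density_drop:
            continue  # density drop: thin the core
        if in_core:
            column = (
                _skewed_column(rng, s)
                if rng.random() < sw.sfs_skew
                else _neutral_column(rng, s, weights)
            )
        elif core < abs(offset) <= core + flank:
            templates = left_templates if offset < 0 else right_templates
            if rng.random() < sw.flank_pattern_homogeneity:
                column = templates[int(rng.integers(len(templates)))]
            elif rng.random() < sw.sfs_skew:
                column = _skewed_column(rng, s)
            else:
                column = _neutral_column(rng, s, weights)
        else:
            column = _neutral_column(rng, s, weights)
        keep.append(pos)
        columns.append(column)
    ds = Dataset(
        genotypes=np.vstack(columns),
        locations=np.asarray(keep, dtype=np.int64),
        region_length=length,
        name=f"sweep.seed{spec.seed}",
    )
    return ds, ms_text([ds])


def generate(spec: FixtureSpec) -> tuple[Dataset, str]:
    """Dispatch on the presence of a sweep block."""
    return generate_sweep(spec) if spec.sweep is not None else generate_neutral(spec)
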