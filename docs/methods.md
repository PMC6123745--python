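# Methods

## Model and procedure

`mustat` scores a genomic region for recent hard selective sweeps with the
composite μ statistic.  The scan is SNP-driven: a window of a fixed *number
of SNPs* (not base pairs) slides one SNP at a time, so windows are narrow in
SNP-dense regions and wide in sparse ones and no per-dataset window-length
tuning is needed.  For a region of `D_ln` bp with `D_sz` SNPs, sample size
`S` haplotypes, and an even window size `W_sz` split into halves `L`/`R`:

* diversity factor `μ_VAR` — bp span of the window divided by
  `D_ln · W_sz`.  Under a constant mutation rate a fixed SNP count spans
  more base pairs exactly where the polymorphism level has dropped, the
  primary hitchhiking footprint.
* SFS factor `μ_SFS` — fraction of window SNPs whose derived-allele count is
  1 or `S − 1`.  It lies in [0, 1] by construction.
* LD factor `μ_LD` — occurrence counts over distinct SNP-vector patterns
  (whole alignment columns): `(n_SL·n_PL + n_SR·n_PR) / (P_Lsz·P_Rsz)`.
  Column multiplicities enter the first term of each product (a half whose
  SNPs repeat few side-private patterns scores high), pattern-set
  memberships the second.  A half's pattern set is always computed within
  the current window only, never from a wider cache.  When the two halves
  share every pattern the numerator, and hence μ, is 0.

The composite score is `μ = D_ln · μ_VAR · μ_SFS · μ_LD`, attributed to the
real-valued bp midpoint of the window's end SNPs.  For `k = 1` the `D_ln`
factor cancels against the `μ_VAR` denominator, so scores are invariant to
the nominal region length; the weighted form `(μ_VAR)^k · μ_SFS · μ_LD`
(`0 ≤ k ≤ 1`) is available for data where the mutation rate varies along the
chromosome and the diversity signal is unreliable.

Assumptions: binary, polarized alleles (0 ancestral, 1 derived); samples are
haplotypes; monomorphic columns are removed before scanning (the SFS and LD
factors are undefined on them).  Unpolarized data still scan — pattern
equality is exact content equality, no complement matching — but `μ_SFS`
then conflates counts 1 and `S − 1` with their complements' mirror images;
an `AA` INFO key can repolarize VCF input.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `window_size` (`-w`) | 50 SNPs | halves of 25 SNPs give stable pattern counts at `S ≈ 20`; must be even (the LD factor needs equal halves) |
| `k` | 1.0 | exponent on `μ_VAR`; lower it toward 0 when θ varies strongly along the chromosome |
| pool budget | 1 MiB | memory cap for the pattern pool; capacity = budget / ceil(S/8) bytes per pattern (packed-bit accounting), and must hold at least one window's worth of patterns |
| `region_length` (`-L`) | required for ms input | ms positions are unit-interval fractions; bp = round(fraction·L), halves up, clamped to ≥ 1 |
| mask (`-X`) | none | BED intervals (e.g. centromeres and flanks); windows whose midpoint falls inside are kept in the raw track but suppressed from reports |

## The two-step engine

SNPs stream through a fixed-size pattern pool; each SNP becomes a (pattern
ID, location, derived count) triplet in the current chunk.  When the pool
fills, all windows fully contained in the chunk are computed, then the last
`W_sz − 1` SNPs are relocated into a fresh pool/chunk so boundary-spanning
windows are computed exactly once in the next pass.  Window math keeps the
left/right pattern multisets plus four integer exclusivity counters
(side-exclusive SNPs and side-exclusive distinct patterns) and the
singleton/high-frequency count; each one-SNP shift updates them in O(1).
All counters are integers and divisions happen only at score emission, so
the incremental scanner reproduces the from-scratch oracle bit for bit —
the test suite asserts equality across 200 randomized datasets and several
chunkings.

Numerical/degenerate choices: duplicate columns and duplicate (even
zero-width) windows are legal; best-score location ties break leftmost;
positions are never rounded internally and reports print them with 2
decimals alongside the raw window span; datasets with fewer SNPs than one
window yield an empty track and a warning, not an error.

## Evaluation protocol

A run is reduced to its maximum μ and the leftmost midpoint attaining it
(max is the standard outlier reduction for a per-run summary).  Accuracy is
`100·|best − target|/D_ln`; the success rate counts runs with distance
< 1% of the region length.  Significance cutoffs are empirical order
statistics of neutral best scores — for level α and n runs, the
`ceil(n(1−α))`-th order statistic, the tightest cutoff whose empirical
exceedance is ≤ α (no interpolation: with ~1000 neutral runs the 95th
percentile is a clean order statistic).  TPR/FPR count runs *strictly*
above the cutoff (documented choice; matters only at ties).  ROC curves
sweep the cutoff over all observed scores; TPR-at-FPR reads the curve at
the largest achieved FPR ≤ the requested level.  Scores are interpolated
onto external grids by nearest evaluated midpoint (ties leftmost,
out-of-span clamps) so scores at evaluated points are preserved exactly.
Misspecification cells are `log10(rate_matched / rate_actual)`; a uniform
random classifier against a mid-region target has expected distance 25% of
the region length, the reference for "no power".

## The fixture generator

The generator manufactures the three sweep signatures directly rather than
simulating a coalescent, so the expected value of every factor is
analytically checkable.  Neutral columns: distinct uniform integer
positions; derived count drawn with probability ∝ 1/i (the neutral SFS);
carriers uniform.  A sweep fixture centred at `c` for a region of `L` bp
overlays, by default:

* core (`c ± 0.025·L`): SNPs kept with probability `1/density_drop`
  (default 4) — the diversity trough; survivors redrawn as singleton or
  `S−1`-count columns with probability `sfs_skew` (default 0.7);
* flanks (next `0.15·L` per side): columns replaced with probability
  `flank_pattern_homogeneity` (default 0.85) by one of 2 side-specific
  template patterns.  Templates carry `S − 1` derived alleles with a
  side-distinct ancestral carrier, emulating hitchhiked variants near
  fixation — flank homogeneity therefore feeds both the LD factor
  (side-private, repeated patterns) and the SFS factor.  Non-template flank
  columns are SFS-skewed at the core rate;
* elsewhere: neutral columns.

Defaults were chosen once as a strong, analytically transparent hard-sweep
emulation at the study scale used throughout (S = 20, ~1000 SNPs, 100 kb,
sweep at the centre).  What the generator does *not* reproduce: gradual
recombination-driven decay of the signatures with distance, asymmetry,
demographic perturbation of the background SFS, and correlated genealogies.
Passing the sweep-response tests therefore demonstrates that the statistic
and scanner respond to the three signatures as designed — not field power
on real genomes, which depends on demography and must be calibrated with
matched neutral simulations (the cutoff machinery exists for exactly that).

## Problem sizes

The test suite and `scripts/acceptance.py` use 100-replicate fixture sets
(~1000 SNPs each) for power properties, 200 randomized datasets
(S ∈ 4..64, up to 2000 SNPs) for oracle equivalence, and 1e5 draws for the
random-classifier baseline — sizes at which the order statistics and
binomial error bands in the assertions are meaningful.  All quantities the
documentation cites are computed by those scripts at run time.

## Known limitations

* Haplotype assignment for unphased heterozygotes is "as written" —
  deterministic but arbitrary; pattern-based factors are mildly sensitive
  to phasing errors.
* No complement/folded pattern matching for unpolarized data.
* The pool eviction policy is flush-on-full with window-tail relocation
  only; no cross-chunk pattern reuse beyond the tail.
* Single-threaded by design; the memory contract (resident SNP storage
  bounded by pool capacity + tail) is asserted via instrumentation
  counters, not OS measurement.
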