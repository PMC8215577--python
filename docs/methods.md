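# Methods

`hboscnv` detects copy-number variants (CNVs) from a single tumor sample's
read-depth (RD) profile, with no matched normal. The pipeline has five
stages per chromosome: (1) binning and GC correction, (2) gap splitting and
normal-weighted smoothing, (3) dynamic-width histogram density estimation,
(4) histogram-based outlier scoring (HBOS), (5) fence thresholding, call
assembly, and purity/copy-number assignment. This note records the model,
the parameters that matter, the numerical choices made where the design was
open, and what the simulator does and does not emulate.

## Signal model and preprocessing

The chromosome is cut into non-overlapping bins of `bin_size` bases
(default 1000; 500 is a common alternative). Each read is counted once, at
its leftmost mapped base, so a bin's raw RD `r~_m` is the mean read-start
count over its non-`N` reference positions. Bins whose reference is more
than 50% `N` (or entirely `N`) are masked out of every later stage.

GC bias is removed by stratification: bins are grouped in GC-fraction
windows of width 0.01 and each bin is rescaled as

    r_m = (rbar / rbar_gc[m]) * r~_m

with `rbar` the chromosome's mean raw RD and `rbar_gc[m]` the **median**
raw RD of bin *m*'s stratum. The median rather than the mean is used
because a stratum's mean is dragged by whatever CNV bins happen to share
its GC window; with the median, a locally constant profile stays exactly
constant after correction and event signal does not leak into normal bins.
Strata with fewer than 10 bins borrow the nearest populated stratum.
`rbar` is per-chromosome, matching every later stage.

## Gap splitting and smoothing

Telomeres and centromeres produce Mb-scale runs of (near-)zero RD. Usable
bins are clustered into two 1-D K-means groups (deterministic
initialisation at the min and max RD value); a bin is a gap candidate when
it falls in the lower-mean cluster *and* its RD is at most 10% of the mean.
Only candidate runs of at least 1 Mb are flagged as gaps. The length guard
is essential: a homozygous deletion in a high-purity sample also has RD ~ 0
but is at most a few hundred kb, while true gaps are Mb-scale; without the
guard such deletions would be unreachable by the caller.

Each non-gap segment is smoothed by a discrete convolution whose weights
are a normal density evaluated at integer bin offsets `-w..w`, renormalised
to sum to one so constant regions are preserved; segment ends are
reflect-padded to avoid edge attenuation that would mimic losses. The
half-width follows the `w = max(1, round(0.0001 * n))` rule (5 bins for a
47 Mb chromosome at 1 kb bins), so smaller bins imply a wider window.

The kernel's standard deviation (in bins) is data-driven:

    std = 2 * w * min(sigma, sigma_noise)

where `sigma = mean(|r_i - rbar|) / rbar` is the profile's relative mean
absolute deviation and `sigma_noise = median(|diff r|) / (sqrt(2) * 0.6745
* rbar)` is a robust first-difference estimate of the purely stochastic
bin-to-bin dispersion (insensitive to the sparse large jumps at CNV
boundaries). Using the dispersion *ratio* directly as a bandwidth in bins
would always yield a near-delta kernel (the ratio is ~0.05-0.2 on any
realistic profile), i.e. no smoothing at all; scaling by the window width
makes the bandwidth track the data as intended — noisier profiles get a
flatter kernel — while a noise-free piecewise-constant profile yields
`sigma_noise = 0` and hence an exact identity kernel. Typical WGS noise
(relative dispersion ~0.15) places the kernel std near 1.5 bins.

## Density estimation and scoring

Smoothed RD values of all usable bins (gap bins included) are sorted and
packed into `k = round(sqrt(n))` columns of `S = n/k` consecutive sorted
values each (fractional quotas are distributed by cumulative rounding, so
counts always sum to `n`). A column absorbs every value tied with its last
one, so identical RD values always share a column and a score. Column
height is `count / ((r_max - r_min) + 1)`; heights are normalised so the
tallest column is 1.0, and each bin scores

    HBOS = ln(1 / normalised_height)

The tallest column — on a gapped chromosome, the giant overflow column of
zero-RD gap bins; otherwise the densest normal column — scores exactly 0.
This is why gaps are immune to calling: their thousands of tied zeros give
a height that dominates the normalisation. The log base is immaterial (the
threshold is quantile-based); natural log is used. The `+1` in the height
denominator is kept verbatim; note it makes scores depend on the RD
scale (on count-scale RD ~ tens to hundreds it flattens the bulk columns'
scores, which the fence below relies on).

## Thresholding, calls, purity, copy number

The outlier threshold is the Tukey boxplot upper fence `Q3 + 1.5 * IQR`
over all usable bins' scores, with type-7 (linear interpolation)
quartiles. Bins strictly above the fence are outliers. Maximal runs of
outlier bins are assembled into calls, bridging at most `merge_gap = 1`
scoreable sub-threshold bin; gap and masked bins neither seed nor bridge
calls. Calls spanning fewer than `min_bins = 10` bins (10 kb at the
default bin size — the smallest event the method targets) are dropped;
this is the main false-positive control, since the fence intrinsically
admits ~2-3% of normal bins and short correlated-noise runs would
otherwise dominate the call set. Both knobs are CLI-tunable.

Classification and quantification use the GC-corrected *unsmoothed* RD
(the smoothed statistic is for scoring only; its edge bias would drag
event means toward the normal level). With `rbar` recomputed over normal
(non-called, non-gap) bins: a call is a gain iff its mean RD `r_t` exceeds
`rbar`, and its absolute copy number is

    CN = (r_t - (1 - phi) * rbar) * rho / (phi * rbar),   rho = 2

floored at 0, reported raw and rounded. Tumor purity `phi` is estimated
from the loss calls via the two loss-level equations
`r_hem = phi*rbar/2 + (1-phi)*rbar` and `r_hom = (1-phi)*rbar`, inverted
as `phi1 = 2*(1 - r_hem/rbar)` and `phi2 = 1 - r_hom/rbar`, with
`phi = (phi1 + phi2)/2` clipped to (0, 1]. Hemizygous and homozygous
levels are identified by clustering the loss calls' `r_t/rbar` ratios
(1-D 2-means, size-weighted centres): if the two centres separate by more
than 0.08 the lower level is homozygous; otherwise a single unresolved
level is split at the fixed `0.25 * rbar` boundary. A fixed boundary
alone would misclassify homozygous losses whenever purity < ~0.5 (a
homozygous loss at purity 0.4 sits at `0.6 * rbar`). Samples without
losses fall back to a user-supplied purity (default 1.0, with a warning).

## The simulator

`simulate_profile` emulates the benchmark design at RD level: per-bin
expected count `base * (phi*CN/rho + (1-phi)) * gc_response(gc)` with
`base = coverage * bin_size / read_length`, negative-binomial noise
(`var = mean + alpha * mean^2`), zero-coverage gaps, and a recorded truth
set. Defaults are the benchmark conditions: a 47 Mb chromosome, 1 kb bins,
8x coverage, purity 0.6, 14 disjoint CNVs of 10-500 kb with copy numbers
balanced over {0, 1, 3, 4}, dispersion `alpha = 0.01` (var/mean ~ 1.8 at
80 counts/bin, typical WGS overdispersion), a smooth sinusoidal GC track
(0.45 +/- 0.08, 3 Mb period, 0.01 jitter) with a unimodal depth response
dropping 20% in the GC tails, and Mb-scale telomere/centromere gaps.
Events are placed disjointly, bin-aligned, at least 10 bins from each
other and from gaps. Everything is reproducible from the seed.

What the simulator does **not** emulate: mappability artifacts, alignment
errors, sub-bin breakpoints, multi-chromosome structure, or SNV/BAF
signal. Detection metrics on it are therefore an upper bound on read-level
or real-data performance — the pipeline at 8x / purity 0.6 scores a mean
bin-level F1 around 0.95-0.98 here, whereas read-level benchmarks of the
same design report ~0.93.

Evaluation is bin-level: sensitivity is the fraction of truth bins covered
by a call of the matching direction, precision the fraction of called bins
inside a matching truth event, F1 their harmonic mean; an event-level
sensitivity (>= 50% of an event's bins covered) is reported alongside.
With no calls, precision uses the 0 convention; an empty truth set reports
NaN sensitivity.

## Numerical choices and degenerate inputs

- Quartiles: numpy's default linear interpolation (type 7).
- "Greater than the threshold" is strict, so a constant score vector
  (fence = Q3) produces zero calls.
- Kernel sigma floor 1e-6; below ~0.03 bins the off-centre weights
  underflow and the kernel is an exact identity.
- K-means steps are deterministic (fixed init at the data extremes,
  `n_init=1`, fixed random_state).
- A profile with fewer than 2 distinct RD values: one segment, no gaps.
- Fewer than 4 finite scores: thresholding raises rather than guessing.
- An all-zero or fully masked profile raises "no usable bins".
- Problem sizes in the test suite (10 replicates for the headline check, 6
  per purity level for the trend check, 1000 vectors for the oracle check)
  keep the full suite in the seconds-to-a-minute range while leaving the
  Monte-Carlo error well below the asserted margins.

## Known limitations

- Breakpoints are bin-resolution; no sub-bin refinement.
- The fence threshold has no significance model; extreme score
  distributions can inflate the false-positive rate (a parametric null for
  HBOS would be the principled upgrade).
- Purity estimation needs at least one loss; gain-only samples require
  `--purity`.
- Per-chromosome processing assumes the chromosome is large enough for the
  sqrt-rule histogram to be populated (a few thousand bins); very small
  contigs should be pooled or skipped.
- The GC correction targets human-like WGS; amplicon or exome capture bias
  is out of scope.
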