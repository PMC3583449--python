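# Methods

## Coordinate system and geometry

Internal coordinates are 0-based half-open; mutation tables and VCF are
read as 1-based, BED as 0-based half-open.  The chromosome is circular and
single-contig by assumption; multi-contig input is rejected.  Clockwise
distance from OriC is (pos − oric) mod L; a position belongs to the
clockwise replichore when that distance is strictly less than L/2, with the
midpoint assigned to the counterclockwise replichore (an arbitrary but
fixed tie-break).  The packaged *E. coli* K-12 geometry uses the exact
NC_000913.2 length (4,641,652 bp) with kb-rounded landmarks (OriC 3924 kb;
TerD 1279, TerA 1340, TerC 1607, TerB 1682 kb); both the exact and a
kb-rounded 4640-kb length put the four Ter sites in bins 20/21/24/24 of the
default 46-bin scheme.

## Binning

Bin width is real-valued (L/n bins) with floor indexing, so the division
remainder is spread uniformly rather than accumulated in a ragged last bin;
an integer-width variant (last bin absorbs the remainder) is available via
`BinConfig(integer_width=True)`.  `offset_fraction` displaces the start of
bin 1 by that fraction of one width (0.5 implements the half-bin
displacement used as a stability control).  Counts are conserved exactly
under every configuration.  Binning does not re-weight by callable
(non-repeat) length per bin, matching how such data are usually reported;
mutations cannot occur in repeats by construction of both the caller
upstream and the generator here.

Feature tables are aggregated per bin by sum (discrete counts such as
binding sites) or mean (qualitative per-gene values such as expression);
empty bins are 0 under sum and NaN under mean, and NaN bins are dropped
pairwise in correlations.  Averaging is usually the better-behaved choice
because summing confounds the per-gene signal with gene density; the test
suite demonstrates the effect on a synthetic gene track.

## Replichore folding and symmetry

Folding pairs bin k with bin n+1−k (k = 1 … ⌊n/2⌋); for odd n the middle
bin has no mirror partner and is dropped.  Symmetry is quantified by
Pearson's ρ between the paired vectors with the two-tailed p-value from
t = ρ√((n−2)/(1−ρ²)) on n−2 df — the same convention used for all
correlation p-values in the package.

## Gap analysis

Gaps are circular successive differences of the sorted positions; they sum
to L exactly and there is one gap per mutation.  Sites mutated in two lines
yield zero-length gaps and are kept by default (they are genuine
recurrences that contribute to short-range clustering); a flag collapses
them.  A gap is excluded when its open interval overlaps a repeat interval
(interval arithmetic; touching exactly at an endpoint does not exclude),
evaluated on the circle so the wrap-around gap is handled on both of its
linear segments.  After exclusion the mean gap is
effective length / retained count.

The randomness test compares the retained gaps to Exp(μ), μ fixed at the
mean gap, using K equal-probability quantile classes (default 20, reduced
so expected counts stay ≥ 5) and χ² with K−1 df.  Because μ is computed
from the same data, the test is mildly conservative: calibrated type-I
error over 1000 i.i.d. exponential samples is 0.03–0.045 at α = 0.05
(n = 200–1600).  A quartile Q-Q summary accompanies the statistic.

## Monte Carlo placement null

Each simulation draws the observed number of mutations: a substitution
class from the observed six-class spectrum, then a uniformly random
callable site whose base pair matches the class (an A:T>G:C mutation may
land on an A or a T — classes are strand-collapsed).  Repeat intervals are
excluded from eligibility because real calls there are impossible, so the
null and the data share the same territory.  Without a sequence the
placement degrades to uniform over callable sites (logged).  Totals are
conserved exactly per simulation; the ensemble reports per-simulation
bin-count variances and their summary.  For 1625 uniform placements in 46
bins the expected per-simulation sample variance is the multinomial value
m(1−1/n)·n/(n−1) ≈ 35.3 (m = mean count), which the ensemble reproduces
within Monte Carlo error.

The dispersion test reports (n−1)s²/x̄ against χ²(n−1), two-sided: both
clustering (overdispersion) and regularity matter.  The pattern χ²
Σ(sim−obs)²/obs on n−1 df measures whether a simulated placement could
pass for the observed pattern.  Note a calibration subtlety: when the
reference vector is itself a noisy draw rather than the expected (flat)
vector, the statistic roughly doubles (both vectors fluctuate), so
uniform-p calibration of the χ² machinery is checked against the flat
expectation.

## Wavelet smoothing

"Fourth-order Daubechies" is implemented as the 8-tap `db4` filter (the
Mathematica DaubechiesWavelet[4] convention); the 4-tap `db2` is available
behind a flag.  The transform uses periodization — the chromosome is
genuinely circular, so the periodic boundary is the faithful choice — and
smoothing zeroes the finest `levels_zeroed` detail bands (default 2 at 46
bins) rather than thresholding coefficients, giving a fixed-bandwidth
curve independent of amplitude.  Perfect reconstruction holds at any
length ≥ 8; energy never increases under zeroing; the mean is preserved
exactly when the length divides by 2^levels and to a few parts in 10³
otherwise (periodized odd-length stages pad internally), and rotation by a
multiple of 2^levels commutes with the smoother.

The multiscale scan re-bins the same mutations at 11–141 bins, smooths
each, converts to per-bp density, interpolates periodically onto a common
axis, and correlates each curve with the 46-bin reference.  By default the
decomposition depth adapts per resolution so every curve keeps an
approximation band of ~11 coefficients (2 levels at 46 bins): a fixed
depth would under-smooth fine binnings relative to coarse ones and destroy
comparability.  Two caveats discovered in calibration are worth knowing:
(i) at ≤ ~12 bins a 1000-kb wave is under-sampled (≈2 bins per period) and
the pattern genuinely degrades, which is the expected behaviour, not a
bug; (ii) re-binning one uniform point set at several scales produces
*correlated* smoothed curves (~0.8) because all binnings share the same
low-frequency sampling fluctuations — a meaningful "no structure" control
must therefore use independent noise vectors per scale, which is how the
contrast test is built.

## Feature statistics

Pearson's product-moment and Spearman's rank correlation (midrank ties)
are computed per feature; both p-values use the t-distribution formula
above.  Storey q-values are computed jointly over the battery: π₀ is
estimated by the smoother method — π₀(λ) = #{p > λ}/(m(1−λ)) on
λ = 0, 0.05, …, 0.90, cubic polynomial fit, evaluated at λ = 0.90, clamped
to (0, 1] — then qᵢ = min over p ≥ pᵢ of π₀·m·p/rank(p), monotone in p and
equal to π₀-scaled Benjamini–Hochberg values.  At m = 200 the raw π₀(0.90)
estimate carries binomial noise of sd ≈ 0.22 and the cubic boundary fit
retains roughly half of it, so π₀ on a fully null battery lands within
0.15 of 1 in ~78% of runs and within 0.30 in ~95%; batteries of a few
dozen features (the realistic case) should treat π₀ as a coarse
stabiliser, not an estimate.

Density models are ordinary least squares of counts on feature subsets.
Selection is exhaustive best-subset (batteries ≤ 20 features) minimising
AIC = n·ln(RSS/n) + 2(k+2), a fixed convention so rankings are comparable;
AICc adds 2(k+2)(k+3)/(n−k−3) behind a flag.  Exhaustive search is
deterministic where stepwise selection is path-dependent.  Rank-deficient
subsets are skipped; the selected subset is refit with statsmodels OLS for
coefficients, standard errors, and the overall F-test.  The recovery
experiment in the test suite draws ten N(0,1) features and generates
counts as 16 + 7.8·f₁ + 1.5·f₂ + ε with ε ~ N(0, 2.5²), chosen so the weak
term has |t| ≈ 4 and is individually resolvable at 46 observations; at
that power the selector recovers both terms with coefficients within 2
standard errors in ~84% of runs.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses assume:
~1625 BPSs pooled from 34 MA lines (375 generations each — line identity
is metadata only; within-line clustering is not modelled because the
analyses pool lines), a six-class spectrum dominated by A:T>G:C
transitions (defaults 0.55/0.33/0.04/0.03/0.03/0.02), a cosine intensity
λ(d) = b(1 + a·cos(2πd/P + φ)) over replichore distance with period
defaulting to 1000 kb on the full-size chromosome (peaks near 1000 kb and
2100 kb from the origin) and amplitude 0.5 (giving replichore-fold ρ of
the magnitude seen in real data at n = 1625), two asymmetric regional
hotspots (600–700 kb clockwise, 1900–2000 kb counterclockwise; fold 2.0 —
a free parameter, not an estimate), non-overlapping repeat intervals that
are excluded from placement (uncallable territory), and i.i.d. sequence at
50.8% GC.  Positions are drawn by thinning uniform proposals restricted to
sites whose base pair matches the drawn class; without a sequence,
placement is unconstrained and labels are type-only.  Fixed seeds give
byte-identical output.

Passing tests on these data show the machinery is correct under the
generative model; they do not show that real chromosomes lack spatial
structure the model omits (operon organisation, replication timing,
context-dependent mutability, within-line correlation), so conclusions
about real data still require the real calls.

## Problem sizes and determinism

The test suite and the acceptance script run stochastic components at
fixed seeds and moderate sizes chosen as standard for this kind of
calibration: 1000-replicate type-I calibrations, 100-run recovery
experiments, 1000-simulation nulls, and a quarter-length (1.16-Mb)
chromosome for sequence-heavy fixtures, keeping the full suite under a
minute while leaving Monte Carlo standard errors well inside the asserted
bands.  All randomness flows through `numpy.random.default_rng` seeded
explicitly; pipeline outputs embed the seed, package version, and input
checksums.

## Known limitations

Linear chromosomes, plasmids, and multi-contig genomes are out of scope;
no liftover between genome versions; no within-line or per-generation
simulation; no indels or structural variants; no context-dependent
(trinucleotide) placement null; no continuous wavelet transform or
threshold-based denoising.  The gap χ² depends mildly on the class count
K; K = 20 is the default and the df convention (K−1, mean fixed) is
deliberate.  Reproducing published per-feature coefficients requires the
original calls and external feature datasets; with user-supplied tables
the full workflow runs through `mutwave correlate` / `mutwave regress`.
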