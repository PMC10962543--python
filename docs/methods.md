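# Methods

This note documents the models, numerical choices and limitations behind
`goldsip`. It is the package's own account of its science; every empirical
statement here is something the test suite or `scripts/acceptance.py`
actually computes.

## Data model and conventions

A session holds one multilayer stack per detected species — ¹²C⁻, ¹²C¹⁴N⁻,
¹⁹⁷Au⁻(1) in half-cycle 1; ¹²C₂⁻, ¹²C¹⁵N⁻, ³¹P⁻, ¹⁹⁷Au⁻(2) in half-cycle 2;
secondary electrons in both. Pixel coordinates are 0-based row-major;
acquisition cycles are 1-based in every user-facing interface (cycle ranges
such as "1–95" are inclusive). Counts are integers in raw stacks and reals
after correction. The secondary-electron signal is modelled as a single
stack that follows half-cycle 1 during alignment: it is used only for the
topography exclusion rule, which is insensitive to the sub-pixel difference
between the two half-cycle recordings.

## Detector corrections

**Dead time.** Non-paralyzable form n′ = n/(1 − (n/T)τ), applied per pixel
with the per-pixel dwell time T (default 5 ms). τ defaults to 44 ns — a
conventional value for the electron multipliers of this detector family —
and is configurable; the downstream isotope ratios are insensitive to τ at
the per-mille level because both CN⁻ channels are corrected identically.
Rates at or above 1/τ raise a saturation error naming the pixel. The
correction is strictly increasing and convex in n; the simulator's
`distort_counts` applies the exact algebraic inverse, and the round-trip
recovers counts to ≤ 10⁻⁶ relative error (measured ~10⁻¹⁶).

**QSA.** The linear form n′ = n(1 + βK) with β = 1.1/1.06/1.05 for
C⁻/C₂⁻/CN⁻ and no β for Au⁻, P⁻ and SE. K (the secondary-to-primary ion
ratio) depends on instrument conditions that archives do not carry, so K
defaults to 0 per species — making QSA an explicit, conservative no-op
unless the user supplies K in the configuration. The functional form is a
documented package choice; the β values are the standard sensitivity
factors for these ions.

**Order of operations** is fixed and logged: dead time → QSA → per-cycle
drift tracking → half-cycle alignment.

## Alignment

Drift is estimated per cycle at integer-pixel resolution by maximizing the
circular cross-correlation of mean-subtracted reference planes (¹⁹⁷Au⁻(1)
for half-cycle 1, ¹⁹⁷Au⁻(2) for half-cycle 2) against cycle 1, searched
within a configurable radius (default 10 px); ties break toward the smaller
displacement, then row, then column, so results are deterministic.
Sub-pixel resampling is deliberately avoided: it would destroy the Poisson
semantics of the counts that every downstream statistic relies on. Shifting
never alters values — pixels moved out of frame are recorded in per-half-
cycle validity stacks and excluded from all later sums, so total valid
counts can only decrease. A single inter-half-cycle offset is then
estimated from the two accumulated Au images (or supplied manually) and
applied to all half-cycle-2 planes. On synthetic data with a ≤ 1 px/cycle
drift walk and a constant half-cycle offset, both are recovered exactly.

## Ratio and isotope maps

Ratio maps divide accumulated corrected counts and carry an explicit
validity raster; division by zero is handled by masking, never by adding an
epsilon (an epsilon biases low-count at% estimates). The at% ¹⁵N map is
100·n15/(n14+n15) on accumulated counts and is invariant under common
per-pixel scaling of both CN channels, which is what cancels topography.
The 0.63 at% display floor is rendering metadata only; stored values are
never clipped, and no smoothing is applied to maps used for statistics.

## ROI funnel

1. **Exclusion.** Pixels below the 5 % quantile of accumulated ¹²C⁻ or of
   the SE signal are excluded as strong topography. The raw quantile rule
   necessarily tags isolated background pixels in the Poisson tail as well,
   so the mask is cleaned by a binary opening (radius 1): topographic lows
   are spatially coherent, isolated tail pixels are not.
2. **Candidates.** The early-window (cumulative Cs⁺ fluence ≤ 3.7×10¹⁶
   ions·cm⁻² when metadata carries a fluence schedule, else the first third
   of cycles) ¹⁹⁷Au⁻:¹²C⁻ map is thresholded. The "auto" threshold is
   background mean + 3 SD with the background moments estimated by
   iterative sigma clipping (stopping before the clip degenerates to the
   zero-count mass), so hotspots do not inflate their own threshold. On a
   sparse channel like Au⁻ a couple of stray counts over a low denominator
   can exceed any ratio threshold, so detection additionally requires the
   numerator counts to exceed a Poisson count gate: the smallest level
   whose Bonferroni-corrected false-positive probability under the
   background rate (estimated from the zero fraction, λ = −ln P(0), which
   is insensitive to hotspot contamination) stays below 1 %. Gold decorates
   the cell envelope, so hotspots are rings: a morphological closing
   (radius 2) plus hole filling turns rings into cell-covering components,
   and a 1-px erosion trims the halo of background pixels so in-ROI medians
   reflect the cell interior. Components overlapping the exclusion mask,
   smaller than 4 px or larger than 400 px (biofilm-scale at 512×512 over
   ~50 µm) are dropped; ordering is deterministic (top-left-most pixel).
   An optional late-window rescan adds hotspots that emerge deeper in the
   material, deduplicated at ≥ 50 % mask overlap.
3. **Classification.** A candidate becomes Au+P when its median ³¹P⁻:¹²C⁻
   exceeds the background median + 3 MAD (robust to hotspot skew; the
   median-based in-ROI statistic is a package choice), and Au+P+¹⁵N when it
   additionally passes the significance rule below. Masks are frozen at
   candidate definition; later cycles never reshape them.

## Isotope statistics

Per-ROI at% is computed from cycle-summed counts (Poisson-optimal, and
consistent with defining the counting error on total counts); the
alternative mean-of-per-cycle-at% is available behind a switch and agrees
for homogeneous signals. The Poisson error is the first-order propagation
σ = 100·sqrt(n15·n14/(n15+n14)³), validated against a Monte-Carlo oracle
(10⁵ paired Poisson draws) to well within 5 % relative at totals ≥ 100.

Significance uses two clauses with k = 6 (configurable): at% above the
control mean + k·SD, and k·σ_Poisson below the deviation from the control
mean. The control fit uses the sample SD (n−1); the threshold is always
derived from mean, SD and k, never stored. On 10⁴ synthetic
natural-abundance ROIs the rule produces 0 false positives.

The label-dilution factor is 1/(1 − loss) carried at full precision
(1/(1−0.39) = 1.6393…); rounding to two decimals happens only in display
columns. Correction is linear, so averaging and correcting commute.
Cross-area comparison is a one-way ANOVA plus Tukey HSD (scipy); it is a
pure report — no pipeline behavior depends on it.

## Synthetic acquisitions

The simulator draws independent per-pixel/cycle/species Poisson counts from
composed expected-rate fields: elliptical cells (uniform non-overlapping
placement), whose CN⁻ emission is split binomially into ¹⁴N/¹⁵N channels at
the cell's isotope fraction — exactly the statistical structure the
estimator assumes; a gold shell on the cell envelope present from cycle 1
while the cell's ¹⁵N fraction switches from natural abundance (0.366 at%)
to its true value only at an onset cycle, reproducing the observed depth
delay between gold and ¹⁵N detection; integer drift (random walk, step ≤ 1
px) plus a constant half-cycle offset applied to the rate fields before
drawing; low-signal trenches; and sparse non-specific gold specks as
false-positive bait. One seed determines everything bit-exactly, and the
truth manifest records cell geometry, per-cycle expected CN splits per
cell, the drift schedule and the trench mask.

The desk-scale default scenario uses a 256×256 field over 30 cycles with
~30 cells (lognormal enrichment, median ≈ 1.6 at%, 10 % unlabelled), sized
so the full simulate-plus-pipeline run takes seconds on one CPU while
every count regime of interest (sparse Au, moderate CN, dense C) is
represented. What the simulator does *not* model: sputter-yield evolution
and erosion physics, charging, sub-pixel drift, instrumental mass
fractionation, correlated noise, or realistic root-surface texture.
Passing tests therefore demonstrate the correctness of the evaluation
chain under the stated statistical model, not performance on any
particular instrument's data.

## Degenerate inputs and tie-breaks

Zero-total-CN ROIs yield an invalid-flagged result rather than an error;
all-zero drift-reference cycles and saturated pixels raise errors naming
the cycle/pixel; empty candidate lists are valid outputs; identical control
values give SD exactly 0. Correlation ties in shift estimation break
deterministically (smallest displacement, then row, then col). Display
rounding is half-even to 2 decimals.

## Known limitations

* The QSA K source and exact functional form vary between evaluation
  environments; with K = 0 the correction is a no-op by default.
* The Au+P "correlation" criterion is operationalized as a median/MAD
  threshold; a visual-inspection step in manual workflows has no single
  numeric equivalent.
* Funnel counts depend on scenario and thresholds; they are outcomes, not
  targets.
* Integer-pixel alignment leaves up to half a pixel of residual
  registration error, negligible for ROI-aggregated statistics but visible
  in single-pixel profiles.
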