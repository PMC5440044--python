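# Methods

## Population model of replication

A locus x replicates, in one cell, at the earliest arrival of any fork:
origin i (position p_i) fires at time τ_i + s_i·Z (Z standard normal) if it
is competent in that cell (probability e_i), and its fork reaches x after
|x − p_i| / (v·m_i), with v the genome-wide fork speed and m_i an optional
per-origin speed modifier.  Firing events are independent across origins, so
the population replicated fraction has the exact product form

    R(t, x) = 1 − Π_i [ 1 − e_i · Φ((t − d_i/(v·m_i) − τ_i) / s_i) ].

Passive replication needs no special handling: the minimum over origins
already encodes it.  Assumptions worth keeping in mind:

- firing times are Normal — a modelling choice made for its two-parameter
  sigmoid form, which is also the shape fitted downstream; any unimodal
  firing distribution with similar spread would behave comparably;
- fork speed is constant in space and time within a condition;
- no re-replication, checkpoint feedback or sister-strand asymmetry;
- BrdU is present from release, so IP signal follows the *cumulative*
  replicated fraction R(t, x), not instantaneous synthesis.

The per-locus half-replication point expressed on the global-extent axis
(the G value at which R(t,x) crosses 0.5, with G(t) the bin-average of R) is
the simulator's ground truth for the fitted μ.

## The measurement chain

Counts enter in fixed 300-bp bins (0-based, half-open; the terminal partial
bin of each chromosome is dropped so A/T denominators are uniform).  Read
centers are `floor((start+end)/2)`; paired mates are counted independently
by default, with a `--fragments` mode that counts each proper template once
at its midpoint.  Alignments below MAPQ 10 are skipped (configurable);
strand is ignored at this resolution.

The chain N → E → E′ → smoothed E′ is as in the README.  Undefined bins are
masked (NaN), never zero-filled: bins with raw input count below 5, A/T
ratio below 0.05, or all-N sequence.  Masks propagate; the moving average
(±8 bins, truncated and renormalised at chromosome ends, never crossing a
chromosome boundary) may fill a masked bin from unmasked neighbours but
leaves bins with no unmasked neighbour masked.  E′ is not renormalised to a
genome mean of 1 after A/T correction.

## Per-bin timing fit

For each bin, the points (G(t), L′(t,x)) over the fit time points (defaults:
70, 75, 80, 85, 90 min; the 160-min sample is the standardisation reference)
are fitted with Φ((G − μ)/σ) by bounded least squares:

- L′ clipped to [0, 1.2] before fitting (Poisson noise pushes ratios past 1);
- bounds μ ∈ [−0.25, 1.5], σ ∈ [0.01, 1.0] — μ may lie outside the observed
  G range for very early/late loci, σ is kept away from degeneracy;
- solver: a coarse grid over (μ, σ) seeds a damped Gauss–Newton iteration
  run vectorised across all bins simultaneously (the 2×2 normal equations
  are solved in closed form per bin, with per-bin Levenberg damping).  This
  reproduces `scipy.optimize.curve_fit` per-bin solutions (cross-checked in
  the tests) at a small fraction of the cost, which matters at ~17k bins ×
  2 conditions per run;
- a bin is *converged* when the optimiser reaches a projected-gradient
  stationary point of the bounded problem.  Bins with fewer than 3 usable
  points are *masked*; bins with < 0.05 dynamic range in L′ (e.g. constantly
  1) or a non-stationary fit fall back to a monotone (running-maximum)
  linear interpolant of (G, clipped L′), recorded as
  *fallback-interpolation*.  Note that an interpolant through already
  monotone noisy points has zero residual by construction, so residual
  comparison cannot define convergence — stationarity does.

F(G, x) = Φ((G − μ)/σ) for converged bins (interpolant for fallback bins),
clipped to [0, 1]; it is nondecreasing in G by construction.  Condition
comparisons use ΔF(G,x) = F_a − F_b at G = 0.5 by default with a
Mann–Whitney rank test per region class (test name recorded in output); the
paper-style "lateness" of a locus is the rank of 1 − F_control(0.75, x), and
the pipeline reports its Spearman correlation with ΔF.

## Origin meta-analysis

Origins are local maxima of the smoothed HU-arrest enrichment profile with
prominence ≥ 0.25 × (99th percentile − median), separated by ≥ 9 kb (higher
peak wins; ties leftmost).  A shoulder extends from the peak while
enrichment stays above the profile median, stopping at the midpoint to the
neighbouring origin; origins with ≥ 15 kb of shoulder on both sides are
designated replication tracks with a uniform ±15-kb overlay window so
offsets align across tracks.  Overlays divide each track by its own maximum
(peak = 1) and average per offset; the full width at half maximum of the
average is measured with linear sub-bin interpolation, because the
fork-speed effect on track width at matched global extent is sub-kilobase —
firing-time jitter s maps to spatial spread v·s, so slower forks sharpen
each track's flank — and would be invisible on a 300-bp grid.  Two
conditions are compared at *matched* global extent by linearly
interpolating E′ between the two time points whose G values bracket the
target (default G = 0.3, early enough that tracks fit inside the ±15-kb
window).

Region classes: origin class = bins within ±1 bin of designated peaks; late
class = ±1 bin around midpoints between adjacent designated origins
(collisions removed, so classes are disjoint).  Deviant-late selection
calibrates a null band on the origin class — origins barely shift between
conditions because their timing is set by firing, not fork travel — and
selects late bins with ΔF(0.5) above mean + 2 SD of that band.

## S1-gel fragment fractions

Ladder calibration interpolates log10(size) piecewise-linearly against pixel
(orientation auto-detected; extrapolation beyond the outermost markers
continues the terminal segment and is flagged).  Lane intensity, after
subtracting the in-range minimum as background, is converted to a number
fraction per pixel as w_j = I_j / l_j — label deposits in proportion to
fragment length, so dividing by length counts molecules — normalised to
Σ n_j = 1.  The weighting exponent is exposed (`length_exponent`) because
transfer/staining nonlinearity can alter the effective power; fractions are
reported per source pixel without Jacobian re-binning onto a uniform length
axis.  The gel simulator draws fragment lengths Exponential(mean) —
stochastic gap spacing along uniformly labelled nascent strands — deposits
length-proportional intensity at the calibrated pixel and convolves with a
Gaussian band spread (default 2 px).

## What the simulator does and does not emulate

Emulated: per-cell origin firing and fork travel, cumulative BrdU labelling,
Poisson read sampling with A/T-proportional IP capture bias (b(x) =
AT(x)/mean AT), uniform pre-release input coverage, dot-blot signals
proportional to G(t) with optional multiplicative noise, HU arrest as a
triangular replication extent of configurable half-width around each origin
over a small uniform background, and S1 fragment-length distributions.

Not emulated: mappability and copy-number structure, PCR duplicates,
fragment-length variation in sequencing, GC amplification bias beyond the
linear A/T model, chromatin-dependent origin interference, checkpoint
effects, or gel image artefacts (lane warping, saturation).  Passing tests
therefore demonstrate correctness of the analysis chain under the stated
generative model, not robustness to every artefact of real libraries.

## Study conditions packaged as defaults

- genome: three chromosomes of 2.2/1.6/1.2 Mb (5 Mb total), 300-bp bins;
- origins: spaced 55–75 kb, firing 55–80 min after release, SD 6 min,
  efficiency 0.8–1.0 — an efficient-origin layout at fission-yeast-like
  density, shared between conditions so fork speed is the only contrast;
- fork speed 1.0 kb/min (control) vs 0.8 kb/min (slow condition);
- time points 60–90 min plus 160 min (replication complete); fits use
  70–90 min, where G spans ≈ 0.1–0.6;
- sequencing depth: 100 expected reads per fully replicated bin for IP and
  input.  The overlay-narrowing experiment uses depth 400: the expected
  FWHM difference at matched G is a few hundred bp, and shot noise on the
  interpolated half-maximum crossings must sit below it;
- HU arrest half-width: 5 kb at the emitter level (isolated peaks for
  detection tests); the packaged demo uses 20 kb, reflecting that fission
  yeast forks keep elongating slowly under HU, which is what makes ≥15-kb
  shoulders — and hence track designation — possible at all;
- gel: exponential fragment means 4 kb (control) vs 2 kb (doubled gap
  rate), 2×10⁵ fragments, 2-px band spread.

Problem sizes in the tests and acceptance script (10⁴ reads for the binning
oracle, 10³ bins for recovery, 10⁴ Monte-Carlo cells, 2-Mb origin-recovery
chromosome, the full 5-Mb demo for the end-to-end and condition-contrast
checks) were chosen so each check resolves its effect with comfortable
statistical margin at desk scale.

## Numerical details and edge cases

- One root seed; every emitter draws from a named, documented substream
  (`simulate.Stream`), so outputs are independently byte-reproducible.
- Monte-Carlo vs closed-form agreement is asserted within 3 binomial SE
  plus a 2/n discreteness allowance: where n·p < 1 the Gaussian band is
  narrower than a single count.
- G(t) non-monotonicity (possible with noisy dot-blots) warns but does not
  fail; G(t_ref) = 1 by construction.
- Division guards throughout mask rather than clamp: zero input, zero
  L(t_last), zero A/T.
- `curve_fwhm` returns NaN when the average curve never falls to half its
  maximum inside the window (the overlay target G should then be lowered).
- All stage files are plain text with self-describing `#` headers (stage,
  binning, parameters); the run manifest records SHA-256 of every output
  plus the config hash and seed.

## Known limitations

- μ for loci completing after the last fitted G value (~0.6 in the demo) is
  an extrapolation; its *rank* is reliable (Spearman ≈ 0.99 against truth)
  but its absolute value less so.
- The deviant-late rule (origin-calibrated mean + 2 SD) is a pragmatic
  operationalisation; with very few designated origins the null band is
  poorly estimated.
- The overlay FWHM contrast at matched global extent is intrinsically small
  under this model (hundreds of bp); comparing at matched *time* instead
  yields the much larger, G-confounded difference seen in raw profile
  comparisons.
- The A/T correction is linear; strongly non-linear capture bias would leak
  into E′.
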