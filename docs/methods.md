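# Methods

This note records the models the package implements, the defaults it
ships, what the synthetic-data generators do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Worm-like-chain force spectroscopy (`chromotopo.wlc`)

A tethered DNA or chromatin fiber under tension F at extension x is
modelled by the Marko–Siggia interpolation of the worm-like chain,

    F(x) = (kBT/Lp) [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

with persistence length Lp (nm) and contour length Lc (nm) as the two free
parameters. The formula is exact in the limits x → 0 and x → Lc and within
~10% elsewhere, which is ample for extracting Lp and Lc from stepped
tension ramps. Magnetic tweezers clamp tension and read extension, so
`fit_wlc` minimises squared *extension* residuals at fixed tension, using
the numerically inverted model (vectorised bisection in x/Lc, relative
tolerance < 1e−9). Points above a tension cutoff (default 10 pN) are
excluded: above that scale nucleosomal fibers unfold and the entropic
description fails. The cutoff is a parameter, not a constant, because it
is an empirical observation about a particular fiber preparation.

Defaults and rationale:

- temperature 298.15 K (kBT ≈ 4.116 pN·nm) — room-temperature flow-cell
  experiments;
- optimisation bounds Lp ∈ [0.5, 500] nm, Lc ∈ (max observed extension,
  50× that]; initial guess Lp = 50 nm, Lc = 1.05 × max extension — a
  robust basin for Marko–Siggia fits on monotone data;
- standard errors from the Gauss–Newton curvature (JᵀJ) at the optimum.

`spring_constant` reports the zero-extension slope k = 3kBT/(2·Lp·Lc):
softer fibers (shorter Lp) are *stronger* entropic springs. Condition
summaries report both the across-tether SD of Lp and the mean per-fit SE,
because published ± values may be either; both are kept side by side
rather than guessing.

## Topoisomer ladders and the Morse estimator (`chromotopo.topo`)

Closed-circular plasmids extracted from cells carry a Boltzmann
distribution of linking number; on a chloroquine gel they resolve into a
band ladder with intensities Gaussian in ΔLk: ln I_k = −a(k − c)² + const.
At high chloroquine concentration (150 µg/ml regime) the more relaxed,
more positive-ΔLk species migrate further.

The Morse estimator locates the distribution center c from band
intensities alone: index the brightest band 0 (slower bands −1, −2, …;
faster +1, +2, …) and regress y_i = (1/ΔLk_i)·ln(I_i/I_max) on ΔLk_i over
the bands with ΔLk ≠ 0 (the 0 band's ordinate is 0/0 and is excluded —
forced by the formula). For Gaussian intensities the line has slope
m = −a and intercept b = 2ac, so the center is recovered *exactly* as
−b/(2m), at distance |b/2m| from the brightest band. Sign convention:
positive = shifted toward faster-migrating bands, so relaxation of
negative supercoils is a positive shift. The regression is unweighted (a
weighted variant is available but off by default). An intensity-weighted
centroid Σ I·ΔLk / Σ I serves as an independent location oracle.

Brightest-band-relative centers from two lanes are **not** directly
comparable: if the brightest topoisomer itself differs between conditions
the relative centers disagree by that integer. Lanes run on the same gel
share a migration axis, so `morse_center` also reports the center as a
migration coordinate (brightest-band position + center × band spacing)
and `delta_lk` compares centers in those gel units, falling back to
relative centers only when positions are unavailable. Replicate
differences feed a paired one-sample t-test (or Welch when pairing
breaks), and results carry both SD and SEM since published ± values could
be either.

Band calling: peaks are detected on a lightly smoothed
(Gaussian, σ ≈ 0.08 band spacings) baseline-subtracted trace — without
smoothing, read noise in band-free stretches occasionally seeds spurious
bands that corrupt the index assignment. The baseline is a rolling
minimum with a window of 3× the band spacing (gel backgrounds are
smooth). Quantification integrates the trace over ± spacing/2 around each
peak above a *scalar* background (the median of the rolling-minimum
baseline): subtracting the rolling minimum itself under the bands would
deflate bright bands by 2–3%, because inside the ladder the rolling
minimum tracks inter-band troughs rather than true background. Bands more
than 4 spacings from the ladder are discarded as nicked/linear species.
Intensity ties for brightest are broken toward the band whose neighbours
carry more summed intensity (the distribution mode).

Known bias: with realistic trace noise the full detect → index → regress
pipeline recovers injected linking-number shifts with a small systematic
bias (≲ 0.04 ΔLk) that dominates the very small replicate SEM; recovery
tests therefore allow 3·SEM plus a 0.05 absolute term. The null
calibration of the paired test is verified directly (type-I rate ≈ 5%
over 1000 replicate resamplings).

## MNase nucleosome scanning (`chromotopo.nucscan`)

Protection of an amplicon from MNase digestion is computed from qPCR
cycle thresholds assuming amplification efficiency 2 per cycle:
protection = 100 × 2^(Ct_undig − Ct_dig), which depends only on ΔCt and
not on template amount. Efficiency is fixed at 2.0 (primer pairs matched
within half a cycle); a per-amplicon efficiency column can be supplied.
Protection is not clipped at 100% — noise can push it above, and clipping
would bias replicate means — but values > 120% raise a data-quality
warning. Digested reactions at or beyond 40 cycles are censored ("no
amplification"). Coordinates are 1-based inclusive from the gene's 5′
end; BED export converts to 0-based half-open. Both raw and
max-normalised profiles are available and labelled, since protection is
sometimes rescaled to the most protected amplicon.

`design_tiling` reproduces the scanning design (100 ± 8 bp amplicons
overlapping 30 ± 10 bp, step 70 bp from bp 1) and appends a terminal
amplicon anchored at the region end when more than 8 bp would otherwise
go uncovered; that terminal amplicon may overlap its neighbour by more
than the nominal tolerance — coverage wins over overlap regularity at the
3′ edge. Profile comparison uses per-amplicon Welch tests from replicate
summary statistics plus a global trend statistic (mean signed difference
with a one-sample t-test) to capture uniform sensitivity shifts that no
single amplicon can resolve at n = 3.

## Dual-luciferase compensation (`chromotopo.compensate`)

Relative activity is firefly/Renilla per sample; compensation is the
ratio of relative activities between roX-bearing and roX-less plasmid
arms. Replicates are paired by experiment and the fold is the mean of
per-replicate ratios ("experiments averaged"); the ratio of arm means is
reported alongside, since the two differ under noise. Treatment effects
(e.g. mock vs ISWI knockdown) are compared by Welch's t-test on the
per-replicate ratios.

## Two-angle fiber simulation (`chromotopo.fibersim`)

Chains of nucleosome frames are built by composing, per step, a random
twist about the local fiber axis (uniform on center ± half-width; a
Gaussian option exists because "random variation" does not fix a
distribution) with a fixed bend equal to the linker entry/exit angle, then
stepping one linker length along the new axis. Twist half-width is the
disorder parameter; defaults are twist center 110°, entry/exit 50°,
linker 20 nm, 200 nucleosomes × ≥ 100 chains. The entry/exit angle and
linker length are exposed configuration — no numeric claim depends on
them, and only the *direction* of the disorder → softening effect is
asserted. Whether a quoted "range of variation" is a half- or full-width
is ambiguous in the literature; here `twist_range` is a half-width,
stated in the dataclass docstring.

Persistence length is estimated two independent ways: (i) a log-linear
fit (through the origin) of the tangent–tangent correlation against
contour separation, over separations where the correlation exceeds 0.05;
(ii) inversion of the worm-like-chain end-to-end relation
⟨R²⟩ = 2LpL − 2Lp²(1 − e^(−L/Lp)) at the ensemble mean, with a
delta-method standard error from the chain-to-chain spread of R². The
estimators agree within ~15% once twist disorder is large enough
(half-width ≳ 90°) to scramble helical coherence; at weak disorder the
tangent correlation is oscillatory (helical backbone) and the two
quantities measure different things, so disorder scans are ranked on the
end-to-end estimate. Chains whose correlation never decays (e.g. zero
disorder) are flagged rigid and both values are lower bounds. Scans reuse
the same seed across disorder levels (common random numbers) so the
monotone softening trend is not masked by Monte Carlo noise.

## Synthetic data: what it emulates, what it does not

Generators produce, deterministically per mandatory seed: WLC
tension–extension tables with homoscedastic Gaussian extension noise;
topoisomer lane traces (Gaussian band shapes over a flat background plus
Gaussian read noise, +ΔLk at larger migration, a given topoisomer always
at the same coordinate); Ct tables implied by an occupancy map (surviving
fraction = covered fraction + (1 − digestion completeness) × uncovered
fraction; cycle noise on digested reactions); and paired luciferase
tables whose per-replicate ratio has median equal to the true fold and
coefficient of variation exactly cv (lognormal scatter split across
arms — the ratio's expectation carries a +cv² convexity factor, ~2% at
cv 0.15).

The paper-facing study conditions are built in as defaults: bare-DNA
Lp 34 nm on the 5049-bp (1716.7 nm) template; chromatin conditions at
Lp ∈ {22, 19, 11, 10} nm; ladder curvature a = 0.3 with 2–6 bands per
side; 633/509-bp scanned regions under ~147-bp protected intervals;
2-fold reporter enhancement with ≥ 3 replicates. Because the instruments'
noise magnitudes are not published, the noise defaults are field-typical
choices, fixed once: 10 nm bead-tracking extension noise, lane read noise
0.5% of peak band intensity, 0.3 cycles of qPCR noise, 15% replicate cv.

What passing tests show: the estimators are exact or unbiased under their
own generating model and robust at these noise scales. What they do not
show: robustness to model violations absent from the generators — drift
and tracking artefacts in bead trajectories, band-shape asymmetry, smile
and lane-to-lane migration distortion in gels, qPCR efficiency spread
beyond the fixed 2.0, plate-position effects in luciferase readings, and
partial octamer occupancy on reconstituted arrays.

## Numerical details and degenerate inputs

- WLC inversion: 100 bisection steps on x/Lc ∈ [0, 1); exact at F = 0.
- `morse_center` refuses nonpositive intensities (log undefined), ladders
  with < 3 nonzero-index bands, and |slope| < 1e−6 (flat distribution —
  center undefined).
- Flat or band-free traces raise `InsufficientLadderError` rather than
  returning something quantitative.
- Fully digested amplicons (surviving fraction 0) are censored at 40
  cycles and flagged, not treated as protection 0 of a valid reaction.
- The end-to-end inversion uses expm1 for numerical stability and flags
  saturation (⟨R²⟩ → L²) as rigidity.

## Problem sizes

Default verification runs use 20 tethers × 30 points per condition,
5 replicate lanes per arm with 1000 (tests) / 500 (acceptance script)
null resamplings, 9–13 amplicons × 3 qPCR replicates, and 500 chains ×
200 nucleosomes per disorder level — sizes at which every stochastic
assertion is stable across seeds while the full suite stays fast.
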