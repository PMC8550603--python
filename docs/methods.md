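# Methods

This note documents the models, numerical choices and limitations of
`regtex` at the level of detail a user extending or auditing the package
needs.

## Stimulus geometry

All geometry is in arcmin of visual angle. The three spacing levels place
elements on notional square lattices of 9×9, 7×7 and 6×6 elements with
pitches of 17.52, 21.41 and 25.30 arcmin; element diameters are 9.73,
12.65 and 15.57 arcmin for the three size levels; the five jitter levels
have ranges 2.92, 3.89, 5.84, 7.79 and 9.73 arcmin. Crossing the levels
gives the 45-condition design used throughout (canonical ordering:
jitter-major, then size, then spacing — the block layout of the
conjoint-proportions matrix).

**Jitter range = full width.** Each element's offset is drawn per
coordinate from a uniform distribution on [−r/2, +r/2]. This reading is
fixed by the closed form for the mean Euclidean offset,
E√(x²+y²) = (r/2)(√2 + ln(1+√2))/3, which yields 1.12, 1.49, 2.23, 2.98
and 3.72 arcmin at the five ranges — the displacement scale the design is
calibrated to. A Monte-Carlo check of this identity is part of the test
suite.

**Overlap rejection.** Two elements overlap when their centre distance is
below the element diameter (equal touching circles). The default
placement policy (`policy="global"`) jitters every element and then
repeatedly redraws any element that overlaps any other, within the same
range, until the entire layout is overlap-free; a per-element redraw cap
(1000) and a sweep cap (500) turn pathological configurations into
explicit errors. A `sequential` policy (raster-order placement checked
against already-placed elements only) is retained for comparison; it
conditions the ensemble much more weakly. Under the global policy the
realised mean displacement in the tightest geometry (spacing 1, size 3)
comes out at ≈ 1.06, 1.36, 1.97, 2.71 and 3.41 arcmin for the five levels
— overlap rejection compresses the nominal jitter, most visibly at high
jitter, because configurations in which an element drifts far toward a
neighbour are excluded. In the five looser spacing × size geometries the
diameter is below the closest possible approach of two jittered
neighbours, so the constraint cannot bind and the unconstrained means
apply; averaging the level-5 mean over all nine geometries therefore
lands near 3.6 arcmin, dominated by the unconstrained conditions.

**Rendering.** Elements are zero-balanced DoGs with centre sigma =
diameter/4 (2.43 arcmin at size 1), surround sigma twice that, and the
surround amplitude fixed by A_c σ_c² = A_s σ_s² so the 2-D integral
vanishes (surround/centre sigma ratio configurable). The analysis raster
is 256×256 pixels spanning the 2.91° aperture (≈ 0.682 arcmin/pixel).
The notional lattices poke slightly beyond the circular aperture at their
corners, so elements whose nominal footprint would cross the aperture
edge are omitted rather than sliced — slicing a zero-balanced element
would leave a net luminance residue. The rendered image mean consequently
stays at the background level to well within 0.5 % of the element peak.
The small vertical offset applied to stimulus pairs on screen during the
experiment affects display only and is not modelled.

## Observer simulation

A simulated observer assigns each condition a normal internal-regularity
distribution; on each trial one value is drawn per stimulus and the
larger draw is chosen, so the choice probability for pair (A, B) is
Φ((μ_A − μ_B)/√(σ_A² + σ_B²)). The default fixed SD is 1/√2, making the
paired decision noise exactly the probit model's unit — fitted estimates
then recover the generating means one-to-one, which is what the
parameter-recovery check asserts (regression slope within [0.95, 1.05]
at 400 repetitions of the 1035-pair design).

The default condition means (`synthetic_observer_means`) emulate the
qualitative structure of human regularity scales: a strong monotone
jitter effect reaching −3.6 noise units at level 5, small additive
spacing (+0.25 at level 3) and size (−0.25 at level 2) effects, and
multiplicative jitter-gain interactions (1.25/1.0/0.67 across spacing
levels, 0.80/1.0/1.21 across sizes) so the jitter effect is stronger at
small spacing and large size — the edge-to-edge-distance signature. The
gains were set from the reported ~1.9× and ~1.5× interaction contrasts;
they are a structural emulation, not a fit to any observer's data.
What passing tests on these observers shows is that the machinery
(design, fitting, battery, recovery) is correct; they do not certify any
claim about human vision, whose scales, lapses and sequential effects the
simulator deliberately omits.

## Three-factor MLCM

Responses are aggregated over the four repetitions of each unordered pair
(grouped-binomial likelihood, identical to the per-trial Bernoulli one).
Each model is a difference-coded design: the row for a pair is the
loading of its first-listed condition minus that of the second, entries
in {−1, 0, +1}. Reference constraints pin the first level of each factor
(one-factor and additive models), every cell touching level 1 (two-way
cell models and the all-two-way model), or the (1,1,1) cell (full model)
at zero, giving free-parameter counts 0, 2, 2, 4, 6, 6, 4, 14, 14, 8, 28
and 44 for models 1–12. All twelve designs have full column rank on the
exhaustive 1035-pair data.

Fitting is by iteratively reweighted least squares for the probit link
with the internal-noise SD fixed at 1 (the identifiability scale; all
estimates are in noise-SD units). Convergence is declared at a deviance
change below 1e-8 (max 100 iterations); step-halving keeps the deviance
monotone through early overshoots. Complete separation — possible in the
44-parameter full model at only 4 repetitions when a condition wins or
loses uniformly — is flagged (|coefficient| > 10) and the fit returned
with a warning rather than an error. Standard errors come from the
inverse Fisher information. The optimiser is cross-checked against an
independent GLM implementation in the test suite.

The battery runs seven likelihood-ratio tests: models 2/3/4 vs 1 (main
effects), 8 vs 5, 9 vs 6, 10 vs 7 (two-way interactions,
Bonferroni-corrected across the three tests) and 12 vs 11 (three-way,
read at the stricter 0.01 criterion). Deviance differences are referred
to χ² with df equal to the parameter-count difference.

**Group scales.** One-factor estimates are normalized per observer so the
jitter level-5 estimate maps to −1 (the jitter range is the unit), then
averaged; full-model 45-condition estimates are normalized per observer
by the maximum absolute estimate before averaging (a `jt5`-anchored
variant is available — the choice matters little because the maximum is
the jitter-5 region). Interaction profiles are summarised by pooling
normalized per-observer cell estimates, not by refitting pooled data.
Because the probit fit marginalises nonlinearly over the third factor,
cell-model profiles compress multiplicative generator contrasts somewhat
(≈ 1.8 recovered from a 1.87 gain ratio at 60 repetitions).

## Log-Gabor energy models

The bank holds 50 log-spaced centre frequencies from 0.23 to 512 cycles
per image (constant ratio (512/0.23)^(1/49) ≈ 1.17) at 12 orientations
0–165° in 15° steps. The radial transfer is Gaussian on log frequency
with σ_on_f = 0.65 (≈ 1.6-octave bandwidth); the angular transfer is a
single-sided Gaussian in orientation with spread 1.2 × (half the 15°
spacing). Both are configurable; DC gain is exactly zero. Channels above
the raster's Nyquist frequency (128 cpi at 256 pixels) are evaluated as
frequency-domain truncations and retained, keeping the full stated SF
range.

Pixel values are squared before filtering (rudimentary second-order
processing; it exposes the circular-aperture envelope as a low-SF
component and is switchable off via `square_pixels=False`). The
pixelwise RMS of each complex filter response is computed in the
frequency domain through Parseval's identity — exact, and it avoids 600
inverse FFTs per image — then divided by the square of the filter's
spatial size, defined as image size / centre frequency.

**Normalization index fix.** As printed in the source formulas, the
mean-normalization denominators are indexed so that the downstream
marginal would be identically flat (dividing each SF row by its own
orientation mean makes the orientation-averaged SF distribution
constant, and vice versa), contradicting the stated intent of equating
totals *across orientations* (or across SFs) and the published marginal
plots. The implementation therefore swaps the index: `equate-orientations`
divides each orientation channel by its mean over SF (every orientation
totals 50), `equate-sfs` divides each SF channel by its mean over
orientations (every SF totals 12). The literal printed forms are kept as
`literal-*` audit modes. All normalized statistics are invariant to
global image contrast.

**Distribution statistics.** Kurtosis and skew are population-moment
ratios of the energy *values* (E(x−μ)⁴/σ⁴, E(x−μ)³/σ³ with 1/N moments);
peakedness is the maximum; SD is the population standard deviation; FWHM
is measured by linear interpolation in log₁₀-SF units, taking the
outermost half-maximum crossings with a multimodality warning, and an
axis endpoint when an edge never falls below half maximum. Constant
vectors are rejected (σ = 0). Cross-channel spreads (the `*_std`
statistics) use the sample (N−1) divisor, matching the printed formulas.
FWHM is omitted from the orientation-marginal models, whose bimodal,
sharp-edged shape makes a half-maximum width meaningless.

Per-condition statistics average over 10 freshly generated stimulus
samples by default (seeded; the appropriate sample count per condition
is not prescribed anywhere, and 10 keeps the sampling error of the
`*_std` statistics a small fraction of their between-condition range).

## Linking statistics to perception

Pearson correlations are computed per statistic against the 45-condition
group regularity scale; forward stepwise regression enters, at each
step, the candidate with the smallest partial-F p-value (F with
(1, n−k−1) df) and stops when that p exceeds 0.05. There is no removal
step. Ties are broken by canonical column order; constant or collinear
candidates are excluded. With a single selected predictor R² equals the
squared Pearson correlation, which the tests verify, and the procedure
is invariant to predictor order.

## Known limitations

* The overlap criterion, redraw policy and DoG surround/centre ratio are
  defaults chosen for geometric simplicity; the generating code of the
  original stimuli is not available, so residual differences at the few-
  percent level in constrained-jitter statistics are expected.
* The wavelet statistics depend quantitatively (not qualitatively) on the
  filter bandwidth parameters; only the defaults above are tested.
* Replication of the human-data quantities (deviance-ratio summaries,
  encoding-model correlations) requires the deposited per-trial response
  CSVs under `data/deposited/`; without them those checks fail by design
  rather than silently passing.
* The simulator draws trials independently; sequential dependencies,
  lapses and left/right response biases present in real data are out of
  scope.
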