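# Methods

This note documents the models, parameter choices and numerical decisions
behind `periacuity`, and what the synthetic pipeline does and does not say
about real peripheral-acuity data.

## Display model and stimuli

The display is a linear luminance grid: 0.98 arcmin/pixel, 85 Hz refresh,
45 cd/m² mean background luminance, and a symmetric 0–90 cd/m² displayable
range (so black and white targets have equal Weber contrast on the gray
background). Degrees convert to pixels by `round(deg·60/0.98)` — a 1.5°
letter is 92 px — and seconds to frames by `round(s·85)` — a 530 ms trial is
45 frames (45/85 = 529.4 ms). No gamma stage, phosphor dynamics or optics
are modelled; luminance maps linearly to code values on export.

**Optotype.** The letter C is built on the standard 5×5 Sloan/Landolt
construction: an annulus whose stroke width and gap width are each one fifth
of the letter diameter, the gap cut as a parallel-sided slot along the gap
direction. Orientation is the gap direction, counter-clockwise from
rightward horizontal, restricted to the four oblique responses
(45° upper-right, 135° upper-left, 225° lower-left, 315° lower-right,
matching keypad keys 5/4/1/2). Target pixels take the displayable minimum
(black) or maximum (white); the overlay onto the background is opaque
replacement. Letters below 2 px are refused as unrenderable.

**Noise backgrounds.** Brownian textures are synthesized directly in the
Fourier domain: white Gaussian noise is filtered with amplitude ∝ f⁻¹
(power ∝ f⁻²) inside (0, 6] cycles/degree and zero outside, the DC term is
removed exactly, and the texture is scaled so its 0.1–99.9 percentile range
spans 90 % of the displayable Michelson range about the mean, with residual
pixels hard-clipped. Two consequences are worth stating precisely:

- clipping the ~0.2 % tail reintroduces a little broadband power above the
  6 c/deg cutoff (measured < 10⁻³ of in-band power, i.e. < −30 dB); with a
  contrast fraction low enough that nothing clips, out-of-band power is zero
  to numerical precision. Tests check both statements.
- texture deviations are quantized onto a 2⁻³² grid of the contrast
  amplitude (~10⁻⁸ cd/m², far below any perceptual scale) so that polarity
  reversal about the mean, `L → 2·45 − L`, is an exact involution in
  float64 and a full reversal cycle averages to the mean luminance exactly.

The nominal 4 c/deg, 1-octave "element" parameters of the texture family
are carried as provenance fields; the synthesis targets the spectral
end-state (band-limited 1/f² power) directly. A single texture is drawn
fresh per trial from the trial seed.

**Temporal profiles.** Polarity reversal is square-wave on the frame grid:
the flip rate must divide the frame rate, giving 5 frames per polarity state
at 17 Hz and 10 at 8.5 Hz. Reversing targets start at a random polarity.
Backgrounds reverse by flipping the texture's contrast about the mean; only
noise backgrounds can reverse (a uniform field has no contrast to flip),
which the condition type enforces. A trial movie holds at most four distinct
images (target polarity × background sign), so `FrameSequence` stores those
plus a per-frame index and materializes the dense stack only on demand.

## Observers

The parametric observer is a Weibull 4AFC psychometric function
`P(correct|s) = γ + (1−γ−λ)(1−e^{−(s/α)^β})` with γ = 0.25 fixed by the
task, slope β = 2.5 and lapse rate λ = 0.01 by default (conventional
values; both configurable). Wrong responses are uniform over the three
incorrect alternatives. The scale α for a desired 79.4 %-correct point has
a closed form; a bisection inverse of the forward function is kept as an
independent cross-check.

The template observer correlates the temporally pooled, mean-subtracted
stimulus patch with each orientation's rendered template (maximized over
template polarity), adds independent Gaussian internal noise per
orientation, and picks the argmax (ties broken at random). The default
pooling is the rectified mean — the time-average of |L − 45| — so that
contrast-reversing targets do not cancel themselves; plain-mean pooling is
available and demonstrably destroys the matched filter over complete
reversal cycles. Because the match is maximized over polarity, this
observer is blind to target polarity by construction: it verifies that the
rendered task is solvable in all 16 conditions, and deliberately cannot
reproduce the black-target advantage humans show, which is a perceptual
finding rather than a stimulus property.

## Staircase

3-down/1-up from 1.5°: three consecutive correct responses move the letter
size down one step, any error moves it up, so the procedure converges on
the size where `p³ = 0.5`, i.e. 79.4 % correct. Step sizes follow
0.4, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05, 0.025, 0.025°, advancing one slot per
reversal and holding at 0.025° thereafter. By default the move that causes
a reversal still uses the pre-reversal step (the schedule "changes with
each reversal" for subsequent moves); the alternative advance-before-move
convention is available behind a flag. Reversal sizes are recorded at the
size presented on the reversal trial. A staircase completes at the first
trial with ≥50 trials and ≥9 reversals; the threshold is the mean of the
final six reversal sizes. Sizes are clamped to [2 px ≈ 0.033°, 3°];
a staircase pinned at the ceiling for >200 consecutive trials raises a
non-convergence error, while one pinned at the floor (an observer who is
never wrong at the smallest renderable size) terminates with the floor as
its threshold, since no further reversals can occur.

**Estimator bias.** Implemented exactly as above, the reversal-averaged
estimator is not unbiased: for the default observer (β = 2.5, λ = 0.01)
with its 79.4 % point at 0.5°, the mean over 10 000 simulated staircases is
0.5246° (+4.9 % ± 0.14 %). Most runs stop right at the ninth reversal, so
the "final six" reach back to reversals taken at the 0.1°/0.05° steps during
the oscillation that follows the initial descent, which is asymmetric
(descent needs three corrects, ascent one error). Reversals occurring after
the schedule is exhausted average 0.502°, confirming the rule itself targets
the 79.4 % point; the bias is a finite-procedure property, shrinking with
steeper psychometric slopes, lower lapse rates and longer runs. The test
suite asserts a 4 % band on this convergence, which the procedure as printed
does not meet — the failure is retained deliberately as a documented
property of the procedure rather than papered over by a steeper test
observer.

## Experiment runner and cohorts

Each simulated participant runs all 16 conditions in an independently
shuffled order, with `n` staircases per cell (default 6; per-participant
overrides emulate unbalanced designs). All randomness descends from one
master seed through `numpy` `SeedSequence.spawn`, so any single staircase is
replayable; the run manifest records seeds, condition orders and a config
hash.

Cohorts draw, for participant *i* and condition *c*, a true threshold
`t_ic = m_c + b_i (+ u_ic)` where `m_c` are the per-condition population
means, `b_i ~ N(0, 0.04²)` is a participant intercept shared across
conditions, and the optional participant-by-condition jitter `u_ic`
defaults to zero so the generating process matches the mixed model's
random-intercept structure exactly. The default `m_c` are the measured
group means for the 16 conditions (worst 0.602° for the static white target
on static noise — tied with white on the 8.5 Hz background — best 0.438°
for the 17 Hz target on the 8.5 Hz background). The Weibull α is solved so
the observer's 79.4 % point sits exactly at `t_ic`.

Threshold tables come from either the **full path** (actual staircases) or
the **fast path**, which samples `N(t_ic, 0.02²)` per staircase — a normal
approximation to the staircase estimator centered on the true threshold.
The two paths therefore differ by the estimator's +~5 % overshoot described
above; tests validate the full path against an independently simulated
estimator expectation and the fast path against the specified means. The
0.04°/0.02° variability defaults are synthetic choices of plausible
magnitude, not measured quantities.

## Mixed model

The analysis model is `y_icj = μ_c + b_i + s_ij + e_icj` with a full
16-cell fixed-effect mean structure (equivalent to two four-level factors
plus their interaction — the cell-level comparisons of interest require
cell-level estimates), a participant random intercept, a staircase-within-
participant intercept and a residual. Estimation is REML: for given
variance ratios `γ = (σ²_p, σ²_s)/σ²_e` the fixed effects and σ²_e are
profiled out analytically and the criterion
`log|W| + log|X'W⁻¹X| + (n−p)·log(r'W⁻¹r)` is minimized over `log γ` by
L-BFGS-B from three fixed starts (with a derivative-free polish if the line
search ends abnormally at a flat optimum). The marginal covariance is block
diagonal by participant, so every evaluation uses small per-participant
Cholesky factors; fits on 960-row tables take well under a second.

With one threshold per staircase the staircase effect's design matrix is
the identity and σ²_s is not identifiable; the default "strict" variant
detects this, emits an `IdentifiabilityWarning` and absorbs σ²_s into the
residual. The genuine three-component fit engages whenever staircases
contribute multiple rows. Balanced zero-variance data collapse exactly to
per-cell sample means.

Contrast inference uses Satterthwaite degrees of freedom,
`df = 2·g²/(∇g'A∇g)` with `g` the contrast variance, `∇g` its numerical
gradient in the variance components, and `A` the inverse observed REML
information (numerical Hessian, pseudo-inverted; df falls back to the
residual df when the boundary makes the information singular). Bonferroni
correction is applied within declared families: single-cell-pair
comparisons belong to the family of all 120 pairwise cell contrasts, and
the report's pooled (multi-cell) comparisons form their own family. The
standard report computes five families — black vs white per background,
reversing vs static targets on the uniform and on the noise background,
background-reversal effects per rate, and synchronous vs asynchronous
reversal — plus raw and model-adjusted cell means (which differ under
unbalanced staircase counts) and the worst-to-best range in logMAR and
chart letters (0.02 logMAR per letter).

## What the synthetic tests do and do not show

Passing tests show that the machinery is correct: stimuli meet their
spectral and timing contracts, the staircase implements its rule exactly
and tracks the 79.4 % point up to its documented bias, the REML fit matches
brute-force GLS, the type-I error of the corrected pooled contrast is
controlled, and the full pipeline recovers a planted condition structure
(extreme cells, synchrony sign pattern) reliably. They do not validate any
claim about human vision: the simulated observers have no polarity
asymmetry, no temporal-segmentation mechanism, no crowding, learning,
fatigue or fixational eye movements, and the between-participant and
between-staircase variances are assumptions. Effects recovered from
synthetic cohorts are, by construction, the effects planted in them.

## Problem sizes used by the validation suite

Monte-Carlo checks use 500 staircases for convergence, 500 reduced cohorts
(5 participants × 2 staircases) for the type-I rate, and 100 default-size
cohorts (10 × 16 × 6, fast path) for end-to-end recovery; the acceptance
script runs one default cohort and 500 staircases. These sizes put
Monte-Carlo error well inside each asserted tolerance while keeping the
whole suite around two minutes.
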