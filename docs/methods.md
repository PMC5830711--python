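# Methods

## Physical model

A body surface element with unit normal **n** under a sky with luminance
distribution L(ω) receives irradiance

    E(n) = ∫_{ω·n>0, ω above horizon} L(ω) (ω·n) dω.

Surfaces are Lambertian, so the radiance leaving a face with reflectance ρ
is ρE/π, independent of view direction. The *optimal countershading
pattern* for a given sky inverts the irradiance field, ρᵢ = k/Eᵢ, making
ρE — and hence the apparent brightness — constant over the body. We take
k = min Eᵢ so that the maximum reflectance is exactly 1 (a physically
realizable pattern: darkest where light is strongest, white where it is
weakest); an alternative normalization matching a prescribed mean
reflectance is available for background-matching work. Faces receiving
zero irradiance have no finite optimal reflectance and raise an error
rather than being clamped; with the default convex ellipsoid and either
sky the minimum face irradiance is small but strictly positive.

### Skies

Two members of the CIE standard sky family stand in for the weather
extremes the pipeline contrasts:

* **overcast** ("cloudy"): L(Z) = Lz (1 + 2 cos Z)/3, azimuth-symmetric,
  purely diffuse.
* **clear with sun** ("sunny"): relative luminance = gradation
  φ(Z) = 1 − exp(−0.32/cos Z) times scattering indicatrix
  f(χ) = 1 + 10(e^{−3χ} − e^{−3π/2}) + 0.45 cos²χ (χ = angular distance
  to the sun), normalized to Lz at the zenith, plus a separate direct
  solar delta term.

The direct term's strength is set by `sun_irradiance_ratio`, the direct
irradiance on a sun-facing plane as a multiple of the diffuse horizontal
irradiance; the default 5.0 puts the scene firmly in the strong-gradient
regime typical of bright sunshine (clear-sky diffuse fractions of order
15–20%). The sun sits at azimuth 270° (behind the viewer) and altitude
45°. A degenerate **isotropic** sky (constant luminance over the full
sphere, E = πLz for every normal) provides the all-round-uniform reference
under which the optimal pattern is uniform. Ground-reflected light is
ignored throughout: the lower hemisphere contributes nothing, which is
the main reason irradiance on belly-facing surfaces is driven entirely by
the near-horizon sky.

Irradiance is integrated on a product grid — Gauss–Legendre in
cos(zenith), uniform midpoint in azimuth (spectrally accurate for the
periodic factor) — with 64 × 128 nodes by default; doubling the
resolution changes E by well under 0.1%, and the overcast upward-normal
value matches the closed form 7πLz/9 to machine precision. The renderer
uses a 32 × 64 grid, whose ~10⁻³ relative quadrature difference is
invisible at 8/16-bit output and keeps matched-pattern cancellation far
below the 2% pixel-cv criterion.

### Shading diagnostics

`shading_metrics` summarizes a radiance field by its area-weighted
coefficient of variation (cv; 0 = perfectly flat appearance) and by the
area-weighted correlation between radiance and the vertical component of
the face normal (*vertical gradient*: positive = lit-from-above convex
appearance, negative = inverted/concave appearance). The depth of a
pattern's dorsoventral gradient is the ratio of mean reflectance over the
belly strip to the back strip, where the strips are faces whose normals
lie within 30° of straight down/up. Polar caps rather than hemispheres
are compared deliberately: under directional light the optimal pattern
also carries an azimuthal (sun-facing vs sun-averted) gradient, and the
bright sun-averted *upper* flank would otherwise dilute the dorsoventral
contrast that the cloudy-vs-sunny comparison is about. With the cap
definition the sunny optimum is reliably deeper than the cloudy one
across cap angles up to 45° and across mesh resolutions.

## Stimulus geometry

The target is a prolate ellipsoid, 120 mm long with aspect ratio
1.27:0.4 (≈3.18:1, from the published on-screen proportions), long axis
horizontal at the reference orientation (pitch = yaw = roll = 0).
Distractor "leaves" share the target's elliptical outline: each half of
the flat ellipse is rotated inward by 15° about the long axis (a 30°
angle between the halves' normals) and the sheet is then displaced
vertically by c·cos(x/l), with c drawn per leaf from Normal(l/6, (l/6)²),
l = 120 mm. Distractors keep pitch = yaw = 0 and take a random roll from
Normal(0°, 50°²); leaves are rendered as two-sided Lambertian sheets.

Item centres are drawn uniformly in a fronto-parallel square at 2 m, with
every pairwise separation at least 1.3 × the distractor length (156 mm),
by sequential dart throwing with whole-scene restarts. The placement
square is 1600 mm on a side. This is a deliberate design choice: the
separation rule and the published angular sizes (items 1.27°, scene
10.58°) are jointly unsatisfiable for 40 distractors — they would demand
a hard-disk coverage of ≈0.78, far beyond the ≈0.55 jamming limit of
random sequential placement — so the package keeps the separation rule
and the whole-scene angle exact and lets the per-item angle follow from
the geometry (≈0.79° for a 120 mm item in a 1600 mm field). At 1600 mm
the 41-item coverage is 0.31 and scene generation succeeds essentially
always within the 10⁴-restart budget.

Rendering is a flat-shaded perspective z-buffer rasterizer (one radiance
per face, nearest surface wins), with the camera framing the placement
square and a uniform backdrop at 4 m whose radiance defaults to the mean
item radiance, emulating the brightness-matched background. Cast shadows
are off: with the sun high and behind the viewer they fall outside the
field of view, and item-on-item shadows are rare and
condition-independent. Display mapping divides by the 99th-percentile
pixel luminance and clips the brighter remainder to 1.

## Synthetic observer

Each session is 10 training trials (unrecorded) plus 120 test trials: 20
per weather × pattern cell, each cell split 10/10 between 20 and 40
distractors, order randomized. Correctness is Bernoulli on the logit
scale and reaction time gamma-distributed with a log-linear mean — the
gamma is parameterized by (shape, mean) precisely so the simulator's
linear predictor coincides with the log-link model that analyses it.
Participant intercepts are Normal, independent per response scale and
shared across sessions.

Cell effects are specified per weather × pattern cell (not additively)
because the phenomenon is an interaction: the weather-matched pattern is
cryptic under *both* skies. Defaults: uniform-target accuracy 0.92,
matched-CS accuracy 0.46 (half), matched-CS reaction-time multiplier 3.0
(the middle of the 2–4× range such search-cost effects span), a mild
benefit of the sun-optimized pattern under cloud (accuracy 0.85, RT
×1.15) and none for the cloud-optimized pattern under sun, a small
positive session effect on accuracy (+0.15 logit) and a speed-up in
session 2 (−0.10 log), intercept SDs 0.3 (logit) and 0.15 (log), gamma
shape 4 (RT coefficient of variation 0.5), baseline mean RT 1.2 s, 9
participants × 2 sessions. With these settings the pooled matched/uniform
reaction-time ratio is 3.0 and the detection decrease ≈48–50%.

What the simulator does *not* model: the second-stage dial-selection
mechanics, timeouts or censoring, learning within a session, set-size
(20 vs 40) effects, and any image-computable link between the rendered
stimuli and performance — it is a statistical observer, not a perceptual
one. Passing tests therefore certify the analysis machinery and the
generative calibration, not human behaviour.

## Mixed models

Both families put a Normal random intercept u_i per participant on the
linear predictor: binomial-logit for accuracy, gamma with log link (the
default; inverse link available) for reaction time, gamma shape estimated
jointly by maximum likelihood. The marginal likelihood integrates u_i out
with *adaptive* Gauss–Hermite quadrature: per participant the integrand
is recentred at its mode (vectorized Newton iterations) and rescaled by
its curvature, then an n-node Hermite rule is applied; n = 1 is exactly
the Laplace approximation, and the default n = 8 changes estimates by
< 10⁻⁵ relative to n = 16 on the default design. The outer optimization
is L-BFGS-B over (β, σ_u, log shape) started from an ordinary GLM fit,
with σ_u bounded below by 10⁻⁸ so boundary (zero-variance) fits are
representable; standard errors come from the observed information
(central-difference Hessian). On a fixed simulated dataset the binomial
fit agrees with lme4::glmer (nAGQ = 8) to ~10⁻⁵ in every coefficient and
in σ_u, and the gamma fit matches glmer's coefficients to ~10⁻³ while
attaining a slightly higher marginal likelihood (glmer handles the gamma
dispersion outside the likelihood).

Factor tests are likelihood-ratio χ² (full vs factor-dropped refit;
dropping the 3-level pattern factor gives df = 2), matching the reporting
convention of such analyses; Wald z per coefficient is also available.
Pairwise comparisons use the single-step max-|z| (Tukey-style)
adjustment: p = P(max_j |Z_j| ≥ |z|) under the joint normal law of all
pairwise contrasts, evaluated by quasi-random (Sobol, fixed seed, 2¹⁷
points) integration; a single contrast needs no adjustment and uses the
exact normal tail. The default analysis fits per-weather subset models
(pattern + session fixed, participant random), which yields the df = 2
pattern test directly; a full factorial weather × pattern model is
available as a variant, as is a correct-trials-only filter for the
reaction-time models.

The tolerant reader for external trial tables maps column names through
an alias table (case-insensitive), normalizes factor spellings, preserves
unknown columns as annotations, and flags reaction-time columns whose
median exceeds 100 as likely milliseconds, converting only on an explicit
flag.

## Problem sizes and numerical choices

Default mesh: 32 latitudinal bands (3968 faces), sub-pixel facets at the
default 512² image. Simulation studies in the test suite use 1000 null
replicates (8 participants × 120 trials) for the type-I calibration of
the LR test and 200 replicates at 40 participants × 240 trials for
fixed-effect recovery; generative calibration uses ~10⁵ simulated trials.
Ties in the z-buffer resolve to the first-drawn triangle; degenerate
(zero-area) faces are rejected at mesh construction. All randomness
derives from explicit `numpy` Generators; a single master seed
reproduces every scene, trial table and fitted model.

## Known limitations

* No ground-reflected or interreflected light, no cast shadows, no
  spectral/chromatic dimension: radiometry is relative and achromatic.
* The convex-body irradiance assumption is exact for the ellipsoid but
  approximate for folded leaves (their concavity can occlude part of the
  sky locally).
* The optimal-pattern normalization (max ρ = 1) fixes contrast with the
  background only up to the brightness-matching convention used by the
  renderer.
* The GLMM supports a single scalar random intercept — no random slopes
  or crossed random effects.
* The published angular item size is not reproduced simultaneously with
  the separation rule (see Stimulus geometry); the scene-level angle and
  the separation rule take precedence.
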