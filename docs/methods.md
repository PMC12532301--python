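# Methods

## Model overview

`rayleighsim` predicts Rayleigh matches by the cone-excitation-ratio
construction: multiply the field's spectral power distribution by each of
the observer's two Rayleigh-range cone sensitivities, sum over wavelength
(energy units throughout; no quantal conversion), and intersect the
mixture's excitation-ratio curve with the amber field's fixed ratio.  The
short-wave cone is constructed but never used in match computations: it is
essentially insensitive beyond ~560 nm, where all three primaries of every
modeled instrument live.

All spectra share one uniform wavelength grid (default 390–780 nm at 1 nm).
Excitations are linear in each channel's output, so the ratio curve is
evaluated from six precomputed channel-by-cone inner products; this makes
match prediction a scalar root-finding problem.

## Spectral synthesis

* **LED primaries** are Gaussians in wavelength parameterized by peak and
  FWHM (red 623/20 nm, green 523/30 nm, amber 592/16 nm for the Penn-like
  preset; 670/545/589 nm for the Oculus-like, 666/537/589 nm for the
  Nagel-like).  Published sources give the peak wavelengths but not the
  measured band shapes, so a unimodal narrowband model is used; the green
  channel accepts an optional second Gaussian component for the
  long-wavelength shoulder some tricolor LEDs show (amplitude 0 by default,
  so it never biases results silently).
* **Filters** are logistic cut-on (long-pass) curves.  The deep-yellow
  filter screening the amber channel is calibrated so T(590 nm) = 0.90
  (t_max 0.92, slope 0.25 nm⁻¹, cut-on solved in closed form); the orange
  gel on the red/green channel uses cut-on 540 nm, slope 0.05 nm⁻¹,
  t_max 0.95.  Only a single transmittance point is documented for the real
  filters; everything else is a smooth-shape assumption.
* **Output curves.**  The Penn-like mixture control λ ∈ [0, 1] drives the
  red output linearly (r(λ) = λ) while the green output is constant up to a
  knee at λ = 0.3 and then falls linearly to zero at λ = 1 — so total
  mixture output varies along the scale, as on the physical device.  The
  0–73-scale presets use complementary linear outputs (0 = pure green).
  Channel SPDs are peak-normalized; the *relative radiometric balance* of
  the channels is therefore a model convention, and predicted λ\* values
  are meaningful within the model, not as reproductions of any physical
  instrument's scale positions.

## Observers

Normal cone fundamentals come from an A1 visual-pigment absorbance template
(alpha plus beta band, parameterized by peak wavelength: L 559, M 530,
S 421 nm) attenuated by lens and macular optical densities and renormalized
to peak 1.  A CSV loader accepts tabulated fundamentals when available.

The pre-receptoral densities shipped with the package are **synthetic
analytic stand-ins** for the standard 2° tables: lens density
exp(−(w−400)/60) (log10 units, ≈1.0 at 400 nm) and a macular Gaussian band
(0.35 peak density at 458 nm, σ 28 nm, hence < 0.01 above 550 nm).  In the
Rayleigh range (≥ ~540 nm) both are small, so match predictions are
insensitive to their exact shapes; a CSV loader accepts measured tables.

Anomalous pigments use the classical construction: strip the pre-receptoral
densities, translate the template on a wavenumber abscissa, restore the
densities, renormalize to peak 1.  Protan variants (M′) shift the M
template; deutan variants (L′) shift the L template.  Sign convention:
**positive shifts move the peak toward shorter wavelengths** (new peak =
1e7/(ν_peak + s) nm).  The translation is evaluated with a shape-preserving
PCHIP interpolant in wavenumber, which keeps bands unimodal, makes a zero
shift an exact identity, and keeps the double-shift composition error below
1e-4.

**Zero-shift degeneracy.**  A zero-shift anomalous observer has two
identical cones; its mixture and amber excitation ratios coincide at every
setting, so it accepts the entire scale (a dichromat, behaviorally) and
`predict_match` raises a dedicated indeterminate-match error rather than
inventing a setting.  λ\*(s) is continuous through s = 0 in the limit
(both one-sided limits agree to ~1e-4 of the scale), but that limit is an
interior setting unrelated to the *normal* observer's match — the normal
match involves the L/M pair, which the degenerate observer lacks.

`fit_shift_to_match` inverts the model by grid search (default step
10 cm⁻¹, bounds ±2000 cm⁻¹, ties toward the smaller |shift|); targets
outside the control range, or unreachable by any on-scale match, are
rejected explicitly.

## Match solver

The solver works on f(λ) = log ratio_mix(λ) − log ratio_amber: a 64-point
scan brackets sign changes (choosing the one nearest mid-scale, with a
warning, if several exist — a single intersection is the expected
geometry), then bisection runs until |f| ≤ 1e-8 **and** the bracket has
shrunk below 1e-12 of the scale span, so the returned λ\* is pinned
independently of last-ulp perturbations (e.g. rescaling the amber
intensity).  A no-crossing scan raises an error carrying the sign of f at
both scale ends, which diagnoses beyond which end the match lies; this is
the mechanism by which extreme anomalous observers are excluded.  The
matching range is the connected sublevel set |f| ≤ δ around λ\*
(default δ = 0.01 in log-ratio units — a free Weber-like tolerance, since
no discrimination threshold is published), with `touches_end` flagging
ranges that reach a scale end.  `brute_force_match` (uniform grid argmin of
|f|, ties toward the smallest setting) serves as an independent oracle and
agrees with the bisection solver to the oracle resolution.

The amber intensity dimension is handled separately:
`brightness_match_intensity` equates the *summed* two-cone excitation of
the two fields (linear in the amber intensity, hence always solvable;
values beyond the amber dial are clamped and logged).  It feeds the
simulated amber-setting column only — the chromatic match λ\* is determined
by the ratio intersection alone.

## Synthetic cohorts

Between-observer variation is spectral, not additive on the instrument
scale: anomalous shifts are drawn per class, and normal observers get a
small L-pigment jitter.  Cross-instrument correlation structure therefore
emerges from observer metamerism — the same pigments are multiplied into
each instrument's own primaries — rather than being injected.

Default study conditions (fixed once, by calibration against the model's
own predictions, before any acceptance checks were run):

| parameter | default | rationale |
|---|---|---|
| cohort | 24 normal, 4 protan, 4 deutan | the reference study's composition |
| protan shift | −300 ± 60 cm⁻¹ | variant ~8–9 nm long of M; match clearly displaced yet on-scale on both presets |
| deutan shift | +300 ± 80 cm⁻¹ | variant ~9 nm short of L; same criterion |
| normal L jitter | 60 cm⁻¹ SD | ≈1.9 nm at the L peak, polymorphism-scale variation |
| setting noise | 0.005 of the control span per setting | plausible adjustment SD; per-setting SDs are not published |
| amber noise | 2% proportional | record-keeping realism only |
| settings/session | 3 | the study's minimum |
| sessions | instrument 1 × 2 visits, instrument 2 × 1 visit | the two-visit design |

Setting noise is Gaussian, homoscedastic per observer, scaled by each
instrument's control-range span (the same *relative* precision on a unit
scale and a 0–73 scale), and clipped at scale ends with a flag — never
silently.  Randomness is fully reproducible: one master seed, with
per-(observer, instrument, session) streams derived by stable hashing, so
any cell can be regenerated independently.

What the generator does **not** emulate: learning/fatigue and order
effects, session-level drifts (calibration or adaptation changes between
visits), heteroscedastic noise near scale ends, optical-density variation
among pigments, and any spatial/field-geometry effects.  Passing
reliability checks therefore shows the statistical pipeline is correct
under the stated noise model, not that a physical instrument achieves
these correlations.

## Analysis

Session means are the analysis unit.  Correlations are Pearson and
Spearman (midranks) with two-sided t-approximation p-values on n−2 df,
computed via scipy; zero-variance inputs are rejected explicitly rather
than returning NaN.  Test-retest reliability across session means follows
the variance-ratio closed form R ≈ σ_b²/(σ_b² + σ_w²/n), which the
simulation reproduces within ±0.05 over 200 replicates.

Classification is model-anchored: the normal reference point is the
model's own normal match on the instrument at hand; the normal interval is
closed with halfwidth 4× the normals' between-observer match SD
(propagated from the jitter SD through the model's local match
sensitivity); and the side carried by each anomalous class is the sign of
its archetype's displacement, computed per instrument.  Contradictory
diagnoses are observers labeled on opposite anomalous sides by two
instruments.

## Numerical choices and limitations

* Ratios are compared on the log scale for symmetry across observer types.
* Grid arithmetic is exact-match only: no silent resampling inside
  operations; a resampling step is explicit and pads out-of-support values
  with zeros (logged).
* On the Penn-like preset as modeled, the normal match sits high on the
  scale (λ\* ≈ 0.93) and protan displacement is small — a direct
  consequence of the short 623 nm red primary exciting M weakly, and
  consistent with the general rule that wider primary separation separates
  phenotypes better.  Mild protans can therefore fall inside the normal
  classification interval on this preset; this is a property of the modeled
  instrument, not a pipeline artifact.
* Predicted λ\* values depend on the assumed channel balance and band
  shapes and are not comparable to physical instruments' published norms.
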