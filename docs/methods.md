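# Methods

`colorgrain` implements a biologically constrained colorimetry: Lambertian
objects under varieties of daylight, anchored on a white reference. This
note records the models, conventions and numerical choices, and what the
synthetic-data generators do and do not capture.

## Colorimetric core

Spectra live on a uniform wavelength grid over the visual range, by default
380–720 nm at 1 nm, inclusive of both endpoints. The observer is the CIE
1931 2° standard observer; the standard illuminant is CIE d65. Both are
bundled as the standard published 5 nm tables and linearly interpolated
onto the working grid. Tristimulus integration uses the trapezoid rule
throughout; a single weight vector (`cell_weights`) is shared by every
integral in the package so that linear identities (anchoring, canonical
round trips, null-space blacks) hold to machine precision rather than to
quadrature tolerance.

Object colors are white-anchored: the tristimulus of the reflected beam
`F·D` divided componentwise by that of the white beam `D`, in the rgb-parts
basis. This implements a von-Kries-style automatic white balance; the white
and black objects (and the whole achromatic diagonal) are exactly invariant
under spectral changes of the illuminant.

## Color solid and crate

The color solid of an illuminant is the convex set of colors of beams
`S ≤ D`. Its boundary colors come from 0/1 characteristic spectra with at
most two transitions; we mesh it with all band and band-stop spectra on an
`n × n` lattice of cut pairs (default `n = 100`) and take the convex hull
(`scipy.spatial.ConvexHull`). The hull volume changes by less than 0.1%
from `n = 100` to `n = 200`.

Cut positions are continuous. Two consistent partial-integral conventions
are used:

* for the **crate objective** (and the boundary mesh) the integrand `D·cmf`
  is treated as piecewise linear between samples, making the cumulative
  integral piecewise quadratic in the cut position. This is the continuum
  limit of the trapezoid rule; with piecewise-*constant* (area-weighted
  occupancy) integrands the objective is piecewise linear in each cut and
  its maxima always snap to sample-cell edges, which would make sub-nm cut
  loci meaningless.
* for the **sampled part spectra** of a chosen tripartition, the cut cell
  is split by fractional occupancy and the green part is the exact residual
  `D − blue − red`, so the three parts partition the illuminant exactly at
  every sample and their trapezoid tristimulus vectors are exactly the
  columns of the basis matrix. The two conventions agree to O(step²).

The largest inscribed crate is found by an exhaustive 1 nm lattice scan of
`|det[B G R]|` over all cut pairs followed by nested lattice refinement
(five levels, each 10× finer, down to 10⁻⁵ nm); ties beyond 1e-6 relative
volume at well-separated cut pairs raise an error. For d65 with the CIE
1931 observer the optimum is at λ₁ ≈ 489.34 nm, λ₂ ≈ 569.95 nm, claiming
≈ 64.3% of the solid volume. The objective is remarkably flat — cut pairs
7 nm away lose under 2% of volume — so the optimum location is sensitive
at the several-nm level to the CMF tabulation used; published values for
this construction differ accordingly (see Limitations).

## Homomorphic domains

Reflectance statistics are computed in the log spectral-signature domain
ρ = log(K/S) with the Kubelka–Munk relation K/S = (1−R)²/(2R) for an
optically thick turbid layer; radiant power statistics in the log domain.
`g = f⁻¹` is evaluated in the cancellation-free form
`r = 1/(1+k+√(k(k+2)))`, `k = e^ρ`. Boundary reflectances are clamped
inward by 1e-4 (counted and logged). Because generation happens in these
domains and is mapped back through `g` / `exp`, every generated spectrum is
physical by construction — no clipping is ever needed.

## Generative models

**Daylight** (log domain): ensemble mean (log d65 by default) plus two
principal directions — spectral slope and curvature, realized as Legendre
P₁ and P₂ normalized to unit rms over the grid — with independent normal
coefficients (SDs 0.15 and 0.05 log units), plus a fractal fuzz (exponent
4, rms 0.01 log units). These amplitudes produce a daylight-locus-like,
slope-dominated chromaticity scatter around the d65 white point; they are
deliberate, overridable defaults, since fitted values for real daylight
ensembles are not bundled. Instances are normalized so the maximum rgb
coordinate of the implied white is 1 (anchoring makes this cosmetic).

**Reflectance** (signature domain): a baseline — a database mean signature,
or by default a constant spectral slope of −0.004 per nm about the mid-gray
level ρ = 0 (r ≈ 0.27) — plus a fractal articulation with Fourier power
∝ f⁻⁴ (fractal dimension two), rms 1.0 signature units, and autocorrelation
halfwidth equal to the visual-range width: natural spectra vary only
gradually with wavelength.

**Fractal synthesis.** Random-phase Fourier synthesis with amplitude
spectrum ∝ k^(−exponent/2), no DC term, on an *extended periodic support*
whose length is solved from the requested correlation halfwidth (the
half-crossing angle of the harmonic-sum autocorrelation; ≈ 6.6× the
halfwidth for exponent 4); the visual-range window is then cropped out and
scaled to the requested process rms. Synthesizing directly on the window
would pin the autocorrelation halfwidth to ≈ 1/6 of the range, far short of
the intended width. A second flavor replaces the Fourier fractal with
randomly located Gaussian bumps of a single width (an explicit model of
many independent physical causes, each imprinting local spectral
structure).

**Estimators.** Spectral histograms report per-wavelength median and
quartiles in the signature domain. The articulation power spectrum removes
a mean-and-slope trend per item, applies a Hanning window, averages
periodograms, and fits the log-log slope over 4–40 cycles per visual range.
The band starts at 4 because the first few bins carry curvature leftovers
of sub-bin (trend-scale) components that the linear detrend cannot remove;
including them biases a true exponent of 4 to ≈ 4.4, while the 4–40 band
recovers exponents 4, 3 and 0 (white noise) to within ±0.1 at n = 500.
Model fitting (`fit_daylight_model`, `fit_reflectance_model`) uses
per-item log shifts, the ensemble mean, scikit-learn PCA rescaled to
unit-rms components, the coefficient covariance of the projections, and the
power-law fit of the residual.

## Metamers

A metameric black is built from four model reflectance instances, each
apodized with a full-range Hanning window (raw combinations have unusable
amplitudes near the spectrum limits), combined through the 1-D null space
of their 3×4 tristimulus matrix under the standard illuminant;
rank-deficient draws are redrawn (up to 10 times). The sign is fixed by
making the largest-magnitude coefficient positive and the black is
normalized to unit rms before scaling. Metamers of a color are its
canonical three-level spectrum plus a black scaled to the full physical
headroom (`max_scale`, closed form from per-sample headroom) — a
deliberately pessimistic choice; uniform scaling in [0, s_max] is
available. Colors on the cube boundary have zero headroom and hence no
metamers.

## Grain of color space

A confusion ellipsoid is the sample-covariance ellipsoid at the 95% level:
semiaxes are √(eigenvalue × χ²₀.₉₅,₃) with χ²₀.₉₅,₃ ≈ 7.815; volume is
(4/3)π·abc, with an eigenvalue floor of 1e-18 flagging degenerate clouds.
The illuminant-only pipeline puts every object under every illuminant; the
full pipeline draws, per fiducial color and per sample, one maximally
scaled random black and one fresh daylight instance, and recomputes the
anchored color (the sequential protocol; a factorial mode is available via
the library by fixing the daylight model). Field summaries report quartiles
and ranges of the equivalent radius (equal-volume sphere) and maximum
radius (largest semiaxis), the mean volume, and `n_marks = 1/mean volume` —
the number of color categories stable under ecological variation.
`coordinate_grain` converts any color count to the implied per-coordinate
uncertainty (cube root of the reciprocal).

Default problem sizes — 50 interior fiducials (or the 27-point 0.25-spaced
lattice) × 200 samples — give stable summaries in a few seconds; the
Monte-Carlo run in the acceptance checks uses exactly these sizes.

## Hue-swap exhibit

The constructive demonstration that colors are not object properties.
Both sources are the standard beam plus a radiant metameric black:
`I₁ = D(1−m)`, `I₂ = D(1+m)` with `m` a smooth zero-tristimulus modulation
(Gaussian-bump basis projected onto the null space of the tristimulus
operator, ≈ 5 cycles across the range, depth 0.92). Symmetry matters: with
one source left unmodulated each anchored coordinate can change between
sources by at most a factor (1+depth), which provably rules out strong
swaps such as 0.2 ↔ 0.7; with symmetric modulation the bound becomes
(1+depth)/(1−depth). The modulation must also change sign within each part
of the spectrum, because rose and violet need opposite effective modulation
on the same coordinate. Rose and violet reflectances are solved by SLSQP
least squares over a 32-bump-plus-constant basis with pointwise bounds
0.001 ≤ F ≤ 0.999; the default targets (0.7, 0.2, 0.2) ↔ (0.2, 0.3, 0.7)
close with residual ≈ 3e-4, and infeasible targets raise with the best
residual. The daisy (F ≡ 1) maps to (1, 1, 1) under all sources — the
proof that both fakes are "white light".

## What the synthetic data does and does not show

The generators emulate the *statistical texture* of natural spectra:
physicality, smoothness (inverse-fourth-power articulation, range-wide
correlation), a shared spectral gradient, slope-dominated daylight
variation. They do not emulate database-specific structure: chlorophyll
bands, pigment families, bimodal signature histograms, measurement noise,
or the heavy tails of real daylight ensembles (overcast vs. clear-sky
extremes). Consequently the pipeline's absolute grain numbers are
conservative relative to ones computed from real databases: the synthetic
ecology varies less, confusion ellipsoids come out several times smaller in
radius, and the implied mark count correspondingly larger. Passing tests
certify the machinery and its invariants, not database-specific values —
those require feeding the real CSV databases through `summarize-db`,
`fit_*` and `grain`.

## Known limitations

* The crate cut loci are only as sharp as the flat objective allows:
  different CMF tabulations move the optimum by several nm while changing
  the claimed volume fraction by well under 1%.
* The two-transition boundary characterization can fail marginally near the
  spectrum ends with real CMFs (non-convexity of the spectrum locus); we
  assert it only on a coarse 12-band partition, where it holds exactly.
* Metameric-black sampling uses the maximum physical scale; the true
  probability density of black amplitudes in nature is unknown, so grain
  estimates are pessimistic in that direction while the mild default
  ensembles push the other way.
* No ecological/ethological weighting of colors: every fiducial counts
  equally.
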