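# Methods

## Quasistatic plasmon model

The optical response of the modulated film is computed in the quasistatic
(electrostatic) approximation: structure dimensions (L ≈ 400 nm, h ≈ 80 nm,
d ≈ 15 nm) are treated as small against the wavelength, and the film as
thinner than the metal's skin depth. Both assumptions are only marginally
satisfied for the default design (L/λ ≈ 0.51); `plasmon.validity_report`
prints the relevant ratios with an explicit caveat, using the conventional
skin-depth proxy λ/(2π·Im √ε_m), but the model is evaluated regardless —
its role is closed-form design guidance, not full-wave accuracy. Radiative
loss, retardation and quadrupole/higher-order resonances are not modelled;
only the dipole (n = 1) harmonic of the interior source is carried through
as a closed form, since it is the mode relevant to SERS operation. The
logarithmic (circular-field) term of the source expansion is independent of
the metal permittivity and is therefore excluded from enhancement maps.

Time convention is e^(−iωt), hence passive media have Im ε ≥ 0; inputs with
Im ε < 0 are rejected rather than silently conjugated, since a sign error
here flips the loss into gain. All core lengths are nanometres; wavenumbers
(cm⁻¹) exist only in the spectra module.

The four potential coefficients (A, B, C, D) of the dipole harmonic are
obtained two independent ways: the closed-form expression for A, and a 4×4
linear system enforcing continuity of potential and normal displacement at
both cylinder interfaces. The two agree to 1e−8 relative over a broad
(a, α) grid; the matching solver is also the only practical route to B, C, D
and to |A| at resonance, because the textbook closed form for the resonance
maximum of A is numerically fragile (only its Q_m scaling is reliable,
and that scaling is what the code asserts).

Two statements about the depression field deserve care. First, with the
y-convention used here (illuminated side at y → +∞, depressions at the
minima of y_u) the intensity ratio between a depression bottom and a crest
is exp(+4πh/L) ≈ 12.3 — the field is *larger* in the depressions; the ratio
is sometimes quoted with the opposite sign of the exponent, which is a pure
convention artefact. Second, the resonant depression-bottom amplitude
estimate evaluates to ≈ 16 (amplitude) for the default silver design, i.e.
≈ 2.6 × 10² in intensity; claims of a "hundred-fold" field should be read
against whichever of the two scales is meant. The code reports the
amplitude and leaves the squaring to the caller.

Resonance scans over film thickness use a 512-point grid followed by
golden-section refinement (relative tolerance 1e−9), ties broken toward
smaller d; h = 0 and d = 0 are legitimate flat-film limits, while a ≥ 1 or
α ≤ a are hard errors.

## Spectrum processing and the limit of detection

Baselines use an asymmetrically reweighted penalised least-squares smoother
(second-difference penalty, weights iteratively re-derived from the negative
residuals). Stiffness λ = 1e5 is the default for the 600–1700 cm⁻¹ range
sampled at 0.5 cm⁻¹; the estimator settles through the middle of the noise
in signal-free regions (so the noise statistic below is unbiased) while
staying below peaks. No published baseline algorithm is attached to this
workflow, so the smoother and its parameters are deliberately ordinary and
config-exposed; what matters downstream is reproducibility, which the
property tests pin (ramp residual < 1% of range, band area preserved to 5%).

Noise is the mean absolute baseline-subtracted residual over the quiet
windows 600–650 and 1650–1700 cm⁻¹ (configurable); for Gaussian noise its
expectation is σ√(2/π), which the tests verify to 5%.

Band intensity defaults to the window maximum of the baseline-subtracted
signal in 1589 ± 15 cm⁻¹ ("height"; "area" is available). For
dilution-series S/N two refinements are applied, both exposed as options:

* the residual is Gaussian-smoothed with a 3 cm⁻¹ kernel before taking the
  maximum. A raw window maximum has a noise-order-statistic floor of about
  2σ (≈ 2.5 S/N units for a 31–61 sample window), which makes sub-μM points
  of the calibration series nonlinear; smoothing at the band scale lowers
  that floor to ≈ 0.35 S/N units at the cost of ~15% attenuation of a
  5 cm⁻¹ band, which cancels in a calibrated S/N ratio;
* the noise figure is pooled (averaged) across the series. The noise belongs
  to the instrument and acquisition settings, which are common to the whole
  calibration run; pooling removes the dominant variance term of the fitted
  intercept (a per-spectrum multiplicative jitter of several percent that
  otherwise propagates into the LOD as ±50% swings).

The S/N-vs-concentration line is fitted by ordinary least squares *with* an
intercept (a through-origin fit is available); the LOD solves
slope·c + intercept = 3. The criterion 3 is a named constant. If the fitted
intercept already exceeds the criterion the LOD is flagged as an
extrapolation below the measured range rather than silently returned.

Whether such a calibration fit should carry an intercept, and whether
"band intensity" means height or area, has no single convention; the
defaults above are this package's choices and both alternatives remain one
keyword away.

## Synthetic data

The spectrum generator is a sum of Gaussian bands on a polynomial baseline
plus seeded white Gaussian noise, on a 600–1700 cm⁻¹ grid at 0.5 cm⁻¹
(typical CCD dispersion over this range). The dilution-series generator
scales the 1589 cm⁻¹ band so that the *expectation of the measured* S/N
equals slope·c: a fast Monte-Carlo inversion of the window-max statistic is
refined by secant iteration through the actual pipeline (baseline
estimation, pooled noise, smoothed height) with fixed internal seeds, so the
generated series is linear in exactly the quantity the pipeline measures —
which is how a real calibration series behaves, since an experimental S/N
axis *is* the measured ratio. Default concentrations are 50, 5, 0.5 and
0.05 μM with slope 15 per μM, so the implied LOD is 0.2 μM. (Reported series for this reporter vary in their lowest point between
0.2 μM and 0.05 μM; the fixture uses 0.05 μM, the harder case, since that
point lies below the detection criterion.) A zero-noise series is
flagged as a fit-only fixture because S/N is undefined without noise.

The surface generator emulates a doubly modulated metasurface as the
separable sum of the closed-form film profile along both axes, scaled so the
map's peak-to-valley equals h (the 2-D form of the doubly modulated surface
is not defined anywhere; the separable sum is a documented stand-in).
Defaults: L = 400 nm, h = 80 nm, 1024 × 1024 pixels over a 10 × 10 μm field
(pixel ≈ 9.77 nm, an integer 25 lattice periods per field so spectral tests
are leakage-free). On top of the lattice:

* exosomes and polymer imperfections are spherical caps, diameter 60–120 nm
  (within the 30–150 nm vesicle gate) and apex height 0.3–0.6 of the
  diameter — no measured exosome profile model exists, so the cap and its
  aspect range are exposed parameters;
* silver-deposition defects suppress the current with no height signature;
* the current map is a unit baseline with 5% multiplicative noise, floored
  at 0.01 on exosome and defect footprints (conductance physics is not
  modelled, only the qualitative contrast that vesicles and voids do not
  conduct);
* height noise has two components chosen to mimic AFM data of an evaporated
  film: white pixel-scale roughness (8 nm RMS — instrument noise plus
  unresolved grain) and a smooth multiplicative disorder of the lattice
  amplitude (10% RMS, correlation ≈ 2L) reproducing the fabrication spread
  of the modulation depth that a cross-section shows as per-period swing
  variability.

Objects are anchored at depression centres (the surface is morphologically
complementary to vesicles) with a minimum separation of 3L so sites remain
individually resolvable; edge-overlapping objects are rejected with a
warning. Everything is deterministic under the model seed; ground truth
retains one labelled row per placed object.

What passing tests on these fixtures do *not* show: robustness to tip
convolution, drift or scan-line artefacts in AFM, electrochemical SSRM
contrast mechanisms, correlated (non-white) CCD noise, or real exosome
spectral variability. The generators are a controlled stand-in for study
conditions, not an instrument model.

## Correlative classification

The lattice is removed by zeroing the 2-D FFT in ±1-bin notches around the
lattice frequency and its first two harmonics on both frequency axes
(including the cross terms of the double modulation), DC preserved. Bump
detection then median-centres the residual (classification is invariant to a
global height offset), smooths it with a 1.5-pixel Gaussian, thresholds at
15 nm, and measures each candidate's lateral FWHM as the equivalent diameter
of the half-maximum footprint *around the peak on the field* — not on the
thresholded blob, which would clip bumps peaking just above threshold.
Candidates outside the 30–150 nm gate are dropped; blobs with several
distinct local maxima are flagged as clusters (aggregate rather than single
vesicle). Low-conductivity sites are connected regions below 10% of the
median current (scale-invariant by construction). SSRM and AFM candidates
within 200 nm (half a period — depression-centred deposition) merge into one
site, classified by the decision table low-conductivity × bump →
{exosome, silver_defect, imperfection, clean}. The conductivity threshold
and matching radius have no measured counterparts; they are stated defaults,
config-exposed.

The period estimator averages row and column power spectra, excludes the two
lowest bins (DC and drift), and requires the dominant bin to stand 8× above
the median spectral power — otherwise it raises rather than returning a
meaningless number. Cross-sections interpolate bilinearly along a polyline
and report per-period peak-to-valley swings between consecutive crests; on
the separable-sum surface the canonical crest-to-depression sequence runs
along the diagonal.

## Problem sizes

Default test and acceptance runs use 20 seeded dilution series (4 spectra of
2201 samples each) for LOD statistics and 10 seeded 1024² map pairs for
classification statistics; these sizes give ≈ 1% standard error on the mean
LOD and resolve single misclassifications per map, which is the precision
the assertions need.

## Known limitations

* The quasistatic closed forms overestimate enhancement where radiative loss
  matters; full-wave solvers are out of scope by design.
* The dipole-term field map is x-independent in its closed form; near-crest
  accuracy is limited at large h/L.
* The classifier assumes co-registered maps (a combined instrument); no
  image registration is attempted, and unregistered inputs are an error.
* Laser-wavelength-to-shift conversion, multivariate spectral classification
  and spectral unmixing are out of scope.
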