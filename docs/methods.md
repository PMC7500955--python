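# Methods

This note documents the measurement models implemented in `centromorph`,
the defaults that matter, the synthetic data the package validates itself
against, and the design choices made where the procedure was genuinely
open.

## Unit model

All geometry is expressed in biological nanometres.  U-ExM acquires images
of the expanded gel, so a pixel (default 35 nm in x, y; 120 nm z-steps)
corresponds to `pixel_nm / X` biological nm, where the expansion factor
`X = gel size (mm) / 12 mm` is measured per gel with a caliper.  Reported
expansion factors are rounded half-up to two decimals; internal
computation keeps full precision.  Every measurement routine takes an
`ExpansionCalibration` and converts at the last step, so pipelines mixing
gels stay consistent.

## Radial mapping (top views)

The ring center is first estimated as the intensity centroid of the
thresholded tubulin channel, then refined by Nelder–Mead minimization of
the angular variance of the intensity-weighted wall radius.  The centroid
alone is biased by up to ~1.5 px on broken rings (a missing wall sector
shifts the center of mass); the radial-spread objective only uses sectors
that contain wall signal and keeps the center within 1 px of truth on
60°-broken synthetic rings, and within 0.1 px on intact ones.

Spokes are cast at the angular maxima of the angularly unrolled tubulin
wall (max-over-radius trace per 1° sector, circularly smoothed) rather
than at fixed angles, emulating per-triplet manual line scans and making
the measurement orientation independent.  Each spoke averages both
channels over an 8° wedge, sampled radially at 0.5 px with bilinear
interpolation.

Peaks are refined by 3-point quadratic interpolation, which at 35 nm
pixels delivers ~1–2 nm accuracy without model fitting.  The protein peak
is searched within ±60 nm (biological) of the tubulin peak — wide enough
for the deepest scaffold shell (~28 nm), narrow enough to exclude the
opposite wall (~220 nm away).  A spoke is *unresolved*, and excluded from
the summary, when either channel lacks a peak with prominence ≥ 0.2 of
that channel's maximum; this is the automated counterpart of measuring
only triplets with a resolved signal in both channels.  The offset sign
convention is `Δ = r_tubulin − r_protein`, positive toward the lumen, so
wall components read ~0 and scaffold components read positive values.

Ring-curvature bias is negligible at these scales: wedge averaging over
±4° shifts both channels' peaks inward by `R⟨θ²⟩/2 ≈ 0.1 nm`, and the
differential effect on Δ is < 0.05 nm, far below the ±3 nm recovery
tolerance, so no correction is applied.

## Longitudinal metrics (lateral views)

The centriole long axis is found in two stages.  A coarse scan takes the
direction minimizing the projected extent of the thresholded tubulin
pixels (the wall-to-wall width) and sets the axis perpendicular to it; a
second-moment eigen decomposition is deliberately *not* used because the
moment tensor of a barrel turns isotropic when length ≈ √3 × diameter
(≈ 380 nm at a 220 nm diameter — inside the observed length range), where
its eigenvectors are meaningless.  The residual tilt is then removed by
fitting a line through the per-column intensity centroids of the barrel
midline, giving sub-degree alignment.  Both channels are rotated into the
axis frame; the axial profile averages the rows spanned by the tubulin
mask.

Signal length is the full width at half maximum of the axial profile:
the extent between the outermost crossings of
`background + 0.5 × (signal − background)`, with linearly interpolated
crossing positions.  The manual criterion behind published length values
is unstated; FWHM is the least arbitrary choice, is scale invariant, and
the fraction is configurable.  The background is the median of the lowest
decile of the profile and the signal level is the median of the samples in
the top quarter of the dynamic range — using the raw maximum instead
inflates the threshold by the shot-noise excursion and biases lengths low
by several nm.

Coverage is `100 × protein length / tubulin length`; position is the band
midpoint as % of the tubulin extent from the proximal end.  Proximal
orientation follows the inner-scaffold positioning rule (band midpoint in
the proximal half); callers with an explicit proximal marker channel can
override.  Summaries round coverage to integer percent and lengths to
integer nm.

Diameter is the distance between the two outermost sub-pixel-refined peaks
of the transverse profile, averaged over a 50 px band clipped to the
region interval.  Regions follow the protein band: control rule —
proximal below the band, core = band, distal above it; depleted rule —
proximal below the remaining belt, core just above it, distal = last
100 nm of the centriole.

## Shape and integrity (top views)

Wall peaks are local maxima of the angular wall trace (prominence ≥ 0.2 of
the trace range, separation ≥ 20°), radially refined.  Roundness is the
minor/major axis ratio of a least-squares ellipse fit to the peak points —
the convention of the analysis software this field uses — with the
peak-polygon circularity `4πA/P²` reported alongside, since "connecting
the peaks" admits a polygon reading.  Views whose wall-peak radial spread
exceeds 15 % of the mean radius are flagged as tilted and should not be
scored ("perfectly imaged top views" admission rule): an oblique view
projects a circle into an ellipse and fakes ellipticity.

Wall integrity: sectors whose trace value falls below 0.15 of the maximum
(above the floor) are *missing*; the largest contiguous missing arc,
refined by interpolating the threshold crossings, is compared with a gap
threshold.  The default threshold is **30°**: with nine discrete triplets
and the default acquisition blur, an intact ring shows inter-triplet voids
of ≲ 12°, while a single fully missing triplet leaves a ~40° void (the
80° inter-peak separation minus two ~19° PSF flank penetrations), so 30°
separates the two populations with ≥ 10° margin on either side.  A
threshold at 45° would systematically miss single-triplet breaks under
this crossing geometry.  The measured gap is therefore smaller than the
geometric break arc by twice the flank penetration; the flag, not the raw
arc, is the decision output.

## Foci, intensity, normalization

Foci are local maxima of a Laplacian-of-Gaussian band-pass at the
diffraction scale, above `median + k·MAD·1.4826` of the filtered image
(default k = 5), non-maximum suppressed at 3 px.  Centrosomal intensity
integrates the background-subtracted signal over the *20 pixels nearest
the center* — the area reading of a "20 pixel" region; a box mode is
selectable since the phrase also admits a side-length reading, and the
choice is logged.  Centriolar profile intensity averages a 25-point
interpolated line profile.  Normalization divides every measurement by
the control-group mean, making the control mean exactly 1 (A.U.) by
construction and idempotent under re-normalization.

## Periodicity

Profiles are detrended by subtracting a moving average with window equal
to the upper search bound, then autocorrelated with unbiased lag
normalization (so the finite-window taper does not drag the peak toward
shorter lags).  The dominant lag in the 6–12 nm search window — bracketing
the 8 nm tubulin dimer repeat — is refined by quadratic interpolation.
Significance requires the autocorrelation peak to stand ≥ 3 baseline SDs
above zero, with the baseline excluding ±25 % neighborhoods of the
period's harmonics.  A zero-padded periodogram provides an independent
spectral estimate; on clean synthetic trains the two agree within 0.2 nm.

## Statistics

Mann–Whitney U is computed exactly — by enumerating all group labelings of
the pooled sample, which handles ties by construction — for combined n ≤ 12,
and by the tie-corrected, continuity-corrected normal approximation above
that.  One-way ANOVA is followed by all-pairs t comparisons on the pooled
within-group mean square, adjusted by the Holm–Šidák step-down rule
`adj(i) = max_{j≤i} [1 − (1 − p(j))^(m−j+1)]`, capped at 1; adjusted
values never fall below raw values and are invariant to input order.
Fisher's exact test sums hypergeometric probabilities ≤ the observed
table's.  SDs are sample SDs (n − 1).  Stars follow *p<0.05, **p<0.01,
***p<0.001, ****p<0.0001.  An automatic normality gate (choosing t vs
Mann–Whitney) is deliberately off by default — silent test switching harms
reproducibility — and the chosen test is always logged.  Two-factor ANOVA
is out of scope.

## Synthetic data: what it emulates, and what it does not

Top views render the nine triplets as isotropic Gaussian wall elements
(SD 8 nm biological) equally spaced on an ellipse of mean radius 110 nm —
giving a ~220 nm wall-to-wall diameter, a documented geometry default, as
control diameters are not printed in the source tables.  The A/B/C tubules
are not resolved individually; the analysis operates on peak positions,
which this preserves.  The protein shell uses the same geometry offset
Δ toward the lumen.  Lateral views render two parallel wall lines (exact
error-function edges) and a protein band.  Images are blurred with a
Gaussian PSF (FWHM 140 nm expanded-space), scaled to a peak of ~500
expected photons, Poisson sampled, and given Gaussian read noise (SD 3)
over a constant background (10) — plausible high-SNR deconvolved confocal
statistics; the source acquisitions' photon statistics are not published,
so these defaults are calibrated only so that recovery scatter is of the
same order as the published per-measurement SDs.

Presets draw tubulin lengths and protein coverages from truncated normal
distributions with the published means and SDs; per-centriole radial
offsets are drawn with SD = half the published per-measurement scatter,
the remainder arising from photon noise in the measurement itself.
Per-image substreams are spawned deterministically from one master seed,
so batches are bit-reproducible.  Breaks delete the wall elements whose
centers fall inside the break arc; the wall-integrity fixture renders its
breaks on round walls (ellipticity is a separate phenotype with its own
draw) so the flagged fraction isolates the break detector.  The depleted
preset places the residual protein belt at the proximal extremity of the
core (band start at 20 % of the tubulin length) and draws ellipse ratios
uniformly in [0.70, 0.95].

Not emulated: vectorial/depth-dependent PSFs, expansion anisotropy and
local gel distortion, the cartwheel and distal appendages, resolved A/B/C
tubules, centriole pairs/procentrioles in one field, and real antibody
labeling noise (punctate epitope accessibility).  Passing recovery tests
therefore demonstrates that the measurement operators are unbiased on
idealized geometry at realistic SNR — not that they are robust to every
artifact of real specimens.

## Problem sizes and numerical notes

Recovery experiments use 30 images per condition for radial offsets and
coverage, 90 for lengths, and 150 (15 broken) for the integrity fixture —
the sample sizes of the corresponding published measurements.  Degenerate
inputs raise typed exceptions (`EmptyImageError`, `NoMeasurementError`,
`AmbiguousAxisError`, `UnresolvedWallError`, …) rather than returning
NaNs.  Tie-breaks: the tubulin peak is the most prominent radial maximum;
the protein candidate is the highest peak inside the search window; peak
refinement falls back to the discrete maximum at array edges.
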