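# Methods

`tropus` is a simulation and reconstruction toolkit for hybrid ring-array
imaging of fatty liver disease: multispectral optoacoustic tomography
(MSOT), reflection ultrasound computed tomography (RUCT) and transmission
speed-of-sound (SoS) imaging share one circular transducer array
surrounding a 2D cross-section. Because no imaging data are deposited with
the study this package models, every stage is exercised on digital
phantoms whose generating parameters are the published group statistics;
this note describes the models, the defaults and what the synthetic
validation does and does not establish.

## Instrument model

The physical array has 512 elements on a 40 mm radius ring, 5 MHz centre
frequency, 60% fractional bandwidth, sampled at 40 MS/s with 2030 samples
per optoacoustic record. Geometry is ideal: element *k* sits at angle
2πk/N (counter-clockwise, element 0 on +x); element width and kerf are
ignored (the stated 0.37 mm + 0.1 mm pitch does not exactly tile the
circumference, so an idealised uniform ring is used). Receiver subsets
reproduce the published counts exactly: the transmission (SoS) mode uses
the 2·⌊N·θ/2π⌋+1 elements within a 60° half-angle of the point opposite
the emitter (171 of 512), and pulse-echo delay-and-sum uses the
round(N·90/360) contiguous channels centred on the transmitter
(128 of 512, split 63/64 for even counts).

Desk scale. All tests and the acceptance script run a scaled instrument:
128 elements, 20 MS/s sampling (still 2.5× the 8 MHz upper band edge),
1280-sample records (64 µs, so diametric transmissions across the 80 mm
ring at ~53 µs stay in-window), and a 96×96 grid at 0.5 mm pixels. The
corresponding receiver subsets are 43 (opposite arc) and 32 (DAS
aperture). These sizes keep a full study tractable on one CPU core; the
full-scale configuration is available (`full_scale_config`) but is not
exercised by the test suite.

## Digital phantoms and cohorts

A cross-section is: an elliptical body (or a ~20 mm agarose cylinder for
excised-liver sections) with area drawn from the published group
distribution; a smooth liver blob (radius modulated by low-order
harmonics) occupying 15–30% of the body; per-pixel speed of sound (water
1523 m/s at the 34 °C operating temperature, non-liver tissue 1540 m/s
with an optional ±8 m/s smooth heterogeneity field in vivo, agarose
1520 m/s ex vivo, liver drawn from the group normal); chromophore
concentration maps for Hb, HbO2, melanin and lipid; blood vessels as
small high-haemoglobin disks; a pigmented melanin skin rim in vivo; and
acoustic scatterers — a dense reflective skin/agarose interface, a weaker
liver capsule and 200–1000 random sub-resolution interior scatterers.

Group parameters are the published means/STDs: liver SoS 1538±18 /
1475±34 / 1473±26 m/s (in vivo control, 24-week and 36-week disease) and
1525±15 / 1495±12 m/s (ex vivo control / disease); body areas 333±21 /
562±29 / 598±25 mm²; weights 30.7 / 42.3 / 42.9 g (STDs are not
published; a 10% coefficient of variation is assumed); disease liver
lipid contrasts 1.47 (ex vivo), 1.16 and 1.37 (in vivo). The default
study layout is 3 groups × 4 mice × 5 sections = 60 sections. The lipid
contrast scales the liver lipid *excess over the in-body baseline* — the
quantity the background-removed lipid metric measures — so the generated
ground-truth ratios equal the published percent differences even in vivo
where the baseline is non-zero. Everything is deterministic given
(group spec, section index, seed).

Liver area fraction, vessel density and scatterer reflectivities are not
published; the defaults above are package choices.

## Chromophore spectra

The packaged library is a synthetic tabulation on a 1 nm grid
(700–1000 nm): smooth parametric curves shaped after the standard
literature compilations, in relative units. They reproduce the features
the unmixing chain relies on: Hb exceeds HbO2 at 740 nm and decays across
the band (its 757 nm band is rendered as a gentle shoulder), HbO2
dominates beyond the ~800 nm crossing, melanin decays monotonically, and
lipid has its band maximum exactly at 920 nm. The 11-wavelength
(740–940/20 nm) design matrix has full column rank (condition number
~100). A prominent 757 nm Hb peak is deliberately avoided: under the
flat-spectrum fluence model below, it would make *every* Hb-dominated
tissue spectrum rise from 740 to 760 nm, contradicting the
monotonically-decreasing control-liver spectra the pipeline is validated
against. User-supplied spectra can be loaded from CSV
(`wavelength_nm,hb,hbo2,melanin,lipid`).

## Forward models

Both simulators use straight-ray kinematics — travel time is the line
integral of slowness along the path — matching the path model of the
inversions. This is an intentional "inverse crime": it makes analytic
time-of-flight oracles exact and isolates algorithmic errors from model
mismatch. Refraction, full-wave diffraction, acoustic attenuation and 3D
effects are out of scope.

**Optoacoustic.** Initial pressure p0(x, λ) = μa(x, λ)·Φ(x), with μa from
the concentration maps × spectra and Φ the modified-Bessel disc fluence
(below); the Grüneisen coefficient and pulse energy are absorbed into the
arbitrary units. Per-element records are circular-arc projections of p0
(two-segment water/tissue delays), differentiated in time and filtered by
the transducer band; fluence is wavelength-independent (no spectral
colouring — listed as a non-goal). White noise defaults to 1% of the
clean peak per frame; a configurable fraction of repeated frames is
corrupted by a rigid ≥2-pixel shift to exercise motion rejection.

**Pulse-echo/transmission (STA).** The transmit wavelet is a 0.16 µs
single-cycle bipolar square filtered to the array band (zero-phase),
evaluated through a cubic spline so sub-sample delays and the exact
time-derivative (needed by the waveform-inversion gradient) are
consistent to machine precision. For each transmission: the traversing
wave arrives at every receiver after the straight-ray travel time, scaled
by 1/√distance; each scatterer echoes with delay t(tx→s)+t(s→rx) and
two-leg spreading. Noise defaults to 1% of a median-distance transmission
amplitude (the global peak would be the adjacent-element crosstalk, an
unrepresentative reference). Records too short for the slowest
transmission raise an explicit error.

## MSOT reconstruction

Per wavelength: zero-phase 0.1–6 MHz band-pass → motion-frame rejection
(normalized correlation of each repeat's sinogram with the per-pixel
median sinogram; frames below 0.90 are rejected) → averaging of kept
frames → universal back-projection (term 2s − 2t·s′, linear trace
interpolation) with dual-speed delays splitting each pixel–element
segment into its in-water and in-body parts → fluence correction.

The fluence model is a modified-Bessel disc: Φ = I0(μ_eff·ρ)/I0(μ_eff·R)
with R the equal-area disc radius of the body mask and ρ the distance to
its centroid; corrected = image / max(Φ, 0.01); μ_eff defaults to
0.15 mm⁻¹. The same Φ is used by the simulator, so the correction is
model-consistent by construction — its validation shows the pipeline's
internal coherence, not the adequacy of the disc model for real mice.

Two products are kept deliberately separate: the *quantitative stack*
(no contrast enhancement) feeds spectral unmixing, because adaptive
histogram equalization is non-linear and would destroy the spectral
proportionality that linear unmixing assumes; the *display composite*
applies CLAHE (clip limit 0.01) and a Frangi vesselness overlay
(0.1–0.5 mm scales), multiplied by the body mask. Body masks default to
the simulator ground truth (the study segmented manually); an automatic
RUCT-based mask is available.

## Spectral unmixing and the lipid metric

Per in-mask pixel, concentrations solve min‖A·c − s‖² with A the
11×4 spectra matrix; non-negative least squares is the default
(concentrations are physical), the unconstrained solution is retained for
oracle comparisons, and the per-pixel residual norm is stored. The liver
lipid metric is the liver-mean lipid minus the "non-distinct absorption
background", implemented as the median lipid value over the body outside
the liver (the published description is qualitative; the median is this
package's concrete choice), floored at zero. A melanin-saturation QC flag
(configurable quantile/level) mirrors the study's exclusion of two
heavily pigmented animals.

## RUCT reconstruction and body area

Each transmission event is beamformed over its 90° receive aperture with
Hann apodization and linear trace interpolation at the round-trip delay
(uniform water speed). Beamforming operates on the analytic (Hilbert)
signal and each view is envelope-detected: the echo wavelet is bipolar,
so raw-RF values at the exact round-trip delay sit on a zero crossing and
full-ring coherent summation cancels at true scatterer positions.
Compounding sums the per-view envelopes (incoherent across views), then
log-compresses to a 40 dB dynamic range. Contributions whose round-trip
path lies within a wavelet length of the direct tx–rx chord are muted:
the transmitted wave is not an echo and would otherwise paint chords
across the image. On the desk-scale instrument the compounded point
response is ~1.0 mm (−6 dB).

Body segmentation: Otsu threshold → 0.5 mm morphological closing →
largest connected component → hole filling. The threshold is computed on
the linear envelope (Otsu on the log-compressed values is unstable
against the water sidelobe halo), with isolated hot pixels clipped at the
99.5th percentile before the histogram split. Threshold segmentation of
a bright interface systematically overshoots outward by a fraction of
the lateral point-spread width, so quantified areas subtract a calibrated
radial bias times the measured mask perimeter (Crofton estimate). The
bias (~0.7 mm at desk scale) is measured once per instrument
configuration on a few generator phantoms with known masks, drawn with a
fixed internal seed disjoint from any study section; the per-perimeter
bias is a property of the imaging configuration, not of body size, so a
control-geometry calibration transfers across groups. Residual bias on
fresh control sections is ~+4 mm² against a ±9.4 mm² acceptance band.

## Speed-of-sound imaging

1. **References.** For every opposite-arc pair, the water-path reference
   waveform and its analytic travel time d/c_water (the coupling medium is
   homogeneous, so the water acquisition is synthesised exactly).
2. **Time-of-flight picking.** Each measured trace, windowed around the
   water arrival, is decomposed by matching pursuit into scaled,
   time-shifted copies of the reference wavelet (iterative
   cross-correlation peak extraction; at most 5 components; stop when the
   residual energy drops below 5% or a component falls below 20% of the
   first). Sub-sample shifts use an integer-lag parabola followed by a
   quarter-sample re-fit with the wavelet spline — necessary because the
   correlation oscillates at the carrier (~4 samples/period at desk
   scale); picker error is ≤0.02 samples on synthetic shifts. The TOF is
   the *earliest* retained shift, which keeps overlapping multipath
   arrivals from biasing the pick late. Pairs with empty traces or
   arrivals faster than 0.8× the water path are flagged invalid.
3. **Travel-time initialisation.** Damped SIRT sweeps (20 sweeps,
   relaxation 0.7, damping 0.05, 1-pixel Gaussian smoothing per sweep as
   spatial regularisation) solve L·Δslowness = ΔTOF over the valid pairs;
   pixels outside the support mask stay at water; the result is clamped
   to 1300–1700 m/s.
4. **Waveform inversion.** Each pair's window is modelled as the
   reference wavelet averaged over a fan of 7 paths (straight ray plus
   bent rays through control points offset within the first Fresnel-zone
   half-width 0.5·√(λd)); each path's delay is its slowness line
   integral minus a static correction equal to the path's water-path
   excess over the straight ray, so the fan reduces exactly to the
   reference in pure water (without this the bent paths' extra geometric
   length biases the inversion fast by ~0.2%). The loss is the
   mean-squared sample error over valid pairs in windows −1.5/+2.5 µs
   around the water arrival (wide enough to contain the up-to-±1.7 µs
   physical shifts across a large body). Gradient descent uses a
   Barzilai–Borwein step after the first iteration, safeguarded by a
   backtracking line search (up to 8 halvings; only loss-decreasing steps
   are accepted, so the recorded loss history is non-increasing), with
   projection onto the speed bounds and the water-outside-support
   constraint. 40 iterations are the default, as in the study. The
   analytic gradient matches central finite differences to ~1e-7
   relative.

Liver-mask mean errors on held-out phantoms are 2–5 m/s (0.15–0.35%)
against a 1% acceptance band, and the inversion improves on its
travel-time initialisation.

## Group statistics

Per-section metrics (liver mean SoS, lipid metric, area, weight) are
aggregated per group (sample mean, n−1 STD, n) and compared pairwise with
a pooled-variance Student t-test (Welch available by flag; the study
names only an "unpaired t-test"). No multiple-testing correction is
applied, matching the study's raw pairwise p-values. Statistics are per
cross-section (n = 20/group by default); per-mouse aggregation is
available since the study is ambiguous on the unit of analysis. The
study's printed p-values themselves are not reproducible from the
printed means/STDs/n under any standard t-test variant, so p-values are
treated as non-targets; instead a power property is verified: at the
published group parameters, control vs 24-week disease SoS is significant
at p < 0.001 in ≥95% of replicates.

## What the synthetic validation shows — and does not

Passing tests establish that the algorithms are internally correct:
sub-sample TOF picking, exact gradients, exact noiseless unmixing,
sub-pixel localization, and end-to-end recovery of the generating group
parameters through the full chains. Because the simulators share their
kinematic and fluence models with the reconstructions, these results do
not bound errors on real tissue, where refraction, speckle-correlated
scattering, wavelength-dependent fluence and element directivity all
violate the models. The package's claims are therefore about the
published *analysis*, reproduced under its own stated assumptions.

## Numerical choices and degenerate inputs

Tolerances and conventions not covered above: ring positions validated to
1e-9 relative; speed-of-sound images constrained to 1300–1700 m/s;
fluence floored at 0.01; all-zero TOF traces are flagged invalid rather
than raising; an all-rejected motion set raises with advice to lower the
threshold; empty masks and rank-deficient spectra matrices raise named
errors; non-positive sampled body areas are resampled up to 10 times with
a warning. Seeds derive from `numpy.random.SeedSequence` combinations of
(user seed, group seed, section index), so phantoms are bit-reproducible
across platforms.
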