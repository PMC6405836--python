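# Methods

## Measurement model

A trans-illumination scanner excites the specimen from below with a 980 nm
laser and records, from above, one detector frame per raster position. In
hyperspectral (HSI) mode the frame's long axis *a* disperses wavelength
(900–1700 nm over the detector width; 320 physical pixels give 2.5 nm/pixel)
and the short axis *b* collects defocused photons of the same energy, so the
reduction to the HyperSpectral Cube is the exact sum over *b*:
HSC(x, y, λ_a) = Σ_b frames(x, y, a, b). No windowing is applied along *b*;
total counts are conserved. In hyperdiffuse (HDI) mode the frame is a plain
image of the exit surface through a bandpass filter; the HyperDiffuse Cube
stores the mean intensity per radial bin about the beam centre,
HDC(x, y, r). The beam centre is the intensity centroid of the
median-subtracted frame (sub-pixel); bins are uniform and half-open with a
default width of one projected pixel pitch; per-bin *means* (not sums) keep
profiles amplitude-comparable across radii; bins with no pixels (radii
reached only in frame corners) are flagged missing and excluded from fits
rather than zero-filled.

## Spectral features

PCA over per-pixel spectra (mean-centred per wavelength, no variance
scaling, so band amplitude drives the loadings) separates emitter sources;
components below a 1 % explained-variance floor are dropped. For each
retained component, wavelengths with |loading| ≥ 0.5 × the component maximum
form contiguous runs; runs sharing at least one wavelength sample merge into
a band that records the union of its supporting components. Band classes are
fixed intervals around the four recurring families — α [950, 1020) nm
(excitation leakage), β [1020, 1250), γ [1250, 1500), δ [1500, 1700] — and
are configurable.

Per band and pixel, with baseline b(x, y) the median of the spectrum outside
all identified bands (0 if none) and w(λ) = max(I − b, 0) inside the band:

* SI = Σ_λ∈band (I − b), clipped at 0 (counts);
* SP = Σ λ·w / Σ w (nm), flagged missing where Σ w = 0;
* SW = 2√(2 ln 2) × weighted std of λ (Gaussian-equivalent FWHM, nm);
* SI_i/j = SI_i / max(SI_j, ε), ε = 1 count.

The centroid/second-moment definitions of SP and SW were chosen over
argmax/FWHM-crossing alternatives for noise robustness; they reduce to the
same values on symmetric single lines. The Stokes shift used to classify
autofluorescence is 10⁷(1/λ_ex − 1/λ_em) cm⁻¹, with < 2000 cm⁻¹ "small" and
> 2500 cm⁻¹ "large".

## Diffuse features

Each radial profile is fitted by least squares with
I(r) = A·exp(−r²/2σ²) + c over populated bins (≥ 4 required), initialised by
moments (offset = tail median, amplitude = peak excess, width = half-maximum
crossing). Flat profiles and solver failures return `converged = False` and
propagate as missing pixels, never zeros. From a converged fit:

* DI = 2πAσ² — the continuous plane integral of the offset-free Gaussian.
  Using the integral instead of a grid sum makes DI independent of the
  radial binning (pinned by a quadrature-oracle test); the offset c is
  excluded as background.
* SR = σ√(2 ln 2) — the fitted profile's half-width at half-maximum.

PCA over the profile matrix is the homogeneity diagnostic: in a homogeneous
medium profiles vary only in amplitude, so the first component should
dominate (≥ 0.95 observed on simulated homogeneous slabs; exactly-identical
profiles short-circuit to dominance 1 with zero retained components).

## Depth calibration and 3-D placement

There is no closed-form SR→depth law, so depth inversion goes through a
calibration curve: (depth, feature) samples are isotonically regularised
(direction chosen from the overall trend) and interpolated piecewise
linearly. A trailing region where the local slope falls below 5 % of the
initial slope is trimmed from the validity range — the saturation rule:
a plateauing feature (as SR does at large depth in a finite phantom, where
edge effects cap the measurable spread) must not be used for depth. Feature
values beyond the untrimmed range clamp to the nearest endpoint and are
flagged extrapolated; values past a trimmed (saturated) end return no point
estimate. The uncertainty of an inverted depth is the half-width of the
depth interval mapped by ±1 caller-supplied feature-noise standard
deviation.

Probes are localized as 4-connected components above a threshold: by
default the robust median + 5·MAD of the map (suited to compact sources on
flat background); for deeply scattered multi-source scenes, where the blur
FWHM is comparable to the source spacing, a fraction-of-peak threshold is
used instead (0.3 of the map maximum in the bundled letter-phantom analysis
— cross-band leak-through sits around 1 % of peak, well below it, while the
strokes of one glyph stay connected). Detections from several band maps are
merged within an 8 mm radius (half the letter spacing; several times the
raster step), keeping the brightest and unioning provenance.

Fiducial registration is the Kabsch algorithm — SVD of the centred marker
cross-covariance with the determinant correction — giving a proper rigid
transform (no scale, no reflection; fiducials and scanner share metric
units) plus RMSD. Collinear markers are rejected as degenerate. Each probe
is finally placed at the transformed (x, y) with z = Z_surface − depth,
Z_surface by nearest-neighbour lookup in the surface cloud — the
homogeneous-medium assumption that optical depth equals geometric depth.
No motion correction is attempted. Cube inspection uses exact axis sums,
maximum-intensity projections, and an opacity mask at 0.5 of the normalised
intensity (a display convention only).

## Forward simulator

The simulator is the package's synthetic-data source and defines the
conditions under which the pipeline is tested.

**Transport.** Emission from a probe at depth d below the exit surface
reaches the surface with the steady-state diffusion dipole under the
extrapolated-boundary condition (z_b = 2D, D = 1/3(μ_a + μ_s′)), extended to
a finite slab by the infinite image-source series truncated at 10⁻⁸
relative term size. Radiance detected at radius ρ from the source axis:
J(ρ) = Σ_m [z⁺_m(μ_eff + 1/r⁺)e^(−μ_eff r⁺)/4πr⁺² − z⁻_m(...)], with
μ_eff = √(3μ_a(μ_a + μ_s′)). The public profile function takes an optional
slab thickness (semi-infinite without it). An independent Monte-Carlo oracle
— isotropic random walk with exponential step length 1/μ_s′, continuous
absorption weighting e^(−μ_a·path), absorbing faces, exit radii histogrammed
— agrees with the diffusion profile to 2–4 % relative L2 at 10 mm depth in
the phantom preset (10⁵ packets), comfortably within the 10 % consistency
target.

**Excitation** is simplified to Beer–Lambert decay with μ_eff(980 nm) over
the bottom-face-to-probe distance, with a normalized lateral Gaussian about
the scan position whose variance grows by 1 mm² per mm of propagation
(diffusive spread). This is adequate for generating test fixtures — the
detection-side Green's function, not the excitation model, carries the
depth information the pipeline measures. Emitted power scales with cluster
volume (size³) and quantum efficiency; the scene `power` constant folds
laser power, exposure and detector gain into detector counts (default 5·10⁸
counts·mm², chosen so a 1 mm cluster at 20–30 mm depth yields
10³–10⁴-count peaks, typical of a cooled InGaAs camera).

**Spectra.** Probe lines are Gaussians: Er at 1125 nm (relative amplitude
0.5) and 1575 nm (1.0), Ho at 1175 nm, Pr at 1350 nm, widths σ = 12–15 nm.
Autofluorescence is two fixed shapes at 1075 nm (Stokes shift ≈ 900 cm⁻¹ <
2000, "small") and 1345 nm (≈ 2770 cm⁻¹ > 2500, "large"), attenuated from
mid-depth as a crude depth-integrated volumetric source. Residual excitation
leakage is a 980 nm line attenuated through the full slab. Detection applies
Poisson shot noise plus Gaussian read noise (σ = 5 counts) from a single
generator seeded per scene, so identical scenes and seeds are bit-identical.

**Tissue presets** (phantom, brain, fat, skin, muscle, bone) are synthetic:
μ_s′(λ) follows a Mie-like power law scale·(λ/1000 nm)^−1.2 with scales
0.5–1.2 mm⁻¹ ordered so muscle and brain scatter most strongly; μ_a(λ) is
tabulated on 8 knots with a water-like rise beyond 1450 nm and a lipid bump
near 1200 nm for fat (0.004–0.06 mm⁻¹). The magnitudes are
literature-plausible NIR values, not measurements. One consequence worth
stating: with water-like absorption at 1575 nm, the δ-band signal of an Er
probe through the phantom is overtaken by its β-band line near 15 mm depth,
so at the letter-phantom's 20 mm the β band dominates for Er — the
shallow-δ/deep-β ordering holds, with the crossover depth set by the
synthetic absorption table.

**Canned scenes.** The letter phantom places 1 mm clusters tracing "M"
(Er), "I" (Pr) and "T" (Ho) at a common 20 mm depth on a 60 × 24 mm field
with a 2 mm raster — spacing chosen so the glyphs, blurred to roughly
20-mm FWHM at that depth, remain separable per band. The whole-body scene
is a single 0.1 mm Er cluster at mid-depth under a synthetic half-ellipsoid
"animal back" point cloud with four labelled fiducials. The tumour-size
helper is plain volume conservation, D = d_cell·n^(1/3), linking cell
counts to equivalent sphere diameters (125 cells of 20 µm ↔ 0.1 mm).

## Problem sizes and numerical choices

Test and acceptance scenes use a 16 × 16 grid (2 mm pitch) with 64 × 64 HDI
frames at 0.75 mm pitch and 160 spectral pixels; the letter phantom uses a
31 × 13 grid. The Monte-Carlo cross-check launches 10⁵ packets; Gaussian-fit
fidelity uses 100 replicates at peak SNR 20 (amplitude 400 counts under
Poisson statistics). The depth-calibration curve for recovery experiments is
built from {2, 5, 10, 20, 30, 40} mm knots and evaluated at 5–30 mm; its
radial binning deliberately mirrors what `build_hdc` produces from a centred
frame (bins out to the corner half-diagonal) so calibration and measurement
share a fit range — the fitted σ of a non-Gaussian diffusion profile depends
on the radial extent, and a mismatched extent introduces a systematic
depth bias of order 10 %.

Ties and degeneracies: single-sample bands are allowed (loading threshold
1.0); constant cubes and flat profiles retain zero PCA components or return
unconverged fits with warnings, not errors; all-zero HDI frames fall back to
the geometric frame centre with a warning; empty detection lists are valid
results.

## Limitations

The simulator's world is a homogeneous slab with isotropic (reduced)
scattering; it does not emulate heterogeneous or layered tissue, anisotropic
phase functions, spectral reabsorption line-shape distortion, instrument
point-spread functions, stage jitter, or physiological motion. SW/SP depth
trends are present only insofar as the absorption tables impose
wavelength-dependent attenuation, so depth inversion is exercised mainly
through SR. Passing tests therefore demonstrate the correctness and internal
consistency of the processing chain under the stated transport model — not
the absolute optical properties of any real tissue.
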