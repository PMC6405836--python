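# translume

Analysis and simulation toolkit for **trans-illumination NIR-II fluorescence
imaging** of deep-tissue probes. A specimen sitting on a 980 nm laser is
raster-scanned while an InGaAs camera records, from the opposite side, either
the full emission spectrum at each scan position (hyperspectral mode, HSI) or
the 2-D diffuse spread of the transmitted light through a bandpass filter
(hyperdiffuse mode, HDI). Because scattering and water absorption in the
second near-infrared window (1000–1700 nm) are low, probe emission survives
several centimetres of tissue — but it arrives spectrally entangled with
autofluorescence and excitation leakage, and spatially blurred by diffusion.
This package implements the data-processing chain that untangles both, and a
slab-diffusion forward simulator so the whole chain can be developed and
tested without an instrument:

1. **Cube reduction** (`translume.hypercube`) — raw 4-D scans to a
   HyperSpectral Cube HSC(x, y, λ) by summing the detector's defocus axis,
   and to a HyperDiffuse Cube HDC(x, y, r) by radially averaging each frame
   about its beam centre.
2. **Spectral unmixing** (`translume.spectral`) — PCA over per-pixel spectra
   separates emitter sources with no prior knowledge of the background;
   strong-loading wavelength runs become spectral bands, classified into the
   α (~980 nm excitation leakage), β (~1100 nm), γ (~1350 nm) and δ
   (~1600 nm) families. Per band and pixel: Spectral Intensity
   SI = Σ_λ (I − baseline), Spectral Position SP (intensity-weighted centroid,
   nm), Spectral Width SW = 2√(2 ln 2)·σ_λ (Gaussian-equivalent FWHM), plus
   inter-band ratios SI_i/j.
3. **Diffuse analysis** (`translume.diffuse`) — each HDC profile is fitted
   with I(r) = A·exp(−r²/2σ²) + c; Diffuse Intensity DI = 2πAσ² and
   Scattering Radius SR = σ√(2 ln 2) map probe brightness and depth-dependent
   broadening; PCA over profiles gives a one-component homogeneity
   diagnostic.
4. **3-D reconstruction** (`translume.reconstruct3d`) — probes are localized
   as connected components of SI/DI contrast maps; a monotone (isotonic +
   piecewise-linear) calibration of SR (or SW/SP) versus depth is inverted to
   place each probe below the exit surface, with a saturation rule that
   refuses depth estimates from the plateau region of the calibration; rigid
   (Kabsch) fiducial registration ties the imaging frame to a 3-D surface
   scan.
5. **Forward simulation** (`translume.slabsim`) — steady-state diffusion
   dipole/image-series transport through a homogeneous slab, validated
   against a vectorised Monte-Carlo photon random walk; probe line spectra
   (Er 1125/1575 nm, Ho 1175 nm, Pr 1350 nm), small- and large-Stokes-shift
   autofluorescence, excitation leakage, and Poisson + read noise.

A thin `translume` CLI chains the stages
(`simulate | reduce | spectral | diffuse | reconstruct | report`).

## Worked example

Simulate a 1 mm Er-NP cluster 15 mm deep in a 40 mm breast-mimic phantom,
run the hyperdiffuse pipeline on the β band, and invert the scattering
radius for depth:

```python
import numpy as np
from translume import (
    WavelengthCalibration, dispersion_nm_per_pixel, equivalent_tumor_diameter,
    tissue_preset, probe_preset, SlabScene, simulate_hdi_scan, build_hdc,
    scatter_maps, localize_probe, build_depth_calibration, invert_depth,
    sr_depth_series,
)
from translume.slabsim import ProbePlacement
from translume.diffuse import di_map

cal = WavelengthCalibration(320, 900, 1700)
print(f"dispersion: {dispersion_nm_per_pixel(cal):.2f} nm/pixel")
print(f"125 cells of 20 um -> {equivalent_tumor_diameter(125):.3f} mm tumor")

tissue = tissue_preset("phantom", thickness_mm=40.0)
scene = SlabScene(
    tissue=tissue,
    probes=[ProbePlacement(probe_preset("Er-NP"), 14.0, 18.0, depth_mm=15.0)],
    x_mm=np.arange(0.0, 31.0, 2.0), y_mm=np.arange(0.0, 31.0, 2.0), seed=1,
)
hdc = build_hdc(simulate_hdi_scan(scene, (1075.0, 1175.0)))
maps = scatter_maps(hdc)
probe = max(localize_probe(di_map(maps)), key=lambda e: e.total_value)

depths = np.array([2.0, 5.0, 10.0, 20.0, 30.0, 40.0])
calib = build_depth_calibration(depths, sr_depth_series(tissue, 1125.0, depths))
ix = int(np.argmin(np.abs(hdc.x_mm - probe.xy_mm[0])))
iy = int(np.argmin(np.abs(hdc.y_mm - probe.xy_mm[1])))
est = invert_depth(float(maps.sr[ix, iy]), calib)
print(f"probe at ({probe.xy_mm[0]:.1f}, {probe.xy_mm[1]:.1f}) mm, "
      f"SR = {maps.sr[ix, iy]:.2f} mm -> depth {est.depth_mm:.1f} mm (true 15.0)")
```

which prints

```
dispersion: 2.50 nm/pixel
125 cells of 20 um -> 0.100 mm tumor
probe at (14.0, 18.0) mm, SR = 10.75 mm -> depth 15.4 mm (true 15.0)
```

The detector covers 900–1700 nm in 320 pixels (2.5 nm/pixel); a 125-cell
cluster of 20 µm cells is volumetrically equivalent to a 0.1 mm sphere; and
the end-to-end pipeline localizes the probe to the exact grid point and
recovers its depth within 3 % from the diffuse broadening alone.

The same flow from a shell:

```sh
translume simulate  --out-dir run --seed 1 --scene single
translume reduce    --raw run/raw.h5 --out-dir run --config run/config.yaml
translume spectral  --hsc run/hsc.h5 --out-dir run --config run/config.yaml
translume diffuse   --hdc run/hdc_1075-1175nm.h5 --out-dir run --config run/config.yaml
translume reconstruct --run-dir run --out-dir run --config run/config.yaml
translume report    --run-dir run
```

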