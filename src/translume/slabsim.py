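"""Forward simulator: trans-illumination of probes through a homogeneous slab.

The scene model is a homogeneous tissue slab of given thickness, excited by a
980 nm laser from the bottom face, with point-like fluorescent probe clusters
embedded at known (x, y, depth-below-exit-surface).  Light transport uses the
steady-state diffusion approximation:

* excitation fluence at the probe decays as Beer-Lambert with the effective
  attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')), with a Gaussian lateral
  spread about the scan position whose variance grows linearly with the
  propagation distance;
* probe emission propagates from its depth to the exit surface with the
  diffusion-dipole Green's function of an isotropic point source under an
  extrapolated boundary, extended to a slab by the standard infinite
  image-source series (truncated at 1e-8 relative term size).

A vectorised Monte-Carlo random walk (exponential step length 1/mu_s',
continuous absorption weighting exp(-mu_a * path), isotropic scattering — the
reduced-coefficient similarity relation) serves as an independent transport
oracle for the diffusion profile.

Probe emission spectra are sums of Gaussian lines (Er 1125/1575 nm,
Ho 1175 nm, Pr 1350 nm); autofluorescence is modelled as one small-Stokes
(<2000 cm^-1) and one large-Stokes (>2500 cm^-1) spectral shape, and a
residual 980 nm excitation-leakage line is added.  Detection applies Poisson
shot noise plus additive Gaussian read noise from a single seeded generator,
so identical scenes and seeds give bit-identical stacks.

Tissue optical coefficients are synthetic presets with literature-plausible
NIR magnitudes (water-like absorption rising beyond 1450 nm, Mie-like
power-law reduced scattering, muscle and brain scattering most strongly);
they define the simulator's world, not any measured tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .diffuse import fit_gaussian_profile, scattering_radius
from .errors import ConfigurationError, DomainError
from .hypercube import RawHDIStack, RawHSIStack, WavelengthCalibration
from .reconstruct3d import SurfacePointCloud

__all__ = [
    "TissueOpticalModel",
    "ProbeSpectrum",
    "ProbePlacement",
    "Excitation",
    "Autofluorescence",
    "Detector",
    "SlabScene",
    "TISSUE_LABELS",
    "PROBE_NAMES",
    "tissue_preset",
    "probe_preset",
    "effective_attenuation",
    "slab_surface_profile",
    "mc_photon_oracle",
    "mc_diffusion_discrepancy",
    "simulate_hsi_scan",
    "simulate_hdi_scan",
    "sr_depth_series",
    "mit_phantom_scene",
    "mit_letter_boxes",
    "whole_body_scene",
    "equivalent_tumor_diameter",
    "cells_for_diameter",
]


# ---------------------------------------------------------------------------
# Tissue optical presets
# ---------------------------------------------------------------------------

_MUA_KNOTS_NM = np.array([900.0, 980.0, 1100.0, 1200.0, 1300.0, 1450.0, 1575.0, 1700.0])

# absorption tables in mm^-1; water-like rise beyond 1450 nm, lipid bump near
# 1200 nm for fat
_MUA_TABLES = {
    "phantom": [0.004, 0.004, 0.004, 0.005, 0.008, 0.035, 0.025, 0.020],
    "brain": [0.006, 0.006, 0.007, 0.009, 0.012, 0.050, 0.035, 0.030],
    "fat": [0.004, 0.004, 0.005, 0.010, 0.008, 0.030, 0.022, 0.018],
    "skin": [0.008, 0.008, 0.009, 0.011, 0.014, 0.055, 0.040, 0.033],
    "muscle": [0.008, 0.009, 0.010, 0.013, 0.016, 0.060, 0.040, 0.035],
    "bone": [0.005, 0.005, 0.006, 0.007, 0.009, 0.040, 0.028, 0.024],
}

# reduced-scattering amplitude at 1000 nm in mm^-1 (power-law exponent 1.2);
# muscle and brain scatter most strongly
_MUSP_SCALE = {
    "phantom": 0.50,
    "brain": 1.10,
    "fat": 0.90,
    "skin": 1.00,
    "muscle": 1.20,
    "bone": 0.95,
}
_MUSP_POWER = 1.2

TISSUE_LABELS = tuple(_MUA_TABLES)


@dataclass(frozen=True)
class TissueOpticalModel:
    """Homogeneous slab optics: tabulated mu_a(lambda), mu_s'(lambda), thickness."""

    label: str
    wavelength_knots_nm: np.ndarray
    mu_a_knots: np.ndarray
    mu_s_prime_knots: np.ndarray
    thickness_mm: float

    def __post_init__(self):
        object.__setattr__(self, "wavelength_knots_nm",
                           np.asarray(self.wavelength_knots_nm, float))
        object.__setattr__(self, "mu_a_knots", np.asarray(self.mu_a_knots, float))
        object.__setattr__(self, "mu_s_prime_knots",
                           np.asarray(self.mu_s_prime_knots, float))
        if np.any(self.mu_a_knots <= 0) or np.any(self.mu_s_prime_knots <= 0):
            raise DomainError("optical coefficients must be positive")
        wl = self.wavelength_knots_nm
        if wl[0] > 900.0 or wl[-1] < 1700.0:
            raise ConfigurationError("coefficient tables must cover 900-1700 nm")
        if self.thickness_mm <= 0:
            raise ConfigurationError("thickness_mm must be positive")

    def mu_a(self, wavelength_nm):
        return np.interp(wavelength_nm, self.wavelength_knots_nm, self.mu_a_knots)

    def mu_s_prime(self, wavelength_nm):
        return np.interp(
            wavelength_nm, self.wavelength_knots_nm, self.mu_s_prime_knots
        )


def tissue_preset(label: str, thickness_mm: float = 20.0) -> TissueOpticalModel:
    """One of the six built-in tissue presets at the given slab thickness."""
    if label not in _MUA_TABLES:
        raise ConfigurationError(f"unknown tissue label {label!r}; "
                                 f"choose from {TISSUE_LABELS}")
    musp = _MUSP_SCALE[label] * (_MUA_KNOTS_NM / 1000.0) ** (-_MUSP_POWER)
    return TissueOpticalModel(
        label, _MUA_KNOTS_NM, np.array(_MUA_TABLES[label]), musp, thickness_mm
    )


def effective_attenuation(mu_a, mu_s_prime):
    """mu_eff = sqrt(3 mu_a (mu_a + mu_s')), mm^-1."""
    return np.sqrt(3.0 * np.asarray(mu_a) * (np.asarray(mu_a) + np.asarray(mu_s_prime)))


# ---------------------------------------------------------------------------
# Probes, excitation, noise
# ---------------------------------------------------------------------------

# (center nm, sigma nm, relative amplitude); Er emits at both 1125 and 1575
_PROBE_LINES = {
    "Er-1125": ((1125.0, 12.0, 1.0),),
    "Er-1575": ((1575.0, 15.0, 1.0),),
    "Ho-1175": ((1175.0, 12.0, 1.0),),
    "Pr-1350": ((1350.0, 15.0, 1.0),),
    "Er-NP": ((1125.0, 12.0, 0.5), (1575.0, 15.0, 1.0)),
}

PROBE_NAMES = tuple(_PROBE_LINES)


@dataclass(frozen=True)
class ProbeSpectrum:
    """Emission model of one probe species: Gaussian lines, cluster size, QE."""

    name: str
    lines: tuple[tuple[float, float, float], ...]
    size_mm: float = 1.0
    quantum_efficiency: float = 1.0

    def __post_init__(self):
        for center, width, _amp in self.lines:
            if not (900.0 <= center <= 1700.0):
                raise ConfigurationError(
                    f"probe line at {center} nm outside the 900-1700 nm range"
                )
            if width <= 0:
                raise ConfigurationError("line widths must be positive")

    def spectrum(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, float)
        out = np.zeros_like(wl)
        for center, width, amp in self.lines:
            out += amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        return out

    @property
    def volume_factor(self) -> float:
        """Cluster volume relative to a 1 mm cluster (emitted power scales
        with the number of emitters, i.e. with volume)."""
        return self.size_mm**3


def probe_preset(name: str, size_mm: float = 1.0) -> ProbeSpectrum:
    if name not in _PROBE_LINES:
        raise ConfigurationError(f"unknown probe {name!r}; choose from {PROBE_NAMES}")
    return ProbeSpectrum(name, _PROBE_LINES[name], size_mm=size_mm)


@dataclass(frozen=True)
class ProbePlacement:
    spectrum: ProbeSpectrum
    x_mm: float
    y_mm: float
    depth_mm: float  # below the exit (top) surface


@dataclass(frozen=True)
class Excitation:
    """Bottom-face 980 nm laser. ``power`` folds source power, exposure and
    detector gain into effective detector counts per unit Green's function."""

    wavelength_nm: float = 980.0
    spot_sigma_mm: float = 1.75
    power: float = 5e8
    leak_fraction: float = 1e-4


@dataclass(frozen=True)
class Autofluorescence:
    """Two fixed tissue-emission shapes: a small-Stokes-shift component
    (980 -> 1075 nm is ~900 cm^-1) and a large-Stokes-shift component
    (980 -> 1345 nm is ~2770 cm^-1).  Amplitudes are surface counts per
    spectral pixel before depth attenuation."""

    small_amplitude: float = 500.0
    small_center_nm: float = 1075.0
    small_sigma_nm: float = 45.0
    large_amplitude: float = 300.0
    large_center_nm: float = 1345.0
    large_sigma_nm: float = 60.0

    def spectrum(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, float)
        return self.small_amplitude * np.exp(
            -((wl - self.small_center_nm) ** 2) / (2.0 * self.small_sigma_nm**2)
        ) + self.large_amplitude * np.exp(
            -((wl - self.large_center_nm) ** 2) / (2.0 * self.large_sigma_nm**2)
        )


@dataclass(frozen=True)
class Detector:
    """InGaAs-like detector model for both configurations."""

    n_spectral_pixels: int = 160
    lambda_min_nm: float = 900.0
    lambda_max_nm: float = 1700.0
    n_defocus_pixels: int = 16
    defocus_sigma_px: float = 2.5
    hdi_shape: tuple[int, int] = (64, 64)
    pixel_pitch_mm: float = 0.75
    read_noise_sigma: float = 5.0
    poisson: bool = True

    def calibration(self) -> WavelengthCalibration:
        return WavelengthCalibration(
            self.n_spectral_pixels, self.lambda_min_nm, self.lambda_max_nm
        )


@dataclass
class SlabScene:
    """Complete simulator world: tissue, probes, illumination, scan geometry,
    noise model and the seed that makes a scene reproducible."""

    tissue: TissueOpticalModel
    probes: list[ProbePlacement]
    x_mm: np.ndarray
    y_mm: np.ndarray
    excitation: Excitation = field(default_factory=Excitation)
    autofluorescence: Autofluorescence = field(default_factory=Autofluorescence)
    detector: Detector = field(default_factory=Detector)
    seed: int = 0

    def __post_init__(self):
        self.x_mm = np.asarray(self.x_mm, float)
        self.y_mm = np.asarray(self.y_mm, float)
        for p in self.probes:
            if not (0.0 < p.depth_mm < self.tissue.thickness_mm):
                raise ConfigurationError(
                    f"probe depth {p.depth_mm} mm outside the slab "
                    f"(0, {self.tissue.thickness_mm}) mm"
                )


# ---------------------------------------------------------------------------
# Diffusion Green's function at the exit surface
# ---------------------------------------------------------------------------


def slab_surface_profile(
    depth_mm: float,
    mu_a,
    mu_s_prime,
    radius_grid,
    thickness_mm: float | None = None,
    rel_tol: float = 1e-8,
    max_terms: int = 500,
) -> np.ndarray:
    """Radial fluence-exit profile at the top surface for a point source.

    Steady-state diffusion dipole for an isotropic point source at
    ``depth_mm`` below the exit surface, with the extrapolated-boundary
    condition (z_b = 2D).  With ``thickness_mm`` the bottom boundary is
    included through the infinite image-source series, truncated when the
    largest new term falls below ``rel_tol`` of the accumulated profile;
    without it the medium is semi-infinite (the m = 0 source/image pair).
    Normalised to unit source power.

    ``mu_a`` / ``mu_s_prime`` may be arrays (e.g. per wavelength); the output
    shape is ``mu_shape + radius_shape``.  A warning is attached outside the
    diffusive validity regime (mu_s' not >> mu_a, or source shallower than
    three transport mean free paths).
    """
    mu_a = np.asarray(mu_a, float)
    mu_sp = np.asarray(mu_s_prime, float)
    if np.any(mu_a <= 0) or np.any(mu_sp <= 0):
        raise DomainError("optical coefficients must be positive")
    if depth_mm <= 0:
        raise DomainError("source depth must be positive")
    if np.any(mu_sp < 10.0 * mu_a) or depth_mm < 3.0 / float(np.min(mu_sp)):
        warnings.warn(
            "outside the diffusive validity regime (needs mu_s' >> mu_a and "
            "depth >= 3 transport mean free paths); profile is approximate",
            stacklevel=2,
        )
    mu_a, mu_sp = np.broadcast_arrays(mu_a, mu_sp)
    mu_shape = mu_a.shape
    r = np.asarray(radius_grid, float)
    r_shape = r.shape
    mu_a = mu_a.reshape(-1, 1)
    mu_sp = mu_sp.reshape(-1, 1)
    r = r.reshape(1, -1)

    d_coef = 1.0 / (3.0 * (mu_a + mu_sp))
    zb = 2.0 * d_coef
    mueff = np.sqrt(3.0 * mu_a * (mu_a + mu_sp))

    def term(z_plane):
        rho = np.sqrt(r**2 + z_plane**2)
        return z_plane * (mueff + 1.0 / rho) * np.exp(-mueff * rho) / (
            4.0 * np.pi * rho**2
        )

    # m = 0 dipole pair: source at +d, negative image at -(d + 2 zb)
    total = term(depth_mm) - term(-(depth_mm + 2.0 * zb))
    if thickness_mm is not None:
        period = 2.0 * (thickness_mm + 2.0 * np.max(zb))
        for m in range(1, max_terms + 1):
            added = np.zeros_like(total)
            for sgn in (+1.0, -1.0):
                shift = sgn * m * 2.0 * (thickness_mm + 2.0 * zb)
                added += term(depth_mm + shift) - term(-(depth_mm + 2.0 * zb) + shift)
            total += added
            if np.max(np.abs(added)) < rel_tol * max(np.max(np.abs(total)), 1e-300):
                break
        del period
    return np.clip(total, 0.0, None).reshape(mu_shape + r_shape)


# ---------------------------------------------------------------------------
# Monte-Carlo transport oracle
# ---------------------------------------------------------------------------


@dataclass
class McExitProfile:
    """Radial histogram of photon weight exiting the top face."""

    radius_mm: np.ndarray  # bin centres
    weight: np.ndarray  # exited weight per bin (within range)
    counts: np.ndarray  # exited packets per bin
    total_top_weight: float
    total_bottom_weight: float
    n_launched: int
    bin_width_mm: float

    @property
    def profile_per_area(self) -> np.ndarray:
        """Exit weight per unit surface area per launched photon."""
        edges = np.arange(self.radius_mm.size + 1) * self.bin_width_mm
        area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        return self.weight / area / self.n_launched


def mc_photon_oracle(
    depth_mm: float,
    mu_a: float,
    mu_s_prime: float,
    n_photons: int = 100_000,
    seed: int = 0,
    thickness_mm: float | None = None,
    bin_width_mm: float = 1.0,
    n_bins: int = 60,
    weight_cutoff: float = 1e-7,
) -> McExitProfile:
    """Isotropic random-walk photon packets from a point source in the slab.

    Step lengths are exponential with mean 1/mu_s', scattering is isotropic
    (the reduced-coefficient similarity relation) and absorption is the
    continuous survival weight exp(-mu_a * path).  Both faces are absorbing:
    packets are tallied where their trajectory first crosses z = 0 (top,
    histogrammed by exit radius) or z = thickness (bottom).  Deterministic
    for a fixed seed.
    """
    if mu_a < 0 or mu_s_prime <= 0:
        raise DomainError("mu_a must be >= 0 and mu_s_prime > 0")
    n = int(n_photons)
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[:, 2] = depth_mm
    path = np.zeros(n)
    # generous cap: survival weight below cutoff ends a packet anyway
    if mu_a > 0:
        path_cutoff = -np.log(weight_cutoff) / mu_a
    else:
        path_cutoff = np.inf
    max_steps = 500_000

    radii: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    bottom_weight = 0.0
    lost_weight = 0.0
    steps = 0
    while pos.shape[0] and steps < max_steps:
        steps += 1
        m = pos.shape[0]
        cos_t = rng.uniform(-1.0, 1.0, m)
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        sin_t = np.sqrt(1.0 - cos_t**2)
        step = rng.exponential(1.0 / mu_s_prime, m)
        delta = np.column_stack(
            (sin_t * np.cos(phi) * step, sin_t * np.sin(phi) * step, cos_t * step)
        )
        new = pos + delta
        z0, z1 = pos[:, 2], new[:, 2]

        t_top = np.where(z1 < 0.0, z0 / np.maximum(z0 - z1, 1e-300), np.inf)
        if thickness_mm is not None:
            t_bot = np.where(
                z1 > thickness_mm,
                (thickness_mm - z0) / np.maximum(z1 - z0, 1e-300),
                np.inf,
            )
        else:
            t_bot = np.full(m, np.inf)

        exit_top = t_top <= t_bot
        exit_top &= np.isfinite(t_top)
        exit_bot = (t_bot < t_top) & np.isfinite(t_bot)

        if exit_top.any():
            t = t_top[exit_top]
            exit_path = path[exit_top] + t * step[exit_top]
            w = np.exp(-mu_a * exit_path)
            ex = pos[exit_top, 0] + delta[exit_top, 0] * t
            ey = pos[exit_top, 1] + delta[exit_top, 1] * t
            radii.append(np.hypot(ex, ey))
            weights.append(w)
        if exit_bot.any():
            t = t_bot[exit_bot]
            bottom_weight += float(
                np.exp(-mu_a * (path[exit_bot] + t * step[exit_bot])).sum()
            )

        alive = ~(exit_top | exit_bot)
        pos = new[alive]
        path = path[alive] + step[alive]
        absorbed = path > path_cutoff
        if absorbed.any():
            alive2 = ~absorbed
            pos = pos[alive2]
            path = path[alive2]
    if pos.shape[0]:
        lost_weight = float(np.exp(-mu_a * path).sum())
        warnings.warn(f"{pos.shape[0]} packets hit the step cap "
                      f"(weight {lost_weight:.3g})", stacklevel=2)

    all_r = np.concatenate(radii) if radii else np.zeros(0)
    all_w = np.concatenate(weights) if weights else np.zeros(0)
    edges = np.arange(n_bins + 1) * bin_width_mm
    hist_w, _ = np.histogram(all_r, bins=edges, weights=all_w)
    hist_n, _ = np.histogram(all_r, bins=edges)
    return McExitProfile(
        radius_mm=0.5 * (edges[:-1] + edges[1:]),
        weight=hist_w,
        counts=hist_n,
        total_top_weight=float(all_w.sum()),
        total_bottom_weight=bottom_weight,
        n_launched=n,
        bin_width_mm=bin_width_mm,
    )


def mc_diffusion_discrepancy(
    depth_mm: float = 10.0,
    tissue: TissueOpticalModel | None = None,
    wavelength_nm: float = 1125.0,
    n_photons: int = 100_000,
    seed: int = 0,
    min_counts: int = 20,
) -> tuple[float, int]:
    """Relative L2 difference between normalised MC and diffusion profiles.

    Both profiles are evaluated on the MC radial bins (restricted to bins
    with at least ``min_counts`` exited packets for statistical stability)
    and normalised to unit L2 norm before comparison.  Returns
    ``(relative_l2, n_photons)``.
    """
    tissue = tissue or tissue_preset("phantom")
    mu_a = float(tissue.mu_a(wavelength_nm))
    mu_sp = float(tissue.mu_s_prime(wavelength_nm))
    mc = mc_photon_oracle(depth_mm, mu_a, mu_sp, n_photons=n_photons, seed=seed)
    good = mc.counts >= min_counts
    r = mc.radius_mm[good]
    p_mc = mc.profile_per_area[good]
    p_diff = slab_surface_profile(depth_mm, mu_a, mu_sp, r)
    p_mc = p_mc / np.linalg.norm(p_mc)
    p_diff = p_diff / np.linalg.norm(p_diff)
    return float(np.linalg.norm(p_mc - p_diff) / np.linalg.norm(p_diff)), n_photons


# ---------------------------------------------------------------------------
# Scan synthesis
# ---------------------------------------------------------------------------


def _excitation_at_probes(scene: SlabScene, xx, yy):
    """Excitation fluence factor per probe at every grid point.

    Beer-Lambert decay with mu_eff(980) over the bottom-face-to-probe
    distance, times a normalized lateral Gaussian about the scan position
    whose variance grows by 1 mm^2 per mm of propagation (diffusive spread).
    """
    tis = scene.tissue
    exc = scene.excitation
    mueff = float(
        effective_attenuation(tis.mu_a(exc.wavelength_nm), tis.mu_s_prime(exc.wavelength_nm))
    )
    factors = []
    for p in scene.probes:
        climb = tis.thickness_mm - p.depth_mm  # bottom face -> probe
        sigma2 = exc.spot_sigma_mm**2 + climb
        rho2 = (xx - p.x_mm) ** 2 + (yy - p.y_mm) ** 2
        factors.append(
            exc.power * np.exp(-mueff * climb) * np.exp(-rho2 / (2.0 * sigma2))
        )
    return factors


def _leak_level(scene: SlabScene) -> float:
    tis = scene.tissue
    exc = scene.excitation
    mueff = float(
        effective_attenuation(tis.mu_a(exc.wavelength_nm), tis.mu_s_prime(exc.wavelength_nm))
    )
    return exc.power * exc.leak_fraction * np.exp(-mueff * tis.thickness_mm)


def _af_spectrum(scene: SlabScene, wl: np.ndarray) -> np.ndarray:
    """Autofluorescence surface spectrum: fixed shapes attenuated from
    mid-depth (a crude depth-integrated volumetric source)."""
    tis = scene.tissue
    mueff = effective_attenuation(tis.mu_a(wl), tis.mu_s_prime(wl))
    return scene.autofluorescence.spectrum(wl) * np.exp(
        -mueff * tis.thickness_mm / 2.0
    )


def _apply_noise(frames: np.ndarray, det: Detector, rng) -> np.ndarray:
    out = frames
    if det.poisson:
        out = rng.poisson(out).astype(float)
    if det.read_noise_sigma > 0:
        out = out + rng.normal(0.0, det.read_noise_sigma, out.shape)
    return np.clip(out, 0.0, None)


def simulate_hsi_scan(scene: SlabScene) -> RawHSIStack:
    """Render a raw hyperspectral raster scan of the scene.

    Per grid point the surface spectrum collects: each probe's emission
    (excitation fluence x quantum efficiency x cluster volume x line
    spectrum, propagated by the slab Green's function at each wavelength),
    the two autofluorescence shapes, and residual excitation leakage.  The
    spectrum goes on detector axis ``a`` with a fixed Gaussian defocus spread
    on axis ``b``; Poisson and read noise are seeded by the scene.
    """
    det = scene.detector
    wl = det.calibration().wavelength_axis()
    tis = scene.tissue
    nx, ny = scene.x_mm.size, scene.y_mm.size
    xx, yy = np.meshgrid(scene.x_mm, scene.y_mm, indexing="ij")
    spec = np.zeros((nx, ny, wl.size))

    mu_a = tis.mu_a(wl)
    mu_sp = tis.mu_s_prime(wl)
    exc_factors = _excitation_at_probes(scene, xx, yy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # validity warnings handled at scene level
        for p, exc in zip(scene.probes, exc_factors):
            rho = np.hypot(xx - p.x_mm, yy - p.y_mm).ravel()
            green = slab_surface_profile(
                p.depth_mm, mu_a, mu_sp, rho, thickness_mm=tis.thickness_mm
            )  # (n_wl, n_grid)
            amp = exc * p.spectrum.quantum_efficiency * p.spectrum.volume_factor
            s = p.spectrum.spectrum(wl)
            spec += amp[:, :, None] * (green.T.reshape(nx, ny, wl.size) * s)

    spec += _af_spectrum(scene, wl)[None, None, :]
    leak_line = np.exp(
        -((wl - scene.excitation.wavelength_nm) ** 2) / (2.0 * 4.0**2)
    )
    spec += _leak_level(scene) * leak_line[None, None, :]

    b = np.arange(det.n_defocus_pixels)
    g_b = np.exp(
        -((b - (det.n_defocus_pixels - 1) / 2.0) ** 2) / (2.0 * det.defocus_sigma_px**2)
    )
    g_b /= g_b.sum()
    frames = spec[:, :, :, None] * g_b[None, None, None, :]
    rng = np.random.default_rng(scene.seed)
    frames = _apply_noise(frames, det, rng)
    return RawHSIStack(frames, scene.x_mm, scene.y_mm, wl)


def _band_interval(band) -> tuple[float, float, str]:
    if hasattr(band, "lambda_lo_nm"):
        return float(band.lambda_lo_nm), float(band.lambda_hi_nm), band.name
    lo, hi = float(band[0]), float(band[1])
    return lo, hi, f"{lo:.0f}-{hi:.0f}nm"


def simulate_hdi_scan(scene: SlabScene, band) -> RawHDIStack:
    """Render a raw hyperdiffuse raster scan through one bandpass filter.

    ``band`` is a (lo, hi) wavelength pair in nm or a SpectralBand.  Each
    frame images the surface region centred on the scan position; every
    probe contributes its in-band emission spread by the slab Green's
    function evaluated at the band's intensity-weighted wavelength (narrow-
    filter approximation).  In-band autofluorescence is a flat background;
    residual 980 nm leakage (if in band) appears as a broad spot at the scan
    position.  Noise is seeded by the scene (offset so HSI and HDI stacks of
    the same scene are independent).
    """
    lo, hi, label = _band_interval(band)
    det = scene.detector
    tis = scene.tissue
    wl = det.calibration().wavelength_axis()
    in_band = (wl >= lo) & (wl <= hi)
    if not in_band.any():
        raise ConfigurationError(f"filter band [{lo}, {hi}] nm outside detector range")
    nx, ny = scene.x_mm.size, scene.y_mm.size
    nu, nv = det.hdi_shape
    off_u = (np.arange(nu) - (nu - 1) / 2.0) * det.pixel_pitch_mm
    off_v = (np.arange(nv) - (nv - 1) / 2.0) * det.pixel_pitch_mm
    xx, yy = np.meshgrid(scene.x_mm, scene.y_mm, indexing="ij")
    frames = np.zeros((nx, ny, nu, nv))

    r_fine = np.linspace(0.0, np.hypot(
        np.ptp(scene.x_mm) if nx > 1 else 0.0, np.ptp(scene.y_mm) if ny > 1 else 0.0
    ) + np.hypot(off_u.max(), off_v.max()) + det.pixel_pitch_mm, 600)
    exc_factors = _excitation_at_probes(scene, xx, yy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p, exc in zip(scene.probes, exc_factors):
            s = p.spectrum.spectrum(wl[in_band])
            power_band = float(s.sum())
            if power_band <= 0:
                continue
            lam_eff = float((wl[in_band] * s).sum() / s.sum())
            green = slab_surface_profile(
                p.depth_mm,
                float(tis.mu_a(lam_eff)),
                float(tis.mu_s_prime(lam_eff)),
                r_fine,
                thickness_mm=tis.thickness_mm,
            )
            du = scene.x_mm[:, None] + off_u[None, :] - p.x_mm  # (nx, nu)
            dv = scene.y_mm[:, None] + off_v[None, :] - p.y_mm  # (ny, nv)
            dist = np.sqrt(
                du[:, None, :, None] ** 2 + dv[None, :, None, :] ** 2
            )
            blob = np.interp(dist, r_fine, green)
            amp = exc * p.spectrum.quantum_efficiency * p.spectrum.volume_factor
            frames += amp[:, :, None, None] * power_band * blob

    frames += float(_af_spectrum(scene, wl)[in_band].sum())
    if lo <= scene.excitation.wavelength_nm <= hi:
        sigma2 = scene.excitation.spot_sigma_mm**2 + tis.thickness_mm
        spot = np.exp(-(off_u[:, None] ** 2 + off_v[None, :] ** 2) / (2.0 * sigma2))
        frames += _leak_level(scene) * spot[None, None, :, :]

    rng = np.random.default_rng(scene.seed + int(lo))
    frames = _apply_noise(frames, det, rng)
    return RawHDIStack(frames, label, det.pixel_pitch_mm, scene.x_mm, scene.y_mm)


def sr_depth_series(
    tissue: TissueOpticalModel,
    wavelength_nm: float,
    depths_mm,
    radius_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Scattering radius versus source depth for one tissue and wavelength.

    Generates the noiseless exit profile at each depth on the HDI radial
    binning and fits it exactly as the measurement pipeline does, so the
    resulting curve is directly usable as a depth calibration.
    """
    if radius_mm is None:
        # mirror the radial binning build_hdc derives from a centred HDI
        # frame (bins out to the corner half-diagonal), so calibration and
        # measurement share the same fit range
        det = Detector()
        half_diag_px = np.hypot(det.hdi_shape[0] - 1, det.hdi_shape[1] - 1) / 2.0
        nb = int(np.floor(half_diag_px)) + 1  # bin width = one pixel pitch
        radius_mm = (np.arange(nb) + 0.5) * det.pixel_pitch_mm
    mu_a = float(tissue.mu_a(wavelength_nm))
    mu_sp = float(tissue.mu_s_prime(wavelength_nm))
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in np.asarray(depths_mm, float):
            prof = slab_surface_profile(
                d, mu_a, mu_sp, radius_mm, thickness_mm=tissue.thickness_mm
            )
            fit = fit_gaussian_profile(radius_mm, prof)
            out.append(scattering_radius(fit))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Canned scenes
# ---------------------------------------------------------------------------

_MIT_BOXES = {
    "M": (2.0, 18.0, 4.0, 20.0),
    "I": (26.0, 34.0, 4.0, 20.0),
    "T": (42.0, 58.0, 4.0, 20.0),
}


def mit_letter_boxes() -> dict[str, tuple[float, float, float, float]]:
    """Bounding boxes (x_lo, x_hi, y_lo, y_hi) in mm of the three letters."""
    return dict(_MIT_BOXES)


def _letter_points() -> dict[str, list[tuple[float, float]]]:
    m_pts = [(4.0, y) for y in np.arange(6.0, 19.0, 2.0)]
    m_pts += [(16.0, y) for y in np.arange(6.0, 19.0, 2.0)]
    m_pts += [(7.0, 15.0), (10.0, 12.0), (13.0, 15.0)]
    i_pts = [(30.0, y) for y in np.arange(6.0, 19.0, 2.0)]
    t_pts = [(x, 18.0) for x in np.arange(44.0, 57.0, 2.0)]
    t_pts += [(50.0, y) for y in np.arange(6.0, 17.0, 2.0)]
    return {"M": m_pts, "I": i_pts, "T": t_pts}


def mit_phantom_scene(depth_mm: float = 20.0, seed: int = 7) -> SlabScene:
    """Three-probe letter phantom: 'M' of Er-NP, 'I' of Pr-NP, 'T' of Ho-NP,
    all at one fixed depth in the breast-mimic phantom preset.

    Each letter is a set of 1 mm probe clusters tracing the glyph on the
    raster grid (2 mm pitch, 60 x 24 mm field).
    """
    tissue = tissue_preset("phantom", thickness_mm=depth_mm + 2.0)
    species = {"M": "Er-NP", "I": "Pr-1350", "T": "Ho-1175"}
    probes = [
        ProbePlacement(probe_preset(species[letter]), x, y, depth_mm)
        for letter, pts in _letter_points().items()
        for (x, y) in pts
    ]
    return SlabScene(
        tissue=tissue,
        probes=probes,
        x_mm=np.arange(0.0, 61.0, 2.0),
        y_mm=np.arange(0.0, 25.0, 2.0),
        seed=seed,
    )


def whole_body_scene(
    thickness_mm: float = 20.0,
    probe_size_mm: float = 0.1,
    seed: int = 11,
) -> tuple[SlabScene, SurfacePointCloud]:
    """Single small Er-NP cluster at mid-depth under a synthetic animal back.

    Returns the scene and a matching synthetic surface point cloud (upper
    half-ellipsoid 'body') carrying 4 labelled fiducial markers.
    """
    tissue = tissue_preset("phantom", thickness_mm=thickness_mm)
    cx = cy = 16.0
    probe = ProbePlacement(
        probe_preset("Er-NP", size_mm=probe_size_mm), cx + 3.0, cy - 2.0,
        thickness_mm / 2.0,
    )
    scene = SlabScene(
        tissue=tissue,
        probes=[probe],
        x_mm=np.arange(0.0, 33.0, 2.0),
        y_mm=np.arange(0.0, 33.0, 2.0),
        seed=seed,
    )

    gx, gy = np.meshgrid(np.arange(0.0, 33.0, 1.0), np.arange(0.0, 33.0, 1.0),
                         indexing="ij")
    bulge = 1.0 - ((gx - cx) / 24.0) ** 2 - ((gy - cy) / 24.0) ** 2
    gz = thickness_mm * np.sqrt(np.clip(bulge, 0.0, None))
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def z_at(x, y):
        b = 1.0 - ((x - cx) / 24.0) ** 2 - ((y - cy) / 24.0) ** 2
        return thickness_mm * np.sqrt(max(b, 0.0))

    fiducials = {
        name: np.array([x, y, z_at(x, y)])
        for name, (x, y) in {
            "F1": (6.0, 16.0), "F2": (26.0, 16.0), "F3": (16.0, 6.0),
            "F4": (16.0, 26.0),
        }.items()
    }
    return scene, SurfacePointCloud(points, fiducials)


# ---------------------------------------------------------------------------
# Cell-count <-> tumor-size arithmetic
# ---------------------------------------------------------------------------


def equivalent_tumor_diameter(n_cells: float, cell_diameter_um: float = 20.0) -> float:
    """Volume-conserving spherical diameter (mm) of a cluster of cells.

    D = d_cell * n^(1/3): e.g. 125 cells of 20 um pack a 0.1 mm sphere.
    """
    if n_cells <= 0 or cell_diameter_um <= 0:
        raise DomainError("cell count and diameter must be positive")
    return cell_diameter_um / 1000.0 * float(n_cells) ** (1.0 / 3.0)


def cells_for_diameter(diameter_mm: float, cell_diameter_um: float = 20.0) -> int:
    """Inverse of :func:`equivalent_tumor_diameter`, rounded to nearest cell."""
    if diameter_mm <= 0 or cell_diameter_um <= 0:
        raise DomainError("diameters must be positive")
    return int(round((diameter_mm * 1000.0 / cell_diameter_um) ** 3))
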