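"""Diffuse-profile analysis of HyperDiffuse Cubes.

Each radial profile of an HDC is fitted with a symmetric Gaussian
``I(r) = A exp(-r^2 / (2 sigma^2)) + c`` by least squares.  Two per-pixel
scattering features summarise the fit:

* DI (Diffuse Intensity)   -- area of the fitted, offset-free Gaussian over
  the plane, 2*pi*A*sigma^2 (counts*mm^2).  Using the continuous integral
  rather than a grid sum makes DI independent of the radial binning.
* SR (Scattering Radius)   -- half-width at half-maximum of the fitted
  Gaussian, sigma*sqrt(2 ln 2) (mm).

PCA over the profiles is a homogeneity diagnostic: a homogeneous slab varies
only in amplitude across the grid, so a single principal component should
dominate the profile matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DomainError
from .hypercube import HyperDiffuseCube
from .spectral import FeatureMap, PCAResult, pca_matrix

HWHM_PER_SIGMA = float(np.sqrt(2.0 * np.log(2.0)))

__all__ = [
    "DiffuseFit",
    "ScatterMaps",
    "fit_gaussian_profile",
    "scattering_radius",
    "diffuse_intensity",
    "pca_profiles",
    "scatter_maps",
    "di_map",
    "sr_map",
    "fit_table_to_csv",
]


@dataclass
class DiffuseFit:
    """Symmetric-Gaussian fit of one radial diffuse profile.

    ``converged`` is False when the solver failed or the solution is
    degenerate (vanishing amplitude, or a width far beyond the sampled radii,
    as happens for a constant profile); callers must not use ``sigma_mm`` of
    an unconverged fit.
    """

    amplitude: float
    sigma_mm: float
    offset: float
    residual_rms: float
    converged: bool


def _gauss(r, a, sigma, c):
    return a * np.exp(-(r**2) / (2.0 * sigma**2)) + c


def fit_gaussian_profile(
    radius_mm: np.ndarray,
    profile: np.ndarray,
    bin_counts: np.ndarray | None = None,
) -> DiffuseFit:
    """Least-squares Gaussian fit of a radial profile over populated bins.

    Initialisation is by moments: the offset from the tail median, the
    amplitude from the innermost excess over it, and the width from the
    half-maximum crossing radius.  Requires at least 4 populated bins.
    Non-convergence is reported through the ``converged`` flag, never as an
    exception.
    """
    r = np.asarray(radius_mm, float)
    y = np.asarray(profile, float)
    valid = np.isfinite(y) & np.isfinite(r)
    if bin_counts is not None:
        valid &= np.asarray(bin_counts) > 0
    if int(valid.sum()) < 4:
        raise DomainError("Gaussian fit needs at least 4 populated bins")
    r, y = r[valid], y[valid]
    order = np.argsort(r)
    r, y = r[order], y[order]
    span = max(r[-1] - r[0], r[-1], 1e-9)
    if np.ptp(y) <= 1e-12 * max(float(np.abs(y).max()), 1.0):
        # flat (e.g. all-zero) profile: no width information
        return DiffuseFit(0.0, np.nan, float(y.mean()), 0.0, converged=False)

    tail = y[r >= r[0] + 0.75 * (r[-1] - r[0])]
    c0 = float(np.median(tail)) if tail.size else float(y[-1])
    a0 = max(float(y.max()) - c0, 1e-12)
    below = np.flatnonzero(y <= c0 + 0.5 * a0)
    r_half = float(r[below[0]]) if below.size else 0.5 * span
    s0 = float(np.clip(r_half / HWHM_PER_SIGMA, 1e-3 * span, 10.0 * span))

    try:
        popt, _ = curve_fit(
            _gauss,
            r,
            y,
            p0=[a0, s0, c0],
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, s, c = (float(v) for v in popt)
        solver_ok = True
    except (RuntimeError, ValueError):
        a, s, c = a0, s0, c0
        solver_ok = False
    rms = float(np.sqrt(np.mean((_gauss(r, a, s, c) - y) ** 2)))
    scale = max(float(np.abs(y).max()), 1e-12)
    degenerate = (a <= 1e-9 * scale) or (s > 10.0 * span) or not np.isfinite(a + s + c)
    return DiffuseFit(a, s, c, rms, converged=solver_ok and not degenerate)


def scattering_radius(fit: DiffuseFit) -> float:
    """SR: half-width at half-maximum of the fitted Gaussian, sigma*sqrt(2 ln 2)."""
    if not fit.converged:
        raise DomainError("scattering radius of an unconverged fit is undefined")
    return fit.sigma_mm * HWHM_PER_SIGMA


def diffuse_intensity(fit: DiffuseFit) -> float:
    """DI: plane integral of the fitted offset-free Gaussian, 2*pi*A*sigma^2.

    The background offset is excluded: it is ambient/readout level, not probe
    signal.
    """
    if not fit.converged:
        raise DomainError("diffuse intensity of an unconverged fit is undefined")
    return float(2.0 * np.pi * fit.amplitude * fit.sigma_mm**2)


def pca_profiles(
    hdc: HyperDiffuseCube, variance_floor: float = 0.01
) -> tuple[PCAResult, float]:
    """PCA over the grid of radial profiles, plus the PC-1 dominance fraction.

    Radius bins that are missing in any frame are excluded.  The dominance
    fraction (explained variance of the first retained component; 1.0 when
    the profiles are identical) is the homogeneity diagnostic: for a
    homogeneous medium there should be a single main principal component.
    """
    nx, ny, nr = hdc.profile.shape
    if nx * ny < 2:
        raise ConfigurationError("profile PCA needs at least 2 grid points")
    X = hdc.profile.reshape(nx * ny, nr)
    cols = np.all(np.isfinite(X), axis=0)
    res = pca_matrix(X[:, cols], variance_floor)
    if res.n_components == 0:
        return res, 1.0
    return res, float(res.explained_variance_fraction[0])


@dataclass
class ScatterMaps:
    """Per-pixel DI / SR maps with fit diagnostics.

    Unconverged or unfittable pixels are NaN in every map; ``fit_table``
    lists the raw per-pixel fit parameters.
    """

    di: np.ndarray
    sr: np.ndarray
    fit_quality: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    band_label: str
    fit_table: pd.DataFrame


def scatter_maps(hdc: HyperDiffuseCube) -> ScatterMaps:
    """Fit every grid point's profile and assemble DI, SR and quality maps.

    ``fit_quality`` is the fit residual RMS in counts.  Pixels whose fits do
    not converge propagate as missing values (NaN), never as zeros.
    """
    nx, ny, _ = hdc.profile.shape
    if hdc.profile.size == 0 or not np.any(np.nan_to_num(hdc.profile) > 0):
        warnings.warn("HDC carries no signal; all scatter-map pixels are missing",
                      stacklevel=2)
    di = np.full((nx, ny), np.nan)
    sr = np.full((nx, ny), np.nan)
    quality = np.full((nx, ny), np.nan)
    rows = []
    for i in range(nx):
        for j in range(ny):
            counts = hdc.bin_counts[i, j] if hdc.bin_counts is not None else None
            try:
                fit = fit_gaussian_profile(hdc.radius_mm, hdc.profile[i, j], counts)
            except DomainError:
                fit = DiffuseFit(np.nan, np.nan, np.nan, np.nan, False)
            if fit.converged:
                di[i, j] = diffuse_intensity(fit)
                sr[i, j] = scattering_radius(fit)
                quality[i, j] = fit.residual_rms
            rows.append(
                {
                    "x_mm": hdc.x_mm[i],
                    "y_mm": hdc.y_mm[j],
                    "amplitude": fit.amplitude,
                    "sigma_mm": fit.sigma_mm,
                    "offset": fit.offset,
                    "residual_rms": fit.residual_rms,
                    "converged": fit.converged,
                }
            )
    return ScatterMaps(
        di, sr, quality, hdc.x_mm.copy(), hdc.y_mm.copy(), hdc.band_label,
        pd.DataFrame(rows),
    )


def di_map(maps: ScatterMaps) -> FeatureMap:
    return FeatureMap(maps.di, maps.x_mm, maps.y_mm, "DI", units="counts*mm^2")


def sr_map(maps: ScatterMaps) -> FeatureMap:
    return FeatureMap(maps.sr, maps.x_mm, maps.y_mm, "SR", units="mm")


def fit_table_to_csv(maps: ScatterMaps, path) -> None:
    maps.fit_table.to_csv(path, index=False)
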