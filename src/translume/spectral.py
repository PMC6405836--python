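"""Spectral unmixing and per-pixel band features.

PCA over the per-pixel spectra of a HyperSpectral Cube separates emitter
sources that emit at different wavelengths (probe emission lines, excitation
leakage, small- and large-Stokes-shift autofluorescence).  Contiguous
wavelength runs where a component's loading is strong define spectral bands;
each band is then summarised per pixel by three intra-band features:

* SI (Spectral Intensity)  -- baseline-subtracted counts summed over the band,
* SP (Spectral Position)   -- intensity-weighted centroid wavelength (nm),
* SW (Spectral Width)      -- Gaussian-equivalent FWHM of the in-band
  intensity distribution, 2*sqrt(2 ln 2) times its weighted std dev (nm),

plus the inter-band intensity ratio SI_i/j.  Bands are classified into the
alpha (excitation leakage, ~980 nm), beta (~1100 nm), gamma (~1350 nm) and
delta (~1600 nm) families by their centre wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DomainError
from .hypercube import HyperSpectralCube

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: band-class boundaries in nm: [lo, hi) except delta which is closed above
DEFAULT_BAND_CLASS_BOUNDARIES: dict[str, tuple[float, float]] = {
    "alpha": (950.0, 1020.0),
    "beta": (1020.0, 1250.0),
    "gamma": (1250.0, 1500.0),
    "delta": (1500.0, 1700.0),
}

__all__ = [
    "PCAResult",
    "SpectralBand",
    "FeatureMap",
    "pca_spectra",
    "identify_bands",
    "classify_band",
    "spectral_intensity",
    "spectral_position",
    "spectral_width",
    "interband_ratio",
    "stokes_shift",
    "feature_map_to_tiff",
    "feature_map_to_csv",
    "bands_to_csv",
    "DEFAULT_BAND_CLASS_BOUNDARIES",
]


@dataclass
class PCAResult:
    """Retained principal components of a spectra (or profile) matrix.

    ``loadings`` are unit-norm component vectors (component x feature),
    ``scores`` the per-observation coordinates, and
    ``explained_variance_fraction`` the fraction of total variance each
    retained component explains, in descending order.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class SpectralBand:
    """A contiguous wavelength interval with its PCA provenance."""

    name: str
    lambda_lo_nm: float
    lambda_hi_nm: float
    pc_indices: tuple[int, ...] = ()
    band_class: str = "other"

    def __post_init__(self):
        if self.lambda_hi_nm < self.lambda_lo_nm:
            raise ConfigurationError("lambda_hi_nm must be >= lambda_lo_nm")

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.lambda_lo_nm + self.lambda_hi_nm)

    def mask(self, wavelength_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelength_nm, float)
        return (wl >= self.lambda_lo_nm) & (wl <= self.lambda_hi_nm)


@dataclass
class FeatureMap:
    """One scalar per raster grid point (NaN = missing / unevaluable pixel)."""

    values: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    kind: str
    band: SpectralBand | None = None
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.x_mm = np.asarray(self.x_mm, float)
        self.y_mm = np.asarray(self.y_mm, float)
        if self.values.shape != (self.x_mm.size, self.y_mm.size):
            raise ConfigurationError("feature-map shape must match the grid")


# ---------------------------------------------------------------------------
# PCA machinery (shared with the diffuse module)
# ---------------------------------------------------------------------------


def pca_matrix(X: np.ndarray, variance_floor: float) -> PCAResult:
    """Mean-centred PCA of an (observations x features) matrix.

    Components with an explained-variance fraction below ``variance_floor``
    are dropped.  A matrix with (numerically) zero variance yields zero
    retained components and a warning, not an error.
    """
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0, keepdims=True)
    total = float((Xc**2).sum())
    scale = max(float((X**2).sum()), 1.0)
    empty = PCAResult(
        loadings=np.zeros((0, X.shape[1])),
        scores=np.zeros((X.shape[0], 0)),
        explained_variance_fraction=np.zeros(0),
    )
    if not np.isfinite(total) or total <= 1e-18 * scale:
        warnings.warn("no variance across observations; retaining 0 components",
                      stacklevel=2)
        return empty
    pca = PCA(svd_solver="full").fit(X)
    keep = pca.explained_variance_ratio_ >= variance_floor
    if not keep.any():
        warnings.warn("no component reaches the variance floor", stacklevel=2)
        return empty
    return PCAResult(
        loadings=pca.components_[keep],
        scores=pca.transform(X)[:, keep],
        explained_variance_fraction=pca.explained_variance_ratio_[keep],
    )


def pca_spectra(hsc: HyperSpectralCube, variance_floor: float = 0.01) -> PCAResult:
    """Deconvolve emitter sources by PCA over per-pixel spectra.

    Spectra are mean-centred per wavelength (no unit-variance scaling, so
    band amplitudes drive the loadings); components are ordered by explained
    variance and those explaining less than ``variance_floor`` are dropped.
    """
    nx, ny, nl = hsc.intensity.shape
    if nx * ny < 2:
        raise ConfigurationError("PCA needs at least 2 grid points")
    return pca_matrix(hsc.intensity.reshape(nx * ny, nl), variance_floor)


# ---------------------------------------------------------------------------
# Band identification and classification
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs as inclusive (lo, hi) index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1]) - 1) for i in range(0, len(edges), 2)]


def classify_band(
    center_nm: float,
    boundaries: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Assign a band centre to the alpha/beta/gamma/delta taxonomy.

    Defaults: alpha [950, 1020), beta [1020, 1250), gamma [1250, 1500),
    delta [1500, 1700]; anything else (including centres outside
    900-1700 nm) is 'other'.
    """
    bounds = DEFAULT_BAND_CLASS_BOUNDARIES if boundaries is None else boundaries
    for name, (lo, hi) in bounds.items():
        closed_hi = name == "delta" or hi == max(b[1] for b in bounds.values())
        if lo <= center_nm < hi or (closed_hi and center_nm == hi):
            return name
    return "other"


def identify_bands(
    pca: PCAResult,
    wavelength_nm: np.ndarray,
    loading_threshold: float = 0.5,
    boundaries: dict[str, tuple[float, float]] | None = None,
) -> list[SpectralBand]:
    """Group strong-loading wavelengths into spectral bands.

    For each retained component, wavelengths whose |loading| reaches
    ``loading_threshold`` times the component's maximum |loading| are grouped
    into maximal contiguous runs.  Runs from different components that share
    at least one wavelength sample are merged, with their supporting
    component indices unioned.  With a threshold of 1.0 bands degenerate to
    single-sample intervals at the loading maxima.
    """
    wl = np.asarray(wavelength_nm, float)
    intervals: list[tuple[int, int, set[int]]] = []
    for ci in range(pca.n_components):
        mag = np.abs(pca.loadings[ci])
        peak = mag.max()
        if peak <= 0:
            continue
        for lo, hi in _runs(mag >= loading_threshold * peak):
            intervals.append((lo, hi, {ci}))
    intervals.sort(key=lambda t: (t[0], t[1]))
    merged: list[list] = []
    for lo, hi, pcs in intervals:
        if merged and lo <= merged[-1][1]:  # shares >= 1 sample
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] |= pcs
        else:
            merged.append([lo, hi, set(pcs)])
    bands: list[SpectralBand] = []
    seen: dict[str, int] = {}
    for lo, hi, pcs in merged:
        lam_lo, lam_hi = float(wl[lo]), float(wl[hi])
        cls = classify_band(0.5 * (lam_lo + lam_hi), boundaries)
        name = f"{cls}_{0.5 * (lam_lo + lam_hi):.0f}nm"
        if name in seen:
            seen[name] += 1
            name = f"{name}_{seen[name]}"
        else:
            seen[name] = 0
        bands.append(
            SpectralBand(name, lam_lo, lam_hi, tuple(sorted(pcs)), cls)
        )
    return bands


# ---------------------------------------------------------------------------
# Intra- and inter-band features
# ---------------------------------------------------------------------------


def _band_masks(
    hsc: HyperSpectralCube,
    band: SpectralBand,
    all_bands: list[SpectralBand] | None,
) -> tuple[np.ndarray, np.ndarray]:
    wl = hsc.wavelength_nm
    in_mask = band.mask(wl)
    if not in_mask.any():
        raise DomainError(
            f"band [{band.lambda_lo_nm}, {band.lambda_hi_nm}] nm lies outside "
            "the cube wavelength axis"
        )
    bands = all_bands if all_bands else [band]
    any_band = np.zeros_like(in_mask)
    for b in bands:
        any_band |= b.mask(wl)
    return in_mask, ~any_band


def _baseline(hsc: HyperSpectralCube, out_mask: np.ndarray) -> np.ndarray:
    """Per-pixel baseline: median of the out-of-band spectrum, 0 if none."""
    if not out_mask.any():
        return np.zeros(hsc.grid_shape)
    return np.median(hsc.intensity[:, :, out_mask], axis=2)


def spectral_intensity(
    hsc: HyperSpectralCube,
    band: SpectralBand,
    all_bands: list[SpectralBand] | None = None,
) -> FeatureMap:
    """SI: baseline-subtracted counts summed over the band, clipped at 0.

    The baseline is the per-pixel median over wavelengths outside *all*
    identified bands (``all_bands``, defaulting to just ``band``).
    """
    in_mask, out_mask = _band_masks(hsc, band, all_bands)
    base = _baseline(hsc, out_mask)
    si = hsc.intensity[:, :, in_mask].sum(axis=2) - in_mask.sum() * base
    return FeatureMap(
        np.clip(si, 0.0, None), hsc.x_mm, hsc.y_mm, "SI", band, units="counts"
    )


def _band_weights(hsc, band, all_bands):
    in_mask, out_mask = _band_masks(hsc, band, all_bands)
    base = _baseline(hsc, out_mask)
    w = np.clip(hsc.intensity[:, :, in_mask] - base[:, :, None], 0.0, None)
    return hsc.wavelength_nm[in_mask], w, w.sum(axis=2)


def spectral_position(
    hsc: HyperSpectralCube,
    band: SpectralBand,
    all_bands: list[SpectralBand] | None = None,
) -> FeatureMap:
    """SP: intensity-weighted centroid wavelength inside the band (nm).

    Pixels whose in-band, baseline-subtracted intensity is all zero are
    flagged missing (NaN) rather than propagating a divide-by-zero.
    """
    lam, w, wsum = _band_weights(hsc, band, all_bands)
    sp = np.full(hsc.grid_shape, np.nan)
    ok = wsum > 0
    np.divide((w * lam).sum(axis=2), wsum, out=sp, where=ok)
    return FeatureMap(sp, hsc.x_mm, hsc.y_mm, "SP", band, units="nm")


def spectral_width(
    hsc: HyperSpectralCube,
    band: SpectralBand,
    all_bands: list[SpectralBand] | None = None,
) -> FeatureMap:
    """SW: Gaussian-equivalent FWHM, 2*sqrt(2 ln 2) times the weighted
    standard deviation of wavelength inside the band (nm)."""
    lam, w, wsum = _band_weights(hsc, band, all_bands)
    sw = np.full(hsc.grid_shape, np.nan)
    ok = wsum > 0
    mean = np.zeros_like(sw)
    np.divide((w * lam).sum(axis=2), wsum, out=mean, where=ok)
    var = np.zeros_like(sw)
    np.divide(
        (w * (lam[None, None, :] - mean[:, :, None]) ** 2).sum(axis=2),
        wsum,
        out=var,
        where=ok,
    )
    sw[ok] = FWHM_PER_SIGMA * np.sqrt(np.clip(var[ok], 0.0, None))
    return FeatureMap(sw, hsc.x_mm, hsc.y_mm, "SW", band, units="nm")


def interband_ratio(
    si_i: FeatureMap, si_j: FeatureMap, epsilon: float = 1.0
) -> FeatureMap:
    """SI_i/j: per-pixel ratio of two SI maps with a denominator guard.

    ``epsilon`` (default 1 count) bounds the denominator away from zero so
    the ratio stays finite on empty background pixels.
    """
    if si_i.values.shape != si_j.values.shape or not (
        np.array_equal(si_i.x_mm, si_j.x_mm) and np.array_equal(si_i.y_mm, si_j.y_mm)
    ):
        raise DomainError("interband ratio requires identical grids")
    values = si_i.values / np.maximum(si_j.values, epsilon)
    name_i = si_i.band.name if si_i.band else "i"
    name_j = si_j.band.name if si_j.band else "j"
    return FeatureMap(
        values, si_i.x_mm, si_i.y_mm, f"ratio:{name_i}/{name_j}", si_i.band,
        units="dimensionless",
    )


def stokes_shift(lambda_ex_nm: float, lambda_em_nm: float) -> tuple[float, str]:
    """Stokes shift in wavenumbers and its autofluorescence class.

    shift = 1e7 * (1/lambda_ex - 1/lambda_em) cm^-1; shifts below 2000 cm^-1
    are 'small', above 2500 cm^-1 'large', otherwise 'intermediate'.
    Anti-Stokes emission (lambda_em < lambda_ex) is out of scope.
    """
    if lambda_ex_nm <= 0 or lambda_em_nm <= 0:
        raise DomainError("wavelengths must be positive")
    if lambda_em_nm < lambda_ex_nm:
        raise DomainError("anti-Stokes shift (lambda_em < lambda_ex) not supported")
    shift = 1e7 * (1.0 / lambda_ex_nm - 1.0 / lambda_em_nm)
    if shift < 2000.0:
        cls = "small"
    elif shift > 2500.0:
        cls = "large"
    else:
        cls = "intermediate"
    return shift, cls


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def feature_map_to_tiff(fmap: FeatureMap, path) -> None:
    tifffile.imwrite(str(path), fmap.values.astype(np.float32))


def feature_map_to_csv(fmap: FeatureMap, path) -> None:
    xx, yy = np.meshgrid(fmap.x_mm, fmap.y_mm, indexing="ij")
    pd.DataFrame(
        {"x_mm": xx.ravel(), "y_mm": yy.ravel(), "value": fmap.values.ravel()}
    ).to_csv(path, index=False)


def bands_to_csv(bands: list[SpectralBand], path) -> None:
    pd.DataFrame(
        [
            {
                "name": b.name,
                "lambda_lo_nm": b.lambda_lo_nm,
                "lambda_hi_nm": b.lambda_hi_nm,
                "band_class": b.band_class,
                "pc_indices": ";".join(map(str, b.pc_indices)),
            }
            for b in bands
        ]
    ).to_csv(path, index=False)
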