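"""Raster-scan containers and raw-to-cube reduction.

A trans-illumination scan acquires one 2-D detector frame per raster grid
point, so the raw dataset is four-dimensional.  In the hyperspectral (HSI)
configuration the detector axes are (a, b): axis ``a`` disperses wavelength
and axis ``b`` collects the defocused photons of equal energy, so summing
over ``b`` yields a HyperSpectral Cube HSC(x, y, lambda).  In the
hyperdiffuse (HDI) configuration the frame is a plain surface image whose
blob is the diffuse spread of the transmitted light; radially averaging each
frame about its beam centre yields a HyperDiffuse Cube HDC(x, y, r).

Cubes are stored in a small HDF5 container (groups ``/hsc`` and ``/hdc``);
raw stacks can be exchanged as multi-page TIFF with a JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np
import tifffile

from .errors import ConfigurationError, DomainError, FormatError

SCHEMA_VERSION = "1.0"

__all__ = [
    "WavelengthCalibration",
    "RawHSIStack",
    "RawHDIStack",
    "HyperSpectralCube",
    "HyperDiffuseCube",
    "dispersion_nm_per_pixel",
    "reduce_hsi_stack",
    "radial_profile",
    "frame_centroid",
    "build_hdc",
    "write_cube",
    "read_cube",
    "write_raw_tiff",
    "read_raw_tiff",
]


def _farr(x, name: str, ndim: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if ndim is not None and arr.ndim != ndim:
        raise ConfigurationError(f"{name} must be {ndim}-D, got {arr.ndim}-D")
    return arr


def _check_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ConfigurationError(f"{name} must be strictly increasing")


def _check_nonnegative(arr: np.ndarray, name: str) -> None:
    if arr.size and np.nanmin(arr) < 0:
        raise ConfigurationError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthCalibration:
    """Linear mapping of the spectral detector axis to wavelength.

    ``n_pixels`` detector columns cover [lambda_min_nm, lambda_max_nm]; the
    dispersion is the covered range divided by the pixel count (e.g. 320
    pixels over 900-1700 nm give 2.5 nm/pixel).
    """

    n_pixels: int
    lambda_min_nm: float
    lambda_max_nm: float

    def __post_init__(self):
        if self.n_pixels == 0:
            raise DomainError("n_pixels must be nonzero")
        if self.n_pixels < 2:
            raise ConfigurationError("calibration needs at least 2 pixels")
        if not self.lambda_max_nm > self.lambda_min_nm:
            raise ConfigurationError("lambda_max_nm must exceed lambda_min_nm")

    @property
    def dispersion_nm_per_pixel(self) -> float:
        return (self.lambda_max_nm - self.lambda_min_nm) / self.n_pixels

    def wavelength_axis(self) -> np.ndarray:
        """Pixel-centre wavelengths, ascending, in nm."""
        step = self.dispersion_nm_per_pixel
        return self.lambda_min_nm + (np.arange(self.n_pixels) + 0.5) * step


def dispersion_nm_per_pixel(cal: WavelengthCalibration) -> float:
    """Spectral sampling of the detector in nm per pixel."""
    return cal.dispersion_nm_per_pixel


@dataclass
class RawHSIStack:
    """Raw hyperspectral scan: frames indexed (x, y, a, b) in counts.

    Axis ``a`` is the spectral axis (calibrated by ``wavelength_nm``),
    axis ``b`` the defocus axis that the reduction sums over.
    """

    frames: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    wavelength_nm: np.ndarray

    def __post_init__(self):
        self.frames = _farr(self.frames, "frames", 4)
        self.x_mm = _farr(self.x_mm, "x_mm", 1)
        self.y_mm = _farr(self.y_mm, "y_mm", 1)
        self.wavelength_nm = _farr(self.wavelength_nm, "wavelength_nm", 1)
        _check_nonnegative(self.frames, "frames")
        _check_increasing(self.x_mm, "x_mm")
        _check_increasing(self.y_mm, "y_mm")
        _check_increasing(self.wavelength_nm, "wavelength_nm")
        nx, ny, na, _ = self.frames.shape
        if self.x_mm.size != nx or self.y_mm.size != ny:
            raise ConfigurationError("grid coordinates do not match frame grid")
        if self.wavelength_nm.size != na:
            raise ConfigurationError(
                f"wavelength calibration length {self.wavelength_nm.size} does "
                f"not match spectral axis extent {na}"
            )


@dataclass
class RawHDIStack:
    """Raw hyperdiffuse scan for one bandpass filter: frames (x, y, u, v)."""

    frames: np.ndarray
    band_label: str
    pixel_pitch_mm: float
    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self):
        self.frames = _farr(self.frames, "frames", 4)
        self.x_mm = _farr(self.x_mm, "x_mm", 1)
        self.y_mm = _farr(self.y_mm, "y_mm", 1)
        _check_nonnegative(self.frames, "frames")
        _check_increasing(self.x_mm, "x_mm")
        _check_increasing(self.y_mm, "y_mm")
        if self.pixel_pitch_mm <= 0:
            raise ConfigurationError("pixel_pitch_mm must be positive")
        nx, ny = self.frames.shape[:2]
        if self.x_mm.size != nx or self.y_mm.size != ny:
            raise ConfigurationError("grid coordinates do not match frame grid")


@dataclass
class HyperSpectralCube:
    """Reduced hyperspectral dataset I(x, y, lambda) in detector counts."""

    intensity: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    wavelength_nm: np.ndarray

    def __post_init__(self):
        self.intensity = _farr(self.intensity, "intensity", 3)
        self.x_mm = _farr(self.x_mm, "x_mm", 1)
        self.y_mm = _farr(self.y_mm, "y_mm", 1)
        self.wavelength_nm = _farr(self.wavelength_nm, "wavelength_nm", 1)
        _check_nonnegative(self.intensity, "intensity")
        _check_increasing(self.wavelength_nm, "wavelength_nm")
        _check_increasing(self.x_mm, "x_mm")
        _check_increasing(self.y_mm, "y_mm")
        if self.intensity.shape != (
            self.x_mm.size,
            self.y_mm.size,
            self.wavelength_nm.size,
        ):
            raise ConfigurationError("intensity shape inconsistent with axes")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensity.shape[:2]


@dataclass
class HyperDiffuseCube:
    """Radially averaged diffuse dataset I(x, y, r).

    ``profile`` holds the mean counts per radial bin; bins that contain no
    detector pixels (large radii reached only in frame corners) are flagged
    missing with NaN and carry ``bin_counts`` of zero.  Radial bins are
    uniform and half-open, [k*dr, (k+1)*dr).
    """

    profile: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    radius_mm: np.ndarray
    band_label: str = ""
    bin_counts: np.ndarray | None = None

    def __post_init__(self):
        self.profile = _farr(self.profile, "profile", 3)
        self.x_mm = _farr(self.x_mm, "x_mm", 1)
        self.y_mm = _farr(self.y_mm, "y_mm", 1)
        self.radius_mm = _farr(self.radius_mm, "radius_mm", 1)
        if self.profile.size:
            _check_nonnegative(self.profile, "profile")
        if self.radius_mm.size > 1:
            dr = np.diff(self.radius_mm)
            if not np.allclose(dr, dr[0]) or dr[0] <= 0:
                raise ConfigurationError("radius bins must be uniform ascending")
        if self.profile.shape != (
            self.x_mm.size,
            self.y_mm.size,
            self.radius_mm.size,
        ):
            raise ConfigurationError("profile shape inconsistent with axes")
        if self.bin_counts is not None:
            self.bin_counts = np.asarray(self.bin_counts)
            if self.bin_counts.shape != self.profile.shape:
                raise ConfigurationError("bin_counts shape must match profile")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.profile.shape[:2]


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------


def reduce_hsi_stack(raw: RawHSIStack) -> HyperSpectralCube:
    """Collapse the defocus axis: I(x, y, lambda_a) = sum_b frames(x, y, a, b).

    Total counts are conserved exactly; grid and wavelength axes are copied
    through unchanged.
    """
    return HyperSpectralCube(
        intensity=raw.frames.sum(axis=3),
        x_mm=raw.x_mm.copy(),
        y_mm=raw.y_mm.copy(),
        wavelength_nm=raw.wavelength_nm.copy(),
    )


def radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    bin_width_mm: float,
    pixel_pitch_mm: float = 1.0,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radially averaged intensity about a sub-pixel centre.

    Bin ``k`` holds the mean of the pixels whose distance to ``center`` (in
    mm) falls in the half-open interval [k*dr, (k+1)*dr).  Empty bins are
    returned as NaN with a zero pixel count.

    Returns ``(radius_mm, mean, counts)`` where ``radius_mm`` are the bin
    centres.
    """
    img = _farr(image, "image", 2)
    if bin_width_mm <= 0:
        raise DomainError("bin_width_mm must be positive")
    u0, v0 = float(center[0]), float(center[1])
    nu, nv = img.shape
    if not (0.0 <= u0 <= nu - 1 and 0.0 <= v0 <= nv - 1):
        raise DomainError(f"center {center} outside frame of shape {img.shape}")
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    dist = np.hypot(uu - u0, vv - v0) * pixel_pitch_mm
    idx = np.floor(dist / bin_width_mm).astype(np.intp)
    nb = int(idx.max()) + 1 if n_bins is None else int(n_bins)
    idx = np.minimum(idx, nb - 1) if n_bins is not None else idx
    counts = np.bincount(idx.ravel(), minlength=nb)[:nb]
    sums = np.bincount(idx.ravel(), weights=img.ravel(), minlength=nb)[:nb]
    mean = np.full(nb, np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)
    radius = (np.arange(nb) + 0.5) * bin_width_mm
    return radius, mean, counts


def frame_centroid(frame: np.ndarray) -> tuple[float, float]:
    """Sub-pixel beam centre: intensity centroid after median subtraction.

    Falls back to the geometric frame centre when the frame carries no
    signal above its median (e.g. an all-zero frame).
    """
    img = _farr(frame, "frame", 2)
    w = np.clip(img - np.median(img), 0.0, None)
    total = w.sum()
    nu, nv = img.shape
    if total <= 0:
        return (nu - 1) / 2.0, (nv - 1) / 2.0
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    return float((uu * w).sum() / total), float((vv * w).sum() / total)


def build_hdc(
    raw: RawHDIStack,
    centers: Sequence[tuple[float, float]] | None = None,
    bin_width_mm: float | None = None,
) -> HyperDiffuseCube:
    """Reduce a raw hyperdiffuse stack to HDC(x, y, r).

    Each frame is radially averaged about its beam centre (default: the
    median-subtracted intensity centroid) onto a radius axis shared across
    the whole grid.  The default bin width is one projected pixel pitch;
    per-bin means (not sums) keep profiles amplitude-comparable across radii.
    """
    nx, ny = raw.frames.shape[:2]
    dr = raw.pixel_pitch_mm if bin_width_mm is None else float(bin_width_mm)
    if nx * ny == 0:
        return HyperDiffuseCube(
            profile=np.zeros((nx, ny, 0)),
            x_mm=raw.x_mm,
            y_mm=raw.y_mm,
            radius_mm=np.zeros(0),
            band_label=raw.band_label,
            bin_counts=np.zeros((nx, ny, 0), dtype=int),
        )
    flat = raw.frames.reshape(nx * ny, *raw.frames.shape[2:])
    if centers is None:
        centers = []
        for k, frame in enumerate(flat):
            if frame.max() <= 0:
                i, j = divmod(k, ny)
                warnings.warn(
                    f"all-zero frame at grid point ({i}, {j}); its profile is zero",
                    stacklevel=2,
                )
            centers.append(frame_centroid(frame))
    else:
        centers = [tuple(c) for c in centers]
        if len(centers) != nx * ny:
            raise ConfigurationError("need one beam center per grid point")

    nu, nv = raw.frames.shape[2:]
    corners = np.array([[0, 0], [0, nv - 1], [nu - 1, 0], [nu - 1, nv - 1]], float)
    max_dist = max(
        np.hypot(corners[:, 0] - c[0], corners[:, 1] - c[1]).max() for c in centers
    ) * raw.pixel_pitch_mm
    nb = int(np.floor(max_dist / dr)) + 1

    profile = np.full((nx * ny, nb), np.nan)
    counts = np.zeros((nx * ny, nb), dtype=int)
    for k, (frame, c) in enumerate(zip(flat, centers)):
        radius, mean, cnt = radial_profile(
            frame, c, dr, pixel_pitch_mm=raw.pixel_pitch_mm, n_bins=nb
        )
        profile[k] = mean
        counts[k] = cnt
    return HyperDiffuseCube(
        profile=profile.reshape(nx, ny, nb),
        x_mm=raw.x_mm.copy(),
        y_mm=raw.y_mm.copy(),
        radius_mm=(np.arange(nb) + 0.5) * dr,
        band_label=raw.band_label,
        bin_counts=counts.reshape(nx, ny, nb),
    )


# ---------------------------------------------------------------------------
# Cube container I/O (HDF5)
# ---------------------------------------------------------------------------

_HSC_KEYS = ("intensity", "x_mm", "y_mm", "wavelength_nm")
_HDC_KEYS = ("profile", "x_mm", "y_mm", "radius_mm")


def _dset(group: h5py.Group, name: str, data: np.ndarray) -> None:
    # track_times=False keeps repeated writes byte-identical
    group.create_dataset(name, data=data, track_times=False)


def write_cube(path, cube) -> None:
    """Write an HSC or HDC to the HDF5 cube container.

    Layout: ``/hsc/{intensity,x_mm,y_mm,wavelength_nm}`` or
    ``/hdc/{profile,x_mm,y_mm,radius_mm[,bin_counts]}`` with the band label
    as a group attribute; the schema version is a root attribute.  The
    write/read pair is lossless to full floating precision (NaN missing-bin
    flags included).
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["creator"] = "translume"
        if isinstance(cube, HyperSpectralCube):
            g = f.create_group("hsc")
            _dset(g, "intensity", cube.intensity)
            _dset(g, "x_mm", cube.x_mm)
            _dset(g, "y_mm", cube.y_mm)
            _dset(g, "wavelength_nm", cube.wavelength_nm)
        elif isinstance(cube, HyperDiffuseCube):
            g = f.create_group("hdc")
            _dset(g, "profile", cube.profile)
            _dset(g, "x_mm", cube.x_mm)
            _dset(g, "y_mm", cube.y_mm)
            _dset(g, "radius_mm", cube.radius_mm)
            if cube.bin_counts is not None:
                _dset(g, "bin_counts", cube.bin_counts)
            g.attrs["band_label"] = cube.band_label
        else:
            raise TypeError(f"cannot write object of type {type(cube).__name__}")


def read_cube(path):
    """Read a cube container; returns a HyperSpectralCube or HyperDiffuseCube."""
    with h5py.File(path, "r") as f:
        if "hsc" in f:
            g = f["hsc"]
            for key in _HSC_KEYS:
                if key not in g:
                    raise FormatError(f"cube file missing dataset 'hsc/{key}'")
            return HyperSpectralCube(
                intensity=g["intensity"][()],
                x_mm=g["x_mm"][()],
                y_mm=g["y_mm"][()],
                wavelength_nm=g["wavelength_nm"][()],
            )
        if "hdc" in f:
            g = f["hdc"]
            for key in _HDC_KEYS:
                if key not in g:
                    raise FormatError(f"cube file missing dataset 'hdc/{key}'")
            return HyperDiffuseCube(
                profile=g["profile"][()],
                x_mm=g["x_mm"][()],
                y_mm=g["y_mm"][()],
                radius_mm=g["radius_mm"][()],
                band_label=str(g.attrs.get("band_label", "")),
                bin_counts=g["bin_counts"][()] if "bin_counts" in g else None,
            )
    raise FormatError("cube file contains neither an 'hsc' nor an 'hdc' group")


# ---------------------------------------------------------------------------
# Raw-stack exchange format (multi-page TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def write_raw_tiff(path, stack) -> None:
    """Write a raw stack as multi-page TIFF (one page per grid point).

    The grid geometry and calibration go into a ``<path>.json`` sidecar.
    """
    path = str(path)
    if isinstance(stack, RawHSIStack):
        meta = {
            "kind": "hsi",
            "x_mm": stack.x_mm.tolist(),
            "y_mm": stack.y_mm.tolist(),
            "wavelength_nm": stack.wavelength_nm.tolist(),
        }
    elif isinstance(stack, RawHDIStack):
        meta = {
            "kind": "hdi",
            "x_mm": stack.x_mm.tolist(),
            "y_mm": stack.y_mm.tolist(),
            "band_label": stack.band_label,
            "pixel_pitch_mm": stack.pixel_pitch_mm,
        }
    else:
        raise TypeError(f"cannot write object of type {type(stack).__name__}")
    nx, ny = stack.frames.shape[:2]
    pages = stack.frames.reshape(nx * ny, *stack.frames.shape[2:])
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh)


def read_raw_tiff(path):
    """Read a raw stack written by :func:`write_raw_tiff`."""
    path = str(path)
    try:
        with open(path + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError as exc:
        raise FormatError(f"missing sidecar '{path}.json'") from exc
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    nx, ny = len(meta["x_mm"]), len(meta["y_mm"])
    frames = pages.reshape(nx, ny, *pages.shape[1:])
    if meta.get("kind") == "hsi":
        return RawHSIStack(frames, meta["x_mm"], meta["y_mm"], meta["wavelength_nm"])
    if meta.get("kind") == "hdi":
        return RawHDIStack(
            frames, meta["band_label"], meta["pixel_pitch_mm"], meta["x_mm"], meta["y_mm"]
        )
    raise FormatError("sidecar 'kind' must be 'hsi' or 'hdi'")
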