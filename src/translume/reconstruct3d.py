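"""Probe localization, depth inversion and 3-D scene assembly.

The 2-D probe position comes from connected components of a contrast map (SI
or DI); the depth below the exit surface comes from inverting a monotone
depth calibration of a scattering/spectral feature (SR in diffuse mode, SW or
SP in spectral mode).  A rigid fiducial registration places the imaging frame
in the coordinate system of a 3-D surface scan, and each probe is finally
dropped below the local surface height by its estimated depth, assuming a
homogeneous optical medium.

Also houses the volume-rendering reductions used for cube inspection: axis
sums, maximum-intensity projection and the transparency (opacity) mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigurationError, DegenerateGeometryError, DomainError
from .hypercube import HyperDiffuseCube, HyperSpectralCube
from .spectral import FeatureMap

__all__ = [
    "ProbeEstimate",
    "DepthEstimate",
    "DepthCalibration",
    "SurfacePointCloud",
    "RigidTransform",
    "ReconstructedScene",
    "localize_probe",
    "merge_probe_estimates",
    "build_depth_calibration",
    "invert_depth",
    "register_fiducials",
    "reconstruct_scene",
    "project_cube",
    "mip",
    "opacity_mask",
    "read_point_cloud",
    "write_point_cloud",
]


# ---------------------------------------------------------------------------
# 2-D localization
# ---------------------------------------------------------------------------


@dataclass
class ProbeEstimate:
    """One detected contrast source."""

    xy_mm: tuple[float, float]
    extent_mm: tuple[float, float, float, float]  # (x_lo, x_hi, y_lo, y_hi)
    peak_value: float
    total_value: float
    source_maps: tuple[str, ...] = ()
    depth_mm: float | None = None
    depth_uncertainty_mm: float | None = None
    depth_flags: tuple[str, ...] = ()


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def localize_probe(
    contrast_map: FeatureMap,
    detection_threshold: float | None = None,
    threshold_frac: float | None = None,
) -> list[ProbeEstimate]:
    """Detect probes as 4-connected components above a detection threshold.

    The default threshold is the robust ``median + 5 * MAD`` of the map,
    suited to compact sources on a flat background.  For deeply scattered
    scenes where several blurred sources share one map, ``threshold_frac``
    thresholds at a fraction of the map maximum instead.  Each component is
    summarised by its intensity-weighted centroid and bounding box; an empty
    list (nothing above threshold) is not an error.
    """
    v = contrast_map.values
    finite = np.isfinite(v)
    if detection_threshold is None:
        if threshold_frac is not None:
            detection_threshold = threshold_frac * float(np.nanmax(v))
        else:
            med = float(np.nanmedian(v))
            mad = float(np.nanmedian(np.abs(v - med)))
            detection_threshold = med + 5.0 * mad
    mask = finite & (v > detection_threshold)
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    xx, yy = np.meshgrid(contrast_map.x_mm, contrast_map.y_mm, indexing="ij")
    out = []
    for k in range(1, n + 1):
        sel = labels == k
        w = np.where(sel, np.nan_to_num(v), 0.0)
        total = float(w.sum())
        if total <= 0:  # flat component; fall back to unweighted centroid
            w = sel.astype(float)
            total = float(w.sum())
        cx = float((xx * w).sum() / total)
        cy = float((yy * w).sum() / total)
        out.append(
            ProbeEstimate(
                xy_mm=(cx, cy),
                extent_mm=(
                    float(xx[sel].min()),
                    float(xx[sel].max()),
                    float(yy[sel].min()),
                    float(yy[sel].max()),
                ),
                peak_value=float(np.nanmax(v[sel])),
                total_value=float(np.nansum(v[sel])),
                source_maps=(contrast_map.kind,),
            )
        )
    return out


def merge_probe_estimates(
    estimates: list[ProbeEstimate], merge_radius_mm: float
) -> list[ProbeEstimate]:
    """Union of detections from several maps, merging duplicates.

    Estimates whose centroids lie within ``merge_radius_mm`` of each other
    are taken to be the same physical source; the brightest one is kept and
    the source-map provenance is unioned.
    """
    merged: list[ProbeEstimate] = []
    for est in sorted(estimates, key=lambda e: -e.total_value):
        for kept in merged:
            d = np.hypot(est.xy_mm[0] - kept.xy_mm[0], est.xy_mm[1] - kept.xy_mm[1])
            if d <= merge_radius_mm:
                kept.source_maps = tuple(sorted(set(kept.source_maps + est.source_maps)))
                break
        else:
            merged.append(est)
    return merged


# ---------------------------------------------------------------------------
# Depth calibration and inversion
# ---------------------------------------------------------------------------


@dataclass
class DepthCalibration:
    """Monotone feature-versus-depth calibration with a saturation-trimmed
    validity range.

    ``depth_mm``/``feature_values`` are the isotonically regularised samples;
    ``knot_depth_mm``/``knot_feature`` the strictly monotone knots inside the
    validity window actually used for inversion.  ``saturated`` records that
    a trailing low-slope (plateau) region was trimmed: feature values landing
    there do not predict depth and are flagged unreliable on inversion.
    """

    feature_kind: str
    depth_mm: np.ndarray
    feature_values: np.ndarray
    validity: tuple[float, float]
    tissue_label: str = ""
    increasing: bool = True
    saturated: bool = False
    knot_depth_mm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    knot_feature: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def feature_at(self, depth: float) -> float:
        """Piecewise-linear interpolant of the calibration inside validity."""
        # knots are stored in increasing orientation; undo the flip on output
        h = np.interp(depth, self.knot_depth_mm, self.knot_feature)
        return float(h if self.increasing else -h)


@dataclass
class DepthEstimate:
    depth_mm: float | None
    uncertainty_mm: float | None
    extrapolated: bool
    reliable: bool


def build_depth_calibration(
    depth_mm: np.ndarray,
    feature_values: np.ndarray,
    slope_floor: float = 0.05,
    feature_kind: str = "SR",
    tissue_label: str = "",
) -> DepthCalibration:
    """Build a monotone piecewise-linear depth calibration from samples.

    The samples are regularised by isotonic regression (direction chosen by
    the overall trend), then the trailing region where the local slope falls
    below ``slope_floor`` times the initial slope is trimmed from the
    validity range — the saturation rule: a plateauing feature (e.g. SR
    saturating at large depth in a finite phantom) must not be used to
    estimate depth.  If interior ties remain, validity is further restricted
    to the largest strictly monotone prefix, with a warning.
    """
    d = np.asarray(depth_mm, float)
    f = np.asarray(feature_values, float)
    if d.size != f.size:
        raise ConfigurationError("depth and feature arrays must have equal length")
    if d.size < 3:
        raise ConfigurationError("depth calibration needs at least 3 samples")
    order = np.argsort(d)
    d, f = d[order], f[order]
    increasing = bool(np.polyfit(d, f, 1)[0] >= 0)
    iso = IsotonicRegression(increasing=increasing)
    g = iso.fit_transform(d, f)
    # work in increasing orientation
    h = g if increasing else -g

    slopes = np.diff(h) / np.diff(d)
    pos = slopes[slopes > 0]
    if pos.size == 0:
        warnings.warn("feature is flat over the whole depth range; calibration "
                      "degenerate", stacklevel=2)
        return DepthCalibration(
            feature_kind, d, g, (float(d[0]), float(d[0])), tissue_label,
            increasing, True, d[:1], h[:1],
        )
    s0 = pos[0]
    k = d.size  # number of knots kept
    saturated = False
    while k >= 3 and slopes[k - 2] < slope_floor * s0:
        k -= 1
        saturated = True

    # strictly monotone prefix inside the trimmed range
    kept_d, kept_h = [d[0]], [h[0]]
    for i in range(1, k):
        if h[i] > kept_h[-1]:
            kept_d.append(d[i])
            kept_h.append(h[i])
        else:
            warnings.warn(
                "non-monotone calibration after regularization; validity "
                "restricted to the largest monotone prefix", stacklevel=2,
            )
            break
    kept_d = np.asarray(kept_d)
    kept_h = np.asarray(kept_h)
    return DepthCalibration(
        feature_kind=feature_kind,
        depth_mm=d,
        feature_values=g,
        validity=(float(kept_d[0]), float(kept_d[-1])),
        tissue_label=tissue_label,
        increasing=increasing,
        saturated=saturated or k < d.size,
        knot_depth_mm=kept_d,
        knot_feature=kept_h,
    )


def _invert_value(value_h: float, cal: DepthCalibration) -> float:
    return float(np.interp(value_h, cal.knot_feature, cal.knot_depth_mm))


def invert_depth(
    feature_value: float,
    cal: DepthCalibration,
    feature_noise_sd: float | None = None,
) -> DepthEstimate:
    """Invert the calibration: feature value -> depth below the exit surface.

    Values beyond the feature range of validity clamp to the nearest endpoint
    and are flagged ``extrapolated`` — except values past the validity end of
    a saturation-trimmed calibration, which are flagged unreliable with no
    point estimate (the plateau does not determine depth).  The uncertainty
    is the half-width of the depth interval mapped by +/- one caller-supplied
    feature-noise standard deviation.
    """
    if cal.knot_depth_mm.size < 2:
        raise ConfigurationError("calibration has no usable monotone range")
    h = feature_value if cal.increasing else -feature_value
    lo, hi = cal.knot_feature[0], cal.knot_feature[-1]
    if h > hi and cal.saturated:
        return DepthEstimate(None, None, extrapolated=True, reliable=False)
    extrapolated = bool(h < lo or h > hi)
    depth = _invert_value(np.clip(h, lo, hi), cal)
    unc = None
    if feature_noise_sd is not None:
        sd = abs(feature_noise_sd)
        d_lo = _invert_value(np.clip(h - sd, lo, hi), cal)
        d_hi = _invert_value(np.clip(h + sd, lo, hi), cal)
        unc = 0.5 * abs(d_hi - d_lo)
    return DepthEstimate(depth, unc, extrapolated=extrapolated, reliable=True)


# ---------------------------------------------------------------------------
# Rigid fiducial registration (Kabsch)
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Proper rigid transform (rotation + translation, no scale/reflection)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def register_fiducials(
    source_markers: np.ndarray, target_markers: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping source fiducials onto targets.

    Kabsch algorithm: SVD of the cross-covariance of the centred marker sets,
    with the determinant correction that forbids reflections.  Requires at
    least 3 non-collinear paired markers.
    """
    src = np.asarray(source_markers, float)
    dst = np.asarray(target_markers, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ConfigurationError("marker sets must be matching (n, 3) arrays")
    if src.shape[0] < 3:
        raise ConfigurationError("registration needs at least 3 paired markers")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    for pts, name in ((src_c, "source"), (dst_c, "target")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-30):
            raise DegenerateGeometryError(f"{name} fiducials are collinear")
    u, _, vt = np.linalg.svd(src_c.T @ dst_c)
    sign = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, sign])) @ vt
    rot = rot.T  # maps source -> target as row vectors @ R.T
    trans = dst.mean(axis=0) - src.mean(axis=0) @ rot.T
    resid = src @ rot.T + trans - dst
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rot, trans, rmsd)


# ---------------------------------------------------------------------------
# Surface cloud and scene assembly
# ---------------------------------------------------------------------------


@dataclass
class SurfacePointCloud:
    """Surface scan point cloud with optional labelled fiducial markers."""

    points: np.ndarray
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.fiducials = {k: np.asarray(v, float) for k, v in self.fiducials.items()}


@dataclass
class ReconstructedScene:
    surface: SurfacePointCloud
    probe_table: pd.DataFrame


def reconstruct_scene(
    surface: SurfacePointCloud,
    probes: list[ProbeEstimate],
    transform: RigidTransform | None = None,
) -> ReconstructedScene:
    """Place probes in 3-D: transformed (x, y), at local surface Z minus depth.

    The surface height under each probe is the Z of the nearest cloud point
    in XY (homogeneous-medium assumption: the optical depth below the exit
    surface equals the geometric depth).  Probes whose XY falls outside the
    cloud footprint are flagged and placed below the nearest surface point.
    An empty probe list yields a surface-only scene.
    """
    rows = []
    tree = cKDTree(surface.points[:, :2]) if surface.points.size else None
    xs, ys = surface.points[:, 0], surface.points[:, 1]
    for est in probes:
        p = np.array([est.xy_mm[0], est.xy_mm[1], 0.0])
        if transform is not None:
            p = transform.apply(p[None])[0]
        flags = list(est.depth_flags)
        if tree is None:
            raise ConfigurationError("surface cloud is empty")
        _, idx = tree.query(p[:2])
        z_surface = float(surface.points[idx, 2])
        inside = (xs.min() <= p[0] <= xs.max()) and (ys.min() <= p[1] <= ys.max())
        if not inside:
            flags.append("outside_footprint")
        depth = est.depth_mm if est.depth_mm is not None else np.nan
        rows.append(
            {
                "x_mm": p[0],
                "y_mm": p[1],
                "z_mm": z_surface - depth,
                "depth_mm": depth,
                "depth_uncertainty_mm": est.depth_uncertainty_mm,
                "flags": ";".join(flags),
            }
        )
    cols = ["x_mm", "y_mm", "z_mm", "depth_mm", "depth_uncertainty_mm", "flags"]
    return ReconstructedScene(surface, pd.DataFrame(rows, columns=cols))


# ---------------------------------------------------------------------------
# Volume-rendering reductions
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def _cube_array(cube) -> np.ndarray:
    if isinstance(cube, HyperSpectralCube):
        return cube.intensity
    if isinstance(cube, HyperDiffuseCube):
        return cube.profile
    return np.asarray(cube, float)


def project_cube(cube, axis: str = "z") -> np.ndarray:
    """Sum the cube along one axis ('z' is the spectral/radial axis)."""
    if axis not in _AXES:
        raise DomainError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return np.nansum(_cube_array(cube), axis=_AXES[axis])


def mip(cube, axis: str = "z") -> np.ndarray:
    """Maximum-intensity projection along one axis."""
    if axis not in _AXES:
        raise DomainError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return np.nanmax(_cube_array(cube), axis=_AXES[axis])


def opacity_mask(cube, threshold: float = 0.5) -> np.ndarray:
    """Transparency mask: voxels with normalized intensity >= threshold.

    The default 0.5 is a display convention for volume rendering, not an
    analysis parameter.
    """
    arr = _cube_array(cube)
    peak = np.nanmax(arr) if arr.size else 0.0
    if peak <= 0:
        return np.zeros(arr.shape, dtype=bool)
    return np.nan_to_num(arr / peak) >= threshold


# ---------------------------------------------------------------------------
# PLY point-cloud I/O
# ---------------------------------------------------------------------------


def write_point_cloud(path, cloud: SurfacePointCloud) -> None:
    """Write the cloud as ASCII PLY (fiducials appended as labelled comments)."""
    pts = cloud.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        for label, xyz in cloud.fiducials.items():
            fh.write(f"comment fiducial {label} {xyz[0]} {xyz[1]} {xyz[2]}\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x} {y} {z}\n")


def read_point_cloud(path) -> SurfacePointCloud:
    """Read an ASCII PLY point cloud written by :func:`write_point_cloud`."""
    import trimesh

    fiducials: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("comment fiducial "):
                parts = line.split()
                fiducials[parts[2]] = np.asarray(parts[3:6], dtype=float)
            if line == "end_header":
                break
    mesh = trimesh.load(str(path), process=False)
    points = np.asarray(mesh.vertices, float)
    return SurfacePointCloud(points, fiducials)
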