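"""Left-ventricular coordinate frame and raytraced wall compartmentalization.

The LV is described by a long axis (base -> apex), an anterior reference
direction fixing angle zero, and a wall model giving the transmural depth of
any point inside the myocardial shell.  All sampling operations — transmural
bands, the AHA 16-segment model, and the high-resolution 3 x 34 x 72 atlas
compartments — are radial assignments in this cylindrical frame:

* axial position ``t`` in mm from the base plane toward the apex;
* azimuth ``theta`` measured from the anterior reference, increasing in the
  AHA counterclockwise numbering direction as viewed from the apex;
* transmural depth, 0 at the endocardial and 1 at the epicardial surface.

Longitudinal layers partition [base, apex] uniformly (layer 1 = base); the 72
angular sectors are 5 degrees each with sector 1 starting at the anterior cut,
which coincides with the center of AHA segment 1.  Indices are 0-based
internally and 1-based in exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelVolume

logger = logging.getLogger("ecvatlas")

AHA_BANDS = ("subendo", "subepi")
#: fractional wall-depth limits of the two-band polar-map definition:
#: subendocardium 10-50 %, subepicardium 50-90 % of the wall.
AHA_BAND_LIMITS = (0.10, 0.50, 0.90)
ATLAS_DEPTH_NAMES = ("subendocardium", "midwall", "subepicardium")


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate LV geometry."""


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError(f"{name} must be a nonzero vector")
    return v / n


class AnalyticCapsuleShell:
    """Half-capsule myocardial shell: a cylinder closed by a hemispherical apex.

    The cylindrical barrel runs from the (open) base plane over
    ``cyl_length`` mm; beyond it the wall continues as a hemispherical cap
    centered on the axis.  Transmural depth is linear in the radial (barrel)
    or spherical (cap) distance between the endo- and epicardial surfaces.
    """

    def __init__(self, endo_radius: float, epi_radius: float, cyl_length: float):
        if not 0 < endo_radius < epi_radius:
            raise GeometryError("need 0 < endo_radius < epi_radius")
        if cyl_length <= 0:
            raise GeometryError("cyl_length must be positive")
        self.endo_radius = float(endo_radius)
        self.epi_radius = float(epi_radius)
        self.cyl_length = float(cyl_length)

    @property
    def wall_thickness(self) -> float:
        return self.epi_radius - self.endo_radius

    def surface_distance(self, t: np.ndarray, r_perp: np.ndarray) -> np.ndarray:
        """Distance from the long axis (barrel) / cap center (apex) in mm."""
        t = np.asarray(t, float)
        r_perp = np.asarray(r_perp, float)
        cap = t > self.cyl_length
        return np.where(cap, np.hypot(r_perp, np.where(cap, t - self.cyl_length, 0.0)), r_perp)

    def depth(self, points: np.ndarray, t: np.ndarray, r_perp: np.ndarray) -> np.ndarray:
        s = self.surface_distance(t, r_perp)
        return (s - self.endo_radius) / self.wall_thickness

    def contains(self, t: np.ndarray, r_perp: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        d = self.depth(None, t, r_perp)
        return (np.asarray(t) >= -tol) & (d >= -tol) & (d <= 1 + tol)


class MaskWallModel:
    """Transmural depth derived from a myocardium label mask.

    The depth of each mask voxel is ``d_endo / (d_endo + d_epi)``, where the
    two terms are Euclidean distances (respecting anisotropic spacing) to the
    cavity and to the outside.  The cavity is identified as the background
    component that does not touch the lateral/apical borders of the grid;
    this requires the grid to start at the base plane, so the open base does
    not connect cavity and exterior.  Queries outside the mask return NaN.
    """

    def __init__(self, mask: VoxelVolume):
        m = mask.values.astype(bool)
        if not m.any():
            raise GeometryError("myocardium mask is empty")
        labels, n = ndimage.label(~m)
        border = np.zeros_like(m)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, -1] = True  # apex-side face; base face (z=0) excluded
        outside_ids = np.setdiff1d(np.unique(labels[border]), [0])
        outside = np.isin(labels, outside_ids)
        cavity = (~m) & (~outside)
        if not cavity.any():
            raise GeometryError("could not identify an LV cavity in the mask")
        d_endo = ndimage.distance_transform_edt(~cavity, sampling=mask.spacing)
        d_epi = ndimage.distance_transform_edt(~outside, sampling=mask.spacing)
        depth = np.full(m.shape, np.nan)
        depth[m] = d_endo[m] / (d_endo[m] + d_epi[m])
        self._depth = VoxelVolume(depth, mask.spacing, mask.origin)

    def depth(self, points: np.ndarray, t: np.ndarray, r_perp: np.ndarray) -> np.ndarray:
        idx = self._depth.index_of(points)
        idx = np.clip(idx, 0, np.asarray(self._depth.shape) - 1)
        return self._depth.values[idx[:, 0], idx[:, 1], idx[:, 2]]


@dataclass
class LVGeometry:
    """LV coordinate frame: long axis, base/apex extent, wall model.

    Parameters
    ----------
    long_axis
        Unit vector pointing from base toward apex (normalized on init).
    base_point
        A point on the axis lying in the (open) base plane, world mm.
    axis_length
        Distance base -> apex along the axis, mm.
    anterior
        Direction perpendicular to the long axis defining azimuth 0 (the
        anterior cut, center of AHA segment 1).  Orthogonalized on init.
    wall
        Wall model supplying transmural depth (analytic shell or mask-based).
    """

    long_axis: np.ndarray
    base_point: np.ndarray
    axis_length: float
    anterior: np.ndarray
    wall: object

    def __post_init__(self) -> None:
        self.long_axis = _unit(self.long_axis, "long_axis")
        self.base_point = np.asarray(self.base_point, float)
        if self.axis_length <= 0:
            raise GeometryError("axis_length must be positive (degenerate axis)")
        a = np.asarray(self.anterior, float)
        a = a - np.dot(a, self.long_axis) * self.long_axis
        self.anterior = _unit(a, "anterior (after removing the axial component)")
        # Completes the triad; theta grows from anterior toward this vector,
        # which is the AHA counterclockwise numbering direction seen from apex.
        self.circumferential = np.cross(self.long_axis, self.anterior)

    def coordinates(self, points: np.ndarray):
        """Cylindrical LV coordinates of world points.

        Returns ``(t, theta, depth, r_perp)``: axial mm from base, azimuth in
        radians in [0, 2*pi), transmural depth fraction, and distance from
        the long axis in mm.
        """
        points = np.atleast_2d(np.asarray(points, float))
        rel = points - self.base_point
        t = rel @ self.long_axis
        u = rel - np.outer(t, self.long_axis)
        x = u @ self.anterior
        y = u @ self.circumferential
        theta = np.mod(np.arctan2(y, x), 2 * np.pi)
        r_perp = np.hypot(x, y)
        depth = self.wall.depth(points, t, r_perp)
        return t, theta, depth, r_perp


def capsule_geometry(
    lv_length: float,
    outer_diameter: float,
    wall_thickness: float,
    base_point=(0.0, 0.0, 0.0),
    long_axis=(0.0, 0.0, 1.0),
    anterior=(1.0, 0.0, 0.0),
) -> LVGeometry:
    """Analytic half-capsule LV geometry from its three defining lengths."""
    epi = outer_diameter / 2.0
    if not 0 < wall_thickness < epi:
        raise GeometryError("wall_thickness must lie in (0, outer_diameter/2)")
    if lv_length <= epi:
        raise GeometryError("lv_length must exceed the apex cap radius")
    shell = AnalyticCapsuleShell(epi - wall_thickness, epi, lv_length - epi)
    return LVGeometry(long_axis, base_point, float(lv_length), anterior, shell)


def wall_depth(point: np.ndarray, geometry: LVGeometry) -> float:
    """Transmural depth of a single point: 0 at endo-, 1 at the epicardium.

    Raises :class:`GeometryError` if the point lies outside the shell.
    """
    t, _, depth, _ = geometry.coordinates(point)
    d = float(depth[0])
    tol = 1e-9
    if not np.isfinite(d) or d < -tol or d > 1 + tol or t[0] < -tol:
        raise GeometryError(f"point {np.asarray(point).tolist()} is outside the myocardial shell")
    return min(max(d, 0.0), 1.0)


def bin_index(x: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Uniform floor binning of ``x`` in [lo, hi] into ``n`` bins.

    Values equal to the upper limit fall in the last bin; this single rule is
    shared by layer, sector, depth-band and AHA-ring assignment so that every
    partition in the package uses identical boundary semantics.
    """
    idx = np.floor((np.asarray(x, float) - lo) / (hi - lo) * n).astype(int)
    return np.clip(idx, 0, n - 1)


def sector_index(theta: np.ndarray, n_sectors: int = 72) -> np.ndarray:
    """0-based angular sector of azimuth ``theta`` (radians from anterior)."""
    return bin_index(np.mod(theta, 2 * np.pi), 0.0, 2 * np.pi, n_sectors)


def aha_segment_ids(t: np.ndarray, theta: np.ndarray, axis_length: float) -> np.ndarray:
    """1-based AHA 16-segment id for voxels at axial position t, azimuth theta.

    Basal/mid rings hold 6 segments of 60 degrees, the apical ring 4 of
    90 degrees; segment 1 (basal anterior) is centered on azimuth 0.
    """
    ring = bin_index(t, 0.0, axis_length, 3)
    deg = np.degrees(np.mod(theta, 2 * np.pi))
    six = np.floor(np.mod(deg + 30.0, 360.0) / 60.0).astype(int)
    four = np.floor(np.mod(deg + 45.0, 360.0) / 90.0).astype(int)
    seg = np.where(ring == 0, 1 + six, np.where(ring == 1, 7 + six, 13 + four))
    return seg


@dataclass
class CompartmentGrid:
    """Raytraced (depth x layer x sector) compartments with per-cell stats.

    ``mean_ecv`` holds the arithmetic mean of the *unclipped* ECV fraction of
    the voxels assigned to each cell (NaN where the cell is empty);
    ``voxel_count`` the number of contributing voxels.  Depth order is
    subendocardium -> midwall -> subepicardium; layer 1 is the base.
    """

    mean_ecv: np.ndarray  # (depth_bands, n_layers, n_sectors), fraction
    voxel_count: np.ndarray  # same shape, int
    band_limits: tuple[float, float]
    voxel_volume_mm3: float
    n_discarded_axis: int = 0

    @property
    def depth_bands(self) -> int:
        return self.mean_ecv.shape[0]

    @property
    def n_layers(self) -> int:
        return self.mean_ecv.shape[1]

    @property
    def n_sectors(self) -> int:
        return self.mean_ecv.shape[2]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table, one row per cell, 1-based indices, ECV in %."""
        d, l, s = np.meshgrid(
            np.arange(1, self.depth_bands + 1),
            np.arange(1, self.n_layers + 1),
            np.arange(1, self.n_sectors + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "depth_layer": d.ravel(),
                "layer": l.ravel(),
                "sector": s.ravel(),
                "mean_ecv_percent": 100.0 * self.mean_ecv.ravel(),
                "voxel_count": self.voxel_count.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        """RFC-4180 CSV export (CRLF line endings, '.' decimal separator)."""
        self.to_dataframe().to_csv(path, index=False, lineterminator="\r\n")


def _myocardial_points(ecv_values: np.ndarray, mask: VoxelVolume, geometry: LVGeometry):
    """LV coordinates and ECV of all mask voxels, discarding near-axis ones.

    Voxels whose distance to the long axis is below one (maximal) voxel
    spacing have an unstable azimuth and are dropped (and counted).
    """
    if ecv_values.shape != mask.shape:
        raise GeometryError(
            f"ECV grid {ecv_values.shape} does not match mask grid {mask.shape}"
        )
    idx = np.argwhere(mask.values > 0)
    if idx.size == 0:
        raise GeometryError("myocardium mask is empty")
    pts = mask.world_coordinates(idx)
    t, theta, depth, r_perp = geometry.coordinates(pts)
    keep = r_perp >= max(mask.spacing)
    n_discarded = int((~keep).sum())
    if n_discarded:
        logger.debug("discarded %d near-axis voxels with unstable azimuth", n_discarded)
    vals = ecv_values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return t[keep], theta[keep], depth[keep], vals[keep], n_discarded


def build_compartments(
    ecv,
    mask: VoxelVolume,
    geometry: LVGeometry,
    n_layers: int = 34,
    n_sectors: int = 72,
    depth_bands: int = 3,
    band_limits: tuple[float, float] = (0.10, 0.90),
) -> CompartmentGrid:
    """Collect myocardial voxels into (depth, layer, sector) compartments.

    Every mask voxel whose transmural depth lies within ``band_limits`` is
    assigned to exactly one cell: the layer partitions [base, apex]
    uniformly, the sector is the 5-degree azimuthal bin from the anterior
    cut, and the depth band divides the ``band_limits`` interval into
    ``depth_bands`` equal slices.  Cell means are taken over unclipped ECV so
    that noise averages without bias.
    """
    values = ecv.values if hasattr(ecv, "values") else np.asarray(ecv)
    t, theta, depth, vals, n_discarded = _myocardial_points(values, mask, geometry)
    lo, hi = band_limits
    in_band = (depth >= lo) & (depth <= hi) & (t >= 0) & (t <= geometry.axis_length)
    t, theta, depth, vals = t[in_band], theta[in_band], depth[in_band], vals[in_band]

    d = bin_index(depth, lo, hi, depth_bands)
    l = bin_index(t, 0.0, geometry.axis_length, n_layers)
    s = sector_index(theta, n_sectors)
    flat = (d * n_layers + l) * n_sectors + s
    ncells = depth_bands * n_layers * n_sectors
    counts = np.bincount(flat, minlength=ncells)
    sums = np.bincount(flat, weights=vals, minlength=ncells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    shape = (depth_bands, n_layers, n_sectors)
    return CompartmentGrid(
        mean_ecv=means.reshape(shape),
        voxel_count=counts.reshape(shape).astype(int),
        band_limits=tuple(band_limits),
        voxel_volume_mm3=mask.voxel_volume_mm3,
        n_discarded_axis=n_discarded,
    )


@dataclass
class AHA16Values:
    """Mean ECV and voxel count per AHA segment (1..16) and wall band.

    Band 0 is the subendocardium (10-50 % depth), band 1 the subepicardium
    (50-90 %); arrays are shaped (16, 2).
    """

    mean_ecv: np.ndarray
    voxel_count: np.ndarray
    band_limits: tuple[float, float, float] = AHA_BAND_LIMITS

    def value(self, segment: int, band: str) -> float:
        """Mean ECV fraction of a 1-based segment in band 'subendo'/'subepi'."""
        return float(self.mean_ecv[segment - 1, AHA_BANDS.index(band)])


def aha16_aggregate(ecv, mask: VoxelVolume, geometry: LVGeometry) -> AHA16Values:
    """Aggregate ECV into the AHA 16-segment model, per transmural band.

    The long axis is split into basal/mid/apical thirds; basal and mid rings
    into six 60-degree sectors, the apical ring into four 90-degree sectors,
    with segment 1 = basal anterior centered on the anterior reference.
    """
    values = ecv.values if hasattr(ecv, "values") else np.asarray(ecv)
    t, theta, depth, vals, _ = _myocardial_points(values, mask, geometry)
    lo, mid_limit, hi = AHA_BAND_LIMITS
    in_band = (depth >= lo) & (depth <= hi) & (t >= 0) & (t <= geometry.axis_length)
    t, theta, depth, vals = t[in_band], theta[in_band], depth[in_band], vals[in_band]
    seg = aha_segment_ids(t, theta, geometry.axis_length) - 1
    band = bin_index(depth, lo, hi, 2)
    flat = seg * 2 + band
    counts = np.bincount(flat, minlength=32)
    sums = np.bincount(flat, weights=vals, minlength=32)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AHA16Values(mean_ecv=means.reshape(16, 2), voxel_count=counts.reshape(16, 2).astype(int))


def atlas_cell_surface_span(
    lv_length: float, outer_diameter: float, n_layers: int = 34, n_sectors: int = 72
) -> tuple[float, float]:
    """Longitudinal and circumferential extent (mm) of one atlas cell at the
    epicardial surface of the barrel."""
    return lv_length / n_layers, np.pi * outer_diameter / n_sectors
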