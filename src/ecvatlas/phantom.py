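"""Synthetic left-ventricle iodine/ECV phantom.

The myocardium is a half-capsule shell — a cylinder of length
``lv_length - outer_diameter/2`` closed by a hemispherical apex cap, with an
open flat base — the simplest smooth shape with a well-defined long axis, an
apex, and a closed-form volume.  Ground-truth ECV is uniform at the
background value except inside user-placed focal lesions (optionally with a
hypo-enhancing MVO core).  Iodine concentration in the myocardium follows
the ECV model ``iodine = ecv * blood_iodine / (1 - hematocrit)``, with
optional additive Gaussian noise emulating photon statistics.

Voxel membership is decided by voxel-center inclusion: a voxel belongs to
the shell iff its center lies between the endo- and epicardial surfaces.
Volume oracles must use the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import VoxelVolume
from .geometry import LVGeometry, capsule_geometry


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass
class LesionSpec:
    """A focal lesion carved into the myocardial shell.

    Parameters
    ----------
    center
        Either ``(layer, sector)`` — 1-based indices into the default
        34 x 72 atlas grid — or a 3-tuple of world mm coordinates.
    angular_extent
        Full azimuthal width of the lesion in degrees.
    longitudinal_extent
        Full axial extent in mm.
    transmural_range
        ``(start, end)`` fractional wall depth covered, 0 = endocardium.
    lesion_ecv
        ECV fraction inside the lesion (scar/edema: typically 0.45-0.70).
    mvo_core
        Optional nested lesion with ECV *below* background, modelling the
        diminished perfusion of a microvascular-obstruction core; must lie
        strictly inside its parent.
    name
        Used in error messages.
    """

    center: tuple
    angular_extent: float
    longitudinal_extent: float
    transmural_range: tuple[float, float] = (0.0, 1.0)
    lesion_ecv: float = 0.55
    mvo_core: "LesionSpec | None" = None
    name: str = "lesion"

    def __post_init__(self) -> None:
        if not 0 < self.lesion_ecv <= 1:
            raise PhantomError(f"{self.name}: lesion_ecv must be in (0, 1]")
        d0, d1 = self.transmural_range
        if not (0 <= d0 < d1 <= 1):
            raise PhantomError(f"{self.name}: transmural_range must be ordered within [0, 1]")
        if self.angular_extent <= 0 or self.longitudinal_extent <= 0:
            raise PhantomError(f"{self.name}: extents must be positive")
        if len(self.center) not in (2, 3):
            raise PhantomError(f"{self.name}: center must be (layer, sector) or (x, y, z) mm")


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of the synthetic LV.

    Defaults reflect a typical adult LV imaged with spectral cardiac CT: a
    7-cm-long, 5-cm-wide shell with a 1-cm wall sampled at
    0.4 x 0.4 x 1.0 mm, background ECV 27 % (inside the normal <30 % range),
    hematocrit 0.40 L/L and a blood-pool iodine concentration of 5 mg/mL in
    the late-enhancement phase.  ``noise_sigma`` is the standard deviation of
    additive Gaussian noise on the iodine image in mg/mL.
    """

    lv_length: float = 70.0
    outer_diameter: float = 50.0
    wall_thickness: float = 10.0
    voxel_spacing: tuple[float, float, float] = (0.4, 0.4, 1.0)
    background_ecv: float = 0.27
    hematocrit: float = 0.40
    blood_iodine: float = 5.0
    noise_sigma: float = 0.0
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0
    aorta: bool = False  # cylindrical blood-pool insert for SNR tests
    aorta_radius: float = 5.0
    aorta_gap: float = 6.0  # gap between epicardium and aorta wall, mm

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness < self.outer_diameter / 2:
            raise PhantomError("wall_thickness must lie in (0, outer_diameter/2)")
        if self.lv_length <= self.outer_diameter / 2:
            raise PhantomError("lv_length must exceed the apex cap radius")
        if not 0 < self.background_ecv < 1:
            raise PhantomError("background_ecv must lie in (0, 1)")
        if not 0 < self.hematocrit < 1:
            raise PhantomError("hematocrit must lie in (0, 1)")
        if self.blood_iodine <= 0:
            raise PhantomError("blood_iodine must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel spacings must be positive")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be nonnegative")
        self.lesions = [
            l if isinstance(l, LesionSpec) else LesionSpec(**l) for l in self.lesions
        ]

    @property
    def epi_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def endo_radius(self) -> float:
        return self.epi_radius - self.wall_thickness

    def shell_volume_mm3(self) -> float:
        """Closed-form volume of the half-capsule shell."""
        r_i, r_o = self.endo_radius, self.epi_radius
        cyl = np.pi * (r_o**2 - r_i**2) * (self.lv_length - r_o)
        cap = 2.0 * np.pi / 3.0 * (r_o**3 - r_i**3)
        return float(cyl + cap)


def add_noise(volume: VoxelVolume, sigma: float, seed: int) -> VoxelVolume:
    """Additive i.i.d. Gaussian noise; deterministic under a fixed seed."""
    if sigma < 0:
        raise PhantomError("noise sigma must be nonnegative")
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    noisy = volume.values + rng.normal(0.0, sigma, size=volume.shape)
    return volume.like(noisy)


def _lesion_center(lesion: LesionSpec, spec: PhantomSpec, geometry: LVGeometry):
    """Axial position (mm) and azimuth (rad) of the lesion center."""
    if len(lesion.center) == 3:
        t, theta, _, _ = geometry.coordinates(np.asarray(lesion.center, float))
        return float(t[0]), float(theta[0])
    layer, sector = lesion.center
    if not (1 <= layer <= 34 and 1 <= sector <= 72):
        raise PhantomError(f"{lesion.name}: (layer, sector) center must be in 1..34 x 1..72")
    t = (layer - 0.5) / 34.0 * spec.lv_length
    theta = np.deg2rad((sector - 0.5) * 5.0)
    return t, theta


def _angular_distance(theta: np.ndarray, theta0: float) -> np.ndarray:
    return np.abs(np.mod(theta - theta0 + np.pi, 2 * np.pi) - np.pi)


def _lesion_region(
    lesion: LesionSpec,
    spec: PhantomSpec,
    geometry: LVGeometry,
    shell: np.ndarray,
    t: np.ndarray,
    theta: np.ndarray,
    depth: np.ndarray,
) -> np.ndarray:
    tc, thc = _lesion_center(lesion, spec, geometry)
    if not 0 <= tc <= spec.lv_length:
        raise PhantomError(f"{lesion.name}: axial center {tc:.1f} mm is outside the shell")
    d0, d1 = lesion.transmural_range
    region = (
        shell
        & (np.abs(t - tc) <= lesion.longitudinal_extent / 2.0)
        & (_angular_distance(theta, thc) <= np.deg2rad(lesion.angular_extent) / 2.0)
        & (depth >= d0)
        & (depth <= d1)
    )
    if not region.any():
        raise PhantomError(f"lesion '{lesion.name}' lies outside the myocardial shell")
    return region


def generate_phantom(spec: PhantomSpec):
    """Build the synthetic LV study.

    Returns
    -------
    iodine_volume : VoxelVolume
        Iodine concentration (mg/mL) including noise; zero outside the
        myocardium (and the optional aorta insert, which carries the
        blood-pool concentration).
    truth : dict
        ``ecv_volume`` (noise-free ECV fraction implied by the iodine
        model), ``myocardium_mask``, ``lesion_mask`` (uint8, subset of the
        myocardium), ``geometry`` (:class:`LVGeometry`), and
        ``aorta_mask`` when the insert is enabled.
    """
    dx, dy, dz = spec.voxel_spacing
    margin = 2.0
    r_o = spec.epi_radius
    x_lo, x_hi = -(r_o + margin), r_o + margin
    if spec.aorta:
        x_hi = r_o + spec.aorta_gap + 2 * spec.aorta_radius + margin
    y_lo, y_hi = -(r_o + margin), r_o + margin
    nx = int(np.ceil((x_hi - x_lo) / dx))
    ny = int(np.ceil((y_hi - y_lo) / dy))
    nz = int(np.ceil((spec.lv_length + 3.0) / dz))
    # Voxel centers: base plane coincides with z = 0, first slice center at dz/2,
    # so the grid starts exactly at the open base (required by mask-derived depth).
    origin = (x_lo + dx / 2.0, y_lo + dy / 2.0, dz / 2.0)

    xs = (origin[0] + np.arange(nx) * dx)[:, None, None]
    ys = (origin[1] + np.arange(ny) * dy)[None, :, None]
    zs = (origin[2] + np.arange(nz) * dz)[None, None, :]

    geometry = capsule_geometry(spec.lv_length, spec.outer_diameter, spec.wall_thickness)
    t = np.broadcast_to(zs, (nx, ny, nz))
    r_perp = np.broadcast_to(np.hypot(xs, ys), (nx, ny, nz))
    cap = t > geometry.wall.cyl_length
    surf = np.where(cap, np.hypot(r_perp, np.where(cap, t - geometry.wall.cyl_length, 0.0)), r_perp)
    depth = (surf - spec.endo_radius) / spec.wall_thickness
    shell = (depth >= 0.0) & (depth <= 1.0) & (t >= 0.0)
    theta = np.broadcast_to(np.mod(np.arctan2(ys, xs), 2 * np.pi), (nx, ny, nz))

    ecv = np.zeros((nx, ny, nz))
    ecv[shell] = spec.background_ecv
    lesion_mask = np.zeros((nx, ny, nz), bool)
    for lesion in spec.lesions:
        region = _lesion_region(lesion, spec, geometry, shell, t, theta, depth)
        ecv[region] = lesion.lesion_ecv
        lesion_mask |= region
        if lesion.mvo_core is not None:
            core = lesion.mvo_core
            core_region = _lesion_region(core, spec, geometry, shell, t, theta, depth)
            if not (region | core_region == region).all():
                raise PhantomError(
                    f"MVO core of lesion '{lesion.name}' is not strictly inside its parent"
                )
            ecv[core_region] = core.lesion_ecv
            lesion_mask |= core_region

    iodine = ecv * spec.blood_iodine / (1.0 - spec.hematocrit)
    truth: dict = {}
    if spec.aorta:
        ax_c = r_o + spec.aorta_gap + spec.aorta_radius
        aorta = np.broadcast_to(
            np.hypot(xs - ax_c, ys) <= spec.aorta_radius, (nx, ny, nz)
        ).copy()
        iodine = np.where(aorta, spec.blood_iodine, iodine)
        ecv = np.where(aorta, 1.0 - spec.hematocrit, ecv)
        truth["aorta_mask"] = VoxelVolume(aorta.astype(np.uint8), spec.voxel_spacing, origin)

    iodine_volume = VoxelVolume(iodine, spec.voxel_spacing, origin)
    if spec.noise_sigma > 0:
        iodine_volume = add_noise(iodine_volume, spec.noise_sigma, spec.seed)

    truth.update(
        ecv_volume=VoxelVolume(ecv, spec.voxel_spacing, origin),
        myocardium_mask=VoxelVolume(shell.astype(np.uint8), spec.voxel_spacing, origin),
        lesion_mask=VoxelVolume(lesion_mask.astype(np.uint8), spec.voxel_spacing, origin),
        geometry=geometry,
    )
    return iodine_volume, truth
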