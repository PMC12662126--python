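"""Pathologic-segment classification from ECV maps.

A myocardial segment-band (AHA segment x {subendocardium, subepicardium}) is
called pathologic if any enabled criterion fires:

* **overlay** — the segment-band contains a 6-connected cluster of voxels
  with voxelwise ECV > 45 % of at least ``overlay_min_cluster`` voxels (a
  size floor preventing single-voxel noise triggers);
* **polar**  — more than 50 % of the segment-band's voxels lie in
  *unfiltered* atlas-resolution cells (two transmural bands matching the
  polar-map definition) with mean ECV > 45 %;
* **atlas**  — more than 25 % of the segment-band's voxels lie in *filtered*
  atlas cells with ECV > 40 %, mapping the three atlas depth layers onto the
  two bands (by default the midwall contributes half its weight to each).

Visual reading of the late-enhancement images is a human criterion; it can
be supplied externally as a per-segment-band boolean vector and is merged by
OR.  All fractions are voxel-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelVolume
from .ecv import ECVVolume
from .geometry import (
    AHA_BANDS,
    GeometryError,
    LVGeometry,
    aha_segment_ids,
    bin_index,
    build_compartments,
    sector_index,
)
from .maps import AtlasMap, build_atlas


@dataclass
class ClassifyConfig:
    """Thresholds and policies of the three automatic criteria.

    ``midwall_policy`` decides how the middle atlas depth layer contributes
    to the two wall bands: ``'split'`` gives half weight to each band,
    ``'both'`` full weight to both.
    """

    overlay_threshold: float = 0.45  # ECV fraction, voxelwise
    overlay_min_cluster: int = 50  # voxels, 6-connected
    polar_threshold: float = 0.45  # ECV fraction, unfiltered cell mean
    polar_min_fraction: float = 0.50
    atlas_threshold: float = 40.0  # percent, filtered cell value
    atlas_min_fraction: float = 0.25
    midwall_policy: str = "split"
    band_limits: tuple[float, float] = (0.10, 0.90)
    enabled: tuple[str, ...] = ("overlay", "polar", "atlas")

    def __post_init__(self) -> None:
        if self.midwall_policy not in ("split", "both"):
            raise ValueError(f"midwall_policy must be 'split' or 'both', got {self.midwall_policy!r}")
        unknown = set(self.enabled) - {"overlay", "polar", "atlas"}
        if unknown:
            raise ValueError(f"unknown criteria enabled: {sorted(unknown)}")


@dataclass
class SegmentCalls:
    """Binary pathologic calls for 16 segments x 2 bands with provenance.

    ``pathologic`` is the OR of all triggered criteria; ``fired`` and
    ``fractions`` record, per criterion, which segment-bands it marked and
    its supporting voxel fraction.
    """

    pathologic: np.ndarray  # (16, 2) bool
    fired: dict[str, np.ndarray]  # criterion -> (16, 2) bool
    fractions: dict[str, np.ndarray]  # criterion -> (16, 2) float
    config: ClassifyConfig

    def triggered_criteria(self, segment: int, band: str) -> set[str]:
        """Criteria that fired for a 1-based segment and band name."""
        b = AHA_BANDS.index(band)
        return {c for c, m in self.fired.items() if m[segment - 1, b]}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for seg in range(1, 17):
            for b, band in enumerate(AHA_BANDS):
                row = {
                    "segment": seg,
                    "band": band,
                    "pathologic": int(self.pathologic[seg - 1, b]),
                    "criteria": ";".join(sorted(self.triggered_criteria(seg, band))),
                }
                for c, fr in self.fractions.items():
                    row[f"{c}_fraction"] = fr[seg - 1, b]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\r\n")


def segments_affected(calls: SegmentCalls) -> np.ndarray:
    """Per-segment involvement: OR over the two wall bands (16 booleans)."""
    return calls.pathologic.any(axis=1)


def _overlay_criterion(
    ecv_values: np.ndarray,
    mask: VoxelVolume,
    seg_vol: np.ndarray,
    band_vol: np.ndarray,
    cfg: ClassifyConfig,
):
    """Cluster-based voxelwise criterion, evaluated per segment-band."""
    supra = (ecv_values > cfg.overlay_threshold) & (mask.values > 0)
    fired = np.zeros((16, 2), bool)
    frac = np.zeros((16, 2), float)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    for seg in range(16):
        for b in range(2):
            in_sb = (seg_vol == seg + 1) & (band_vol == b)
            n_sb = int(in_sb.sum())
            if n_sb == 0:
                frac[seg, b] = np.nan
                continue
            supra_sb = supra & in_sb
            n_supra = int(supra_sb.sum())
            frac[seg, b] = n_supra / n_sb
            if n_supra >= cfg.overlay_min_cluster:
                labels, n_lab = ndimage.label(supra_sb, structure=structure)
                if n_lab and np.bincount(labels.ravel())[1:].max() >= cfg.overlay_min_cluster:
                    fired[seg, b] = True
    return fired, frac


def classify_segments(
    ecv: ECVVolume,
    mask: VoxelVolume,
    geometry: LVGeometry,
    grid=None,
    atlas: AtlasMap | None = None,
    polar=None,
    config: ClassifyConfig | None = None,
    visual_calls: np.ndarray | None = None,
) -> SegmentCalls:
    """Apply the pathologic-segment criteria to one study.

    ``grid`` (the 3-depth compartment grid) and ``atlas`` (its filtered map)
    are computed on the fly when omitted; the unfiltered two-band grid used
    by the polar criterion is always derived internally so its bands match
    the polar-map definition.  ``visual_calls`` is an optional (16, 2)
    boolean array of human overlay readings merged by OR.
    """
    cfg = config or ClassifyConfig()
    if ecv.shape != mask.shape:
        raise GeometryError(f"ECV grid {ecv.shape} does not match mask grid {mask.shape}")

    if grid is None:
        grid = build_compartments(ecv, mask, geometry, band_limits=cfg.band_limits)
    if atlas is None:
        atlas = build_atlas(grid)
    grid2 = build_compartments(
        ecv, mask, geometry, n_layers=grid.n_layers, n_sectors=grid.n_sectors,
        depth_bands=2, band_limits=cfg.band_limits,
    )

    idx = np.argwhere(mask.values > 0)
    pts = mask.world_coordinates(idx)
    t, theta, depth, r_perp = geometry.coordinates(pts)
    lo, hi = cfg.band_limits
    ok = (r_perp >= max(mask.spacing)) & (depth >= lo) & (depth <= hi) \
        & (t >= 0) & (t <= geometry.axis_length)
    idx, t, theta, depth = idx[ok], t[ok], theta[ok], depth[ok]

    seg = aha_segment_ids(t, theta, geometry.axis_length)  # 1..16
    band = bin_index(depth, lo, hi, 2)  # 0 subendo, 1 subepi
    layer = bin_index(t, 0.0, geometry.axis_length, grid.n_layers)
    sector = sector_index(theta, grid.n_sectors)
    d3 = bin_index(depth, lo, hi, 3)

    # voxel-aligned volumes of segment id and band for the overlay criterion
    seg_vol = np.zeros(mask.shape, np.int8)
    band_vol = np.full(mask.shape, -1, np.int8)
    seg_vol[idx[:, 0], idx[:, 1], idx[:, 2]] = seg
    band_vol[idx[:, 0], idx[:, 1], idx[:, 2]] = band

    fired: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {}

    if "overlay" in cfg.enabled:
        fired["overlay"], fractions["overlay"] = _overlay_criterion(
            ecv.values, mask, seg_vol, band_vol, cfg
        )

    if "polar" in cfg.enabled:
        with np.errstate(invalid="ignore"):
            cell_supra = grid2.mean_ecv > cfg.polar_threshold
        vox_supra = cell_supra[band, layer, sector]
        frac = np.zeros((16, 2), float)
        f = np.zeros((16, 2), bool)
        for s in range(16):
            for b in range(2):
                sel = (seg == s + 1) & (band == b)
                n = int(sel.sum())
                frac[s, b] = vox_supra[sel].mean() if n else np.nan
                f[s, b] = n > 0 and frac[s, b] > cfg.polar_min_fraction
        fired["polar"], fractions["polar"] = f, frac

    if "atlas" in cfg.enabled:
        with np.errstate(invalid="ignore"):
            cell_supra3 = atlas.filtered > cfg.atlas_threshold
        vox_supra3 = cell_supra3[d3, layer, sector]
        mid_w = 0.5 if cfg.midwall_policy == "split" else 1.0
        band_weights = (np.array([1.0, mid_w, 0.0]), np.array([0.0, mid_w, 1.0]))
        frac = np.zeros((16, 2), float)
        f = np.zeros((16, 2), bool)
        for s in range(16):
            in_seg = seg == s + 1
            for b in range(2):
                w = band_weights[b][d3[in_seg]]
                tot = w.sum()
                if tot == 0:
                    frac[s, b] = np.nan
                    continue
                frac[s, b] = (w * vox_supra3[in_seg]).sum() / tot
                f[s, b] = frac[s, b] > cfg.atlas_min_fraction
        fired["atlas"], fractions["atlas"] = f, frac

    pathologic = np.zeros((16, 2), bool)
    for m in fired.values():
        pathologic |= m
    if visual_calls is not None:
        visual_calls = np.asarray(visual_calls, bool)
        if visual_calls.shape != (16, 2):
            raise ValueError(f"visual_calls must have shape (16, 2), got {visual_calls.shape}")
        fired["visual"] = visual_calls
        fractions["visual"] = visual_calls.astype(float)
        pathologic |= visual_calls

    return SegmentCalls(pathologic=pathologic, fired=fired, fractions=fractions, config=cfg)
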