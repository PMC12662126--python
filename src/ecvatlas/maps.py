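"""Polar maps and atlas maps.

An *atlas map* unrolls each transmural layer of the compartment grid into a
34 (longitudinal) x 72 (angular) matrix cut open at the anterior reference,
suppresses speckle noise with 5 x 5 median filtration, and marks cells above
45/40/35 % ECV as descending-probability lesion indicators, annotated with
the volume percentage of each layer above every threshold.

The sector axis is a closed ring, so the filter wraps circularly there (the
anterior cut is arbitrary and must not influence the result); longitudinal
edges replicate.  Empty cells carry NaN and are excluded from every window's
median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap, Normalize
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import AHA16Values, ATLAS_DEPTH_NAMES, CompartmentGrid

DEFAULT_THRESHOLDS = (35.0, 40.0, 45.0)  # percent ECV, ascending

_PDF_METADATA = {"CreationDate": None, "ModDate": None}  # byte-stable output


class MapError(ValueError):
    pass


def median_filter_matrix(matrix: np.ndarray, kernel: int = 5, boundary: str = "cylinder") -> np.ndarray:
    """NaN-aware 2-D median filter for layer x sector matrices.

    ``boundary='cylinder'`` (the default, and the only policy meaningful for
    a myocardial ring) wraps the sector axis circularly and replicates the
    longitudinal edges; ``'replicate'`` replicates both.  NaN cells are
    excluded from each window; a window of only NaNs yields NaN.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2:
        raise MapError(f"expected a 2-D matrix, got shape {m.shape}")
    if kernel < 1 or kernel % 2 == 0:
        raise MapError(f"kernel must be a positive odd integer, got {kernel}")
    k = kernel // 2
    if k == 0:
        return m.copy()
    if boundary == "cylinder":
        padded = np.pad(m, ((k, k), (0, 0)), mode="edge")
        padded = np.pad(padded, ((0, 0), (k, k)), mode="wrap")
    elif boundary == "replicate":
        padded = np.pad(m, k, mode="edge")
    else:
        raise MapError(f"unknown boundary policy {boundary!r}")
    windows = sliding_window_view(padded, (kernel, kernel))
    if np.isnan(m).any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            return np.nanmedian(windows, axis=(2, 3))
    return np.median(windows, axis=(2, 3))


@dataclass
class AtlasMap:
    """Filtered, thresholded atlas-map matrices for the three wall layers.

    ``filtered`` holds the median-filtered mean-ECV matrices in percent,
    shaped (3, n_layers, n_sectors) with NaN at empty cells.  For each
    threshold t (percent) ``masks[t]`` flags cells strictly above t and
    ``volume_percent[t]`` gives, per depth layer, the percentage of the
    layer's voxels lying in supra-threshold cells (voxel-count weighted).
    """

    filtered: np.ndarray
    masks: dict[float, np.ndarray]
    volume_percent: dict[float, np.ndarray]
    thresholds: tuple[float, ...]
    kernel: int
    boundary: str
    depth_names: tuple[str, ...] = ATLAS_DEPTH_NAMES


def build_atlas(
    grid: CompartmentGrid,
    kernel: int = 5,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    boundary: str = "cylinder",
) -> AtlasMap:
    """Median-filter each depth layer of the grid and apply ECV thresholds.

    Thresholds are strict ('>') and compared in percent at full precision.
    ``volume_percent[t]`` for a layer is
    ``100 * sum(count | filtered > t) / sum(count | cell non-empty)``.
    """
    thresholds = tuple(sorted(float(t) for t in thresholds))
    filtered = np.empty_like(grid.mean_ecv)
    for d in range(grid.depth_bands):
        if grid.voxel_count[d].sum() == 0:
            raise MapError(f"depth layer {d + 1} contains no voxels")
        filtered[d] = median_filter_matrix(100.0 * grid.mean_ecv[d], kernel, boundary)
        filtered[d][grid.voxel_count[d] == 0] = np.nan
    masks, volume_percent = {}, {}
    for t in thresholds:
        with np.errstate(invalid="ignore"):
            mask = filtered > t
        masks[t] = mask
        totals = np.array(
            [grid.voxel_count[d][grid.voxel_count[d] > 0].sum() for d in range(grid.depth_bands)]
        )
        supra = np.array(
            [grid.voxel_count[d][mask[d]].sum() for d in range(grid.depth_bands)]
        )
        volume_percent[t] = 100.0 * supra / totals
    return AtlasMap(
        filtered=filtered,
        masks=masks,
        volume_percent=volume_percent,
        thresholds=thresholds,
        kernel=kernel,
        boundary=boundary,
    )


def scar_volume(atlas: AtlasMap, grid: CompartmentGrid, threshold: float) -> float:
    """Absolute supra-threshold volume in mm^3 across all depth layers."""
    threshold = float(threshold)
    if threshold not in atlas.masks:
        raise MapError(f"threshold {threshold} not among atlas thresholds {atlas.thresholds}")
    mask = atlas.masks[threshold]
    return float(grid.voxel_count[mask].sum() * grid.voxel_volume_mm3)


@dataclass
class PolarMap:
    """AHA 16-segment values plus rendering metadata (continuous color LUT)."""

    aha: AHA16Values
    cmap: str = "turbo"
    vmin: float = 0.0  # percent ECV
    vmax: float = 60.0


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_ATLAS_COLORS = ["#e8e8e8", "#ffd92f", "#fc8d32", "#d7191c"]  # <35, 35-40, 40-45, >45


def _atlas_categories(atlas: AtlasMap, depth: int) -> np.ndarray:
    """0..3 alert level per cell of one depth layer; NaN where empty."""
    f = atlas.filtered[depth]
    cat = np.zeros(f.shape, float)
    for level, t in enumerate(atlas.thresholds, start=1):
        with np.errstate(invalid="ignore"):
            cat[f > t] = level
    cat[np.isnan(f)] = np.nan
    return cat


def render_atlas(atlas: AtlasMap, out=None, dpi: int = 150):
    """Render the three stacked layer matrices (base at top of each panel).

    Cells are colored by the 3-level threshold code (>45 strongest) over a
    neutral base; each panel is annotated with its volume percentages.
    Returns the matplotlib figure; writes PDF/PNG when ``out`` is given
    (PDF timestamps are suppressed so output is byte-stable).
    """
    n_depth = atlas.filtered.shape[0]
    fig, axes = plt.subplots(n_depth, 1, figsize=(9, 2.6 * n_depth), squeeze=False)
    cmap = ListedColormap(_ATLAS_COLORS)
    cmap.set_bad("white")
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5], cmap.N)
    ts = atlas.thresholds
    for d in range(n_depth):
        ax = axes[d, 0]
        cat = np.ma.masked_invalid(_atlas_categories(atlas, d))
        ax.imshow(
            cat,
            cmap=cmap,
            norm=norm,
            origin="upper",
            interpolation="nearest",
            aspect="auto",
            extent=(0.5, cat.shape[1] + 0.5, cat.shape[0] + 0.5, 0.5),
        )
        vp = atlas.volume_percent
        label = " / ".join(f">{t:g}%: {vp[t][d]:.1f}%" for t in reversed(ts))
        name = atlas.depth_names[d] if d < len(atlas.depth_names) else f"depth {d + 1}"
        ax.set_title(f"{name} — volume {label}", fontsize=10)
        ax.set_xlabel("sector (anterior cut = 1)")
        ax.set_ylabel("layer (base = 1)")
    fig.tight_layout()
    if out is not None:
        _save(fig, out, dpi)
    return fig


_AHA_RING_SEGMENTS = ((1, 2, 3, 4, 5, 6), (7, 8, 9, 10, 11, 12), (13, 14, 15, 16))


def _segment_wedge(segment: int) -> tuple[float, float, float, float]:
    """(theta1_deg, theta2_deg, r_inner, r_outer) of a segment in the
    bullseye, display angles CCW with anterior (model azimuth 0) at top."""
    if segment <= 6:
        ring, width, phase = 0, 60.0, -30.0
        k = segment - 1
        r_in, r_out = 2.0 / 3.0, 1.0
    elif segment <= 12:
        ring, width, phase = 1, 60.0, -30.0
        k = segment - 7
        r_in, r_out = 1.0 / 3.0, 2.0 / 3.0
    else:
        ring, width, phase = 2, 90.0, -45.0
        k = segment - 13
        r_in, r_out = 0.05, 1.0 / 3.0
    theta1 = 90.0 + phase + k * width
    return theta1, theta1 + width, r_in, r_out


def render_polar(polar: PolarMap, out=None, dpi: int = 150):
    """Standard AHA bullseye, one wheel per transmural band.

    Base segments at the rim, apical ring at the center, continuous color
    scale over a fixed 0-60 % ECV range.  Returns the figure.
    """
    from matplotlib.patches import Wedge

    fig, axes = plt.subplots(1, 2, figsize=(9.5, 4.6))
    cmap = plt.get_cmap(polar.cmap).copy()
    cmap.set_bad("0.85")
    norm = Normalize(polar.vmin, polar.vmax)
    for b, (ax, band_name) in enumerate(zip(axes, ("subendocardium", "subepicardium"))):
        for seg in range(1, 17):
            t1, t2, r_in, r_out = _segment_wedge(seg)
            val = 100.0 * polar.aha.mean_ecv[seg - 1, b]
            color = cmap(norm(val)) if np.isfinite(val) else cmap.get_bad()
            ax.add_patch(
                Wedge((0, 0), r_out, t1, t2, width=r_out - r_in, facecolor=color,
                      edgecolor="white", linewidth=1.0)
            )
            mid = np.deg2rad((t1 + t2) / 2.0)
            r_mid = (r_in + r_out) / 2.0
            ax.text(r_mid * np.cos(mid), r_mid * np.sin(mid), str(seg),
                    ha="center", va="center", fontsize=8)
        ax.set_xlim(-1.05, 1.05)
        ax.set_ylim(-1.05, 1.05)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(band_name)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=axes, fraction=0.04, pad=0.02, label="ECV (%)")
    if out is not None:
        _save(fig, out, dpi)
    return fig


def _save(fig, out, dpi: int) -> None:
    out = str(out)
    if out.endswith(".pdf"):
        fig.savefig(out, dpi=dpi, metadata=_PDF_METADATA)
    else:
        fig.savefig(out, dpi=dpi)
    plt.close(fig)
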