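"""End-to-end pipeline: phantom -> ECV -> compartments -> maps -> calls -> stats.

The pipeline is driven by a YAML/dict configuration and writes every
artifact of a study analysis into one output directory:

    ecv.nii.gz, compartments.csv, atlas.pdf, polar.pdf, calls.csv,
    agreement.json, run.log  (plus the phantom volumes when simulating)

Outputs are deterministic under a fixed seed; every stage logs the
parameters it ran with.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import classify as _classify
from . import stats as _stats
from .core import VoxelVolume
from .ecv import ECVVolume, IodineStudy, compute_ecv
from .geometry import aha16_aggregate, bin_index, build_compartments
from .io import read_geometry, read_volume, write_geometry, write_volume
from .maps import PolarMap, build_atlas, render_atlas, render_polar
from .phantom import LesionSpec, PhantomSpec, generate_phantom

logger = logging.getLogger("ecvatlas")


class ConfigError(ValueError):
    pass


def load_config(config) -> dict:
    """Accept a dict, a YAML string path, or a Path and return a dict."""
    if isinstance(config, dict):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    loaded = yaml.safe_load(path.read_text())
    if not isinstance(loaded, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return loaded


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"config is missing required field '{key}'")
    return cfg[key]


def phantom_spec_from_config(cfg: dict, seed: int | None = None) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from the 'phantom' section of a config."""
    section = dict(cfg.get("phantom") or {})
    lesions = [LesionSpec(**{**l, "center": tuple(l["center"])}) for l in section.pop("lesions", [])]
    if "voxel_spacing" in section:
        section["voxel_spacing"] = tuple(section["voxel_spacing"])
    spec = PhantomSpec(
        hematocrit=_require(cfg, "hematocrit"),
        blood_iodine=_require(cfg, "blood_iodine"),
        lesions=lesions,
        seed=seed if seed is not None else cfg.get("seed", 0),
        **section,
    )
    return spec


def default_demo_config() -> dict:
    """A self-contained demonstration study: one transmural inferolateral
    lesion with noise at the level of a typical late-enhancement scan."""
    return {
        "hematocrit": 0.40,
        "blood_iodine": 5.0,
        "seed": 7,
        "phantom": {
            "noise_sigma": 1.1,
            "lesions": [
                {
                    "center": [0.0, -20.0, 35.0],
                    "angular_extent": 50.0,
                    "longitudinal_extent": 20.0,
                    "transmural_range": [0.0, 1.0],
                    "lesion_ecv": 0.55,
                    "name": "inferolateral-infarct",
                }
            ],
        },
    }


def _truth_reference_calls(truth: dict, band_limits=(0.10, 0.90)) -> np.ndarray:
    """(16, 2) ground-truth involvement from the phantom lesion mask."""
    from .geometry import aha_segment_ids

    lesion = truth["lesion_mask"]
    geometry = truth["geometry"]
    ref = np.zeros((16, 2), bool)
    idx = np.argwhere(lesion.values > 0)
    if idx.size == 0:
        return ref
    pts = lesion.world_coordinates(idx)
    t, theta, depth, r_perp = geometry.coordinates(pts)
    lo, hi = band_limits
    ok = (depth >= lo) & (depth <= hi) & (r_perp >= max(lesion.spacing))
    t, theta, depth = t[ok], theta[ok], depth[ok]
    seg = aha_segment_ids(t, theta, geometry.axis_length) - 1
    band = bin_index(depth, lo, hi, 2)
    ref[seg, band] = True
    return ref


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the full analysis described by ``config`` into ``out_dir``.

    Returns a dict mapping artifact names to file paths.  Raises
    :class:`ConfigError` for invalid configurations; stage failures
    propagate with their stage named in the log.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": out / "run.log"}
    try:
        seed = seed if seed is not None else int(cfg.get("seed", 0))
        hematocrit = float(_require(cfg, "hematocrit"))
        blood_iodine = float(_require(cfg, "blood_iodine"))
        truth = None
        if "volumes" in cfg:
            vols = cfg["volumes"]
            logger.info("stage=load volumes=%s", vols)
            iodine = read_volume(_require(vols, "iodine"))
            mask = read_volume(_require(vols, "myocardium_mask"))
            geometry = read_geometry(_require(vols, "geometry"))
        else:
            spec = phantom_spec_from_config(cfg, seed=seed)
            logger.info("stage=phantom spec=%s", spec)
            iodine, truth = generate_phantom(spec)
            mask = truth["myocardium_mask"]
            geometry = truth["geometry"]
            artifacts["iodine"] = write_volume(iodine, out / "iodine.nii.gz", np.float32)
            artifacts["myocardium_mask"] = write_volume(mask, out / "myocardium_mask.nii.gz")
            artifacts["lesion_mask"] = write_volume(
                truth["lesion_mask"], out / "lesion_mask.nii.gz"
            )
            artifacts["ecv_truth"] = write_volume(
                truth["ecv_volume"], out / "ecv_truth.nii.gz", np.float32
            )
            artifacts["geometry"] = write_geometry(geometry, out / "geometry.yaml")

        logger.info("stage=ecv hematocrit=%.3f blood_iodine=%.3f", hematocrit, blood_iodine)
        study = IodineStudy(iodine, blood_iodine, hematocrit)
        ecv = compute_ecv(study)
        artifacts["ecv"] = write_volume(ecv.as_volume(clipped=True), out / "ecv.nii.gz", np.float32)

        atlas_cfg = dict(cfg.get("atlas") or {})
        kernel = int(atlas_cfg.get("kernel", 5))
        thresholds = tuple(atlas_cfg.get("thresholds", (35.0, 40.0, 45.0)))
        logger.info("stage=compartments layers=34 sectors=72 bands=3")
        grid = build_compartments(ecv, mask, geometry)
        grid.to_csv(out / "compartments.csv")
        artifacts["compartments"] = out / "compartments.csv"

        logger.info("stage=atlas kernel=%d thresholds=%s", kernel, thresholds)
        atlas = build_atlas(grid, kernel=kernel, thresholds=thresholds)
        render_atlas(atlas, out / "atlas.pdf")
        artifacts["atlas"] = out / "atlas.pdf"

        logger.info("stage=polar")
        polar = PolarMap(aha16_aggregate(ecv, mask, geometry))
        render_polar(polar, out / "polar.pdf")
        artifacts["polar"] = out / "polar.pdf"

        clf_cfg = _classify.ClassifyConfig(**(cfg.get("classify") or {}))
        logger.info("stage=classify config=%s", clf_cfg)
        calls = _classify.classify_segments(
            ecv, mask, geometry, grid=grid, atlas=atlas, polar=polar, config=clf_cfg
        )
        calls.to_csv(out / "calls.csv")
        artifacts["calls"] = out / "calls.csv"

        logger.info("stage=agreement")
        ct16 = _classify.segments_affected(calls)
        reference = None
        ref_label = None
        if "reference_calls" in cfg:
            ref_df = read_reference_calls(cfg["reference_calls"])
            reference = ref_df
            ref_label = "external"
        elif truth is not None:
            reference = _truth_reference_calls(truth).any(axis=1)
            ref_label = "phantom-truth"
        agreement = {"reference": ref_label}
        if reference is not None:
            ref16 = np.asarray(reference, bool)
            try:
                res = _stats.cohens_kappa(ct16.astype(int), ref16.astype(int))
                agreement.update(
                    kappa=res.kappa,
                    interpretation=res.interpretation,
                    observed_agreement=res.observed_agreement,
                    expected_agreement=res.expected_agreement,
                )
            except _stats.UndefinedKappaError as exc:
                agreement.update(kappa=None, note=str(exc))
            ct_set = sorted(int(s + 1) for s in np.flatnonzero(ct16))
            ref_set = sorted(int(s + 1) for s in np.flatnonzero(ref16))
            agreement.update(
                concordance=_stats.concordance_category(ct_set, ref_set),
                ct_segments=ct_set,
                reference_segments=ref_set,
            )
        (out / "agreement.json").write_text(json.dumps(agreement, indent=2) + "\n")
        artifacts["agreement"] = out / "agreement.json"
        logger.info("pipeline complete: %d artifacts", len(artifacts))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts


def read_reference_calls(path) -> np.ndarray:
    """Read per-segment reference calls (e.g. MRI) from CSV.

    Expected columns: ``segment`` (1-16), ``band`` ('subendo', 'subepi' or
    'wall') and ``positive`` (0/1).  Returns 16 booleans (whole-wall OR).
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference calls file not found: {path}")
    df = pd.read_csv(path)
    for col in ("segment", "positive"):
        if col not in df.columns:
            raise ConfigError(f"reference calls file {path} misses column '{col}'")
    ref = np.zeros(16, bool)
    for _, row in df.iterrows():
        seg = int(row["segment"])
        if not 1 <= seg <= 16:
            raise ConfigError(f"reference calls: segment {seg} out of range 1..16")
        if int(row["positive"]):
            ref[seg - 1] = True
    return ref
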