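"""Voxelwise extracellular-volume computation from iodine maps.

ECV is the fraction of tissue volume occupied by extracellular space.  With
an extracellular contrast agent at quasi-equilibrium, the myocardial iodine
concentration relates to the blood-pool concentration through the plasma
distribution volume, giving

    ECV = (1 - hematocrit) * iodine_myocardium / iodine_blood.

ECV is stored as a fraction throughout the package and converted to percent
only for display and thresholding; values pushed outside [0, 1] by noise are
kept unclipped (compartment means would otherwise be biased) but counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import VoxelVolume

logger = logging.getLogger("ecvatlas")


class ECVError(ValueError):
    pass


@dataclass
class IodineStudy:
    """Late-enhancement iodine volume plus the quantities needed for ECV.

    ``blood_iodine`` is either a scalar blood-pool concentration (mg/mL) or
    an aortic ROI mask over ``iodine_volume`` whose mean serves as the
    denominator.  ``hematocrit`` is the volume fraction of red cells (L/L).
    """

    iodine_volume: VoxelVolume
    blood_iodine: "float | VoxelVolume"
    hematocrit: float

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise ECVError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")
        if np.isscalar(self.blood_iodine) and self.blood_iodine <= 0:
            raise ECVError("scalar blood_iodine must be positive")

    def blood_reference(self) -> float:
        """The blood-pool iodine denominator, mg/mL."""
        if np.isscalar(self.blood_iodine):
            return float(self.blood_iodine)
        roi = self.blood_iodine.values.astype(bool)
        if not roi.any():
            raise ECVError("blood-pool ROI mask is empty")
        mean = float(self.iodine_volume.values[roi].mean())
        if mean <= 0:
            raise ECVError(f"blood-pool ROI mean must be positive, got {mean:.3g}")
        return mean


@dataclass
class ECVVolume:
    """Voxelwise ECV as a fraction, with out-of-range bookkeeping.

    ``values`` are unclipped; :meth:`clipped_values` returns the display
    version limited to [0, 1].  ``n_below``/``n_above`` count voxels outside
    the physical range (noise-driven).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    n_below: int = 0
    n_above: int = 0

    @property
    def shape(self):
        return self.values.shape

    def clipped_values(self) -> np.ndarray:
        return np.clip(self.values, 0.0, 1.0)

    def as_volume(self, clipped: bool = False) -> VoxelVolume:
        vals = self.clipped_values() if clipped else self.values
        return VoxelVolume(vals, self.spacing, self.origin)


def compute_ecv(study: IodineStudy) -> ECVVolume:
    """Voxelwise ECV = (1 - hct) * iodine / blood_reference.

    NaNs in the iodine image propagate; the denominator is fixed once per
    study (scalar value or aortic-ROI mean).
    """
    blood = study.blood_reference()
    vals = (1.0 - study.hematocrit) * study.iodine_volume.values / blood
    finite = np.isfinite(vals)
    n_below = int((vals[finite] < 0).sum())
    n_above = int((vals[finite] > 1).sum())
    if n_below or n_above:
        logger.info("ECV out of [0,1]: %d below, %d above (kept unclipped)", n_below, n_above)
    vol = study.iodine_volume
    return ECVVolume(vals, vol.spacing, vol.origin, n_below=n_below, n_above=n_above)


def compute_snr(iodine_volume: VoxelVolume, aorta_roi: VoxelVolume) -> float:
    """Aortic signal-to-noise ratio: ROI mean divided by ROI std (ddof=1).

    A constant ROI (zero variance) signals infinite SNR: returns ``inf``
    with a warning rather than raising, since it is a legitimate noise-free
    limit.
    """
    roi = aorta_roi.values.astype(bool)
    vals = iodine_volume.values[roi]
    if vals.size < 2:
        raise ECVError(f"aortic ROI needs at least 2 voxels, got {vals.size}")
    std = vals.std(ddof=1)
    if std == 0:
        warnings.warn("aortic ROI has zero variance; SNR is infinite", stacklevel=2)
        return float("inf")
    return float(vals.mean() / std)
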