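"""Calibration of relative perfusion to absolute units (ml/100 g/min).

Two estimators of the arterial-blood equilibrium magnetisation M0a are
provided. The voxelwise method converts the (median-filtered, edge-corrected)
M0 image to blood M0 via the partition coefficient, with a saturation
correction when the M0 image TR is short. The reference-region method takes
the mean M0 over a conservative single-tissue ROI (ventricular CSF by
default) and corrects it for T1 recovery, optional T2 mismatch and the
tissue:blood water-density ratio to yield one global M0a. Absolute perfusion
is then 6000 * f_rel / M0a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "CalibrationConfig",
    "M0Map",
    "preprocess_m0",
    "voxelwise_m0a",
    "refregion_m0a",
    "calibrate",
    "REFERENCE_TISSUES",
]

#: literature 3 T constants per reference tissue:
#: T1 (s), T2 (ms), water density relative to blood
REFERENCE_TISSUES = {
    "csf": {"t1": 4.3, "t2": 750.0, "density": 1.15},
    "wm": {"t1": 1.0, "t2": 50.0, "density": 0.82},
    "gm": {"t1": 1.3, "t2": 100.0, "density": 0.98},
}

#: transverse relaxation time of arterial blood at 3 T (ms)
T2_BLOOD = 150.0


@dataclass
class CalibrationConfig:
    """Options for M0a estimation.

    ``tr`` is the repetition time of the M0 acquisition (s); ``te`` its echo
    time (ms), enabling the T2-mismatch correction for the reference-region
    method when given. ``t1_correction_tissue`` is the T1 assumed by the
    voxelwise short-TR saturation correction (GM reference value).
    """

    method: str = "voxelwise"
    tr: float = 6.0
    lambda_: float = 0.9
    t1_correction_tissue: float = 1.3
    ref_tissue: str = "csf"
    te: Optional[float] = None
    gain: float = 1.0
    ref_constants: dict = field(default_factory=lambda: REFERENCE_TISSUES)
    t2_blood: float = T2_BLOOD

    def __post_init__(self):
        if self.method not in ("voxelwise", "refregion"):
            raise ConfigurationError(f"unknown calibration method {self.method!r}")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.lambda_ <= 0:
            raise ConfigurationError("lambda_ must be positive")
        if self.ref_tissue not in self.ref_constants:
            raise ConfigurationError(f"unknown reference tissue {self.ref_tissue!r}")


@dataclass
class M0Map:
    """Arterial-blood M0: a voxelwise map or a single global scalar."""

    value: object  # 3D array (voxelwise) or float (refregion)
    method: str
    provenance: dict = field(default_factory=dict)

    @property
    def is_scalar(self) -> bool:
        return np.ndim(self.value) == 0


_KERNEL = np.ones((3, 3, 3), dtype=bool)


def _extrapolate(image: np.ndarray, valid: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Fill target voxels outside `valid` by iterative neighbour-mean growth."""
    out = np.where(valid, image, 0.0)
    valid = valid.copy()
    kernel = _KERNEL.astype(float)
    # each pass fills the one-voxel shell adjacent to already-valid voxels
    while not np.all(valid[target]):
        counts = ndimage.convolve(valid.astype(float), kernel, mode="constant")
        sums = ndimage.convolve(out, kernel, mode="constant")
        shell = target & ~valid & (counts > 0)
        if not shell.any():
            raise DataError("extrapolation cannot reach all masked voxels")
        out[shell] = sums[shell] / counts[shell]
        valid |= shell
    return out


def preprocess_m0(m0: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Erode, extrapolate and median-filter the M0 image within the mask.

    The brain mask is eroded by one 3x3x3 step, discarding the rim voxels
    whose intensity is inflated by CSF partial voluming at the pial boundary;
    the rim (plus a one-voxel pad, so every filter window is covered) is
    refilled by extrapolation from the interior, and a 3x3x3 median filter
    then suppresses noise. Discarding the rim before filtering prevents the
    median from spreading the contaminated values inward.
    """
    m0 = np.asarray(m0, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if np.any(m0[mask] <= 0):
        raise DataError("M0 must be positive inside the mask")
    eroded = ndimage.binary_erosion(mask, structure=_KERNEL)
    if not eroded.any():
        raise DataError(
            "brain mask erodes to empty; disable voxelwise M0 pre-processing "
            "for such small masks"
        )
    padded = ndimage.binary_dilation(mask, structure=_KERNEL)
    extended = _extrapolate(m0, eroded, padded)
    # nearest-mode padding: the extrapolated image already covers a one-voxel
    # ring around the mask, so only the array boundary needs extension
    out = ndimage.median_filter(extended, size=3, mode="nearest")
    out[~mask] = 0.0
    return out


def voxelwise_m0a(m0: np.ndarray, config: CalibrationConfig) -> M0Map:
    """Voxelwise arterial-blood M0: division by the partition coefficient,
    with a saturation correction applied only when TR < 5 s."""
    m0a = np.asarray(m0, dtype=float) / config.lambda_
    corrected = False
    if config.tr < 5.0:
        m0a = m0a / (1.0 - np.exp(-config.tr / config.t1_correction_tissue))
        corrected = True
    m0a = m0a * config.gain
    return M0Map(m0a, "voxelwise", {"tr_correction": corrected})


def refregion_m0a(
    m0: np.ndarray,
    config: CalibrationConfig,
    roi: Optional[np.ndarray] = None,
    pv_map: Optional[np.ndarray] = None,
    ventricle_mask: Optional[np.ndarray] = None,
) -> M0Map:
    """Single global arterial-blood M0 from a reference-tissue ROI.

    Either a ready boolean ``roi`` is supplied, or it is derived from a
    tissue partial-volume map: for CSF the supplied ventricle mask is
    thresholded at 0.1, binarised and eroded before masking the CSF PV map,
    which is then thresholded at 0.9; for WM the PV map is thresholded at
    0.9 with no further masking. The ROI mean is corrected for partial T1
    recovery at the reference tissue's T1, optionally for T2 mismatch, and
    converted to blood M0 via the tissue:blood water-density ratio.
    """
    m0 = np.asarray(m0, dtype=float)
    tissue = config.ref_tissue
    consts = config.ref_constants[tissue]
    if tissue == "gm":
        warnings.warn(
            "a GM reference region is not recommended due to partial volume "
            "effects", stacklevel=2,
        )
    stages = {}
    if roi is None:
        if pv_map is None:
            raise ConfigurationError(
                "refregion_m0a needs either an ROI mask or a PV map"
            )
        pv = np.asarray(pv_map, dtype=float)
        if tissue == "csf":
            if ventricle_mask is None:
                raise ConfigurationError(
                    "CSF reference region requires a ventricle mask"
                )
            vent = np.asarray(ventricle_mask, dtype=float) > 0.1
            stages["ventricle>0.1"] = int(vent.sum())
            vent = ndimage.binary_erosion(vent, structure=_KERNEL)
            stages["eroded"] = int(vent.sum())
            pv = np.where(vent, pv, 0.0)
        roi = pv > 0.9
        stages["pv>0.9"] = int(roi.sum())
    else:
        roi = np.asarray(roi, dtype=bool)
        stages["supplied"] = int(roi.sum())
    if not roi.any():
        raise DataError(
            "reference ROI empty after thresholding; surviving voxel counts "
            f"per stage: {stages}"
        )
    mean_m0 = float(m0[roi].mean())
    # partial T1 recovery of the reference tissue at this TR
    m0_ref = mean_m0 / (1.0 - np.exp(-config.tr / consts["t1"]))
    if config.te is not None:
        # undo reference-tissue T2 decay, re-apply blood T2 decay
        m0_ref = m0_ref * np.exp(config.te / consts["t2"])
        m0_ref = m0_ref * np.exp(-config.te / config.t2_blood)
    m0a = m0_ref / consts["density"] * config.gain
    if m0a <= 0:
        raise DataError("estimated M0a is non-positive")
    prov = {"n_voxels": int(roi.sum()), "stages": stages, "tissue": tissue,
            "mean_m0": mean_m0}
    return M0Map(float(m0a), "refregion", prov)


def calibrate(perfusion_rel: np.ndarray, m0map: M0Map,
              mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Absolute perfusion: 6000 * f_rel / M0a (ml/100 g/min).

    The factor 6000 converts from s^-1 (ml blood per ml tissue per second)
    to ml per 100 g per minute. Voxels with undefined M0a are set to zero.
    """
    f = np.asarray(perfusion_rel, dtype=float)
    if m0map.is_scalar:
        m0a = float(m0map.value)
        if m0a <= 0:
            raise DataError("scalar M0a must be positive")
        return 6000.0 * f / m0a
    m0a = np.asarray(m0map.value, dtype=float)
    if m0a.shape != f.shape:
        raise DataError(
            f"M0a grid {m0a.shape} does not match perfusion grid {f.shape}"
        )
    out = np.zeros_like(f)
    defined = m0a > 0
    if mask is not None:
        defined &= np.asarray(mask, dtype=bool)
    out[defined] = 6000.0 * f[defined] / m0a[defined]
    return out
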