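"""First-pass compartment model for single-volume CT perfusion.

The entire myocardium (left and right ventricular walls combined) is one
compartment.  During the first pass no contrast mass has yet left the
compartment, so average perfusion is the rate of contrast mass accumulation
normalized by tissue mass and the time-averaged aortic input concentration:

    P_ave = dM_c/dt / (M_T * C_IN)        [mL/min/g after the 60 s/min factor]

where dM_c is the whole-compartment contrast mass change between the
pre-contrast bolus-tracking frames and the single contrast-enhanced volume
scan (HU*mL), dt the integration time from contrast arrival to the volume
scan, M_T the myocardial tissue mass (g), and C_IN the average aortic input
concentration (HU) over the same window.

The voxel-wise map distributes P_ave proportionally to per-voxel
enhancement, so its masked mean reproduces P_ave exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import aif as _aif
from .errors import (
    EmptySegmentationError,
    InsufficientBaselineError,
    InvalidParameterError,
    NoEnhancementError,
    ShapeMismatchError,
    StageError,
)

__all__ = [
    "MyocardiumSample",
    "PerfusionResult",
    "baseline_myocardial_hu",
    "tissue_mass",
    "contrast_mass_change",
    "average_perfusion",
    "perfusion_map",
    "measure_study",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

#: standard myocardial tissue density, g/mL
MYOCARDIAL_DENSITY_G_PER_ML = 1.053


@dataclass(frozen=True)
class MyocardiumSample:
    """Myocardial segmentation and the scalar pre-contrast attenuation.

    The model assumes pre-contrast myocardial attenuation is spatially
    homogeneous, estimated as the spatio-temporal mean of the myocardial
    samples in the non-enhanced bolus-tracking frames.
    """

    myo_mask: np.ndarray
    voxel_volume_ml: float
    pre_contrast_hu: float = np.nan  # may be filled in later by the pipeline
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML

    def __post_init__(self):
        mask = np.asarray(self.myo_mask, dtype=bool)
        object.__setattr__(self, "myo_mask", mask)
        if self.voxel_volume_ml <= 0:
            raise InvalidParameterError("voxel volume must be positive")
        if self.density_g_per_ml <= 0:
            raise InvalidParameterError("density must be positive")
        if not mask.any():
            raise EmptySegmentationError("myocardial mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.myo_mask.sum())


@dataclass
class PerfusionResult:
    """Output of the single-volume perfusion measurement."""

    p_ave_ml_min_g: float
    m_t_g: float
    c_in_hu: float
    dmc_hu_ml: float
    dt_s: float
    voxel_map: np.ndarray = field(repr=False)
    aif_fit: "_aif.AifFit | None" = None
    t_arrival_s: float = np.nan
    mean_enhancement_hu: float = np.nan
    baseline_myo_hu: float = np.nan

    def clipped_map(self) -> np.ndarray:
        """Copy of the voxel map with negative (noise) values clipped to 0.

        The stored map retains negative values so the masked-mean identity
        with ``p_ave_ml_min_g`` holds exactly; clip only for export/display.
        """
        return np.clip(self.voxel_map, 0.0, None)

    def summary(self) -> dict:
        return {
            "p_ave_ml_min_g": self.p_ave_ml_min_g,
            "m_t_g": self.m_t_g,
            "c_in_hu": self.c_in_hu,
            "dmc_hu_ml": self.dmc_hu_ml,
            "dt_s": self.dt_s,
            "t_arrival_s": self.t_arrival_s,
            "mean_enhancement_hu": self.mean_enhancement_hu,
            "baseline_myo_hu": self.baseline_myo_hu,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def baseline_myocardial_hu(bolus, n_frames: int) -> float:
    """Pre-contrast myocardial attenuation from early tracking frames.

    Mean of the ``myo_hu`` column over the first ``n_frames`` samples of the
    bolus-tracking table (the non-enhanced frames serve as pre-contrast
    data).
    """
    myo = np.asarray(bolus["myo_hu"], dtype=float)
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if n_frames > myo.size:
        raise InsufficientBaselineError(
            f"requested {n_frames} baseline frames, only {myo.size} available")
    return float(np.mean(myo[:n_frames]))


def tissue_mass(myo_sample: MyocardiumSample) -> float:
    """Myocardial tissue mass M_T in grams.

    Product of segmented voxel count, voxel volume (mL) and tissue density
    (g/mL).
    """
    return myo_sample.n_voxels * myo_sample.voxel_volume_ml * myo_sample.density_g_per_ml


def contrast_mass_change(volume_scan: np.ndarray, myo_sample: MyocardiumSample,
                         baseline_hu: float) -> tuple[float, float]:
    """Whole-compartment contrast mass change dM_c (HU*mL).

    Returns ``(dmc, mean_enhancement)`` where ``mean_enhancement`` is the
    average myocardial enhancement above the pre-contrast baseline and
    ``dmc = mean_enhancement * n_voxels * voxel_volume_ml``.
    """
    vol = np.asarray(volume_scan, dtype=float)
    if vol.shape != myo_sample.myo_mask.shape:
        raise ShapeMismatchError(
            f"volume {vol.shape} vs mask {myo_sample.myo_mask.shape}")
    mean_enh = float(np.mean(vol[myo_sample.myo_mask])) - baseline_hu
    dmc = mean_enh * myo_sample.n_voxels * myo_sample.voxel_volume_ml
    return dmc, mean_enh


def average_perfusion(dmc_hu_ml: float, dt_s: float, m_t_g: float,
                      c_in_hu: float) -> float:
    """Whole-compartment average perfusion P_ave in mL/min/g.

    ``P_ave = 60 * (dM_c/dt) / (M_T * C_IN)``; the factor 60 converts the
    per-second rate to per-minute.
    """
    if dt_s <= 0 or m_t_g <= 0 or c_in_hu <= 0:
        raise InvalidParameterError("dt, M_T and C_IN must be positive")
    return 60.0 * (dmc_hu_ml / dt_s) / (m_t_g * c_in_hu)


def perfusion_map(volume_scan: np.ndarray, myo_sample: MyocardiumSample,
                  baseline_hu: float, p_ave: float) -> np.ndarray:
    """Voxel-wise perfusion map in mL/min/g.

    Per-voxel enhancement change is normalized by the average myocardial
    enhancement and scaled by P_ave, so the masked mean of the map equals
    P_ave exactly.  Zero outside the mask; negative noise voxels are kept.
    """
    vol = np.asarray(volume_scan, dtype=float)
    if vol.shape != myo_sample.myo_mask.shape:
        raise ShapeMismatchError(
            f"volume {vol.shape} vs mask {myo_sample.myo_mask.shape}")
    mask = myo_sample.myo_mask
    mean_enh = float(np.mean(vol[mask])) - baseline_hu
    if mean_enh <= 0:
        raise NoEnhancementError("mean myocardial enhancement is not positive")
    out = np.zeros(vol.shape, dtype=float)
    out[mask] = p_ave * (vol[mask] - baseline_hu) / mean_enh
    return out


def measure_study(bolus, volume_scan: np.ndarray, myo_mask: np.ndarray,
                  aorta_mask: np.ndarray, t_scan_s: float,
                  voxel_volume_ml: float,
                  density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
                  n_baseline_frames: int = 3,
                  arrival_epsilon_hu: float = 1.0) -> PerfusionResult:
    """Full single-volume perfusion measurement pipeline.

    Stages: gamma-variate AIF fit (tracking samples + volume-scan aortic
    point) -> contrast arrival -> C_IN over [arrival, t_scan] -> pre-contrast
    myocardial baseline -> dM_c -> P_ave -> voxel map.  Component errors are
    re-raised wrapped in :class:`~svperf.errors.StageError` with the stage
    name.

    Parameters
    ----------
    bolus : DataFrame-like with columns ``time_s``, ``aorta_hu``, ``myo_hu``
        Bolus-tracking table.
    volume_scan, myo_mask, aorta_mask : 3-D arrays
        The single contrast-enhanced volume and its segmentations.
    t_scan_s : float
        Acquisition time of the volume scan.
    voxel_volume_ml : float
        Volume of one voxel in mL.
    """
    vol = np.asarray(volume_scan, dtype=float)
    aorta = np.asarray(aorta_mask, dtype=bool)
    if not aorta.any():
        raise EmptySegmentationError("aortic mask is empty")
    if vol.shape != aorta.shape:
        raise ShapeMismatchError("volume and aortic mask shapes differ")

    myo_sample = MyocardiumSample(myo_mask=myo_mask,
                                  voxel_volume_ml=voxel_volume_ml,
                                  density_g_per_ml=density_g_per_ml)

    try:
        scan_hu = float(np.mean(vol[aorta]))
        samples = _aif.samples_from_bolus(bolus, t_scan_s, scan_hu)
        fit = _aif.fit_gamma_variate(samples)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("aif", exc) from exc

    try:
        t_arr = _aif.arrival_time(fit, epsilon_hu=arrival_epsilon_hu)
        c_in, dt = _aif.mean_input_concentration(fit, t_arr, t_scan_s)
    except Exception as exc:
        raise StageError("input-concentration", exc) from exc

    try:
        baseline = baseline_myocardial_hu(bolus, n_baseline_frames)
        m_t = tissue_mass(myo_sample)
        dmc, mean_enh = contrast_mass_change(vol, myo_sample, baseline)
        p_ave = average_perfusion(dmc, dt, m_t, c_in)
        vmap = perfusion_map(vol, myo_sample, baseline, p_ave)
    except Exception as exc:
        raise StageError("compartment-model", exc) from exc

    return PerfusionResult(p_ave_ml_min_g=p_ave, m_t_g=m_t, c_in_hu=c_in,
                           dmc_hu_ml=dmc, dt_s=dt, voxel_map=vmap,
                           aif_fit=fit, t_arrival_s=t_arr,
                           mean_enhancement_hu=mean_enh,
                           baseline_myo_hu=baseline)
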