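"""Seeded digital cardiac phantom for the single-volume acquisition.

The phantom emulates the acquisition protocol end to end: contrast
injection drives a gamma-variate aortic enhancement curve; bolus tracking
samples the descending aorta every cardiac cycle until the enhancement
rises 80 HU above baseline; the volume scan is acquired half the injection
duration plus 2 s after the trigger, near the aortic peak.  Myocardial
voxels accumulate contrast under the first-pass assumption (no contrast
leaves the compartment), so voxel enhancement at scan time is

    HU(v) = baseline_myo + (P(v)/60) * rho * AUC(t0 -> t_scan)

with P(v) the ground-truth perfusion (mL/min/g), rho the tissue density
(g/mL) and AUC the area under the aortic enhancement above baseline
(HU*s).  Geometry is an ellipsoidal left-ventricular shell (optionally a
second shell) and a cylindrical descending aorta; coronary centerlines are
laid on the epicardial surface and define the ground-truth territories.

Everything is deterministic given the seed: identical configurations give
bit-identical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import aif as _aif
from .dosimetry import DISPERSION_DELAY_S, TRIGGER_RISE_HU
from .errors import InvalidParameterError, ProtocolFailureError
from .territory import Centerline, TerritoryMap, assign_territories, write_centerlines_csv

__all__ = [
    "AifParams",
    "EllipsoidShell",
    "CylinderGeometry",
    "PhantomConfig",
    "SyntheticStudy",
    "aif_value",
    "simulate_study",
    "write_study",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AifParams(_StrictModel):
    """Gamma-variate AIF parameters: peak enhancement A (HU), shape alpha,
    time constant beta (s), arrival t0 (s)."""

    a_hu: float = 400.0
    alpha: float = 2.5
    beta_s: float = 4.0
    t0_s: float = 6.0

    @model_validator(mode="after")
    def _check(self):
        if not (self.a_hu > 0 and self.alpha > 0 and self.beta_s > 0
                and self.t0_s >= 0):
            raise ValueError("require A > 0, alpha > 0, beta > 0, t0 >= 0")
        return self


class EllipsoidShell(_StrictModel):
    """Ellipsoidal myocardial shell: voxels between the inner and outer
    ellipsoids.  Coordinates and radii in world mm, ordered (z, y, x)."""

    center_mm: tuple[float, float, float]
    outer_radii_mm: tuple[float, float, float]
    inner_radii_mm: tuple[float, float, float]

    @model_validator(mode="after")
    def _check(self):
        if not all(i < o for i, o in zip(self.inner_radii_mm, self.outer_radii_mm)):
            raise ValueError("inner radii must be smaller than outer radii")
        if min(self.inner_radii_mm) <= 0:
            raise ValueError("radii must be positive")
        return self


class CylinderGeometry(_StrictModel):
    """Descending-aorta cylinder, axis along z."""

    center_yx_mm: tuple[float, float]
    radius_mm: float = Field(gt=0)


class PhantomConfig(_StrictModel):
    """Full phantom + acquisition configuration.

    Defaults describe a swine-sized heart in a 64-voxel cube at the
    protocol's reconstruction voxel size, with rest perfusion of
    0.92 mL/min/g in all three coronary territories and the injection
    duration of a 54.3-kg animal receiving 0.5 mL/kg at 5 mL/s.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (0.50, 0.468, 0.468)  # (z, y, x)
    myo_geometry: EllipsoidShell = EllipsoidShell(
        center_mm=(16.0, 15.0, 15.0),
        outer_radii_mm=(13.0, 11.0, 11.0),
        inner_radii_mm=(8.0, 6.5, 6.5))
    rv_geometry: Optional[EllipsoidShell] = None
    aorta_geometry: CylinderGeometry = CylinderGeometry(
        center_yx_mm=(26.0, 26.0), radius_mm=2.5)
    baseline_blood_hu: float = 40.0
    baseline_myo_hu: float = 45.0
    aif_params: AifParams = AifParams()
    territory_truth: dict[str, float] = {"LAD": 0.92, "LCx": 0.92, "RCA": 0.92}
    tissue_density_g_per_ml: float = Field(default=1.053, gt=0)
    injection_duration_s: float = Field(default=5.43, ge=0)
    bolus_sampling_interval_s: float = Field(default=0.75, gt=0)
    noise_sigma_hu: float = Field(default=0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if min(self.grid_shape) < 4:
            raise ValueError("grid too small")
        if min(self.voxel_size_mm) <= 0:
            raise ValueError("voxel sizes must be positive")
        if not self.territory_truth:
            raise ValueError("territory_truth must name at least one artery")
        if any(p <= 0 for p in self.territory_truth.values()):
            raise ValueError("all ground-truth perfusion values must be positive")
        return self

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        import yaml
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class SyntheticStudy:
    """Everything the measurement pipeline consumes, plus ground truth."""

    volume_scan: np.ndarray
    t_scan_s: float
    bolus: pd.DataFrame          # columns time_s, aorta_hu, myo_hu
    myo_mask: np.ndarray
    aorta_mask: np.ndarray
    centerlines: list
    truth_perfusion_map: np.ndarray
    truth_territories: TerritoryMap
    trigger_time_s: float
    config: PhantomConfig = field(repr=False)

    def __post_init__(self):
        t = self.bolus["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("bolus times must be strictly increasing")
        if not self.t_scan_s > self.trigger_time_s:
            raise InvalidParameterError("t_scan must follow the trigger")
        on = self.truth_perfusion_map > 0
        if not np.array_equal(on, self.myo_mask.astype(bool)):
            raise InvalidParameterError(
                "truth perfusion must be positive exactly on the myocardium")

    @property
    def truth_mean_perfusion(self) -> float:
        return float(self.truth_perfusion_map[self.myo_mask.astype(bool)].mean())


def aif_value(aif_params: AifParams, baseline_blood_hu: float, t) -> float:
    """Aortic attenuation (HU) at time t under the phantom AIF."""
    return _aif.gamma_variate(t, aif_params.a_hu, aif_params.alpha,
                              aif_params.beta_s, aif_params.t0_s,
                              baseline_blood_hu)


def _config_fit(config: PhantomConfig) -> _aif.AifFit:
    """The phantom's AIF wrapped as a fit object, for closed-form AUC."""
    p = config.aif_params
    return _aif.AifFit(A=p.a_hu, alpha=p.alpha, beta=p.beta_s, t0=p.t0_s,
                       baseline_hu=config.baseline_blood_hu, rss=0.0,
                       converged=True)


def _world_grids(config: PhantomConfig):
    vz, vy, vx = config.voxel_size_mm
    nz, ny, nx = config.grid_shape
    z = np.arange(nz)[:, None, None] * vz
    y = np.arange(ny)[None, :, None] * vy
    x = np.arange(nx)[None, None, :] * vx
    return z, y, x


def _shell_mask(shell: EllipsoidShell, config: PhantomConfig) -> np.ndarray:
    z, y, x = _world_grids(config)
    cz, cy, cx = shell.center_mm

    def quad(radii):
        rz, ry, rx = radii
        return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2

    return (quad(shell.outer_radii_mm) <= 1.0) & (quad(shell.inner_radii_mm) > 1.0)


def _aorta_mask(config: PhantomConfig) -> np.ndarray:
    z, y, x = _world_grids(config)
    cy, cx = config.aorta_geometry.center_yx_mm
    r = config.aorta_geometry.radius_mm
    return np.broadcast_to((y - cy) ** 2 + (x - cx) ** 2 <= r ** 2,
                           config.grid_shape).copy()


def make_centerlines(config: PhantomConfig, n_points: int = 24) -> list:
    """Epicardial coronary centerlines, one per ground-truth artery.

    Each polyline follows the outer surface of the myocardial shell from
    base toward apex at a fixed azimuth (equally spaced around the shell,
    with a slight twist), mimicking the course of an epicardial vessel.
    """
    shell = config.myo_geometry
    cz, cy, cx = shell.center_mm
    rz, ry, rx = shell.outer_radii_mm
    arteries = list(config.territory_truth)
    extent = (np.asarray(config.grid_shape) - 1) * np.asarray(config.voxel_size_mm)
    lines = []
    for i, artery in enumerate(arteries):
        phi0 = 2 * np.pi * i / len(arteries)
        theta = np.linspace(0.15 * np.pi, 0.85 * np.pi, n_points)
        phi = phi0 + 0.3 * (theta - theta[0])
        pts = np.stack([cz + rz * np.cos(theta),
                        cy + ry * np.sin(theta) * np.cos(phi),
                        cx + rx * np.sin(theta) * np.sin(phi)], axis=1)
        pts = np.clip(pts, 0.0, extent)
        lines.append(Centerline(artery=artery, points_mm=pts))
    return lines


def simulate_study(config: PhantomConfig) -> SyntheticStudy:
    """Run the simulated acquisition and return all pipeline inputs + truth.

    Raises :class:`~svperf.errors.ProtocolFailureError` if the aortic
    enhancement never reaches the 80-HU trigger before the bolus peak
    (false triggering / protocol failure).
    """
    rng = np.random.default_rng(config.seed)
    fit = _config_fit(config)
    p = config.aif_params

    # --- geometry -------------------------------------------------------
    myo = _shell_mask(config.myo_geometry, config)
    if config.rv_geometry is not None:
        myo |= _shell_mask(config.rv_geometry, config)
    aorta = _aorta_mask(config)
    myo &= ~aorta
    if not myo.any():
        raise InvalidParameterError("phantom geometry yields an empty myocardium")

    centerlines = make_centerlines(config)
    territories = assign_territories(myo, centerlines, config.voxel_size_mm)
    truth = np.zeros(config.grid_shape, dtype=float)
    for artery, perf in config.territory_truth.items():
        truth[territories.mask_for(artery)] = perf
    mean_truth = float(truth[myo].mean())

    # --- bolus tracking -------------------------------------------------
    dt_samp = config.bolus_sampling_interval_s
    n_pre = int(np.floor(p.t0_s / dt_samp))
    if n_pre < 3:
        raise InvalidParameterError(
            "sampling interval too coarse: fewer than 3 pre-arrival frames")
    # horizon: one sample past the bolus peak; later samples only decay
    horizon = p.t0_s + p.alpha * p.beta_s + dt_samp
    times = np.arange(0.0, horizon + 1e-9, dt_samp)
    aorta_clean = np.asarray(aif_value(p, config.baseline_blood_hu, times))
    auc_to = np.array([_aif.auc(fit, 0.0, t) if t > p.t0_s else 0.0 for t in times])
    myo_clean = (config.baseline_myo_hu
                 + (mean_truth / 60.0) * config.tissue_density_g_per_ml * auc_to)
    aorta_hu = aorta_clean + rng.normal(0.0, config.noise_sigma_hu, times.size)
    myo_hu = myo_clean + rng.normal(0.0, config.noise_sigma_hu, times.size)

    threshold = config.baseline_blood_hu + TRIGGER_RISE_HU
    hit = np.nonzero(aorta_hu >= threshold)[0]
    if hit.size == 0:
        raise ProtocolFailureError(
            f"aortic enhancement never reached the {TRIGGER_RISE_HU:g}-HU "
            "trigger before the bolus peak")
    trig = int(hit[0])
    trigger_time = float(times[trig])
    bolus = pd.DataFrame({"time_s": times[:trig + 1],
                          "aorta_hu": aorta_hu[:trig + 1],
                          "myo_hu": myo_hu[:trig + 1]})

    # --- volume scan ----------------------------------------------------
    t_scan = trigger_time + config.injection_duration_s / 2.0 + DISPERSION_DELAY_S
    auc_scan = _aif.auc(fit, p.t0_s, t_scan)
    volume = np.zeros(config.grid_shape, dtype=float)
    volume[myo] = (config.baseline_myo_hu
                   + (truth[myo] / 60.0) * config.tissue_density_g_per_ml * auc_scan)
    volume[aorta] = aif_value(p, config.baseline_blood_hu, t_scan)
    if config.noise_sigma_hu > 0:
        volume += rng.normal(0.0, config.noise_sigma_hu, volume.shape)

    return SyntheticStudy(volume_scan=volume, t_scan_s=t_scan, bolus=bolus,
                          myo_mask=myo, aorta_mask=aorta,
                          centerlines=centerlines, truth_perfusion_map=truth,
                          truth_territories=territories,
                          trigger_time_s=trigger_time, config=config)


def _save_nifti(array: np.ndarray, voxel_size_mm, path) -> None:
    import nibabel as nib

    vz, vy, vx = voxel_size_mm
    affine = np.diag([vx, vy, vz, 1.0])
    # store in conventional (x, y, z) axis order
    nib.save(nib.Nifti1Image(np.ascontiguousarray(array.T).astype(np.float32),
                             affine), str(path))


def load_nifti(path) -> np.ndarray:
    """Load a NIfTI written by this package back into (z, y, x) order."""
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata()).T


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write all study artifacts to a directory; returns the file map.

    Volume, masks and truth map go to NIfTI (.nii.gz); the bolus series and
    centerlines to CSV; ground truth and protocol times to JSON.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vsz = study.config.voxel_size_mm
    files = {
        "volume": out / "volume.nii.gz",
        "myo_mask": out / "myo_mask.nii.gz",
        "aorta_mask": out / "aorta_mask.nii.gz",
        "truth_perfusion": out / "truth_perfusion.nii.gz",
        "truth_territories": out / "truth_territories.nii.gz",
        "bolus": out / "bolus.csv",
        "centerlines": out / "centerlines.csv",
        "protocol": out / "protocol.json",
    }
    _save_nifti(study.volume_scan, vsz, files["volume"])
    _save_nifti(study.myo_mask.astype(np.uint8), vsz, files["myo_mask"])
    _save_nifti(study.aorta_mask.astype(np.uint8), vsz, files["aorta_mask"])
    _save_nifti(study.truth_perfusion_map, vsz, files["truth_perfusion"])
    _save_nifti(study.truth_territories.labels.astype(np.int16), vsz,
                files["truth_territories"])
    study.bolus.to_csv(files["bolus"], index=False)
    write_centerlines_csv(study.centerlines, files["centerlines"])
    with open(files["protocol"], "w") as fh:
        json.dump({
            "trigger_time_s": study.trigger_time_s,
            "t_scan_s": study.t_scan_s,
            "injection_duration_s": study.config.injection_duration_s,
            "voxel_size_mm": list(vsz),
            "territory_truth": study.config.territory_truth,
            "territory_codes": study.truth_territories.arteries,
            "truth_mean_perfusion_ml_min_g": study.truth_mean_perfusion,
            "seed": study.config.seed,
        }, fh, indent=2)
    return {k: str(v) for k, v in files.items()}
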