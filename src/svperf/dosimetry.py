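"""Acquisition-timing and radiation-dose arithmetic.

The single-volume protocol triggers on an 80-HU rise in the descending
aorta, then waits half the contrast injection duration plus a 2-s
dispersion delay before acquiring the volume scan at approximately the
aortic peak.  Dose is summarized by the standard CT quantities: CTDI_vol,
dose-length product (DLP), size-specific dose estimate (SSDE = CTDI times a
patient-size conversion factor) and effective dose (DLP times an anatomic
conversion factor; 0.014 mSv/(mGy*cm) for chest).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "DoseRecord",
    "scan_delay",
    "effective_dose",
    "ssde",
    "trigger_threshold_hu",
    "CHEST_K_MSV_PER_MGY_CM",
    "TRIGGER_RISE_HU",
    "DISPERSION_DELAY_S",
]

#: chest DLP-to-effective-dose conversion factor, mSv/(mGy*cm)
CHEST_K_MSV_PER_MGY_CM = 0.014

#: bolus-tracking trigger: rise above baseline blood pool, HU
TRIGGER_RISE_HU = 80.0

#: fixed dispersion delay added to half the injection duration, s
DISPERSION_DELAY_S = 2.0


@dataclass(frozen=True)
class DoseRecord:
    """Dose descriptors of one acquisition."""

    ctdi_mgy: float
    dlp_mgy_cm: float
    ssde_conversion: float
    chest_k_msv_per_mgy_cm: float = CHEST_K_MSV_PER_MGY_CM

    def __post_init__(self):
        if min(self.ctdi_mgy, self.dlp_mgy_cm, self.ssde_conversion,
               self.chest_k_msv_per_mgy_cm) <= 0:
            raise InvalidParameterError("all dose quantities must be positive")

    @property
    def ssde_mgy(self) -> float:
        return ssde(self.ctdi_mgy, self.ssde_conversion)

    @property
    def effective_dose_msv(self) -> float:
        return effective_dose(self.dlp_mgy_cm, self.chest_k_msv_per_mgy_cm)


def scan_delay(injection_duration_s: float) -> float:
    """Trigger-to-scan delay: half the injection duration plus 2 s."""
    if injection_duration_s < 0:
        raise InvalidParameterError("injection duration must be non-negative")
    return injection_duration_s / 2.0 + DISPERSION_DELAY_S


def effective_dose(dlp_mgy_cm: float,
                   k_msv_per_mgy_cm: float = CHEST_K_MSV_PER_MGY_CM) -> float:
    """Effective dose in mSv: DLP times the anatomic conversion factor."""
    if dlp_mgy_cm <= 0 or k_msv_per_mgy_cm <= 0:
        raise InvalidParameterError("DLP and k must be positive")
    return dlp_mgy_cm * k_msv_per_mgy_cm


def ssde(ctdi_mgy: float, conversion_factor: float) -> float:
    """Size-specific dose estimate in mGy.

    ``CTDI_vol`` scaled by a patient-size conversion factor (AAPM-204
    style); the factor is supplied by the caller from the patient's
    effective diameter.
    """
    if ctdi_mgy <= 0 or conversion_factor <= 0:
        raise InvalidParameterError("CTDI and conversion factor must be positive")
    return ctdi_mgy * conversion_factor


def trigger_threshold_hu(baseline_blood_hu: float) -> float:
    """Absolute trigger HU for a given baseline blood pool attenuation."""
    return baseline_blood_hu + TRIGGER_RISE_HU


def injection_duration_s(weight_kg: float, dose_ml_per_kg: float = 0.5,
                         rate_ml_per_s: float = 5.0) -> float:
    """Contrast injection duration for a weight-based protocol.

    Default protocol: 0.5 mL/kg injected at 5 mL/s.
    """
    if weight_kg <= 0 or dose_ml_per_kg <= 0 or rate_ml_per_s <= 0:
        raise InvalidParameterError("weight, dose and rate must be positive")
    return weight_kg * dose_ml_per_kg / rate_ml_per_s
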