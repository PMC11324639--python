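"""Aortic input function (AIF) reconstruction from bolus-tracking data.

The single-volume acquisition records only a handful of aortic enhancement
samples: sparse bolus-tracking points on the rising edge of the bolus plus
one point from the volume scan taken near the aortic peak.  The full
enhancement curve is reconstructed by fitting a gamma-variate to these
samples; the time-averaged input concentration over the integration window
(contrast arrival to volume-scan time) then drives the compartment model.

The gamma-variate is peak-normalized,

    C(t) = baseline + A * ((t - t0) / (alpha*beta))**alpha
                        * exp(alpha - (t - t0)/beta)        for t > t0,

so that ``A`` is the peak enhancement above baseline (in HU) and the peak
occurs at ``t0 + alpha*beta``.  The area under the enhancement (above
baseline) has a closed form in the regularized lower incomplete gamma
function, used for exact integration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, special

from .errors import InvalidParameterError, NoEnhancementError

__all__ = [
    "AifSamples",
    "AifFit",
    "gamma_variate",
    "fit_gamma_variate",
    "arrival_time",
    "auc",
    "mean_input_concentration",
    "InputConcentration",
]

#: threshold above baseline used to locate pre-arrival samples and
#: initialize the fitted arrival time t0
_T0_INIT_THRESHOLD_HU = 10.0

#: optimizer bounds; sparse 4-8 point tracking data need tight, physical boxes
_ALPHA_BOUNDS = (0.1, 10.0)
_BETA_BOUNDS = (0.1, 20.0)


def gamma_variate(t, A: float, alpha: float, beta: float, t0: float,
                  baseline: float = 0.0):
    """Peak-normalized gamma-variate enhancement curve in HU.

    Parameters
    ----------
    t : float or array
        Time in seconds (>= 0).
    A : float
        Peak enhancement above baseline, HU.
    alpha : float
        Shape parameter (dimensionless, > 0).
    beta : float
        Time constant, s (> 0).
    t0 : float
        Contrast arrival time, s (>= 0); curve equals ``baseline`` for
        ``t <= t0`` and is continuous there.
    baseline : float
        Baseline blood HU.

    Returns
    -------
    float or ndarray
        Enhancement value(s); scalar in, scalar out.
    """
    params = (A, alpha, beta, t0, baseline)
    if not all(math.isfinite(p) for p in params):
        raise InvalidParameterError(f"non-finite gamma-variate parameters {params}")
    if alpha <= 0 or beta <= 0:
        raise InvalidParameterError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    tau = np.clip(t - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        # log-space evaluation avoids overflow for large alpha
        logval = alpha * np.log(tau / (alpha * beta)) + alpha - tau / beta
    out = baseline + np.where(tau > 0, A * np.exp(logval), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AifSamples:
    """Sparse aortic enhancement samples feeding the gamma-variate fit.

    ``times_s``/``hu`` are the bolus-tracking measurements in the descending
    aorta; ``scan_time_s``/``scan_hu`` is the single additional point taken
    from the segmented aorta of the volume scan near peak enhancement.
    """

    times_s: np.ndarray
    hu: np.ndarray
    scan_time_s: float
    scan_hu: float

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.hu, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "hu", y)
        if t.shape != y.shape or t.ndim != 1:
            raise InvalidParameterError("times_s and hu must be matching 1-D sequences")
        if t.size + 1 < 4:
            raise InvalidParameterError("need at least 4 samples including the scan point")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("bolus-tracking times must be strictly increasing")
        if not self.scan_time_s > t[-1]:
            raise InvalidParameterError("scan time must follow the last tracking sample")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))
                and math.isfinite(self.scan_time_s) and math.isfinite(self.scan_hu)):
            raise InvalidParameterError("samples must be finite")

    @property
    def all_times(self) -> np.ndarray:
        return np.append(self.times_s, self.scan_time_s)

    @property
    def all_hu(self) -> np.ndarray:
        return np.append(self.hu, self.scan_hu)


@dataclass(frozen=True)
class AifFit:
    """Fitted gamma-variate arterial input function."""

    A: float            # peak enhancement above baseline, HU
    alpha: float        # shape, dimensionless
    beta: float         # time constant, s
    t0: float           # contrast arrival, s
    baseline_hu: float
    rss: float          # residual sum of squares, HU^2
    converged: bool

    def __post_init__(self):
        if self.converged:
            if not (self.A > 0 and self.alpha > 0 and self.beta > 0 and self.t0 >= 0):
                raise InvalidParameterError("fitted parameters out of range")
        if self.rss < 0:
            raise InvalidParameterError("rss must be non-negative")

    def __call__(self, t):
        """Evaluate the fitted enhancement curve (HU, baseline included)."""
        return gamma_variate(t, self.A, self.alpha, self.beta, self.t0,
                             self.baseline_hu)

    @property
    def t_peak(self) -> float:
        """Time of peak enhancement, ``t0 + alpha*beta``."""
        return self.t0 + self.alpha * self.beta

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AifFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def _estimate_baseline(times: np.ndarray, hu: np.ndarray) -> tuple[float, int]:
    """Mean of pre-arrival samples and the index of the first enhanced one.

    A provisional baseline (median of the first three samples) locates the
    first sample more than 10 HU above it; all earlier samples are averaged
    for the final baseline estimate.
    """
    provisional = float(np.median(hu[:3]))
    above = np.nonzero(hu > provisional + _T0_INIT_THRESHOLD_HU)[0]
    if above.size == 0:
        raise NoEnhancementError(
            "no sample rises more than "
            f"{_T0_INIT_THRESHOLD_HU:g} HU above the pre-arrival baseline")
    first = int(above[0])
    if first == 0:
        # enhancement from the very first frame: no pre-arrival window
        return provisional, first
    return float(np.mean(hu[:first])), first


def fit_gamma_variate(samples: AifSamples) -> AifFit:
    """Fit a gamma-variate to bolus-tracking samples plus the scan point.

    Unweighted nonlinear least squares over ``(A, alpha, beta, t0)``; the
    baseline is fixed to the mean of the pre-arrival tracking samples.
    Initialization: ``t0`` from the 10-HU threshold crossing of the raw
    samples, ``alpha = 3``, ``beta`` from the peak-time guess.  The
    pre-arrival window is refined once the fitted ``t0`` is known (samples
    earlier than the fitted arrival), re-estimating the baseline and
    refitting until the window is stable: this keeps faint just-arrived
    samples below the detection threshold out of the baseline mean.

    Returns a non-converged :class:`AifFit` (``converged=False``) rather
    than raising if the optimizer fails; raises
    :class:`~svperf.errors.NoEnhancementError` when no sample is enhanced.
    """
    t = samples.all_times
    y = samples.all_hu
    baseline, first_idx = _estimate_baseline(t, y)

    t0_init = t[first_idx - 1] if first_idx > 0 else max(t[0] - 1.0, 0.0)
    peak_guess = float(t[int(np.argmax(y))])
    alpha_init = 3.0
    lower = [1e-6, _ALPHA_BOUNDS[0], _BETA_BOUNDS[0], 0.0]
    upper = [np.inf, _ALPHA_BOUNDS[1], _BETA_BOUNDS[1], samples.scan_time_s]

    def solve(baseline_val, x0):
        def residuals(p):
            A, alpha, beta, t0 = p
            return gamma_variate(t, A, alpha, beta, t0, baseline_val) - y

        res = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=5000)
        return res, float(np.sum(res.fun ** 2))

    beta_init = float(np.clip((peak_guess - t0_init) / alpha_init,
                              _BETA_BOUNDS[0] * 1.01, _BETA_BOUNDS[1] * 0.99))
    x0 = [max(float(np.max(y) - baseline), 1.0), alpha_init, beta_init,
          min(max(t0_init, 0.0), samples.scan_time_s)]
    ok = False
    A, alpha, beta, t0 = x0
    rss = np.inf
    try:
        n_pre_prev = first_idx
        for _ in range(4):
            res, rss = solve(baseline, x0)
            ok = bool(res.success)
            A, alpha, beta, t0 = (float(v) for v in res.x)
            n_pre = int(np.sum(samples.times_s < t0))
            if n_pre == n_pre_prev or n_pre == 0:
                break
            baseline = float(np.mean(samples.hu[:n_pre]))
            n_pre_prev = n_pre
            x0 = [A, alpha, beta, t0]
    except Exception:
        pass
    if not np.isfinite(rss):
        rss = float(np.sum((gamma_variate(t, A, alpha, beta, t0, baseline) - y) ** 2))
    return AifFit(A=A, alpha=alpha, beta=beta, t0=t0, baseline_hu=baseline,
                  rss=rss, converged=ok)


def arrival_time(fit: AifFit, epsilon_hu: float = 1.0) -> float:
    """Contrast arrival: where the fitted curve first inflects up.

    Operationalized as the earliest time at which the fitted enhancement
    exceeds ``epsilon_hu`` above baseline (default 1 HU).  The curve leaves
    baseline at ``t0`` with zero slope for ``alpha > 1``, so a small
    threshold is more stable than a second-derivative criterion.
    """
    if not fit.converged:
        raise InvalidParameterError("arrival time requires a converged fit")
    if epsilon_hu <= 0:
        raise InvalidParameterError("epsilon_hu must be positive")
    if epsilon_hu >= fit.A:
        # threshold above the peak: the curve never crosses it
        return fit.t_peak

    def f(tau):
        return gamma_variate(fit.t0 + tau, fit.A, fit.alpha, fit.beta,
                             fit.t0, 0.0) - epsilon_hu

    # enhancement rises monotonically on (t0, t_peak): bracket and bisect
    hi = fit.alpha * fit.beta
    lo = hi * 1e-12
    while f(lo) > 0 and lo > 1e-300:
        lo *= 1e-3
    tau_star = optimize.brentq(f, lo, hi, xtol=1e-12)
    return fit.t0 + float(tau_star)


def auc(fit: AifFit, t_start: float, t_end: float) -> float:
    """Area under the fitted enhancement curve above baseline, HU*s.

    Closed form: with tau = t - t0, the integral of
    ``A * (tau/(alpha*beta))**alpha * exp(alpha - tau/beta)`` is
    ``A * e**alpha * beta**(alpha+1) * Gamma(alpha+1) / (alpha*beta)**alpha``
    times the regularized lower incomplete gamma ``P(alpha+1, tau/beta)``
    evaluated between the window bounds.  ``t_end = inf`` is allowed.
    """
    if not t_start < t_end:
        raise InvalidParameterError("require t_start < t_end")
    a, b, A, t0 = fit.alpha, fit.beta, fit.A, fit.t0
    tau1 = max(t_start - t0, 0.0) / b
    tau2 = np.inf if math.isinf(t_end) else max(t_end - t0, 0.0) / b
    scale = A * math.exp(a) * b ** (a + 1) * special.gamma(a + 1) / (a * b) ** a
    p2 = 1.0 if math.isinf(tau2) else special.gammainc(a + 1, tau2)
    return float(scale * (p2 - special.gammainc(a + 1, tau1)))


class InputConcentration(NamedTuple):
    """Time-averaged aortic input concentration and its integration time."""

    c_in_hu: float
    dt_s: float


def mean_input_concentration(fit: AifFit, t_arrival: float,
                             t_scan: float) -> InputConcentration:
    """Average input concentration C_IN over [arrival, scan] in HU.

    C_IN = AUC(arrival, scan) / (scan - arrival).  The returned ``dt_s`` is
    the integration time of the compartment model.
    """
    if not t_arrival < t_scan:
        raise InvalidParameterError("require t_arrival < t_scan")
    dt = t_scan - t_arrival
    return InputConcentration(c_in_hu=auc(fit, t_arrival, t_scan) / dt, dt_s=dt)


def samples_from_bolus(bolus, scan_time_s: float, scan_hu: float) -> AifSamples:
    """Build :class:`AifSamples` from a bolus table with columns
    ``time_s`` and ``aorta_hu`` (a pandas DataFrame or mapping of arrays)."""
    return AifSamples(times_s=np.asarray(bolus["time_s"], dtype=float),
                      hu=np.asarray(bolus["aorta_hu"], dtype=float),
                      scan_time_s=float(scan_time_s), scan_hu=float(scan_hu))
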