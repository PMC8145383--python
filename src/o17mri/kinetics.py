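"""Kinetic-model fitting of H2(17)O excess-concentration time-courses.

Three estimators are provided, mirroring the quantification approaches in
common use:

* :func:`fit_linear` — the simplified model: CMRO2 = a / (2 alpha), with
  ``a`` the OLS slope of the inhalation-phase signal.  Valid when the
  circulation delay is negligible and inhalation is short (it is the
  restriction of the three-phase model to K_G = K_L = 0, Tc = 0).
* :func:`fit_three_phase` — bounded nonlinear least squares of the full
  analytic forward model (baseline / inhalation / washout) with fixed
  enrichment fraction alpha and circulation time Tc; fits CMRO2, K_G, K_L.
* :func:`fit_washout` — mono-exponential decay of the post-inhalation
  signal, k1 * exp(-k_washout t) + k2; k_washout indexes cerebral blood
  flow.

All fits act on excess (baseline-subtracted) concentration and are
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .protocol import (
    CBF_CONVERSION_FACTOR_RAT,
    S_PER_MIN,
    AcquisitionProtocol,
    KineticParams,
)
from .synthetic import VoxelTimeCourse, excess_concentration

__all__ = [
    "LinearFitResult",
    "ThreePhaseFitResult",
    "WashoutFitResult",
    "fit_linear",
    "fit_three_phase",
    "fit_washout",
    "cbf_absolute",
]


@dataclass
class LinearFitResult:
    slope_a: float  # umol/g/min
    cmro2: float  # umol/g/min; = slope_a / (2 alpha)
    slope_se: float
    cmro2_se: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class ThreePhaseFitResult:
    params: KineticParams
    alpha: float
    tc: float
    se: dict[str, float]
    residual_ss: float
    converged: bool
    degenerate: bool = False
    message: str = ""


@dataclass
class WashoutFitResult:
    k1: float  # umol/g
    k2: float  # umol/g
    k_washout: float  # min^-1
    se: dict[str, float]
    residual_ss: float
    converged: bool
    degenerate: bool = False

    @property
    def cbf_index(self) -> float:
        """k_washout itself, used as a relative CBF index."""
        return self.k_washout


def _get_protocol(
    curve: VoxelTimeCourse, protocol: AcquisitionProtocol | None
) -> AcquisitionProtocol:
    protocol = protocol or curve.protocol
    if protocol is None:
        raise ValueError("an AcquisitionProtocol is required (curve carries none)")
    return protocol


def fit_linear(
    curve: VoxelTimeCourse,
    alpha: float,
    protocol: AcquisitionProtocol | None = None,
) -> LinearFitResult:
    """OLS fit of the inhalation-phase slope; CMRO2 = slope / (2 alpha).

    Uses the frames whose midpoints fall inside the nominal (undelayed)
    inhalation window [t_baseline, t_baseline + t_inhale], i.e. the fit is
    over the entire inhalation period.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    protocol = _get_protocol(curve, protocol)
    lo = protocol.t_baseline
    hi = protocol.t_baseline + protocol.t_inhale
    mask = (curve.t_s >= lo) & (curve.t_s <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 frames inside the inhalation window")
    t_min = curve.t_s[mask] / S_PER_MIN
    y = curve.excess[mask]
    res = stats.linregress(t_min, y)
    return LinearFitResult(
        slope_a=float(res.slope),
        cmro2=float(res.slope) / (2.0 * alpha),
        slope_se=float(res.stderr),
        cmro2_se=float(res.stderr) / (2.0 * alpha),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(mask.sum()),
    )


def _lsq_se(res, n: int, p: int) -> np.ndarray:
    """Parameter SEs from the Jacobian at the solution."""
    if n <= p:
        return np.full(p, np.nan)
    sigma2 = 2.0 * res.cost / (n - p)
    try:
        cov = sigma2 * np.linalg.pinv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(p, np.nan)


def fit_three_phase(
    curve: VoxelTimeCourse,
    alpha: float,
    tc: float,
    init: KineticParams | None = None,
    protocol: AcquisitionProtocol | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> ThreePhaseFitResult:
    """Fit (CMRO2, K_G, K_L) of the three-phase model; alpha and Tc fixed.

    Bounded (>= 0) trust-region least squares over all frames of the excess
    curve.  Default initialization: CMRO2 from the linear fit, K_L from the
    washout fit, K_G = K_L; a small number of multiplicatively jittered
    restarts guards against local minima (jitter stream fixed by ``seed``).
    Non-convergence is flagged and the best-so-far solution returned.
    """
    protocol = _get_protocol(curve, protocol)
    fit_protocol = protocol.with_(alpha=alpha, tc=tc)
    t, y = curve.t_s, curve.excess

    if np.max(np.abs(y)) < 1e-12:
        return ThreePhaseFitResult(
            params=KineticParams(0.0, 0.0, 0.0),
            alpha=alpha,
            tc=tc,
            se={"cmro2": np.nan, "k_g": np.nan, "k_l": np.nan},
            residual_ss=0.0,
            converged=True,
            degenerate=True,
            message="all-zero curve: parameters unidentifiable",
        )

    if init is None:
        try:
            cmro2_0 = max(fit_linear(curve, alpha, protocol).cmro2, 1e-3)
        except ValueError:
            cmro2_0 = 1.0
        try:
            wres = fit_washout(curve, protocol)
            k_l0 = wres.k_washout if not wres.degenerate else 0.3
        except ValueError:
            k_l0 = 0.3
        k_l0 = min(max(k_l0, 1e-3), 10.0)
        init = KineticParams(cmro2_0, k_l0, k_l0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = KineticParams(*np.clip(theta, 0.0, None))
        return excess_concentration(t, params, fit_protocol) - y

    rng = np.random.default_rng(seed)
    x0 = init.as_array()
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0 * rng.lognormal(0.0, 0.3, size=3))

    best = None
    for start in starts:
        res = optimize.least_squares(
            residuals,
            np.clip(start, 1e-6, None),
            bounds=(0.0, np.inf),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res

    se = _lsq_se(best, n=t.size, p=3)
    return ThreePhaseFitResult(
        params=KineticParams(*best.x),
        alpha=alpha,
        tc=tc,
        se={"cmro2": float(se[0]), "k_g": float(se[1]), "k_l": float(se[2])},
        residual_ss=float(2.0 * best.cost),
        converged=bool(best.status > 0),
        message=str(best.message),
    )


def fit_washout(
    curve: VoxelTimeCourse,
    protocol: AcquisitionProtocol | None = None,
) -> WashoutFitResult:
    """Mono-exponential fit of the washout phase: k1 exp(-k_washout t') + k2.

    ``t'`` is time since the nominal end of inhalation, in minutes.
    Initialization: k2 = mean of the last 5 frames, k1 = first washout
    frame minus k2, k_washout = 0.3 min^-1.  A flat curve is flagged
    degenerate (k1 ~ 0 makes k_washout unidentifiable).
    """
    protocol = _get_protocol(curve, protocol)
    t_end = protocol.t_baseline + protocol.t_inhale
    mask = curve.t_s > t_end
    if mask.sum() < 5:
        raise ValueError("need at least 5 frames in the washout phase")
    t_min = (curve.t_s[mask] - t_end) / S_PER_MIN
    y = curve.excess[mask]

    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return WashoutFitResult(
            k1=0.0,
            k2=float(np.mean(y)),
            k_washout=np.nan,
            se={},
            residual_ss=0.0,
            converged=True,
            degenerate=True,
        )

    k2_0 = float(np.mean(y[-5:]))
    k1_0 = float(y[0] - k2_0)
    x0 = np.array([k1_0 if k1_0 != 0 else np.ptp(y), k2_0, 0.3])

    def residuals(theta: np.ndarray) -> np.ndarray:
        k1, k2, kw = theta
        return k1 * np.exp(-kw * t_min) + k2 - y

    res = optimize.least_squares(
        residuals,
        x0,
        bounds=([-np.inf, -np.inf, 0.0], np.inf),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    se = _lsq_se(res, n=t_min.size, p=3)
    degenerate = abs(res.x[0]) < 1e-10 or res.x[2] <= 0
    return WashoutFitResult(
        k1=float(res.x[0]),
        k2=float(res.x[1]),
        k_washout=float(res.x[2]),
        se={"k1": float(se[0]), "k2": float(se[1]), "k_washout": float(se[2])},
        residual_ss=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        degenerate=degenerate,
    )


def cbf_absolute(
    res: WashoutFitResult, factor: float = CBF_CONVERSION_FACTOR_RAT
) -> float:
    """Absolute CBF estimate, factor x k_washout (min^-1 scale).

    The default factor 1.86 was calibrated in rats; for other species it
    is an uncalibrated convenience scale.
    """
    if res.degenerate or not np.isfinite(res.k_washout):
        raise ValueError("cannot convert a degenerate washout fit")
    return factor * res.k_washout
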