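"""Synthetic H2(17)O time-course, image-series and cohort generation.

The forward model is the three-phase kinetic description of the excess
(above natural abundance) H2(17)O concentration M(t) in a brain voxel
during a 17O2 inhalation experiment:

    dM/dt = 2 * CMRO2 * A(t) - K_L * M(t) + K_G * B(t)

with A(t) the arterial 17O2 enrichment input and B(t) the body-water
labeled-water input.  A(t) is modelled as a rectangle at level alpha,
delayed by the circulation time Tc; B(t) as a linear ramp during the same
delayed window that plateaus afterwards (the body water pool is large
compared to the washout duration).  Both inputs are proportional to alpha,
so a curve depends on its parameters only through (alpha*CMRO2, alpha*K_G,
K_L); this is what makes enrichment-fraction rescaling of fits exact.

The ODE is linear with piecewise-polynomial forcing and is solved
analytically phase by phase; frames sample the solution at their midpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import (
    D_BRAIN,
    S_PER_MIN,
    AcquisitionProtocol,
    GroupSpec,
    KineticParams,
    NoiseSpec,
)

__all__ = [
    "VoxelTimeCourse",
    "arterial_input",
    "body_water_input",
    "excess_concentration",
    "simulate_timecourse",
    "add_noise",
    "make_image_series",
    "Subject",
    "make_group_dataset",
    "cohort_to_frame",
    "save_cohort_csv",
    "load_cohort_csv",
]


@dataclass
class VoxelTimeCourse:
    """A sampled H2(17)O concentration time-course for one voxel or ROI.

    ``excess`` is the concentration above natural abundance (umol/g
    tissue); ``total``, when present, is ``D + excess``.
    """

    t_s: np.ndarray
    excess: np.ndarray
    total: np.ndarray | None = None
    phase: np.ndarray | None = None
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.excess = np.asarray(self.excess, dtype=float)
        if self.t_s.shape != self.excess.shape:
            raise ValueError("t_s and excess must have the same shape")

    @property
    def t_min(self) -> np.ndarray:
        return self.t_s / S_PER_MIN


def arterial_input(t: float | np.ndarray, protocol: AcquisitionProtocol) -> np.ndarray:
    """Fraction of arterial 17O2 in excess of natural abundance, A(t).

    Zero before ``t_baseline + tc``, equal to the enrichment fraction
    ``alpha`` during the Tc-delayed inhalation window, zero afterwards
    (blood saturation taken as 100%).
    """
    t = np.asarray(t, dtype=float)
    start = protocol.t_baseline + protocol.tc
    stop = start + protocol.t_inhale
    return np.where((t >= start) & (t < stop), protocol.alpha, 0.0)


def body_water_input(t: float | np.ndarray, protocol: AcquisitionProtocol) -> np.ndarray:
    """Relative amount of labeled water in blood, B(t), in alpha*minutes.

    Ramps linearly from zero over the delayed inhalation window (the body
    produces labeled water at a rate proportional to alpha while labeled
    gas is breathed) and stays constant afterwards.  The absolute scale of
    body production is unknown; it is absorbed into the fitted K_G.
    """
    t = np.asarray(t, dtype=float)
    start = protocol.t_baseline + protocol.tc
    ramp_min = np.clip((t - start) / S_PER_MIN, 0.0, protocol.t_inhale / S_PER_MIN)
    return protocol.alpha * ramp_min


def excess_concentration(
    t_s: np.ndarray,
    params: KineticParams,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Analytic solution M(t) of the three-phase model at times ``t_s`` (s).

    Piecewise solution of the linear ODE with M = 0 during baseline.
    During the delayed inhalation window (tau = minutes since window
    start), with c = 2*CMRO2*alpha and g = K_G*alpha:

        M(tau) = c * phi1(tau) + g * phi2(tau),
        phi1 = (1 - exp(-K_L tau)) / K_L,   phi2 = (tau - phi1) / K_L,

    which reduces to M = c*tau + g*tau^2/2 when K_L = 0.  After the window
    M relaxes exponentially at rate K_L toward the recirculation plateau
    K_G * alpha * t_inhale(min) / K_L (or grows linearly when K_L = 0).
    """
    t_s = np.asarray(t_s, dtype=float)
    alpha, tc = protocol.alpha, protocol.tc
    start = protocol.t_baseline + tc
    stop = start + protocol.t_inhale
    t_in_min = protocol.t_inhale / S_PER_MIN

    c = 2.0 * params.cmro2 * alpha
    g = params.k_g * alpha
    k_l = params.k_l

    # minutes since window start, clipped to the window
    tau = np.clip((t_s - start) / S_PER_MIN, 0.0, t_in_min)
    # minutes since window end
    tau2 = np.maximum((t_s - stop) / S_PER_MIN, 0.0)

    # below ~1e-10 min^-1 the loss term is numerically invisible over the
    # scan; use the K_L = 0 polynomial limit to avoid 1/K_L blow-up
    if k_l < 1e-10:
        m_window = c * tau + 0.5 * g * tau**2
        m_end = c * t_in_min + 0.5 * g * t_in_min**2
        m = np.where(t_s <= stop, m_window, m_end + g * t_in_min * tau2)
    else:
        phi1 = -np.expm1(-k_l * tau) / k_l
        phi2 = (tau - phi1) / k_l
        m_window = c * phi1 + g * phi2
        phi1_end = -np.expm1(-k_l * t_in_min) / k_l
        m_end = c * phi1_end + g * (t_in_min - phi1_end) / k_l
        m_inf = g * t_in_min / k_l
        m = np.where(
            t_s <= stop,
            m_window,
            m_inf + (m_end - m_inf) * np.exp(-k_l * tau2),
        )
    return m


def simulate_timecourse(
    params: KineticParams, protocol: AcquisitionProtocol
) -> VoxelTimeCourse:
    """Noiseless excess-concentration time-course at frame midpoints."""
    t = protocol.frame_times()
    excess = excess_concentration(t, params, protocol)
    return VoxelTimeCourse(
        t_s=t,
        excess=excess,
        total=D_BRAIN + excess,
        phase=protocol.phase_of(t),
        protocol=protocol,
    )


def add_noise(curve: VoxelTimeCourse, noise: NoiseSpec) -> VoxelTimeCourse:
    """Add i.i.d. per-frame noise; bit-reproducible under a fixed seed."""
    if noise.sigma == 0.0:
        excess = curve.excess.copy()
    else:
        rng = np.random.default_rng(noise.seed)
        if noise.distribution == "gaussian":
            excess = curve.excess + noise.sigma * rng.standard_normal(curve.excess.shape)
        elif noise.distribution == "rician":
            total = D_BRAIN + curve.excess
            re = total + noise.sigma * rng.standard_normal(total.shape)
            im = noise.sigma * rng.standard_normal(total.shape)
            excess = np.hypot(re, im) - D_BRAIN
        else:  # pragma: no cover - guarded by NoiseSpec
            raise ValueError(f"unknown noise distribution {noise.distribution!r}")
    return VoxelTimeCourse(
        t_s=curve.t_s.copy(),
        excess=excess,
        total=D_BRAIN + excess,
        phase=None if curve.phase is None else curve.phase.copy(),
        protocol=curve.protocol,
    )


def make_image_series(
    mask: np.ndarray,
    param_map: KineticParams | dict[str, np.ndarray],
    protocol: AcquisitionProtocol,
    noise: NoiseSpec | None = None,
    fov_mm: Sequence[float] = (48.0, 48.0, 48.0),
):
    """Build a 4D magnitude image series from a per-voxel parameter map.

    Every in-mask voxel carries the baseline concentration D plus its
    simulated excess curve; out-of-mask voxels carry noise only.  The
    parameter map is either one :class:`KineticParams` broadcast over the
    mask or a dict of arrays ``{"cmro2", "k_g", "k_l"}`` congruent with it.
    """
    from .recon import ImageSeries4D  # local import to avoid a cycle

    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D array")
    if isinstance(param_map, KineticParams):
        param_map = {
            "cmro2": np.full(mask.shape, param_map.cmro2),
            "k_g": np.full(mask.shape, param_map.k_g),
            "k_l": np.full(mask.shape, param_map.k_l),
        }
    for key in ("cmro2", "k_g", "k_l"):
        if param_map[key].shape != mask.shape:
            raise ValueError(f"param_map[{key!r}] shape does not match mask")

    t = protocol.frame_times()
    data = np.zeros(mask.shape + (t.size,), dtype=float)
    for idx in np.argwhere(mask):
        i, j, k = idx
        params = KineticParams(
            cmro2=float(param_map["cmro2"][i, j, k]),
            k_g=float(param_map["k_g"][i, j, k]),
            k_l=float(param_map["k_l"][i, j, k]),
        )
        data[i, j, k] = D_BRAIN + excess_concentration(t, params, protocol)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + noise.sigma * rng.standard_normal(data.shape)
    return ImageSeries4D(
        data=data,
        fov_mm=tuple(float(f) for f in fov_mm),
        frame_dt=protocol.frame_dt,
        domain="image_magnitude",
    )


@dataclass
class Subject:
    """One synthetic animal: its group, true parameters and measured curve."""

    subject_id: str
    group: str
    true_params: KineticParams
    curve: VoxelTimeCourse


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at 0 by rejection (sd << mean in practice)."""
    if sd == 0.0:
        return mean
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if v >= 0.0:
            return float(v)
    raise RuntimeError("truncated-normal rejection sampling failed")


def make_group_dataset(
    groups: Sequence[GroupSpec],
    protocol: AcquisitionProtocol,
    noise: NoiseSpec,
    seed: int | None = None,
) -> list[Subject]:
    """Generate a labeled cohort: one noisy curve per subject.

    Per-subject parameters are drawn from the group distribution (normal
    truncated at 0).  The stream is fully reproducible: ``seed`` (defaults
    to ``noise.seed``) drives both parameter draws and per-subject noise.
    """
    if len(groups) == 0:
        raise ValueError("at least one group is required")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    cohort: list[Subject] = []
    for spec in groups:
        for i in range(spec.n_subjects):
            params = KineticParams(
                cmro2=_draw_truncated(rng, spec.params_mean.cmro2, spec.params_sd.cmro2),
                k_g=_draw_truncated(rng, spec.params_mean.k_g, spec.params_sd.k_g),
                k_l=_draw_truncated(rng, spec.params_mean.k_l, spec.params_sd.k_l),
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            curve = add_noise(
                simulate_timecourse(params, protocol),
                NoiseSpec(noise.sigma, noise.distribution, sub_seed),
            )
            cohort.append(
                Subject(
                    subject_id=f"{spec.label}-{i + 1:02d}",
                    group=spec.label,
                    true_params=params,
                    curve=curve,
                )
            )
    return cohort


def cohort_to_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    """Long-format table: subject_id, group, t_s, conc_umol_per_g (excess)."""
    rows = []
    for sub in cohort:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sub.subject_id,
                    "group": sub.group,
                    "t_s": sub.curve.t_s,
                    "conc_umol_per_g": sub.curve.excess,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def save_cohort_csv(
    cohort: Sequence[Subject],
    path: str | Path,
    config: dict | None = None,
) -> None:
    """Write the cohort as CSV; optionally a JSON sidecar with the config."""
    path = Path(path)
    cohort_to_frame(cohort).to_csv(path, index=False)
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(config, indent=2))


def load_cohort_csv(
    path: str | Path, protocol: AcquisitionProtocol | None = None
) -> list[Subject]:
    """Read a cohort CSV written by :func:`save_cohort_csv`."""
    df = pd.read_csv(path)
    cohort = []
    for sid, sub_df in df.groupby("subject_id", sort=False):
        t = sub_df["t_s"].to_numpy()
        curve = VoxelTimeCourse(
            t_s=t,
            excess=sub_df["conc_umol_per_g"].to_numpy(),
            phase=None if protocol is None else protocol.phase_of(t),
            protocol=protocol,
        )
        cohort.append(
            Subject(
                subject_id=str(sid),
                group=str(sub_df["group"].iloc[0]),
                true_params=None,  # unknown for loaded data
                curve=curve,
            )
        )
    return cohort
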