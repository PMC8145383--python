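"""Acquisition protocol, kinetic parameters and physical constants.

Time is carried in seconds at the API boundary of the acquisition protocol
(scanner frames, phase durations); kinetic rate constants are expressed in
min^-1 and CMRO2 in umol O2 / g tissue / min, the units the field reports.
All second<->minute conversions are centralized here (:data:`S_PER_MIN`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

S_PER_MIN = 60.0

#: Natural abundance of H2(17)O in water, umol per g of water.
NAT_ABUNDANCE_WATER = 20.35
#: Water/brain-tissue partition coefficient (g water per g tissue).
BETA_BRAIN = 0.79
#: Baseline H2(17)O concentration of brain tissue at natural abundance,
#: umol per g of tissue (operative literature value of the product
#: NAT_ABUNDANCE_WATER * BETA_BRAIN).
D_BRAIN = 16.07

#: Empirical k_washout -> absolute CBF conversion factor, calibrated in rats.
#: Exposed for convenience; uncalibrated for mice.
CBF_CONVERSION_FACTOR_RAT = 1.86


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of a 17O2 inhalation experiment.

    The experiment has three phases: baseline breathing of unlabeled O2,
    inhalation of 17O-enriched O2, and washout.  One image frame is acquired
    every ``frame_dt`` seconds; each frame is attributed to its midpoint
    time ``t_k = (k + 1/2) * frame_dt``.

    Parameters
    ----------
    t_baseline, t_inhale, t_washout : float
        Phase durations in seconds (defaults: 5 min / 200 s / 15 min).
    frame_dt : float
        Frame duration in seconds (default 18.2 s).
    alpha : float
        17O enrichment fraction of the delivered gas, in (0, 1].
    tc : float
        Blood circulation time in seconds: the delay between the start of
        inhalation and availability of labeled oxygen to the tissue.
    """

    t_baseline: float = 300.0
    t_inhale: float = 200.0
    t_washout: float = 900.0
    frame_dt: float = 18.2
    alpha: float = 0.7
    tc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_baseline", "t_inhale", "t_washout", "frame_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tc < 0:
            raise ValueError("tc must be >= 0")
        if self.tc >= self.t_inhale:
            raise ValueError("tc must be smaller than t_inhale")

    @property
    def total_duration(self) -> float:
        """Total scan time in seconds."""
        return self.t_baseline + self.t_inhale + self.t_washout

    @property
    def n_frames(self) -> int:
        """Number of whole frames covering baseline + inhalation + washout."""
        return int(np.floor(self.total_duration / self.frame_dt))

    def frame_times(self) -> np.ndarray:
        """Frame midpoint times in seconds."""
        k = np.arange(self.n_frames)
        return (k + 0.5) * self.frame_dt

    def phase_of(self, t_s: np.ndarray) -> np.ndarray:
        """Nominal phase label ('baseline'/'inhalation'/'washout') per time."""
        t_s = np.asarray(t_s, dtype=float)
        out = np.full(t_s.shape, "inhalation", dtype=object)
        out[t_s < self.t_baseline] = "baseline"
        out[t_s >= self.t_baseline + self.t_inhale] = "washout"
        return out.astype(str)

    def with_(self, **kwargs) -> "AcquisitionProtocol":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class KineticParams:
    """Rate parameters of the three-phase H2(17)O kinetic model.

    Attributes
    ----------
    cmro2 : float
        Cerebral metabolic rate of oxygen, umol O2 / g tissue / min.
        Two labeled water molecules are produced per O2 consumed.
    k_g : float
        Gain rate constant (min^-1): recirculation of labeled water
        produced throughout the body.
    k_l : float
        Loss rate constant (min^-1): efflux of labeled water from the
        voxel, mostly perfusion (washout).
    """

    cmro2: float
    k_g: float
    k_l: float

    def __post_init__(self) -> None:
        if self.cmro2 < 0 or self.k_g < 0 or self.k_l < 0:
            raise ValueError("kinetic parameters must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.cmro2, self.k_g, self.k_l], dtype=float)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive per-frame measurement noise on concentration.

    ``sigma`` is the per-frame SD in umol/g.  The gaussian model adds noise
    directly to the excess concentration (high-SNR magnitude regime); the
    rician model applies magnitude-detection noise to the total signal
    D + excess and converts back to excess.  ``seed`` fixes the noise
    stream completely (same seed => identical output).
    """

    sigma: float = 0.5
    distribution: Literal["gaussian", "rician"] = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.distribution not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")


@dataclass(frozen=True)
class GroupSpec:
    """A cohort group: label, size and between-subject parameter spread.

    Per-subject parameters are drawn from normal distributions truncated
    at zero with means ``params_mean`` and SDs ``params_sd``.
    """

    label: str
    n_subjects: int
    params_mean: KineticParams
    params_sd: KineticParams = field(
        default_factory=lambda: KineticParams(0.0, 0.0, 0.0)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
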