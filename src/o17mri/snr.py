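"""Normalized SNR and temporal SNR for sequence comparison.

Both metrics normalize the raw signal-to-noise ratio by the effective
voxel volume and by the square root of the total acquisition time, giving
units of min^-1/2 uL^-1 so that sequences with different voxel sizes and
scan times can be compared head to head.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compute_snr", "compute_tsnr", "noise_sd_from_box"]


def compute_snr(
    signal: float,
    noise_sd: float,
    veff_ul: float,
    block_time_min: float,
    nr: int = 1,
) -> float:
    """Normalized SNR of a repetition-averaged image (min^-1/2 uL^-1).

        SNR = (signal / SD(noise)) / (V_eff * sqrt(block_time * NR))

    ``signal`` is a single-pixel value from the NR-averaged image and
    ``noise_sd`` the SD over a noise ROI outside the object.  The square
    root covers the total scan time block_time * NR, which makes the units
    dimensionally consistent.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if veff_ul <= 0 or block_time_min <= 0:
        raise ValueError("veff and block_time must be > 0")
    if nr < 1:
        raise ValueError("NR must be >= 1")
    return (signal / noise_sd) / (veff_ul * np.sqrt(block_time_min * nr))


def compute_tsnr(
    signal_series: np.ndarray,
    veff_ul: float,
    block_time_min: float,
) -> float:
    """Normalized temporal SNR over repeated acquisitions (min^-1/2 uL^-1).

        tSNR = (mean_n signal_n / SD_n signal_n) / (V_eff * sqrt(block_time))

    The temporal SD uses the n-1 denominator.
    """
    series = np.asarray(signal_series, dtype=float)
    if series.size < 2:
        raise ValueError("tSNR requires at least 2 repetitions")
    if veff_ul <= 0 or block_time_min <= 0:
        raise ValueError("veff and block_time must be > 0")
    sd = series.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate series: zero temporal SD")
    return (series.mean() / sd) / (veff_ul * np.sqrt(block_time_min))


def noise_sd_from_box(
    image: np.ndarray, origin: tuple[int, ...], size: tuple[int, ...]
) -> float:
    """SD over a rectangular noise ROI (e.g. 6 x 6 pixels outside the object)."""
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    box = np.asarray(image)[sl]
    if box.size < 2:
        raise ValueError("noise box is empty or too small")
    return float(box.std(ddof=1))
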