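"""Image/spectral preprocessing: k-space filtering, reconstruction, CSI
spectral integration, effective-volume computation, and conversion of ROI
signal to absolute H2(17)O concentration.

The pipeline entry point is Cartesian complex k-space (after any vendor
regridding) or magnitude images.  K-space is stored with its origin at
index N//2 on each axis (even N), voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .protocol import D_BRAIN, AcquisitionProtocol
from .synthetic import VoxelTimeCourse

__all__ = [
    "ImageSeries4D",
    "SRFSpec",
    "hamming_window",
    "hamming_filter",
    "reconstruct_image",
    "csi_spectral_pipeline",
    "compute_veff",
    "normalize_to_concentration",
    "extract_roi",
]


@dataclass
class ImageSeries4D:
    """A 3D grid x frames series with geometry.

    ``data`` has shape (nx, ny, nz, n_frames); ``domain`` states whether it
    holds complex k-space or reconstructed magnitude images.
    """

    data: np.ndarray
    fov_mm: tuple[float, float, float]
    frame_dt: float
    domain: Literal["kspace_complex", "image_magnitude"]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if any(n < 2 for n in self.data.shape[:3]):
            raise ValueError("grid dims must be >= 2 per axis")
        if self.data.shape[3] < 1:
            raise ValueError("at least one frame required")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("FOV must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1 with voxel size FOV/N and frame duration in dt."""
        import nibabel as nib

        zooms = [f / n for f, n in zip(self.fov_mm, self.grid_shape)]
        affine = np.diag(zooms + [1.0])
        img = nib.Nifti1Image(np.abs(self.data).astype(np.float64), affine)
        img.header.set_zooms(tuple(zooms) + (self.frame_dt,))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageSeries4D":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        zooms = img.header.get_zooms()
        fov = tuple(z * n for z, n in zip(zooms[:3], data.shape[:3]))
        frame_dt = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(data=data, fov_mm=fov, frame_dt=frame_dt, domain="image_magnitude")


@dataclass(frozen=True)
class SRFSpec:
    """Spatial-response-function specification for one acquisition.

    ``t2star_ms`` (with ``readout_ms``) adds an exponential signal-decay
    weighting along the readout, mapped to k-space radius as in a
    center-out radial acquisition.
    """

    window: Literal["uniform", "hamming"]
    matrix: tuple[int, int, int]
    fov_mm: tuple[float, float, float]
    t2star_ms: float | None = None
    readout_ms: float | None = None

    def __post_init__(self) -> None:
        if self.t2star_ms is not None and self.readout_ms is None:
            raise ValueError("readout_ms required when t2star_ms is set")


def hamming_window(n: int) -> np.ndarray:
    """Periodic Hamming window centered on the k-space origin (index n//2).

    w[m] = 0.54 + 0.46 cos(2 pi (m - n//2) / n): exactly 1 at the center
    sample and 0.08 at the edge sample m = 0.
    """
    m = np.arange(n)
    return 0.54 + 0.46 * np.cos(2.0 * np.pi * (m - n // 2) / n)


def _axis_windows(shape: Sequence[int], window: str) -> list[np.ndarray]:
    if window == "hamming":
        return [hamming_window(n) for n in shape]
    if window == "uniform":
        return [np.ones(n) for n in shape]
    raise ValueError(f"unknown window {window!r}")


def hamming_filter(frame: np.ndarray) -> np.ndarray:
    """Apply a separable 3D Hamming window to a complex k-space frame.

    The window is centered on the k-space origin and normalized to 1 at the
    center sample, so the DC component (hence the mean image level) is
    unchanged.  Linear operator.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3:
        raise ValueError("frame must be a 3D k-space grid")
    wx, wy, wz = _axis_windows(frame.shape, "hamming")
    return frame * wx[:, None, None] * wy[None, :, None] * wz[None, None, :]


def hamming_filter_series(series: ImageSeries4D) -> ImageSeries4D:
    """Hamming-filter every frame of a k-space series."""
    if series.domain != "kspace_complex":
        raise ValueError("hamming filtering expects complex k-space data")
    wx, wy, wz = _axis_windows(series.grid_shape, "hamming")
    w3 = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    return ImageSeries4D(
        data=series.data * w3[..., None],
        fov_mm=series.fov_mm,
        frame_dt=series.frame_dt,
        domain="kspace_complex",
    )


def reconstruct_image(frame: np.ndarray) -> np.ndarray:
    """Centered inverse FFT of a k-space frame, returned as magnitude.

    Uses the orthonormal FFT convention so energy is conserved (Parseval)
    before the magnitude is taken.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3:
        raise ValueError("frame must be a 3D k-space grid")
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(frame), norm="ortho"))
    return np.abs(img)


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Forward counterpart of :func:`reconstruct_image` (complex, ortho)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image), norm="ortho"))


def reconstruct_series(series: ImageSeries4D) -> ImageSeries4D:
    """Reconstruct every frame of a k-space series to magnitude images."""
    if series.domain != "kspace_complex":
        raise ValueError("reconstruction expects complex k-space data")
    out = np.empty(series.data.shape, dtype=float)
    for f in range(series.n_frames):
        out[..., f] = reconstruct_image(series.data[..., f])
    return ImageSeries4D(
        data=out, fov_mm=series.fov_mm, frame_dt=series.frame_dt,
        domain="image_magnitude",
    )


def csi_spectral_pipeline(
    fids: np.ndarray,
    dwell_s: float = 8.4e-6,
    lb_hz: float = 6000.0,
    zf_points: int = 256,
    integ_points: int = 9,
) -> np.ndarray:
    """Per-voxel FID -> peak-integral image (CSI spectral processing).

    Steps per voxel: exponential line broadening exp(-pi * lb * t) (to
    suppress the truncation artifact of the short acquisition), zero-fill,
    FFT to the spectrum, zero-order phase so the dominant peak is
    absorptive, then integrate the real part over ``integ_points`` samples
    centered on the peak maximum.

    ``fids`` has the complex time axis last; the returned array drops it.
    """
    fids = np.asarray(fids, dtype=complex)
    npts = fids.shape[-1]
    if integ_points > zf_points:
        raise ValueError("integ_points exceeds the zero-filled spectrum length")
    t = np.arange(npts) * dwell_s
    apodized = fids * np.exp(-np.pi * lb_hz * t)
    spec = np.fft.fftshift(np.fft.fft(apodized, n=zf_points, axis=-1), axes=-1)

    flat = spec.reshape(-1, zf_points)
    out = np.empty(flat.shape[0])
    half = integ_points // 2
    for v, s in enumerate(flat):
        peak = int(np.argmax(np.abs(s)))
        s_phased = s * np.exp(-1j * np.angle(s[peak]))
        lo = max(0, peak - half)
        hi = min(zf_points, peak + half + 1)
        out[v] = np.sum(s_phased[lo:hi].real)
    return out.reshape(fids.shape[:-1])


def _srf_weights(spec: SRFSpec) -> np.ndarray:
    """3D k-space weighting: apodization window x T2* readout decay."""
    wx, wy, wz = _axis_windows(spec.matrix, spec.window)
    w3 = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    if spec.t2star_ms is not None:
        # center-out radial readout: k-space radius ~ acquisition time
        axes = [
            (np.arange(n) - n // 2) / (n // 2) for n in spec.matrix
        ]
        r = np.sqrt(
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        w3 = w3 * np.exp(-r * spec.readout_ms / spec.t2star_ms)
    return w3


def compute_veff(spec: SRFSpec) -> float:
    """Effective voxel volume (mm^3 = uL) of the spatial response function.

    The SRF is the Fourier transform of the k-space weighting w (window x
    T2* decay).  The effective volume used here is

        V_eff = (integral of SRF)^2 / integral of SRF^2,

    evaluated over one FOV period.  For a trigonometric polynomial these
    integrals reduce exactly to FOV-volume x w(0) and FOV-volume x sum
    |w_k|^2 (a finely zero-padded DFT Riemann sum gives the identical
    value, by orthogonality), so

        V_eff = prod(FOV) * w(0)^2 / sum(w^2).

    A uniform window with no decay returns exactly the nominal voxel
    volume prod(FOV_i / N_i).
    """
    w3 = _srf_weights(spec)
    center = tuple(n // 2 for n in spec.matrix)
    w0 = w3[center]
    fov_vol = float(np.prod(spec.fov_mm))
    return fov_vol * w0**2 / float(np.sum(w3**2))


def normalize_to_concentration(
    roi_signal: np.ndarray,
    baseline_frames: int,
    t_s: np.ndarray | None = None,
    protocol: AcquisitionProtocol | None = None,
    d: float = D_BRAIN,
) -> VoxelTimeCourse:
    """Convert raw ROI signal to absolute H2(17)O concentration.

    The signal is normalized to the mean over the first ``baseline_frames``
    frames and scaled by the natural-abundance baseline concentration D:
    total(t) = D * S(t)/S_baseline, excess(t) = total(t) - D.  The baseline
    mean of the excess is zero by construction, and any global coil/gain
    scale cancels.
    """
    roi_signal = np.asarray(roi_signal, dtype=float)
    if baseline_frames < 2:
        raise ValueError("need at least 2 baseline frames")
    if baseline_frames > roi_signal.size:
        raise ValueError("baseline_frames exceeds the series length")
    base = float(np.mean(roi_signal[:baseline_frames]))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    total = d * roi_signal / base
    if t_s is None:
        t_s = np.arange(roi_signal.size, dtype=float)
    return VoxelTimeCourse(
        t_s=np.asarray(t_s, dtype=float),
        excess=total - d,
        total=total,
        phase=None if protocol is None else protocol.phase_of(t_s),
        protocol=protocol,
    )


def extract_roi(
    series: ImageSeries4D, voxel_indices: Sequence[Sequence[int]]
) -> np.ndarray:
    """Unweighted per-frame mean over the listed voxels.

    The analysis convention is 8 adjacent voxels forming a 2x2x2 block;
    adjacency is the caller's responsibility and is not enforced.
    """
    if len(voxel_indices) == 0:
        raise ValueError("voxel_indices must not be empty")
    idx = np.asarray(voxel_indices, dtype=int)
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("voxel_indices must be a list of (i, j, k) triples")
    shape = series.grid_shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise IndexError("voxel index outside the image grid")
    return np.mean(series.data[idx[:, 0], idx[:, 1], idx[:, 2], :], axis=0)
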