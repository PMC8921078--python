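"""DCE series calibration against reference muscle, noise estimation, denoising.

Raw scanner intensities carry an arbitrary affine scale, but the blanket FD
is *not* invariant to amplitude rescaling, so every series is mapped to a
canonical intensity unit before fractal analysis: the internal obturator
muscle's pre-contrast mean maps to 0 and its contrast-enhanced mean to 100
calibrated units. Image noise is estimated as the standard deviation of the
muscle signal pooled over pre-contrast frames and each frame is denoised
with an edge-preserving bilateral filter whose range parameter is tied to
that estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.restoration import denoise_bilateral

from .errors import CalibrationError, InputError, ParameterError

#: Default bilateral spatial standard deviation (mm), ~ in-plane resolution.
DEFAULT_SPATIAL_SD_MM: float = 1.5

#: Default bilateral range standard deviation as a multiple of the noise sd.
DEFAULT_RANGE_FACTOR: float = 2.0

#: Calibration anchors (calibrated units): muscle pre-contrast mean and
#: muscle enhanced-phase mean.
CAL_PRE_ANCHOR: float = 0.0
CAL_ENHANCED_ANCHOR: float = 100.0


@dataclass(frozen=True)
class DceSeries:
    """Dynamic contrast-enhanced series indexed (t, z, y, x).

    ``spacing`` is (dz, dy, dx) in mm, ``times`` the frame acquisition
    times in seconds (strictly increasing; the reference protocol samples
    every 3.5 s for 2:40 min). ``sigma`` holds the noise estimate in the
    current intensity units once computed.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    times: np.ndarray
    calibrated: bool = False
    sigma: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)
        if data.ndim != 4:
            raise InputError(f"series must be 4D (t, z, y, x), got shape {data.shape}")
        if len(times) != data.shape[0]:
            raise InputError("number of frame times must match number of frames")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InputError("frame times must be strictly increasing")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[1], self.spacing[2]

    def frame(self, t: int, z: int) -> np.ndarray:
        return self.data[t, z]


@dataclass(frozen=True)
class MuscleRoi:
    """Reference-muscle mask with pre-contrast and enhanced frame index sets."""

    mask: np.ndarray  # (z, y, x) bool
    pre_frames: tuple[int, ...]
    enhanced_frames: tuple[int, ...]

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "pre_frames", tuple(int(i) for i in self.pre_frames))
        object.__setattr__(self, "enhanced_frames", tuple(int(i) for i in self.enhanced_frames))
        if not mask.any():
            raise InputError("muscle mask is empty")
        if not self.pre_frames:
            raise InputError("no pre-contrast frames given")
        if not self.enhanced_frames:
            raise InputError("no enhanced frames given")
        if set(self.pre_frames) & set(self.enhanced_frames):
            raise InputError("pre-contrast and enhanced frame sets overlap")


def default_muscle_roi(mask: np.ndarray, n_frames: int, n_pre: int = 3) -> MuscleRoi:
    """MuscleRoi with the first ``n_pre`` frames as baseline and the final
    quarter of the series (plateau) as the enhanced phase."""
    start = max(n_pre, int(np.ceil(0.75 * n_frames)))
    return MuscleRoi(
        mask=mask,
        pre_frames=tuple(range(n_pre)),
        enhanced_frames=tuple(range(start, n_frames)),
    )


def estimate_noise(series: DceSeries, roi: MuscleRoi) -> float:
    """Noise sd: sample standard deviation (ddof=1) of muscle voxels pooled
    over the pre-contrast frames, in the series' current intensity units."""
    if series.calibrated:
        raise InputError("noise is estimated on the raw series, before calibration")
    vals = series.data[list(roi.pre_frames)][:, roi.mask].ravel()
    if vals.size < 2:
        return 0.0
    return float(np.std(vals, ddof=1))


def calibrate(series: DceSeries, roi: MuscleRoi) -> DceSeries:
    """Affine intensity calibration anchored to the reference muscle.

    Maps the muscle pre-contrast mean to 0 and the muscle enhanced-phase
    mean to 100 calibrated units; the noise estimate is rescaled by the
    same gain (and computed first if absent). The map must be strictly
    increasing: a muscle that does not enhance signals a failed series.
    """
    if series.calibrated:
        raise CalibrationError("series is already calibrated")
    pre_mean = float(series.data[list(roi.pre_frames)][:, roi.mask].mean())
    enh_mean = float(series.data[list(roi.enhanced_frames)][:, roi.mask].mean())
    if enh_mean <= pre_mean:
        raise CalibrationError(
            f"degenerate calibration: muscle enhanced mean ({enh_mean:.3g}) "
            f"does not exceed pre-contrast mean ({pre_mean:.3g})"
        )
    sigma = series.sigma if series.sigma is not None else estimate_noise(series, roi)
    gain = (CAL_ENHANCED_ANCHOR - CAL_PRE_ANCHOR) / (enh_mean - pre_mean)
    data = (series.data - pre_mean) * gain + CAL_PRE_ANCHOR
    return replace(series, data=data, calibrated=True, sigma=sigma * gain)


def denoise(
    frame: np.ndarray,
    sigma: float,
    spatial_scale_mm: float = DEFAULT_SPATIAL_SD_MM,
    pixel_spacing_mm: float = 1.5,
    range_factor: float = DEFAULT_RANGE_FACTOR,
) -> np.ndarray:
    """Edge-preserving bilateral denoising of one calibrated frame.

    The range (intensity) standard deviation is ``range_factor * sigma``
    (default 2 sigma) and the spatial standard deviation is
    ``spatial_scale_mm`` converted to pixels. ``sigma = 0`` is the
    identity.
    """
    if sigma < 0:
        raise ParameterError(f"noise sd must be non-negative, got {sigma}")
    if spatial_scale_mm <= 0:
        raise ParameterError(f"spatial scale must be positive, got {spatial_scale_mm}")
    img = np.asarray(frame, dtype=float)
    if sigma == 0:
        return img.copy()
    # shift to non-negative; the bilateral filter is shift-equivariant
    offset = float(img.min())
    out = denoise_bilateral(
        img - offset,
        sigma_color=range_factor * sigma,
        sigma_spatial=spatial_scale_mm / pixel_spacing_mm,
        mode="edge",
    )
    return out + offset
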