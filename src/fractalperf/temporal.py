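"""Margin mean-FD time curve and its maximum.

For every frame of the calibrated series the selected slice is denoised,
converted to a local FD map, and averaged over the margin band. The highest
mean FD over the time sequence ("FDmax") captures the maximum geometrical
complexity of the perfusion pattern, which is typically reached during the
early phase of contrast enhancement. Optional per-frame motion adjustment
re-centers the band by an integer-pixel normalized-cross-correlation search
against the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import fractal, preprocess
from .errors import InputError
from .margin import MarginBand, propagate_and_mean
from .preprocess import DceSeries

MAX_SHIFT_PX = 3  # motion-adjustment search radius

#: A nonzero shift is applied only when its NCC beats the unshifted NCC by
#: this margin AND reaches SHIFT_MIN_NCC; frames without trackable shared
#: structure (pure noise, decorrelated texture) keep the nominal position.
SHIFT_ACCEPT_MARGIN = 0.05
SHIFT_MIN_NCC = 0.7


@dataclass
class FdTimeCurve:
    """Per-frame margin mean FD, ordered by acquisition time."""

    times: np.ndarray  # (t,) seconds
    mean_fd: np.ndarray  # (t,), NaN for frames that failed
    n_pixels: np.ndarray  # (t,) band pixel counts
    shifts: np.ndarray  # (t, 2) applied integer (dy, dx) band shifts
    slice_index: int = 0
    flagged: list[int] = field(default_factory=list)

    @property
    def argmax_index(self) -> int:
        if not np.any(np.isfinite(self.mean_fd)):
            raise InputError("all frames failed FD computation")
        return int(np.nanargmax(self.mean_fd))  # earliest frame on ties

    @property
    def fdmax(self) -> float:
        return float(self.mean_fd[self.argmax_index])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "mean_fd": self.mean_fd,
                "n_pixels": self.n_pixels,
                "shift_y": self.shifts[:, 0],
                "shift_x": self.shifts[:, 1],
            }
        )


def max_fd(curve: FdTimeCurve) -> tuple[float, int]:
    """Maximum mean FD and its frame index (earliest frame on ties)."""
    idx = curve.argmax_index
    return float(curve.mean_fd[idx]), idx


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _best_shift(reference: np.ndarray, current: np.ndarray, window: np.ndarray) -> tuple[int, int]:
    """Integer shift (dy, dx) within +-MAX_SHIFT_PX maximizing the NCC of the
    shifted current frame against the reference inside the window."""
    ys, xs = np.where(window)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    ref_patch = reference[y0:y1, x0:x1]
    zero_score = _ncc(ref_patch, current[y0:y1, x0:x1])
    best = (0, 0)
    best_score = zero_score
    for dy in range(-MAX_SHIFT_PX, MAX_SHIFT_PX + 1):
        for dx in range(-MAX_SHIFT_PX, MAX_SHIFT_PX + 1):
            if (dy, dx) == (0, 0):
                continue
            yy0, yy1 = y0 + dy, y1 + dy
            xx0, xx1 = x0 + dx, x1 + dx
            if yy0 < 0 or xx0 < 0 or yy1 > current.shape[0] or xx1 > current.shape[1]:
                continue
            score = _ncc(ref_patch, current[yy0:yy1, xx0:xx1])
            if score > best_score + 1e-12:
                best_score = score
                best = (dy, dx)
    if best_score < SHIFT_MIN_NCC or best_score < zero_score + SHIFT_ACCEPT_MARGIN:
        return (0, 0)
    return best


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    ny, nx = mask.shape
    ys, xs = np.where(mask)
    ys = ys + dy
    xs = xs + dx
    keep = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
    out[ys[keep], xs[keep]] = True
    return out


def fd_time_curve(
    series: DceSeries,
    band: MarginBand,
    per_frame_adjust: bool = False,
    ref_frame: int | None = None,
    kernel: int = 3,
    scales: tuple[int, ...] = fractal.DEFAULT_SCALES,
    connectivity: int = 4,
    spatial_scale_mm: float = preprocess.DEFAULT_SPATIAL_SD_MM,
) -> FdTimeCurve:
    """Margin mean-FD curve across the DCE time series.

    Frames failing FD computation are flagged (NaN) and excluded from the
    maximum. With ``per_frame_adjust`` the band is re-centered per frame by
    an integer-shift NCC search around the core neighborhood against
    ``ref_frame`` (default: the frame with the highest mean intensity in
    the band neighborhood, i.e. the first-pass peak).
    """
    if not series.calibrated:
        raise InputError("series must be calibrated before FD analysis")
    z = band.slice_index
    sigma = series.sigma if series.sigma is not None else 0.0
    pixel_mm = series.in_plane_spacing[1]

    # core neighborhood: the band plus its filled interior (the core), whose
    # enhancement structure is the trackable content across frames
    neighborhood = ndimage.binary_dilation(ndimage.binary_fill_holes(band.mask),
                                           iterations=2 * MAX_SHIFT_PX)
    if ref_frame is None:
        means = [float(series.data[t, z][neighborhood].mean()) for t in range(series.n_frames)]
        ref_frame = int(np.argmax(means))

    denoised = [
        preprocess.denoise(series.data[t, z], sigma, spatial_scale_mm=spatial_scale_mm,
                           pixel_spacing_mm=pixel_mm)
        for t in range(series.n_frames)
    ]

    n = series.n_frames
    mean_fd = np.full(n, np.nan)
    n_pixels = np.zeros(n, dtype=int)
    shifts = np.zeros((n, 2), dtype=int)
    flagged: list[int] = []
    for t in range(n):
        try:
            if per_frame_adjust and t != ref_frame:
                dy, dx = _best_shift(denoised[ref_frame], denoised[t], neighborhood)
                shifts[t] = (dy, dx)
                mask = _shift_mask(band.mask, dy, dx)
            else:
                mask = band.mask
            frame_band = MarginBand(mask=mask, width_mm=band.width_mm,
                                    excluded_arc=band.excluded_arc, slice_index=z)
            fd_map = fractal.local_fd_map(denoised[t], kernel=kernel, scales=scales,
                                          connectivity=connectivity, timepoint=t)
            mean_fd[t], n_pixels[t] = propagate_and_mean(frame_band, fd_map)
        except Exception:
            flagged.append(t)
    return FdTimeCurve(times=series.times.copy(), mean_fd=mean_fd, n_pixels=n_pixels,
                       shifts=shifts, slice_index=z, flagged=flagged)
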