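"""ROI-based signal-to-noise metrics for photoacoustic/ultrasound images.

SNR is defined on normalized pixel values as

    SNR = 20 * log10(S_R / S_n)   [dB]

with S_R the mean pixel value inside a signal region of interest and S_n
the mean over a background region.  The uncertainty is estimated by
recomputing S_R over several randomly placed sub-regions within the signal
mask and reporting the mean and standard deviation of the resulting SNRs.

Images are normalized by their maximum pixel value before the ratio is
taken; since SNR is a ratio statistic this leaves it invariant to any
positive rescaling of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageRoi", "snr_db", "frame_average"]

DEFAULT_N_SUBSAMPLES = 10


@dataclass
class ImageRoi:
    """A 2D image plus disjoint signal and background pixel masks."""

    image: np.ndarray
    signal_region: np.ndarray
    background_region: np.ndarray
    n_subsamples: int = DEFAULT_N_SUBSAMPLES

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.signal_region = np.asarray(self.signal_region, dtype=bool)
        self.background_region = np.asarray(self.background_region, dtype=bool)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if (
            self.signal_region.shape != self.image.shape
            or self.background_region.shape != self.image.shape
        ):
            raise ValueError("masks must match the image shape")
        if not self.signal_region.any() or not self.background_region.any():
            raise ValueError("signal and background masks must be non-empty")
        if (self.signal_region & self.background_region).any():
            raise ValueError("signal and background masks must be disjoint")
        if np.any(self.image < 0):
            raise ValueError("pixel values must be >= 0")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


def _normalize(image: np.ndarray) -> np.ndarray:
    peak = image.max()
    if peak <= 0:
        raise ValueError("image has no positive pixels; SNR undefined")
    return image / peak


def _sub_roi_masks(
    signal: np.ndarray,
    n_subsamples: int,
    rng: np.random.Generator,
    shape: tuple[int, int] | None = None,
) -> list[np.ndarray]:
    """Randomly placed rectangular sub-ROIs of ~half the signal area.

    By default each sub-ROI is a rectangle of 1/sqrt(2) the bounding-box
    extent per axis (area about half the signal region for compact masks),
    placed uniformly so that it overlaps the signal mask; only its
    intersection with the signal mask is used.
    """
    rows, cols = np.nonzero(signal)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if shape is not None:
        h, w = shape
    else:
        h = max(1, int(round((r1 - r0) / np.sqrt(2.0))))
        w = max(1, int(round((c1 - c0) / np.sqrt(2.0))))
    masks = []
    for _ in range(n_subsamples):
        for _attempt in range(100):
            rr = int(rng.integers(r0, max(r0 + 1, r1 - h + 1)))
            cc = int(rng.integers(c0, max(c0 + 1, c1 - w + 1)))
            sub = np.zeros_like(signal)
            sub[rr : rr + h, cc : cc + w] = True
            sub &= signal
            if sub.any():
                masks.append(sub)
                break
        else:  # pragma: no cover - signal mask is non-empty by invariant
            masks.append(signal.copy())
    return masks


def snr_db(
    roi: ImageRoi,
    seed: int = 0,
    sub_roi_shape: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Mean and standard deviation of the ROI SNR in dB.

    The point estimate for each resample uses the mean of a random sub-ROI
    of the signal mask over the fixed background mean; the reported mean is
    the SNR of the full signal mask (so constant regions reproduce
    closed-form values exactly) and the std quantifies placement
    sensitivity.  ``sub_roi_shape`` overrides the default half-area sub-ROI
    rectangle; it must not exceed the signal region.
    """
    if sub_roi_shape is not None:
        h, w = sub_roi_shape
        if h < 1 or w < 1:
            raise ValueError("sub_roi_shape entries must be >= 1")
        if h * w > int(roi.signal_region.sum()):
            raise ValueError("sub-ROI is larger than the signal region")
    img = _normalize(roi.image)
    s_n = float(img[roi.background_region].mean())
    if s_n == 0.0:
        raise ValueError("background mean is zero; SNR undefined")
    s_r = float(img[roi.signal_region].mean())
    mean_snr = 20.0 * np.log10(s_r / s_n)
    rng = np.random.default_rng(seed)
    resampled = []
    for sub in _sub_roi_masks(
        roi.signal_region, roi.n_subsamples, rng, shape=sub_roi_shape
    ):
        sr_i = float(img[sub].mean())
        if sr_i > 0:
            resampled.append(20.0 * np.log10(sr_i / s_n))
    std_snr = float(np.std(resampled)) if len(resampled) > 1 else 0.0
    return float(mean_snr), std_snr


def frame_average(frames) -> np.ndarray:
    """Pixelwise mean of a stack of equally shaped 2D frames."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("all frames must share one shape")
    return np.mean(np.stack(frames, axis=0), axis=0)
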