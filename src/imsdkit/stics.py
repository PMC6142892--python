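"""Spatiotemporal intensity-fluctuation correlation of an image stack.

The correlation function

    G(xi, chi, tau) = < dI(x, y, t) dI(x+xi, y+chi, t+tau) > / <I>^2

with ``dI = I - <I>`` is averaged over all pixel positions (periodic FFT
convention) and over every frame pair separated by ``tau``.  It is the raw
material of the iMSD analysis: for mobile fluorescent particles its spatial
profile at each temporal lag is approximately Gaussian with a squared radius
that grows like the particles' mean square displacement.

The implementation is O(N log N): spatial FFTs per frame followed by an FFT
along time (zero-padded, so every frame pair at each lag contributes exactly
once, never wrapping).  It agrees with the direct quadruple-sum definition
to floating-point precision.

Mean subtraction uses the grand (whole-stack) mean by default; per-frame
mean subtraction is available but also removes genuine particle-number
fluctuations, so it is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.fft
import tifffile

from .io import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationFunction",
    "compute_correlation",
    "preprocess",
    "correlation_evolution",
    "correlation_to_tiff",
]


@dataclass
class CorrelationFunction:
    """G over spatial lags, per temporal lag.

    ``G`` has shape (n_tau, 2*max_lag+1, 2*max_lag+1) with the zero spatial
    lag at the central pixel; axis order is (tau, chi rows, xi columns).
    ``tau`` starts at one frame time.  ``n_pairs[i]`` is the number of frame
    pairs averaged at ``tau[i]`` (= n_frames - lag_frames).
    """

    G: np.ndarray
    tau: np.ndarray
    max_lag: int
    n_pairs: np.ndarray
    pixel_size_nm: float
    frame_time_s: float

    def __post_init__(self) -> None:
        side = 2 * self.max_lag + 1
        if self.G.shape[1:] != (side, side):
            raise ValueError(f"G spatial shape {self.G.shape[1:]} != ({side}, {side})")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")

    @property
    def n_tau(self) -> int:
        return self.G.shape[0]


def compute_correlation(
    stack: ImageStack,
    max_tau_frames: int,
    max_spatial_lag: int,
    mean_mode: str = "grand",
) -> CorrelationFunction:
    """Spatiotemporal correlation of ``stack`` up to the given lags.

    Parameters
    ----------
    max_tau_frames
        Largest temporal lag, in frames (1 <= value < n_frames).
    max_spatial_lag
        Largest spatial lag, in pixels, per axis (<= min(rows, cols)/2).
    mean_mode
        "grand" subtracts the whole-stack mean; "per_frame" subtracts each
        frame's own mean (also removing number fluctuations).
    """
    data = stack.data
    T, ny, nx = data.shape
    if not 1 <= max_tau_frames < T:
        raise ValueError(f"max_tau_frames must be in [1, {T - 1}], got {max_tau_frames}")
    if max_spatial_lag > min(ny, nx) // 2:
        raise ValueError(
            f"max_spatial_lag {max_spatial_lag} exceeds min(rows, cols)/2 = {min(ny, nx) // 2}"
        )
    if mean_mode not in ("grand", "per_frame"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")

    grand_mean = data.mean()
    if mean_mode == "grand":
        dI = data - grand_mean
    else:
        dI = data - data.mean(axis=(1, 2), keepdims=True)
    if grand_mean == 0 or np.ptp(dI) == 0:
        raise ValueError("no fluctuations: stack is constant (dI == 0)")

    # spatial spectra per frame, then cross-correlate along time via FFT
    F = scipy.fft.rfft2(dI, axes=(1, 2))
    nfft = scipy.fft.next_fast_len(T + max_tau_frames, real=True)
    A = scipy.fft.fft(F, n=nfft, axis=0)
    power = (A.real**2 + A.imag**2)
    del A
    # S[k] = sum_t conj(F_t) F_{t+k}; zero-padding prevents temporal wrap
    S = scipy.fft.ifft(power, axis=0)[1 : max_tau_frames + 1]
    del power

    lags = np.arange(1, max_tau_frames + 1)
    n_pairs = T - lags
    L = max_spatial_lag
    cy, cx = ny // 2, nx // 2
    G = np.empty((max_tau_frames, 2 * L + 1, 2 * L + 1))
    norm = grand_mean**2 * ny * nx
    for i in range(max_tau_frames):
        C = scipy.fft.irfft2(S[i], s=(ny, nx))
        C = np.fft.fftshift(C) / (norm * n_pairs[i])
        G[i] = C[cy - L : cy + L + 1, cx - L : cx + L + 1]

    tau = lags * stack.meta.frame_time_s
    return CorrelationFunction(
        G=G,
        tau=tau,
        max_lag=L,
        n_pairs=n_pairs,
        pixel_size_nm=stack.meta.pixel_size_nm,
        frame_time_s=stack.meta.frame_time_s,
    )


def preprocess(
    stack: ImageStack,
    background_percentile: float | None = None,
    detrend_bleach: bool = False,
) -> ImageStack:
    """Optional background subtraction and bleaching detrend (both off by default).

    Background is estimated as a low percentile of the intensity histogram
    and subtracted as a constant (clipped at zero).  The bleaching detrend
    rescales every frame so its mean matches the first frame's mean.  With
    both options off the input is returned unchanged (bit-identical data).
    """
    if background_percentile is None and not detrend_bleach:
        return stack
    data = stack.data
    if background_percentile is not None:
        if not 0 <= background_percentile < 100:
            raise ValueError(
                f"background_percentile must be in [0, 100), got {background_percentile}"
            )
        bg = np.percentile(data, background_percentile)
        logger.info("preprocess: subtracting background constant %.4g", bg)
        data = np.clip(data - bg, 0.0, None)
    if detrend_bleach:
        means = data.mean(axis=(1, 2))
        if np.any(means == 0):
            raise ValueError("cannot detrend: some frame means are zero")
        logger.info("preprocess: bleaching detrend to first-frame mean %.4g", means[0])
        data = data * (means[0] / means)[:, None, None]
    return ImageStack(data=data, meta=stack.meta)


def correlation_evolution(corr: CorrelationFunction) -> pd.DataFrame:
    """Zero-spatial-lag amplitude of G vs temporal lag (spreadsheet block)."""
    c = corr.max_lag
    return pd.DataFrame(
        {"tau_s": corr.tau, "G0": corr.G[:, c, c], "n_pairs": corr.n_pairs}
    )


def correlation_to_tiff(corr: CorrelationFunction, path) -> None:
    """Export G as a float32 per-tau image stack for visual inspection."""
    tifffile.imwrite(path, corr.G.astype(np.float32))
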