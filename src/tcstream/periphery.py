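"""Early auditory model: waveform -> auditory spectrogram, and its inverse.

The analysis cascade is a constant-Q complex filterbank on a log-frequency
axis (128 channels over 5.2 octaves by default), half-wave rectification,
cube-root compression, lateral inhibition across channels, leaky temporal
integration, and decimation to the frame rate. Inversion runs an iterative
analysis-synthesis projection that imposes the target channel envelopes on
the current estimate's subband decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.signal import lfilter

from .config import PeripheryConfig, RunConfig
from .io import resample_waveform
from .stimuli import Waveform


@dataclass
class AudSpec:
    """Auditory spectrogram: nonnegative frames x channels matrix."""

    values: np.ndarray          # (T, F), >= 0
    frame_rate: float           # Hz
    cfs: np.ndarray             # (F,) center frequencies, log-spaced

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cfs = np.asarray(self.cfs, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.cfs.size:
            raise ValueError("AudSpec values must be (frames, n_channels)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def span_octaves(self) -> float:
        return float(np.log2(self.cfs[-1] / self.cfs[0]))


def center_frequencies(cfg: PeripheryConfig) -> np.ndarray:
    k = np.arange(cfg.n_channels)
    return cfg.f_min * 2 ** (cfg.span_octaves * k / (cfg.n_channels - 1))


_FB_CACHE: dict = {}


def _filterbank(n: int, cfg: PeripheryConfig) -> np.ndarray:
    """Gaussian constant-Q magnitude responses on the positive FFT bins.

    Returns an (F, n) array that is zero on negative frequencies, so a
    product with the signal FFT yields analytic subbands directly.
    """
    key = (n, cfg.sample_rate, cfg.n_channels, cfg.f_min, cfg.span_octaves,
           cfg.filter_sigma_oct)
    if key in _FB_CACHE:
        return _FB_CACHE[key]
    freqs = np.fft.fftfreq(n, d=1.0 / cfg.sample_rate)
    cfs = center_frequencies(cfg)
    H = np.zeros((cfg.n_channels, n))
    pos = freqs > 0
    logf = np.log2(freqs[pos])
    for k, cf in enumerate(cfs):
        H[k, pos] = np.exp(-((logf - np.log2(cf)) ** 2)
                           / (2 * cfg.filter_sigma_oct ** 2))
    if len(_FB_CACHE) > 8:
        _FB_CACHE.clear()
    _FB_CACHE[key] = H
    return H


def _analytic_subbands(x: np.ndarray, H: np.ndarray, n: int) -> np.ndarray:
    """Complex analytic subbands (F, len(x)) via the one-sided filterbank."""
    X = fft(x, n)
    # factor 2 restores the amplitude of the real part after dropping
    # negative frequencies
    S = ifft(2.0 * H * X[None, :], axis=1)
    return S[:, : x.size]


def _lateral_inhibition(y: np.ndarray) -> np.ndarray:
    """Across-channel sharpening: discrete Laplacian, half-wave rectified.

    The symmetric kernel sharpens spectral ridges without displacing their
    peak position along the channel axis.
    """
    padded = np.pad(y, ((1, 1), (0, 0)), mode="edge")
    sharp = y - 0.5 * (padded[:-2] + padded[2:])
    return np.maximum(sharp, 0.0)


def auditory_spectrogram(w: Waveform, cfg: RunConfig,
                         compression: bool = True,
                         lateral_inhibition: bool = True) -> AudSpec:
    """Transform a waveform into the 128-channel auditory spectrogram.

    ``compression`` / ``lateral_inhibition`` can be disabled to expose the
    linear stage of the cascade (used by the model's linearity checks).
    """
    p = cfg.periphery
    x = w.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("input waveform contains non-finite samples")
    if w.sample_rate != p.sample_rate:
        x = resample_waveform(x, w.sample_rate, p.sample_rate)
    if x.size == 0:
        return AudSpec(np.zeros((0, p.n_channels)), p.frame_rate,
                       center_frequencies(p))
    n = next_fast_len(x.size + p.sample_rate // 4)
    H = _filterbank(n, p)
    sub = _analytic_subbands(x, H, n)
    y = np.maximum(sub.real, 0.0).T           # (N, F) half-wave rectified
    if compression:
        # cube root with a soft knee: avoids blowing up numerical noise
        knee = p.compression_knee
        y = np.cbrt(y + knee) - np.cbrt(knee)
    if lateral_inhibition:
        y = _lateral_inhibition(y.T).T
    a = np.exp(-1.0 / (p.integration_tau * p.sample_rate))
    y = lfilter([1 - a], [1, -a], y, axis=0)  # leaky integration
    hop = p.hop
    frames = y[hop - 1 :: hop]
    return AudSpec(frames, p.frame_rate, center_frequencies(p))


def _synthesize(subbands: np.ndarray, H: np.ndarray, n: int,
                out_len: int) -> np.ndarray:
    """Least-squares resynthesis of modified analytic subbands."""
    S = fft(subbands, n, axis=1)
    num = np.einsum("kn,kn->n", H, S)
    den = np.sum(H ** 2, axis=0)
    den = den + 1e-3 * den.max()
    x = ifft(num / den)
    # analytic subbands carry doubled positive frequencies; Re halves back
    return np.real(x[:out_len])


def invert_spectrogram(spec: AudSpec, cfg: RunConfig,
                       init: Waveform | None = None,
                       n_iter: int | None = None,
                       seed: int = 0) -> tuple[Waveform, np.ndarray]:
    """Reconstruct audio whose auditory spectrogram matches ``spec``.

    Iterative projection: analyze the current estimate, rescale each
    channel's subband by the ratio of target to measured envelope, and
    resynthesize. When ``init`` is given (typically the mixture), its
    subband phases seed the iteration; otherwise a seeded noise init is
    used. Returns the waveform and the per-iteration relative residuals.
    """
    p = cfg.periphery
    n_iter = p.n_invert_iter if n_iter is None else n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    target = np.maximum(spec.values, 0.0)
    hop = p.hop
    out_len = spec.n_frames * hop
    if target.size == 0 or target.max() == 0:
        return Waveform(np.zeros(out_len), p.sample_rate), np.zeros(0)

    if init is not None:
        x = init.samples
        if init.sample_rate != p.sample_rate:
            x = resample_waveform(x, init.sample_rate, p.sample_rate)
        x = np.pad(x[:out_len], (0, max(0, out_len - x.size)))
        x = x.astype(np.float64).copy()
        if np.max(np.abs(x)) == 0:
            x = None
    else:
        x = None
    if x is None:
        rng = np.random.default_rng(seed)
        x = 1e-2 * rng.standard_normal(out_len)

    n = next_fast_len(out_len + p.sample_rate // 4)
    H = _filterbank(n, p)
    a = np.exp(-1.0 / (p.integration_tau * p.sample_rate))
    floor = 1e-4 * target.max()
    residuals = []
    best_x, best_resid = x, np.inf
    for _ in range(n_iter):
        measured = auditory_spectrogram(Waveform(x, p.sample_rate), cfg).values
        measured = measured[: spec.n_frames]
        num = np.linalg.norm(measured - target)
        residuals.append(num / (np.linalg.norm(target) + 1e-30))
        if residuals[-1] < best_resid:
            best_x, best_resid = x.copy(), residuals[-1]
        gains = (target + floor) / (measured + floor)
        gains = np.clip(gains, 0.0, 10.0) ** 0.7   # damped update
        # per-sample channel gains, smoothed to avoid frame-edge steps
        g = np.repeat(gains, hop, axis=0)
        g = lfilter([1 - a], [1, -a], g, axis=0)
        sub = _analytic_subbands(x, H, n)
        sub = sub * g.T[:, : sub.shape[1]]
        x = _synthesize(sub, H, n, out_len)
        peak = np.max(np.abs(x))
        if peak > 1.0:
            x /= peak
    measured = auditory_spectrogram(Waveform(x, p.sample_rate), cfg).values
    final = (np.linalg.norm(measured[: spec.n_frames] - target)
             / (np.linalg.norm(target) + 1e-30))
    if final < best_resid:
        best_x, best_resid = x, final
    residuals.append(final)
    return Waveform(best_x, p.sample_rate), np.asarray(residuals)
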