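"""Cortical spectrotemporal analysis and its inverse.

Two factorized wavelet decompositions: complex Gabor receptive fields along
the log-frequency axis (scales, cyc/oct), then causal complex modulation
filters along time (rates, Hz) applied to the modulus of the scale outputs
plus any appended pitch/auxiliary channels. Inversion recombines rates and
scales with conjugate-filter (Wiener) weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.signal import fftconvolve

from .config import RunConfig
from .periphery import AudSpec


# ---------------------------------------------------------------------------
# channel bookkeeping
# ---------------------------------------------------------------------------

KIND_SPECTRAL, KIND_PITCH, KIND_AUX = 0, 1, 2


@dataclass
class ChannelMap:
    """Provenance of every feature-field column.

    Spectral columns are ordered scale-major: column ``s * F + f`` is
    frequency channel ``f`` seen at scale ``s``, so each scale holds a full
    copy of the spectrogram channels. Pitch columns follow, then at most
    one auxiliary column.
    """

    kinds: np.ndarray            # (D,) in {spectral, pitch, aux}
    cf: np.ndarray               # (D,) center frequency Hz (nan if n/a)
    scale: np.ndarray            # (D,) cyc/oct (nan if n/a)
    pitch_hz: np.ndarray         # (D,) pitch candidate Hz (nan if n/a)
    n_freq: int
    n_scales: int

    @property
    def n_channels(self) -> int:
        return self.kinds.size

    def spectral_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == KIND_SPECTRAL)

    def pitch_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == KIND_PITCH)

    def aux_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == KIND_AUX)

    def pitch_in_range(self, lo: float, hi: float) -> np.ndarray:
        return np.flatnonzero(
            (self.kinds == KIND_PITCH) & (self.pitch_hz >= lo) & (self.pitch_hz <= hi)
        )

    def spectral_near(self, freq: float, width_oct: float = 0.1) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            d = np.abs(np.log2(self.cf / freq))
        return np.flatnonzero((self.kinds == KIND_SPECTRAL) & (d <= width_oct))

    def with_aux(self) -> "ChannelMap":
        nan = np.array([np.nan])
        return ChannelMap(
            np.concatenate([self.kinds, [KIND_AUX]]),
            np.concatenate([self.cf, nan]),
            np.concatenate([self.scale, nan]),
            np.concatenate([self.pitch_hz, nan]),
            self.n_freq, self.n_scales,
        )


def spectral_channel_map(cfs: np.ndarray, scales: Sequence[float]) -> ChannelMap:
    F, S = cfs.size, len(scales)
    kinds = np.full(F * S, KIND_SPECTRAL)
    cf = np.tile(cfs, S)
    scale = np.repeat(np.asarray(scales, dtype=float), F)
    pitch = np.full(F * S, np.nan)
    return ChannelMap(kinds, cf, scale, pitch, F, S)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScaleField:
    values: np.ndarray           # (T, F, S) complex
    scales: tuple
    frame_rate: float
    cfs: np.ndarray


@dataclass
class FeatureField:
    values: np.ndarray           # (T, D) nonnegative
    channel_map: ChannelMap
    frame_rate: float


@dataclass
class CorticalTensor:
    values: np.ndarray           # (T, D, R) complex
    rates: tuple
    channel_map: ChannelMap
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_rates(self) -> int:
        return self.values.shape[2]


# ---------------------------------------------------------------------------
# scale (spectral modulation) analysis
# ---------------------------------------------------------------------------

def _scale_kernel(s: float, spacing_oct: float) -> np.ndarray:
    """Complex Gabor receptive field tuned to ``s`` cyc/oct, zero-mean.

    The Gaussian envelope width scales inversely with ``s`` (constant-Q,
    about one period wide), and the mean is removed so a flat spectral
    slice produces exactly zero response.
    """
    sigma = 1.0 / (2.0 * s)                     # octaves
    half = int(np.ceil(3.5 * sigma / spacing_oct))
    x = np.arange(-half, half + 1) * spacing_oct
    g = np.exp(-x ** 2 / (2 * sigma ** 2)) * np.exp(1j * 2 * np.pi * s * x)
    g -= g.mean()
    # unit magnitude response at the center spectral modulation
    resp = np.abs(np.sum(g * np.exp(-1j * 2 * np.pi * s * x)))
    return g / resp


def _scale_transfers(scales: Sequence[float], spacing_oct: float,
                     n_fft: int) -> np.ndarray:
    """(S, n_fft) transfer functions of the centered Gabor kernels."""
    out = np.zeros((len(scales), n_fft), dtype=complex)
    for i, s in enumerate(scales):
        ker = _scale_kernel(s, spacing_oct)
        half = ker.size // 2
        buf = np.zeros(n_fft, dtype=complex)
        buf[: half + 1] = ker[half:]
        buf[-half:] = ker[:half]
        out[i] = fft(buf)
    return out


def scale_transform(spec: AudSpec, scales: Optional[Sequence[float]] = None,
                    cfg: Optional[RunConfig] = None) -> ScaleField:
    """Convolve each spectral slice with the multi-scale Gabor bank."""
    if scales is None:
        scales = cfg.cortical.scales if cfg is not None else (1.0, 2.0, 4.0, 8.0)
    spacing = spec.span_octaves / (spec.n_channels - 1)
    T, F = spec.values.shape
    out = np.empty((T, F, len(scales)), dtype=complex)
    for i, s in enumerate(scales):
        ker = _scale_kernel(s, spacing)
        out[:, :, i] = fftconvolve(spec.values, ker[None, :], mode="same", axes=1)
    return ScaleField(out, tuple(scales), spec.frame_rate, spec.cfs)


def inverse_scale(field_values: np.ndarray, scales: Sequence[float],
                  spacing_oct: float, eps: float = 1e-3) -> np.ndarray:
    """Recombine scale responses into spectral slices (conjugate weighting).

    ``field_values`` is (T, F, S) complex; returns (T, F) real. The Gabor
    bank is band-pass in spectral modulation, so the slice's spectral mean
    (DC) is not represented and the output is zero-mean along frequency.
    """
    T, F, S = field_values.shape
    n_fft = next_fast_len(2 * F)
    G = _scale_transfers(scales, spacing_oct, n_fft)
    den = np.sum(np.abs(G) ** 2, axis=0)
    den = den + eps * den.max()
    Z = fft(field_values, n_fft, axis=1)
    num = np.einsum("tks,sk->tk", Z, np.conj(G))
    slices = ifft(num / den[None, :], axis=1)[:, :F]
    return 2.0 * np.real(slices)


# ---------------------------------------------------------------------------
# rate (temporal modulation) analysis
# ---------------------------------------------------------------------------

def _rate_kernel(rate: float, frame_rate: float) -> np.ndarray:
    """Causal complex modulation filter tuned to ``rate`` Hz.

    Gamma (order-2) envelope t*exp(-beta*t) with beta = 1.5*pi*rate, which
    gives an effective impulse-response duration of ~1/rate (about 250 ms
    at 4 Hz). The carrier is corrected so the transfer function vanishes
    exactly at DC (strictly band-pass), and peak gain at the center rate
    is normalized to one.
    """
    beta = 1.5 * np.pi * rate
    n = max(8, int(np.ceil(12.0 / beta * frame_rate)))
    t = (np.arange(n) + 0.5) / frame_rate
    env = t * np.exp(-beta * t)
    w = 2 * np.pi * rate
    carrier = np.exp(1j * w * t)
    # subtract a scaled envelope so the discrete kernel sums to exactly zero
    c = np.sum(env * carrier) / np.sum(env)
    h = env * (carrier - c)
    gain = np.abs(np.sum(h * np.exp(-1j * w * t)))
    return h / gain


def rate_transform(ff: FeatureField, rates: Optional[Sequence[float]] = None,
                   cfg: Optional[RunConfig] = None) -> CorticalTensor:
    """Apply the causal modulation filterbank along time to every channel."""
    if rates is None:
        rates = cfg.cortical.rates if cfg is not None else (2, 4, 8, 16, 32)
    T, D = ff.values.shape
    out = np.empty((T, D, len(rates)), dtype=complex)
    for i, r in enumerate(rates):
        h = _rate_kernel(r, ff.frame_rate)
        y = fftconvolve(ff.values.astype(complex), h[:, None], mode="full", axes=0)
        out[:, :, i] = y[:T]
    return CorticalTensor(out, tuple(rates), ff.channel_map, ff.frame_rate)


def inverse_rates(values: np.ndarray, rates: Sequence[float],
                  frame_rate: float, eps: float = 1e-3) -> np.ndarray:
    """Invert the rate filterbank: (T, D, R) complex -> (T, D) real.

    Conjugate-filter Wiener combination; recovers each channel's 2-32 Hz
    band-limited modulation (the band the rate filters tile). Content
    outside the band, including DC, is not represented.
    """
    T, D, R = values.shape
    kernels = [_rate_kernel(r, frame_rate) for r in rates]
    n_fft = next_fast_len(T + max(k.size for k in kernels))
    Hs = np.stack([fft(k, n_fft) for k in kernels])       # (R, n_fft)
    den = np.sum(np.abs(Hs) ** 2, axis=0)
    den = den + eps * den.max()
    Y = fft(values, n_fft, axis=0)                        # (n_fft, D, R)
    num = np.einsum("ndr,rn->nd", Y, np.conj(Hs))
    u = ifft(num / den[:, None], axis=0)[:T]
    return 2.0 * np.real(u)


def inverse_cortical(ct: CorticalTensor, channel_map: Optional[ChannelMap] = None,
                     scale_phase: Optional[np.ndarray] = None,
                     dc: Optional[np.ndarray] = None,
                     cfs: Optional[np.ndarray] = None,
                     scales: Optional[Sequence[float]] = None) -> AudSpec:
    """Invert a (possibly masked) cortical tensor back to an auditory spectrogram.

    Rates are inverted with conjugate weighting to per-channel envelopes;
    an optional per-channel ``dc`` offset restores the sustained level the
    band-pass rate filters discard. Spectral slices are then recombined
    across scales (pitch/aux channels are dropped at this stage), using the
    mixture's scale-field phases when ``scale_phase`` is given. Output is
    clipped at zero.
    """
    cmap = channel_map if channel_map is not None else ct.channel_map
    env = inverse_rates(ct.values, ct.rates, ct.frame_rate)
    if dc is not None:
        env = env + dc
    spec_idx = cmap.spectral_indices()
    F, S = cmap.n_freq, cmap.n_scales
    env_fs = np.maximum(env[:, spec_idx], 0.0).reshape(env.shape[0], S, F)
    env_fs = np.transpose(env_fs, (0, 2, 1))              # (T, F, S)
    if scale_phase is not None:
        Z = env_fs * np.exp(1j * np.angle(scale_phase))
    else:
        Z = env_fs.astype(complex)
    if scales is None:
        scales = sorted(set(cmap.scale[spec_idx]))
    cfs_arr = np.asarray(cfs) if cfs is not None else cmap.cf[spec_idx][:F]
    spacing = np.log2(cfs_arr[-1] / cfs_arr[0]) / (F - 1)
    slices = inverse_scale(Z, tuple(scales), spacing)
    return AudSpec(np.maximum(slices, 0.0), ct.frame_rate, cfs_arr)
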