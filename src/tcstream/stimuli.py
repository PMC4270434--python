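"""Synthetic stimuli with ground-truth stream labels.

Every generator returns a :class:`Waveform` plus a :class:`GroundTruth`
whose scaled components sum exactly to the mixture, so end-to-end
segregation quality can always be scored against known sources.

Stimulus classes covered: alternating tone sequences, crossing glide
sequences, overlapping tone complexes with controlled onset asynchrony,
harmonic complexes (and alternating pairs of them), two-source mixtures
at a stated SNR, and auxiliary co-modulated envelope traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .config import DEFAULT_SAMPLE_RATE

RAMP_DUR = 0.010  # s, raised-cosine on/off ramps on every tone


@dataclass
class Waveform:
    """Mono audio: dimensionless samples (peak <= 1) at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, gain: float) -> "Waveform":
        return Waveform(self.samples * gain, self.sample_rate)


@dataclass
class GroundTruth:
    """Pre-mix sources, their onset schedules, and stream labels.

    ``components[i]`` (already scaled by any mixing gain) sum to the mixture.
    ``onsets[i]`` is a list of (t_on, t_off) pairs; ``component_freqs[i]``
    lists each tone's frequency in the same order. ``labels[i]`` is the
    stream id of component ``i``; alternative labelings (e.g. the
    "bouncing" register labeling of crossing sequences) live in ``extras``.
    """

    components: list
    onsets: list
    labels: list
    component_freqs: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def mixture_residual(self, mix: Waveform) -> float:
        total = np.zeros_like(mix.samples)
        for c in self.components:
            total[: c.samples.size] += c.samples
        denom = np.linalg.norm(mix.samples) or 1.0
        return float(np.linalg.norm(mix.samples - total) / denom)


def _check_freq(f: float, sr: int) -> None:
    if f >= sr / 2:
        raise ValueError(f"frequency {f} Hz is at or above Nyquist ({sr / 2} Hz)")
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")


def _ramped_tone(freq: float, dur: float, sr: int, amp: float,
                 ramp: float = RAMP_DUR, phase: float = 0.0) -> np.ndarray:
    n = int(round(dur * sr))
    t = np.arange(n) / sr
    tone = amp * np.cos(2 * np.pi * freq * t + phase)
    return tone * _envelope(n, sr, ramp)


def _envelope(n: int, sr: int, ramp: float) -> np.ndarray:
    env = np.ones(n)
    nr = min(int(round(ramp * sr)), n // 2)
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def _place(buf: np.ndarray, tone: np.ndarray, onset: float, sr: int) -> None:
    i0 = int(round(onset * sr))
    i1 = min(i0 + tone.size, buf.size)
    buf[i0:i1] += tone[: i1 - i0]


# ---------------------------------------------------------------------------
# tone sequences
# ---------------------------------------------------------------------------

def gen_alternating_tones(fA: float, fB: float, tone_dur: float = 0.1,
                          ioi: float = 0.15, reps: int = 10,
                          sr: int = DEFAULT_SAMPLE_RATE, amp: float = 0.5,
                          ) -> tuple[Waveform, GroundTruth]:
    """ABAB... alternating tone sequence (classic two-tone streaming)."""
    _check_freq(fA, sr), _check_freq(fB, sr)
    if tone_dur > ioi:
        raise ValueError("tone_dur must not exceed the inter-onset interval")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = int(round(2 * reps * ioi * sr))
    comps = [np.zeros(n), np.zeros(n)]
    onsets: list = [[], []]
    freqs: list = [[], []]
    for k in range(reps):
        for j, f in enumerate((fA, fB)):
            t0 = (2 * k + j) * ioi
            _place(comps[j], _ramped_tone(f, tone_dur, sr, amp), t0, sr)
            onsets[j].append((t0, t0 + tone_dur))
            freqs[j].append(f)
    mix = Waveform(comps[0] + comps[1], sr)
    labels = [1, 1] if fA == fB else [1, 2]
    truth = GroundTruth([Waveform(c, sr) for c in comps], onsets, labels, freqs)
    return mix, truth


def gen_crossing_tones(f_start_low: float, f_start_high: float,
                       step: float = 1.6, reps: int = 16,
                       tone_dur: float = 0.08, ioi: float = 0.1,
                       sr: int = DEFAULT_SAMPLE_RATE, amp: float = 0.5,
                       ) -> tuple[Waveform, GroundTruth]:
    """Two interleaved glide sequences whose frequency tracks cross.

    The low track ascends and the high track descends by ``step`` semitones
    per tone, for ``reps`` tones each. Ground truth carries both the
    by-source ("crossing") labeling and the by-register ("bouncing")
    labeling relative to the geometric crossover frequency.
    """
    if f_start_low > f_start_high:
        raise ValueError("f_start_low must not exceed f_start_high")
    low = [f_start_low * 2 ** (k * step / 12) for k in range(reps)]
    high = [f_start_high * 2 ** (-k * step / 12) for k in range(reps)]
    for f in (*low, *high):
        _check_freq(f, sr)
    n = int(round(2 * reps * ioi * sr))
    comps = [np.zeros(n), np.zeros(n)]
    onsets: list = [[], []]
    freqs: list = [low, high]
    for k in range(reps):
        for j, f in enumerate((low[k], high[k])):
            t0 = (2 * k + j) * ioi
            _place(comps[j], _ramped_tone(f, tone_dur, sr, amp), t0, sr)
            onsets[j].append((t0, t0 + tone_dur))
    crossover = math.sqrt(f_start_low * f_start_high)
    register = [
        [2 if f >= crossover else 1 for f in low],
        [2 if f >= crossover else 1 for f in high],
    ]
    mix = Waveform(comps[0] + comps[1], sr)
    truth = GroundTruth(
        [Waveform(c, sr) for c in comps], onsets, [1, 2], freqs,
        extras={"crossover_hz": crossover, "register_labels": register},
    )
    return mix, truth


def gen_tone_complexes(base_freqs: Sequence[float],
                       overlap_freqs: Sequence[float],
                       onset_asynchrony: float = 0.0, reps: int = 6,
                       tone_dur: float = 0.12, period: float = 0.24,
                       sr: int = DEFAULT_SAMPLE_RATE, amp: float = 0.25,
                       ) -> tuple[Waveform, GroundTruth]:
    """Repeating pair of multi-tone complexes with offset onsets.

    Complex A starts each repetition at ``k*period``; complex B at
    ``k*period + onset_asynchrony``. Asynchrony 0 gives one synchronous
    super-complex.
    """
    if not 0 <= onset_asynchrony < period:
        raise ValueError("onset_asynchrony must lie in [0, period)")
    for f in (*base_freqs, *overlap_freqs):
        _check_freq(f, sr)
    n = int(round((reps * period + onset_asynchrony + tone_dur) * sr))
    comps = [np.zeros(n), np.zeros(n)]
    onsets: list = [[], []]
    freqs: list = [[], []]
    for k in range(reps):
        for j, (fs, delay) in enumerate(
            ((base_freqs, 0.0), (overlap_freqs, onset_asynchrony))
        ):
            t0 = k * period + delay
            for f in fs:
                _place(comps[j], _ramped_tone(f, tone_dur, sr, amp), t0, sr)
                freqs[j].append(f)
            onsets[j].append((t0, t0 + tone_dur))
    mix = Waveform(comps[0] + comps[1], sr)
    truth = GroundTruth([Waveform(c, sr) for c in comps], onsets, [1, 2], freqs)
    return mix, truth


def gen_harmonic_complex(f0: float, n_harm: int, dur: float = 0.3,
                         amps: Optional[Sequence[float]] = None,
                         sr: int = DEFAULT_SAMPLE_RATE,
                         ramp: float = RAMP_DUR,
                         ) -> tuple[Waveform, GroundTruth]:
    """Sum of cosine partials at k*f0, k = 1..n_harm (equal amps unless given)."""
    if n_harm < 1:
        raise ValueError("n_harm must be >= 1")
    _check_freq(n_harm * f0, sr)
    if amps is None:
        amps = [0.9 / n_harm] * n_harm
    if len(amps) != n_harm:
        raise ValueError("amps must have one entry per harmonic")
    n = int(round(dur * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        x += a * np.cos(2 * np.pi * k * f0 * t)
    x *= _envelope(n, sr, ramp)
    w = Waveform(x, sr)
    truth = GroundTruth([w], [[(0.0, dur)]], [1],
                        [[k * f0 for k in range(1, n_harm + 1)]])
    return w, truth


def gen_alternating_complexes(f0a: float, f0b: float, n_harm_a: int = 8,
                              n_harm_b: int = 8, tone_dur: float = 0.15,
                              ioi: float = 0.2, reps: int = 5,
                              sr: int = DEFAULT_SAMPLE_RATE,
                              ) -> tuple[Waveform, GroundTruth]:
    """Alternating harmonic complexes of two different pitches (Fig 3 style)."""
    n = int(round(2 * reps * ioi * sr))
    comps = [np.zeros(n), np.zeros(n)]
    onsets: list = [[], []]
    freqs: list = [[], []]
    for k in range(reps):
        for j, (f0, nh) in enumerate(((f0a, n_harm_a), (f0b, n_harm_b))):
            tone, _ = gen_harmonic_complex(f0, nh, dur=tone_dur, sr=sr)
            t0 = (2 * k + j) * ioi
            _place(comps[j], tone.samples, t0, sr)
            onsets[j].append((t0, t0 + tone_dur))
            freqs[j].extend(h * f0 for h in range(1, nh + 1))
    mix = Waveform(comps[0] + comps[1], sr)
    truth = GroundTruth([Waveform(c, sr) for c in comps], onsets, [1, 2],
                        [sorted(set(f)) for f in freqs],
                        extras={"f0": [f0a, f0b]})
    return mix, truth


def am_modulate(w: Waveform, am_rate: float, depth: float = 1.0,
                phase: float = 0.0) -> Waveform:
    """Sinusoidally amplitude-modulate a waveform (raised-cosine envelope).

    Full depth gives an envelope (1 - cos(2 pi r t + phase)) / 2 in [0, 1];
    the slow co-modulation it imposes is the cue the temporal-coherence
    model clusters on.
    """
    t = np.arange(w.samples.size) / w.sample_rate
    env = 1.0 - depth * 0.5 * (1.0 + np.cos(2 * np.pi * am_rate * t + phase))
    return Waveform(w.samples * env, w.sample_rate)


def gen_am_tone(freq: float, am_rate: float, dur: float = 1.2,
                depth: float = 1.0, phase: float = 0.0,
                sr: int = DEFAULT_SAMPLE_RATE, amp: float = 0.7,
                ) -> tuple[Waveform, GroundTruth]:
    """Amplitude-modulated pure tone."""
    _check_freq(freq, sr)
    w, _ = gen_harmonic_complex(freq, 1, dur=dur, amps=[amp], sr=sr)
    w = am_modulate(w, am_rate, depth, phase)
    truth = GroundTruth([w], [[(0.0, dur)]], [1], [[freq]])
    return w, truth


def gate_bursts(w: Waveform, rate: float, duty: float = 0.5,
                phase_frac: float = 0.0, ramp: float = RAMP_DUR) -> Waveform:
    """Gate a waveform into periodic ramped bursts at ``rate`` Hz.

    Burst duration is ``duty / rate``; ``phase_frac`` shifts the burst
    train by a fraction of a period. Burst trains have a rich modulation
    spectrum (onsets excite the whole rate bank), like the repeating tone
    complexes and syllabic envelopes the model is built for.
    """
    sr = w.sample_rate
    period = 1.0 / rate
    nb = max(int(duty * period * sr), 1)
    burst = _envelope(nb, sr, ramp)
    env = np.zeros(w.samples.size)
    t0 = -phase_frac * period
    while t0 < w.duration:
        i0 = int(round(t0 * sr))
        s0, s1 = max(i0, 0), min(i0 + nb, env.size)
        if s1 > s0:
            env[s0:s1] = burst[s0 - i0 : s1 - i0]
        t0 += period
    return Waveform(w.samples * env, sr)


def gen_benchmark_pairs(n_pairs: int = 20, dur: float = 2.0,
                        sr: int = DEFAULT_SAMPLE_RATE, seed: int = 0) -> list:
    """Two-source test corpus: disjoint-band burst-modulated sources.

    Half the pairs are harmonic complexes in disjoint spectral bands (low
    fundamental vs high), half are tone pairs at least ~2 octaves apart.
    Each source is gated into periodic bursts at its own rate (2.5-4 Hz vs
    5-7 Hz, random phase), so it is internally co-modulated but incoherent
    with its partner. Deterministic given the seed.

    Returns a list of (w1, w2, info) triples.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        ra, rb = rng.uniform(2.5, 4.0), rng.uniform(5.0, 7.0)
        pa, pb = rng.uniform(0.0, 1.0, 2)
        if i % 2 == 0:
            f0a = rng.uniform(110, 180)
            f0b = rng.uniform(1100, 1500)
            wa, _ = gen_harmonic_complex(f0a, 4, dur=dur, sr=sr)
            wb, _ = gen_harmonic_complex(f0b, 2, dur=dur, sr=sr)
            info = {"kind": "burst_complexes", "f0": (f0a, f0b),
                    "freqs": ([k * f0a for k in range(1, 5)],
                              [k * f0b for k in range(1, 3)])}
        else:
            fa = rng.uniform(300, 650)
            fb = fa * 2 ** rng.uniform(1.8, 2.6)
            wa, _ = gen_harmonic_complex(fa, 1, dur=dur, sr=sr)
            wb, _ = gen_harmonic_complex(fb, 1, dur=dur, sr=sr)
            info = {"kind": "burst_tones", "freqs": ([fa], [fb])}
        wa, wb = gate_bursts(wa, ra, phase_frac=pa), gate_bursts(wb, rb, phase_frac=pb)
        info["burst_rates"] = (ra, rb)
        pairs.append((wa, wb, info))
    return pairs


# ---------------------------------------------------------------------------
# mixing and auxiliary traces
# ---------------------------------------------------------------------------

def gen_mixture(w1: Waveform, w2: Waveform, snr_db: float,
                ) -> tuple[Waveform, GroundTruth]:
    """Mix two waveforms at a stated SNR (power of w1 over scaled w2).

    ``snr_db = inf`` returns ``w1`` unchanged. If the sum would clip, mixture
    and components are rescaled together so the decomposition is preserved.
    """
    if w1.sample_rate != w2.sample_rate:
        raise ValueError("sample rates must match")
    n = max(w1.samples.size, w2.samples.size)
    x1 = np.pad(w1.samples, (0, n - w1.samples.size))
    x2 = np.pad(w2.samples, (0, n - w2.samples.size))
    p1, p2 = float(np.mean(x1 ** 2)), float(np.mean(x2 ** 2))
    if math.isinf(snr_db) and snr_db > 0:
        if p1 == 0:
            raise ValueError("w1 has zero power")
        truth = GroundTruth([Waveform(x1, w1.sample_rate)], [[]], [1])
        return Waveform(x1, w1.sample_rate), truth
    if p1 == 0 or p2 == 0:
        raise ValueError("cannot mix a silent waveform at a finite SNR")
    g = math.sqrt(p1 / p2 * 10 ** (-snr_db / 10))
    mix = x1 + g * x2
    peak = np.max(np.abs(mix))
    scale = 1.0 / peak if peak > 1 else 1.0
    sr = w1.sample_rate
    truth = GroundTruth(
        [Waveform(scale * x1, sr), Waveform(scale * g * x2, sr)],
        [[], []], [1, 2], extras={"gain": g, "rescale": scale},
    )
    return Waveform(scale * mix, sr), truth


def gen_aux_envelope(w: Waveform, cutoff: float = 8.0,
                     frame_rate: float = 125.0) -> np.ndarray:
    """Magnitude envelope of ``w``: rectified, low-passed, at the frame rate.

    Stands in for any co-modulated 1-D auxiliary trace (e.g. an inter-lip
    distance track). ``cutoff`` must stay within the cortical rate range.
    """
    if cutoff > 32.0:
        raise ValueError("cutoff must be <= 32 Hz (cortical rate range)")
    env = np.abs(w.samples)
    if env.max() == 0:
        n_frames = int(w.samples.size * frame_rate / w.sample_rate)
        return np.zeros(n_frames)
    b, a = butter(4, cutoff / (w.sample_rate / 2))
    env = filtfilt(b, a, env)
    hop = int(round(w.sample_rate / frame_rate))
    return np.maximum(env[hop - 1 :: hop], 0.0)
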