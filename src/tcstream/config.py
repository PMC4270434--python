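"""Run configuration: every tunable parameter of the model in one place.

The defaults reproduce the standard operating point of the model: a
128-channel constant-Q auditory spectrogram over 5.2 octaves, spectral
(scale) analysis at 1-8 cyc/oct, temporal (rate) analysis at 2-32 Hz in
half-octave steps, a 50-1000 Hz harmonic-template pitch grid, and a
two-unit rectified-linear auto-encoder for the coincidence clustering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

DEFAULT_SAMPLE_RATE = 16000


def _half_octave_rates(lo: float = 2.0, hi: float = 32.0) -> tuple[float, ...]:
    n = int(round(2 * math.log2(hi / lo)))
    return tuple(lo * 2 ** (k / 2) for k in range(n + 1))


@dataclass
class PeripheryConfig:
    """Early auditory model parameters."""

    sample_rate: int = DEFAULT_SAMPLE_RATE
    n_channels: int = 128
    f_min: float = 110.0           # Hz, lowest center frequency
    span_octaves: float = 5.2      # log-frequency span of the filterbank
    frame_rate: float = 125.0      # Hz, spectrogram frame rate (8-ms frames)
    filter_sigma_oct: float = 1.0 / 16.0  # cochlear filter width (octaves)
    compression_knee: float = 1e-4  # soft threshold of the cube-root stage
    integration_tau: float = 0.008  # s, leaky integrator time constant
    n_invert_iter: int = 20        # default spectrogram-inversion iterations

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("periphery.sample_rate must be positive")
        if self.n_channels < 2:
            raise ValueError("periphery.n_channels must be >= 2")
        if self.span_octaves <= 0:
            raise ValueError("periphery.span_octaves must be positive")
        f_max = self.f_min * 2 ** self.span_octaves
        if f_max >= self.sample_rate / 2:
            raise ValueError(
                f"periphery: top center frequency {f_max:.0f} Hz is not below "
                f"Nyquist ({self.sample_rate / 2:.0f} Hz)"
            )
        hop = self.sample_rate / self.frame_rate
        if abs(hop - round(hop)) > 1e-9:
            raise ValueError(
                "periphery.frame_rate must divide sample_rate evenly "
                f"(got hop {hop:.3f} samples)"
            )

    @property
    def hop(self) -> int:
        return int(round(self.sample_rate / self.frame_rate))


@dataclass
class CorticalConfig:
    """Scale (spectral modulation) and rate (temporal modulation) filterbanks."""

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)   # cyc/oct
    rates: tuple[float, ...] = field(default_factory=_half_octave_rates)  # Hz

    def validate(self, periphery: PeripheryConfig) -> None:
        if not self.scales or not self.rates:
            raise ValueError("cortical.scales and cortical.rates must be nonempty")
        ch_per_oct = (periphery.n_channels - 1) / periphery.span_octaves
        for s in self.scales:
            if not 0 < s < ch_per_oct / 2:
                raise ValueError(
                    f"cortical.scales entry {s} outside (0, {ch_per_oct / 2:.1f}) cyc/oct"
                )
        for r in self.rates:
            if not 0 < r < periphery.frame_rate / 2:
                raise ValueError(
                    f"cortical.rates entry {r} Hz not below frame-rate Nyquist "
                    f"({periphery.frame_rate / 2:.1f} Hz)"
                )


@dataclass
class PitchConfig:
    """Harmonic-template pitch-gram parameters."""

    enabled: bool = True
    f_min: float = 50.0
    f_max: float = 1000.0
    steps_per_octave: int = 48
    n_harm_template: int = 8
    bump_width_channels: float = 2.0
    gain: float = 1.0              # weight of pitch channels in the feature field
    sharpen_exp: float = 4.0       # salience contrast exponent for the
                                   # feature-field pitch channels (estimation
                                   # itself uses the raw salience)

    def validate(self, periphery: PeripheryConfig) -> None:
        if self.f_min <= 0 or self.f_max <= self.f_min:
            raise ValueError("pitch grid bounds must satisfy 0 < f_min < f_max")
        if self.steps_per_octave < 1:
            raise ValueError("pitch.steps_per_octave must be >= 1")
        if self.n_harm_template < 1:
            raise ValueError("pitch.n_harm_template must be >= 1")

    def grid(self) -> tuple[float, ...]:
        n = int(math.floor(self.steps_per_octave * math.log2(self.f_max / self.f_min)))
        return tuple(
            self.f_min * 2 ** (k / self.steps_per_octave) for k in range(n + 1)
        )


@dataclass
class ClusterConfig:
    """Auto-encoder (nonlinear PCA) parameters."""

    n_streams: int = 2             # K, hidden units = streams
    n_passes: int = 1              # sweeps of the per-frame loop; extra
                                   # passes warm-start from the previous
                                   # pass's final weights (rarely needed:
                                   # the energetic-frame init already seeds
                                   # converged units from frame zero)
    l2: float = 1e-4               # weight decay on encoder/decoder
    activity_l1: float = 1e-3      # sparsity on hidden activations; makes
                                   # redundant units shut off instead of
                                   # sharing a single source's reconstruction
    max_iter: int = 200            # L-BFGS iterations, cold start
    warm_max_iter: int = 15        # L-BFGS iterations, warm-started frames
    gtol: float = 1e-6
    eps: float = 1e-8              # mask-normalization floor
    init: str = "pca"              # cold start: "pca" (deterministic paired
                                   # +/- principal directions of the first
                                   # batch) or "random" (seeded uniform)
    use_modulus: bool = False      # coincidence as |z z^H| instead of Re{z z^H}
    normalize_cmatrix: bool = False  # correlation-normalize C blocks
    mask_source: str = "decoder"   # "decoder" or "encoder" weights as masks

    def validate(self) -> None:
        if self.n_streams < 2:
            raise ValueError("cluster.n_streams must be >= 2")
        if self.l2 < 0:
            raise ValueError("cluster.l2 must be >= 0")
        if self.mask_source not in ("decoder", "encoder"):
            raise ValueError("cluster.mask_source must be 'decoder' or 'encoder'")
        if self.init not in ("pca", "random"):
            raise ValueError("cluster.init must be 'pca' or 'random'")


@dataclass
class StimuliConfig:
    """Default parameters of the overlapping-complex (onset asynchrony) stimulus.

    The two 3-tone complexes interleave within a shared spectral region; the
    second complex is delayed by the onset asynchrony under study.
    """

    base_freqs: tuple[float, ...] = (400.0, 800.0, 1600.0)
    overlap_freqs: tuple[float, ...] = (566.0, 1131.0, 2263.0)
    tone_dur: float = 0.12
    period: float = 0.24
    reps: int = 8

    def validate(self) -> None:
        if self.tone_dur <= 0 or self.period <= 0 or self.reps < 1:
            raise ValueError("stimuli: durations must be positive, reps >= 1")
        if self.tone_dur > self.period:
            raise ValueError("stimuli.tone_dur must not exceed stimuli.period")


@dataclass
class RunConfig:
    periphery: PeripheryConfig = field(default_factory=PeripheryConfig)
    cortical: CorticalConfig = field(default_factory=CorticalConfig)
    pitch: PitchConfig = field(default_factory=PitchConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    stimuli: StimuliConfig = field(default_factory=StimuliConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.periphery.validate()
        self.cortical.validate(self.periphery)
        self.pitch.validate(self.periphery)
        self.cluster.validate()
        self.stimuli.validate()
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key == "seed":
                cfg.seed = int(value)
                continue
            if key not in sections or key == "seed":
                raise ValueError(f"unknown config section '{key}'")
            sub = getattr(cfg, key)
            legal = {f.name for f in dataclasses.fields(sub)}
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            for k, v in value.items():
                if k not in legal:
                    raise ValueError(
                        f"unknown key '{key}.{k}' (legal: {sorted(legal)})"
                    )
                current = getattr(sub, k)
                if isinstance(current, tuple):
                    v = tuple(v)
                setattr(sub, k, v)
        return cfg.validate()

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load and validate a YAML/JSON config file; ``None`` gives full defaults."""
    if path is None:
        return RunConfig().validate()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig().validate()
    if not isinstance(data, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    return RunConfig.from_dict(data)


def reduced_config(pitch: bool = False, seed: int = 0) -> RunConfig:
    """A lighter operating point used for tone/complex simulations.

    Two scales and octave-spaced rates keep the per-frame clustering cheap
    while spanning the same 1-8 cyc/oct and 2-32 Hz ranges.
    """
    cfg = RunConfig(seed=seed)
    cfg.cortical.scales = (2.0, 8.0)
    cfg.cortical.rates = (2.0, 4.0, 8.0, 16.0, 32.0)
    cfg.pitch.enabled = pitch
    return cfg.validate()
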