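"""End-to-end segregation (mixture -> streams) and evaluation metrics.

The pipeline: auditory spectrogram -> pitch-gram -> scale analysis ->
feature field -> rate analysis -> per-frame coincidence columns ->
warm-started auto-encoder -> per-frame masks -> masked cortical tensors ->
inverse cortical transform -> (optional) spectrogram inversion to audio.

Evaluation follows the model's own currency: signal-to-noise ratios and
coincidence scores computed on cortical-representation magnitudes against
the known clean sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import (AEWeights, init_from_columns, init_weights,
                         masks_from_weights, step_frame)
from .coherence import AnchorSpec, coincidence_columns, augment_with_aux
from .config import RunConfig
from .cortical import (CorticalTensor, FeatureField, ScaleField,
                       inverse_cortical, rate_transform, scale_transform)
from .periphery import AudSpec, auditory_spectrogram, invert_spectrogram
from .pitch import PitchGram, build_feature_field, pitch_salience
from .stimuli import GroundTruth, Waveform, gen_tone_complexes

log = logging.getLogger("tcstream")

SNR_CAP_DB = 100.0


@dataclass
class Analysis:
    """Forward cascade of one waveform up to the cortical tensor."""

    waveform: Waveform
    spec: AudSpec
    scale_field: ScaleField
    pitch_gram: Optional[PitchGram]
    feature_field: FeatureField
    tensor: CorticalTensor

    @property
    def channel_map(self):
        return self.tensor.channel_map


@dataclass
class SegResult:
    mixture: Waveform
    analysis: Analysis
    masks: np.ndarray                    # (T, K, R, D) float32
    masked_tensors: list                 # K CorticalTensor
    spectrograms: list                   # K AudSpec
    waveforms: Optional[list]            # K Waveform or None
    foreground: int
    final_weights: AEWeights
    weight_trace: Optional[list]
    config_snapshot: dict
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def n_streams(self) -> int:
        return self.masks.shape[1]


def analyze(w: Waveform, cfg: RunConfig) -> Analysis:
    """Run the forward cascade (no clustering) on one waveform."""
    spec = auditory_spectrogram(w, cfg)
    sf = scale_transform(spec, cfg.cortical.scales)
    pg = pitch_salience(spec, cfg=cfg) if cfg.pitch.enabled else None
    ff = build_feature_field(sf, pg, cfg.pitch.gain, cfg.pitch.sharpen_exp)
    ct = rate_transform(ff, cfg.cortical.rates)
    return Analysis(w, spec, sf, pg, ff, ct)


def segregate(mix: Waveform, cfg: RunConfig,
              anchor: Optional[AnchorSpec] = None,
              aux: Optional[np.ndarray] = None,
              reconstruct_audio: bool = True,
              keep_weight_trace: bool = False) -> SegResult:
    """Segregate a mono mixture into K streams.

    Deterministic given (input, config, seed). ``anchor`` restricts the
    C-matrix columns driving the decomposition; ``aux`` appends a
    co-modulated auxiliary channel (required for anchor mode "aux").
    """
    cfg.validate()
    warnings: list = []
    if np.max(np.abs(mix.samples)) == 0:
        warnings.append("silent mixture: returning silent streams")
        log.warning(warnings[-1])
    anchor = anchor or AnchorSpec("all")
    analysis = analyze(mix, cfg)
    ct = analysis.tensor
    if aux is not None:
        ct = augment_with_aux(ct, aux, cfg)
    cmap = ct.channel_map
    sel = anchor.resolve(cmap)
    anchor_idx = sel if anchor.mode != "all" else None

    T, D, R = ct.n_frames, ct.n_channels, ct.n_rates
    K = cfg.cluster.n_streams
    cc = cfg.cluster
    weights: Optional[AEWeights] = None
    if cc.init == "pca" and T > 0:
        # deterministic cold start from the most energetic frame: its
        # coincidence matrix reflects the established coherence structure
        # (the model is offline), so the principal contrast direction
        # seeds the unit split before the per-frame tracking begins. In
        # anchored mode, energy is measured on the anchor channels so the
        # chosen frame has the attended source on.
        frame_energy = np.sum(np.abs(ct.values[:, sel, :]) ** 2, axis=(1, 2))
        t_star = int(np.argmax(frame_energy))
        X0 = coincidence_columns(ct, t_star, sel, use_modulus=cc.use_modulus)
        if np.abs(X0).max() > 1e-30:
            from .clustering import fit_autoencoder
            weights = init_from_columns(X0, K)
            weights, _ = fit_autoencoder(X0, init=weights, config=cc,
                                         max_iter=cc.max_iter)
    masks = np.empty((T, K, R, D), dtype=np.float64)
    unit_scores = np.zeros(K)
    trace = [] if keep_weight_trace else None
    for sweep in range(max(1, cc.n_passes)):
        last = sweep == max(1, cc.n_passes) - 1
        unit_scores[:] = 0.0
        for t in range(T):
            X = coincidence_columns(ct, t, sel, use_modulus=cc.use_modulus)
            activity = None
            if np.abs(X).max() < 1e-30:
                if weights is None:
                    weights = init_weights(K, R * D, seed=cfg.seed)
            else:
                weights, _ = step_frame(X, weights, config=cc, seed=cfg.seed)
                H = weights.hidden(X / np.abs(X).max())
                activity = np.sqrt(np.mean(H ** 2, axis=1))
                if anchor_idx is None:
                    unit_scores += np.sum(H ** 2, axis=1) * np.sum(
                        weights.decoder ** 2, axis=0)
            if not last:
                continue
            ms = masks_from_weights(weights, R, D, anchor_indices=anchor_idx,
                                    unit_activity=activity,
                                    eps=cc.eps, mask_source=cc.mask_source)
            masks[t] = ms.masks
            if anchor_idx is not None:
                unit_scores += ms.scores
            if trace is not None:
                trace.append(weights.copy())
    foreground = int(np.argmax(unit_scores))

    ff_dc = analysis.feature_field.values.mean(axis=0)   # per-channel DC
    if aux is not None:
        ff_dc = np.concatenate([ff_dc, [0.0]])
    # rate-energy profile per (frame, channel): weights the DC routing so
    # masks at rates a channel does not occupy cannot leak its sustained level
    energy = np.abs(ct.values)                           # (T, D, R)
    energy_tot = energy.sum(axis=2) + 1e-30
    masked_tensors, spectrograms, waveforms = [], [], [] if reconstruct_audio else None
    for k in range(K):
        mk = masks[:, k].astype(np.float64)              # (T, R, D)
        masked = ct.values * np.transpose(mk, (0, 2, 1))
        mt = CorticalTensor(masked, ct.rates, cmap, ct.frame_rate)
        masked_tensors.append(mt)
        mbar = np.einsum("trd,tdr->td", mk, energy) / energy_tot
        dc = ff_dc[None, :] * mbar                       # (T, D) routed DC
        spec_k = inverse_cortical(
            mt, cmap, scale_phase=analysis.scale_field.values, dc=dc,
            cfs=analysis.spec.cfs, scales=cfg.cortical.scales,
        )
        spectrograms.append(spec_k)
        if reconstruct_audio:
            wav_k, _ = invert_spectrogram(spec_k, cfg, init=mix, seed=cfg.seed)
            n = mix.samples.size
            samples = np.pad(wav_k.samples[:n], (0, max(0, n - wav_k.samples.size)))
            waveforms.append(Waveform(samples, wav_k.sample_rate))

    return SegResult(mix, analysis, masks, masked_tensors, spectrograms,
                     waveforms, foreground, weights, trace,
                     cfg.to_dict(), cfg.seed, warnings)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class SNRReport:
    snr_segregated: np.ndarray           # dB per stream
    snr_mixture: np.ndarray              # dB per stream
    improvement: np.ndarray              # dB per stream
    coincidence_own: np.ndarray          # per stream
    coincidence_other: np.ndarray        # per stream
    pairing: np.ndarray                  # stream -> component index

    def to_dict(self) -> dict:
        return {
            "snr_segregated_db": self.snr_segregated.tolist(),
            "snr_mixture_db": self.snr_mixture.tolist(),
            "improvement_db": self.improvement.tolist(),
            "coincidence_own": self.coincidence_own.tolist(),
            "coincidence_other": self.coincidence_other.tolist(),
            "pairing": self.pairing.tolist(),
        }


def _magnitudes(ct: CorticalTensor, keep: np.ndarray) -> np.ndarray:
    return np.abs(ct.values[:, keep, :])


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.sum(a * b) / (na * nb))


def _db_ratio(signal: float, noise: float) -> float:
    if signal <= 0:
        raise ValueError("zero-power original in SNR computation")
    if noise <= 0:
        return SNR_CAP_DB
    return float(np.clip(10 * np.log10(signal / noise), -SNR_CAP_DB, SNR_CAP_DB))


def cortical_snr(seg: SegResult, originals: GroundTruth,
                 cfg: RunConfig) -> SNRReport:
    """SNR of each segregated stream against its clean source.

    SNR_seg = 10 log10(||X_o||^2 / ||X_s - X_o||^2) on cortical-magnitude
    tensors, SNR_mix likewise with the mixture tensor; improvement is their
    difference. Streams are paired to sources by maximal coincidence.
    """
    cmap = seg.masked_tensors[0].channel_map
    keep = np.flatnonzero(cmap.kinds != 2)               # drop aux channel
    clean = [analyze(c, cfg).tensor for c in originals.components]
    Xo = [np.abs(c.values) for c in clean]
    Xm = np.abs(seg.analysis.tensor.values)
    Xs = [_magnitudes(mt, keep) for mt in seg.masked_tensors]

    K, C = len(Xs), len(Xo)
    sim = np.array([[_cos(Xs[k], Xo[c]) for c in range(C)] for k in range(K)])
    rows, cols = linear_sum_assignment(-sim)
    pairing = np.full(K, -1)
    pairing[rows] = cols

    snr_seg = np.zeros(K)
    snr_mix = np.zeros(K)
    own = np.zeros(K)
    other = np.zeros(K)
    for k in range(K):
        c = pairing[k]
        if c < 0:
            continue
        sig = float(np.sum(Xo[c] ** 2))
        snr_seg[k] = _db_ratio(sig, float(np.sum((Xs[k] - Xo[c]) ** 2)))
        snr_mix[k] = _db_ratio(sig, float(np.sum((Xm - Xo[c]) ** 2)))
        own[k] = sim[k, c]
        others = [sim[k, j] for j in range(C) if j != c]
        other[k] = max(others) if others else 0.0
    return SNRReport(snr_seg, snr_mix, snr_seg - snr_mix, own, other, pairing)


def coincidence_scores(seg: SegResult, originals: GroundTruth,
                       cfg: RunConfig) -> list:
    """(own, other) cortical coincidence per stream, Fig-6B style."""
    report = cortical_snr(seg, originals, cfg)
    return [(float(report.coincidence_own[k]), float(report.coincidence_other[k]))
            for k in range(len(report.coincidence_own))]


# ---------------------------------------------------------------------------
# stimulus-level scoring helpers
# ---------------------------------------------------------------------------

def label_channels_by_component(cfs: np.ndarray, truth: GroundTruth,
                                width_oct: float = 0.15) -> np.ndarray:
    """Assign each spectrogram channel to the component whose tone it serves.

    Returns an (F,) array of component indices, -1 for channels that are
    ambiguous or belong to neither.
    """
    logcf = np.log2(cfs)
    dists = []
    for freqs in truth.component_freqs:
        fl = np.log2(np.asarray(sorted(set(freqs)), dtype=float))
        dists.append(np.min(np.abs(logcf[:, None] - fl[None, :]), axis=1))
    dists = np.stack(dists)                              # (C, F)
    labels = np.argmin(dists, axis=0)
    near = dists.min(axis=0) <= width_oct
    margin = np.sort(dists, axis=0)
    ambiguous = (margin[1] - margin[0]) <= width_oct if len(dists) > 1 else np.zeros(
        cfs.size, bool)
    labels[~near | ambiguous] = -1
    return labels


def stream_component_energy(seg: SegResult, truth: GroundTruth,
                            width_oct: float = 0.15) -> np.ndarray:
    """(K, C) energy of each stream's spectrogram in each component's channels."""
    cfs = seg.analysis.spec.cfs
    labels = label_channels_by_component(cfs, truth, width_oct)
    C = len(truth.component_freqs)
    out = np.zeros((seg.n_streams, C))
    for k, spec in enumerate(seg.spectrograms):
        for c in range(C):
            out[k, c] = float(np.sum(spec.values[:, labels == c] ** 2))
    return out


def tone_energy_fractions(seg: SegResult, truth: GroundTruth,
                          width_oct: float = 0.15) -> np.ndarray:
    """(K, C) fraction of each stream's labeled energy per component."""
    energy = stream_component_energy(seg, truth, width_oct)
    totals = energy.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return energy / totals


def tone_stream_assignment(seg: SegResult, truth: GroundTruth,
                           width_oct: float = 0.08) -> list:
    """Assign each ground-truth tone to the stream carrying most of its energy.

    Returns a list of (frequency_hz, assigned_stream, onset_s) over all
    tones of all components, using each tone's onset window and the
    channels near its frequency.
    """
    fr = seg.analysis.spec.frame_rate
    cfs = seg.analysis.spec.cfs
    n_frames = seg.spectrograms[0].n_frames
    out = []
    for comp, (onsets, freqs) in enumerate(
            zip(truth.onsets, truth.component_freqs)):
        for (t_on, t_off), f in zip(onsets, freqs):
            f0, f1 = int(t_on * fr), min(int(np.ceil(t_off * fr)) + 2, n_frames)
            chans = np.flatnonzero(np.abs(np.log2(cfs / f)) <= width_oct)
            if f1 <= f0 or chans.size == 0:
                continue
            energies = [float(np.sum(s.values[f0:f1][:, chans] ** 2))
                        for s in seg.spectrograms]
            out.append((float(f), int(np.argmax(energies)), float(t_on)))
    return out


def bounce_accuracy(seg: SegResult, truth: GroundTruth,
                    guard_oct: float = 0.1) -> float:
    """Fraction of tones assigned to the register-consistent stream.

    Tones above the crossover frequency should sit in one stream and tones
    below in the other ("bouncing" percept); tones within ``guard_oct`` of
    the crossover are ambiguous and excluded. The better of the two
    stream-to-register pairings is scored.
    """
    crossover = truth.extras["crossover_hz"]
    tones = [(f, k) for f, k, _ in tone_stream_assignment(seg, truth)
             if abs(np.log2(f / crossover)) > guard_oct]
    if not tones:
        return 0.0
    upper_is_0 = sum((f > crossover) == (k == 0) for f, k in tones)
    return max(upper_is_0, len(tones) - upper_is_0) / len(tones)


def ridge_register_fractions(seg: SegResult, crossover_hz: float,
                             rel_threshold: float = 0.1) -> np.ndarray:
    """Per stream, the fraction of active frames whose spectral ridge sits
    above the crossover frequency (register consistency of "bouncing")."""
    out = np.zeros(seg.n_streams)
    cfs = seg.analysis.spec.cfs
    for k, spec in enumerate(seg.spectrograms):
        peaks = spec.values.max(axis=1)
        active = peaks > rel_threshold * (peaks.max() or 1.0)
        if not np.any(active):
            continue
        ridge_cf = cfs[np.argmax(spec.values[active], axis=1)]
        out[k] = float(np.mean(ridge_cf >= crossover_hz))
    return out


# ---------------------------------------------------------------------------
# onset-asynchrony sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepPoint:
    asynchrony: float
    segregated: bool
    dominance: np.ndarray                # per-stream max fraction
    components: np.ndarray               # per-stream dominant component


@dataclass
class SweepResult:
    boundary: Optional[float]            # s, fused->segregated midpoint
    points: list
    message: str = ""


def asynchrony_sweep(asynchronies: Sequence[float], cfg: RunConfig,
                     dominance_threshold: float = 0.7,
                     warm_max_iter: int = 40, n_passes: int = 2,
                     **stim_overrides) -> SweepResult:
    """Run the full pipeline per onset asynchrony and locate the boundary.

    A run counts as segregated when the two streams are dominated (at or
    above ``dominance_threshold`` of labeled energy) by different
    complexes. The boundary is the midpoint between the largest
    non-segregating and the smallest consistently-segregating asynchrony.

    Near-threshold asynchronies sit at shallow optima of the per-frame
    factorization, so the sweep runs a higher optimization-effort profile
    than the pipeline default (more warm L-BFGS iterations and a second
    sweep of the frame loop); otherwise the fused/segregated call close to
    the boundary is decided by optimizer under-convergence rather than by
    the stimulus.
    """
    taus = sorted(float(t) for t in asynchronies)
    run_cfg = RunConfig.from_dict(cfg.to_dict())
    run_cfg.cluster.warm_max_iter = warm_max_iter
    run_cfg.cluster.n_passes = n_passes
    st = run_cfg.stimuli
    kwargs = dict(base_freqs=st.base_freqs, overlap_freqs=st.overlap_freqs,
                  tone_dur=st.tone_dur, period=st.period, reps=st.reps,
                  sr=run_cfg.periphery.sample_rate)
    kwargs.update(stim_overrides)
    points = []
    for tau in taus:
        mix, truth = gen_tone_complexes(onset_asynchrony=tau, **kwargs)
        seg = segregate(mix, run_cfg, reconstruct_audio=False)
        frac = tone_energy_fractions(seg, truth)
        dominant = np.argmax(frac, axis=1)
        dominance = frac.max(axis=1)
        segregated = (len(set(dominant.tolist())) == seg.n_streams
                      and bool(np.all(dominance >= dominance_threshold)))
        points.append(SweepPoint(tau, segregated, dominance, dominant))
        log.info("asynchrony %.0f ms: %s (dominance %s)", tau * 1e3,
                 "segregated" if segregated else "fused",
                 np.round(dominance, 3))
    flags = [p.segregated for p in points]
    if not any(flags):
        return SweepResult(None, points, "no segregation in range")
    # smallest asynchrony from which every larger one also segregates
    idx = len(flags) - 1
    while idx > 0 and flags[idx - 1]:
        idx -= 1
    if idx == 0:
        return SweepResult(taus[0], points,
                           "segregated over the whole range")
    boundary = 0.5 * (taus[idx - 1] + taus[idx])
    return SweepResult(boundary, points, "")
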