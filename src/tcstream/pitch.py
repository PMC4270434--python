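"""Harmonic-template pitch salience (pitch-gram).

Each candidate fundamental on a log-spaced grid owns a template of Gaussian
bumps at its harmonics on the log-frequency channel axis, with 1/sqrt(k)
amplitude decay. Per-frame salience is the cosine similarity between the
spectral slice and the template, so a missing-fundamental complex still
peaks at its common fundamental while a pure tone peaks at its own
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .cortical import (KIND_PITCH, ChannelMap, FeatureField, ScaleField,
                       spectral_channel_map)
from .periphery import AudSpec


@dataclass
class PitchGram:
    values: np.ndarray           # (T, P) salience in [0, 1]
    pitch_grid: np.ndarray       # (P,) candidate fundamentals, Hz
    frame_rate: float
    frame_norms: Optional[np.ndarray] = None  # (T,) spectral slice norms


def harmonic_templates(cfs: np.ndarray, grid: Sequence[float],
                       n_harm: int = 8,
                       bump_width_channels: float = 2.0) -> np.ndarray:
    """(P, F) unit-norm harmonic templates on the log-frequency axis.

    Harmonics above the top center frequency are dropped (truncated
    template); weights decay as 1/sqrt(k).
    """
    logf = np.log2(cfs)
    spacing = (logf[-1] - logf[0]) / (cfs.size - 1)
    sigma = bump_width_channels * spacing
    templates = np.zeros((len(grid), cfs.size))
    for i, p in enumerate(grid):
        for k in range(1, n_harm + 1):
            fk = k * p
            if fk > cfs[-1]:
                break
            templates[i] += (k ** -0.5) * np.exp(
                -((logf - np.log2(fk)) ** 2) / (2 * sigma ** 2)
            )
    # normalize by the norm of a complete template (unit bump at mid-axis,
    # all n_harm weights), so candidates whose harmonics fall off the axis
    # are penalized rather than advantaged
    mid = 0.5 * (logf[0] + logf[-1])
    bump_norm = np.linalg.norm(np.exp(-((logf - mid) ** 2) / (2 * sigma ** 2)))
    weight_norm = np.sqrt(sum(1.0 / k for k in range(1, n_harm + 1)))
    templates /= bump_norm * weight_norm
    return templates


def pitch_salience(spec: AudSpec, grid: Optional[Sequence[float]] = None,
                   n_harm_template: Optional[int] = None,
                   cfg: Optional[RunConfig] = None) -> PitchGram:
    """Per-frame normalized harmonic-template salience over the pitch grid.

    Salience is scale-invariant (cosine similarity); an empty frame yields
    a zero salience row.
    """
    pc = cfg.pitch if cfg is not None else None
    if grid is None:
        grid = pc.grid() if pc is not None else tuple(
            50.0 * 2 ** (k / 48) for k in range(208)
        )
    if n_harm_template is None:
        n_harm_template = pc.n_harm_template if pc is not None else 8
    width = pc.bump_width_channels if pc is not None else 2.0
    T = harmonic_templates(spec.cfs, grid, n_harm_template, width)
    norms = np.linalg.norm(spec.values, axis=1)
    sal = spec.values @ T.T
    active = norms > 0
    sal[active] /= norms[active, None]
    sal[~active] = 0.0
    return PitchGram(np.clip(sal, 0.0, 1.0), np.asarray(grid, float),
                     spec.frame_rate, norms)


def estimate_pitch(pg: PitchGram, frames: Optional[slice] = None) -> float:
    """Grid frequency of maximal energy-weighted time-averaged salience.

    Weighting by the spectral slice norm keeps silent or transient frames
    (whose normalized salience is uninformative) from biasing the average.
    """
    values = pg.values if frames is None else pg.values[frames]
    if values.size == 0 or values.max() == 0:
        raise ValueError("no salience to estimate a pitch from")
    if pg.frame_norms is not None:
        w = pg.frame_norms if frames is None else pg.frame_norms[frames]
        total = w.sum()
        if total > 0:
            mean = (values * w[:, None]).sum(axis=0) / total
            return float(pg.pitch_grid[np.argmax(mean)])
    return float(pg.pitch_grid[np.argmax(values.mean(axis=0))])


def build_feature_field(sf: ScaleField, pg: Optional[PitchGram] = None,
                        pitch_gain: float = 1.0,
                        sharpen_exp: float = 4.0) -> FeatureField:
    """Concatenate |scale outputs| with gain-scaled pitch salience channels.

    The salience entering the feature field is contrast-sharpened
    (``salience ** sharpen_exp``) so that the broad cosine-similarity
    background (~0.4 for an unrelated complex) does not inject correlated
    activity across pitch channels of different sources. Salience is O(1)
    while compressed spectral envelopes are orders of magnitude smaller,
    so the sharpened pitch block is rescaled to the spectral block's RMS;
    ``pitch_gain`` then weights the two blocks relative to that equal
    footing.
    """
    T, F, S = sf.values.shape
    spectral = np.abs(sf.values).transpose(0, 2, 1).reshape(T, S * F)
    cmap = spectral_channel_map(sf.cfs, sf.scales)
    if pg is None or pg.values.shape[1] == 0:
        return FeatureField(spectral, cmap, sf.frame_rate)
    if pg.values.shape[0] != T:
        raise ValueError(
            f"frame mismatch: scale field has {T} frames, "
            f"pitch-gram has {pg.values.shape[0]}"
        )
    P = pg.pitch_grid.size
    salience = pg.values ** sharpen_exp
    spec_rms = float(np.sqrt(np.mean(spectral ** 2)))
    sal_rms = float(np.sqrt(np.mean(salience ** 2)))
    scale = pitch_gain * (spec_rms / sal_rms if sal_rms > 0 else 1.0)
    values = np.concatenate([spectral, scale * salience], axis=1)
    kinds = np.concatenate([cmap.kinds, np.full(P, KIND_PITCH)])
    cf = np.concatenate([cmap.cf, np.full(P, np.nan)])
    scale = np.concatenate([cmap.scale, np.full(P, np.nan)])
    pitch_hz = np.concatenate([cmap.pitch_hz, pg.pitch_grid])
    cmap = ChannelMap(kinds, cf, scale, pitch_hz, F, S)
    return FeatureField(values, cmap, sf.frame_rate)
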