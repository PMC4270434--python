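"""Per-rate coincidence (C-) matrices and anchored column selection.

At each frame the model forms, for every rate r, the outer product of the
complex rate-filtered channel vector with itself; the real part keeps the
sign distinction between coherent (positive) and anti-correlated channels.
The R blocks are stacked vertically so one auto-encoder decomposition
couples all rates. Attention modes select a subset of columns: a pitch
range, explicit channels, or the auxiliary (envelope / lip) channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .cortical import ChannelMap, CorticalTensor, FeatureField, rate_transform


@dataclass
class CMatrixStack:
    """Per-rate D x D coincidence blocks at one frame."""

    blocks: np.ndarray           # (R, D, D) real
    frame_index: int

    @property
    def stacked(self) -> np.ndarray:
        R, D, _ = self.blocks.shape
        return self.blocks.reshape(R * D, D)


@dataclass
class AnchorSpec:
    """Which C-matrix columns drive the decomposition (the model's attention).

    mode "all": every column; "pitch_range": pitch channels whose candidate
    fundamental lies in ``pitch_range`` Hz; "channel_set": explicit channel
    indices; "aux": the auxiliary co-modulated channel.
    """

    mode: str = "all"
    pitch_range: Optional[tuple] = None
    channels: Optional[Sequence[int]] = None

    def resolve(self, channel_map: ChannelMap) -> np.ndarray:
        if self.mode == "all":
            idx = np.arange(channel_map.n_channels)
        elif self.mode == "pitch_range":
            lo, hi = self.pitch_range
            idx = channel_map.pitch_in_range(lo, hi)
        elif self.mode == "channel_set":
            idx = np.asarray(list(self.channels), dtype=int)
        elif self.mode == "aux":
            idx = channel_map.aux_indices()
        else:
            raise ValueError(f"unknown anchor mode {self.mode!r}")
        if idx.size == 0:
            raise ValueError(
                f"anchor {self.mode!r} selected no columns "
                f"(channel map: {channel_map.n_channels} channels, "
                f"{channel_map.pitch_indices().size} pitch, "
                f"{channel_map.aux_indices().size} aux)"
            )
        return idx

    @classmethod
    def parse(cls, text: Optional[str]) -> "AnchorSpec":
        """Parse 'pitch:450-550' | 'channels:1,2,3' | 'aux' | 'all'."""
        if text is None or text == "all":
            return cls("all")
        if text == "aux":
            return cls("aux")
        kind, _, arg = text.partition(":")
        if kind == "pitch":
            lo, _, hi = arg.partition("-")
            return cls("pitch_range", pitch_range=(float(lo), float(hi)))
        if kind == "channels":
            return cls("channel_set", channels=[int(v) for v in arg.split(",")])
        raise ValueError(f"cannot parse anchor spec {text!r}")


def coincidence_stack(ct: CorticalTensor, t: int,
                      use_modulus: bool = False,
                      normalize: bool = False,
                      eps: float = 1e-8) -> CMatrixStack:
    """All R coincidence matrices at frame ``t``.

    block_r = Re{ z_r z_r^H } (or its modulus), optionally normalized to
    correlations with an ``eps`` floor on the diagonal.
    """
    if not 0 <= t < ct.n_frames:
        raise IndexError(f"frame {t} out of range [0, {ct.n_frames})")
    z = ct.values[t]                           # (D, R)
    prod = np.einsum("dr,er->rde", z, np.conj(z))
    blocks = np.abs(prod) if use_modulus else np.real(prod)
    if normalize:
        diag = np.sqrt(np.maximum(np.einsum("rdd->rd", blocks), 0.0))
        denom = diag[:, :, None] * diag[:, None, :] + eps
        blocks = blocks / denom
    return CMatrixStack(np.ascontiguousarray(blocks), t)


def coincidence_columns(ct: CorticalTensor, t: int, indices: np.ndarray,
                        use_modulus: bool = False) -> np.ndarray:
    """Selected columns of the stacked C-matrix, shape (R*D, n_sel).

    Equivalent to ``coincidence_stack(ct, t).stacked[:, indices]`` but
    without materializing the full D x D blocks.
    """
    z = ct.values[t]                           # (D, R)
    prod = np.einsum("dr,er->rde", z, np.conj(z[indices]))
    cols = np.abs(prod) if use_modulus else np.real(prod)
    R, D, n_sel = cols.shape
    return cols.reshape(R * D, n_sel)


def select_columns(cms: CMatrixStack, anchor: AnchorSpec,
                   channel_map: ChannelMap) -> tuple[np.ndarray, np.ndarray]:
    """Columns of the stacked C-matrix for the anchor's channels."""
    idx = anchor.resolve(channel_map)
    return cms.stacked[:, idx], idx


def augment_with_aux(ct: CorticalTensor, aux: np.ndarray,
                     cfg: Optional[RunConfig] = None) -> CorticalTensor:
    """Append one rate-filtered auxiliary channel to the tensor (D -> D+1).

    The aux series must already be sampled at the spectrogram frame rate
    and match the tensor's frame count; its C-matrix column then encodes
    the coincidence of every channel with the auxiliary signal.
    """
    aux = np.asarray(aux, dtype=np.float64).ravel()
    if aux.size != ct.n_frames:
        raise ValueError(
            f"aux series has {aux.size} frames, tensor has {ct.n_frames}"
        )
    cmap = ct.channel_map.with_aux()
    ff = FeatureField(aux[:, None], cmap, ct.frame_rate)
    aux_ct = rate_transform(ff, ct.rates)
    values = np.concatenate([ct.values, aux_ct.values], axis=1)
    return CorticalTensor(values, ct.rates, cmap, ct.frame_rate)
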