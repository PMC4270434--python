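"""WAV and HDF5 readers/writers plus provenance bookkeeping."""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Optional

import h5py
import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from . import __version__
from .config import RunConfig

log = logging.getLogger("tcstream")

_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path, target_sr: Optional[int] = None):
    """Read a WAV file as a mono float waveform in [-1, 1].

    PCM16/PCM32 are rescaled to float; stereo is downmixed with a warning;
    resampled with a polyphase filter when ``target_sr`` differs.
    Returns ``(samples, sample_rate)``.
    """
    sr, data = wavfile.read(path)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path!r}")
    if samples.ndim == 2:
        log.warning("downmixing %d-channel input %r to mono", samples.shape[1], path)
        samples = samples.mean(axis=1)
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"non-finite samples in {path!r}")
    if target_sr is not None and target_sr != sr:
        log.info("resampling %r from %d to %d Hz", path, sr, target_sr)
        samples = resample_waveform(samples, sr, target_sr)
        sr = target_sr
    return samples, sr


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write a float32 WAV, normalizing only if the peak exceeds 1."""
    samples = np.asarray(samples, dtype=np.float64)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        log.warning("peak %.3f > 1; normalizing %r on write", peak, path)
        samples = samples / peak
    wavfile.write(path, int(sample_rate), samples.astype(np.float32))


def resample_waveform(samples: np.ndarray, sr_in: int, sr_out: int) -> np.ndarray:
    frac = Fraction(int(sr_out), int(sr_in)).limit_denominator(1000)
    return resample_poly(samples, frac.numerator, frac.denominator)


def _provenance(group: h5py.Group, config: Optional[RunConfig], seed: Optional[int]):
    group.attrs["tcstream_version"] = __version__
    if config is not None:
        group.attrs["config_hash"] = config.hash()
    if seed is not None:
        group.attrs["seed"] = int(seed)


def write_h5(path, datasets: dict, attrs: Optional[dict] = None,
             config: Optional[RunConfig] = None, seed: Optional[int] = None):
    """Write a flat mapping of dataset-name -> array, with provenance attrs."""
    with h5py.File(path, "w") as fh:
        for name, value in datasets.items():
            fh.create_dataset(name, data=np.asarray(value))
        for key, value in (attrs or {}).items():
            fh.attrs[key] = value
        _provenance(fh, config, seed)


def read_h5(path) -> tuple[dict, dict]:
    """Read every dataset (and root attrs) from an HDF5 file."""
    out, attrs = {}, {}
    with h5py.File(path, "r") as fh:
        def _visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        fh.visititems(_visit)
        attrs.update(fh.attrs)
    return out, attrs


def read_aux_series(path) -> np.ndarray:
    """Load a 1-D auxiliary trace from plain text or HDF5 (/aux or sole dataset)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        data, _ = read_h5(path)
        if "aux" in data:
            arr = data["aux"]
        elif len(data) == 1:
            arr = next(iter(data.values()))
        else:
            raise ValueError(f"{path!r}: ambiguous HDF5 aux file (datasets {sorted(data)})")
    else:
        arr = np.loadtxt(path)
    arr = np.asarray(arr, dtype=np.float64).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in aux series {path!r}")
    return arr
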