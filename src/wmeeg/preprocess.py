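"""Signal cleaning chain: bad-channel removal, peak-noise thresholding,
average re-referencing and mean filtering.

Stages run in that fixed order; each can be disabled independently. The
peak-noise stage treats the amplitude threshold as a clipping bound:
out-of-range samples are replaced by linear interpolation between the
nearest in-range neighbours rather than rejecting the whole trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .recording import Recording

__all__ = [
    "PreprocessConfig",
    "remove_bad_channels",
    "threshold_peak_noise",
    "rereference_average",
    "mean_filter",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Tunables of the cleaning chain.

    amplitude_threshold
        Bound in microvolts beyond which a sample is treated as peak noise.
        100 uV is a conventional artifact bound for scalp EEG.
    bad_channel_flat_tol
        Variance floor below which a channel counts as flat (disconnected).
    mean_filter_width
        Odd window length of the smoothing moving average, in samples.
        Width 5 at 1000 Hz leaves the gamma band (30-44 Hz) largely intact.
    """

    amplitude_threshold: float = 100.0
    bad_channel_flat_tol: float = 1e-12
    mean_filter_width: int = 5
    do_remove_bad_channels: bool = True
    do_threshold: bool = True
    do_rereference: bool = True
    do_mean_filter: bool = True

    def __post_init__(self) -> None:
        if self.amplitude_threshold <= 0:
            raise ValueError("amplitude_threshold must be > 0")
        if self.bad_channel_flat_tol <= 0:
            raise ValueError("bad_channel_flat_tol must be > 0")
        if self.mean_filter_width < 1 or self.mean_filter_width % 2 == 0:
            raise ValueError("mean_filter_width must be odd and >= 1")


def remove_bad_channels(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[Recording, list[str]]:
    """Drop channels that are flat (variance below the floor) or contain
    non-finite samples; returns the reduced recording and the removed names."""
    cfg = cfg or PreprocessConfig()
    bad: list[str] = []
    keep: list[int] = []
    for i, name in enumerate(rec.channel_names):
        ch = rec.data[i]
        if not np.isfinite(ch).all() or (ch.size and ch.var() < cfg.bad_channel_flat_tol):
            bad.append(name)
        else:
            keep.append(i)
    if not keep:
        raise ValueError("all channels are bad; recording is unusable")
    if not bad:
        return rec, []
    out = replace(
        rec,
        channel_names=[rec.channel_names[i] for i in keep],
        data=rec.data[keep],
    )
    return out, bad


def threshold_peak_noise(signal: np.ndarray, threshold: float) -> np.ndarray:
    """Replace samples with |value| > threshold by linear interpolation
    between the nearest in-range neighbours; leading/trailing runs without a
    neighbour are clamped into [-threshold, threshold]."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.asarray(signal, dtype=float)
    bad = np.abs(x) > threshold
    if not bad.any():
        return x.copy()
    if bad.all():
        raise ValueError("every sample exceeds the threshold")
    out = x.copy()
    idx = np.arange(x.size)
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    # np.interp holds the first/last good value beyond the good range, which
    # is already in range; clamp defensively anyway.
    np.clip(out, -threshold, threshold, out=out)
    return out


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def mean_filter(signal: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically-as-possible
    at the edges (it spans max(0, i-h) .. min(n, i+h+1))."""
    x = np.asarray(signal, dtype=float)
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if width > x.size:
        raise ValueError("width exceeds signal length")
    h = width // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(x.size)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def preprocess_pipeline(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> Recording:
    """Apply the enabled stages in their fixed order:
    bad channels -> peak-noise threshold -> average re-reference -> mean filter.
    """
    cfg = cfg or PreprocessConfig()
    out = rec
    if cfg.do_remove_bad_channels:
        out, removed = remove_bad_channels(out, cfg)
        if removed:
            warnings.warn(f"removed bad channels: {removed}", stacklevel=2)
    if cfg.do_threshold:
        out = replace(
            out,
            data=np.vstack(
                [threshold_peak_noise(ch, cfg.amplitude_threshold) for ch in out.data]
            ),
        )
    if cfg.do_rereference:
        out = rereference_average(out)
    if cfg.do_mean_filter and out.n_samples >= cfg.mean_filter_width:
        out = replace(
            out,
            data=np.vstack([mean_filter(ch, cfg.mean_filter_width) for ch in out.data]),
        )
    return out
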