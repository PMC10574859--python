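"""Band powers, band power ratios, 30-component feature vectors, and
z-score standardization of features and performance labels.

A feature vector holds, channel-major, the alpha (8-13 Hz), beta
(13-30 Hz) and gamma (30-44 Hz) band power ratios of each montage channel,
each normalised by the total 1-44 Hz power, so the full 10-channel montage
yields 30 components. Band edges are half-open [lo, hi): the printed bands
share endpoints, so 13 Hz belongs to beta only.

Performance labels are z-scores of inverse task completion time: the faster
a subject finishes the memory task, the larger the label, and the score
expresses the subject's ranking within the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Montage, Recording

__all__ = [
    "BandDefinition",
    "ALPHA",
    "BETA",
    "GAMMA",
    "TOTAL",
    "DEFAULT_BANDS",
    "FeatureVector",
    "ZScaler",
    "PerformanceLabel",
    "band_power",
    "band_power_ratio",
    "extract_features",
    "zscore_fit",
    "zscore_apply",
    "performance_label",
    "feature_table",
    "read_feature_table",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, exclusive

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 < lo < hi")


ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 44.0)
TOTAL = BandDefinition("total", 1.0, 44.0)
DEFAULT_BANDS = (ALPHA, BETA, GAMMA)


@dataclass
class FeatureVector:
    """Ordered band-power-ratio features, channel-major
    (per channel: alpha, beta, gamma)."""

    subject_id: str
    trial_id: str
    state: str
    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    band_names: tuple[str, ...] = ("alpha", "beta", "gamma")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size

    def as_matrix(self) -> np.ndarray:
        """Reshape to (n_channels, n_bands)."""
        return self.values.reshape(-1, len(self.band_names))


def band_power(signal: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Power in [band.lo, band.hi) from the Hann-windowed periodogram of
    the full segment (no Welch averaging)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if band.hi > fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz exceeds Nyquist {fs / 2} Hz"
        )
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann")
    mask = (freqs >= band.lo) & (freqs < band.hi)
    return float(pxx[mask].sum())


def band_power_ratio(
    signal: np.ndarray, fs: float, band: BandDefinition, total: BandDefinition = TOTAL
) -> float:
    """band_power(band) / band_power(total); 0 with a warning when the
    total band carries no power."""
    if band.lo < total.lo or band.hi > total.hi:
        raise ValueError(f"band {band.name} not contained in {total.name}")
    denom = band_power(signal, fs, total)
    if denom == 0.0:
        warnings.warn("total band power is zero; returning ratio 0", stacklevel=2)
        return 0.0
    return band_power(signal, fs, band) / denom


def extract_features(
    rec: Recording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    total: BandDefinition = TOTAL,
    montage: Montage | None = None,
) -> FeatureVector:
    """Assemble the channel-major ratio vector (len = n_bands x n_channels).

    When a montage is given, channels are taken in montage order and a
    missing channel is an error; otherwise the recording's own channel
    order is used (degraded montages are allowed and simply yield fewer
    components).
    """
    if montage is not None:
        order = list(montage.required_channels)
    else:
        order = list(rec.channel_names)
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for ch in order:
            try:
                x = rec.channel(ch)
            except KeyError as exc:
                raise ValueError(f"required channel {ch!r} missing") from exc
            for band in bands:
                values.append(band_power_ratio(x, rec.fs, band, total))
    return FeatureVector(
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        state=rec.state,
        values=np.array(values),
        channel_names=order,
        band_names=tuple(b.name for b in bands),
    )


@dataclass
class ZScaler:
    """Per-dimension standardizer z = (x - mu) / sigma with population
    (divide-by-n) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive on every dimension")


def zscore_fit(X: np.ndarray) -> ZScaler:
    """Fit means and population standard deviations column-wise; a
    zero-variance dimension is an error."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a z-scaler")
    sigma = X.std(axis=0)  # population (ddof=0)
    if (sigma == 0).any():
        bad = np.flatnonzero(sigma == 0).tolist()
        raise ValueError(f"zero variance on dimension(s) {bad}")
    return ZScaler(mu=X.mean(axis=0), sigma=sigma)


def zscore_apply(scaler: ZScaler, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != scaler.mu.size:
        raise ValueError(
            f"input dimension {x.shape[-1]} != scaler dimension {scaler.mu.size}"
        )
    return (x - scaler.mu) / scaler.sigma


@dataclass
class PerformanceLabel:
    """Task performance: completion time, its inverse, and the cohort
    z-score of the inverse (larger z = faster = better)."""

    subject_id: str
    trial_id: str
    time_seconds: float
    inverse_time: float
    z: float


def performance_label(
    times: "np.ndarray | list[float]",
    subject_ids: "list[str] | None" = None,
    trial_ids: "list[str] | None" = None,
) -> list[PerformanceLabel]:
    """Z-score inverse completion times over the whole group.

    The group passed in defines the standardization cohort (all trials of
    the same task type across subjects).
    """
    t = np.asarray(times, dtype=float)
    if (t <= 0).any():
        raise ValueError("completion times must be positive")
    x = 1.0 / t
    scaler = zscore_fit(x[:, None])
    z = zscore_apply(scaler, x[:, None]).ravel()
    n = t.size
    subject_ids = subject_ids or [f"s{i}" for i in range(n)]
    trial_ids = trial_ids or [f"t{i}" for i in range(n)]
    return [
        PerformanceLabel(subject_ids[i], trial_ids[i], float(t[i]), float(x[i]), float(z[i]))
        for i in range(n)
    ]


def feature_table(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors: columns subject, trial, state, then
    <channel>_<band> in channel-major order."""
    if not fvs:
        raise ValueError("no feature vectors given")
    cols = [
        f"{ch}_{band}" for ch in fvs[0].channel_names for band in fvs[0].band_names
    ]
    rows = []
    for fv in fvs:
        rows.append([fv.subject_id, fv.trial_id, fv.state, *fv.values])
    return pd.DataFrame(rows, columns=["subject", "trial", "state", *cols])


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
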