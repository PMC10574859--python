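"""Synthetic working-memory study generator.

Emulates the study conditions end to end so the whole pipeline is testable
without recorded data: a cohort of subjects with a latent standard-normal
working-memory ability, resting and task band-power-ratio features obeying
the working-memory model (task onset lowers the alpha ratio and raises
beta/gamma, more so for abler subjects), raw band-limited time series that
invert the feature extractor, and noisy task-completion-time labels whose
inverse is z-scored into the performance score.

The generative model works on log band powers. Per channel c with region
coupling r_c, the log power of band b is

    l_b = log(baseline_b) + trait_b [+ s_b * effect * r_c * softplus(1 + 0.8 theta) if task]
          + N(0, noise_sd) truncated at 3 sd

with band signs s_alpha = -1, s_beta = s_gamma = +1 (s = 0 for the 1-8 Hz
remainder), baselines alpha/beta/gamma/remainder = 0.45/0.20/0.10/0.25
(alpha-dominant resting EEG), and trait_b a per-subject, per-channel,
per-band offset (truncated Gaussian, sd ``subject_offset_sd``, cut at
2 sd) shared between the resting and task states — the stable individual
spectral fingerprint ("mind print") that makes subject-grouped validation
necessary. Ratios are the softmax composition of the four components
scaled by 0.95, so each lies in (0, 0.95) and the three bands sum to at
most 0.95 of total power. Because the softmax is monotone and the task
shift is strictly positive for every ability value, the energy-shift
proposition (alpha down, beta/gamma up) holds exactly for every subject
and channel at zero trial noise, whatever the trait offsets; the shift
grows with ability. Region couplings are strongest occipitally and
weakest frontally, mirroring the empirical pattern that prefrontal
channels engage higher cognition rather than the memory task itself.

Completion times are log-normal, T = 60 * exp(-0.3 * theta + eps) seconds
with eps ~ N(0, label_noise_sd): positive, right-skewed, and monotone
decreasing in ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureVector, PerformanceLabel, performance_label
from .recording import DEFAULT_CHANNELS, Recording

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "simulate_abilities",
    "simulate_subject_offsets",
    "simulate_band_ratios",
    "simulate_timeseries",
    "simulate_labels",
    "generate_dataset",
    "features_matrix",
    "labels_vector",
    "rest_task_arrays",
]

REST_BASELINES = {"alpha": 0.45, "beta": 0.20, "gamma": 0.10, "remainder": 0.25}
BAND_SIGNS = np.array([-1.0, +1.0, +1.0, 0.0])  # alpha down, beta/gamma up on task
T0_SECONDS = 60.0
ABILITY_TIME_SLOPE = 0.3
RATIO_SUM_CAP = 0.95

#: per-channel coupling of the latent ability to the band-ratio shift;
#: occipital (cuneus) strongest, prefrontal weakest.
REGION_COUPLING = {
    "Fpz": 0.4, "Fz": 0.4,
    "F7": 0.7, "F8": 0.7, "T7": 0.7, "T8": 0.7,
    "Cz": 0.9, "Pz": 0.9,
    "Poz": 1.0, "Oz": 1.0,
}


@dataclass
class SynthConfig:
    n_subjects: int = 20
    n_sessions: int = 2
    n_trials_per_session: int = 3
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 1000.0
    segment_seconds: float = 2.0
    effect_size: float = 0.5  # log-power coupling of ability to ratio shifts
    noise_sd: float = 0.3  # log-power trial noise
    subject_offset_sd: float = 0.5  # per-subject spectral trait ("mind print")
    label_noise_sd: float = 0.2  # log-time noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sessions, self.n_trials_per_session) < 1:
            raise ValueError("cohort counts must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.effect_size < 0 or self.noise_sd < 0 or self.label_noise_sd < 0:
            raise ValueError("effect and noise magnitudes must be >= 0")

    @property
    def n_task_records(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_trials_per_session


@dataclass
class SynthRecord:
    subject_id: str
    trial_id: str
    task_type: str
    true_ability: float
    rest_features: FeatureVector
    task_features: FeatureVector
    time_seconds: float
    label: PerformanceLabel | None = None


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_abilities(cfg: SynthConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. standard-normal latent ability per subject, seeded."""
    rng = rng or np.random.default_rng(cfg.seed)
    return rng.standard_normal(cfg.n_subjects)


def _coupling(cfg: SynthConfig) -> np.ndarray:
    return np.array([REGION_COUPLING.get(c, 0.8) for c in cfg.channels])


def _truncated_normal(
    rng: np.random.Generator, sd: float, size, cut: float
) -> np.ndarray:
    """Gaussian noise with tails clipped at ``cut`` standard deviations."""
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size=size), -cut * sd, cut * sd)


def simulate_subject_offsets(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Stable per-subject spectral fingerprint: (n_subjects, C, 4)
    log-power offsets, truncated Gaussian, identical in rest and task."""
    rng = rng or np.random.default_rng(cfg.seed)
    return _truncated_normal(
        rng, cfg.subject_offset_sd, (cfg.n_subjects, len(cfg.channels), 4), cut=2.0
    )


def simulate_band_ratios(
    theta: np.ndarray,
    state: str,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Band-power ratios for a batch of records.

    theta: (n,) latent ability per record; offsets: optional (n, C, 4)
    per-record subject trait offsets (freshly drawn when omitted). Returns
    (n, n_channels, 3) ratios in band order (alpha, beta, gamma), each in
    (0, 0.95) with the three bands summing to at most 0.95.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    n, C = theta.size, len(cfg.channels)
    base = np.log(
        [REST_BASELINES[b] for b in ("alpha", "beta", "gamma", "remainder")]
    )
    logp = np.broadcast_to(base, (n, C, 4)).copy()
    if offsets is None:
        offsets = _truncated_normal(rng, cfg.subject_offset_sd, (n, C, 4), cut=2.0)
    logp += offsets
    if state == "task":
        drive = _softplus(1.0 + 0.8 * theta)  # (n,), strictly positive
        logp += (
            cfg.effect_size
            * drive[:, None, None]
            * _coupling(cfg)[None, :, None]
            * BAND_SIGNS[None, None, :]
        )
    elif state != "rest":
        raise ValueError("state must be 'rest' or 'task'")
    if cfg.noise_sd > 0:
        logp += _truncated_normal(rng, cfg.noise_sd, logp.shape, cut=3.0)
    powers = np.exp(logp)
    shares = RATIO_SUM_CAP * powers / powers.sum(axis=2, keepdims=True)
    return shares[:, :, :3]


def simulate_timeseries(
    target_ratios: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
    trial_id: str = "t0",
    state: str = "task",
    task_type: str = "none",
) -> Recording:
    """Synthesize a recording whose extracted band-power ratios match the
    (n_channels, 3) targets.

    Each channel is a sum of band-limited Gaussian noise components
    (1-8, 8-13, 13-30, 30-44 Hz, constructed in the Fourier domain) with
    component variances proportional to the target power fractions; the
    1-8 Hz component absorbs the remainder of the total (1-44 Hz) power.
    """
    targets = np.atleast_2d(np.asarray(target_ratios, dtype=float))
    if targets.ndim != 2 or targets.shape[1] != 3:
        raise ValueError("target_ratios must be (n_channels, 3)")
    if ((targets <= 0) | (targets >= 1)).any() or (targets.sum(axis=1) >= 1).any():
        raise ValueError("ratios must lie in (0, 1) and sum to < 1 per channel")
    if cfg.fs < 2 * 44.0:
        raise ValueError("sampling rate too low for the gamma band")
    from .features import BandDefinition, band_power

    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.segment_seconds))
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    band_edges = [(1.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 44.0)]
    data = np.zeros((targets.shape[0], n))
    for ci, (ra, rb_, rg) in enumerate(targets):
        fractions = [1.0 - (ra + rb_ + rg), ra, rb_, rg]
        x = np.zeros(n)
        for (lo, hi), frac in zip(band_edges, fractions):
            mask = (freqs >= lo) & (freqs < hi)
            spec = np.zeros(freqs.size, dtype=complex)
            phases = rng.uniform(0, 2 * np.pi, size=int(mask.sum()))
            spec[mask] = np.exp(1j * phases)
            comp = np.fft.irfft(spec, n=n)
            # random phases interfere under the analysis window, so calibrate
            # against the same periodogram the feature extractor uses
            measured = band_power(comp, cfg.fs, BandDefinition("comp", lo, hi))
            if measured > 0:
                comp *= np.sqrt(frac / measured)
            x += comp
        data[ci] = 50.0 * x  # scale to a plausible microvolt range
    return Recording(
        subject_id=subject_id,
        trial_id=trial_id,
        state=state,
        task_type=task_type,
        fs=cfg.fs,
        channel_names=list(cfg.channels),
        data=data,
    )


def simulate_labels(
    theta: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    subject_ids: list[str] | None = None,
    trial_ids: list[str] | None = None,
) -> tuple[np.ndarray, list[PerformanceLabel]]:
    """Log-normal completion times, monotone decreasing in ability, and the
    cohort z-scores of their inverses."""
    rng = rng or np.random.default_rng(cfg.seed)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eps = rng.normal(0.0, cfg.label_noise_sd, size=theta.size) if cfg.label_noise_sd > 0 else 0.0
    times = T0_SECONDS * np.exp(-ABILITY_TIME_SLOPE * theta + eps)
    if theta.size == 1:
        # a cohort of one has no ranking: its z-score is 0 by convention
        labels = [
            PerformanceLabel(
                (subject_ids or ["s0"])[0],
                (trial_ids or ["t0"])[0],
                float(times[0]),
                float(1.0 / times[0]),
                0.0,
            )
        ]
        return times, labels
    labels = performance_label(times, subject_ids, trial_ids)
    return times, labels


def generate_dataset(
    cfg: SynthConfig | None = None,
    outdir: str | Path | None = None,
    include_recordings: bool = False,
) -> list[SynthRecord]:
    """Generate the full cohort: one task record per subject x session x
    trial plus one resting-state feature set per subject; optionally write
    feature/label tables (and raw recordings) to disk.

    Session 1 is the word task, session 2 the picture task; labels are
    z-scored within task type (the standardization group is all trials of
    the same task across subjects).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    theta = simulate_abilities(cfg, rng)
    offsets = simulate_subject_offsets(cfg, rng)
    channels = list(cfg.channels)
    subjects = [f"s{i + 1:03d}" for i in range(cfg.n_subjects)]

    rest_ratios = simulate_band_ratios(theta, "rest", cfg, rng, offsets=offsets)
    rest_fvs = [
        FeatureVector(subjects[s], "rest", "rest", rest_ratios[s].ravel(), channels)
        for s in range(cfg.n_subjects)
    ]

    # one row per task record; theta and trait offsets repeat within subject
    n_rec = cfg.n_task_records
    rec_subject = np.repeat(np.arange(cfg.n_subjects), cfg.n_sessions * cfg.n_trials_per_session)
    rec_theta = theta[rec_subject]
    task_ratios = simulate_band_ratios(
        rec_theta, "task", cfg, rng, offsets=offsets[rec_subject]
    )

    task_types, trial_ids = [], []
    for s in range(cfg.n_subjects):
        for sess in range(cfg.n_sessions):
            ttype = "word" if sess % 2 == 0 else "picture"
            for tr in range(cfg.n_trials_per_session):
                task_types.append(ttype)
                trial_ids.append(f"sess{sess + 1}_trial{tr + 1}")
    task_types_arr = np.array(task_types)

    times = np.empty(n_rec)
    zs = np.empty(n_rec)
    for ttype in np.unique(task_types_arr):
        sel = np.flatnonzero(task_types_arr == ttype)
        t_sel, labels_sel = simulate_labels(rec_theta[sel], cfg, rng)
        times[sel] = t_sel
        zs[sel] = [lab.z for lab in labels_sel]

    records: list[SynthRecord] = []
    for i in range(n_rec):
        s = rec_subject[i]
        fv = FeatureVector(
            subjects[s], trial_ids[i], "task", task_ratios[i].ravel(), channels
        )
        label = PerformanceLabel(
            subjects[s], trial_ids[i], float(times[i]), float(1.0 / times[i]), float(zs[i])
        )
        records.append(
            SynthRecord(
                subject_id=subjects[s],
                trial_id=trial_ids[i],
                task_type=task_types[i],
                true_ability=float(rec_theta[i]),
                rest_features=rest_fvs[s],
                task_features=fv,
                time_seconds=float(times[i]),
                label=label,
            )
        )

    if outdir is not None:
        _write_tables(records, rest_fvs, Path(outdir), cfg, rng, include_recordings)
    return records


def _write_tables(
    records: list[SynthRecord],
    rest_fvs: list[FeatureVector],
    outdir: Path,
    cfg: SynthConfig,
    rng: np.random.Generator,
    include_recordings: bool,
) -> None:
    from .features import feature_table
    from .recording import write_recording

    outdir.mkdir(parents=True, exist_ok=True)
    feature_table([r.task_features for r in records]).to_csv(
        outdir / "task_features.tsv", sep="\t", index=False
    )
    feature_table(rest_fvs).to_csv(outdir / "rest_features.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "trial": [r.trial_id for r in records],
            "task_type": [r.task_type for r in records],
            "time_seconds": [r.time_seconds for r in records],
            "z": [r.label.z for r in records],
            "true_ability": [r.true_ability for r in records],
        }
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if include_recordings:
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for r in records:
            rec = simulate_timeseries(
                r.task_features.as_matrix(),
                cfg,
                rng,
                subject_id=r.subject_id,
                trial_id=r.trial_id,
                state="task",
                task_type=r.task_type,
            )
            write_recording(rec, rec_dir / f"{r.subject_id}_{r.trial_id}.tsv")


def features_matrix(records: list[SynthRecord]) -> np.ndarray:
    """(n, 30) task feature matrix in record order."""
    return np.vstack([r.task_features.values for r in records])


def labels_vector(records: list[SynthRecord]) -> np.ndarray:
    return np.array([r.label.z for r in records])


def rest_task_arrays(records: list[SynthRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-subject arrays for proposition analysis: rest (S, C, 3), task
    (S, T, C, 3) with T trials per subject, and the subject order."""
    subjects = sorted({r.subject_id for r in records})
    by_subj = {s: [r for r in records if r.subject_id == s] for s in subjects}
    counts = {len(v) for v in by_subj.values()}
    if len(counts) != 1:
        raise ValueError("subjects have unequal trial counts")
    rest = np.stack([by_subj[s][0].rest_features.as_matrix() for s in subjects])
    task = np.stack(
        [np.stack([r.task_features.as_matrix() for r in by_subj[s]]) for s in subjects]
    )
    return rest, task, subjects
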