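"""Multichannel EEG recordings: container, montage, and plain-text I/O.

The canonical on-disk representation is a small self-describing columnar
text dialect::

    # fs=1000
    # subject=s01 trial=t01 state=task task_type=word
    Fpz<TAB>Fz<TAB>...
    0.12<TAB>-3.4<TAB>...
    ...

The first comment line declares the sampling rate in Hz and is mandatory;
further ``# key=value`` pairs carry trial metadata. The header row names the
channels and every subsequent row is one sample across channels. EDF files
can be read as a convenience when :mod:`mne` is installed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "MontageReport",
    "RecordingFormatError",
    "DEFAULT_CHANNELS",
    "read_recording",
    "write_recording",
    "validate_montage",
]

#: 10-10 montage used throughout: prefrontal (Fpz), frontal (Fz, F7, F8),
#: temporal (T7, T8), parietal (Cz, Pz) and occipital (Poz, Oz) electrodes.
DEFAULT_CHANNELS = ("Fpz", "Fz", "F7", "F8", "T7", "T8", "Cz", "Pz", "Poz", "Oz")

STATES = ("rest", "task")
TASK_TYPES = ("word", "picture", "none")


class RecordingFormatError(ValueError):
    """Raised when a recording file violates the columnar text dialect."""


def _canon(name: str) -> str:
    """Channel names match case-insensitively with surrounding whitespace
    stripped; montage labels vary across vendors."""
    return name.strip().lower()


@dataclass
class Recording:
    """One EEG segment: ``data`` is channels x samples in microvolts."""

    subject_id: str
    trial_id: str
    state: str
    fs: float
    channel_names: list[str]
    data: np.ndarray
    task_type: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.task_type not in TASK_TYPES:
            raise ValueError(
                f"task_type must be one of {TASK_TYPES}, got {self.task_type!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.data).all())

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector of a channel (case-insensitive lookup)."""
        wanted = _canon(name)
        for i, ch in enumerate(self.channel_names):
            if _canon(ch) == wanted:
                return self.data[i]
        raise KeyError(f"channel {name!r} not present in recording")


@dataclass
class Montage:
    """Required channel set and the region groupings used for analysis.

    Regions follow the anatomical groupings of the study design: the
    superior frontal gyrus maps to the prefrontal/frontal midline electrodes
    (Fpz, Fz), the cuneus to the occipital ones (Poz, Oz), and ``full`` to
    the whole montage.
    """

    required_channels: tuple[str, ...] = DEFAULT_CHANNELS
    region_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.region_map:
            self.region_map = {
                "superior_frontal_gyrus": ("Fpz", "Fz"),
                "cuneus": ("Poz", "Oz"),
                "full": tuple(self.required_channels),
            }
        required = {_canon(c) for c in self.required_channels}
        for region, chans in self.region_map.items():
            if not chans:
                raise ValueError(f"region {region!r} is empty")
            extra = {_canon(c) for c in chans} - required
            if extra:
                raise ValueError(
                    f"region {region!r} refers to channels {sorted(extra)} "
                    "outside the required montage"
                )

    def region_indices(self, region: str) -> list[int]:
        """Indices of a region's channels within ``required_channels`` order."""
        chans = {_canon(c) for c in self.region_map[region]}
        return [i for i, c in enumerate(self.required_channels) if _canon(c) in chans]


@dataclass
class MontageReport:
    ok: bool
    missing: list[str]
    extra: list[str]


def validate_montage(rec: Recording, montage: Montage | None = None) -> MontageReport:
    """Report-only montage check: which required channels are absent and
    which recorded channels are not part of the montage."""
    montage = montage or Montage()
    have = {_canon(c): c for c in rec.channel_names}
    need = {_canon(c): c for c in montage.required_channels}
    missing = [orig for canon, orig in need.items() if canon not in have]
    extra = [orig for canon, orig in have.items() if canon not in need]
    return MontageReport(ok=not missing, missing=missing, extra=extra)


_META_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


def read_recording(path: str | Path, dialect: str = "columnar_text") -> Recording:
    """Read a recording from the columnar text dialect or (optionally) EDF."""
    path = Path(path)
    if dialect == "edf":
        return _read_edf(path)
    if dialect != "columnar_text":
        raise ValueError(f"unknown dialect {dialect!r}")

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].lstrip().startswith("#"):
        meta.update(_META_RE.findall(lines[i]))
        i += 1
    if "fs" not in meta:
        raise RecordingFormatError(f"{path}: missing '# fs=<Hz>' declaration")
    try:
        fs = float(meta["fs"])
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: non-numeric fs {meta['fs']!r}") from exc
    if i >= len(lines):
        raise RecordingFormatError(f"{path}: missing channel header row")
    channels = [c for c in lines[i].split("\t") if c.strip()]
    i += 1

    rows = []
    for row_idx, line in enumerate(lines[i:]):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(channels):
            raise RecordingFormatError(
                f"{path}: row {row_idx} has {len(cells)} cells, expected {len(channels)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise RecordingFormatError(
                f"{path}: non-numeric cell in row {row_idx}"
            ) from exc
    data = np.array(rows, dtype=float).reshape(len(rows), len(channels)).T

    return Recording(
        subject_id=meta.get("subject", "unknown"),
        trial_id=meta.get("trial", "unknown"),
        state=meta.get("state", "task"),
        task_type=meta.get("task_type", "none"),
        fs=fs,
        channel_names=channels,
        data=data,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write the columnar text dialect; refuses non-finite samples."""
    if not rec.is_finite():
        raise ValueError("recording contains non-finite samples; refusing to write")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(
            f"# subject={rec.subject_id} trial={rec.trial_id} "
            f"state={rec.state} task_type={rec.task_type}\n"
        )
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.12g", delimiter="\t")


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        subject_id=path.stem,
        trial_id=path.stem,
        state="task",
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=raw.get_data() * 1e6,  # mne loads volts; store microvolts
    )
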