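"""Recording containers, z-score normalization, and random-window sampling.

The classifier never sees a whole walk: training consumes contiguous windows
of random size and random location, and evaluation consumes fixed-size windows
at random locations.  This module owns both sampling rules, plus the on-disk
CSV format (one file per recording, a manifest tying files to labels).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 30
CHANNELS = ("xL", "yL", "zL", "xR", "yR", "zR")
N_CHANNELS = len(CHANNELS)

#: training windows span 20-200 samples (0.67-6.67 s at 30 Hz)
T_MIN_DEFAULT = 20
T_MAX_DEFAULT = 200


class DatasetError(Exception):
    """Malformed dataset on disk (missing file, wrong columns, bad manifest)."""


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class AccelRecording:
    """One labeled 10 m walk: an L x 6 array of bilateral accelerometer samples.

    Channel order is xL, yL, zL, xR, yR, zR at a fixed 30 Hz sample rate.
    The recording is the unit of cross-validation: windows cut from one
    recording never appear on both sides of a train/test split.
    """

    recording_id: str
    user_id: int
    trial_id: int
    samples: np.ndarray  # (L, 6) float
    sample_rate: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != N_CHANNELS:
            raise ValueError(
                f"recording {self.recording_id!r}: expected (L, {N_CHANNELS}) samples, "
                f"got shape {s.shape}"
            )
        if s.shape[0] < T_MIN_DEFAULT:
            raise ValueError(
                f"recording {self.recording_id!r}: length {s.shape[0]} < {T_MIN_DEFAULT}"
            )
        if self.sample_rate != SAMPLE_RATE_HZ:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE_HZ} Hz")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class Window:
    """A contiguous T x 6 slice of one recording, half-open [start, start+T)."""

    data: np.ndarray  # (T, 6)
    user_id: int
    source_recording: str
    start_index: int

    @property
    def size(self) -> int:
        return self.data.shape[0]


def normalize(recording: AccelRecording) -> AccelRecording:
    """Z-score each channel independently over the whole recording.

    After normalization every channel has sample mean 0 and (population,
    ddof=0) standard deviation 1.  Normalization is per recording so that
    inference on a new walk needs no statistics from the training set.

    Raises
    ------
    DegenerateChannelError
        If any channel is constant (zero variance).
    """
    x = recording.samples
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(CHANNELS[i] for i in bad)
        raise DegenerateChannelError(
            f"recording {recording.recording_id!r}: zero-variance channel(s) {names}"
        )
    return replace(recording, samples=(x - mean) / sd)


def sample_training_window(
    recording: AccelRecording,
    rng: np.random.Generator,
    t_min: int = T_MIN_DEFAULT,
    t_max: int = T_MAX_DEFAULT,
) -> Window:
    """Draw one training window of random size at a random location.

    The window size T is uniform on the integers [t_min, min(t_max, L)] and
    the start index uniform on [0, L - T]; both draws come from ``rng``.
    """
    L = recording.n_samples
    if L < t_min:
        raise ValueError(f"recording length {L} < minimum window size {t_min}")
    hi = min(t_max, L)
    t = int(rng.integers(t_min, hi + 1))
    start = int(rng.integers(0, L - t + 1))
    return Window(
        data=recording.samples[start : start + t],
        user_id=recording.user_id,
        source_recording=recording.recording_id,
        start_index=start,
    )


def extract_test_windows(
    recording: AccelRecording,
    t: int,
    k: int,
    rng: np.random.Generator,
) -> list[Window]:
    """Cut ``k`` windows of exact size ``t`` at uniform random starts.

    Starts are drawn with replacement, so the same placement may recur; each
    window carries the recording's user label.  Deterministic given ``rng``.
    """
    L = recording.n_samples
    if t > L:
        raise ValueError(f"window size {t} exceeds recording length {L}")
    if t < 1 or k < 1:
        raise ValueError("window size and count must be positive")
    starts = rng.integers(0, L - t + 1, size=k)
    return [
        Window(
            data=recording.samples[s : s + t],
            user_id=recording.user_id,
            source_recording=recording.recording_id,
            start_index=int(s),
        )
        for s in starts
    ]


# ---------------------------------------------------------------------------
# on-disk format: one CSV per recording + a manifest CSV

MANIFEST_NAME = "manifest.csv"
_MANIFEST_COLS = ["recording_id", "user_id", "trial_id", "n_samples", "path"]


def write_dataset(recordings: list[AccelRecording], directory: str | Path) -> Path:
    """Write one CSV per recording plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.recording_id}.csv"
        df = pd.DataFrame(rec.samples, columns=list(CHANNELS))
        df.to_csv(directory / fname, index=False, float_format="%.9g")
        rows.append(
            {
                "recording_id": rec.recording_id,
                "user_id": rec.user_id,
                "trial_id": rec.trial_id,
                "n_samples": rec.n_samples,
                "path": fname,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(manifest, index=False)
    return manifest


def _read_csv_lenient(path: Path) -> pd.DataFrame:
    # tolerate CRLF and a UTF-8 BOM
    with open(path, "rb") as fh:
        raw = fh.read()
    return pd.read_csv(io.StringIO(raw.decode("utf-8-sig")))


def read_dataset(manifest_path: str | Path) -> list[AccelRecording]:
    """Read a dataset back from its manifest; inverse of :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetError(f"manifest not found: {manifest_path}")
    try:
        manifest = _read_csv_lenient(manifest_path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise DatasetError(f"unreadable manifest {manifest_path}: {exc}") from exc
    missing = set(_MANIFEST_COLS) - set(manifest.columns)
    if missing:
        raise DatasetError(
            f"manifest {manifest_path} missing column(s): {sorted(missing)}"
        )
    base = manifest_path.parent
    recordings = []
    for row in manifest.itertuples(index=False):
        fpath = base / str(row.path)
        if not fpath.exists():
            raise DatasetError(f"recording file not found: {fpath}")
        df = _read_csv_lenient(fpath)
        if list(df.columns) != list(CHANNELS):
            raise DatasetError(
                f"{fpath}: expected columns {list(CHANNELS)}, got {list(df.columns)}"
            )
        rec = AccelRecording(
            recording_id=str(row.recording_id),
            user_id=int(row.user_id),
            trial_id=int(row.trial_id),
            samples=df.to_numpy(dtype=np.float64),
        )
        if rec.n_samples != int(row.n_samples):
            raise DatasetError(
                f"{fpath}: manifest says {row.n_samples} samples, file has {rec.n_samples}"
            )
        recordings.append(rec)
    return recordings
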