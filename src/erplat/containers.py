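"""Core in-memory containers shared across the pipeline.

All voltages are in microvolts (uV), all latencies in milliseconds relative
to stimulus onset unless a field name says otherwise (``time_s`` is seconds
from recording start).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: 10-10 posterior sites used by default, plus the two mastoids (M1/M2)
#: that serve as the offline reference.
POSTERIOR_MONTAGE: tuple[str, ...] = (
    "P3", "Pz", "P4",
    "PO3", "POz", "PO4", "PO7", "PO8",
    "O1", "Oz", "O2",
    "I3", "Iz", "I4", "I5", "I6",
    "M1", "M2",
)

#: Default reference sites (left and right mastoid).
MASTOIDS: tuple[str, str] = ("M1", "M2")

EVENT_COLUMNS = ("time_s", "type", "label")


class NoDataError(ValueError):
    """Raised when an operation has zero surviving trials/subjects to work on."""


class FormatError(ValueError):
    """Raised when a serialized container is inconsistent or truncated."""


@dataclass
class EventTable:
    """Time-stamped events: stimuli, luminance targets, and button presses.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``time_s`` (float, seconds), ``type`` (``stimulus``/``target``/``response``)
    and ``label`` (condition string, empty for non-stimulus events).
    Rows are kept sorted by time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        self.frame = (
            self.frame.loc[:, list(EVENT_COLUMNS)]
            .sort_values("time_s", kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records: Sequence[tuple[float, str, str]]) -> "EventTable":
        return cls(pd.DataFrame(records, columns=list(EVENT_COLUMNS)))

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame({"time_s": [], "type": [], "label": []}))

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["type"] == kind]

    def times(self, kind: str) -> np.ndarray:
        return self.of_type(kind)["time_s"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))


@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG: ``data`` is channels x samples in uV."""

    data: np.ndarray
    sampling_rate_hz: float
    montage: tuple[str, ...]
    events: EventTable
    reference: str = "common average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.montage = tuple(self.montage)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.montage)} montage sites"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, site: str) -> int:
        try:
            return self.montage.index(site)
        except ValueError:
            raise ValueError(f"site {site!r} not in montage") from None

    def copy_with(self, **kw) -> "ContinuousRecording":
        if "data" in kw:
            kw["data"] = np.array(kw["data"], dtype=float)
        else:
            kw["data"] = self.data.copy()
        return replace(self, **kw)


def epoch_sample_offsets(sampling_rate_hz: float,
                         window_ms: tuple[float, float] = (-200.0, 600.0)) -> np.ndarray:
    """Integer sample offsets (relative to the t=0 sample) covering the
    half-open epoch window ``[start, stop)`` in ms.

    The t=0 sample is included on the post-stimulus side; a sample lands in
    the epoch iff ``start <= 1000*k/fs < stop``.
    """
    start_ms, stop_ms = window_ms
    if not start_ms < stop_ms:
        raise ValueError("epoch window must have start < stop")
    k_min = -int(np.floor(-start_ms * sampling_rate_hz / 1000.0))
    k_stop = int(np.ceil(stop_ms * sampling_rate_hz / 1000.0))
    return np.arange(k_min, k_stop)


def epoch_time_axis(sampling_rate_hz: float,
                    window_ms: tuple[float, float] = (-200.0, 600.0)) -> np.ndarray:
    """Per-sample latencies in ms for the standard epoch window."""
    k = epoch_sample_offsets(sampling_rate_hz, window_ms)
    return 1000.0 * k / sampling_rate_hz


@dataclass
class Epochs:
    """Epoched EEG: ``data`` is trials x channels x samples in uV.

    ``rejected`` marks trials excluded from every average; ``reasons`` holds a
    short tag per rejected trial (empty string for kept trials). ``onset_s``
    optionally records each trial's stimulus time in the source recording
    (needed for the button-press exclusion rule).
    """

    data: np.ndarray
    time_ms: np.ndarray
    labels: np.ndarray
    sampling_rate_hz: float
    montage: tuple[str, ...]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reasons: np.ndarray = field(default=None)  # type: ignore[assignment]
    onset_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.montage = tuple(self.montage)
        n = self.data.shape[0]
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel count does not match montage")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("sample count does not match time axis")
        if self.labels.size != n:
            raise ValueError("labels length must equal number of trials")
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reasons is None:
            self.reasons = np.array([""] * n, dtype=object)
        else:
            self.reasons = np.asarray(self.reasons, dtype=object)
        if self.onset_s is not None:
            self.onset_s = np.asarray(self.onset_s, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return ~self.rejected

    def channel_index(self, site: str) -> int:
        try:
            return self.montage.index(site)
        except ValueError:
            raise ValueError(f"site {site!r} not in montage") from None

    def copy_with(self, **kw) -> "Epochs":
        out = {
            "data": self.data.copy(),
            "time_ms": self.time_ms.copy(),
            "labels": self.labels.copy(),
            "sampling_rate_hz": self.sampling_rate_hz,
            "montage": self.montage,
            "rejected": self.rejected.copy(),
            "reasons": self.reasons.copy(),
            "onset_s": None if self.onset_s is None else self.onset_s.copy(),
        }
        out.update(kw)
        return Epochs(**out)


@dataclass
class ERPWaveform:
    """Averaged waveform: ``data`` is channels x samples in uV.

    ``level`` is ``"subject"`` (trial average) or ``"grand"`` (subject
    average); ``n`` counts the trials or subjects that went in.
    ``provenance`` lists the condition labels pooled (or describes a
    difference wave).
    """

    data: np.ndarray
    time_ms: np.ndarray
    montage: tuple[str, ...]
    level: str
    n: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.montage = tuple(self.montage)
        if self.level not in ("subject", "grand"):
            raise ValueError("level must be 'subject' or 'grand'")
        if self.data.shape != (len(self.montage), self.time_ms.size):
            raise ValueError("waveform shape does not match montage/time axis")
        if self.n <= 0:
            raise ValueError("n must be positive")

    def channel_index(self, site: str) -> int:
        try:
            return self.montage.index(site)
        except ValueError:
            raise ValueError(f"site {site!r} not in montage") from None

    def site_series(self, site: str) -> np.ndarray:
        return self.data[self.channel_index(site)]


def check_compatible(a, b) -> None:
    """Raise unless two waveform-like objects share montage and time axis."""
    if tuple(a.montage) != tuple(b.montage):
        raise ValueError("montage mismatch")
    if a.time_ms.shape != b.time_ms.shape or not np.allclose(a.time_ms, b.time_ms):
        raise ValueError("time axis mismatch")
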