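"""Condition averaging, grand averaging, difference waves, window means.

All four operations are linear in the data, so differencing and averaging
commute; pooling across condition labels is trial-weighted (each surviving
trial counts once, so sub-conditions with more surviving trials weigh more).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import Epochs, ERPWaveform, NoDataError, check_compatible

__all__ = [
    "MeasurementWindow",
    "average_condition",
    "grand_average",
    "difference_wave",
    "mean_amplitude",
]


@dataclass(frozen=True)
class MeasurementWindow:
    """A fixed site and half-open latency window ``[t_start, t_end)`` in ms."""

    site: str
    t_start_ms: float
    t_end_ms: float

    def __post_init__(self) -> None:
        if not self.t_start_ms < self.t_end_ms:
            raise ValueError("window must have t_start < t_end")


def average_condition(epochs: Epochs, labels: Iterable[str] | str) -> ERPWaveform:
    """Trial-weighted mean over all non-rejected trials whose label is in
    ``labels`` (a single label or a set to pool)."""
    if isinstance(labels, str):
        labels = {labels}
    labels = set(labels)
    pick = epochs.kept & np.isin(epochs.labels, list(labels))
    n = int(pick.sum())
    if n == 0:
        raise NoDataError(f"no surviving trials for labels {sorted(labels)}")
    return ERPWaveform(
        data=epochs.data[pick].mean(axis=0),
        time_ms=epochs.time_ms,
        montage=epochs.montage,
        level="subject",
        n=n,
        provenance="+".join(sorted(labels)),
    )


def grand_average(waveforms: Sequence[ERPWaveform]) -> ERPWaveform:
    """Unweighted mean across subjects (one waveform per subject)."""
    if not waveforms:
        raise NoDataError("no subject waveforms to average")
    first = waveforms[0]
    for w in waveforms[1:]:
        check_compatible(first, w)
    return ERPWaveform(
        data=np.mean([w.data for w in waveforms], axis=0),
        time_ms=first.time_ms,
        montage=first.montage,
        level="grand",
        n=len(waveforms),
        provenance=first.provenance,
    )


def difference_wave(minuend: ERPWaveform, subtrahend: ERPWaveform) -> ERPWaveform:
    """Sample-wise ``minuend - subtrahend`` (e.g. contrast minus homogeneous)."""
    check_compatible(minuend, subtrahend)
    if minuend.level != subtrahend.level:
        raise ValueError("cannot difference waveforms at different levels")
    return ERPWaveform(
        data=minuend.data - subtrahend.data,
        time_ms=minuend.time_ms,
        montage=minuend.montage,
        level=minuend.level,
        n=min(minuend.n, subtrahend.n),
        provenance=f"({minuend.provenance})-({subtrahend.provenance})",
    )


def mean_amplitude(waveform: ERPWaveform, window: MeasurementWindow) -> float:
    """Arithmetic mean amplitude at ``window.site`` over samples with
    ``t_start <= t < t_end``."""
    series = waveform.site_series(window.site)
    mask = (waveform.time_ms >= window.t_start_ms) & (waveform.time_ms < window.t_end_ms)
    if not mask.any():
        raise ValueError("measurement window contains no samples")
    return float(series[mask].mean())
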