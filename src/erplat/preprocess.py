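"""Continuous-to-clean-epochs preprocessing.

Pipeline order follows the offline recording convention: re-reference to the
mastoid average, zero-phase filtering (Blackman windowed-sinc low-pass,
first-order Butterworth high-pass applied forward-backward), epoch
extraction on a [-200, 600) ms window, amplitude and button-press artifact
rejection, and pre-stimulus baseline correction.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import (
    MASTOIDS,
    ContinuousRecording,
    Epochs,
    EventTable,
    epoch_sample_offsets,
)

__all__ = [
    "rereference",
    "design_lowpass_fir",
    "apply_zero_phase_filter",
    "highpass_iir",
    "extract_epochs",
    "reject_artifacts",
    "baseline_correct",
]


def rereference(recording: ContinuousRecording,
                ref_sites=MASTOIDS) -> ContinuousRecording:
    """Subtract the mean of ``ref_sites`` from every channel, sample-wise."""
    idx = [recording.channel_index(s) for s in ref_sites]
    ref = recording.data[idx].mean(axis=0)
    return recording.copy_with(
        data=recording.data - ref[None, :],
        reference=f"average of {'/'.join(ref_sites)}",
    )


def design_lowpass_fir(cutoff_halfamp_hz: float, transition_bw_hz: float,
                       sampling_rate_hz: float) -> np.ndarray:
    """Blackman windowed-sinc low-pass kernel.

    ``cutoff_halfamp_hz`` is the half-amplitude (-6 dB) point; the tap count
    is ``ceil(5.5 * fs / transition_bw)`` (the Blackman window's normalized
    transition width), rounded up to odd so the kernel is symmetric about a
    center tap. Taps are normalized to unit DC gain.
    """
    nyq = sampling_rate_hz / 2.0
    if not 0 < cutoff_halfamp_hz < nyq:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    if transition_bw_hz <= 0:
        raise ValueError("transition bandwidth must be positive")
    numtaps = int(np.ceil(5.5 * sampling_rate_hz / transition_bw_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, cutoff_halfamp_hz, window="blackman",
                         fs=sampling_rate_hz)


def _filter_array(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase FIR application along the last axis.

    The symmetric kernel is applied once with its group delay compensated by
    centering; edges are reflection-padded so length is preserved.
    """
    half = len(kernel) // 2
    if data.shape[-1] <= len(kernel):
        raise ValueError("signal must be longer than the filter kernel")
    padded = np.concatenate(
        [data[..., 1:half + 1][..., ::-1], data, data[..., -half - 1:-1][..., ::-1]],
        axis=-1,
    )
    shape = [1] * padded.ndim
    shape[-1] = len(kernel)
    out = signal.oaconvolve(padded, kernel.reshape(shape), mode="valid", axes=-1)
    return out


def apply_zero_phase_filter(obj, kernel: np.ndarray):
    """Apply a linear-phase FIR kernel with zero net phase shift.

    Accepts a :class:`ContinuousRecording`, :class:`Epochs`, or a bare
    array (filtered along its last axis); returns the same type.
    """
    kernel = np.asarray(kernel, dtype=float)
    if isinstance(obj, ContinuousRecording):
        return obj.copy_with(data=_filter_array(obj.data, kernel))
    if isinstance(obj, Epochs):
        return obj.copy_with(data=_filter_array(obj.data, kernel))
    return _filter_array(np.asarray(obj, dtype=float), kernel)


def highpass_iir(recording: ContinuousRecording,
                 cutoff_halfamp_hz: float = 0.1) -> ContinuousRecording:
    """First-order Butterworth high-pass, forward-backward (zero phase).

    A first-order Butterworth has amplitude 1/sqrt(2) at its corner; two
    passes square the magnitude, so the corner frequency is exactly the
    half-amplitude point of the combined filter.
    """
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < cutoff_halfamp_hz < nyq:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    b, a = signal.butter(1, cutoff_halfamp_hz, btype="highpass",
                         fs=recording.sampling_rate_hz)
    out = signal.filtfilt(b, a, recording.data, axis=-1)
    return recording.copy_with(data=out)


def extract_epochs(recording: ContinuousRecording,
                   window_ms: tuple[float, float] = (-200.0, 600.0)) -> Epochs:
    """One epoch per stimulus event on the half-open ``[start, stop)`` window.

    The t=0 sample is the first sample at/after the event time (no
    interpolation). Events whose window would run off the recording are kept
    but flagged rejected with reason ``edge``.
    """
    fs = recording.sampling_rate_hz
    offsets = epoch_sample_offsets(fs, window_ms)
    time_ms = 1000.0 * offsets / fs
    stim = recording.events.of_type("stimulus")
    n = len(stim)
    n_chan = recording.data.shape[0]
    data = np.zeros((n, n_chan, offsets.size))
    rejected = np.zeros(n, dtype=bool)
    reasons = np.array([""] * n, dtype=object)
    onsets = np.zeros(n)
    labels = stim["label"].to_numpy(dtype=object) if n else np.array([], dtype=object)
    for i, t_s in enumerate(stim["time_s"].to_numpy(dtype=float)):
        onsets[i] = t_s
        i0 = int(np.ceil(t_s * fs - 1e-9))
        lo, hi = i0 + offsets[0], i0 + offsets[-1] + 1
        if lo < 0 or hi > recording.n_samples:
            rejected[i] = True
            reasons[i] = "edge"
            continue
        data[i] = recording.data[:, lo:hi]
    return Epochs(
        data=data, time_ms=time_ms, labels=labels,
        sampling_rate_hz=fs, montage=recording.montage,
        rejected=rejected, reasons=reasons, onset_s=onsets if n else None,
    )


def reject_artifacts(epochs: Epochs, threshold_uV: float = 70.0,
                     response_events: EventTable | None = None,
                     exclusion_ms: tuple[float, float] = (-650.0, 650.0),
                     reference_sites=MASTOIDS) -> Epochs:
    """Flag amplitude and button-press artifacts.

    A trial is rejected if any sample on any non-reference channel strictly
    exceeds ``threshold_uV`` in absolute value (a sample at exactly the
    threshold is kept), or if its stimulus onset lies within the inclusive
    ``exclusion_ms`` window around any response event. Existing rejection
    flags (e.g. ``edge``) are preserved; reasons accumulate comma-separated.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy_with()
    if out.n_trials == 0:
        return out
    chan_mask = np.array([s not in reference_sites for s in out.montage])
    over = np.abs(out.data[:, chan_mask, :]).max(axis=(1, 2)) > threshold_uV

    near_press = np.zeros(out.n_trials, dtype=bool)
    if response_events is not None and out.onset_s is not None:
        presses = response_events.times("response")
        if presses.size:
            lo, hi = exclusion_ms[0] / 1000.0, exclusion_ms[1] / 1000.0
            diff = out.onset_s[:, None] - presses[None, :]
            # endpoints inclusive; tolerate float rounding at the boundary
            near_press = np.any((diff >= lo - 1e-9) & (diff <= hi + 1e-9), axis=1)

    for i in range(out.n_trials):
        tags = [out.reasons[i]] if out.reasons[i] else []
        if over[i]:
            tags.append("amplitude")
        if near_press[i]:
            tags.append("button_press")
        if tags and not (len(tags) == 1 and tags[0] == out.reasons[i]):
            out.reasons[i] = ",".join(tags)
        out.rejected[i] = out.rejected[i] or over[i] or near_press[i]
    return out


def baseline_correct(epochs: Epochs,
                     baseline_ms: tuple[float, float] = (-100.0, 0.0)) -> Epochs:
    """Subtract the per-trial, per-channel mean over ``[start, stop)`` ms."""
    lo, hi = baseline_ms
    mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    if not mask.any():
        raise ValueError("baseline window lies outside the epoch")
    step_ms = 1000.0 / epochs.sampling_rate_hz
    if lo < epochs.time_ms[0] or hi > epochs.time_ms[-1] + step_ms + 1e-9:
        raise ValueError("baseline window lies outside the epoch")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)
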