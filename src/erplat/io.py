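"""On-disk formats: the epochs container and optional EDF import.

The epochs container is a JSON sidecar (``<base>.json``) plus a raw
little-endian float32 binary (``<base>.bin``) in trial-major order
(trial, channel, sample) — bit-exact and language-neutral. Waveform-level
metadata rides in the sidecar so ERPs can round-trip through the same pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import ContinuousRecording, Epochs, EventTable, FormatError

__all__ = [
    "write_epochs_container",
    "read_epochs_container",
    "read_edf",
]

SCHEMA_VERSION = 1


def _paths(base) -> tuple[Path, Path]:
    base = Path(base)
    if base.suffix in (".json", ".bin"):
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".bin")


def write_epochs_container(epochs: Epochs, base_path) -> Path:
    """Write ``<base>.json`` + ``<base>.bin``; returns the sidecar path.

    Data is stored as little-endian float32 (in-memory float64 is downcast).
    """
    sidecar_path, bin_path = _paths(base_path)
    data32 = np.ascontiguousarray(epochs.data, dtype="<f4")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "epochs",
        "shape": list(data32.shape),
        "dtype": "float32",
        "byte_order": "little",
        "order": ["trial", "channel", "sample"],
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "montage": list(epochs.montage),
        "time_ms": [float(t) for t in epochs.time_ms],
        "labels": [str(l) for l in epochs.labels],
        "rejected": [bool(r) for r in epochs.rejected],
        "reasons": [str(r) for r in epochs.reasons],
        "onset_s": None if epochs.onset_s is None else [float(t) for t in epochs.onset_s],
    }
    bin_path.write_bytes(data32.tobytes())
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_epochs_container(base_path) -> Epochs:
    """Read a container written by :func:`write_epochs_container`.

    Raises :class:`FormatError` naming the offending field on schema
    mismatch, shape/montage disagreement, or a truncated binary.
    """
    sidecar_path, bin_path = _paths(base_path)
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"sidecar is not valid JSON: {e}") from e
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"schema_version {version!r} unsupported (expected {SCHEMA_VERSION})")
    if sidecar.get("dtype") != "float32" or sidecar.get("byte_order") != "little":
        raise FormatError("dtype/byte_order must be little-endian float32")
    shape = tuple(sidecar["shape"])
    if len(shape) != 3:
        raise FormatError("shape must have 3 dimensions (trial, channel, sample)")
    montage = sidecar["montage"]
    if shape[1] != len(montage):
        raise FormatError(
            f"montage lists {len(montage)} channels but shape declares {shape[1]}"
        )
    time_ms = np.asarray(sidecar["time_ms"], dtype=float)
    if shape[2] != time_ms.size:
        raise FormatError("time_ms length disagrees with shape")
    raw = bin_path.read_bytes()
    expected = int(np.prod(shape)) * 4
    if len(raw) != expected:
        raise FormatError(
            f"binary holds {len(raw)} bytes but shape requires {expected}"
        )
    data = np.frombuffer(raw, dtype="<f4").reshape(shape)
    n = shape[0]
    for field_name in ("labels", "rejected", "reasons"):
        if len(sidecar[field_name]) != n:
            raise FormatError(f"{field_name} length disagrees with trial count")
    onset = sidecar.get("onset_s")
    return Epochs(
        data=np.array(data, dtype=float),
        time_ms=time_ms,
        labels=np.array(sidecar["labels"], dtype=object),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        montage=tuple(montage),
        rejected=np.array(sidecar["rejected"], dtype=bool),
        reasons=np.array(sidecar["reasons"], dtype=object),
        onset_s=None if onset is None else np.asarray(onset, dtype=float),
    )


def read_edf(path, events: EventTable | None = None) -> ContinuousRecording:
    """Import a continuous EDF recording (requires the optional ``mne`` extra).

    Voltages are converted to microvolts; channel names become the montage.
    """
    try:
        import mne  # noqa: PLC0415
    except ImportError as e:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF import needs the optional dependency 'mne' (pip install erplat[edf])"
        ) from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return ContinuousRecording(
        data=raw.get_data() * 1e6,
        sampling_rate_hz=float(raw.info["sfreq"]),
        montage=tuple(raw.ch_names),
        events=events if events is not None else EventTable.empty(),
        reference="as recorded",
    )
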