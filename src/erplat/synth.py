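"""Synthetic stimuli, EEG epochs, and behavior streams.

The generator plants parameterized ERP components (an early C1-like
deflection and a delayed orientation-contrast effect) into multi-subject,
multi-trial epochs with white + 1/f + alpha-band noise, per-subject latency
and amplitude variability, and occasional high-amplitude artifacts, so the
downstream averaging/latency statistics can be exercised by parameter
recovery at desk scale.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    POSTERIOR_MONTAGE,
    Epochs,
    EventTable,
    epoch_time_axis,
)

__all__ = [
    "StimulusSpec",
    "ComponentSpec",
    "NoiseSpec",
    "Condition",
    "SimulationConfig",
    "patch_extent",
    "trials_per_condition",
    "build_texture",
    "simulate_subject_epochs",
    "simulate_subject_erp",
    "simulate_behavior_stream",
    "default_exp1_config",
]


# --------------------------------------------------------------------------
# stimulus geometry
# --------------------------------------------------------------------------

def patch_extent(n_elements: int, spacing_deg: float, element_length_deg: float) -> float:
    """Angular extent of a row/column of ``n_elements`` texture elements.

    Elements of length ``element_length_deg`` with center-to-center spacing
    ``spacing_deg`` span ``(n - 1) * spacing + length`` degrees.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if spacing_deg <= 0 or element_length_deg <= 0:
        raise ValueError("spacing and element length must be positive")
    return (n_elements - 1) * spacing_deg + element_length_deg


def trials_per_condition(n_blocks: int, trials_per_block: int, n_conditions: int) -> int:
    """Per-condition trial count when conditions are equiprobable within blocks."""
    if n_blocks < 1 or trials_per_block < 1 or n_conditions < 1:
        raise ValueError("block structure counts must be >= 1")
    total = n_blocks * trials_per_block
    if total % n_conditions:
        raise ValueError("block structure does not divide evenly across conditions")
    return total // n_conditions


@dataclass
class StimulusSpec:
    """Geometry of one texture stimulus (all lengths in visual degrees)."""

    grid_rows: int = 19
    grid_cols: int = 19
    element_length_deg: float = 0.76
    element_width_deg: float = 0.1
    spacing_deg: float = 1.16
    jitter_deg: float = 0.1
    background_orientation: str = "horizontal"
    contrast_field: str = "none"          # UVF, LVF or none
    contrast_rows: int = 2
    contrast_cols: int = 2
    contrast_eccentricity_deg: float = 7.4

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1 x 1")
        if self.spacing_deg <= 0:
            raise ValueError("spacing must be positive")
        if not 0 <= self.jitter_deg < self.spacing_deg / 2:
            raise ValueError("jitter must lie in [0, spacing/2)")
        if self.background_orientation not in ("horizontal", "vertical"):
            raise ValueError("background_orientation must be horizontal or vertical")
        if self.contrast_field not in ("UVF", "LVF", "none"):
            raise ValueError("contrast_field must be UVF, LVF or none")
        if self.contrast_rows < 1 or self.contrast_cols < 1:
            raise ValueError("contrast patch must be at least 1 x 1")


_ORTHOGONAL = {"horizontal": "vertical", "vertical": "horizontal"}


def build_texture(spec: StimulusSpec, seed: int, fixation_placeholder: bool = False) -> pd.DataFrame:
    """Element table for one texture stimulus.

    Returns one row per line segment with its jittered center (``x_deg``,
    ``y_deg``; fixation at origin, y positive upward), ``orientation`` and
    ``is_contrast``. Two contrast patches (``contrast_rows x contrast_cols``
    of orthogonal elements) are placed bilaterally at 45 deg polar angle in
    the requested hemifield, snapped to the nearest grid cells. Positional
    jitter is drawn uniformly in [0, jitter_deg] per axis from the seeded
    generator. When ``fixation_placeholder`` is true the central element is
    omitted (it is replaced by the fixation cross on screen).
    """
    rng = np.random.default_rng(seed)
    rows = np.arange(spec.grid_rows)
    cols = np.arange(spec.grid_cols)
    y0 = (rows - (spec.grid_rows - 1) / 2) * spec.spacing_deg
    x0 = (cols - (spec.grid_cols - 1) / 2) * spec.spacing_deg
    xx, yy = np.meshgrid(x0, y0)     # yy increases with row index; flip so +y is up
    yy = -yy

    contrast_mask = np.zeros_like(xx, dtype=bool)
    if spec.contrast_field != "none":
        target_y = spec.contrast_eccentricity_deg / math.sqrt(2.0)
        if spec.contrast_field == "LVF":
            target_y = -target_y
        target_x = spec.contrast_eccentricity_deg / math.sqrt(2.0)
        for sx in (-1.0, 1.0):
            ci = int(np.argmin(np.abs(x0 - sx * target_x)))
            ri = int(np.argmin(np.abs(-y0 - target_y)))
            if (abs(x0[ci] - sx * target_x) > spec.spacing_deg / 2 + 1e-9
                    or abs(-y0[ri] - target_y) > spec.spacing_deg / 2 + 1e-9):
                raise ValueError("contrast patch center lies outside the grid")
            r_lo = ri - (spec.contrast_rows - 1) // 2
            c_lo = ci - (spec.contrast_cols - 1) // 2
            r_hi = r_lo + spec.contrast_rows
            c_hi = c_lo + spec.contrast_cols
            if r_lo < 0 or c_lo < 0 or r_hi > spec.grid_rows or c_hi > spec.grid_cols:
                raise ValueError("contrast patch does not fit inside the grid")
            contrast_mask[r_lo:r_hi, c_lo:c_hi] = True

    keep = np.ones_like(contrast_mask)
    if fixation_placeholder:
        keep[spec.grid_rows // 2, spec.grid_cols // 2] = False

    n = int(keep.sum())
    jit = rng.uniform(0.0, spec.jitter_deg, size=(n, 2)) if spec.jitter_deg > 0 else np.zeros((n, 2))
    orient = np.where(contrast_mask[keep],
                      _ORTHOGONAL[spec.background_orientation],
                      spec.background_orientation)
    return pd.DataFrame({
        "x_deg": xx[keep] + jit[:, 0],
        "y_deg": yy[keep] + jit[:, 1],
        "orientation": orient,
        "is_contrast": contrast_mask[keep],
    })


# --------------------------------------------------------------------------
# planted ERP components
# --------------------------------------------------------------------------

@dataclass
class ComponentSpec:
    """One planted ERP deflection.

    The waveform is an asymmetric Gaussian truncated at ``onset_ms``: zero
    before onset, then ``(g(t) - g(onset)) / (1 - g(onset))`` scaled by the
    signed ``amplitude_uV``, where g has SD ``rise_sd_ms`` before the peak
    and ``fall_sd_ms`` after. Defaults put the onset 2.5 rise-SDs before the
    peak so the waveform leaves zero continuously. ``site_weights`` maps
    montage sites to gains in [-1, 1]; unlisted sites get 0.
    """

    name: str
    peak_latency_ms: float
    onset_ms: float
    amplitude_uV: float
    site_weights: dict[str, float] = field(default_factory=dict)
    rise_sd_ms: float | None = None
    fall_sd_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.onset_ms < self.peak_latency_ms:
            raise ValueError("onset must precede the peak")
        if self.rise_sd_ms is None:
            self.rise_sd_ms = (self.peak_latency_ms - self.onset_ms) / 2.5
        if self.fall_sd_ms is None:
            self.fall_sd_ms = 1.4 * self.rise_sd_ms
        for site, w in self.site_weights.items():
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"site weight for {site} outside [-1, 1]")

    def waveform(self, time_ms: np.ndarray,
                 latency_shift_ms: float = 0.0,
                 amplitude_uV: float | None = None) -> np.ndarray:
        """Evaluate the component time course (single channel, unit gain)."""
        amp = self.amplitude_uV if amplitude_uV is None else amplitude_uV
        peak = self.peak_latency_ms + latency_shift_ms
        onset = self.onset_ms + latency_shift_ms
        t = np.asarray(time_ms, dtype=float)
        sd = np.where(t < peak, self.rise_sd_ms, self.fall_sd_ms)
        g = np.exp(-0.5 * ((t - peak) / sd) ** 2)
        g0 = math.exp(-0.5 * ((onset - peak) / self.rise_sd_ms) ** 2)
        out = np.where(t >= onset, (g - g0) / (1.0 - g0), 0.0)
        return amp * out

    def topography(self, montage) -> np.ndarray:
        unknown = set(self.site_weights) - set(montage)
        if unknown:
            raise ValueError(f"site_weights name unknown sites: {sorted(unknown)}")
        return np.array([self.site_weights.get(s, 0.0) for s in montage])


@dataclass
class NoiseSpec:
    """Single-trial noise model (all SDs in uV).

    white: independent Gaussian samples; pink: FFT-shaped 1/f noise of the
    stated SD; alpha: fixed-frequency sinusoid of amplitude ``alpha_amp_uV``
    with a random phase per trial (it therefore attenuates as 1/sqrt(n) in
    the trial average). ``subject_latency_jitter_sd_ms`` and
    ``subject_amp_sd_uV`` perturb each component once per subject.
    Artifact trials receive a 100-ms square pulse of ``artifact_amp_uV`` on
    one random channel.
    """

    white_sd_uV: float = 3.0
    pink_sd_uV: float = 2.5
    alpha_amp_uV: float = 1.5
    alpha_freq_hz: float = 10.0
    subject_latency_jitter_sd_ms: float = 3.0
    subject_amp_sd_uV: float = 0.08
    artifact_rate: float = 0.02
    artifact_amp_uV: float = 120.0

    def __post_init__(self) -> None:
        for name in ("white_sd_uV", "pink_sd_uV", "alpha_amp_uV",
                     "subject_latency_jitter_sd_ms", "subject_amp_sd_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(white_sd_uV=0, pink_sd_uV=0, alpha_amp_uV=0,
                   subject_latency_jitter_sd_ms=0, subject_amp_sd_uV=0,
                   artifact_rate=0)


@dataclass
class Condition:
    label: str
    components: list[ComponentSpec] = field(default_factory=list)


@dataclass
class SimulationConfig:
    """Study-level description of a simulated cohort."""

    conditions: list[Condition]
    n_subjects: int = 24
    n_trials_per_condition: int = 576
    sampling_rate_hz: float = 512.0
    montage: tuple[str, ...] = POSTERIOR_MONTAGE
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.montage = tuple(self.montage)

    def time_axis(self) -> np.ndarray:
        return epoch_time_axis(self.sampling_rate_hz, self.epoch_window_ms)


def _pink_filter(n_samples: int) -> np.ndarray:
    """rFFT amplitude shaping for unit-SD 1/f noise on n samples."""
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    return shape


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with per-trace SD ``sd`` (last axis = time)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * _pink_filter(n)
    out = np.fft.irfft(spec, n=n, axis=-1)
    s = out.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return sd * out / s


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def _subject_perturbations(config: SimulationConfig, subject_index: int):
    """Per-subject component latency shifts and amplitudes (reproducible).

    Keyed by component *name*: a subject's C1 (or contrast effect) is one
    physiological response, so a component shared between conditions gets
    the same subject-level perturbation in each — and cancels exactly in
    within-subject difference waves. Drawn from a dedicated stream so the
    trial-level and subject-average generators agree on the same
    subject-level parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index, 7]))
    noise = config.noise
    out = {}
    for cond in config.conditions:       # stable order: first appearance wins
        for comp in cond.components:
            if comp.name not in out:
                shift = rng.normal(0.0, noise.subject_latency_jitter_sd_ms)
                amp_offset = rng.normal(0.0, noise.subject_amp_sd_uV)
                out[comp.name] = (shift, amp_offset)
    return out


def _condition_template(config: SimulationConfig, cond: Condition,
                        perturb, time_ms: np.ndarray) -> np.ndarray:
    """channels x samples template for one condition and one subject."""
    tmpl = np.zeros((len(config.montage), time_ms.size))
    for comp in cond.components:
        shift, amp_offset = perturb[comp.name]
        wave = comp.waveform(time_ms, latency_shift_ms=shift,
                             amplitude_uV=comp.amplitude_uV + amp_offset)
        tmpl += comp.topography(config.montage)[:, None] * wave[None, :]
    return tmpl


def simulate_subject_epochs(config: SimulationConfig, subject_index: int) -> Epochs:
    """Trial-level epochs for one subject.

    Each trial is the subject-perturbed component template plus fresh noise
    realizations. Reproducible from ``(config.seed, subject_index)``. Trials
    are laid out condition-by-condition in config order.
    """
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _subject_rng(config, subject_index)
    perturb = _subject_perturbations(config, subject_index)
    time_ms = config.time_axis()
    n_samp = time_ms.size
    n_chan = len(config.montage)
    n_trial = config.n_trials_per_condition
    noise = config.noise

    blocks = []
    labels = []
    for cond in config.conditions:
        tmpl = _condition_template(config, cond, perturb, time_ms)
        trials = np.broadcast_to(tmpl, (n_trial, n_chan, n_samp)).copy()
        if noise.white_sd_uV > 0:
            trials += rng.normal(0.0, noise.white_sd_uV, size=trials.shape)
        if noise.pink_sd_uV > 0:
            trials += _pink_noise(rng, trials.shape, noise.pink_sd_uV)
        if noise.alpha_amp_uV > 0:
            phase = rng.uniform(0, 2 * np.pi, size=(n_trial, 1, 1))
            trials += noise.alpha_amp_uV * np.sin(
                2 * np.pi * noise.alpha_freq_hz * time_ms[None, None, :] / 1000.0 + phase
            )
        if noise.artifact_rate > 0:
            hit = rng.random(n_trial) < noise.artifact_rate
            width = max(1, int(round(0.1 * config.sampling_rate_hz)))
            for t in np.flatnonzero(hit):
                ch = rng.integers(n_chan)
                start = rng.integers(0, max(1, n_samp - width))
                trials[t, ch, start:start + width] += noise.artifact_amp_uV
        blocks.append(trials)
        labels.extend([cond.label] * n_trial)

    return Epochs(
        data=np.concatenate(blocks, axis=0),
        time_ms=time_ms,
        labels=np.array(labels, dtype=object),
        sampling_rate_hz=config.sampling_rate_hz,
        montage=config.montage,
    )


def simulate_subject_erp(config: SimulationConfig, subject_index: int,
                         condition_label: str,
                         n_trials: int | None = None) -> np.ndarray:
    """Subject-average waveform (channels x samples) drawn directly.

    Distributionally equivalent to averaging ``n_trials`` independent trials
    from :func:`simulate_subject_epochs` (artifact-free trials): white and
    pink residuals scale by 1/sqrt(n); the random-phase alpha resultant is
    drawn as a complex-normal sum (exact in the CLT limit, n >= a few tens).
    Used by replicate studies where materializing every trial would be waste.
    """
    n = config.n_trials_per_condition if n_trials is None else n_trials
    cond = next((c for c in config.conditions if c.label == condition_label), None)
    if cond is None:
        raise ValueError(f"unknown condition {condition_label!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, subject_index, zlib.crc32(condition_label.encode())]
        )
    )
    perturb = _subject_perturbations(config, subject_index)
    time_ms = config.time_axis()
    noise = config.noise
    out = _condition_template(config, cond, perturb, time_ms)
    shape = (len(config.montage), time_ms.size)
    root_n = math.sqrt(n)
    if noise.white_sd_uV > 0:
        out = out + rng.normal(0.0, noise.white_sd_uV / root_n, size=shape)
    if noise.pink_sd_uV > 0:
        out = out + _pink_noise(rng, shape, noise.pink_sd_uV / root_n)
    if noise.alpha_amp_uV > 0:
        sigma = noise.alpha_amp_uV / math.sqrt(2.0 * n)
        a, b = rng.normal(0.0, sigma, size=(2,) + (len(config.montage), 1))
        wt = 2 * np.pi * noise.alpha_freq_hz * time_ms / 1000.0
        out = out + a * np.sin(wt)[None, :] + b * np.cos(wt)[None, :]
    return out


# --------------------------------------------------------------------------
# behavior stream
# --------------------------------------------------------------------------

def simulate_behavior_stream(duration_s: float,
                             target_interval_s: tuple[float, float] = (3.0, 6.0),
                             hit_model: dict | None = None,
                             seed: int = 0) -> EventTable:
    """Luminance-target events plus simulated button presses.

    Inter-target intervals are uniform in ``target_interval_s``; each target
    is answered with probability ``hit_model['p_hit']`` after a Gaussian
    reaction time (``rt_mean_ms`` / ``rt_sd_ms``, truncated at 0).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    lo, hi = target_interval_s
    if not 0 < lo <= hi < duration_s:
        raise ValueError("target interval range must lie within (0, duration)")
    hm = {"p_hit": 1.0, "rt_mean_ms": 450.0, "rt_sd_ms": 80.0}
    if hit_model:
        hm.update(hit_model)
    rng = np.random.default_rng(seed)
    records: list[tuple[float, str, str]] = []
    t = float(rng.uniform(lo, hi))
    while t < duration_s:
        records.append((t, "target", ""))
        if rng.random() < hm["p_hit"]:
            rt = max(0.0, rng.normal(hm["rt_mean_ms"], hm["rt_sd_ms"])) / 1000.0
            if t + rt < duration_s:
                records.append((t + rt, "response", ""))
        t += float(rng.uniform(lo, hi))
    if not records:
        return EventTable.empty()
    return EventTable.from_records(records)


# --------------------------------------------------------------------------
# canonical planted-component configurations
# --------------------------------------------------------------------------

#: Topography of the C1-like deflection: maximal at the midline
#: parieto-occipital site, falling off at neighbours.
C1_WEIGHTS = {
    "POz": 1.0, "PO3": 0.7, "PO4": 0.7, "Oz": 0.8, "O1": 0.55, "O2": 0.55,
    "Pz": 0.6, "Iz": 0.5, "I3": 0.3, "I4": 0.3,
}

#: Topography of the LVF orientation-contrast effect (central posterior max).
LVF_CONTRAST_WEIGHTS = {
    "POz": 1.0, "Oz": 0.85, "O1": 0.6, "O2": 0.65, "PO3": 0.6, "PO4": 0.65,
    "Iz": 0.55, "Pz": 0.5,
}

#: Topography of the UVF contrast effect (weaker, more lateral-occipital).
UVF_CONTRAST_WEIGHTS = {
    "PO8": 1.0, "PO4": 0.9, "O2": 0.7, "PO7": 0.6, "PO3": 0.5, "O1": 0.45,
    "POz": 0.4,
}


def default_exp1_config(n_subjects: int = 24, n_trials_per_condition: int = 576,
                        sampling_rate_hz: float = 512.0, seed: int = 0,
                        noise: NoiseSpec | None = None) -> SimulationConfig:
    """Planted-component cohort mirroring the first experiment's design.

    Contrast blocks: homogeneous, UVF-contrast and LVF-contrast textures
    share a whole-texture C1-like response (negative at POz, peak 80 ms);
    contrast conditions add a delayed contrast-effect deflection (no polarity
    reversal: positive in both hemifields; LVF onset 68 ms / peak 92 ms,
    UVF later and weaker). Onset blocks: bilateral abrupt-onset stimuli
    evoke a C1 that is negative for UVF and positive for LVF, peak 80 ms.
    """
    texture_c1 = ComponentSpec("texture_C1", peak_latency_ms=80.0, onset_ms=50.0,
                               amplitude_uV=-0.8, site_weights=C1_WEIGHTS)
    lvf_effect = ComponentSpec("contrast_effect", peak_latency_ms=92.0, onset_ms=68.0,
                               amplitude_uV=0.6, site_weights=LVF_CONTRAST_WEIGHTS)
    uvf_effect = ComponentSpec("contrast_effect", peak_latency_ms=97.0, onset_ms=88.0,
                               amplitude_uV=0.4, site_weights=UVF_CONTRAST_WEIGHTS)
    c1_uvf = ComponentSpec("C1", peak_latency_ms=80.0, onset_ms=50.0,
                           amplitude_uV=-0.6, site_weights=C1_WEIGHTS)
    c1_lvf = ComponentSpec("C1", peak_latency_ms=80.0, onset_ms=50.0,
                           amplitude_uV=0.5, site_weights=C1_WEIGHTS)
    conditions = [
        Condition("homogeneous", [texture_c1]),
        Condition("UVF_contrast", [texture_c1, uvf_effect]),
        Condition("LVF_contrast", [texture_c1, lvf_effect]),
        Condition("UVF_onset", [c1_uvf]),
        Condition("LVF_onset", [c1_lvf]),
    ]
    return SimulationConfig(
        conditions=conditions,
        n_subjects=n_subjects,
        n_trials_per_condition=n_trials_per_condition,
        sampling_rate_hz=sampling_rate_hz,
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
    )
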