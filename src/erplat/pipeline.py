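"""End-to-end orchestration of the experiment analyses.

``run_experiment_analysis`` drives the whole chain on synthetic (or
container) data: simulate -> preprocess (low-pass, artifact rejection,
baseline) -> condition averages and difference waves -> fixed-window
amplitude tests -> sliding-window onset detection -> jackknife latency
comparisons -> behavior scores, and assembles a JSON-serializable report
with provenance (config hash, seed, version).

Four experiment layouts are built in: ``exp1_contrast`` (contrast + onset
blocks, centrally symmetric textures), ``exp1_onset`` (onset blocks only),
``exp2_masked`` (backward-masked textures plus an awareness test; the
latency comparison against the unmasked C1 uses the independent-design
jackknife), and ``exp3_hemifield`` (whole texture in one hemifield,
hemifield-matched contrast effects).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import awareness_accuracy, score_detection
from .containers import Epochs, NoDataError
from .erp import MeasurementWindow, average_condition, difference_wave, mean_amplitude
from .io import read_epochs_container, write_epochs_container
from .preprocess import apply_zero_phase_filter, baseline_correct, design_lowpass_fir, reject_artifacts
from .stats import detect_onset, jackknife_latency_difference, one_sample_t, sliding_window_ttest
from .synth import (
    ComponentSpec,
    Condition,
    NoiseSpec,
    SimulationConfig,
    simulate_behavior_stream,
    simulate_subject_epochs,
)
from .synth import C1_WEIGHTS, LVF_CONTRAST_WEIGHTS, UVF_CONTRAST_WEIGHTS

__all__ = ["AnalysisConfig", "AnalysisReport", "run_experiment_analysis", "simulate_to_dir"]

EXPERIMENTS = ("exp1_contrast", "exp1_onset", "exp2_masked", "exp3_hemifield")


@dataclass
class AnalysisConfig:
    """Tunable knobs of one experiment analysis.

    Defaults run a desk-scale cohort (8 subjects, 64 trials/condition);
    the full study sizes (24 subjects, 576 trials) are plain overrides.
    """

    experiment: str = "exp1_contrast"
    seed: int = 0
    n_subjects: int = 8
    n_trials_per_condition: int = 64
    sampling_rate_hz: float = 512.0
    lowpass_cutoff_hz: float = 40.0
    lowpass_transition_hz: float = 20.0
    rejection_threshold_uV: float = 70.0
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    c1_window_ms: tuple[float, float] = (50.0, 70.0)
    measurement_site: str = "POz"
    onset_sites: tuple[str, ...] = ("POz", "PO4", "Oz", "O2")
    onset_range_ms: tuple[float, float] = (50.0, 110.0)
    alpha: float = 0.05
    run_length: int = 5
    window_len_ms: float = 20.0
    step_ms: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_ms"] = list(self.baseline_ms)
        d["c1_window_ms"] = list(self.c1_window_ms)
        d["onset_range_ms"] = list(self.onset_range_ms)
        d["onset_sites"] = list(self.onset_sites)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        for key in ("baseline_ms", "c1_window_ms", "onset_range_ms"):
            if key in d:
                d[key] = tuple(d[key])
        if "onset_sites" in d:
            d["onset_sites"] = tuple(d["onset_sites"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class AnalysisReport(dict):
    """Plain dict with a JSON writer; every statistic traces to the config."""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# --------------------------------------------------------------------------
# experiment layouts
# --------------------------------------------------------------------------

def _components(experiment: str) -> list[Condition]:
    texture = ComponentSpec("texture_C1", 80.0, 50.0, -0.8, C1_WEIGHTS)
    lvf_eff = ComponentSpec("contrast_effect", 92.0, 68.0, 0.6, LVF_CONTRAST_WEIGHTS)
    uvf_eff = ComponentSpec("contrast_effect", 97.0, 88.0, 0.4, UVF_CONTRAST_WEIGHTS)
    c1_uvf = ComponentSpec("C1", 80.0, 50.0, -0.6, C1_WEIGHTS)
    c1_lvf = ComponentSpec("C1", 80.0, 50.0, 0.5, C1_WEIGHTS)
    if experiment == "exp1_contrast":
        return [
            Condition("homogeneous", [texture]),
            Condition("UVF_contrast", [texture, uvf_eff]),
            Condition("LVF_contrast", [texture, lvf_eff]),
            Condition("UVF_onset", [c1_uvf]),
            Condition("LVF_onset", [c1_lvf]),
        ]
    if experiment == "exp1_onset":
        return [Condition("UVF_onset", [c1_uvf]), Condition("LVF_onset", [c1_lvf])]
    if experiment == "exp2_masked":
        masked_eff = ComponentSpec("contrast_effect", 88.0, 66.0, 0.55, LVF_CONTRAST_WEIGHTS)
        return [
            Condition("homogeneous", [texture]),
            Condition("UVF_contrast", [texture]),       # masked UVF effect absent
            Condition("LVF_contrast", [texture, masked_eff]),
            Condition("LVF_onset", [c1_lvf]),           # reference cohort condition
        ]
    # exp3_hemifield
    exp3_eff = ComponentSpec("contrast_effect", 92.0, 68.0, 0.35, LVF_CONTRAST_WEIGHTS)
    c1_lvf3 = ComponentSpec("C1", 80.0, 50.0, 0.6, C1_WEIGHTS)
    return [
        Condition("UVF_homogeneous", [c1_uvf]),
        Condition("UVF_contrast", [c1_uvf]),            # no early UVF effect planted
        Condition("LVF_homogeneous", [c1_lvf3]),
        Condition("LVF_contrast", [c1_lvf3, exp3_eff]),
    ]


_EFFECTS = {
    "exp1_contrast": {
        "UVF_contrast_effect": ("UVF_contrast", "homogeneous"),
        "LVF_contrast_effect": ("LVF_contrast", "homogeneous"),
    },
    "exp1_onset": {},
    "exp2_masked": {
        "UVF_contrast_effect": ("UVF_contrast", "homogeneous"),
        "LVF_contrast_effect": ("LVF_contrast", "homogeneous"),
    },
    "exp3_hemifield": {
        "UVF_contrast_effect": ("UVF_contrast", "UVF_homogeneous"),
        "LVF_contrast_effect": ("LVF_contrast", "LVF_homogeneous"),
    },
}

#: name -> (effect_or_condition_a, b, design, site_a, site_b,
#:          window_a, window_b, polarity_a, polarity_b)
_JACKKNIFE = {
    "exp1_contrast": [
        ("LVF_contrast_vs_C1", "LVF_contrast_effect", "LVF_onset", "paired",
         "POz", "POz", (60.0, 150.0), (50.0, 120.0), "positive", "positive"),
        ("UVF_contrast_vs_C1", "UVF_contrast_effect", "UVF_onset", "paired",
         "PO4", "POz", (60.0, 150.0), (50.0, 120.0), "positive", "negative"),
    ],
    "exp1_onset": [],
    "exp2_masked": [
        ("LVF_contrast_vs_C1", "LVF_contrast_effect", "LVF_onset", "independent",
         "POz", "POz", (60.0, 150.0), (50.0, 120.0), "positive", "positive"),
    ],
    "exp3_hemifield": [
        ("LVF_contrast_vs_C1", "LVF_contrast_effect", "LVF_pooled", "paired",
         "POz", "POz", (60.0, 150.0), (50.0, 120.0), "positive", "positive"),
    ],
}

#: Pooled condition averages (trial-weighted across labels).
_POOLS = {
    "exp3_hemifield": {
        "UVF_pooled": ("UVF_homogeneous", "UVF_contrast"),
        "LVF_pooled": ("LVF_homogeneous", "LVF_contrast"),
    },
}


def simulation_config(cfg: AnalysisConfig) -> SimulationConfig:
    return SimulationConfig(
        conditions=_components(cfg.experiment),
        n_subjects=cfg.n_subjects,
        n_trials_per_condition=cfg.n_trials_per_condition,
        sampling_rate_hz=cfg.sampling_rate_hz,
        noise=cfg.noise,
        seed=cfg.seed,
    )


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def _preprocess(cfg: AnalysisConfig, epochs: Epochs) -> Epochs:
    kernel = design_lowpass_fir(cfg.lowpass_cutoff_hz, cfg.lowpass_transition_hz,
                                epochs.sampling_rate_hz)
    out = apply_zero_phase_filter(epochs, kernel)
    out = reject_artifacts(out, threshold_uV=cfg.rejection_threshold_uV)
    return baseline_correct(out, cfg.baseline_ms)


def _load_subjects(cfg: AnalysisConfig, data_source) -> list[Epochs]:
    if data_source == "synthetic":
        sim = simulation_config(cfg)
        return [simulate_subject_epochs(sim, s) for s in range(cfg.n_subjects)]
    root = Path(data_source)
    bases = sorted(p.with_suffix("") for p in root.glob("*.json"))
    if not bases:
        raise NoDataError(f"no epoch containers under {root}")
    return [read_epochs_container(b) for b in bases]


def run_experiment_analysis(cfg: AnalysisConfig, data_source="synthetic",
                            out_dir=None) -> AnalysisReport:
    """Execute one experiment end-to-end; deterministic given (cfg, seed)."""
    effects_map = _EFFECTS[cfg.experiment]
    pools = _POOLS.get(cfg.experiment, {})
    subjects_raw = _load_subjects(cfg, data_source)

    per_subject: list[dict] = []
    trial_counts: dict[str, dict[str, int]] = {}
    for s_idx, raw in enumerate(subjects_raw):
        try:
            clean = _preprocess(cfg, raw)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"preprocess failed for subject {s_idx}: {e}") from e
        waves = {}
        for label in sorted(set(clean.labels)):
            waves[label] = average_condition(clean, label)
            counts = trial_counts.setdefault(label, {"total": 0, "kept": 0, "rejected": 0})
            sel = clean.labels == label
            counts["total"] += int(sel.sum())
            counts["kept"] += int((sel & clean.kept).sum())
            counts["rejected"] += int((sel & clean.rejected).sum())
        for pool_name, labels in pools.items():
            waves[pool_name] = average_condition(clean, set(labels))
        for eff_name, (minu, subtr) in effects_map.items():
            waves[eff_name] = difference_wave(waves[minu], waves[subtr])
        per_subject.append(waves)

    names = per_subject[0].keys()
    by_name = {nm: [subj[nm] for subj in per_subject] for nm in names}

    # fixed-window amplitude tests at the measurement site
    window = MeasurementWindow(cfg.measurement_site, *cfg.c1_window_ms)
    window_tests = []
    for nm in sorted(names):
        amps = [mean_amplitude(w, window) for w in by_name[nm]]
        res = one_sample_t(amps)
        window_tests.append({
            "measure": nm, "site": window.site,
            "window_ms": [window.t_start_ms, window.t_end_ms],
            "mean_uV": res.mean, "sem_uV": res.sem,
            "t": res.statistic, "df": res.df, "p": res.p,
        })

    # sliding-window onsets for each contrast effect
    onsets = []
    for eff_name in effects_map:
        for site in cfg.onset_sites:
            sw = sliding_window_ttest(by_name[eff_name], site, cfg.onset_range_ms,
                                      cfg.window_len_ms, cfg.step_ms, alpha=cfg.alpha)
            est = detect_onset(sw, k=cfg.run_length)
            onsets.append({"effect": eff_name, "site": site, "onset_ms": est.onset_ms})

    # jackknife latency comparisons
    jackknives = []
    for (nm, a, b, design, site_a, site_b, win_a, win_b, pol_a, pol_b) in _JACKKNIFE[cfg.experiment]:
        jk = jackknife_latency_difference(
            by_name[a], by_name[b], design=design, site_a=site_a, site_b=site_b,
            search_window_ms=win_a, search_window_b_ms=win_b,
            polarity_a=pol_a, polarity_b=pol_b,
        )
        jackknives.append({
            "comparison": nm, "design": design,
            "D_ms": jk.D_ms, "se_jack_ms": jk.se_jack_ms,
            "t_corrected": jk.t_corrected, "df": jk.df, "p": jk.p,
        })

    # behavior: one luminance-detection stream per subject
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    hit_rates, rts = [], []
    for s_idx in range(len(subjects_raw)):
        stream = simulate_behavior_stream(
            360.0, hit_model={"p_hit": 0.86, "rt_mean_ms": 480.0, "rt_sd_ms": 90.0},
            seed=int(rng.integers(2**31)),
        )
        score = score_detection(stream, stream)
        hit_rates.append(score.hit_rate)
        if score.mean_rt_ms is not None:
            rts.append(score.mean_rt_ms)
    behavior = {
        "hit_rate_mean": float(np.mean(hit_rates)),
        "hit_rate_sem": float(np.std(hit_rates, ddof=1) / np.sqrt(len(hit_rates)))
        if len(hit_rates) > 1 else 0.0,
        "rt_mean_ms": float(np.mean(rts)) if rts else None,
    }
    if cfg.experiment == "exp2_masked":
        # awareness test: 96 trials, half contrast, near-chance observer
        truth = np.array([True] * 48 + [False] * 48)
        p_report = np.where(truth, 0.62, 0.45)
        accs = []
        for _ in range(len(subjects_raw)):
            resp = rng.random(96) < p_report
            accs.append(awareness_accuracy(truth, resp))
        behavior["awareness_accuracy_mean"] = float(np.mean(accs))

    report = AnalysisReport(
        experiment=cfg.experiment,
        seed=cfg.seed,
        config_hash=cfg.hash(),
        software_version=__version__,
        trial_counts=trial_counts,
        window_tests=window_tests,
        onsets=onsets,
        jackknife=jackknives,
        behavior=behavior,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.write(out_dir / "report.json")
    return report


def simulate_to_dir(cfg: AnalysisConfig, out_dir) -> list[Path]:
    """Write one epochs container and one behavior TSV per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulation_config(cfg)
    paths = []
    for s in range(cfg.n_subjects):
        epochs = simulate_subject_epochs(sim, s)
        paths.append(write_epochs_container(epochs, out_dir / f"sub-{s:02d}_epochs"))
        stream = simulate_behavior_stream(360.0, seed=cfg.seed * 1000 + s)
        stream.to_tsv(out_dir / f"sub-{s:02d}_events.tsv")
    return paths
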