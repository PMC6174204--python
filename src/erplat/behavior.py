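"""Fixation luminance-detection scoring, the adaptive target-luminance rule,
and awareness-test accuracy."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import EventTable, NoDataError

__all__ = ["BehaviorScore", "score_detection", "adjust_luminance", "awareness_accuracy"]

#: Correct-hit eligibility window after a target, half-open (200, 1200] ms.
HIT_WINDOW_S = (0.2, 1.2)


@dataclass
class BehaviorScore:
    hit_rate: float
    mean_rt_ms: float | None
    n_targets: int
    n_hits: int


def score_detection(targets: EventTable, responses: EventTable) -> BehaviorScore:
    """Score the luminance-detection task.

    A target is hit if at least one response falls in the half-open window
    ``(t + 200 ms, t + 1200 ms]``. Each response credits at most one target:
    the nearest preceding eligible one, and only if that target has not
    already been credited (so later extra presses are not re-assigned).
    RT is averaged over first crediting responses.
    """
    t_times = targets.times("target")
    if t_times.size == 0:
        raise NoDataError("no targets to score")
    r_times = responses.times("response")
    hit = np.zeros(t_times.size, dtype=bool)
    rts_ms: list[float] = []
    lo, hi = HIT_WINDOW_S
    for r in np.sort(r_times):
        lags = r - t_times
        eligible = (lags > lo) & (lags <= hi)
        if not eligible.any():
            continue
        idx = int(np.flatnonzero(eligible)[-1])  # nearest preceding target
        if not hit[idx]:
            hit[idx] = True
            rts_ms.append(1000.0 * lags[idx])
    n_hits = int(hit.sum())
    return BehaviorScore(
        hit_rate=n_hits / t_times.size,
        mean_rt_ms=float(np.mean(rts_ms)) if rts_ms else None,
        n_targets=int(t_times.size),
        n_hits=n_hits,
    )


def adjust_luminance(hit_rate: float, current_rgb: Sequence[int]) -> tuple[int, int, int]:
    """Between-block staircase on the target's green channel.

    Hit rate strictly above 0.90 lowers G by 10 (harder target); strictly
    below 0.80 raises G by 10 (easier); inside [0.80, 0.90] the value is
    unchanged. Components clip to [0, 255].
    """
    r, g, b = (int(c) for c in current_rgb)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError("RGB components must lie in [0, 255]")
    if hit_rate > 0.90:
        g -= 10
    elif hit_rate < 0.80:
        g += 10
    g = min(255, max(0, g))
    return (r, g, b)


def awareness_accuracy(is_contrast_trial: Sequence[bool],
                       reported_present: Sequence[bool]) -> float:
    """Accuracy of present/absent reports on the awareness test:
    (hits on contrast trials + correct rejections on homogeneous trials)
    divided by the total trial count."""
    truth = np.asarray(is_contrast_trial, dtype=bool)
    resp = np.asarray(reported_present, dtype=bool)
    if truth.size == 0:
        raise NoDataError("empty trial list")
    if truth.size != resp.size:
        raise ValueError("one response record per trial is required")
    return float((truth == resp).mean())
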