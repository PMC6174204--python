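"""Inferential core: t-tests, ANOVA, sliding-window onset detection,
peak latency, and the jackknife latency-difference procedure.

The onset-latency rule: one-sample (or two-group) t-tests on 20-ms window
means sliding in 2-ms steps; the onset is the midpoint of the first window
that opens a run of at least five consecutive windows significant at
alpha = 0.05. Peak-latency differences between grand averages are tested
with leave-one-subject-out jackknifing and the corrected t-statistic
(jackknife SE inflated by (n-1)/n, which undoes the variance shrinkage the
leave-one-out grand averages introduce).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .containers import ERPWaveform

__all__ = [
    "TTestResult",
    "AnovaResult",
    "SlidingWindowResult",
    "OnsetEstimate",
    "JackknifeResult",
    "one_sample_t",
    "independent_t",
    "one_way_anova",
    "sliding_window_ttest",
    "detect_onset",
    "peak_latency",
    "jackknife_se",
    "jackknife_latency_difference",
]


@dataclass
class TTestResult:
    statistic: float
    df: int
    p: float
    mean: float
    sem: float
    n: int
    n2: int | None = None  # second-group size for independent tests


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def _t_to_p(t: float, df: int) -> float:
    if math.isinf(t):
        return 0.0
    return float(2.0 * sps.t.sf(abs(t), df))


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample Student t against ``mu0``.

    Paired comparisons are this test applied to per-subject differences.
    Zero spread degenerates to t = 0 when the mean equals ``mu0`` and to a
    signed infinite statistic otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / math.sqrt(n)
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean == mu0 else math.copysign(math.inf, mean - mu0)
    else:
        t = (mean - mu0) / sem
    return TTestResult(statistic=t, df=df, p=_t_to_p(t, df) if sd else (1.0 if t == 0 else 0.0),
                       mean=mean, sem=sem, n=n)


def independent_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance two-sample t, df = n1 + n2 - 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    diff = float(a.mean() - b.mean())
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if t == 0 else 0.0
    else:
        t = diff / se
        p = _t_to_p(t, df)
    return TTestResult(statistic=t, df=df, p=p, mean=diff, sem=se, n=n1, n2=n2)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Between-subjects one-way ANOVA: F with df (k-1, N-k)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    k = len(arrays)
    N = sum(a.size for a in arrays)
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(F=float(F), df1=k - 1, df2=N - k, p=float(p))


# --------------------------------------------------------------------------
# sliding-window onset detection
# --------------------------------------------------------------------------

@dataclass
class SlidingWindowResult:
    site: str
    midpoints_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    window_len_ms: float
    step_ms: float
    mode: str


@dataclass
class OnsetEstimate:
    onset_ms: float | None
    run_length_required: int
    alpha: float
    site: str = ""


def _window_indices(time_ms: np.ndarray, lo_ms: float, hi_ms: float,
                    fs_hz: float) -> slice:
    """Snap the nominal window edges to the nearest samples (half-open)."""
    t0 = time_ms[0]
    i_lo = int(round((lo_ms - t0) * fs_hz / 1000.0))
    i_hi = int(round((hi_ms - t0) * fs_hz / 1000.0))
    i_lo = max(i_lo, 0)
    i_hi = min(i_hi, time_ms.size)
    return slice(i_lo, i_hi)


def sliding_window_ttest(subject_waveforms: Sequence[ERPWaveform], site: str,
                         analysis_range_ms: tuple[float, float],
                         window_len_ms: float = 20.0, step_ms: float = 2.0,
                         mode: str = "one_sample",
                         group_b: Sequence[ERPWaveform] | None = None,
                         alpha: float = 0.05) -> SlidingWindowResult:
    """t-test per sliding window of per-subject window-mean amplitudes.

    Windows are labelled by their nominal midpoints (multiples of
    ``step_ms``); at sampling rates where the nominal edges fall between
    samples, the edges snap to the nearest sample. ``mode='one_sample'``
    tests the mean against zero; ``mode='independent'`` compares two groups
    of subject waveforms with a pooled-variance t.
    """
    if mode not in ("one_sample", "independent"):
        raise ValueError("mode must be 'one_sample' or 'independent'")
    if mode == "independent" and group_b is None:
        raise ValueError("independent mode requires group_b")
    lo, hi = analysis_range_ms
    if hi - lo < window_len_ms:
        raise ValueError("analysis range shorter than the window length")
    if len(subject_waveforms) < 2:
        raise ValueError("need at least 2 subjects")

    first = subject_waveforms[0]
    fs = 1000.0 / float(np.median(np.diff(first.time_ms)))
    half = window_len_ms / 2.0
    m0 = math.ceil((lo + half) / step_ms) * step_ms
    midpoints = np.arange(m0, hi - half + 1e-9, step_ms)

    def window_means(waves: Sequence[ERPWaveform], mid: float) -> np.ndarray:
        sl = _window_indices(first.time_ms, mid - half, mid + half, fs)
        return np.array([w.site_series(site)[sl].mean() for w in waves])

    t_arr = np.empty(midpoints.size)
    p_arr = np.empty(midpoints.size)
    for j, mid in enumerate(midpoints):
        amps = window_means(subject_waveforms, mid)
        if mode == "one_sample":
            res = one_sample_t(amps)
        else:
            res = independent_t(amps, window_means(group_b, mid))
        t_arr[j] = res.statistic
        p_arr[j] = res.p
    return SlidingWindowResult(
        site=site, midpoints_ms=midpoints, t=t_arr, p=p_arr,
        significant=p_arr < alpha, alpha=alpha,
        window_len_ms=window_len_ms, step_ms=step_ms, mode=mode,
    )


def detect_onset(result: SlidingWindowResult, k: int = 5) -> OnsetEstimate:
    """Midpoint of the first window opening a run of >= k significant windows."""
    sig = np.asarray(result.significant, dtype=bool)
    run = 0
    start = None
    for i, s in enumerate(sig):
        if s:
            run += 1
            if run == 1:
                start = i
            if run >= k:
                return OnsetEstimate(onset_ms=float(result.midpoints_ms[start]),
                                     run_length_required=k, alpha=result.alpha,
                                     site=result.site)
        else:
            run = 0
            start = None
    return OnsetEstimate(onset_ms=None, run_length_required=k,
                         alpha=result.alpha, site=result.site)


# --------------------------------------------------------------------------
# peak latency and jackknife comparison
# --------------------------------------------------------------------------

def peak_latency(waveform: ERPWaveform, site: str,
                 search_window_ms: tuple[float, float],
                 polarity: str) -> float:
    """Latency of the signed extremum within ``search_window_ms`` (inclusive).

    ``polarity='positive'`` takes the maximum, ``'negative'`` the minimum;
    ties break toward the earliest latency (a flat window therefore yields
    the window start, with a warning). Nearest-sample resolution.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    lo, hi = search_window_ms
    mask = (waveform.time_ms >= lo) & (waveform.time_ms <= hi)
    if not mask.any():
        raise ValueError("search window contains no samples")
    series = waveform.site_series(site)[mask]
    times = waveform.time_ms[mask]
    if np.ptp(series) == 0.0:
        warnings.warn("flat waveform in search window; returning window start",
                      stacklevel=2)
        return float(times[0])
    idx = int(np.argmax(series)) if polarity == "positive" else int(np.argmin(series))
    return float(times[idx])


@dataclass
class JackknifeResult:
    D_ms: float
    se_jack_ms: float
    t_corrected: float
    df: int
    p: float
    design: str
    loo_differences_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    criterion: str = "max_amplitude"


def _grand(waves: Sequence[ERPWaveform]) -> ERPWaveform:
    from .erp import grand_average
    return grand_average(list(waves))


def jackknife_se(loo_estimates: Sequence[float]) -> float:
    """Jackknife standard error from the n leave-one-out estimates:
    ``sqrt(((n-1)/n) * sum_i (theta_-i - mean(theta_-i))^2)``.

    For a linear statistic (the sample mean) this reduces exactly to the
    classical SEM.
    """
    loo = np.asarray(loo_estimates, dtype=float)
    n = loo.size
    if n < 2:
        raise ValueError("need at least 2 leave-one-out estimates")
    return math.sqrt((n - 1) / n * float(((loo - loo.mean()) ** 2).sum()))


def jackknife_latency_difference(
        group_a: Sequence[ERPWaveform], group_b: Sequence[ERPWaveform],
        design: str, site_a: str, site_b: str,
        search_window_ms: tuple[float, float],
        polarity_a: str, polarity_b: str,
        search_window_b_ms: tuple[float, float] | None = None) -> JackknifeResult:
    """Jackknife comparison of grand-average peak latencies (A minus B).

    ``D`` is the latency difference on the full grand averages. For the
    paired design (equal n, matched subject order) each subject is left out
    of both grand averages at once and

        se_jack^2 = ((n-1)/n) * sum_i (D_-i - mean(D_-i))^2,  df = n - 1.

    For the independent design each subject is left out of its own group's
    grand average only, the two per-group sums are added with their own
    (n_g - 1)/n_g factors, and df = n1 + n2 - 2. The corrected statistic is
    t = D / se_jack.
    """
    if design not in ("paired", "independent"):
        raise ValueError("design must be 'paired' or 'independent'")
    win_b = search_window_ms if search_window_b_ms is None else search_window_b_ms

    def lat_a(waves) -> float:
        return peak_latency(_grand(waves), site_a, search_window_ms, polarity_a)

    def lat_b(waves) -> float:
        return peak_latency(_grand(waves), site_b, win_b, polarity_b)

    n1, n2 = len(group_a), len(group_b)
    D = lat_a(group_a) - lat_b(group_b)

    if design == "paired":
        if n1 != n2:
            raise ValueError("paired design requires equal group sizes")
        n = n1
        loo = np.array([
            lat_a([w for j, w in enumerate(group_a) if j != i])
            - lat_b([w for j, w in enumerate(group_b) if j != i])
            for i in range(n)
        ])
        var = jackknife_se(loo) ** 2
        df = n - 1
    else:
        full_b = lat_b(group_b)
        full_a = lat_a(group_a)
        loo_a = np.array([
            lat_a([w for j, w in enumerate(group_a) if j != i]) - full_b
            for i in range(n1)
        ])
        loo_b = np.array([
            full_a - lat_b([w for j, w in enumerate(group_b) if j != i])
            for i in range(n2)
        ])
        var = ((n1 - 1) / n1 * float(((loo_a - loo_a.mean()) ** 2).sum())
               + (n2 - 1) / n2 * float(((loo_b - loo_b.mean()) ** 2).sum()))
        loo = np.concatenate([loo_a, loo_b])
        df = n1 + n2 - 2

    se = math.sqrt(var)
    if se == 0.0:
        t = 0.0 if D == 0.0 else math.copysign(math.inf, D)
        p = 1.0 if t == 0 else 0.0
    else:
        t = D / se
        p = _t_to_p(t, df)
    return JackknifeResult(D_ms=D, se_jack_ms=se, t_corrected=t, df=df, p=p,
                           design=design, loo_differences_ms=loo)
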