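"""Clinical response metrics and the stable-vs-fluctuating group comparison.

The motor response to a levodopa test dose is summarized by three
quantities derived from the tapping series: *latency to onset* — the first
time the tapping rate rises at least 15% above the pre-dose baseline;
*duration* — the time from onset until the rate first falls back below that
same +15% threshold; and the *classification* — a patient whose response
returns to baseline within the 4-hour test window is *fluctuating*, one
whose response persists is *stable* (censored duration).

Group comparison uses the exact two-sided Wilcoxon rank-sum test per
estimated parameter with a Bonferroni factor of 9 (the number of estimated
parameters), the nonparametric path being justified by the omnibus
D'Agostino K^2 Gaussianity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, LevotapError
from .series import SampledSeries

__all__ = [
    "PARAMETER_NAMES",
    "ONSET_FRACTION",
    "OBSERVATION_WINDOW_MIN",
    "ResponseMetrics",
    "latency_to_onset",
    "effect_duration",
    "classify_response",
    "response_metrics",
    "compare_groups",
    "gaussianity_check",
]

#: The nine estimated parameters entering the group comparison.
PARAMETER_NAMES = ("k12", "k21", "ketot", "ke3", "D0", "T", "Dmax", "Dc50", "ND")

#: Onset/return threshold: 15% above the pre-dose baseline.
ONSET_FRACTION = 1.15

#: Length of the tapping observation window (minutes).
OBSERVATION_WINDOW_MIN = 240.0

#: Bonferroni factor: all estimated parameters.
BONFERRONI_FACTOR = 9


class UndefinedDurationError(LevotapError, ValueError):
    """Duration requested for a series that never reached onset."""


@dataclass(frozen=True)
class ResponseMetrics:
    """Summary of one patient's motor response to the test dose."""

    baseline: float                  # taps/min, pre-dose
    latency_min: float | None        # None = never reached onset
    duration_min: float | None       # None = censored (no return in window)
    classification: str              # "stable" | "fluctuating"
    no_onset: bool = False           # stable-by-default warning flag


def latency_to_onset(tapping: SampledSeries, baseline: float) -> float | None:
    """First sample time with tapping >= 1.15 x baseline (inclusive)."""
    if baseline <= 0:
        raise InputError("baseline must be strictly positive")
    above = tapping.values >= ONSET_FRACTION * baseline
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return float(tapping.times[idx[0]])


def effect_duration(tapping: SampledSeries, baseline: float) -> float | None:
    """Time from onset to the first post-onset return below 1.15 x baseline.

    ``None`` means censored: no return within the observation window.
    """
    latency = latency_to_onset(tapping, baseline)
    if latency is None:
        raise UndefinedDurationError(
            "duration undefined: the series never reached onset"
        )
    after = tapping.times > latency
    below = tapping.values < ONSET_FRACTION * baseline
    idx = np.flatnonzero(after & below)
    if idx.size == 0:
        return None
    return float(tapping.times[idx[0]] - latency)


def classify_response(tapping: SampledSeries, baseline: float) -> str:
    """``"fluctuating"`` iff the response returned to baseline in-window."""
    return response_metrics(tapping, baseline).classification


def response_metrics(tapping: SampledSeries, baseline: float) -> ResponseMetrics:
    """Latency, duration and classification in one pass."""
    latency = latency_to_onset(tapping, baseline)
    if latency is None:
        # never onset: stable by convention, flagged
        return ResponseMetrics(baseline=baseline, latency_min=None,
                               duration_min=None, classification="stable",
                               no_onset=True)
    duration = effect_duration(tapping, baseline)
    cls = "fluctuating" if duration is not None else "stable"
    return ResponseMetrics(baseline=baseline, latency_min=latency,
                           duration_min=duration, classification=cls)


def compare_groups(
    group1: pd.DataFrame | Mapping[str, Sequence[float]],
    group2: pd.DataFrame | Mapping[str, Sequence[float]],
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> pd.DataFrame:
    """Exact two-sided Wilcoxon rank-sum test per parameter, Bonferroni x9.

    ``group1``/``group2`` are tables with one column per estimated
    parameter (one row per patient).  Returns a DataFrame with columns
    ``parameter, median_g1, median_g2, p_raw, p_bonferroni``.
    """
    g1 = pd.DataFrame(group1)
    g2 = pd.DataFrame(group2)
    if len(g1) < 3 or len(g2) < 3:
        raise InputError("each group needs at least 3 patients")
    rows = []
    for name in parameters:
        if name not in g1.columns or name not in g2.columns:
            raise InputError(f"parameter column {name!r} missing from a group")
        x = np.asarray(g1[name], dtype=float)
        y = np.asarray(g2[name], dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        p = float(res.pvalue)
        rows.append({
            "parameter": name,
            "median_g1": float(np.median(x)),
            "median_g2": float(np.median(y)),
            "p_raw": p,
            "p_bonferroni": min(1.0, BONFERRONI_FACTOR * p),
        })
    return pd.DataFrame(rows)


def gaussianity_check(sample: Sequence[float]) -> tuple[float, float]:
    """Omnibus D'Agostino K^2 normality test (skewness + kurtosis)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise InputError("the omnibus K^2 test needs at least 8 observations")
    stat, p = stats.normaltest(x)
    return float(stat), float(p)
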