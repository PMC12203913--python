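"""FRAP trace normalization and recovery statistics.

Recovery of fluorescence into a bleached nuclear region reports protein
mobility: a chromatin-engaged (or complexed) pool recovers slowly or not at
all. Traces are normalized to the mean pre-bleach intensity and compared
through the relative recovery at a fixed time after the bleach.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import FrapTrace, InvalidConfigError


def normalize_trace(
    raw_times_s, raw_intensity, bleach_time_s: float, condition: str = ""
) -> FrapTrace:
    """Normalize a raw FRAP trace to its mean pre-bleach intensity.

    Requires at least 3 pre-bleach frames; time is re-zeroed at the bleach.
    """
    t = np.asarray(raw_times_s, dtype=float)
    i = np.asarray(raw_intensity, dtype=float)
    pre = t < bleach_time_s
    if pre.sum() < 3:
        raise InvalidConfigError("need >= 3 pre-bleach frames")
    scale = i[pre].mean()
    if scale <= 0:
        raise InvalidConfigError("non-positive pre-bleach intensity")
    return FrapTrace(
        times_s=t - bleach_time_s,
        intensity_norm=i / scale,
        bleach_time_s=0.0,
        condition=condition,
    )


def recovery_at(trace: FrapTrace, t_s: float = 120.0) -> float:
    """Normalized intensity at ``t_s`` after the bleach, by linear interpolation.

    Raises if the trace ends before ``t_s``; extrapolation beyond the
    acquisition is never performed.
    """
    post = trace.times_s >= 0
    t = trace.times_s[post]
    i = trace.intensity_norm[post]
    if t.size == 0 or t[-1] < t_s:
        raise InvalidConfigError(
            f"trace ends at {t[-1] if t.size else np.nan:.1f} s, before {t_s} s"
        )
    return float(np.interp(t_s, t, i))


def compare_groups(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-sided t-test on recovery values; (t, p).

    Student's (equal-variance) test by default; ``equal_var=False`` gives
    the Welch variant.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidConfigError("need >= 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise InvalidConfigError("degenerate test: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
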