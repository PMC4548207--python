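"""Translation-rate estimation from dual-colour degron-reporter time lapses.

Input is a per-cell intensity table (no image processing happens here): GFP
reports new synthesis of a degron-stabilised reporter, mCherry made from the
same transcript normalises for per-cell reporter copy number.  The
processing order is flat-field correction, photobleach correction, background
subtraction, then the normalised rate — the change of the GFP/mCherry ratio
per hour between the start and the end of the observation window.  Under
complete translational shutdown the rate is slightly *negative*, because the
pre-existing GFP pool decays while mCherry stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


def flatfield_correct(intensity, gain_at_position):
    """Divide out the illumination gain (from a uniform fluorescent target).

    The gain map is normalised to mean 1, so a gain of 0.5 means the position
    received half the nominal illumination and the intensity is doubled.
    """
    gain = np.asarray(gain_at_position, dtype=float)
    if np.any(gain <= 0):
        raise ValueError("flat-field gain must be strictly positive")
    return np.asarray(intensity, dtype=float) / gain


def fit_bleach_decay(times_min, control_signal) -> tuple[float, float]:
    """Fit ``a * exp(-k (t - t0))`` to a stable control signal.

    Returns ``(a, k)`` with ``k`` per minute.  Used on, e.g., the mCherry
    channel of non-dividing control cells, whose only systematic trend is
    photobleaching.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(control_signal, dtype=float)
    t0 = t[0]

    def model(t, a, k):
        return a * np.exp(-k * (t - t0))

    k0 = max(1e-6, -np.polyfit(t - t0, np.log(np.maximum(y, 1e-12)), 1)[0])
    popt, _ = curve_fit(model, t, y, p0=(y[0], k0), maxfev=10_000)
    return float(popt[0]), float(popt[1])


def bleach_correct(values, times_min, decay_rate_per_min: float):
    """Rescale a trace by the fitted photobleaching decay.

    The decay curve is ``exp(-k (t - t0))`` (value 1 at the first frame).  A
    negative fitted ``k`` means the control signal was not monotonically
    decreasing; the correction is then skipped with a warning.
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if decay_rate_per_min < 0:
        warnings.warn(
            "fitted bleach decay is non-monotone (k < 0); correction skipped"
        )
        return v
    return v / np.exp(-decay_rate_per_min * (t - t[0]))


class CellExcluded(ValueError):
    """A cell was excluded from rate estimation (reason in the message)."""


def translation_rate(
    times_min,
    gfp,
    mcherry,
    t_start: float | None = None,
    t_end: float | None = None,
    endpoint_frames: int = 2,
) -> float:
    """Normalised translation rate, in GFP/mCherry ratio units per hour.

    ``rate = [G/M (end) - G/M (start)] / (t_end - t_start in hours)``.  The
    endpoint ratios average the first/last ``endpoint_frames`` frames inside
    the window to damp single-frame noise (set 1 for raw single endpoints).
    Inputs must already be corrected and background-subtracted.  Cells whose
    mCherry is non-positive at an endpoint are excluded
    (:class:`CellExcluded`).
    """
    t = np.asarray(times_min, dtype=float)
    g = np.asarray(gfp, dtype=float)
    m = np.asarray(mcherry, dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 2 strictly increasing timepoints")
    lo = t[0] if t_start is None else float(t_start)
    hi = t[-1] if t_end is None else float(t_end)
    if hi <= lo:
        raise ValueError("t_end must exceed t_start")
    inside = (t >= lo) & (t <= hi)
    t, g, m = t[inside], g[inside], m[inside]
    if len(t) < 2:
        raise ValueError("window contains fewer than 2 timepoints")
    f = min(endpoint_frames, len(t) // 2)
    if np.any(m[:f] <= 0) or np.any(m[-f:] <= 0):
        raise CellExcluded("non-positive mCherry at a window endpoint")
    ratio_start = float(np.mean(g[:f] / m[:f]))
    ratio_end = float(np.mean(g[-f:] / m[-f:]))
    dt_hours = (float(np.mean(t[-f:])) - float(np.mean(t[:f]))) / 60.0
    return (ratio_end - ratio_start) / dt_hours


@dataclass
class RateResult:
    """Per-condition summary of normalised translation rates."""

    ratio: float | None
    mean_numerator: float
    mean_reference: float
    sem: float | None
    n_numerator: int
    n_reference: int


def rates_table(
    traces: pd.DataFrame,
    t_start: float | None = None,
    t_end: float | None = None,
    endpoint_frames: int = 2,
    bleach_rate_per_min: float = 0.0,
) -> pd.DataFrame:
    """Per-cell rates from a tidy trace table.

    Expects columns ``cell_id, phase, time_min, gfp, mcherry`` and optional
    ``bg_gfp, bg_mcherry, experiment``.  Background columns are subtracted
    per frame; an optional common bleach decay is divided out first.
    Excluded cells are logged and omitted.  The output records the endpoint
    mode used.
    """
    rows = []
    for cell, tr in traces.groupby("cell_id", sort=False):
        tr = tr.sort_values("time_min")
        t = tr["time_min"].to_numpy(dtype=float)
        g = tr["gfp"].to_numpy(dtype=float)
        m = tr["mcherry"].to_numpy(dtype=float)
        if bleach_rate_per_min:
            g = bleach_correct(g, t, bleach_rate_per_min)
            m = bleach_correct(m, t, bleach_rate_per_min)
        if "bg_gfp" in tr:
            g = g - tr["bg_gfp"].to_numpy(dtype=float)
        if "bg_mcherry" in tr:
            m = m - tr["bg_mcherry"].to_numpy(dtype=float)
        try:
            rate = translation_rate(t, g, m, t_start, t_end, endpoint_frames)
        except CellExcluded as exc:
            logger.info("cell %s excluded: %s", cell, exc)
            continue
        rows.append(
            {
                "cell_id": cell,
                "phase": tr["phase"].iloc[0],
                "experiment": tr["experiment"].iloc[0] if "experiment" in tr else 1,
                "rate_per_hour": rate,
                "endpoint_frames": endpoint_frames,
            }
        )
    return pd.DataFrame(rows)


def rate_ratio(
    rates: pd.DataFrame,
    numerator_phase: str = "mitosis",
    reference_phase: str = "interphase",
) -> RateResult:
    """Ratio of mean normalised rates between two phase groups.

    With an ``experiment`` column distinguishing independent experiments,
    the ratio is computed per experiment and the SEM across experiments is
    reported; otherwise SEM is ``None``.  A non-positive reference mean makes
    the ratio undefined (``None``).
    """
    num = rates[rates["phase"] == numerator_phase]["rate_per_hour"]
    ref = rates[rates["phase"] == reference_phase]["rate_per_hour"]
    if num.empty or ref.empty:
        raise ValueError("need at least one cell per group")
    mean_num, mean_ref = float(num.mean()), float(ref.mean())
    ratio = mean_num / mean_ref if mean_ref > 0 else None

    sem = None
    if "experiment" in rates.columns and rates["experiment"].nunique() > 1:
        per_exp = []
        for _, sub in rates.groupby("experiment"):
            n = sub[sub["phase"] == numerator_phase]["rate_per_hour"].mean()
            r = sub[sub["phase"] == reference_phase]["rate_per_hour"].mean()
            if np.isfinite(n) and np.isfinite(r) and r > 0:
                per_exp.append(n / r)
        if len(per_exp) > 1:
            sem = float(np.std(per_exp, ddof=1) / np.sqrt(len(per_exp)))
    return RateResult(
        ratio=ratio,
        mean_numerator=mean_num,
        mean_reference=mean_ref,
        sem=sem,
        n_numerator=int(len(num)),
        n_reference=int(len(ref)),
    )
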