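"""Developmental time-course assembly.

Different synchronized cohorts are imaged at each timepoint (no per-worm
tracking); small larvae are imaged through a high-magnification objective
and older larvae through a lower one, with one timepoint acquired through
both.  This module stitches the two objective series onto a common scale
using that shared timepoint, normalizes trajectories to a baseline
timepoint, and estimates larval-stage transition times from worm-length
cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TimeSeriesPoint:
    """One cohort: per-worm densities at a single timepoint and objective."""

    timepoint_hr: float
    densities: np.ndarray
    objective: str = ""

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.size == 0:
            raise ValueError("a time-series point needs at least one worm")
        if self.timepoint_hr < 0:
            raise ValueError("timepoint_hr must be >= 0")

    @property
    def mean(self) -> float:
        return float(self.densities.mean())

    @property
    def sem(self) -> float:
        n = self.densities.size
        return float(self.densities.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")


@dataclass
class TransitionEstimate:
    name: str
    time_hr: float | None
    status: str  # ok | before_series | absent


_T_TOL = 1e-9


def _points_at(series: list[TimeSeriesPoint], t: float) -> list[TimeSeriesPoint]:
    return [p for p in series if abs(p.timepoint_hr - t) <= _T_TOL]


def normalize_to_baseline(series: list[TimeSeriesPoint], t0: float) -> list[TimeSeriesPoint]:
    """Divide every density by the mean density at the baseline timepoint.

    The baseline mean pools all worms at t0 (both objectives, if the
    series was stitched), so the trajectory at t0 has mean exactly 1.
    Idempotent when the baseline mean is already 1.
    """
    base_pts = _points_at(series, t0)
    if not base_pts:
        raise ValueError(f"no timepoint at t0 = {t0}")
    base = float(np.concatenate([p.densities for p in base_pts]).mean())
    if base == 0:
        raise ValueError("baseline mean density is zero")
    return [TimeSeriesPoint(p.timepoint_hr, p.densities / base, p.objective)
            for p in series]


def stitch_objectives(series_a: list[TimeSeriesPoint], series_b: list[TimeSeriesPoint],
                      shared_t: float) -> list[TimeSeriesPoint]:
    """Rescale series_b onto series_a's intensity scale via the shared timepoint.

    k = mean_a(shared_t) / mean_b(shared_t); every density in series_b is
    multiplied by k, then the two series are merged and sorted by time.
    Both cohorts at the shared timepoint are retained; their means are
    equal by construction after rescaling.
    """
    a_shared = _points_at(series_a, shared_t)
    b_shared = _points_at(series_b, shared_t)
    if not a_shared or not b_shared:
        raise ValueError(f"shared timepoint {shared_t} missing from one series")
    mean_a = float(np.concatenate([p.densities for p in a_shared]).mean())
    mean_b = float(np.concatenate([p.densities for p in b_shared]).mean())
    if mean_b == 0:
        raise ValueError("cannot stitch: shared-timepoint mean of series_b is zero")
    k = mean_a / mean_b
    merged = list(series_a) + [
        TimeSeriesPoint(p.timepoint_hr, p.densities * k, p.objective) for p in series_b
    ]
    merged.sort(key=lambda p: (p.timepoint_hr, p.objective))
    return merged


# Stage-length cutoffs (µm) are user-supplied in real studies; these
# defaults are rough placeholders for demonstration, not authoritative
# staging values.
DEFAULT_STAGE_CUTOFFS_UM = {"L1-L2": 370.0, "L2-L3": 520.0}


def _median3(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    for i in range(1, len(values) - 1):
        out[i] = np.median(values[i - 1:i + 2])
    return out


def annotate_transitions(lengths: list[tuple[float, float]],
                         thresholds: dict[str, float]) -> list[TransitionEstimate]:
    """Estimate stage-transition times from mean worm length vs time.

    The mean-length curve is smoothed with a 3-point running median (to
    tolerate cohort noise), then each cutoff's first upward crossing is
    located by linear interpolation.  A cutoff below the whole series is
    flagged "before_series" at the first timepoint; a cutoff never reached
    is "absent".
    """
    if len(lengths) < 2:
        raise ValueError("need at least 2 (time, length) points")
    pts = sorted(lengths)
    t = np.array([p[0] for p in pts], dtype=float)
    ell = _median3(np.array([p[1] for p in pts], dtype=float))
    out: list[TransitionEstimate] = []
    for name, cutoff in thresholds.items():
        if cutoff <= ell[0]:
            out.append(TransitionEstimate(name, float(t[0]), "before_series"))
            continue
        idx = None
        for i in range(len(t) - 1):
            if ell[i] < cutoff <= ell[i + 1]:
                idx = i
                break
        if idx is None:
            out.append(TransitionEstimate(name, None, "absent"))
            continue
        frac = (cutoff - ell[idx]) / (ell[idx + 1] - ell[idx])
        out.append(TransitionEstimate(name, float(t[idx] + frac * (t[idx + 1] - t[idx])), "ok"))
    return out


def trajectory_correlation(series: list[TimeSeriesPoint],
                           latent: list[tuple[float, float]]) -> float:
    """Pearson r between cohort-mean densities and a latent (time, value) curve.

    Convenience for benchmarking a stitched trajectory against a known
    ground-truth fat curve; latent values are matched to series points by
    timepoint.
    """
    lat = {round(t, 9): v for t, v in latent}
    xs, ys = [], []
    for p in series:
        key = round(p.timepoint_hr, 9)
        if key in lat:
            xs.append(p.mean)
            ys.append(lat[key])
    if len(xs) < 3:
        raise ValueError("need at least 3 matched timepoints")
    r, _ = sps.pearsonr(xs, ys)
    return float(r)
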