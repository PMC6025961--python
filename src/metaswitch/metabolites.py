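"""Metabolite time-course analysis: production/consumption phases by the
sign of the smoothed time derivative, peak statistics, and alignment of the
phases with reporter fraction-positive time courses.

The phase criterion is the one used for the acetate curve of a growing
culture: the production phase is where the rate of change of concentration
is positive, consumption where it is negative.  Derivatives are central
finite differences (one-sided at the boundaries), optionally smoothed by a
moving average; magnitudes below ``eps`` count as zero to suppress
instrument-scale noise.  Multiple sign changes in noisy data are resolved
by the longest-run rule (``first`` run available by flag).  Phase endpoints
are reported at sample times, not interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["MetaboliteSeries", "PhaseReport", "detect_phases", "phase_alignment"]

DEFAULT_EPS = 0.005  # mM/min; HPLC-scale noise floor on the derivative


@dataclass
class MetaboliteSeries:
    """One analyte's concentration time course."""

    t: np.ndarray
    concentration: np.ndarray
    analyte: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.t.size != self.concentration.size:
            raise ValueError("t and concentration must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class PhaseReport:
    """Production/consumption intervals and the concentration peak."""

    production_interval: Optional[Tuple[float, float]]
    consumption_interval: Optional[Tuple[float, float]]
    t_peak: float
    c_peak: float
    n_production_runs: int
    n_consumption_runs: int
    analyte: str = ""
    rule: str = field(default="sign of smoothed central-difference derivative; "
                              "longest contiguous run per sign")


def _runs(sign: np.ndarray, value: int) -> list:
    """Contiguous index runs where ``sign == value``."""
    runs = []
    start = None
    for i, s in enumerate(sign):
        if s == value and start is None:
            start = i
        elif s != value and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, sign.size - 1))
    return runs


def detect_phases(series: MetaboliteSeries, smooth_window: int = 3,
                  eps: float = DEFAULT_EPS, run_rule: str = "longest"
                  ) -> PhaseReport:
    """Locate the production and consumption phases of a metabolite curve.

    The derivative is computed by central differences (one-sided at the
    boundaries) and smoothed by a ``smooth_window``-point moving average
    (window 1 or 0 disables smoothing).  Derivative magnitudes <= ``eps``
    are treated as zero.  The longest positive run is reported as the
    production interval and the longest negative run as consumption
    (``run_rule="first"`` takes the first run of each sign instead); a
    run's start is extended to the previous sample, where the sign change
    occurred.  The peak is the maximum of the raw series.
    """
    t, c = series.t, series.concentration
    if t.size < 3:
        raise ValueError("phase detection needs at least 3 points")
    if run_rule not in ("longest", "first"):
        raise ValueError("run_rule must be 'longest' or 'first'")

    d = np.gradient(c, t)  # central differences, one-sided at the ends
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        # truncated (renormalised) moving average at the boundaries
        num = np.convolve(d, kernel, mode="same")
        den = np.convolve(np.ones_like(d), kernel, mode="same")
        d = num / den
    sign = np.sign(d)
    sign[np.abs(d) <= eps] = 0

    def pick(value: int) -> Tuple[Optional[Tuple[float, float]], int]:
        runs = _runs(sign, value)
        if not runs:
            return None, 0
        if run_rule == "longest":
            start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        else:
            start, end = runs[0]
        return (float(t[max(start - 1, 0)]), float(t[end])), len(runs)

    production, n_prod = pick(1)
    consumption, n_cons = pick(-1)
    i_peak = int(np.argmax(c))
    return PhaseReport(production_interval=production,
                       consumption_interval=consumption,
                       t_peak=float(t[i_peak]), c_peak=float(c[i_peak]),
                       n_production_runs=n_prod, n_consumption_runs=n_cons,
                       analyte=series.analyte)


def phase_alignment(phases: PhaseReport, fractions: pd.DataFrame) -> dict:
    """Align reporter fraction-positive time courses with metabolite phases.

    ``fractions`` is the output of
    :func:`metaswitch.snapshots.fraction_timecourse` (columns ``t_min``,
    ``reporter``, ``fraction_positive``).  For each reporter the report
    gives the argmax-fraction time, the phase containing it (production
    checked first, intervals inclusive), and the coverage of each phase:
    the fraction of the phase interval during which the reporter's positive
    fraction exceeds half its maximum.
    """
    intervals = {"production": phases.production_interval,
                 "consumption": phases.consumption_interval}
    t_all = fractions["t_min"].to_numpy(dtype=float)
    lo, hi = t_all.min(), t_all.max()
    for name, iv in intervals.items():
        if iv is not None and (iv[1] < lo or iv[0] > hi):
            raise ValueError(
                f"{name} interval {iv} does not overlap the fraction "
                f"time support [{lo}, {hi}]")

    report: dict = {"t_peak": phases.t_peak, "analyte": phases.analyte,
                    "reporters": {}}
    for rep, sub in fractions.groupby("reporter", sort=False):
        t = sub["t_min"].to_numpy(dtype=float)
        f = sub["fraction_positive"].to_numpy(dtype=float)
        fmax = f.max()
        if fmax > 0:
            t_max = float(t[int(np.argmax(f))])
            phase = None
            for name in ("production", "consumption"):
                iv = intervals[name]
                if iv is not None and iv[0] <= t_max <= iv[1]:
                    phase = name
                    break
        else:
            t_max, phase = None, None
        coverage = {}
        for name, iv in intervals.items():
            if iv is None or fmax == 0:
                coverage[name] = 0.0
                continue
            inside = (t >= iv[0]) & (t <= iv[1])
            if not inside.any():
                coverage[name] = 0.0
                continue
            coverage[name] = float((f[inside] > 0.5 * fmax).mean())
        report["reporters"][rep] = {
            "t_argmax": t_max,
            "phase": phase,
            "coverage": coverage,
            "max_fraction": float(fmax),
        }
    return report
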