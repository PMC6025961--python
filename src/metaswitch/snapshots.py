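"""Snapshot-level statistics of single-cell fluorescence distributions.

The heterogeneity screen and subpopulation definitions used throughout the
package: adjusted Fisher-Pearson skewness for flagging heterogeneous
reporters, the ">= mean + k*SD" positive-cell rule (k = 2 by default, the
rule defining sucC+ and alsS+ cells), fraction-positive time courses along
a growth curve, and Hill characterisation of the acetate dose response of
alsS activation.

Threshold statistics are always computed per snapshot (per time point), not
pooled across the growth curve, because the positive fractions of interest
are reported at specific culture densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SnapshotSample",
    "ClassificationResult",
    "HillFit",
    "DegenerateDistributionWarning",
    "skewness",
    "classify_positive",
    "fraction_timecourse",
    "dose_response",
]

SKEWNESS_ESTIMATOR = "adjusted Fisher-Pearson (g1 * sqrt(n(n-1))/(n-2))"


class DegenerateDistributionWarning(UserWarning):
    """Raised when a zero-spread sample makes the 2-SD rule vacuous."""


@dataclass
class SnapshotSample:
    """Per-cell fluorescence values of one reporter at one culture time point."""

    t: float
    od: float
    values: np.ndarray
    reporter_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("snapshot must contain at least one cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluorescence values must be finite")
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be >= 0")


@dataclass
class ClassificationResult:
    """Outcome of the mean + k*SD positive-cell rule on one snapshot."""

    threshold: float
    labels: np.ndarray
    fraction_positive: float
    mean: float
    sd: float
    k: float
    degenerate: bool = False
    rule: str = field(default="value >= mean + k*sd (sample sd, per snapshot)")


def skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson sample skewness, ``g1 * sqrt(n(n-1))/(n-2)``.

    The spreadsheet/statistics-package default estimator; values above ~1
    flag a heavy high-expressing tail in a reporter distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.std(x) == 0:
        raise ValueError("skewness is undefined for a zero-variance sample")
    return float(stats.skew(x, bias=False))


def classify_positive(values: Sequence[float], k: float = 2.0) -> ClassificationResult:
    """Label cells whose value is at least ``k`` sample SDs above the mean.

    Mean and sample SD (n-1 denominator) are taken from the same snapshot.
    The comparison at the threshold is inclusive (``>=``).  A zero-spread
    sample yields zero positives and a :class:`DegenerateDistributionWarning`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("classification requires at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        warnings.warn(
            "zero-variance snapshot: positive-cell rule is degenerate; "
            "returning zero positives", DegenerateDistributionWarning)
        labels = np.zeros(x.size, dtype=bool)
        return ClassificationResult(threshold=mean, labels=labels,
                                    fraction_positive=0.0, mean=mean, sd=0.0,
                                    k=k, degenerate=True)
    threshold = mean + k * sd
    labels = x >= threshold
    return ClassificationResult(
        threshold=threshold, labels=labels,
        fraction_positive=float(labels.mean()), mean=mean, sd=sd, k=k)


def fraction_timecourse(samples: Sequence[SnapshotSample], k: float = 2.0) -> pd.DataFrame:
    """Positive fraction per snapshot along a (time-sorted) growth curve.

    Returns a frame with columns ``t_min, od, reporter, fraction_positive,
    threshold`` and, in ``attrs``, the argmax time per reporter (``None``
    when every fraction is zero).
    """
    if len(samples) == 0:
        raise ValueError("fraction_timecourse needs at least one snapshot")
    t = [s.t for s in samples]
    if any(b < a for a, b in zip(t, t[1:])):
        raise ValueError("snapshots must be sorted by time")
    rows = []
    for s in samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDistributionWarning)
            res = classify_positive(s.values, k=k)
        rows.append((s.t, s.od, s.reporter_name, res.fraction_positive,
                     res.threshold))
    df = pd.DataFrame(rows, columns=["t_min", "od", "reporter",
                                     "fraction_positive", "threshold"])
    argmax: dict = {}
    for rep, sub in df.groupby("reporter", sort=False):
        if sub["fraction_positive"].max() > 0:
            argmax[rep] = float(sub.loc[sub["fraction_positive"].idxmax(), "t_min"])
        else:
            argmax[rep] = None
    df.attrs["argmax_t"] = argmax
    df.attrs["k"] = k
    return df


@dataclass
class HillFit:
    """Bounded least-squares Hill fit of a dose-response curve."""

    amplitude: float
    K: float
    h: float
    baseline: float
    monotone: bool
    non_identifiable: bool
    residual_sd: float

    def predict(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return _hill(d, self.amplitude, self.K, self.h, self.baseline)


def _hill(d, amplitude, K, h, baseline):
    d = np.maximum(np.asarray(d, dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**h / (K**h + d**h), 0.0)
    return baseline + amplitude * frac


def dose_response(doses: Sequence[float], fractions: Sequence[float]) -> HillFit:
    """Fit ``baseline + amplitude * d^h / (K^h + d^h)`` to positive fractions.

    Requires >= 4 distinct doses for the full fit (with >= 2 doses only the
    Spearman monotonicity flag is meaningful).  Bounds: amplitude and
    baseline in [0, 1], K > 0, h in [0.5, 6].  K is initialised at the dose
    closest to half-maximal response and h at 2.  A flat response is
    returned with amplitude ~ 0 and flagged non-identifiable in K and h.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if d.size != y.size:
        raise ValueError("doses and fractions must have equal length")
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct doses")
    order = np.argsort(d)
    d, y = d[order], y[order]
    rho = stats.spearmanr(d, y).statistic if np.std(y) > 0 else 0.0
    monotone = bool(rho >= 0)

    if np.unique(d).size < 4 or np.ptp(y) < 1e-3:
        # not enough structure for a 4-parameter fit
        return HillFit(amplitude=float(np.ptp(y)), K=np.nan, h=np.nan,
                       baseline=float(y.min()), monotone=monotone,
                       non_identifiable=True, residual_sd=float(np.std(y)))

    y0, y1 = float(y.min()), float(y.max())
    half = y0 + 0.5 * (y1 - y0)
    pos = d[d > 0]
    K0 = float(pos[np.argmin(np.abs(y[d > 0] - half))]) if pos.size else 1.0
    K0 = max(K0, 1e-3)
    p0 = [max(y1 - y0, 1e-3), K0, 2.0, y0]
    lo = [0.0, 1e-6, 0.5, 0.0]
    hi = [1.0, max(10.0 * d.max(), 1.0), 6.0, 1.0]
    try:
        popt, _ = optimize.curve_fit(_hill, d, y, p0=p0, bounds=(lo, hi),
                                     maxfev=20000)
    except RuntimeError:
        return HillFit(amplitude=float(np.ptp(y)), K=np.nan, h=np.nan,
                       baseline=y0, monotone=monotone, non_identifiable=True,
                       residual_sd=float(np.std(y)))
    amplitude, K, h, baseline = (float(v) for v in popt)
    resid = y - _hill(d, *popt)
    non_ident = amplitude < 0.02
    return HillFit(amplitude=amplitude, K=K if not non_ident else np.nan,
                   h=h if not non_ident else np.nan, baseline=baseline,
                   monotone=monotone, non_identifiable=non_ident,
                   residual_sd=float(np.std(resid)))
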