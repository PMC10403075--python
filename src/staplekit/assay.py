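"""Numeric post-processing of in-vitro / in-vivo assay readouts.

Covers the three standard transformations used around the peptide assays:
turbidity area-under-curve (DMPC vesicle clearance), saturation-kinetics
dose-response fitting (lipolysis rate vs peptide concentration), and
percent-of-baseline normalization of plasma lipid timecourses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Timeseries",
    "DoseResponseFit",
    "auc",
    "fit_saturation",
    "percent_baseline",
]


@dataclass(frozen=True)
class Timeseries:
    """A sampled signal: times in minutes, y in assay units."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be matching 1-D arrays")


@dataclass(frozen=True)
class DoseResponseFit:
    """Saturation-kinetics fit: response = Vmax * d / (EC50 + d) (+ baseline)."""

    ec50: float
    vmax: float
    baseline: float
    residual_norm: float
    converged: bool
    degenerate: bool = False


def auc(ts: Timeseries) -> float:
    """Trapezoidal area under the curve over the observed interval."""
    if ts.t.size < 2:
        raise ValueError("need at least 2 points for an area")
    if not np.all(np.diff(ts.t) > 0):
        raise ValueError("time values must be strictly increasing")
    return float(np.trapezoid(ts.y, ts.t))


def _hyperbola(d, vmax, ec50):
    return vmax * d / (ec50 + d)


def _hyperbola_baseline(d, vmax, ec50, b):
    return b + vmax * d / (ec50 + d)


def fit_saturation(dose, response, with_baseline: bool = False) -> DoseResponseFit:
    """Least-squares saturation fit of response vs dose.

    Requires at least 3 distinct doses including 0.  A flat or
    monotone-decreasing response is reported as degenerate rather than
    force-fit.
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("dose and response must be matching 1-D arrays")
    if np.unique(d).size < 3 or 0.0 not in d:
        raise ValueError("need >= 3 distinct doses including 0")

    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    slope = float(np.polyfit(d, y, 1)[0]) if np.ptp(d) > 0 else 0.0
    if span <= 1e-12 * scale or slope < 0:
        return DoseResponseFit(ec50=np.nan, vmax=np.nan, baseline=np.nan,
                               residual_norm=float(np.linalg.norm(y - y.mean())),
                               converged=False, degenerate=True)

    positive = d[d > 0]
    p0_ec50 = float(np.median(positive))
    try:
        if with_baseline:
            popt, _ = curve_fit(_hyperbola_baseline, d, y,
                                p0=[span, p0_ec50, float(y[d == 0].mean())],
                                bounds=([-np.inf, 1e-12, -np.inf],
                                        [np.inf, np.inf, np.inf]),
                                maxfev=20000)
            vmax, ec50, base = popt
            resid = y - _hyperbola_baseline(d, *popt)
        else:
            popt, _ = curve_fit(_hyperbola, d, y, p0=[span, p0_ec50],
                                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                                maxfev=20000)
            vmax, ec50 = popt
            base = 0.0
            resid = y - _hyperbola(d, *popt)
    except RuntimeError:
        return DoseResponseFit(ec50=np.nan, vmax=np.nan, baseline=np.nan,
                               residual_norm=np.nan, converged=False)
    return DoseResponseFit(ec50=float(ec50), vmax=float(vmax), baseline=float(base),
                           residual_norm=float(np.linalg.norm(resid)),
                           converged=True)


def percent_baseline(t, values) -> dict:
    """Normalize per-subject timecourses to percent of their t=0 value.

    ``values`` is (n_subjects, n_times); each row is divided by its first
    entry and scaled to percent, then group mean and SD (ddof=1 when
    possible) are taken across subjects.
    """
    t = np.asarray(t, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[1] != t.size:
        raise ValueError("values must have one column per time point")
    baseline = Y[:, 0]
    if np.any(baseline <= 0):
        raise ValueError("baseline (t=0) values must be positive")
    pct = Y / baseline[:, None] * 100.0
    ddof = 1 if Y.shape[0] > 1 else 0
    return {
        "t": t,
        "percent": pct,
        "mean": pct.mean(axis=0),
        "sd": pct.std(axis=0, ddof=ddof),
    }
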