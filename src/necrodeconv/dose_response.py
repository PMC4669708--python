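"""Hill-model dose-response fitting: EC50, IC50 and binding Kd estimation.

All potencies follow the standard four-parameter logistic / Hill form

    response(d) = background + (signal - background) / (1 + (midpoint / d)^slope)

with doses ``d`` in molar.  A positive slope gives a curve increasing in
dose (protection / rescue readouts), a negative slope a decreasing one
(toxicity, enzyme inhibition, competition binding).  At ``d == midpoint``
the response is exactly ``(background + signal) / 2`` for any slope.

Binding constants are fitted with the slope fixed at -1 (one-site
competition) and reported with censoring conventions for serial-dilution
designs: an estimate above the top tested concentration is reported as a
censored code (4/3 x top, i.e. 40 000 nM for the standard 30 000 nM top),
and an estimate below the lowest tested concentration is flagged for
re-measurement with a lower top concentration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "hill_response",
    "serial_dilution_doses",
    "DoseResponseSeries",
    "HillFit",
    "HillCurveFitter",
    "fit_hill",
    "estimate_ec50",
    "estimate_ic50",
    "fit_kd",
]


def hill_response(dose, background, signal, midpoint, slope):
    """Evaluate the Hill curve at ``dose`` (molar, array-like, > 0)."""
    dose = np.asarray(dose, dtype=float)
    return background + (signal - background) / (1.0 + (midpoint / dose) ** slope)


def serial_dilution_doses(top_dose: float, dilution_factor: float, n_points: int) -> np.ndarray:
    """Descending serial-dilution dose grid: top, top/f, ..., top/f^(n-1)."""
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return top_dose / dilution_factor ** np.arange(n_points, dtype=float)


@dataclass
class DoseResponseSeries:
    """Replicated (dose, response) measurements for one compound/readout.

    ``points`` has columns ``dose`` (molar), ``response`` and ``replicate``.
    """

    compound: str
    readout: str
    points: pd.DataFrame

    @classmethod
    def from_arrays(
        cls,
        doses: Sequence[float],
        responses: Sequence[float],
        replicates: Sequence[int] | None = None,
        compound: str = "compound",
        readout: str = "viability_protection",
    ) -> "DoseResponseSeries":
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if replicates is None:
            replicates = np.zeros(len(doses), dtype=int)
        pts = pd.DataFrame(
            {"dose": doses, "response": responses, "replicate": np.asarray(replicates, dtype=int)}
        )
        return cls(compound=compound, readout=readout, points=pts)


@dataclass
class HillFit:
    """Result of one Hill-model fit."""

    background: float
    signal: float
    midpoint: float
    slope: float
    rss: float
    converged: bool
    censored: str | None = None  # None | 'no_effect' | 'above_range' | 'below_range'
    reported_midpoint: float | None = None
    flags: tuple = field(default_factory=tuple)

    def predict(self, dose):
        return hill_response(dose, self.background, self.signal, self.midpoint, self.slope)


class HillCurveFitter(RegressorMixin, BaseEstimator):
    """Least-squares Hill-curve estimator (Levenberg-Marquardt core).

    Parameters
    ----------
    fix_slope : float or None
        If given, the Hill slope is held at this value (e.g. -1 for
        one-site competition binding).
    orientation : {'increasing', 'decreasing', None}
        Expected direction of the response in dose.  Used to seed the
        slope sign; a fitted slope of the wrong sign is flagged, not
        rejected.
    background_bounds, signal_bounds : (low, high) or None
        Soft box bounds for the two asymptotes.  When either is set the
        solver switches from unbounded Levenberg-Marquardt to a bounded
        trust-region reflective scheme.
    weighting : {'relative', 'none'}
        ``'relative'`` (default) divides residuals by
        ``max(|model|, 0.05 * data range)``, the maximum-likelihood
        weighting when measurement error scales with the expected
        response (the usual behavior of luminescence and qPCR
        readouts); ``'none'`` is plain unweighted least squares.
    min_span : float
        Minimum |signal - background| below which the midpoint is deemed
        unidentifiable and the fit censored as ``'no_effect'``.
    censor_range_factor : float
        A fitted midpoint outside [min_dose / f, max_dose * f] is
        censored as out of range.
    xtol : float
        Relative parameter-change convergence tolerance.

    Fitted attributes: ``background_``, ``signal_``, ``midpoint_``,
    ``slope_``, ``rss_``, ``converged_``, ``censored_``, ``result_``.
    The midpoint is optimized on a log10 scale for conditioning of
    serial-dilution designs.
    """

    def __init__(
        self,
        fix_slope: float | None = None,
        orientation: str | None = None,
        background_bounds: tuple | None = None,
        signal_bounds: tuple | None = None,
        weighting: str = "relative",
        min_span: float = 5.0,
        censor_range_factor: float = 100.0,
        xtol: float = 1e-8,
    ):
        self.fix_slope = fix_slope
        self.orientation = orientation
        self.background_bounds = background_bounds
        self.signal_bounds = signal_bounds
        self.weighting = weighting
        self.min_span = min_span
        self.censor_range_factor = censor_range_factor
        self.xtol = xtol

    # ---- internal -------------------------------------------------
    def _validate(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[0] != y.shape[0]:
            raise ValueError("dose and response arrays differ in length")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("doses and responses must be finite")
        if np.any(X <= 0):
            raise ValueError("doses must be strictly positive")
        if np.unique(X).size < 4:
            raise ValueError("at least 4 distinct doses are required")
        return X, y

    def _starts(self, d, y):
        """Multi-start seeds: (background, signal, log10 midpoint, slope)."""
        order = np.argsort(d)
        d_s, y_s = d[order], y[order]
        b0 = float(np.mean(y_s[d_s == d_s[0]]))
        s0 = float(np.mean(y_s[d_s == d_s[-1]]))
        half = 0.5 * (b0 + s0)
        # dose whose mean response is closest to half-maximal
        means = pd.Series(y).groupby(pd.Series(d)).mean()
        bracket = float(means.index[np.argmin(np.abs(means.values - half))])
        geo_med = float(np.exp(np.median(np.log(d))))
        if self.fix_slope is not None:
            slopes = [self.fix_slope]
        elif self.orientation == "increasing":
            slopes = [1.0]
        elif self.orientation == "decreasing":
            slopes = [-1.0]
        else:
            slopes = [1.0, -1.0]
        starts = []
        for m0, h0 in itertools.product({geo_med, bracket}, slopes):
            starts.append((b0, s0, np.log10(m0), h0))
            # also try swapped asymptotes; cheap insurance for noisy ends
            starts.append((s0, b0, np.log10(m0), h0))
        return starts

    def fit(self, X, y):
        d, y = self._validate(X, y)
        if np.ptp(y) < self.min_span:
            # response window narrower than the identifiable span: no dose effect
            fit = HillFit(float(np.mean(y)), float(np.mean(y)), np.nan, np.nan,
                          float(np.sum((y - np.mean(y)) ** 2)), True, censored="no_effect")
            self._finish(fit)
            return self
        fixed = self.fix_slope
        blo, bhi = self.background_bounds or (-np.inf, np.inf)
        slo, shi = self.signal_bounds or (-np.inf, np.inf)
        bounded = self.background_bounds is not None or self.signal_bounds is not None

        def unpack(theta):
            if fixed is None:
                b, s, lm, h = theta
            else:
                b, s, lm = theta
                h = fixed
            return b, s, lm, h

        if self.weighting not in ("relative", "none"):
            raise ValueError("weighting must be 'relative' or 'none'")
        relative = self.weighting == "relative"
        floor = 0.05 * max(float(np.ptp(y)), 1e-12)  # constant, data-derived

        def resid(theta):
            b, s, lm, h = unpack(theta)
            f = hill_response(d, b, s, 10.0 ** lm, h)
            r = f - y
            if relative:
                r = r / np.maximum(np.abs(f), floor)
            return r

        lmid_lo = np.log10(d.min()) - np.log10(self.censor_range_factor) - 1
        lmid_hi = np.log10(d.max()) + np.log10(self.censor_range_factor) + 1
        if fixed is None:
            lower = [blo, slo, lmid_lo, -10.0]
            upper = [bhi, shi, lmid_hi, 10.0]
        else:
            lower = [blo, slo, lmid_lo]
            upper = [bhi, shi, lmid_hi]

        best = None
        for b0, s0, lm0, h0 in self._starts(d, y):
            theta0 = [b0, s0, lm0] if fixed is not None else [b0, s0, lm0, h0]
            try:
                if bounded:
                    theta0 = np.clip(theta0, np.asarray(lower) + 1e-9, np.asarray(upper) - 1e-9)
                    sol = least_squares(resid, theta0, bounds=(lower, upper), xtol=self.xtol, method="trf")
                else:
                    sol = least_squares(resid, theta0, xtol=self.xtol, method="lm")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        flags: list[str] = []
        if best is None:
            fit = HillFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, censored="no_effect",
                          flags=("solver_failed",))
            self._finish(fit)
            return self

        b, s, lm, h = unpack(best.x)
        # the Hill form is invariant under (b, s, h) -> (s, b, -h); when the
        # slope is free, canonicalize to signal >= background so the fitted
        # labeling is deterministic
        if fixed is None and b > s:
            b, s, h = s, b, -h
        mid = 10.0 ** lm
        rss = float(np.sum((hill_response(d, b, s, mid, h) - y) ** 2))
        converged = bool(best.success)
        censored = None
        if abs(s - b) < self.min_span:
            censored = "no_effect"
        elif mid > d.max() * self.censor_range_factor:
            censored = "above_range"
        elif mid < d.min() / self.censor_range_factor:
            censored = "below_range"
        if not converged:
            flags.append("not_converged")
        if self.orientation == "increasing" and h < 0:
            flags.append("orientation_mismatch")
        if self.orientation == "decreasing" and h > 0:
            flags.append("orientation_mismatch")
        reported = mid if censored is None else None
        fit = HillFit(float(b), float(s), float(mid), float(h), rss, converged,
                      censored=censored, reported_midpoint=reported, flags=tuple(flags))
        self._finish(fit)
        return self

    def _finish(self, fit: HillFit):
        self.result_ = fit
        self.background_ = fit.background
        self.signal_ = fit.signal
        self.midpoint_ = fit.midpoint
        self.slope_ = fit.slope
        self.rss_ = fit.rss
        self.converged_ = fit.converged
        self.censored_ = fit.censored

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.result_.predict(X)


# ---- functional wrappers ------------------------------------------


def _series_arrays(series: DoseResponseSeries):
    pts = series.points
    return pts["dose"].to_numpy(float), pts["response"].to_numpy(float)


def fit_hill(series: DoseResponseSeries, fix_slope: float | None = None, **kwargs) -> HillFit:
    """Fit the Hill model to pooled replicate points of a series."""
    d, y = _series_arrays(series)
    est = HillCurveFitter(fix_slope=fix_slope, **kwargs)
    est.fit(d, y)
    return est.result_


def estimate_ec50(series: DoseResponseSeries, **kwargs) -> HillFit:
    """Protection potency: increasing viability-rescue curve, free slope.

    Responses are assumed pre-normalized so the untreated/positive
    control sits at 100%.  Soft asymptote bounds stabilize poorly
    saturated curves; override via ``background_bounds``/``signal_bounds``.
    """
    kwargs.setdefault("orientation", "increasing")
    kwargs.setdefault("background_bounds", (-10.0, 50.0))
    kwargs.setdefault("signal_bounds", (50.0, 150.0))
    return fit_hill(series, **kwargs)


def estimate_ic50(series: DoseResponseSeries, **kwargs) -> HillFit:
    """Toxicity or enzyme-inhibition potency: decreasing curve, free slope."""
    kwargs.setdefault("orientation", "decreasing")
    # for a decreasing curve the high-dose asymptote is 'background'
    kwargs.setdefault("background_bounds", (-10.0, 50.0))
    kwargs.setdefault("signal_bounds", (50.0, 150.0))
    return fit_hill(series, **kwargs)


#: Censored-Kd reporting code as a multiple of the top tested concentration.
#: With the standard 30 000 nM top this yields the conventional 40 000 nM
#: code meaning "Kd > 30 000 nM".
KD_CENSOR_FACTOR = 4.0 / 3.0


def fit_kd(series: DoseResponseSeries, top_dose: float | None = None, **kwargs) -> HillFit:
    """Competition-binding Kd with the Hill slope fixed at -1.

    Censoring conventions for serial-dilution designs:

    * fitted Kd above the top tested concentration -> ``censored ==
      'above_range'`` and ``reported_midpoint = 4/3 * top`` (40 000 nM
      for a 30 000 nM top, read as "> top");
    * fitted Kd below the lowest tested concentration -> flag
      ``'repeat_lower_top'``: re-measure with a lower top concentration.
    """
    d, y = _series_arrays(series)
    top = float(top_dose) if top_dose is not None else float(d.max())
    low = float(d.min())
    kwargs.setdefault("orientation", "decreasing")
    fit = fit_hill(series, fix_slope=-1.0, **kwargs)
    if np.isfinite(fit.midpoint):
        if fit.midpoint > top:
            fit.censored = "above_range"
            fit.reported_midpoint = KD_CENSOR_FACTOR * top
        elif fit.midpoint < low:
            fit.flags = fit.flags + ("repeat_lower_top",)
            fit.reported_midpoint = fit.midpoint
    return fit
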