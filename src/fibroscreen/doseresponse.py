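"""Three-parameter logistic (3PL) concentration–response fitting and
screening-quality statistics.

The model is the standard three-parameter logistic in log10 concentration:

    Y(X) = Bottom + (Top - Bottom) / (1 + 10**(LogEC50 - X))

with Y approaching Bottom at low X and Top at high X; the curve passes
through (Top+Bottom)/2 at X = LogEC50. Direction (ascending/descending) is
carried by the sign of Top - Bottom. Potencies that never reach a
half-maximal crossing inside the tested range are reported as censored
bounds ("> cmax"), the convention used in screening hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "PotencySummary",
    "AssayQuality",
    "logistic3",
    "fit_3pl",
    "summarize_potency",
    "zprime",
    "percent_inhibition",
]

CENSOR_NONE = "none"
CENSOR_ABOVE = "above_max"
CENSOR_BELOW = "below_min"


def logistic3(x, bottom, top, logec50):
    """Three-parameter logistic response at log10 concentration ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - x))


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    logec50: float  # log10 of concentration, units of the input x
    direction: str  # "ascending" | "descending"
    censor: str = CENSOR_NONE
    rss: float = float("nan")
    n_points: int = 0

    @property
    def ec50(self) -> float:
        """EC50/IC50 on the linear concentration scale."""
        return float(10.0 ** self.logec50)

    def predict(self, x):
        return logistic3(x, self.bottom, self.top, self.logec50)


@dataclass
class PotencySummary:
    """Replicate potency summary in the style of screening hit tables."""

    mean_ec50: float | None
    sd: float | None
    n: int
    censored_note: str | None = None

    @property
    def label(self) -> str:
        if self.mean_ec50 is None:
            return f"{self.censored_note} (n = {self.n})"
        if self.sd is None:
            return f"{self.mean_ec50:.0f} (n = {self.n})"
        return f"{self.mean_ec50:.0f} ± {self.sd:.0f} (n = {self.n})"


@dataclass
class AssayQuality:
    """Control-population statistics and the Z' screening-window factor."""

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    zprime: float
    defined: bool = True


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Deterministic starts: Bottom/Top from dose-averaged extremes, LogEC50
    # from the half-crossing of a linear interpolation of dose means.
    xu = np.unique(x)
    ymeans = np.array([y[x == xi].mean() for xi in xu])
    lo, hi = float(ymeans.min()), float(ymeans.max())
    ascending = ymeans[-1] >= ymeans[0]
    bottom, top = (lo, hi) if ascending else (hi, lo)
    half = (lo + hi) / 2.0
    ym = ymeans if ascending else -ymeans
    target = half if ascending else -half
    cross = np.interp(target, ym, xu) if ym[0] <= target <= ym[-1] else xu[len(xu) // 2]
    return bottom, top, float(cross)


def fit_3pl(x, y, direction_hint: str | None = None) -> DoseResponseFit:
    """Unweighted least-squares fit of the 3PL model.

    Parameters
    ----------
    x : array-like
        log10 concentrations (zero-concentration anchor wells are handled
        upstream and must not be included).
    y : array-like
        Responses, same length as ``x``.
    direction_hint : {"ascending", "descending"}, optional
        Used only to orient the reported direction when the fitted Top and
        Bottom are nearly equal; normally inferred from the fit.

    A flat response (no concentration dependence) returns a censored fit
    rather than raising; a fitted LogEC50 outside the tested concentration
    range sets the censor flag (``above_max`` / ``below_min``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 concentration points to fit a 3PL")

    yvar = float(np.var(y))
    span = float(np.ptp(y))
    if yvar == 0.0 or span < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        # No response anywhere in the tested range: potency beyond range.
        direction = direction_hint or "ascending"
        return DoseResponseFit(
            bottom=float(np.mean(y)), top=float(np.mean(y)),
            logec50=float("nan"), direction=direction,
            censor=CENSOR_ABOVE, rss=float(np.sum((y - y.mean()) ** 2)),
            n_points=int(x.size),
        )

    p0 = _initial_guess(x, y)
    try:
        popt, _ = curve_fit(logistic3, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        popt = np.array(p0)
    bottom, top, logec50 = (float(v) for v in popt)
    resid = y - logistic3(x, bottom, top, logec50)
    rss = float(np.sum(resid**2))

    direction = "ascending" if top >= bottom else "descending"
    if abs(top - bottom) < 1e-9 and direction_hint:
        direction = direction_hint

    censor = CENSOR_NONE
    if not np.isfinite(logec50) or logec50 > x.max():
        censor = CENSOR_ABOVE
    elif logec50 < x.min():
        censor = CENSOR_BELOW
    return DoseResponseFit(bottom, top, logec50, direction, censor, rss, int(x.size))


def summarize_potency(fits: list[DoseResponseFit], cmax: float) -> PotencySummary:
    """Summarize replicate EC50/IC50 fits on the linear concentration scale.

    Uncensored fits contribute an arithmetic mean (± SD for n ≥ 2). When
    every fit is censored the summary is the bound annotation ``"> cmax"``
    at the maximum tested concentration.
    """
    if not fits:
        raise ValueError("need at least one fit to summarize")
    ec50s = [f.ec50 for f in fits if f.censor == CENSOR_NONE]
    n = len(fits)
    if not ec50s:
        return PotencySummary(None, None, n, f"> {cmax:,.0f}")
    mean = float(np.mean(ec50s))
    sd = float(np.std(ec50s, ddof=1)) if len(ec50s) >= 2 else None
    note = None
    if len(ec50s) < n:
        note = f"{n - len(ec50s)} of {n} replicates censored at > {cmax:,.0f}"
    return PotencySummary(mean, sd, n, note)


def zprime(pos_effects, neg_effects) -> AssayQuality:
    """Z' screening-window coefficient from control percent effects.

    Z' = 1 - 3(σ_pos + σ_neg)/|μ_pos - μ_neg|, with sample SDs (ddof=1).
    Values approaching 1 indicate a wide separation band between the
    positive (full effect) and negative (no effect) control populations.
    Equal control means leave Z' undefined (flagged, not raised).
    """
    pos = np.asarray(pos_effects, dtype=float)
    neg = np.asarray(neg_effects, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 control values per group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        return AssayQuality(mu_p, sd_p, mu_n, sd_n, float("nan"), defined=False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return AssayQuality(mu_p, sd_p, mu_n, sd_n, float(z))


def percent_inhibition(sample_value: float, mu_neg: float, mu_pos: float) -> float:
    """Control-anchored percent inhibition of a sample readout.

    0% at the negative (stimulated, no compound) control mean and 100% at
    the positive (non-stimulated) control mean; shares the percent-effect
    convention of the imaging arm.
    """
    if mu_neg == mu_pos:
        raise ValueError("degenerate controls: equal means")
    return 100.0 * (mu_neg - sample_value) / (mu_neg - mu_pos)
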