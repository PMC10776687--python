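"""Electrophysiology and uptake fitting equations.

Implements the fitted analysis forms used to extract kinetic constants
from recordings: mono-exponential peak relaxation (flipping rate),
saturating dose-dependent rate curves with the association rate constant
from the closed-form derivative at zero concentration, recovery fits
(dissociation rates), the four-parameter logistic with unit Hill slope
(IC50), the Michaelis-Menten hyperbola, and the competitive /
non-competitive / mixed classification of inhibition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synthetic import CurrentTraceSet

__all__ = [
    "MonoExpFit", "DoseRateFit", "DoseResponseFit", "MMFit", "InhibitionCall",
    "FitConvergenceError", "fit_peak_relaxation", "fit_flipping_dose_curve",
    "fit_recovery", "fit_ic50", "fit_km_vmax", "classify_inhibition",
    "extract_recovery_amplitudes",
]


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear fit cannot converge or is unidentifiable."""


def _confidence_intervals(popt, pcov, n_points, names, level=0.95) -> dict:
    dof = max(n_points - len(popt), 1)
    tval = stats.t.ppf(0.5 + level / 2, dof)
    out = {}
    for i, name in enumerate(names):
        se = np.sqrt(pcov[i, i]) if np.isfinite(pcov[i, i]) else np.inf
        out[name] = (popt[i] - tval * se, popt[i] + tval * se)
    return out


def _saturating(x, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * x))


@dataclass
class MonoExpFit:
    """Y = Y0 + (Plateau - Y0) * (1 - exp(-K x)); K in s^-1 or uM^-1."""

    y0: float
    plateau: float
    k: float
    ci: dict = field(default_factory=dict)
    residual_norm: float = 0.0
    n_points: int = 0
    mode: str = ""

    def __post_init__(self):
        if self.k <= 0:
            raise FitConvergenceError(f"fitted rate is non-positive ({self.k})")
        for name, value in (("y0", self.y0), ("plateau", self.plateau), ("k", self.k)):
            lo, hi = self.ci.get(name, (-np.inf, np.inf))
            if not (lo <= value <= hi):
                raise ValueError(f"CI for {name} does not bracket the estimate")

    def predict(self, x):
        return _saturating(np.asarray(x, float), self.y0, self.plateau, self.k)


def _fit_saturating(x, y, p0, bounds=(-np.inf, np.inf), mode="") -> MonoExpFit:
    try:
        popt, pcov = optimize.curve_fit(_saturating, x, y, p0=p0, bounds=bounds,
                                        maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"mono-exponential fit failed: {exc}") from exc
    if not np.isfinite(pcov).all():
        raise FitConvergenceError("mono-exponential fit is unidentifiable "
                                  "(singular covariance)")
    resid = y - _saturating(x, *popt)
    ci = _confidence_intervals(popt, pcov, len(x), ("y0", "plateau", "k"))
    return MonoExpFit(float(popt[0]), float(popt[1]), float(popt[2]), ci,
                      float(np.linalg.norm(resid)), len(x), mode)


# ---------------------------------------------------------------------------
# peak relaxation (flipping rate)

def fit_peak_relaxation(trace: CurrentTraceSet | tuple, baseline_sd_factor: float = 5.0) -> MonoExpFit:
    """Mono-exponential decay fitted from the capacitive peak onward.

    Fits I(t) = A exp(-k (t - t_peak)) + C; the reported ``k`` (s^-1) is
    the relaxation (flipping) rate. Peak = largest |current - baseline|
    after the pulse onset; onset detection uses the first sample exceeding
    ``baseline_sd_factor`` baseline SDs when no pulse marker is present.
    """
    if isinstance(trace, CurrentTraceSet):
        t, i = trace.time, trace.current
        pulses = trace.protocol.get("pulse_windows") or []
        onset = pulses[0][0] if pulses else None
    else:
        t, i = np.asarray(trace[0], float), np.asarray(trace[1], float)
        onset = None
    t = np.asarray(t, float)
    i = np.asarray(i, float)
    if np.ptp(i) < 1e-14:
        raise FitConvergenceError("trace is constant; no peak to fit")
    if onset is None:
        pre = i[: max(len(i) // 20, 2)]
        thresh = pre.mean() + baseline_sd_factor * max(pre.std(), 1e-12)
        above = np.nonzero(np.abs(i - pre.mean()) > thresh - pre.mean())[0]
        onset = t[above[0]] if len(above) else t[0]
    after = t >= onset
    ta, ia = t[after], i[after]
    p = int(np.argmax(np.abs(ia)))
    tp, ip = ta[p:] - ta[p], ia[p:]
    if len(tp) < 4:
        raise FitConvergenceError("too few samples after the peak")
    tail = ip[-max(len(ip) // 10, 2):].mean()
    a0 = ip[0] - tail
    decayed = np.nonzero(np.abs(ip - tail) < 0.37 * abs(a0))[0]
    k0 = 1.0 / tp[decayed[0]] if len(decayed) and tp[decayed[0]] > 0 else 5.0 / tp[-1]

    def decay(x, a, k, c):
        return a * np.exp(-k * x) + c

    try:
        popt, pcov = optimize.curve_fit(decay, tp, ip, p0=(a0, k0, tail), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"peak relaxation fit failed: {exc}") from exc
    a, k, c = popt
    if k <= 0 or not np.isfinite(pcov).all():
        raise FitConvergenceError("trace does not decay (non-positive rate)")
    resid = ip - decay(tp, *popt)
    ci_raw = _confidence_intervals(popt, pcov, len(tp), ("a", "k", "c"))
    ci = {"y0": tuple(sorted((ci_raw["a"][0] + c, ci_raw["a"][1] + c))),
          "plateau": ci_raw["c"], "k": ci_raw["k"]}
    return MonoExpFit(float(a + c), float(c), float(k), ci,
                      float(np.linalg.norm(resid)), len(tp), "peak_relaxation")


# ---------------------------------------------------------------------------
# dose-dependent flipping rate -> K_on

@dataclass
class DoseRateFit:
    """Saturating rate-vs-concentration fit with the closed-form K_on."""

    fit: MonoExpFit | None
    k_on: float                # (Plateau - Y0) * K = dY/dc at c = 0; uM^-1 s^-1
    k_on_ci: tuple
    reliable: bool

    def derivative_at_zero(self) -> float:
        if self.fit is None:
            return 0.0
        return (self.fit.plateau - self.fit.y0) * self.fit.k


def fit_flipping_dose_curve(concentrations, rates) -> DoseRateFit:
    """Fit k_obs(c) = Y0 + (Plateau - Y0)(1 - exp(-K c)); K_on = (Plateau-Y0)K.

    The association rate constant is the analytic derivative of the fitted
    curve at zero concentration, not a numerical difference.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(rates, float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        warnings.warn("all rates equal: Plateau = Y0, K_on = 0 (unreliable)")
        return DoseRateFit(None, 0.0, (0.0, 0.0), False)
    p0 = (float(y.min()), float(y.max()), 1.0 / max(x.mean(), 1e-12))
    fit = _fit_saturating(x, y, p0, bounds=([-np.inf, -np.inf, 0.0], np.inf),
                          mode="dose_rate")
    k_on = (fit.plateau - fit.y0) * fit.k
    # delta-method CI for the product via the K and amplitude CIs
    k_lo, k_hi = fit.ci["k"]
    amp = fit.plateau - fit.y0
    se_k = (k_hi - k_lo) / 2
    se_amp = ((fit.ci["plateau"][1] - fit.ci["plateau"][0]) / 2) if amp else 0.0
    se = abs(amp) * se_k + abs(fit.k) * se_amp
    reliable = k_lo > 0
    if not reliable:
        warnings.warn("saturation not established (K CI includes 0); "
                      "K_on flagged unreliable")
    return DoseRateFit(fit, float(k_on), (k_on - se, k_on + se), reliable)


# ---------------------------------------------------------------------------
# recovery (K_off)

def extract_recovery_amplitudes(trace: CurrentTraceSet):
    """Per-pulse peak amplitudes relative to the reference (first) pulse."""
    pulses = trace.protocol.get("pulse_windows") or []
    if len(pulses) < 2:
        raise ValueError("trace protocol carries fewer than 2 pulse windows")
    peaks = []
    for start, dur in pulses:
        sel = (trace.time >= start) & (trace.time <= start + dur)
        if not sel.any():
            raise ValueError(f"no samples in pulse window ({start}, {dur})")
        peaks.append(np.abs(trace.current[sel]).max())
    washes = trace.protocol.get("wash_intervals_s")
    if washes is None:
        washes = [pulses[i][0] - (pulses[i - 1][0] + pulses[i - 1][1])
                  for i in range(1, len(pulses))]
    ref = peaks[0]
    if ref <= 0:
        raise ValueError("reference pulse has zero amplitude")
    return np.asarray(washes, float), np.asarray(peaks[1:]) / ref


def fit_recovery(wash_times, fractional_amplitudes, mode: str = "peak_recovery") -> MonoExpFit:
    """Fit Y = Y0 + (Plateau - Y0)(1 - exp(-K t)) to recovered amplitudes.

    ``K`` is the dissociation rate (peak recovery) or the cumulative
    dissociation rate (steady-state recovery), per the protocol ``mode``.
    """
    t = np.asarray(wash_times, float)
    a = np.asarray(fractional_amplitudes, float)
    if len(t) < 4:
        raise ValueError(f"need >= 4 recovery points, got {len(t)}")
    if (a < -0.25).any() or (a > 1.3).any():
        raise ValueError("amplitudes must be fractions of the reference peak "
                         "(expected within [0, 1.2] up to noise)")
    if np.ptp(a) < 1e-9:
        raise FitConvergenceError("amplitudes are flat; K is unidentifiable")
    p0 = (float(a.min()), float(max(a.max(), a.min() + 1e-3)),
          1.0 / max(np.median(t), 1e-9))
    fit = _fit_saturating(t, a, p0, bounds=([-0.5, -0.5, 1e-12], [1.5, 2.0, np.inf]),
                          mode=mode)
    return fit


# ---------------------------------------------------------------------------
# dose-response (IC50)

@dataclass
class DoseResponseFit:
    """Four-parameter logistic with unit Hill slope (optionally free)."""

    bottom: float
    top: float
    log_ic50: float            # log10(uM)
    hill: float
    ci: dict = field(default_factory=dict)
    residual_norm: float = 0.0

    def __post_init__(self):
        if not self.top > self.bottom:
            raise FitConvergenceError("Top must exceed Bottom")
        if not np.isfinite(self.log_ic50):
            raise FitConvergenceError("logIC50 is not finite")

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)

    @property
    def ic50_ci(self) -> tuple:
        lo, hi = self.ci.get("log_ic50", (np.nan, np.nan))
        return (10.0 ** lo, 10.0 ** hi)

    def predict(self, concentrations_um):
        x = np.log10(np.asarray(concentrations_um, float))
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((x - self.log_ic50) * self.hill))


def fit_ic50(concentrations_um, responses, bottom: float | None = None,
             top: float | None = None, free_slope: bool = False) -> DoseResponseFit:
    """Fit the inhibition logistic Y = Bottom + (Top-Bottom)/(1 + 10^(X-logIC50)).

    X = log10(concentration in uM). The Hill slope is fixed at 1 unless
    ``free_slope``. ``bottom``/``top`` pin those asymptotes when given.
    """
    c = np.asarray(concentrations_um, float)
    y = np.asarray(responses, float)
    if (c <= 0).any():
        raise ValueError("concentrations must be positive (log scale)")
    if len(np.unique(c)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    span = np.log10(c.max() / c.min())
    if span < 2.0:
        raise ValueError(f"concentrations span {span:.2f} log units; need >= 2")
    x = np.log10(c)
    slope, _, r, _, _ = stats.linregress(x, y)
    if slope > 0 and r > 0.5:
        raise ValueError("responses increase with concentration; "
                         "not an inhibition curve")

    fixed_b, fixed_t = bottom, top

    def logistic(xv, b, t, logic50, hill):
        return b + (t - b) / (1.0 + 10.0 ** ((xv - logic50) * hill))

    names, p0, lo, hi = [], [], [], []
    if fixed_b is None:
        names.append("bottom"); p0.append(float(y.min())); lo.append(-np.inf); hi.append(np.inf)
    if fixed_t is None:
        names.append("top"); p0.append(float(y.max())); lo.append(-np.inf); hi.append(np.inf)
    names.append("log_ic50")
    half = 0.5 * (y.max() + y.min())
    p0.append(float(x[np.argmin(np.abs(y - half))])); lo.append(x.min() - 3); hi.append(x.max() + 3)
    if free_slope:
        names.append("hill"); p0.append(1.0); lo.append(0.1); hi.append(10.0)

    def wrapped(xv, *params):
        p = dict(zip(names, params))
        return logistic(xv, p.get("bottom", fixed_b), p.get("top", fixed_t),
                        p["log_ic50"], p.get("hill", 1.0))

    try:
        popt, pcov = optimize.curve_fit(wrapped, x, y, p0=p0, bounds=(lo, hi),
                                        maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"IC50 fit failed: {exc}") from exc
    p = dict(zip(names, popt))
    ci = _confidence_intervals(popt, pcov, len(x), names)
    resid = y - wrapped(x, *popt)
    return DoseResponseFit(
        float(p.get("bottom", fixed_b)), float(p.get("top", fixed_t)),
        float(p["log_ic50"]), float(p.get("hill", 1.0)), ci,
        float(np.linalg.norm(resid)))


# ---------------------------------------------------------------------------
# Michaelis-Menten and inhibition mode

@dataclass
class MMFit:
    """v = Vmax * S / (Km + S)."""

    km: float
    vmax: float
    ci: dict = field(default_factory=dict)
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.km <= 0 or self.vmax <= 0:
            raise FitConvergenceError("Km and Vmax must be strictly positive")

    def predict(self, s):
        s = np.asarray(s, float)
        return self.vmax * s / (self.km + s)


def fit_km_vmax(substrate_um, velocity) -> MMFit:
    """Nonlinear least squares on the hyperbola (no linearization)."""
    s = np.asarray(substrate_um, float)
    v = np.asarray(velocity, float)
    if len(np.unique(s)) < 5:
        raise ValueError("need >= 5 distinct substrate concentrations")

    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (float(v.max()), float(np.median(s)))
    try:
        popt, pcov = optimize.curve_fit(mm, s, v, p0=p0,
                                        bounds=([1e-12, 1e-12], np.inf),
                                        maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"Michaelis-Menten fit failed: {exc}") from exc
    vmax, km = popt
    if s.max() < km:
        warnings.warn(f"saturation not approached: max concentration "
                      f"{s.max():.3g} uM < Km estimate {km:.3g} uM")
    ci = _confidence_intervals(popt, pcov, len(s), ("vmax", "km"))
    resid = v - mm(s, *popt)
    return MMFit(float(km), float(vmax), {"km": ci["km"], "vmax": ci["vmax"]},
                 float(np.linalg.norm(resid)))


@dataclass
class InhibitionCall:
    """Competitive / non-competitive / mixed / none classification."""

    verdict: str
    km_ratio: float
    vmax_ratio: float
    threshold: float

    def __post_init__(self):
        if self.verdict not in ("competitive", "non-competitive", "mixed", "none"):
            raise ValueError(f"invalid verdict {self.verdict!r}")


def _ci_overlap(ci_a, ci_b) -> bool:
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]


def classify_inhibition(control: MMFit, treated: MMFit,
                        alpha_ratio: float = 1.5) -> InhibitionCall:
    """Apply the Km-up / Vmax-down hallmarks.

    Km up (ratio >= threshold) with Vmax unchanged (CI overlap) is
    competitive; Vmax down (ratio <= 1/threshold) with Km unchanged is
    non-competitive; both shifts together are mixed; neither is none.
    """
    km_ratio = treated.km / control.km
    vmax_ratio = treated.vmax / control.vmax
    km_up = km_ratio >= alpha_ratio
    vmax_down = vmax_ratio <= 1.0 / alpha_ratio
    km_unchanged = _ci_overlap(treated.ci.get("km", (treated.km, treated.km)),
                               control.ci.get("km", (control.km, control.km)))
    vmax_unchanged = _ci_overlap(treated.ci.get("vmax", (treated.vmax, treated.vmax)),
                                 control.ci.get("vmax", (control.vmax, control.vmax)))
    if km_up and vmax_down:
        verdict = "mixed"
    elif km_up and vmax_unchanged:
        verdict = "competitive"
    elif vmax_down and km_unchanged:
        verdict = "non-competitive"
    else:
        verdict = "none"
    return InhibitionCall(verdict, float(km_ratio), float(vmax_ratio), alpha_ratio)
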