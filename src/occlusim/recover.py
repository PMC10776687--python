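"""Seeded parameter-recovery experiments for the kinetic fits.

Each experiment generates synthetic data from a known ground-truth
constant (the published point estimates are used as generation truths by
the acceptance suite), fits it with the corresponding operation, and
aggregates the recovered values over many seeds.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .kinetics import (FitConvergenceError, fit_flipping_dose_curve, fit_ic50,
                       fit_peak_relaxation, fit_recovery)
from .synthetic import TransportRates, recovery_amplitudes, simulate_patch_clamp

__all__ = ["ic50_recovery", "flipping_rate_recovery", "koff_recovery",
           "kon_recovery"]


def ic50_recovery(truth_um: float, n_seeds: int = 200, seed0: int = 0,
                  n_concentrations: int = 10, n_replicates: int = 3,
                  noise_sd: float = 3.0) -> dict:
    """Simulated uptake-inhibition assays; geometric-mean fitted IC50.

    Concentrations: ``n_concentrations`` half-log steps centred on the
    truth; responses from the unit-slope logistic with Bottom 0 / Top 100
    plus Gaussian noise of ``noise_sd`` response units, in triplicates.
    """
    conc = truth_um * 10.0 ** np.linspace(-2.25, 2.25, n_concentrations)
    c_rep = np.repeat(conc, n_replicates)
    clean = 100.0 / (1.0 + c_rep / truth_um)
    fitted = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        y = clean + rng.normal(0.0, noise_sd, size=c_rep.shape)
        fitted.append(fit_ic50(c_rep, y, bottom=0.0, top=100.0).ic50)
    fitted = np.asarray(fitted)
    return {"value": float(stats.gmean(fitted)), "n": n_seeds,
            "samples": fitted, "truth": truth_um}


def _rates_for(k_flip: float) -> TransportRates:
    # companion constants are irrelevant to the peak-decay shape
    return TransportRates(k_flip=k_flip, K_on=0.05 * k_flip, K_off=0.5,
                          K_off_cumulative=0.1, IC50=1.0)


def flipping_rate_recovery(k_true: float, n_seeds: int = 200, seed0: int = 0,
                           noise_sigma: float = 0.02) -> dict:
    """Simulated 0 mV capacitive peak traces; median fitted relaxation rate."""
    rates = _rates_for(k_true)
    sat = 50.0 * rates.k_flip / rates.K_on   # ~e^-50 from the plateau rate
    fitted = []
    for s in range(n_seeds):
        trace = simulate_patch_clamp(
            rates, {"mode": "peak_0mV", "concentration_um": sat},
            noise_sigma=noise_sigma, seed=seed0 + s)
        try:
            fitted.append(fit_peak_relaxation(trace).k)
        except FitConvergenceError:
            continue
    fitted = np.asarray(fitted)
    return {"value": float(np.median(fitted)), "n": n_seeds,
            "samples": fitted, "truth": k_true}


def koff_recovery(k_off_true: float, wash_times, n_seeds: int = 200,
                  seed0: int = 0, noise_sigma: float = 0.05,
                  mode: str = "peak_recovery") -> dict:
    """Simulated recovery protocols; median fitted (cumulative) K_off."""
    if mode == "peak_recovery":
        rates = TransportRates(100.0, 5.0, k_off_true, 0.1, 1.0)
    else:
        rates = TransportRates(100.0, 5.0, 0.5, k_off_true, 1.0)
    wash_times = np.asarray(wash_times, float)
    fitted = []
    for s in range(n_seeds):
        amps = recovery_amplitudes(rates, wash_times, mode=mode,
                                   noise_sigma=noise_sigma, seed=seed0 + s)
        try:
            fitted.append(fit_recovery(wash_times, amps, mode=mode).k)
        except (FitConvergenceError, ValueError):
            continue
    fitted = np.asarray(fitted)
    return {"value": float(np.median(fitted)), "n": n_seeds,
            "samples": fitted, "truth": k_off_true}


def kon_recovery(k_on_true: float, plateau: float = 104.30, n_seeds: int = 200,
                 seed0: int = 0, noise_fraction: float = 0.03,
                 concentrations=None) -> dict:
    """Simulated dose-dependent flipping-rate curves; median closed-form K_on."""
    K = k_on_true / plateau
    if concentrations is None:
        concentrations = np.array([0.2, 0.5, 1.0, 2.0, 4.0, 8.0]) / K / 4.0
    concentrations = np.asarray(concentrations, float)
    clean = plateau * (1.0 - np.exp(-K * concentrations))
    fitted = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        y = clean * (1.0 + rng.normal(0.0, noise_fraction, size=clean.shape))
        try:
            fitted.append(fit_flipping_dose_curve(concentrations, y).k_on)
        except (FitConvergenceError, ValueError):
            continue
    fitted = np.asarray(fitted)
    return {"value": float(np.median(fitted)), "n": n_seeds,
            "samples": fitted, "truth": k_on_true}
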