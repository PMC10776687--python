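"""Ground-truth-known synthetic world.

Everything measured downstream can be generated here with known answers:
discrete Markov chains (oracles for the MSM estimators), overdamped 2-D
Langevin dynamics on ligand-conditioned two-basin potentials (stand-in for
unbiased trajectories of two-domain occlusion), observable emission (gate
distances, ligand interaction energies, inner-gate distances), and
patch-clamp current traces under peak / steady-state / recovery protocols.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import thermal_energy
from .energy_surface import FreeEnergySurface, from_bin_weights, make_grid
from .io import TIME_COLUMN, validate_feature_table

__all__ = [
    "Well", "PotentialSpec", "LigandProfile", "LatentTrajectory",
    "TransportRates", "CurrentTraceSet",
    "simulate_discrete_chain", "simulate_langevin", "emit_features",
    "make_ligand_ensemble", "simulate_patch_clamp", "recovery_amplitudes",
    "analytic_surface", "default_profile", "DEFAULT_EMISSION_MEANS",
    "REFERENCE_RATES", "LIGAND_NAMES",
]

LIGAND_NAMES = ("apo", "M5HT", "5HT", "P5HT", "B5HT", "COC")


# ---------------------------------------------------------------------------
# potentials

@dataclass(frozen=True)
class Well:
    """Gaussian well: contributes -depth * exp(-sum((x-c)^2 / 2 sigma^2))."""

    center: tuple[float, float]
    depth: float          # kJ/mol, > 0
    width: tuple[float, float]  # sigma per axis, dimensionless

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError(f"well depth must be > 0, got {self.depth}")
        if any(w <= 0 for w in self.width):
            raise ValueError(f"well widths must be > 0, got {self.width}")


@dataclass(frozen=True)
class PotentialSpec:
    """Sum-of-Gaussian-wells potential with harmonic confinement.

    U(x) = -sum_w depth_w exp(-|x-c_w|^2 / 2 sigma_w^2) + confinement |x|^2
    """

    wells: tuple[Well, ...]
    confinement: float = 2.0   # kJ/mol per unit^2
    kt: float = thermal_energy()

    def __post_init__(self):
        if len(self.wells) < 1:
            raise ValueError("need at least one well")
        if self.kt <= 0:
            raise ValueError("kT must be > 0")
        if self.confinement < 0:
            raise ValueError("confinement must be >= 0")

    def energy(self, x) -> np.ndarray:
        """U at positions x (shape (..., 2)), kJ/mol."""
        x = np.asarray(x, dtype=float)
        u = self.confinement * np.sum(x * x, axis=-1)
        for w in self.wells:
            dx = (x[..., 0] - w.center[0]) / w.width[0]
            dy = (x[..., 1] - w.center[1]) / w.width[1]
            u = u - w.depth * np.exp(-0.5 * (dx * dx + dy * dy))
        return u

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = 2.0 * self.confinement * x.copy()
        for w in self.wells:
            dx = x[..., 0] - w.center[0]
            dy = x[..., 1] - w.center[1]
            e = np.exp(-0.5 * ((dx / w.width[0]) ** 2 + (dy / w.width[1]) ** 2))
            g[..., 0] += w.depth * e * dx / w.width[0] ** 2
            g[..., 1] += w.depth * e * dy / w.width[1] ** 2
        return g

    def max_gradient_estimate(self) -> float:
        """Upper-ish bound on |grad U| near the wells (stability check)."""
        r_max = max(math.hypot(*w.center) + 3.0 * max(w.width) for w in self.wells)
        g_conf = 2.0 * self.confinement * r_max
        g_wells = max(w.depth * math.exp(-0.5) / min(w.width) for w in self.wells)
        return g_conf + g_wells

    def min_width(self) -> float:
        return min(min(w.width) for w in self.wells)


# ---------------------------------------------------------------------------
# ligand profiles

#: observable -> (outward-open endpoint, occluded endpoint).
#: Outer-gate distances close (OO > OC), interaction energies strengthen
#: (toward < -20 kJ/mol for substrates), inner-gate distances widen with
#: occlusion. Distances nm, energies kJ/mol. Config-overridable stand-ins:
#: the structure-derived reference values are not fixed by the defaults.
DEFAULT_EMISSION_MEANS: dict[str, tuple[float, float]] = {
    "tm6a_tm9up_nm": (1.75, 1.35),
    "tm1b_tm9up_nm": (1.45, 1.10),
    "e_f335_kjmol": (-5.0, -35.0),
    "e_d98_kjmol": (-8.0, -30.0),
    "d87_f268_nm": (0.80, 1.10),
    "d87_v281_nm": (0.70, 1.00),
    "f268_y289_nm": (1.20, 1.50),
}

DEFAULT_NOISE_SIGMA: dict[str, float] = {
    "tm6a_tm9up_nm": 0.02, "tm1b_tm9up_nm": 0.02,
    "e_f335_kjmol": 1.0, "e_d98_kjmol": 1.0,
    "d87_f268_nm": 0.02, "d87_v281_nm": 0.02, "f268_y289_nm": 0.02,
}

# Relative basin depths (kJ/mol) encoding the qualitative free-energy
# ordering: 5HT favours the occluded basin, P5HT is balanced, B5HT favours
# outward-open, M5HT/COC/apo are essentially outward-open only.
_DEFAULT_DEPTHS: dict[str, tuple[float, float]] = {
    "apo": (12.0, 2.5),
    "M5HT": (14.0, 3.0),
    "5HT": (6.0, 12.0),
    "P5HT": (9.0, 9.0),
    "B5HT": (11.0, 7.0),
    "COC": (14.0, 2.5),
}


@dataclass(frozen=True)
class LigandProfile:
    """Ligand condition: basin depths plus observable emission endpoints."""

    name: str
    oo_depth: float
    oc_depth: float
    oo_center: tuple[float, float] = (-1.0, 0.0)
    oc_center: tuple[float, float] = (1.0, 0.0)
    width: float = 0.35
    confinement: float = 2.0
    kt: float = thermal_energy()
    emission_means: dict = field(default_factory=lambda: dict(DEFAULT_EMISSION_MEANS))
    energy_noise_sigma: float = 1.0
    orth_coupling: float = 0.05  # fast-axis leakage into f268_y289_nm (nm/unit)

    def potential(self) -> PotentialSpec:
        return PotentialSpec(
            wells=(
                Well(self.oo_center, self.oo_depth, (self.width, self.width)),
                Well(self.oc_center, self.oc_depth, (self.width, self.width)),
            ),
            confinement=self.confinement,
            kt=self.kt,
        )

    def occlusion_progress(self, coords) -> np.ndarray:
        """Affine coordinate: 0 at the OO well centre, 1 at the OC centre."""
        coords = np.asarray(coords, dtype=float)
        oo = np.asarray(self.oo_center)
        axis = np.asarray(self.oc_center) - oo
        return (coords - oo) @ axis / float(axis @ axis)


def default_profile(name: str, **overrides) -> LigandProfile:
    """Built-in profile for one of apo, M5HT, 5HT, P5HT, B5HT, COC."""
    try:
        oo, oc = _DEFAULT_DEPTHS[name]
    except KeyError:
        raise KeyError(f"unknown ligand profile {name!r}; known: {LIGAND_NAMES}") from None
    return replace(LigandProfile(name=name, oo_depth=oo, oc_depth=oc), **overrides)


# ---------------------------------------------------------------------------
# discrete chains

def simulate_discrete_chain(transition_matrix, n_steps: int, seed: int,
                            start: int | None = None) -> np.ndarray:
    """Sample a trajectory of state indices from a row-stochastic matrix.

    The stationary distribution of the matrix is used to draw the start
    state when ``start`` is None.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if (T < 0).any():
        raise ValueError("transition matrix entries must be >= 0")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1 within 1e-10")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    k = T.shape[0]
    if start is None:
        evals, evecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
        start = int(rng.choice(k, p=pi))
    cdf = np.cumsum(T, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = start
    s = start
    for i in range(1, n_steps):
        s = int(np.searchsorted(cdf[s], u[i - 1], side="right"))
        out[i] = s
    return out


# ---------------------------------------------------------------------------
# Langevin dynamics

@dataclass
class LatentTrajectory:
    """2-D latent occlusion trajectory (dimensionless coordinates)."""

    coords: np.ndarray   # (T, 2)
    dt: float            # frame spacing, ns
    seed: int
    profile: LigandProfile | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (T, 2), got {self.coords.shape}")
        if len(self.coords) < 2:
            raise ValueError("trajectory must have length >= 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def time_ns(self) -> np.ndarray:
        return np.arange(len(self.coords)) * self.dt


def simulate_langevin(potential: PotentialSpec, n_steps: int, dt: float,
                      diffusion: float, seed: int, x0=None,
                      substeps: int = 1) -> LatentTrajectory:
    """Overdamped Euler-Maruyama integration on ``potential``.

    Emits ``n_steps`` frames spaced ``dt`` ns apart (the first is the start
    position); each frame advance takes ``substeps`` inner steps of
    ``dt/substeps``. Update per inner step of length h:

        x <- x - (D/kT) grad U(x) h + sqrt(2 D h) xi,  xi ~ N(0, I)

    The long-run histogram is proportional to exp(-U/kT) in the small-h
    limit.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0 or diffusion <= 0 or substeps < 1:
        raise ValueError("dt, diffusion must be > 0 and substeps >= 1")
    h = dt / substeps
    drift_scale = h * diffusion * potential.max_gradient_estimate() / potential.kt
    if drift_scale >= potential.min_width():
        warnings.warn(
            f"integration step too coarse: drift per step ~{drift_scale:.3g} "
            f"exceeds narrowest well width {potential.min_width():.3g}; "
            "reduce dt or increase substeps", RuntimeWarning)
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = potential.wells[0].center
    x, y = float(x0[0]), float(x0[1])

    mob = diffusion / potential.kt
    sig = math.sqrt(2.0 * diffusion * h)
    conf2 = 2.0 * potential.confinement
    wells = [(w.center[0], w.center[1],
              w.depth / w.width[0] ** 2, w.depth / w.width[1] ** 2,
              0.5 / w.width[0] ** 2, 0.5 / w.width[1] ** 2)
             for w in potential.wells]

    noise = rng.standard_normal(((n_steps - 1) * substeps, 2)) * sig
    out = np.empty((n_steps, 2))
    out[0] = (x, y)
    idx = 0
    exp = math.exp  # local alias: the loop is the hot path
    for frame in range(1, n_steps):
        for _ in range(substeps):
            gx = conf2 * x
            gy = conf2 * y
            for cx, cy, px, py, ax, ay in wells:
                dx = x - cx
                dy = y - cy
                e = exp(-(ax * dx * dx + ay * dy * dy))
                gx += px * e * dx
                gy += py * e * dy
            x += -mob * gx * h + noise[idx, 0]
            y += -mob * gy * h + noise[idx, 1]
            idx += 1
        if not (math.isfinite(x) and math.isfinite(y)):
            raise RuntimeError(f"non-finite force/position at inner step {idx}")
        out[frame] = (x, y)
    return LatentTrajectory(out, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# observable emission

def emit_features(traj: LatentTrajectory, noise_sigma=None, seed: int = 0,
                  observables=None, profile: LigandProfile | None = None) -> pd.DataFrame:
    """Emit a feature table from a latent trajectory.

    Each observable is an affine map of the occlusion coordinate between
    its OO and OC endpoints plus Gaussian noise; the fast orthogonal axis
    leaks weakly into the TM5 inner-gate distance so that the second
    latent dimension is observable.
    """
    profile = profile or traj.profile
    if profile is None:
        raise ValueError("no ligand profile attached to trajectory or given")
    observables = list(observables) if observables is not None \
        else list(profile.emission_means)
    missing = [o for o in observables if o not in profile.emission_means]
    if missing:
        raise KeyError(f"no emission mean configured for observable(s): {missing}")

    p = profile.occlusion_progress(traj.coords)
    q = traj.coords @ _orth_axis(profile)
    rng = np.random.default_rng(seed)
    sigmas = dict(DEFAULT_NOISE_SIGMA)
    if noise_sigma is not None:
        if np.isscalar(noise_sigma):
            sigmas = {o: float(noise_sigma) for o in observables}
        else:
            sigmas.update(noise_sigma)

    data = {TIME_COLUMN: traj.time_ns}
    for obs in observables:
        oo, oc = profile.emission_means[obs]
        sig = sigmas.get(obs, 0.02 if obs.endswith("_nm") else 1.0)
        values = oo + (oc - oo) * p
        if obs == "e_f335_kjmol":
            sig = max(sig, profile.energy_noise_sigma) if noise_sigma is None else sig
        if obs == "f268_y289_nm":
            values = values + profile.orth_coupling * q
        if sig > 0:
            values = values + rng.normal(0.0, sig, size=len(values))
        data[obs] = values
    return validate_feature_table(pd.DataFrame(data))


def _orth_axis(profile: LigandProfile) -> np.ndarray:
    axis = np.asarray(profile.oc_center) - np.asarray(profile.oo_center)
    axis = axis / np.linalg.norm(axis)
    return np.array([-axis[1], axis[0]])


def make_ligand_ensemble(profile: LigandProfile, n_replicas: int, n_steps: int,
                         seed: int, dt: float = 0.5, substeps: int = 100,
                         diffusion: float = 0.5, noise_sigma=None,
                         observables=None) -> list[pd.DataFrame]:
    """Independent replica feature tables; replica seeds = seed + index."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    pot = profile.potential()
    tables = []
    for r in range(n_replicas):
        traj = simulate_langevin(pot, n_steps, dt=dt, diffusion=diffusion,
                                 seed=seed + r, x0=profile.oo_center,
                                 substeps=substeps)
        traj.profile = profile
        tables.append(emit_features(traj, noise_sigma=noise_sigma,
                                    seed=seed + r, observables=observables))
    return tables


# ---------------------------------------------------------------------------
# patch-clamp protocols

@dataclass(frozen=True)
class TransportRates:
    """Kinetic ground truth driving the synthetic electrophysiology."""

    k_flip: float              # s^-1, saturating peak relaxation rate
    K_on: float                # uM^-1 s^-1
    K_off: float               # s^-1, peak-recovery dissociation rate
    K_off_cumulative: float    # s^-1, steady-state-recovery rate
    IC50: float                # uM
    Km: float = 1.5            # uM
    Vmax: float = 100.0        # response units / min

    def __post_init__(self):
        for name in ("k_flip", "K_on", "K_off", "K_off_cumulative", "IC50", "Km", "Vmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Reported point estimates used as generation ground truth per ligand.
#: The 5HT cumulative off-rate and the Km/Vmax columns are stand-ins (not
#: reported as numbers); all others are the published fits.
REFERENCE_RATES: dict[str, TransportRates] = {
    "M5HT": TransportRates(32.06, 1.2, 3.16, 0.24, 79.35),
    "5HT": TransportRates(104.30, 6.3, 0.55, 0.10, 4.49),
    "P5HT": TransportRates(72.30, 26.1, 0.31, 0.04, 0.59),
    "B5HT": TransportRates(50.05, 20.7, 0.15, 0.03, 0.27),
}

_MODES = ("peak_0mV", "steady_state", "peak_recovery", "steady_recovery")


@dataclass
class CurrentTraceSet:
    """Synthetic patch-clamp trace with its protocol."""

    time: np.ndarray       # s, strictly increasing
    current: np.ndarray
    protocol: dict
    seed: int

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if len(self.time) != len(self.current):
            raise ValueError("time and current lengths differ")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for start, dur in self.protocol.get("pulse_windows", []):
            if start < self.time[0] - 1e-12 or start + dur > self.time[-1] + 1e-12:
                raise ValueError(f"pulse window ({start}, {dur}) outside trace span")


def observed_rate(rates: TransportRates, concentration_um: float) -> float:
    """Dose-dependent relaxation rate: Plateau*(1-exp(-K*c)), Y0 = 0.

    K is chosen so that the initial slope (the association rate constant)
    equals ``rates.K_on``: dY/dc at 0 = Plateau*K = K_on.
    """
    K = rates.K_on / rates.k_flip
    return rates.k_flip * (1.0 - math.exp(-K * concentration_um))


def recovery_amplitudes(rates: TransportRates, wash_times, mode: str = "peak_recovery",
                        noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Fractional recovered amplitudes 1-exp(-K_off*t) at the wash times."""
    if mode not in ("peak_recovery", "steady_recovery"):
        raise ValueError(f"mode must be a recovery mode, got {mode!r}")
    k = rates.K_off if mode == "peak_recovery" else rates.K_off_cumulative
    t = np.asarray(wash_times, dtype=float)
    amp = 1.0 - np.exp(-k * t)
    if noise_sigma > 0:
        amp = amp + np.random.default_rng(seed).normal(0.0, noise_sigma, size=t.shape)
    return amp


def simulate_patch_clamp(rates: TransportRates, protocol: dict,
                         noise_sigma: float = 0.0, seed: int = 0) -> CurrentTraceSet:
    """Generate a current trace for one of the four protocol modes.

    protocol keys: ``mode`` (required), ``concentration_um`` (required),
    ``compound``, ``duration_s``, ``sample_rate_hz``, ``amplitude``,
    ``ec50_um``, ``i_ss``, ``wash_intervals_s``, ``pulse_s``.
    ``noise_sigma`` is the Gaussian noise SD as a fraction of the
    reference amplitude.
    """
    mode = protocol.get("mode")
    if mode not in _MODES:
        raise ValueError(f"invalid protocol mode {mode!r}; valid: {_MODES}")
    c = float(protocol.get("concentration_um", 0.0))
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    rng = np.random.default_rng(seed)
    fs = float(protocol.get("sample_rate_hz", 2000.0))
    a_max = float(protocol.get("amplitude", 1.0))
    ec50 = float(protocol.get("ec50_um", rates.k_flip / rates.K_on))
    k_obs = observed_rate(rates, c)
    amp = a_max * c / (c + ec50) if c > 0 else 0.0

    if mode in ("peak_0mV", "steady_state"):
        dur = float(protocol.get("duration_s", 8.0 / max(k_obs, 1e-6) if c > 0 else 0.1))
        t = np.arange(0.0, dur, 1.0 / fs)
        if c == 0.0:
            i = np.zeros_like(t)
        else:
            i = amp * np.exp(-k_obs * t)
            if mode == "steady_state":
                i_ss = float(protocol.get("i_ss", 0.3 * a_max)) * c / (c + ec50)
                i = i + i_ss * (1.0 - np.exp(-k_obs * t))
        pulses = [(0.0, t[-1] if len(t) else 0.0)]
    else:
        washes = list(protocol.get("wash_intervals_s", [0.5, 1.0, 2.0, 4.0, 8.0]))
        pulse = float(protocol.get("pulse_s", 1.0))
        k_off = rates.K_off if mode == "peak_recovery" else rates.K_off_cumulative
        k_dec = k_obs if c > 0 else rates.k_flip
        segs_t, segs_i, pulses = [], [], []
        t0 = 0.0
        fractions = [1.0] + [1.0 - math.exp(-k_off * w) for w in washes]
        gaps = [0.0] + washes
        for frac, gap in zip(fractions, gaps):
            t0 += gap
            ts = np.arange(0.0, pulse, 1.0 / fs)
            segs_t.append(t0 + ts)
            segs_i.append(amp * frac * np.exp(-k_dec * ts))
            pulses.append((t0, float(ts[-1]) if len(ts) else 0.0))
            t0 += pulse
        t = np.concatenate(segs_t)
        i = np.concatenate(segs_i)
    if noise_sigma > 0 and amp > 0:
        i = i + rng.normal(0.0, noise_sigma * amp, size=i.shape)
    proto = dict(protocol)
    proto.setdefault("compound", "unknown")
    proto["mode"] = mode
    proto["concentration_um"] = c
    proto["pulse_windows"] = pulses
    return CurrentTraceSet(t, i, proto, seed)


# ---------------------------------------------------------------------------
# analytic (Boltzmann-inversion) oracle

def analytic_surface(potential: PotentialSpec, grid=None, bins: int = 50,
                     integrate: bool = False, subdivisions: int = 8) -> FreeEnergySurface:
    """Exact free-energy surface of a potential on a bin grid.

    With ``integrate=False`` (default) G(bin) = U(bin centre) shifted to a
    0 minimum — exact in the narrow-bin limit. With ``integrate=True`` the
    Boltzmann weight is integrated over each bin on a subdivided quadrature
    grid, matching what an equilibrium histogram measures.
    """
    if grid is None:
        cs = np.array([w.center for w in potential.wells])
        ws = np.array([max(w.width) for w in potential.wells])
        lo = (cs - 3.0 * ws[:, None]).min(axis=0)
        hi = (cs + 3.0 * ws[:, None]).max(axis=0)
        grid = make_grid((lo[0], hi[0]), (lo[1], hi[1]), bins)
    x_edges, y_edges = np.asarray(grid[0], float), np.asarray(grid[1], float)
    for w in potential.wells:
        for c, s, edges in ((w.center[0], w.width[0], x_edges),
                            (w.center[1], w.width[1], y_edges)):
            if c - 3 * s < edges[0] - 1e-9 or c + 3 * s > edges[-1] + 1e-9:
                raise ValueError("grid does not cover all well centres +- 3 sigma")
    if integrate:
        n = subdivisions
        fx = np.concatenate([np.linspace(x_edges[i], x_edges[i + 1], n, endpoint=False)
                             + 0.5 * (x_edges[i + 1] - x_edges[i]) / n
                             for i in range(len(x_edges) - 1)])
        fy = np.concatenate([np.linspace(y_edges[j], y_edges[j + 1], n, endpoint=False)
                             + 0.5 * (y_edges[j + 1] - y_edges[j]) / n
                             for j in range(len(y_edges) - 1)])
        xx, yy = np.meshgrid(fx, fy, indexing="ij")
        u = potential.energy(np.stack([xx, yy], axis=-1))
        w = np.exp(-(u - u.min()) / potential.kt)
        wb = w.reshape(len(x_edges) - 1, n, len(y_edges) - 1, n).sum(axis=(1, 3))
        return from_bin_weights(wb / wb.sum(), x_edges, y_edges, potential.kt,
                                meta={"integrate": True})
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    g = potential.energy(np.stack([xx, yy], axis=-1))
    g = g - g.min()
    return FreeEnergySurface(x_edges, y_edges, g,
                             np.zeros_like(g, dtype=bool), potential.kt,
                             meta={"integrate": False})
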