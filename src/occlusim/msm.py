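"""tICA -> microstates -> reversible MSM -> free-energy surface, with validation.

The chain: reduce feature trajectories with time-lagged independent
component analysis, discretise the leading independent components with
k-means, estimate a reversible maximum-likelihood Markov state model on
the largest strongly connected count set, and Boltzmann-invert the
stationary distribution onto a 2-D bin grid. Validation: implied
timescales across lags, the Chapman-Kolmogorov test, and trajectory
bootstrap of the surface.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from . import KB_KJ_PER_MOL_K
from .energy_surface import FreeEnergySurface, from_bin_weights, make_grid
from .io import TIME_COLUMN, frame_spacing_ns

__all__ = [
    "TICAModel", "Discretization", "MSMModel", "ITSCurve", "CKResult",
    "fit_tica", "discretize", "estimate_msm", "count_matrix",
    "implied_timescales", "ck_test", "free_energy_surface", "bootstrap_surface",
]


# ---------------------------------------------------------------------------
# tICA

@dataclass
class TICAModel:
    """Generalized eigendecomposition of symmetrized time-lagged covariances."""

    lag_ns: float
    lag_steps: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray    # descending, real
    components: np.ndarray    # (d, k); columns normalized to unit C0-variance
    columns: list[str] | None = None

    def __post_init__(self):
        if (self.eigenvalues > 1.0 + 1e-6).any():
            raise ValueError("tICA eigenvalues exceed 1 + 1e-6")

    def transform(self, data, dim: int | None = None) -> np.ndarray:
        """Project frames onto the leading ``dim`` independent components."""
        X = _as_matrix(data, self.columns)
        comps = self.components if dim is None else self.components[:, :dim]
        return (X - self.mean) @ comps

    def hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.mean, self.eigenvalues, self.components):
            h.update(np.round(a, 12).tobytes())
        h.update(str(self.lag_steps).encode())
        return h.hexdigest()[:16]


def _as_matrix(data, columns=None) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        cols = columns if columns is not None else \
            [c for c in data.columns if c != TIME_COLUMN]
        return data[cols].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(data, dtype=float))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


def fit_tica(tables, lag_ns: float = 5.0, columns=None, ridge: float = 1e-10) -> TICAModel:
    """Fit tICA on a list of feature tables (or plain (n, d) arrays).

    Covariances are symmetrized; lagged pairs never straddle trajectory
    boundaries. The instantaneous covariance gets a small ridge before the
    generalized eigenproblem C(tau) v = lambda C(0) v.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no input trajectories")
    if isinstance(tables[0], pd.DataFrame):
        dt = frame_spacing_ns(tables[0])
        lag_steps = int(round(lag_ns / dt))
        if abs(lag_steps * dt - lag_ns) > 1e-9 * max(1.0, lag_ns):
            raise ValueError(f"lag {lag_ns} ns is not a multiple of the frame "
                             f"spacing {dt} ns")
        if columns is None:
            columns = [c for c in tables[0].columns if c != TIME_COLUMN]
    else:
        lag_steps = int(round(lag_ns))
    if lag_steps < 1:
        raise ValueError("lag must be at least one frame")

    mats = []
    for i, t in enumerate(tables):
        X = _as_matrix(t, columns)
        if X.shape[0] <= lag_steps:
            warnings.warn(f"trajectory {i} shorter than the lag; skipped")
            continue
        mats.append(X)
    if not mats:
        raise ValueError("all trajectories are shorter than the lag")

    d = mats[0].shape[1]
    n_pairs = 0
    s = np.zeros(d)
    for X in mats:
        s += X[:-lag_steps].sum(axis=0) + X[lag_steps:].sum(axis=0)
        n_pairs += X.shape[0] - lag_steps
    mean = s / (2 * n_pairs)

    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    for X in mats:
        a = X[:-lag_steps] - mean
        b = X[lag_steps:] - mean
        c0 += a.T @ a + b.T @ b
        ctau += a.T @ b + b.T @ a
    c0 /= 2 * n_pairs
    ctau /= 2 * n_pairs
    c0_reg = c0 + (ridge * np.trace(c0) / d) * np.eye(d)

    from scipy.linalg import eigh
    evals, evecs = eigh(ctau, c0_reg)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    return TICAModel(lag_ns, lag_steps, mean, c0, ctau, evals, evecs,
                     list(columns) if columns is not None else None)


# ---------------------------------------------------------------------------
# discretization

@dataclass
class Discretization:
    """k-means microstates over the retained IC coordinates."""

    centers: np.ndarray        # (k, dim)
    dtrajs: list[np.ndarray]   # per-trajectory 0-based state indices
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.centers)

    def assign(self, Y: np.ndarray) -> np.ndarray:
        d2 = ((np.asarray(Y, float)[:, None, :] - self.centers[None]) ** 2).sum(-1)
        return d2.argmin(axis=1)


def discretize(projections, k: int = 500, seed: int = 0,
               fit_subsample: int | None = 200_000) -> Discretization:
    """k-means++ clustering of pooled IC projections (deterministic per seed).

    When the pooled data exceeds ``fit_subsample`` frames, the centres are
    fitted on an equally spaced subsample and every frame is then assigned
    to its nearest centre (identical partitioning rule, much cheaper).
    """
    trajs = [np.atleast_2d(np.asarray(p, float)) for p in (
        projections if isinstance(projections, (list, tuple)) else [projections])]
    trajs = [p.T if p.shape[0] == 1 and p.size > p.shape[0] else p for p in trajs]
    pooled = np.vstack(trajs)
    if k > pooled.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of frames ({pooled.shape[0]})")
    fit_data = pooled
    if fit_subsample is not None and pooled.shape[0] > fit_subsample >= k:
        idx = np.round(np.linspace(0, pooled.shape[0] - 1, fit_subsample)).astype(int)
        fit_data = pooled[idx]
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                tol=1e-6, random_state=seed, algorithm="lloyd").fit(fit_data)
    labels = km.predict(pooled)
    inertia = float(((pooled - km.cluster_centers_[labels]) ** 2).sum())
    dtrajs, at = [], 0
    for p in trajs:
        dtrajs.append(labels[at:at + len(p)].astype(np.int64))
        at += len(p)
    return Discretization(km.cluster_centers_, dtrajs, inertia, seed)


# ---------------------------------------------------------------------------
# MSM estimation

def count_matrix(dtrajs, lag: int, n_states: int | None = None,
                 sliding: bool = True) -> np.ndarray:
    """Transition count matrix at an integer lag (sliding-window by default)."""
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) + 1) for d in dtrajs if len(d)) if dtrajs else 0
    C = np.zeros((n_states, n_states))
    step = 1 if sliding else lag
    for d in dtrajs:
        if len(d) <= lag:
            continue
        i = d[:-lag:step]
        j = d[lag::step]
        np.add.at(C, (i, j), 1.0)
    return C


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    present = (C.sum(axis=0) + C.sum(axis=1)) > 0
    n, labels = connected_components(csr_matrix(C > 0), directed=True,
                                     connection="strong")
    best, best_key = None, (-1, -1.0)
    for comp in range(n):
        members = np.where((labels == comp) & present)[0]
        if len(members) == 0:
            continue
        weight = C[np.ix_(members, members)].sum()
        key = (len(members), weight)
        if key > best_key:
            best, best_key = members, key
    if best is None or len(best) < 2:
        raise ValueError("no strongly connected set with >= 2 states")
    return best


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 100000):
    """Standard self-consistent reversible MLE on (C + C^T) statistics."""
    c_i = C.sum(axis=1)
    X = C + C.T
    X /= X.sum()
    T_prev = None
    for _ in range(max_iter):
        x_i = X.sum(axis=1)
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.where(denom > 0, (C + C.T) / denom, 0.0)
        x_i = X.sum(axis=1)
        T = X / x_i[:, None]
        if T_prev is not None and np.abs(T - T_prev).max() < tol:
            break
        T_prev = T
    pi = x_i / x_i.sum()
    return T, pi


@dataclass
class MSMModel:
    """Row-stochastic transition matrix at lag tau with stationary weights."""

    lag_ns: float
    dt_ns: float
    counts: np.ndarray         # full-state count matrix
    active_set: np.ndarray     # original state indices of the active set
    transition_matrix: np.ndarray
    stationary: np.ndarray
    reversible: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        T, pi = self.transition_matrix, self.stationary
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        if (pi < -1e-12).any() or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("stationary distribution must be a probability vector")
        if np.abs(pi @ T - pi).max() > 1e-8:
            raise ValueError("stationary distribution does not satisfy pi T = pi")
        if self.reversible:
            flux = pi[:, None] * T
            if np.abs(flux - flux.T).max() > 1e-8:
                raise ValueError("detailed balance violated beyond 1e-8")

    @property
    def lag_steps(self) -> int:
        return int(round(self.lag_ns / self.dt_ns))

    @property
    def n_states(self) -> int:
        return len(self.active_set)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        ev = np.linalg.eigvals(self.transition_matrix)
        ev = np.real(ev) if self.reversible else ev
        ev = ev[np.argsort(-np.abs(ev))]
        return ev[:k] if k else ev

    def right_eigenvectors(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        ev, vec = np.linalg.eig(self.transition_matrix)
        order = np.argsort(-np.real(ev))
        return np.real(ev[order[:k]]), np.real(vec[:, order[:k]])

    def timescales(self, n: int = 5) -> np.ndarray:
        """Implied timescales -tau/ln(lambda_i), i >= 2; masked where undefined."""
        ev = np.real(self.eigenvalues(n + 1))[1:]
        out = np.full(len(ev), np.nan)
        ok = (ev > 0) & (ev < 1)
        out[ok] = -self.lag_ns / np.log(ev[ok])
        return out


def estimate_msm(dtrajs, lag_ns: float = 25.0, dt_ns: float = 1.0,
                 reversible: bool = True, count_mode: str = "sliding") -> MSMModel:
    """Estimate an MSM at lag ``lag_ns`` from discrete trajectories.

    The lag must be an integer multiple of the frame spacing ``dt_ns``.
    Counting is sliding-window; the estimate is restricted to the largest
    strongly connected set of the count graph. The reversible estimator is
    the standard self-consistent maximum-likelihood iteration; the
    non-reversible option row-normalizes the counts.
    """
    ratio = lag_ns / dt_ns
    lag = int(round(ratio))
    if abs(ratio - lag) > 1e-9 or lag < 1:
        raise ValueError(f"lag {lag_ns} ns is not a positive multiple of the "
                         f"frame spacing {dt_ns} ns")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    C = count_matrix(dtrajs, lag, sliding=(count_mode == "sliding"))
    active = _largest_connected_set(C)
    dropped = sorted(set(range(C.shape[0])) - set(active.tolist()))
    dropped = [s for s in dropped if C[s].sum() + C[:, s].sum() > 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} disconnected state(s): "
                      f"{dropped[:20]}{'...' if len(dropped) > 20 else ''}")
    Ca = C[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
        ev, vec = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(ev - 1.0)))
        pi = np.abs(np.real(vec[:, i]))
        pi /= pi.sum()
    return MSMModel(lag_ns, dt_ns, C, active, T, pi, reversible,
                    meta={"count_mode": count_mode})


# ---------------------------------------------------------------------------
# validation

@dataclass
class ITSCurve:
    lags_ns: np.ndarray
    timescales: np.ndarray      # (n_lags, n_timescales); NaN where undefined
    lower: np.ndarray | None = None   # bootstrap bands, same shape
    upper: np.ndarray | None = None


def implied_timescales(dtrajs, lags, n_timescales: int = 2, dt_ns: float = 1.0,
                       reversible: bool = True, n_boot: int = 0,
                       seed: int = 0) -> ITSCurve:
    """Implied timescales t_i(tau) = -tau/ln lambda_i(tau) across lags (ns).

    Non-positive (or unit) eigenvalues are reported as NaN, not clamped.
    Optional trajectory bootstrap produces 2.5/97.5 percentile bands.
    """
    lags = np.asarray(lags, dtype=float)
    out = np.full((len(lags), n_timescales), np.nan)
    for a, lag in enumerate(lags):
        m = estimate_msm(dtrajs, lag_ns=lag, dt_ns=dt_ns, reversible=reversible)
        ts = m.timescales(n_timescales)
        out[a, :len(ts)] = ts
    lower = upper = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.full((n_boot, len(lags), n_timescales), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, len(dtrajs), size=len(dtrajs))
            sample = [dtrajs[i] for i in idx]
            for a, lag in enumerate(lags):
                try:
                    m = estimate_msm(sample, lag_ns=lag, dt_ns=dt_ns,
                                     reversible=reversible)
                    boots[b, a, :] = m.timescales(n_timescales)
                except ValueError:
                    pass
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lower = np.nanpercentile(boots, 2.5, axis=0)
            upper = np.nanpercentile(boots, 97.5, axis=0)
    return ITSCurve(lags, out, lower, upper)


@dataclass
class CKResult:
    """Chapman-Kolmogorov comparison on macrostate self-transitions."""

    factors: np.ndarray
    predicted: np.ndarray      # (n_macrostates, n_factors): [T(tau)^k]_mm
    estimated: np.ndarray      # [T(k tau)]_mm re-estimated from data
    estimated_sd: np.ndarray   # bootstrap SD of the estimate
    macrostates: list          # list of arrays of original state indices

    def passes(self, n_sd: float = 2.0, min_sd: float = 0.01) -> bool:
        sd = np.maximum(self.estimated_sd, min_sd)
        ok = np.abs(self.predicted - self.estimated) <= n_sd * sd
        return bool(ok[np.isfinite(self.estimated)].all())


def _macrostate_sets(model: MSMModel, n_macrostates: int) -> list[np.ndarray]:
    """Macrostates from the sign structure of successive right eigenvectors."""
    if n_macrostates < 2:
        raise ValueError("need >= 2 macrostates")
    n_vec = int(np.ceil(np.log2(n_macrostates))) + 1
    _, vecs = model.right_eigenvectors(n_vec)
    signs = vecs[:, 1:] >= 0
    patterns = [tuple(row) for row in signs]
    uniq = sorted(set(patterns))
    groups = {p: i for i, p in enumerate(uniq[:n_macrostates])}
    # states whose pattern is beyond the first n groups join the nearest group
    sets: list[list[int]] = [[] for _ in range(min(n_macrostates, len(uniq)))]
    for state, p in enumerate(patterns):
        g = groups.get(p, 0)
        sets[g].append(state)
    return [model.active_set[np.asarray(s, dtype=int)] for s in sets if s]


def _macro_self_transition(T: np.ndarray, pi: np.ndarray, active: np.ndarray,
                           members: np.ndarray) -> float:
    pos = {s: i for i, s in enumerate(active.tolist())}
    rows = [pos[s] for s in members.tolist() if s in pos]
    if not rows:
        return np.nan
    rows = np.asarray(rows)
    w = pi[rows]
    return float((w @ T[np.ix_(rows, rows)].sum(axis=1)) / w.sum())


def ck_test(model: MSMModel, dtrajs, n_macrostates: int = 2,
            factors=(1, 2, 3, 4, 5), n_boot: int = 20, seed: int = 0) -> CKResult:
    """Compare [T(tau)^k] vs re-estimated [T(k tau)] on macrostate self-transitions."""
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    sets = _macrostate_sets(model, n_macrostates)
    longest = max(len(d) for d in dtrajs)
    kept = []
    for k in factors:
        if k * model.lag_steps < longest:
            kept.append(int(k))
        else:
            warnings.warn(f"factor {k}: lag {k * model.lag_ns} ns exceeds the "
                          "trajectory length; dropped")
    factors = np.asarray(kept)
    n_m = len(sets)
    predicted = np.full((n_m, len(factors)), np.nan)
    estimated = np.full((n_m, len(factors)), np.nan)
    est_sd = np.full((n_m, len(factors)), np.nan)
    rng = np.random.default_rng(seed)

    for j, k in enumerate(factors):
        Tk = np.linalg.matrix_power(model.transition_matrix, k)
        for m, members in enumerate(sets):
            predicted[m, j] = _macro_self_transition(
                Tk, model.stationary, model.active_set, members)
        try:
            mk = estimate_msm(dtrajs, lag_ns=k * model.lag_ns, dt_ns=model.dt_ns,
                              reversible=model.reversible)
        except ValueError:
            continue
        for m, members in enumerate(sets):
            estimated[m, j] = _macro_self_transition(
                mk.transition_matrix, mk.stationary, mk.active_set, members)
        boots = np.full((n_boot, n_m), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, len(dtrajs), size=len(dtrajs))
            try:
                mb = estimate_msm([dtrajs[i] for i in idx],
                                  lag_ns=k * model.lag_ns, dt_ns=model.dt_ns,
                                  reversible=model.reversible)
            except ValueError:
                continue
            for m, members in enumerate(sets):
                boots[b, m] = _macro_self_transition(
                    mb.transition_matrix, mb.stationary, mb.active_set, members)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est_sd[:, j] = np.nanstd(boots, axis=0)
    return CKResult(factors, predicted, estimated, est_sd,
                    [np.asarray(s) for s in sets])


# ---------------------------------------------------------------------------
# free-energy surfaces

def free_energy_surface(model: MSMModel, disc: Discretization, grid=None,
                        temperature_k: float = 310.0, bins: int = 50,
                        pad_fraction: float = 0.05, weighting: str = "centers",
                        projections=None) -> FreeEnergySurface:
    """Boltzmann-invert the MSM stationary weights onto a 2-D bin grid.

    ``weighting="centers"`` (default): each bin's weight is the sum of the
    stationary weights of the microstates whose centres fall in it;
    G = -kB T ln(weight), min-shifted; empty bins masked. This is exact in
    the many-microstates-per-bin limit but quantizes when microstate cells
    are comparable to the bin size.

    ``weighting="frames"``: each microstate's stationary weight is spread
    uniformly over its member frames (requires ``projections``, the IC
    coordinates aligned with ``disc.dtrajs``); converges to the same
    surface with far less quantization error at finite k.
    """
    kt = KB_KJ_PER_MOL_K * temperature_k
    centers = disc.centers[model.active_set][:, :2]
    if grid is None:
        grid = make_grid((disc.centers[:, 0].min(), disc.centers[:, 0].max()),
                         (disc.centers[:, 1].min(), disc.centers[:, 1].max()),
                         bins, pad_fraction)
    x_edges, y_edges = np.asarray(grid[0], float), np.asarray(grid[1], float)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    if weighting == "centers":
        ix = np.digitize(centers[:, 0], x_edges) - 1
        iy = np.digitize(centers[:, 1], y_edges) - 1
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        if not inside.all():
            raise ValueError(f"{(~inside).sum()} active microstate centre(s) "
                             "fall outside the bin grid")
        weights = np.zeros((nx, ny))
        np.add.at(weights, (ix, iy), model.stationary)
    elif weighting == "frames":
        if projections is None:
            raise ValueError("frame weighting requires the IC projections")
        pts = np.vstack([np.atleast_2d(np.asarray(p, float)) for p in projections])
        states = np.concatenate([np.asarray(d) for d in disc.dtrajs])
        if len(pts) != len(states):
            raise ValueError("projections do not align with disc.dtrajs")
        pi_full = np.zeros(disc.k)
        pi_full[model.active_set] = model.stationary
        n_frames = np.bincount(states, minlength=disc.k)
        frame_w = np.where(n_frames[states] > 0,
                           pi_full[states] / np.maximum(n_frames[states], 1), 0.0)
        weights, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                       bins=(x_edges, y_edges), weights=frame_w)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return from_bin_weights(weights, x_edges, y_edges, kt,
                            meta={"lag_ns": model.lag_ns, "weighting": weighting,
                                  "temperature_k": temperature_k})


def bootstrap_surface(dtrajs, disc: Discretization, grid, lag_ns: float,
                      dt_ns: float = 1.0, n_boot: int = 100, seed: int = 0,
                      temperature_k: float = 310.0, reversible: bool = True,
                      max_redraws: int = 10) -> dict:
    """Trajectory bootstrap (with replacement) of the free-energy surface.

    tICA and the cluster centres stay fixed (surfaces share a common
    support); only whole trajectories are resampled. Replicates whose
    resample has no connected set are redrawn up to ``max_redraws`` times.
    Returns mean and SD surfaces over replicates; bins unoccupied in a
    replicate do not contribute to its statistics.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if len(dtrajs) < 2:
        raise ValueError("need >= 2 trajectories to bootstrap")
    rng = np.random.default_rng(seed)
    stack = []
    for _ in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, len(dtrajs), size=len(dtrajs))
            try:
                m = estimate_msm([dtrajs[i] for i in idx], lag_ns=lag_ns,
                                 dt_ns=dt_ns, reversible=reversible)
                surf = free_energy_surface(m, disc, grid,
                                           temperature_k=temperature_k)
                break
            except ValueError:
                if attempt == max_redraws - 1:
                    raise ValueError("bootstrap replicate failed after "
                                     f"{max_redraws} redraws")
        g = surf.g.copy()
        g[surf.mask] = np.nan
        stack.append(g)
    stack = np.array(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_g = np.nanmean(stack, axis=0)
        sd_g = np.nanstd(stack, axis=0)
    mask = ~np.isfinite(mean_g)
    kt = KB_KJ_PER_MOL_K * temperature_k
    x_edges, y_edges = np.asarray(grid[0], float), np.asarray(grid[1], float)
    mean_surf = FreeEnergySurface(x_edges, y_edges, mean_g, mask, kt,
                                  meta={"n_boot": n_boot, "kind": "mean"})
    sd_g = np.where(mask, np.nan, sd_g)
    sd_surf = FreeEnergySurface(x_edges, y_edges, sd_g, mask, kt,
                                meta={"n_boot": n_boot, "kind": "sd"})
    return {"mean": mean_surf, "sd": sd_surf, "n_boot": n_boot}
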