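"""Collective-motion analysis: PCA and functional mode analysis (FMA).

PCA operates on pooled, superposed coordinate (or feature) matrices. FMA
extracts the collective mode maximising covariance with a scalar query
series via partial-least-squares iteration; the mode-filtered trajectory
yields per-residue RMSF profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "FMAModel", "RMSFProfile", "fit_pca", "project",
           "fit_fma", "filtered_rmsf", "equally_spaced_indices", "rmsf"]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax takes the lowest index on ties
        if col[i] < 0:
            vectors[:, j] = -col
    return vectors


@dataclass
class PCAModel:
    """Eigendecomposition of the pooled frame covariance."""

    mean: np.ndarray          # (d,)
    components: np.ndarray    # (d, k), orthonormal columns
    eigenvalues: np.ndarray   # (k,), descending, >= 0
    n_frames: int

    def __post_init__(self):
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvector matrix is not orthonormal within 1e-8")

    def hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for a in (self.mean, self.components, self.eigenvalues):
            h.update(np.round(a, 12).tobytes())
        return h.hexdigest()[:16]


def _pool(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return np.asarray(data, float)
    return np.vstack([np.asarray(d, float) for d in data])


def fit_pca(data) -> PCAModel:
    """PCA of pooled frames (single (n, d) array or a list of them)."""
    X = _pool(data)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 frames for PCA, got {X.shape[0]}")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    return PCAModel(mean, evecs, evals, X.shape[0])


def project(data, model: PCAModel, components=None) -> np.ndarray:
    """Centered projections onto the requested components (default: all)."""
    X = _pool(data)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(f"dimension mismatch: data has {X.shape[1]} columns, "
                         f"model expects {model.mean.shape[0]}")
    comps = model.components if components is None else model.components[:, list(components)]
    return (X - model.mean) @ comps


def equally_spaced_indices(n: int, n_out: int) -> np.ndarray:
    """Rounded linear index grid, first and last always included."""
    if n <= n_out:
        return np.arange(n)
    return np.unique(np.round(np.linspace(0, n - 1, n_out)).astype(int))


@dataclass
class FMAModel:
    """Collective mode maximising covariance with a scalar query."""

    mode: np.ndarray               # unit vector, coordinate/feature space
    coefficients: np.ndarray       # regression vector (mode * scale)
    mean_x: np.ndarray
    mean_y: float
    n_components: int
    training_correlation: float
    cv_correlation: float | None   # time-blocked held-out correlation

    def __post_init__(self):
        if not np.isfinite(self.mode).all() or np.linalg.norm(self.mode) == 0:
            raise ValueError("mode vector must be finite and non-zero")
        if abs(self.training_correlation) > 1 + 1e-9:
            raise ValueError("correlation out of range")

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Projection of frames onto the unit mode."""
        return (np.asarray(X, float) - self.mean_x) @ self.mode

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_x) @ self.coefficients + self.mean_y


def _pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """PLS1 (NIPALS) regression vector for centered X, y."""
    Xa, ya = X.copy(), y.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = Xa.T @ t / tt
        q = ya @ t / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        raise ValueError("query has no covariance with the coordinates")
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


def fit_fma(coordinates, query_series, n_components: int = 10,
            n_frames: int = 2000, cross_validate: bool = True) -> FMAModel:
    """Fit the maximally query-correlated collective mode.

    Frames are subsampled to ``n_frames`` equally spaced indices. The
    combined mode is the PLS regression-optimal combination of the
    ``n_components`` most covariant directions. Cross-validation uses a
    time-blocked first-half-train / second-half-test split.
    """
    X = _pool(coordinates)
    y = np.asarray(query_series, float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError(f"query length {len(y)} != frame count {X.shape[0]}")
    idx = equally_spaced_indices(X.shape[0], n_frames)
    X, y = X[idx], y[idx]
    if np.std(y) < 1e-12:
        raise ValueError("query series is constant (zero variance)")

    def _fit(Xt, yt):
        mx, my = Xt.mean(axis=0), yt.mean()
        b = _pls1(Xt - mx, yt - my, n_components)
        return mx, my, b

    mx, my, b = _fit(X, y)
    pred = (X - mx) @ b + my
    r_train = float(np.corrcoef(pred, y)[0, 1])
    r_cv = None
    if cross_validate and len(y) >= 20:
        half = len(y) // 2
        try:
            mx1, my1, b1 = _fit(X[:half], y[:half])
            pred2 = (X[half:] - mx1) @ b1 + my1
            if np.std(pred2) > 1e-12 and np.std(y[half:]) > 1e-12:
                r_cv = float(np.corrcoef(pred2, y[half:])[0, 1])
            else:
                r_cv = 0.0
        except ValueError:
            r_cv = 0.0
    mode = b / np.linalg.norm(b)
    if mode[int(np.argmax(np.abs(mode)))] < 0:
        mode, b = -mode, b  # unit mode sign fixed; coefficients keep fit scale
    return FMAModel(mode, b, mx, my, n_components, r_train, r_cv)


@dataclass
class RMSFProfile:
    residues: np.ndarray
    rmsf: np.ndarray   # nm, >= 0

    def __post_init__(self):
        if (np.asarray(self.rmsf) < 0).any():
            raise ValueError("RMSF values must be >= 0")


def rmsf(coordinates, residue_map) -> RMSFProfile:
    """Per-residue RMSF of a (n_frames, d) coordinate matrix.

    ``residue_map`` assigns a residue id to every coordinate column (for
    xyz layouts each residue appears three times).
    """
    X = _pool(coordinates)
    residue_map = np.asarray(residue_map)
    if len(residue_map) != X.shape[1]:
        raise ValueError("residue_map length must equal coordinate dimension")
    fluct = X - X.mean(axis=0)
    msf_per_coord = (fluct ** 2).mean(axis=0)
    residues = np.unique(residue_map)
    values = np.array([msf_per_coord[residue_map == r].sum() for r in residues])
    return RMSFProfile(residues, np.sqrt(values))


def filtered_rmsf(model: FMAModel, coordinates, residue_map) -> RMSFProfile:
    """RMSF of the mode-filtered trajectory: mean + score * mode."""
    X = _pool(coordinates)
    if X.shape[1] != model.mode.shape[0]:
        raise ValueError("coordinate layout differs from the fitted model")
    s = model.scores(X)
    filtered = model.mean_x + np.outer(s, model.mode)
    return rmsf(filtered, residue_map)
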