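"""Partial least squares discriminant analysis of activity features.

Linear baseline relating the six rehabilitation parameters to end-point
bridging status (1 = union, 0 = nonunion).  Features are z-scored, the
response is centered, and latent variables are extracted with the SIMPLS
algorithm (de Jong 1993), which underlies MATLAB's ``plsregress``.  A
nearest-class-centroid rule in latent-variable score space serves as the
classifier; bootstrap resampling of subjects yields percentile confidence
intervals on the loadings, and stratified k-fold cross-validation yields
the accuracy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PLSDAModel",
    "LoadingCI",
    "LoadingCIList",
    "fit_plsda",
    "cv_accuracy",
    "bootstrap_loadings",
]


class LoadingCIList(list):
    """List of :class:`LoadingCI` carrying the degenerate-resample redraw
    count as ``n_redrawn``."""

    n_redrawn: int = 0


@dataclass
class PLSDAModel:
    n_components: int
    feature_names: list[str]
    x_weights: np.ndarray  # (p, A), projection weights R: T = Xc @ R
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    pct_variance: np.ndarray  # (2, A): row 0 = X%, row 1 = Y%
    r_squared: float
    coef: np.ndarray  # (p,) regression coefficients on z-scored X
    x_mean: np.ndarray = field(repr=False, default=None)
    x_std: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0
    class_centroids: dict[int, np.ndarray] = field(default_factory=dict)
    classifier_rule: str = "nearest class centroid in LV score space"

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return Xc @ self.x_weights

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        """Continuous PLS prediction of the (0/1) response."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return Xc @ self.coef + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        scores = self.transform(X)
        labels = sorted(self.class_centroids)
        cents = np.stack([self.class_centroids[c] for c in labels])
        d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(labels)[np.argmin(d2, axis=1)]


@dataclass(frozen=True)
class LoadingCI:
    feature: str
    lv: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def _simpls(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """SIMPLS for a univariate response.

    Returns (R, P, q, T) with orthonormal-in-columns score matrix T,
    projection weights R (T = Xc R), X loadings P and y loadings q.
    """
    n, p = Xc.shape
    A = min(n_components, p, n - 1)
    s = Xc.T @ yc  # (p,)
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    V = np.zeros((p, A))  # orthonormal basis of X loadings
    for a in range(A):
        r = s.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t)
        if t_norm < 1e-12:
            R, P, q, T, V = R[:, :a], P[:, :a], q[:a], T[:, :a], V[:, :a]
            break
        t /= t_norm
        r /= t_norm
        p_a = Xc.T @ t
        q_a = float(yc @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v_norm = np.linalg.norm(v)
        if v_norm < 1e-12:
            R, P, q, T, V = R[:, :a], P[:, :a], q[:a], T[:, :a], V[:, :a]
            break
        v /= v_norm
        s = s - v * (v @ s)
        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, p_a, q_a, t, v
    return R, P, q, T


def _apply_sign_convention(R, P, q, T):
    """Flip each LV so its largest-|loading| entry is positive."""
    for a in range(P.shape[1]):
        j = int(np.argmax(np.abs(P[:, a])))
        if P[j, a] < 0:
            R[:, a] *= -1
            P[:, a] *= -1
            q[a] *= -1
            T[:, a] *= -1
    return R, P, q, T


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    feature_names: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model of bridging status on z-scored features.

    Raises if ``y`` has a single class or any feature has zero variance
    (the offending feature is named).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class; PLSDA needs both")
    names = feature_names or [f"x{j}" for j in range(p)]
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    zero = np.nonzero(x_std < 1e-12)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance feature(s): {[names[j] for j in zero]}"
        )
    Xc = (X - x_mean) / x_std
    y_mean = float(y.mean())
    yc = y - y_mean

    R, P, q, T = _simpls(Xc, yc, n_components)
    R, P, q, T = _apply_sign_convention(R, P, q, T)

    # T columns are orthonormal, so per-LV explained variance separates.
    ssx = float((Xc**2).sum())
    ssy = float((yc**2).sum())
    pct_x = 100.0 * (P**2).sum(axis=0) / ssx
    pct_y = 100.0 * q**2 / ssy if ssy > 0 else np.zeros_like(q)

    coef = R @ q
    y_hat = Xc @ coef
    ss_res = float(((yc - y_hat) ** 2).sum())
    r_squared = 1.0 - ss_res / ssy if ssy > 0 else 0.0

    scores = Xc @ R
    centroids = {
        int(c): scores[y == c].mean(axis=0) for c in classes
    }
    return PLSDAModel(
        n_components=R.shape[1],
        feature_names=list(names),
        x_weights=R,
        x_loadings=P,
        y_loadings=q,
        scores=scores,
        pct_variance=np.vstack([pct_x, pct_y]),
        r_squared=r_squared,
        coef=coef,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        class_centroids=centroids,
    )


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    n_components: int = 2,
) -> float:
    """Stratified k-fold cross-validated classification accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    n_err = 0
    for train, test in skf.split(X, y):
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold contains a single class")
        model = fit_plsda(X[train], y[train], n_components=n_components)
        pred = model.predict_class(X[test])
        n_err += int((pred != y[test]).sum())
    return 1.0 - n_err / y.size


def bootstrap_loadings(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    n_components: int = 2,
    feature_names: list[str] | None = None,
) -> list[LoadingCI]:
    """Percentile 95% confidence intervals on the LV loadings.

    Subjects are resampled with replacement; each replicate refit is
    sign-aligned (per LV, by the sign of its dot product with the
    full-data loading vector) before percentiles are taken.  Degenerate
    resamples (a single class present) are redrawn; the redraw count is
    recorded on the returned list as ``.n_redrawn``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    full = fit_plsda(X, y, n_components=n_components,
                     feature_names=feature_names)
    p, A = full.x_loadings.shape
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boot = np.full((n_boot, p, A), np.nan)
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size >= 2 and np.all(
                np.std(X[idx], axis=0) > 1e-12
            ):
                break
            n_redrawn += 1
        else:  # pragma: no cover - pathological input
            raise RuntimeError("could not draw a non-degenerate resample")
        m = fit_plsda(X[idx], y[idx], n_components=n_components)
        L = m.x_loadings
        for a in range(min(A, L.shape[1])):
            sign = np.sign(L[:, a] @ full.x_loadings[:, a]) or 1.0
            boot[b, :, a] = sign * L[:, a]
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    out = LoadingCIList()
    for a in range(A):
        for j in range(p):
            out.append(
                LoadingCI(
                    feature=full.feature_names[j],
                    lv=a + 1,
                    lower=float(lo[j, a]),
                    upper=float(hi[j, a]),
                )
            )
    out.n_redrawn = n_redrawn
    return out
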