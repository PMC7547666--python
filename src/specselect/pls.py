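"""Single-response partial least squares (PLS1) regression.

The bilinear PLS model decomposes the centered predictor matrix as
``X = T P' + E`` and relates the response through ``y = T q + f``, which
collapses to the regression form ``y = X b + g`` with coefficient vector
``b``.  Components (latent variables) are extracted by NIPALS with deflation
of ``X`` only; for a single response the NIPALS weight vector is ``X'y`` up
to normalisation, so each component is obtained in one pass without an inner
iteration loop.

The number of components is chosen from a PRESS curve: the predicted
residual error sum of squares over repeated block-stratified Monte Carlo
splits, evaluated for 1..c_max components on identical splits, with the
"elbow" defined as the first component count whose relative improvement
falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import _as_rng, block_stratified_split

__all__ = [
    "FitError",
    "PLSModel",
    "PressCurve",
    "standardize",
    "fit_pls",
    "predict",
    "press_curve",
    "select_components_elbow",
]


class FitError(ValueError):
    """Raised when a PLS fit is infeasible (bad c, degenerate X, ...)."""


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    ``coefficients_B`` lives on the centered (and, if ``x_scale != 1``,
    standardized) predictor scale: predictions are
    ``yhat = ((X - x_mean) / x_scale) @ B + y_mean``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    scores_T: np.ndarray
    x_loadings_P: np.ndarray
    y_loadings_Q: np.ndarray
    weights_W: np.ndarray
    coefficients_B: np.ndarray
    ssr_train: float

    def to_json_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "x_scale": self.x_scale.tolist(),
            "scores_T": self.scores_T.tolist(),
            "x_loadings_P": self.x_loadings_P.tolist(),
            "y_loadings_Q": self.y_loadings_Q.tolist(),
            "weights_W": self.weights_W.tolist(),
            "coefficients_B": self.coefficients_B.tolist(),
            "ssr_train": float(self.ssr_train),
        }


@dataclass
class PressCurve:
    """PRESS per candidate component count (same MC splits for every count)."""

    components: np.ndarray
    press: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=int)
        self.press = np.asarray(self.press, dtype=float)
        if self.components.size != self.press.size or self.components.size == 0:
            raise ValueError("components and press must be equal-length, non-empty")
        if np.any(self.press < 0):
            raise ValueError("press values must be non-negative")


def standardize(X) -> tuple[np.ndarray, np.ndarray]:
    """Center each column and scale it to unit sample standard deviation.

    Returns the transformed matrix and the per-column scale (sample sd,
    ddof=1) used, for back-transformation of coefficients.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least two rows")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise FitError(f"zero-variance column(s) at indices {zero.tolist()}")
    return (X - X.mean(axis=0)) / sd, sd


def _nipals(Xc: np.ndarray, yc: np.ndarray, c: int, allow_early_stop: bool = False):
    """NIPALS extraction of ``c`` components from centered data.

    Returns (W, P, q, T, c_eff).  With ``allow_early_stop`` the extraction
    halts silently once the deflated X (or its covariance with y) is
    numerically exhausted; otherwise that condition raises :class:`FitError`.
    """
    n, p = Xc.shape
    W = np.zeros((p, c))
    P = np.zeros((p, c))
    q = np.zeros(c)
    T = np.zeros((n, c))
    X = Xc.copy()
    ref_w = np.linalg.norm(Xc.T @ yc)
    ref_t = float(np.abs(Xc).max()) or 1.0
    if ref_w == 0:
        # y carries no covariance with X at all: the 0-component model
        if allow_early_stop:
            return W, P, q, T, 0
        # b = 0 is still a valid (if vacuous) answer for any c
        return W, P, q, T, 0
    for a in range(c):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * ref_w:
            if allow_early_stop:
                return W, P, q, T, a
            raise FitError(
                f"X exhausted after {a} components; requested {c} "
                "(rank-deficient or degenerate data)"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= (1e-12 * ref_t) ** 2 * n:
            if allow_early_stop:
                return W, P, q, T, a
            raise FitError(f"degenerate score vector at component {a + 1}")
        p_a = X.T @ t / tt
        q_a = float(yc @ t) / tt
        X -= np.outer(t, p_a)
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T, c


def _nested_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Coefficient vectors for every nested model, column ``a`` = a+1 comps.

    Uses the rotation ``R`` with ``r_a = w_a - sum_{b<a} (p_b'w_a) r_b`` so
    that ``B_c = R[:, :c] q[:c]``.
    """
    p, c = W.shape
    R = np.zeros((p, c))
    for a in range(c):
        r = W[:, a].copy()
        if a:
            r -= R[:, :a] @ (P[:, :a].T @ W[:, a])
        R[:, a] = r
    return np.cumsum(R * q[np.newaxis, :], axis=1)


def fit_pls(X, y, n_components: int, scale: bool = False) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    Parameters
    ----------
    X : array (n, p)
    y : array (n,)
    n_components : int
        Must satisfy ``1 <= c <= min(n - 1, p)``.
    scale : bool
        If true, columns are additionally scaled to unit sample sd
        (zero-variance columns get scale 1 and contribute nothing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise FitError("X must be 2-D")
    n, p = X.shape
    if y.size != n:
        raise FitError(f"y has length {y.size}, expected {n}")
    c = int(n_components)
    if not 1 <= c <= min(n - 1, p):
        raise FitError(
            f"n_components must be in [1, {min(n - 1, p)}] for n={n}, p={p}; got {c}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise FitError("X and y must be finite")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
    else:
        x_scale = np.ones(p)
    Xc = (X - x_mean) / x_scale
    if not np.any(Xc):
        raise FitError("X is constant after centering; nothing to fit")
    yc = y - y_mean
    W, P, q, T, c_eff = _nipals(Xc, yc, c)
    if c_eff < c:
        # only reachable via the zero-covariance early return
        B = np.zeros(p)
    else:
        B = _nested_coefficients(W, P, q)[:, c - 1]
    yhat = Xc @ B + y_mean
    ssr = float(((y - yhat) ** 2).sum())
    return PLSModel(
        n_components=c,
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        scores_T=T,
        x_loadings_P=P,
        y_loadings_Q=q,
        weights_W=W,
        coefficients_B=B,
        ssr_train=ssr,
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict responses: ``yhat = ((X - x_mean)/x_scale) @ B + y_mean``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return ((X - model.x_mean) / model.x_scale) @ model.coefficients_B + model.y_mean


def _fit_nested_for_split(Xcal, ycal, c_max):
    """Center on the calibration subset, return (x_mean, y_mean, B_nested).

    ``B_nested`` has ``c_max`` columns; if the calibration matrix runs out of
    rank earlier, the last attainable coefficient vector is repeated (the
    model cannot improve past the rank).
    """
    x_mean = Xcal.mean(axis=0)
    y_mean = float(ycal.mean())
    W, P, q, T, c_eff = _nipals(Xcal - x_mean, ycal - y_mean, c_max, allow_early_stop=True)
    if c_eff == 0:
        B = np.zeros((Xcal.shape[1], c_max))
    else:
        B = _nested_coefficients(W[:, :c_eff], P[:, :c_eff], q[:c_eff])
        if c_eff < c_max:
            B = np.hstack([B, np.repeat(B[:, -1:], c_max - c_eff, axis=1)])
    return x_mean, y_mean, B


def press_curve(X, y, c_max: int, n_v: int, N: int, seed) -> PressCurve:
    """PRESS for 1..c_max components over N shared block-stratified splits.

    The same N Monte Carlo splits are used for every component count so the
    curve is comparable across counts; the result is deterministic for a
    given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_v < n:
        raise ValueError(f"n_v must be in [1, {n - 1}], got {n_v}")
    c_max = int(c_max)
    if not 1 <= c_max <= min(n - n_v - 1, p):
        raise FitError(
            f"c_max must be in [1, {min(n - n_v - 1, p)}] "
            f"for n={n}, p={p}, n_v={n_v}; got {c_max}"
        )
    rng = _as_rng(seed)
    press = np.zeros(c_max)
    for _ in range(int(N)):
        split = block_stratified_split(y, n_v, rng)
        cal, val = split.calibration, split.validation
        x_mean, y_mean, B = _fit_nested_for_split(X[cal], y[cal], c_max)
        pred = (X[val] - x_mean) @ B + y_mean  # (n_v, c_max)
        press += ((pred - y[val][:, np.newaxis]) ** 2).sum(axis=0)
    return PressCurve(components=np.arange(1, c_max + 1), press=press)


def select_components_elbow(curve: PressCurve, rel_tol: float = 0.02) -> int:
    """Smallest component count where the PRESS curve plateaus.

    Returns the first ``c`` whose relative improvement to ``c+1``,
    ``(PRESS_c - PRESS_{c+1}) / PRESS_c``, is strictly below ``rel_tol``;
    if no such point exists, returns the largest count on the curve.  A zero
    PRESS short-circuits (a perfect model cannot improve).
    """
    press = curve.press
    comps = curve.components
    for i in range(press.size - 1):
        if press[i] == 0:
            return int(comps[i])
        if (press[i] - press[i + 1]) / press[i] < rel_tol:
            return int(comps[i])
    return int(comps[-1])
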