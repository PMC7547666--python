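"""Monte Carlo cross-validation and calibration error metrics.

MCCV repeatedly splits the data into a calibration set of size ``n - n_v``
and a validation set of size ``n_v`` (block-stratified on concentration so
every validation set spans the range), refits the model on each calibration
subset — re-centering included, so no information leaks from the held-out
samples — and pools the validation residuals:

    RMSECV_MC = sqrt( (1 / (N * n_v)) * sum_i sum_j (y_ij - yhat_ij)^2 )

Test-set performance uses RMSEP = sqrt(mean squared residual) and the
percent coefficient of determination R2_test = (1 - SSE/SST) * 100.

The per-iteration coefficient vectors of the refits can be collected for
coefficient-distribution diagnostics (histograms of individual coefficients
reveal how unstable they are under resampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SplitIndices, _as_rng, block_stratified_split
from .pls import FitError, _fit_nested_for_split

__all__ = [
    "MCCVResult",
    "mccv",
    "rmsep",
    "r2_test",
    "coefficient_distribution",
]


@dataclass
class MCCVResult:
    """Per-iteration MCCV errors and the pooled RMSECV.

    ``msec_per_iter`` / ``msev_per_iter`` are mean squared errors on the
    calibration and validation halves of each split; the pooled
    ``rmsecv_mc`` equals ``sqrt(mean(msev_per_iter))`` because every
    iteration holds out the same number of samples.
    """

    N: int
    n_v: int
    msec_per_iter: np.ndarray
    msev_per_iter: np.ndarray
    rmsecv_mc: float
    coefficient_samples: np.ndarray | None = None

    def recompute_rmsecv(self) -> float:
        """Pooled RMSECV recomputed from the stored per-iteration MSEVs."""
        return float(np.sqrt(self.msev_per_iter.mean()))

    def to_json_dict(self) -> dict:
        return {
            "N": int(self.N),
            "n_v": int(self.n_v),
            "msec_per_iter": self.msec_per_iter.tolist(),
            "msev_per_iter": self.msev_per_iter.tolist(),
            "rmsecv_mc": float(self.rmsecv_mc),
        }


def _make_splits(y, n_v: int, N: int, rng) -> list[SplitIndices]:
    return [block_stratified_split(y, n_v, rng) for _ in range(int(N))]


def _mccv_errors(
    X: np.ndarray,
    y: np.ndarray,
    c: int,
    splits: list[SplitIndices],
    scale: bool = False,
    collect: bool = False,
):
    """Refit on each split's calibration half; return (msec, msev, coefs).

    With ``scale`` the calibration subset is standardized per split
    (zero-variance columns get scale 1); collected coefficients are then on
    the standardized scale.
    """
    n, p = X.shape
    msec = np.empty(len(splits))
    msev = np.empty(len(splits))
    coefs = np.empty((len(splits), p)) if collect else None
    for i, split in enumerate(splits):
        cal, val = split.calibration, split.validation
        Xcal, ycal = X[cal], y[cal]
        if scale:
            sd = Xcal.std(axis=0, ddof=1)
            x_scale = np.where(sd > 0, sd, 1.0)
            Xcal = Xcal / x_scale
        x_mean, y_mean, B_nested = _fit_nested_for_split(Xcal, ycal, c)
        B = B_nested[:, -1]
        pred_cal = (Xcal - x_mean) @ B + y_mean
        msec[i] = ((pred_cal - ycal) ** 2).mean()
        Xval = X[val] / x_scale if scale else X[val]
        pred_val = (Xval - x_mean) @ B + y_mean
        msev[i] = ((pred_val - y[val]) ** 2).mean()
        if collect:
            coefs[i] = B
    return msec, msev, coefs


def mccv(
    X,
    y,
    n_components: int,
    n_v: int,
    N: int,
    seed,
    collect_coefficients: bool = False,
    scale: bool = False,
) -> MCCVResult:
    """Monte Carlo cross-validation with ``N`` block-stratified splits.

    The component count is fixed for the whole run (models with
    predetermined wavelengths and latent variables are being validated, not
    re-selected).  Deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_v < n:
        raise ValueError(f"n_v must be in [1, {n - 1}], got {n_v}")
    c = int(n_components)
    if not 1 <= c <= min(n - n_v - 1, p):
        raise FitError(
            f"n_components must be in [1, {min(n - n_v - 1, p)}] "
            f"for n={n}, p={p}, n_v={n_v}; got {c}"
        )
    rng = _as_rng(seed)
    splits = _make_splits(y, n_v, N, rng)
    msec, msev, coefs = _mccv_errors(X, y, c, splits, scale=scale, collect=collect_coefficients)
    return MCCVResult(
        N=int(N),
        n_v=int(n_v),
        msec_per_iter=msec,
        msev_per_iter=msev,
        rmsecv_mc=float(np.sqrt(msev.mean())),
        coefficient_samples=coefs,
    )


def rmsep(y, yhat) -> float:
    """Root mean squared error of prediction on an independent test set."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty test set")
    if y.size != yhat.size:
        raise ValueError("y and yhat must have the same length")
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def r2_test(y, yhat) -> float:
    """Percent coefficient of determination, ``(1 - SSE/SST) * 100``."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2 or y.size != yhat.size:
        raise ValueError("need equal-length vectors with at least 2 entries")
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("R2 undefined for a constant reference vector")
    sse = ((y - yhat) ** 2).sum()
    return float((1.0 - sse / sst) * 100.0)


def coefficient_distribution(
    X, y, n_components: int, n_v: int, N: int, seed, scale: bool = True
) -> np.ndarray:
    """Per-iteration MCCV coefficient vectors (N x p) for histogramming.

    Coefficients default to the standardized-predictor scale, where their
    magnitudes are comparable across wavelengths; set ``scale=False`` for
    raw-scale models.
    """
    result = mccv(
        X, y, n_components, n_v, N, seed, collect_coefficients=True, scale=scale
    )
    return result.coefficient_samples
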