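"""Coefficient-based wavelength selection: the beta method and EUV.

The beta method ranks wavelengths by the magnitude of the PLS regression
coefficients of the *standardized* predictor matrix — scaling each column by
the inverse of its standard deviation prevents low-amplitude, high-variance
channels from masquerading as important.  A quantile threshold on |b'|
produces the selection mask.

Elimination of Uninformative Variables (EUV) additionally accounts for the
resampling uncertainty of each coefficient through the reliability

    c_i = mean(b_i) / sd(b_i)

(the t-statistic for "this coefficient is zero"), with mean and sd taken
over resampled refits.  The cutoff is calibrated by augmenting the spectra
with artificial random columns: any real wavelength whose |c_i| does not
exceed the largest |c| among the artificial columns is deemed uninformative.
By construction the artificial columns themselves are never selected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import SplitIndices, _as_rng
from .validation import _make_splits, _mccv_errors

__all__ = [
    "SelectionResult",
    "beta_importance",
    "euv_reliability",
    "euv_select",
]

METHODS = ("beta", "euv", "ipls", "fs_ipls", "mwpls", "ga", "full")


@dataclass
class SelectionResult:
    """Per-wavelength importance score plus a boolean selection mask.

    One shape for every selector: ``score`` holds the method's importance
    measure (|b'|, |c_i|, P_GA, ...), ``mask`` the selected wavelengths, and
    ``params`` the threshold rule that derived the mask from the score.
    """

    method: str
    score: np.ndarray
    mask: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.score = np.asarray(self.score, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.score.shape != self.mask.shape or self.score.ndim != 1:
            raise ValueError("score and mask must be 1-D and equally long")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "score": self.score.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "params": self.params,
            "n_selected": self.n_selected,
        }

    def save(self, directory, wavenumbers=None, stem: str | None = None) -> None:
        """Write JSON plus two-column (wavenumber, score) and mask TSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or self.method
        with open(directory / f"{stem}_selection.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh)
        axis = (
            np.asarray(wavenumbers, dtype=float)
            if wavenumbers is not None
            else np.arange(self.score.size, dtype=float)
        )
        with open(directory / f"{stem}_score.tsv", "w", encoding="utf-8") as fh:
            fh.write("wavenumber\tscore\n")
            for w, s in zip(axis, self.score):
                fh.write(f"{w:.10g}\t{s:.10g}\n")
        with open(directory / f"{stem}_mask.tsv", "w", encoding="utf-8") as fh:
            fh.write("wavenumber\tselected\n")
            for w, m in zip(axis, self.mask):
                fh.write(f"{w:.10g}\t{int(m)}\n")


def beta_importance(
    X,
    y,
    n_components: int,
    n_v: int = 5,
    N: int = 1,
    seed=0,
    quantile: float = 0.8,
) -> SelectionResult:
    """Standardized-coefficient (beta) wavelength importance.

    With ``N=1`` this is the plain method: one PLS fit on the standardized
    data, score = |b'_i|.  With ``N>1`` the score is the mean |b'| over N
    block-stratified MCCV refits, which stabilises the ranking.  The mask
    keeps scores at or above the ``quantile`` of the score distribution
    (default 0.8, i.e. the top 20 %).

    Zero-variance columns cannot be standardized; they are excluded with a
    warning and receive score 0.
    """
    from .pls import fit_pls  # local import to avoid cycle at module load

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance column(s) from beta scoring"
        )
    Xk = X[:, keep]
    if N == 1:
        model = fit_pls(Xk, y, n_components, scale=True)
        score_k = np.abs(model.coefficients_B)
    else:
        rng = _as_rng(seed)
        splits = _make_splits(y, n_v, N, rng)
        _, _, coefs = _mccv_errors(Xk, y, n_components, splits, scale=True, collect=True)
        score_k = np.abs(coefs).mean(axis=0)
    score = np.zeros(p)
    score[keep] = score_k
    threshold = float(np.quantile(score_k, quantile))
    mask = np.zeros(p, dtype=bool)
    mask[keep] = score_k >= threshold
    return SelectionResult(
        method="beta",
        score=score,
        mask=mask,
        params={
            "n_components": int(n_components),
            "n_v": int(n_v),
            "N": int(N),
            "quantile": float(quantile),
            "threshold": threshold,
        },
    )


def euv_reliability(coef_samples) -> np.ndarray:
    """Reliability ``c_i = mean(b_i) / sd(b_i)`` per coefficient column.

    The sd uses the N-1 denominator (t-statistic analogy).  Columns with
    zero sd get a signed-infinity sentinel so callers can flag them.
    """
    B = np.asarray(coef_samples, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need a (N, p) matrix with N >= 2 coefficient samples")
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.copysign(np.inf, mean))
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            f"zero-sd coefficient column(s) {degenerate.tolist()}: "
            "reliability set to signed infinity"
        )
    return rel


def _loo_splits(n: int) -> list[SplitIndices]:
    full = np.arange(n)
    return [
        SplitIndices(calibration=np.delete(full, i), validation=np.array([i]))
        for i in range(n)
    ]


def euv_select(
    X,
    y,
    n_components: int,
    n_artificial: int | None = None,
    noise_amplitude: float | None = None,
    resampling: str = "loo",
    seed=0,
    n_v: int = 5,
    N: int = 100,
) -> SelectionResult:
    """Elimination of Uninformative Variables with a random-column cutoff.

    The spectra are augmented with ``n_artificial`` uniform-noise columns of
    small amplitude, coefficient reliabilities are estimated over resampled
    refits (leave-one-out by default, or MCCV with ``N`` splits of size
    ``n_v``), and the cutoff is ``max(|c|)`` over the artificial columns.
    Real wavelengths with ``|c_i|`` strictly above the cutoff are selected;
    artificial columns never are.

    Defaults: ``n_artificial = min(p, 300)`` and amplitude
    ``1e-3 * median(|X|)`` — weak enough not to perturb the fit, present in
    every resample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_artificial is None:
        n_artificial = min(p, 300)
    if n_artificial < 1:
        raise ValueError("n_artificial must be >= 1")
    if noise_amplitude is None:
        med = float(np.median(np.abs(X)))
        noise_amplitude = 1e-3 * (med if med > 0 else 1.0)
    if noise_amplitude <= 0:
        raise ValueError("noise_amplitude must be > 0")
    if resampling not in ("loo", "mccv"):
        raise ValueError("resampling must be 'loo' or 'mccv'")
    rng = _as_rng(seed)
    artificial = rng.uniform(0.0, 1.0, size=(n, n_artificial)) * noise_amplitude
    Xa = np.hstack([X, artificial])
    if resampling == "loo":
        splits = _loo_splits(n)
    else:
        splits = _make_splits(y, n_v, N, rng)
    # centered-only refits: the reliability t-ratio is scale-invariant, and
    # autoscaling would inflate the tiny artificial columns to unit variance,
    # letting them perturb the very fit they are meant to leave untouched
    _, _, coefs = _mccv_errors(Xa, y, n_components, splits, scale=False, collect=True)
    rel = euv_reliability(coefs)
    rel_real = np.abs(rel[:p])
    cutoff = float(np.abs(rel[p:]).max())
    mask = rel_real > cutoff
    return SelectionResult(
        method="euv",
        score=rel_real,
        mask=mask,
        params={
            "n_components": int(n_components),
            "n_artificial": int(n_artificial),
            "noise_amplitude": float(noise_amplitude),
            "resampling": resampling,
            "cutoff": cutoff,
        },
    )
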