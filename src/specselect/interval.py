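"""Interval-based wavelength selection: iPLS, forward-selection iPLS, MWPLS.

Interval PLS splits the spectrum into ``k`` equidistant contiguous intervals
and scores each by the Monte Carlo cross-validated RMSECV of a local PLS
model; the forward-selection variant greedily accumulates intervals while
the combined model keeps improving, optionally micro-optimising each
accepted interval by expanding or truncating its edges one wavelength at a
time.  Moving-window PLS slides a fixed-length window across the spectrum
and records the training sum of squared residuals (SSR) for 1..c_max
components at every position: informative windows reach a low SSR with few
components, while windows over noise keep "improving" as components soak up
noise.

All RMSECV evaluations within one call share the same Monte Carlo splits so
intervals are compared on identical resamples and the micro-optimisation
descent is a true hill-climb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coef_select import SelectionResult
from .dataset import SpectraDataset, _as_rng
from .pls import _nipals, _nested_coefficients
from .validation import _make_splits, _mccv_errors

__all__ = [
    "Interval",
    "IntervalReport",
    "MWPLSReport",
    "make_intervals",
    "ipls",
    "fs_ipls",
    "micro_optimize",
    "mwpls",
    "mwpls_select",
]


@dataclass
class Interval:
    """A contiguous index range [start_index, end_index], both inclusive."""

    start_index: int
    end_index: int
    start_wavenumber: float = float("nan")
    end_wavenumber: float = float("nan")

    def __post_init__(self) -> None:
        if self.start_index < 0 or self.end_index < self.start_index:
            raise ValueError(
                f"invalid interval [{self.start_index}, {self.end_index}]"
            )

    @property
    def width(self) -> int:
        return self.end_index - self.start_index + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)

    def with_axis(self, wavenumbers) -> "Interval":
        wn = np.asarray(wavenumbers, dtype=float)
        return Interval(
            self.start_index,
            self.end_index,
            float(wn[self.start_index]),
            float(wn[self.end_index]),
        )


@dataclass
class IntervalReport:
    """Per-interval RMSECVs and (for FS mode) the greedy selection path."""

    intervals: list
    rmsecv_per_interval: np.ndarray
    selected_sequence: list
    rmsecv_trajectory: np.ndarray
    final_mask: np.ndarray
    final_mask_raw: np.ndarray | None = None
    optimized_intervals: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "intervals": [
                [int(iv.start_index), int(iv.end_index)] for iv in self.intervals
            ],
            "rmsecv_per_interval": self.rmsecv_per_interval.tolist(),
            "selected_sequence": [int(i) for i in self.selected_sequence],
            "rmsecv_trajectory": self.rmsecv_trajectory.tolist(),
            "final_mask": np.asarray(self.final_mask, dtype=int).tolist(),
        }


@dataclass
class MWPLSReport:
    """Training SSR curves for every window position and component count."""

    window_length: int
    centers: np.ndarray
    ssr_curves: np.ndarray  # (n_centers, c_max)

    def to_json_dict(self) -> dict:
        return {
            "window_length": int(self.window_length),
            "centers": self.centers.tolist(),
            "ssr_curves": self.ssr_curves.tolist(),
        }


def make_intervals(p: int, k: int, wavenumbers=None) -> list[Interval]:
    """Partition ``0..p-1`` into ``k`` contiguous intervals, larger first.

    Sizes differ by at most one; the first ``p mod k`` intervals carry the
    extra wavelength.
    """
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    base, rem = divmod(p, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    intervals = []
    start = 0
    for size in sizes:
        iv = Interval(start, start + size - 1)
        if wavenumbers is not None:
            iv = iv.with_axis(wavenumbers)
        intervals.append(iv)
        start += size
    return intervals


def _rmsecv_for_columns(X, y, cols, c, splits) -> float:
    """Pooled RMSECV of a PLS model restricted to ``cols`` on fixed splits."""
    cols = np.asarray(cols)
    width = cols.size if cols.dtype != bool else int(cols.sum())
    n_cal = splits[0].calibration.size
    c_eff = min(c, width, n_cal - 1)
    _, msev, _ = _mccv_errors(X[:, cols], y, c_eff, splits)
    return float(np.sqrt(msev.mean()))


def _effective_c(c: int, width: int, n_cal: int, context: str) -> int:
    c_eff = min(c, width, n_cal - 1)
    if c_eff < c:
        warnings.warn(f"{context}: reducing components from {c} to {c_eff}")
    return c_eff


def ipls(
    ds: SpectraDataset, k: int, n_components: int, n_v: int, N: int, seed
) -> IntervalReport:
    """Interval PLS: score each of ``k`` equidistant intervals by RMSECV.

    Every interval is evaluated on the same N block-stratified splits; the
    best interval (lowest RMSECV, ties to the lower start index) forms the
    final mask.
    """
    X, y = ds.absorbance, ds.concentration
    intervals = make_intervals(ds.p, k, ds.wavenumbers)
    rng = _as_rng(seed)
    splits = _make_splits(y, n_v, N, rng)
    n_cal = ds.n - n_v
    rmsecvs = np.empty(len(intervals))
    for j, iv in enumerate(intervals):
        c_eff = _effective_c(n_components, iv.width, n_cal, f"interval {j}")
        _, msev, _ = _mccv_errors(X[:, iv.indices()], y, c_eff, splits)
        rmsecvs[j] = np.sqrt(msev.mean())
    best = int(np.argmin(rmsecvs))  # argmin takes the first minimum: low index wins ties
    mask = np.zeros(ds.p, dtype=bool)
    mask[intervals[best].indices()] = True
    return IntervalReport(
        intervals=intervals,
        rmsecv_per_interval=rmsecvs,
        selected_sequence=[best],
        rmsecv_trajectory=np.array([rmsecvs[best]]),
        final_mask=mask,
    )


def fs_ipls(
    ds: SpectraDataset,
    k: int,
    n_components: int,
    n_v: int,
    N: int,
    seed,
    max_intervals: int = 10,
    rel_improvement: float = 0.005,
    micro: bool = False,
) -> IntervalReport:
    """Forward-selection iPLS: greedily accumulate intervals.

    At each step the interval whose addition minimises the combined-model
    RMSECV is taken; the search stops once the relative improvement drops
    below ``rel_improvement`` (default 0.5 %) or ``max_intervals`` is
    reached.  With ``micro`` each accepted interval is edge-optimised
    (:func:`micro_optimize`) in the context of the already-selected mask;
    both the raw and the optimised masks are reported.
    """
    if max_intervals < 1:
        raise ValueError("max_intervals must be >= 1")
    X, y = ds.absorbance, ds.concentration
    intervals = make_intervals(ds.p, k, ds.wavenumbers)
    rng = _as_rng(seed)
    splits = _make_splits(y, n_v, N, rng)
    n_cal = ds.n - n_v

    rmsecvs = np.empty(len(intervals))
    for j, iv in enumerate(intervals):
        c_eff = _effective_c(n_components, iv.width, n_cal, f"interval {j}")
        _, msev, _ = _mccv_errors(X[:, iv.indices()], y, c_eff, splits)
        rmsecvs[j] = np.sqrt(msev.mean())

    selected: list[int] = []
    optimized: list[Interval] = []
    mask_raw = np.zeros(ds.p, dtype=bool)
    mask_opt = np.zeros(ds.p, dtype=bool)
    trajectory: list[float] = []
    best_so_far = np.inf
    while len(selected) < max_intervals:
        candidate_scores = np.full(len(intervals), np.inf)
        for j, iv in enumerate(intervals):
            if j in selected:
                continue
            trial = mask_opt.copy()
            trial[iv.indices()] = True
            candidate_scores[j] = _rmsecv_for_columns(X, y, trial, n_components, splits)
        j_best = int(np.argmin(candidate_scores))
        score = candidate_scores[j_best]
        if selected:
            if not np.isfinite(score) or (best_so_far - score) / best_so_far < rel_improvement:
                break
        selected.append(j_best)
        mask_raw[intervals[j_best].indices()] = True
        if micro:
            iv_opt = micro_optimize(
                ds,
                intervals[j_best],
                n_components,
                n_v,
                N,
                seed,
                base_mask=mask_opt,
                _splits=splits,
            )
            optimized.append(iv_opt)
            mask_opt[iv_opt.indices()] = True
            score = _rmsecv_for_columns(X, y, mask_opt, n_components, splits)
        else:
            mask_opt[intervals[j_best].indices()] = True
        trajectory.append(float(score))
        best_so_far = min(best_so_far, float(score))
    return IntervalReport(
        intervals=intervals,
        rmsecv_per_interval=rmsecvs,
        selected_sequence=selected,
        rmsecv_trajectory=np.asarray(trajectory),
        final_mask=mask_opt,
        final_mask_raw=mask_raw,
        optimized_intervals=optimized,
    )


def micro_optimize(
    ds: SpectraDataset,
    interval: Interval,
    n_components: int,
    n_v: int,
    N: int,
    seed,
    mode: str = "two_sided",
    base_mask=None,
    _splits=None,
) -> Interval:
    """Hill-climb an interval's edges one wavelength at a time.

    Candidate moves, in order: expand-left, expand-right, truncate-left,
    truncate-right; the first move that lowers the RMSECV (on splits fixed
    by ``seed``) is accepted and the scan restarts, until no move improves.
    ``one_sided`` mode locks onto the edge of the first accepted move.
    Moves never cross the spectrum boundary and never shrink the interval
    below one wavelength.  The returned interval's RMSECV never exceeds the
    input's on the same splits.
    """
    if mode not in ("one_sided", "two_sided"):
        raise ValueError("mode must be 'one_sided' or 'two_sided'")
    X, y = ds.absorbance, ds.concentration
    if _splits is None:
        rng = _as_rng(seed)
        _splits = _make_splits(y, n_v, N, rng)
    base = (
        np.zeros(ds.p, dtype=bool)
        if base_mask is None
        else np.asarray(base_mask, dtype=bool).copy()
    )

    def score_of(lo: int, hi: int) -> float:
        trial = base.copy()
        trial[lo : hi + 1] = True
        return _rmsecv_for_columns(X, y, trial, n_components, _splits)

    lo, hi = interval.start_index, interval.end_index
    current = score_of(lo, hi)
    locked_edge: str | None = None
    while True:
        moves = [
            ("left", lo - 1, hi),   # expand left
            ("right", lo, hi + 1),  # expand right
            ("left", lo + 1, hi),   # truncate left
            ("right", lo, hi - 1),  # truncate right
        ]
        improved = False
        for edge, new_lo, new_hi in moves:
            if locked_edge is not None and edge != locked_edge:
                continue
            if new_lo < 0 or new_hi > ds.p - 1 or new_lo > new_hi:
                continue
            s = score_of(new_lo, new_hi)
            if s < current:
                lo, hi, current = new_lo, new_hi, s
                if mode == "one_sided" and locked_edge is None:
                    locked_edge = edge
                improved = True
                break
        if not improved:
            break
    return Interval(lo, hi).with_axis(ds.wavenumbers)


def mwpls(ds: SpectraDataset, window_length: int = 31, c_max: int = 5) -> MWPLSReport:
    """Moving-window PLS: training SSR per component count at each position.

    The window (odd length, centered) slides one wavelength at a time; at
    each of the ``p - window_length + 1`` positions a PLS model with
    1..c_max components is fitted on the full dataset and the training SSR
    recorded.  Component counts beyond the window's effective rank repeat
    the last attainable SSR.
    """
    if window_length < 1 or window_length > ds.p:
        raise ValueError(f"window_length must be in [1, {ds.p}]")
    if window_length % 2 == 0:
        raise ValueError("window_length must be odd (centered window)")
    c_max = int(c_max)
    if not 1 <= c_max <= min(ds.n - 1, window_length):
        raise ValueError(
            f"c_max must be in [1, {min(ds.n - 1, window_length)}], got {c_max}"
        )
    X, y = ds.absorbance, ds.concentration
    half = window_length // 2
    centers = np.arange(half, ds.p - half)
    yc = y - y.mean()
    ssr = np.empty((centers.size, c_max))
    for i, center in enumerate(centers):
        Xw = X[:, center - half : center + half + 1]
        Xc = Xw - Xw.mean(axis=0)
        W, P, q, T, c_eff = _nipals(Xc, yc, c_max, allow_early_stop=True)
        if c_eff == 0:
            ssr[i] = float(yc @ yc)
            continue
        B = _nested_coefficients(W[:, :c_eff], P[:, :c_eff], q[:c_eff])
        resid = yc[:, np.newaxis] - Xc @ B  # (n, c_eff)
        curve = (resid**2).sum(axis=0)
        if c_eff < c_max:
            curve = np.concatenate([curve, np.repeat(curve[-1], c_max - c_eff)])
        ssr[i] = curve
    return MWPLSReport(window_length=window_length, centers=centers, ssr_curves=ssr)


def mwpls_select(
    report: MWPLSReport, p: int, c_ref: int = 3, fraction: float = 0.5
) -> SelectionResult:
    """Threshold the stored SSR curves into a wavelength mask.

    A window center is informative when its SSR at ``c_ref`` components
    drops below ``fraction`` of the median SSR at ``c_ref`` over all
    windows.  The score is ``median_ssr / ssr`` (larger = better); edge
    wavelengths without a centered window score 0 and are never selected.
    """
    if not 1 <= c_ref <= report.ssr_curves.shape[1]:
        raise ValueError("c_ref outside the stored component range")
    if not 0 < fraction:
        raise ValueError("fraction must be positive")
    ssr_ref = report.ssr_curves[:, c_ref - 1]
    med = float(np.median(ssr_ref))
    score = np.zeros(p)
    mask = np.zeros(p, dtype=bool)
    with np.errstate(divide="ignore"):
        score[report.centers] = np.where(ssr_ref > 0, med / ssr_ref, np.inf)
    mask[report.centers] = ssr_ref < fraction * med
    return SelectionResult(
        method="mwpls",
        score=score,
        mask=mask,
        params={
            "window_length": int(report.window_length),
            "c_ref": int(c_ref),
            "fraction": float(fraction),
            "median_ssr": med,
        },
    )
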