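"""End-to-end comparison of wavelength-selection methods on one dataset.

The workflow mirrors a standard calibration study: hold out a representative
test set first, run each wavelength-selection method on the training
remainder only, choose the latent-variable count for each reduced model from
its PRESS elbow, estimate RMSECV by Monte Carlo cross-validation of the
reduced model, and finally score RMSEP and %R2 on the untouched test set.
The output is one row per method: {method, n_vars, n_LVs, RMSECV, RMSEP,
R2_test}.

By default the MCCV stage resamples the *full* dataset (test samples
included) so that the printed calibration size is ``n - n_v``; set
``mccv_scope="train"`` to confine MCCV to the training samples as well —
selection itself never sees the test set in either mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ga as ga_mod
from .coef_select import SelectionResult, beta_importance, euv_select
from .dataset import SpectraDataset, _as_rng, read_spectra_csv, representative_test_split
from .interval import fs_ipls, ipls, mwpls, mwpls_select
from .pls import fit_pls, predict, press_curve, select_components_elbow
from .validation import _make_splits, _mccv_errors, r2_test, rmsep

__all__ = ["RunConfig", "MethodRow", "run_comparison", "write_report"]

KNOWN_METHODS = ("full", "beta", "euv", "ipls", "fs_ipls", "mwpls", "ga")


@dataclass
class RunConfig:
    """Configuration of one comparison run.

    ``dataset`` is a :class:`SpectraDataset` or a CSV path.  ``methods``
    lists the selectors to compare; ``method_params`` may override each
    method's defaults.  ``n_components="auto"`` picks each reduced model's
    latent-variable count from its PRESS elbow.
    """

    dataset: object
    methods: tuple = KNOWN_METHODS
    test_n: int = 8
    mccv_N: int = 10000
    mccv_n_v: int = 5
    n_components: object = "auto"
    mccv_scope: str = "all"
    seed: int = 0
    selection_n_v: int = 5
    selection_N: int = 50
    press_c_max: int = 10
    press_rel_tol: float = 0.02
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")
        if self.mccv_scope not in ("all", "train"):
            raise ValueError("mccv_scope must be 'all' or 'train'")
        if self.n_components != "auto" and int(self.n_components) < 1:
            raise ValueError("n_components must be 'auto' or a positive integer")
        if self.test_n < 1:
            raise ValueError("test_n must be >= 1")


@dataclass
class MethodRow:
    method: str
    n_vars: int
    n_lvs: int
    rmsecv: float
    rmsep: float
    r2_test: float

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n_vars": self.n_vars,
            "n_LVs": self.n_lvs,
            "RMSECV": round(self.rmsecv, 4),
            "RMSEP": round(self.rmsep, 4),
            "R2_test": round(self.r2_test, 4),
        }


def _elbow_components(X, y, n_v, c_max, rel_tol, seed, N=20) -> int:
    n, p = X.shape
    cm = min(c_max, n - n_v - 1, p)
    curve = press_curve(X, y, cm, n_v=n_v, N=N, seed=seed)
    return select_components_elbow(curve, rel_tol)


def _run_selector(method, train, cfg: RunConfig, c_full, seed, log) -> SelectionResult:
    params = dict(cfg.method_params.get(method, {}))
    n_v = params.pop("n_v", cfg.selection_n_v)
    N_given = params.pop("N", None)
    N = N_given if N_given is not None else cfg.selection_N
    X, y = train.absorbance, train.concentration
    if method == "full":
        return SelectionResult(
            method="full",
            score=np.ones(train.p),
            mask=np.ones(train.p, dtype=bool),
            params={},
        )
    if method == "beta":
        # plain single-fit method unless an explicit refit count is given
        return beta_importance(
            X, y, c_full, n_v=n_v, N=N_given or 1, seed=seed, **params
        )
    if method == "euv":
        return euv_select(X, y, c_full, seed=seed, n_v=n_v, N=N, **params)
    if method == "ipls":
        k = params.pop("k", 20)
        report = ipls(train, k, c_full, n_v, N, seed, **params)
        best = report.selected_sequence[0]
        score = -report.rmsecv_per_interval
        full_score = np.zeros(train.p)
        for iv, s in zip(report.intervals, score):
            full_score[iv.indices()] = s
        return SelectionResult(
            method="ipls",
            score=full_score,
            mask=report.final_mask,
            params={"k": k, "best_interval": int(best)},
        )
    if method == "fs_ipls":
        k = params.pop("k", 20)
        report = fs_ipls(train, k, c_full, n_v, N, seed, **params)
        full_score = np.zeros(train.p)
        for rank, j in enumerate(report.selected_sequence):
            full_score[report.intervals[j].indices()] = len(report.selected_sequence) - rank
        return SelectionResult(
            method="fs_ipls",
            score=full_score,
            mask=report.final_mask,
            params={"k": k, "sequence": [int(j) for j in report.selected_sequence]},
        )
    if method == "mwpls":
        window = params.pop("window_length", 31)
        c_max = params.pop("c_max", max(c_full, 3))
        report = mwpls(train, window, c_max)
        return mwpls_select(report, train.p, **params)
    if method == "ga":
        threshold = params.pop("threshold", 0.6)
        ga_kwargs = {
            "fitness_n_v": n_v,
            "n_components": c_full,
            "seed": int(seed),
        }
        ga_kwargs.update(params)
        ga_cfg = ga_mod.GAConfig(**ga_kwargs)
        ens = ga_mod.ensemble_ga(X, y, ga_cfg)
        if log:
            log(f"[ga] accepted {ens.n_runs_accepted}/{ens.n_runs_total} runs")
        return ga_mod.select_by_probability(ens, threshold)
    raise ValueError(f"unknown method {method!r}")


def _chunked_rmsecv(X, y, c, n_v, N, seed, log, milestone=1000) -> float:
    """Pooled RMSECV over N splits with progress lines every ``milestone``."""
    rng = _as_rng(seed)
    total_sse = 0.0
    done = 0
    while done < N:
        chunk = min(milestone, N - done)
        splits = _make_splits(y, n_v, chunk, rng)
        _, msev, _ = _mccv_errors(X, y, c, splits)
        total_sse += float(msev.sum()) * n_v
        done += chunk
        if log and N > milestone:
            log(f"[mccv] {done}/{N} iterations")
    return float(np.sqrt(total_sse / (N * n_v)))


def run_comparison(cfg: RunConfig, log=None) -> dict:
    """Run the full selection-and-validation comparison.

    Returns a dict with the split indices, per-method selection results and
    the report rows; deterministic for a given ``cfg.seed``.
    """
    ds = cfg.dataset
    if not isinstance(ds, SpectraDataset):
        ds = read_spectra_csv(ds)
    seeds = np.random.SeedSequence(cfg.seed).spawn(3 + len(cfg.methods))
    as_int = lambda s: int(s.generate_state(1)[0] % 2**31)

    test_split = representative_test_split(ds, cfg.test_n, as_int(seeds[0]))
    train = ds.subset(test_split.calibration)
    test = ds.subset(test_split.validation)
    if log:
        log(f"[split] training n={train.n}, test n={test.n}")

    c_full = _elbow_components(
        train.absorbance,
        train.concentration,
        cfg.selection_n_v,
        cfg.press_c_max,
        cfg.press_rel_tol,
        as_int(seeds[1]),
    )
    if log:
        log(f"[components] full-model PRESS elbow: {c_full} LV(s)")

    rows: list[MethodRow] = []
    selections: dict[str, SelectionResult] = {}
    for i, method in enumerate(cfg.methods):
        sel = _run_selector(method, train, cfg, c_full, as_int(seeds[3 + i]), log)
        selections[method] = sel
        mask = sel.mask
        n_vars = int(mask.sum())
        if n_vars == 0:
            raise RuntimeError(f"method {method!r} selected no wavelengths")
        Xtr = train.absorbance[:, mask]
        if cfg.n_components == "auto":
            n_lvs = _elbow_components(
                Xtr,
                train.concentration,
                cfg.selection_n_v,
                cfg.press_c_max,
                cfg.press_rel_tol,
                as_int(seeds[2]),
            )
        else:
            n_lvs = min(int(cfg.n_components), n_vars, train.n - cfg.selection_n_v - 1)
        if cfg.mccv_scope == "all":
            X_cv, y_cv = ds.absorbance[:, mask], ds.concentration
        else:
            X_cv, y_cv = Xtr, train.concentration
        c_cv = min(n_lvs, y_cv.size - cfg.mccv_n_v - 1, n_vars)
        rmsecv = _chunked_rmsecv(
            X_cv, y_cv, c_cv, cfg.mccv_n_v, cfg.mccv_N, as_int(seeds[2]), log
        )
        c_fit = min(n_lvs, train.n - 1, n_vars)
        model = fit_pls(Xtr, train.concentration, c_fit)
        yhat = predict(model, test.absorbance[:, mask])
        row = MethodRow(
            method=method,
            n_vars=n_vars,
            n_lvs=n_lvs,
            rmsecv=rmsecv,
            rmsep=rmsep(test.concentration, yhat),
            r2_test=r2_test(test.concentration, yhat),
        )
        rows.append(row)
        if log:
            log(
                f"[{method}] n_vars={row.n_vars} LVs={row.n_lvs} "
                f"RMSECV={row.rmsecv:.4f} RMSEP={row.rmsep:.4f} "
                f"R2={row.r2_test:.4f}"
            )
    return {
        "test_split": test_split,
        "selections": selections,
        "rows": rows,
        "n_components_full": c_full,
        "seed": cfg.seed,
    }


def write_report(result: dict, outdir, wavenumbers=None) -> None:
    """Write the comparison report as TSV + JSON plus per-method masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [r.as_dict() for r in result["rows"]]
    with open(outdir / "report.tsv", "w", encoding="utf-8") as fh:
        cols = ["method", "n_vars", "n_LVs", "RMSECV", "RMSEP", "R2_test"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    f"{r[c]:.4f}" if isinstance(r[c], float) else str(r[c])
                    for c in cols
                )
                + "\n"
            )
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rows": rows,
                "seed": result["seed"],
                "n_components_full": result["n_components_full"],
                "test_indices": result["test_split"].validation.tolist(),
            },
            fh,
            indent=2,
        )
    for method, sel in result["selections"].items():
        sel.save(outdir, wavenumbers=wavenumbers, stem=method)
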