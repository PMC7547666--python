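"""Genetic-algorithm wavelength selection with resampled fitness.

Chromosomes are bit-strings over the ``p`` wavelengths (1 = selected).  The
unfitness of a chromosome is the mean calibration MSE over repeated Monte
Carlo resamples of the training data — never a single fit — and three
anti-overfitting layers are built in:

1. every GA run first sets aside its own block-stratified holdout; the
   final solution's RMSEV on that holdout is used exactly once, to accept
   or discard the run (threshold: ``acceptance_factor`` x the RMSEV of the
   all-wavelength model on the same holdout);
2. each fitness evaluation averages MSEC over ``fitness_mccv_iters``
   resampled calibration/validation splits;
3. the GA is run ``n_runs`` times from independent seeds and only the
   ensemble of accepted solutions is interpreted.

Accepted best chromosomes are stacked into ``G``; the co-selection matrix
``H = G' G`` counts how often wavelength ``j`` was selected together with
wavelength ``i``, and the per-wavelength selection probability ``P_GA`` is
the diagonal of ``H`` divided by the number of runs.  Thresholding ``P_GA``
(default 0.6) yields the final wavelength set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coef_select import SelectionResult
from .dataset import block_stratified_split
from .pls import press_curve, select_components_elbow
from .validation import _make_splits, _mccv_errors

__all__ = [
    "GAConfig",
    "GARunResult",
    "GAEnsemble",
    "fitness",
    "run_ga",
    "ensemble_ga",
    "ensemble_from_chromosomes",
    "select_by_probability",
    "synchronous_2d_correlation",
]

#: unfitness assigned to chromosomes too small to support the PLS model
WORST_FITNESS = np.inf


@dataclass
class GAConfig:
    """Tunables of the GA selector; defaults follow the study design.

    ``mutation_rate=None`` resolves to 1/p, ``fitness_n_v=None`` to
    ``max(2, floor(0.2 * n))`` of the per-run evolution set, and
    ``n_components=None`` to the PRESS elbow of the all-wavelength model.
    """

    population_size: int = 64
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    # sparse start: with MSEC-only unfitness (no parsimony term) the drift
    # toward small wavelength sets must come from initialization, or P_GA
    # cannot separate informative bands from background across runs
    init_density: float = 0.05
    fitness_mccv_iters: int = 100
    fitness_n_v: int | None = None
    holdout_n_v: int = 5
    acceptance_factor: float = 1.5
    n_components: int | None = None
    n_runs: int = 100
    seed: int = 0
    elitism: int = 1
    tournament_size: int = 2
    track_chromosomes: bool = False
    press_c_max: int = 10
    press_rel_tol: float = 0.02

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "init_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.acceptance_factor <= 0:
            raise ValueError("acceptance_factor must be > 0")
        for name in ("population_size", "generations", "fitness_mccv_iters",
                     "holdout_n_v", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GARunResult:
    """Outcome of one GA run: best chromosome, histories, holdout verdict."""

    best_chromosome: np.ndarray
    fitness_history: np.ndarray       # best mean-MSEC per generation
    rmsecv_history: np.ndarray        # pooled RMSECV of the best chromosome
    rmsev_history: np.ndarray         # holdout RMSEV of the best chromosome
    holdout_rmsev: float
    full_model_rmsev: float
    accepted: bool
    holdout_indices: np.ndarray
    chromosome_history: np.ndarray | None = None


@dataclass
class GAEnsemble:
    """Stacked accepted solutions G, co-selection counts H, and P_GA."""

    G: np.ndarray
    H: np.ndarray
    p_ga: np.ndarray
    n_runs_total: int
    n_runs_accepted: int
    denominator: str = "accepted"
    n_components: int = 0
    runs: list = field(default_factory=list, repr=False)

    def save(self, directory, wavenumbers=None, config: "GAConfig | None" = None) -> None:
        """Write G (bit matrix), H (integer matrix) and P_GA as TSV files,
        plus a YAML echo of the configuration for provenance."""
        import yaml
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "G.tsv", self.G, fmt="%d", delimiter="\t")
        np.savetxt(directory / "H.tsv", self.H, fmt="%d", delimiter="\t")
        axis = (
            np.asarray(wavenumbers, dtype=float)
            if wavenumbers is not None
            else np.arange(self.p_ga.size, dtype=float)
        )
        with open(directory / "p_ga.tsv", "w", encoding="utf-8") as fh:
            fh.write("wavenumber\tp_ga\n")
            for w, p in zip(axis, self.p_ga):
                fh.write(f"{w:.10g}\t{p:.10g}\n")
        meta = {
            "n_runs_total": int(self.n_runs_total),
            "n_runs_accepted": int(self.n_runs_accepted),
            "denominator": self.denominator,
            "n_components": int(self.n_components),
        }
        if config is not None:
            from dataclasses import asdict

            meta["config"] = asdict(config)
        with open(directory / "ensemble.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)


def _chromosome_stats(chrom, X, y, c, splits):
    """(mean MSEC, mean MSEV) of a chromosome on fixed fitness splits."""
    k = int(chrom.sum())
    if k < c + 1:
        return WORST_FITNESS, WORST_FITNESS
    msec, msev, _ = _mccv_errors(X[:, chrom], y, c, splits)
    return float(msec.mean()), float(msev.mean())


def fitness(chromosome, X, y, cfg: GAConfig, seed) -> float:
    """Mean calibration MSE of a chromosome over resampled splits.

    Lower is better (unfitness).  Chromosomes selecting fewer than
    ``n_components + 1`` wavelengths get the worst-possible sentinel rather
    than raising, so degenerate individuals never crash the GA loop.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    chrom = np.asarray(chromosome, dtype=bool)
    c = cfg.n_components
    if c is None:
        raise ValueError("cfg.n_components must be resolved before fitness evaluation")
    n_v = cfg.fitness_n_v or max(2, int(0.2 * y.size))
    rng = np.random.default_rng(seed)
    splits = _make_splits(y, n_v, cfg.fitness_mccv_iters, rng)
    return _chromosome_stats(chrom, X, y, c, splits)[0]


def resolve_components(X, y, cfg: GAConfig, seed) -> int:
    """PRESS-elbow component count of the all-wavelength model."""
    n, p = np.asarray(X).shape
    c_max = min(cfg.press_c_max, n - cfg.holdout_n_v - 2, p)
    curve = press_curve(X, y, c_max, n_v=cfg.holdout_n_v, N=20, seed=seed)
    return select_components_elbow(curve, cfg.press_rel_tol)


def run_ga(X_train, y_train, cfg: GAConfig, run_seed) -> GARunResult:
    """One GA run: holdout split, evolution, single holdout evaluation.

    Evolution operators: tournament selection (size ``tournament_size``),
    uniform crossover at ``crossover_rate``, per-bit mutation (elites are
    exempt), elitism of ``cfg.elitism`` individuals.  All fitness-evaluation
    splits are drawn from the evolution set only — the run-level holdout
    never enters a fitness split — and the whole run is a deterministic
    function of ``run_seed``.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(run_seed)
    c = cfg.n_components
    if c is None:
        c = resolve_components(X, y, cfg, rng.integers(2**31))
    if not 1 <= cfg.holdout_n_v < n:
        raise ValueError(f"holdout_n_v must be in [1, {n - 1}]")
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / p

    holdout_split = block_stratified_split(y, cfg.holdout_n_v, rng)
    evo, hold = holdout_split.calibration, holdout_split.validation
    X_evo, y_evo = X[evo], y[evo]
    X_hold, y_hold = X[hold], y[hold]
    n_evo = evo.size
    fit_n_v = cfg.fitness_n_v or max(2, int(0.2 * n_evo))
    if not 1 <= fit_n_v < n_evo:
        raise ValueError(f"fitness_n_v must be in [1, {n_evo - 1}]")
    if c > n_evo - fit_n_v - 1:
        raise ValueError(
            f"n_components={c} infeasible for evolution set of {n_evo} "
            f"with fitness_n_v={fit_n_v}"
        )
    fitness_splits = _make_splits(y_evo, fit_n_v, cfg.fitness_mccv_iters, rng)

    from .pls import _fit_nested_for_split

    def holdout_rmsev_of(mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        x_mean, y_mean, B = _fit_nested_for_split(X_evo[:, cols], y_evo, c)
        pred = (X_hold[:, cols] - x_mean) @ B[:, -1] + y_mean
        return float(np.sqrt(((pred - y_hold) ** 2).mean()))

    full_rmsev = holdout_rmsev_of(np.ones(p, dtype=bool))

    pop = rng.random((cfg.population_size, p)) < cfg.init_density
    cache: dict[bytes, tuple[float, float]] = {}

    def stats_of(chrom: np.ndarray) -> tuple[float, float]:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            cache[key] = _chromosome_stats(chrom, X_evo, y_evo, c, fitness_splits)
        return cache[key]

    fitness_history = np.empty(cfg.generations)
    rmsecv_history = np.empty(cfg.generations)
    rmsev_history = np.empty(cfg.generations)
    chrom_history = (
        np.empty((cfg.generations, p), dtype=bool) if cfg.track_chromosomes else None
    )
    best_chrom = pop[0].copy()

    for gen in range(cfg.generations):
        stats = [stats_of(ind) for ind in pop]
        unfit = np.array([s[0] for s in stats])
        order = np.argsort(unfit, kind="stable")
        best = order[0]
        best_chrom = pop[best].copy()
        fitness_history[gen] = unfit[best]
        msev = stats[best][1]
        rmsecv_history[gen] = np.sqrt(msev) if np.isfinite(msev) else np.inf
        rmsev_history[gen] = (
            holdout_rmsev_of(best_chrom) if best_chrom.sum() >= c + 1 else np.inf
        )
        if chrom_history is not None:
            chrom_history[gen] = best_chrom
        if gen == cfg.generations - 1:
            break
        # next generation: elites pass unchanged (and unmutated)
        elite = pop[order[: cfg.elitism]].copy()
        n_children = cfg.population_size - cfg.elitism
        children = np.empty((n_children, p), dtype=bool)
        for i in range(n_children):
            contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
            pa = pop[contenders[np.argmin(unfit[contenders])]]
            contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
            pb = pop[contenders[np.argmin(unfit[contenders])]]
            if rng.random() < cfg.crossover_rate:
                take_a = rng.random(p) < 0.5
                child = np.where(take_a, pa, pb)
            else:
                child = pa.copy()
            flip = rng.random(p) < mut
            children[i] = child ^ flip
        pop = np.vstack([elite, children])

    holdout_rmsev = rmsev_history[cfg.generations - 1]
    accepted = bool(holdout_rmsev <= cfg.acceptance_factor * full_rmsev)
    return GARunResult(
        best_chromosome=best_chrom,
        fitness_history=fitness_history,
        rmsecv_history=rmsecv_history,
        rmsev_history=rmsev_history,
        holdout_rmsev=float(holdout_rmsev),
        full_model_rmsev=full_rmsev,
        accepted=accepted,
        holdout_indices=hold,
        chromosome_history=chrom_history,
    )


def ensemble_ga(X_train, y_train, cfg: GAConfig) -> GAEnsemble:
    """Run the GA ``n_runs`` times and ensemble the accepted solutions.

    Child-run seeds are spawned from ``cfg.seed`` by a counter-based scheme
    (``SeedSequence.spawn``), so the result is independent of execution
    order.  The component count, if unset, is resolved once from the full
    training data and shared by every run.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    p = X.shape[1]
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs + 1)
    cfg_run = cfg
    if cfg.n_components is None:
        c = resolve_components(X, y, cfg, children[0].generate_state(1)[0] % 2**31)
        cfg_run = replace(cfg, n_components=int(c))
    child_seeds = children[1:]
    runs = [run_ga(X, y, cfg_run, seed) for seed in child_seeds]
    accepted = [r for r in runs if r.accepted]
    if not accepted:
        raise RuntimeError(
            "no GA run passed the holdout acceptance test; review the "
            "configuration (acceptance_factor, generations, n_components)"
        )
    ens = ensemble_from_chromosomes(
        [r.best_chromosome for r in accepted], n_runs_total=cfg.n_runs
    )
    ens.n_components = int(cfg_run.n_components)
    ens.runs = runs
    return ens


def ensemble_from_chromosomes(chromosomes, n_runs_total: int) -> GAEnsemble:
    """Stack accepted chromosomes into G and derive H = G'G and P_GA.

    ``H[i, j]`` counts the runs in which wavelengths ``i`` and ``j`` were
    selected together (integer arithmetic); ``P_GA`` is ``diag(H)`` divided
    by the number of accepted runs.
    """
    G = np.vstack([np.asarray(ch, dtype=bool) for ch in chromosomes]).astype(np.int32)
    H = (G.T @ G).astype(np.int32)
    p_ga = np.diag(H).astype(float) / G.shape[0]
    return GAEnsemble(
        G=G,
        H=H,
        p_ga=p_ga,
        n_runs_total=int(n_runs_total),
        n_runs_accepted=G.shape[0],
        denominator="accepted",
    )


def select_by_probability(
    ens: GAEnsemble, threshold: float = 0.6, denominator: str | None = None
) -> SelectionResult:
    """Threshold P_GA into a wavelength mask (keep ``p_ga >= threshold``).

    ``denominator`` may switch the probability normalisation between
    ``"accepted"`` (default, as recorded in the ensemble) and ``"total"``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p_ga = ens.p_ga
    if denominator is not None:
        if denominator not in ("accepted", "total"):
            raise ValueError("denominator must be 'accepted' or 'total'")
        counts = np.diag(ens.H).astype(float)
        denom = ens.n_runs_accepted if denominator == "accepted" else ens.n_runs_total
        p_ga = counts / denom
    mask = p_ga >= threshold
    return SelectionResult(
        method="ga",
        score=p_ga,
        mask=mask,
        params={
            "threshold": float(threshold),
            "denominator": denominator or ens.denominator,
            "n_runs_total": int(ens.n_runs_total),
            "n_runs_accepted": int(ens.n_runs_accepted),
            "n_components": int(ens.n_components),
        },
    )


def synchronous_2d_correlation(X) -> np.ndarray:
    """Synchronous 2D correlation spectrum ``Phi = Xc' Xc / (n - 1)``.

    ``Xc`` is the column-mean-centered spectra matrix; the diagonal is the
    per-wavelength sample variance.  Used as a model-free comparison surface
    for the co-selection matrix H.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two spectra")
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / (X.shape[0] - 1)
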