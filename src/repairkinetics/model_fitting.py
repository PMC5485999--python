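"""Evolutionary parameter estimation for the delayed repair model.

A median %DNA-in-tail time-course is mapped to a kinetic parameter set
by a (mu+lambda) evolution strategy with elitism, followed by an
optional local simplex refinement ("polish").  Rate constants are
searched in log10 space because fitted values span several orders of
magnitude; delays and the baseline ``bn`` are searched linearly.  The
lower bound of every log-scale rate axis decodes to an exact zero, so
the one-pathway submodel (all slow rates zero) is representable inside
the two-pathway search space and nested fits can be warm-started.

The error of fit is the unweighted sum of squared differences between
the predicted observable and the observed medians (RMSE is reported
alongside).  The pre-treatment point is an ordinary observation at a
time before the pulse, where the model predicts ``bn``; no baseline
subtraction is performed because ``bn`` is co-estimated.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import Bounds, minimize

from .dde_engine import SolverConfig, sample_observable, simulate
from .repair_model import IrradiationProtocol, ModelParameters, PathwayRates

__all__ = [
    "ObservationSeries",
    "FitConfig",
    "FitResult",
    "error_of_fit",
    "evolutionary_fit",
    "gradient_polish",
    "reduce_to_one_pathway",
    "predict_observable",
]

_ONE_PATHWAY_KEYS = ("kcleav", "k0_fast", "k1_fast", "k2_fast", "tr_fast", "bn")
_TWO_PATHWAY_KEYS = (
    "kcleav", "k0_fast", "k1_fast", "k2_fast", "tr_fast",
    "k0_slow", "k1_slow", "k2_slow", "tr_slow", "bn",
)
_ZERO_FLOOR_TOL = 1e-9


def _is_rate_key(key: str) -> bool:
    return key.startswith("k")  # kcleav, k0_*, k1_*, k2_* are log-scale


@dataclass
class ObservationSeries:
    """A (time, median %DNA in tail) time-course with optional quartiles.

    Times are minutes relative to the end of the dose-rate pulse;
    negative times denote pre-treatment sampling.
    """

    times: np.ndarray
    medians: np.ndarray
    q1: Optional[np.ndarray] = None
    q3: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.medians = np.asarray(self.medians, dtype=float)
        if self.times.size != self.medians.size:
            raise ValueError("times and medians must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.medians.size and (
                np.nanmin(self.medians) < 0 or np.nanmax(self.medians) > 100):
            raise ValueError("medians must lie in [0, 100] %DNA")
        for name in ("q1", "q3"):
            q = getattr(self, name)
            if q is not None:
                q = np.asarray(q, dtype=float)
                if q.size != self.times.size:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, q)
        if self.q1 is not None and np.any(self.q1 > self.medians + 1e-9):
            raise ValueError("q1 must not exceed the median")
        if self.q3 is not None and np.any(self.q3 < self.medians - 1e-9):
            raise ValueError("q3 must not fall below the median")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_min", "median_pct_dna", "q1", "q3"])
            for i in range(len(self)):
                w.writerow([
                    repr(float(self.times[i])),
                    repr(float(self.medians[i])),
                    "" if self.q1 is None else repr(float(self.q1[i])),
                    "" if self.q3 is None else repr(float(self.q3[i])),
                ])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ObservationSeries":
        times, med, q1, q3 = [], [], [], []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "time_min" not in reader.fieldnames:
                raise ValueError(f"{path}: missing 'time_min' column")
            for row in reader:
                times.append(float(row["time_min"]))
                med.append(float(row["median_pct_dna"]))
                q1.append(float(row["q1"]) if row.get("q1") else np.nan)
                q3.append(float(row["q3"]) if row.get("q3") else np.nan)
        q1a = None if np.all(np.isnan(q1)) else np.asarray(q1)
        q3a = None if np.all(np.isnan(q3)) else np.asarray(q3)
        return cls(times=np.asarray(times), medians=np.asarray(med),
                   q1=q1a, q3=q3a, metadata={"source": str(path)})


@dataclass(frozen=True)
class FitConfig:
    """Settings of the evolutionary search.

    ``bounds`` maps parameter keys to (lo, hi) in the *search* space:
    log10 units for rate constants, minutes for delays, %DNA for ``bn``.
    A ``bn`` upper bound of ``None`` is resolved at fit time to the
    smallest observed median (the baseline cannot exceed any observed
    signal).  ``mutation_scale`` is the Gaussian mutation s.d. in log10
    units for rate axes; linear axes use ``mutation_scale * (hi-lo)/4``.
    The mutation width is annealed geometrically to ``mutation_decay``
    times its initial value over the run.
    """

    pathway_mode: str = "one"
    bounds: Optional[dict] = None
    population: int = 32
    generations: int = 120
    mutation_scale: float = 0.25
    mutation_decay: float = 0.1
    elites: int = 4
    restarts: int = 4
    polish: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pathway_mode not in ("one", "two"):
            raise ValueError("pathway_mode must be 'one' or 'two'")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 < self.elites <= self.population):
            raise ValueError("elites must be in [1, population]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    @property
    def keys(self) -> tuple:
        return _ONE_PATHWAY_KEYS if self.pathway_mode == "one" else _TWO_PATHWAY_KEYS


def default_bounds(pathway_mode: str = "one",
                   obs: Optional[ObservationSeries] = None) -> dict:
    """Default search bounds: rates 1e-4..1e3 (log10), delays 0..60 min,
    bn from 0 to the smallest observed median."""
    keys = _ONE_PATHWAY_KEYS if pathway_mode == "one" else _TWO_PATHWAY_KEYS
    b = {}
    for k in keys:
        if _is_rate_key(k):
            b[k] = (-4.0, 3.0)
        elif k.startswith("tr"):
            b[k] = (0.0, 60.0)
        else:  # bn
            hi = float(np.min(obs.medians)) if obs is not None and len(obs) else 100.0
            b[k] = (0.0, max(hi, 0.0))
    return b


@dataclass
class FitResult:
    """Outcome of an evolutionary fit."""

    parameters: ModelParameters
    error: float               # SSE over observed medians
    rmse: float
    trace: list                # best SSE per generation (non-increasing)
    seed: int
    config: dict               # echo of the fit configuration
    n_evaluations: int = 0
    polish_improved: bool = False

    def to_dict(self) -> dict:
        d = self.parameters.to_dict()
        d.update({
            "error": self.error,
            "rmse": self.rmse,
            "seed": self.seed,
            "trace": list(self.trace),
            "config": self.config,
        })
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# objective


def _model_times(obs_times: np.ndarray, protocol: IrradiationProtocol) -> np.ndarray:
    # observation clocks start at pulse END; pre-pulse samples map to t=0,
    # where the zero initial state makes the observable exactly bn
    return np.clip(np.asarray(obs_times, dtype=float) + protocol.pulse_end, 0.0, None)


def predict_observable(params: ModelParameters, obs_times: Sequence[float],
                       protocol: IrradiationProtocol,
                       solver: Optional[SolverConfig] = None,
                       mode: str = "simple") -> np.ndarray:
    """Model-predicted %DNA in tail at observation times (min after pulse end)."""
    solver = solver or SolverConfig()
    tm = _model_times(np.asarray(obs_times, dtype=float), protocol)
    horizon = max(float(tm.max(initial=0.0)), protocol.pulse_end) + solver.step
    traj = simulate(params, protocol, horizon, solver, mode=mode)
    return sample_observable(traj, tm)


def error_of_fit(params: ModelParameters, obs: ObservationSeries,
                 protocol: IrradiationProtocol,
                 solver: Optional[SolverConfig] = None,
                 mode: str = "simple") -> float:
    """Sum of squared differences between prediction and observed medians."""
    if len(obs) == 0:
        raise ValueError("observation series is empty")
    try:
        pred = predict_observable(params, obs.times, protocol, solver, mode=mode)
    except (ValueError, FloatingPointError) as exc:
        raise RuntimeError(f"simulation failed for {params!r}") from exc
    sse = float(np.sum((pred - obs.medians) ** 2))
    return sse if math.isfinite(sse) else float("inf")


def fit_rmse(sse: float, n: int) -> float:
    return math.sqrt(sse / n) if n else float("nan")


# ---------------------------------------------------------------------------
# search-space transform


def _resolve_bounds(config: FitConfig, obs: ObservationSeries) -> dict:
    bounds = dict(config.bounds) if config.bounds else default_bounds(
        config.pathway_mode, obs)
    if bounds.get("bn") is not None and bounds["bn"][1] is None:
        bounds["bn"] = (bounds["bn"][0], float(np.min(obs.medians)))
    for k in (_ONE_PATHWAY_KEYS if config.pathway_mode == "one" else _TWO_PATHWAY_KEYS):
        if k not in bounds:
            bounds[k] = default_bounds(config.pathway_mode, obs)[k]
        lo, hi = bounds[k]
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
            raise ValueError(f"degenerate bounds for {k}: {(lo, hi)}")
    return bounds


def _encode(params: ModelParameters, keys: tuple, bounds: dict) -> np.ndarray:
    flat = params.to_dict()
    x = np.empty(len(keys))
    for i, k in enumerate(keys):
        lo, hi = bounds[k]
        v = flat[k]
        if _is_rate_key(k):
            xi = math.log10(v) if v > 0.0 else lo
        else:
            xi = v
        x[i] = min(max(xi, lo), hi)
    return x


def _decode(x: np.ndarray, keys: tuple, bounds: dict) -> ModelParameters:
    flat = {k: 0.0 for k in _TWO_PATHWAY_KEYS}
    for i, k in enumerate(keys):
        lo, _ = bounds[k]
        if _is_rate_key(k):
            # exact-zero floor: the lower bound switches the rate off
            flat[k] = 0.0 if x[i] <= lo + _ZERO_FLOOR_TOL else 10.0 ** x[i]
        else:
            flat[k] = float(x[i])
    return ModelParameters.from_dict(flat)


# ---------------------------------------------------------------------------
# evolutionary search


def evolutionary_fit(obs: ObservationSeries, protocol: IrradiationProtocol,
                     config: Optional[FitConfig] = None,
                     solver: Optional[SolverConfig] = None,
                     init_candidates: Optional[Sequence[ModelParameters]] = None,
                     mode: str = "simple") -> FitResult:
    """(mu+lambda) evolution strategy with elitism, restarts and polish.

    Deterministic for a fixed seed.  The search is repeated from
    ``config.restarts`` independent initial populations (the error
    surface of the delayed model is multimodal) and the best final
    candidate is polished.  ``init_candidates`` are injected into every
    initial population (e.g. a one-pathway fit used to warm-start the
    two-pathway model).
    """
    if len(obs) == 0:
        raise ValueError("observation series is empty")
    config = config or FitConfig()
    solver = solver or SolverConfig()
    bounds = _resolve_bounds(config, obs)
    keys = config.keys
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])
    sigma0 = np.array([
        config.mutation_scale if _is_rate_key(k)
        else config.mutation_scale * (bounds[k][1] - bounds[k][0]) / 4.0
        for k in keys
    ])

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            return error_of_fit(_decode(x, keys, bounds), obs, protocol,
                                solver, mode=mode)
        except RuntimeError:
            return float("inf")

    init_x = ([_encode(c, keys, bounds) for c in init_candidates]
              if init_candidates else [])
    P, G, E = config.population, config.generations, config.elites
    mu = max(E, P // 2)
    trace: list = []
    candidates: list = []  # (final_x, final_err) per restart
    running_best = float("inf")
    for child_seed in np.random.SeedSequence(config.seed).spawn(config.restarts):
        rng = np.random.default_rng(child_seed)
        # oversampled initialization: evaluate 4P uniform draws and keep the
        # best P, which seeds the narrow deep basins far more reliably
        pop = lo + rng.random((4 * P, len(keys))) * (hi - lo)
        for j, cx in enumerate(init_x[: 4 * P]):
            pop[j] = cx
        errs = np.array([objective(x) for x in pop])
        order = np.argsort(errs, kind="stable")[:P]
        pop, errs = pop[order], errs[order]
        running_best = min(running_best, float(errs[0]))
        trace.append(running_best)
        for g in range(G):
            frac = g / max(G - 1, 1)
            sigma = sigma0 * (config.mutation_decay ** frac)
            parents = pop[rng.integers(0, mu, size=P)]
            offspring = np.clip(
                parents + rng.normal(size=(P, len(keys))) * sigma, lo, hi)
            off_errs = np.array([objective(x) for x in offspring])
            allpop = np.vstack([pop, offspring])
            allerrs = np.concatenate([errs, off_errs])
            order = np.argsort(allerrs, kind="stable")[:P]
            pop, errs = allpop[order], allerrs[order]
            running_best = min(running_best, float(errs[0]))
            trace.append(running_best)
        candidates.append((pop[0].copy(), float(errs[0])))

    es_best = min(c[1] for c in candidates)
    if config.polish:
        # polish every restart's champion: basins differ between restarts
        # and the local refinement decides which one is actually deepest
        polished = []
        for cx, cerr in candidates:
            px, perr = _polish_x(objective, cx, lo, hi,
                                 maxfev=1500 if len(candidates) > 1 else 4000)
            polished.append((px, perr) if perr < cerr else (cx, cerr))
        candidates = polished
    best_x, best_err = min(candidates, key=lambda c: c[1])
    if config.polish:
        px, perr = _polish_x(objective, best_x, lo, hi)
        if perr < best_err:
            best_x, best_err = px, perr
    polish_improved = best_err < es_best
    running_best = min(running_best, best_err)
    trace.append(running_best)

    best_params = _decode(best_x, keys, bounds)
    final_err = error_of_fit(best_params, obs, protocol, solver, mode=mode)
    trace.append(min(float(final_err), trace[-1]))
    return FitResult(
        parameters=best_params,
        error=float(final_err),
        rmse=fit_rmse(final_err, len(obs)),
        trace=trace,
        seed=config.seed,
        config={
            "pathway_mode": config.pathway_mode,
            "bounds": {k: list(bounds[k]) for k in keys},
            "population": P,
            "generations": G,
            "mutation_scale": config.mutation_scale,
            "mutation_decay": config.mutation_decay,
            "elites": E,
            "restarts": config.restarts,
            "polish": config.polish,
            "solver": {"step": solver.step, "method": solver.method,
                       "clamp_policy": solver.clamp_policy},
            "induction_mode": mode,
        },
        n_evaluations=n_eval,
        polish_improved=polish_improved,
    )


def _polish_x(objective, x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
              maxfev: int = 4000):
    """Local Nelder-Mead refinement in the transformed space."""
    res = minimize(objective, x0, method="Nelder-Mead",
                   bounds=Bounds(lo, hi),
                   options={"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-10})
    return np.clip(res.x, lo, hi), float(res.fun)


def gradient_polish(params: ModelParameters, obs: ObservationSeries,
                    protocol: IrradiationProtocol,
                    solver: Optional[SolverConfig] = None,
                    config: Optional[FitConfig] = None,
                    mode: str = "simple") -> ModelParameters:
    """Local refinement of a parameter set; never worsens the error.

    Runs a bounded simplex descent in the same transformed space as the
    evolutionary search and returns the input unchanged when no
    improvement is found (or when polishing is disabled in the config).
    """
    solver = solver or SolverConfig()
    if config is None:
        pmode = "one" if params.is_one_pathway else "two"
        config = FitConfig(pathway_mode=pmode)
    if not config.polish:
        return params
    bounds = _resolve_bounds(config, obs)
    keys = config.keys
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])

    def objective(x):
        try:
            return error_of_fit(_decode(x, keys, bounds), obs, protocol,
                                solver, mode=mode)
        except RuntimeError:
            return float("inf")

    x0 = _encode(params, keys, bounds)
    err0 = error_of_fit(params, obs, protocol, solver, mode=mode)
    px, perr = _polish_x(objective, x0, lo, hi)
    if perr < err0:
        return _decode(px, keys, bounds)
    return params


def reduce_to_one_pathway(params: ModelParameters) -> ModelParameters:
    """Force the slow-pathway reaction rates to zero (nested submodel).

    The delay of the switched-off pathway is irrelevant and kept as-is;
    all other fields are unchanged.  Idempotent.
    """
    return replace(params, slow=PathwayRates(0.0, 0.0, 0.0, params.slow.tr))
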