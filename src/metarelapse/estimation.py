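"""Nonlinear least-squares estimation of population and covariate parameters.

Estimation minimizes squared discrepancies between empirical DMFS curves and
the model survival function with Nelder-Mead from Latin-hypercube starting
points.  Because the Kaplan-Meier-style data curve estimates the uncensored
survival function and the model simulates uncensored survival directly, the
least-squares route sidesteps explicit censoring handling.

Three objectives are supported:

- ``ss``: sum over grid times of (S_j - S(t_j; theta))^2, summed over
  covariate levels when the data are grouped;
- ``ss_mdiag``: ``ss`` plus ((M - m_diag(theta)) * lambda)^2, anchoring the
  fraction of patients metastatic at diagnosis (M on the percent scale by
  default, with lambda = 0.01 calibrated for that convention);
- ``multithreshold``: for a continuous covariate, patients are dichotomized
  at a ladder of percentile thresholds (15th..85th, step 5) and the objective
  sums, over thresholds l and groups g, the square root of the per-curve sum
  of squares — the shape of the misfit across thresholds is what identifies
  the functional form of the effect.

Optimization of covariate coefficients exploits that a covariate shifts only
the location of log alpha or log mu: survival curves over a grid of location
shifts are tabulated once per fit and interpolated per patient inside the
objective, so a Nelder-Mead evaluation costs a matrix product.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .population import (
    CovariateEffect,
    PopulationParams,
    SurvivalCurve,
    SurvivalEvaluator,
)
from .simulate import default_time_grid, make_dmfs_dataset

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = tuple(range(15, 90, 5))

#: Parameters optimized on the log scale to stay positive.
_LOG_SCALE_PARAMS = ("omega_alpha", "omega_mu")

_POP_PARAMS = ("log_alpha_pop", "omega_alpha", "log_mu_pop", "omega_mu")


@dataclass
class FitSpec:
    """What to estimate and how.

    ``free`` maps parameter names to Latin-hypercube start ranges.  Names may
    be population parameters (log_alpha_pop, omega_alpha, log_mu_pop,
    omega_mu), covariate-effect parameters (b, c, dif) or per-level
    categorical coefficients (b_2, b_3, ...).  Everything else is fixed at
    the values in ``pop`` / ``effect``.
    """

    free: dict[str, tuple[float, float]]
    pop: PopulationParams
    effect: CovariateEffect | None = None
    objective: str = "ss"  # ss | ss_mdiag | multithreshold
    lambda_: float = 0.01
    m_scale: str = "percent"  # percent | fraction
    n_starts: int = 1
    max_grid_points: int = 100
    percentiles: tuple = DEFAULT_PERCENTILES
    evaluator_opts: dict = field(default_factory=dict)
    nm_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.objective not in ("ss", "ss_mdiag", "multithreshold"):
            raise ValueError(f"unknown objective {self.objective!r}")
        for name, rng in self.free.items():
            lo, hi = rng
            if not lo <= hi:
                raise ValueError(f"invalid range for {name}: {rng}")


@dataclass
class FitResult:
    """Best Nelder-Mead solution over the Latin-hypercube starts."""

    estimates: dict[str, float]
    fval: float
    n_evaluations: int
    converged: bool
    initial_point: dict[str, float]
    start_fvals: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Objectives


def objective_ss(data_curve: SurvivalCurve, model_curve: SurvivalCurve) -> float:
    """Sum of squared survival differences on a shared time grid."""
    if data_curve.times.shape != model_curve.times.shape or not np.allclose(
        data_curve.times, model_curve.times
    ):
        raise ValueError("data and model curves must share the same time grid")
    return float(np.sum((data_curve.survival - model_curve.survival) ** 2))


def objective_ss_mdiag(
    data_curve: SurvivalCurve,
    model_curve: SurvivalCurve,
    m_data: float,
    lambda_: float = 0.01,
    m_scale: str = "percent",
) -> float:
    """Curve SS plus the weighted squared mismatch of the metastatic fraction.

    ``m_data`` is given as a fraction; with ``m_scale='percent'`` both data
    and model fractions enter the penalty on the 0-100 scale (the convention
    under which lambda = 0.01 was calibrated).
    """
    if not 0 <= m_data <= 1:
        raise ValueError("M must be in [0, 1]")
    scale = 100.0 if m_scale == "percent" else 1.0
    pen = ((m_data - model_curve.m_diag) * scale * lambda_) ** 2
    return objective_ss(data_curve, model_curve) + pen


def dichotomize_by_percentile(values, percentile: float):
    """Split patient indices at an empirical percentile of a covariate.

    Group 1: value < threshold; group 2: value >= threshold.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    x = np.asarray(values, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant; cannot dichotomize")
    thr = np.percentile(x, percentile)
    idx = np.arange(len(x))
    return idx[x < thr], idx[x >= thr]


def objective_multithreshold(
    data_curves: np.ndarray, model_curves: np.ndarray, valid=None
) -> float:
    """Sum over (threshold, group) of sqrt(sum of squared differences).

    ``data_curves`` and ``model_curves`` have shape (L, 2, n_times); entries
    flagged invalid (empty group at some threshold) are skipped.
    """
    d = np.asarray(data_curves, dtype=float)
    m = np.asarray(model_curves, dtype=float)
    if d.shape != m.shape:
        raise ValueError("curve arrays must share a shape")
    sse = np.sum((d - m) ** 2, axis=-1)
    if valid is not None:
        sse = np.where(valid, sse, 0.0)
    return float(np.sum(np.sqrt(sse)))


def lhs_initial_conditions(
    ranges: dict[str, tuple[float, float]], n_starts: int, rng_seed=None
) -> list[dict[str, float]]:
    """Latin-hypercube starting points: one draw per stratum per parameter."""
    names = list(ranges)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(rng_seed))
    u = sampler.random(n=n_starts)
    pts = lo + u * (hi - lo)
    return [dict(zip(names, p)) for p in pts]


# ---------------------------------------------------------------------------
# Parameter vector plumbing


def _to_internal(name: str, value: float) -> float:
    return math.log(value) if name in _LOG_SCALE_PARAMS else value


def _from_internal(name: str, value: float) -> float:
    return math.exp(value) if name in _LOG_SCALE_PARAMS else value


def _apply_params(spec: FitSpec, params: dict[str, float]):
    """Materialize (pop, effect) with the free parameters substituted."""
    pop_updates = {k: v for k, v in params.items() if k in _POP_PARAMS}
    pop = spec.pop.with_updates(**pop_updates) if pop_updates else spec.pop
    effect = spec.effect
    if effect is not None:
        eff_updates = {}
        bk_updates = {}
        for k, v in params.items():
            if k in ("b", "c", "dif"):
                eff_updates[k] = v
            elif k.startswith("b_"):
                bk_updates[int(k[2:])] = v
        if bk_updates:
            eff_updates["b_k"] = {**(effect.b_k or {}), **bk_updates}
        if eff_updates:
            effect = replace(effect, **eff_updates)
    return pop, effect


# ---------------------------------------------------------------------------
# Fit data preparation


@dataclass
class _GroupedData:
    """Per-level empirical curves for a categorical covariate (level 'all'
    for a no-covariate fit)."""

    levels: list
    grids: dict
    survival: dict
    m_diag: dict
    counts: dict


def _prepare_grouped(cohort: pd.DataFrame, covariate: str | None, spec: FitSpec) -> _GroupedData:
    if covariate is None:
        groups = {"all": cohort}
    else:
        groups = {lv: sub for lv, sub in cohort.groupby(cohort[covariate].astype(int))}
    levels, grids, surv, m, counts = [], {}, {}, {}, {}
    for lv, sub in groups.items():
        grid = default_time_grid(sub, spec.max_grid_points)
        curve, m_frac = make_dmfs_dataset(sub, grid)
        levels.append(lv)
        grids[lv], surv[lv], m[lv], counts[lv] = grid, curve.survival, m_frac, len(sub)
    return _GroupedData(levels, grids, surv, m, counts)


@dataclass
class _ThresholdData:
    """Dichotomized empirical curves at a ladder of covariate thresholds."""

    times: np.ndarray  # common grid (without leading 0)
    data_curves: np.ndarray  # (L, 2, n_t)
    valid: np.ndarray  # (L, 2) bool
    masks: np.ndarray  # (L, 2, n_patients) float
    x: np.ndarray  # covariate values, all patients


def _prepare_thresholds(cohort: pd.DataFrame, covariate: str, spec: FitSpec) -> _ThresholdData:
    x = cohort[covariate].to_numpy(dtype=float)
    grid = default_time_grid(cohort, spec.max_grid_points)
    n = len(cohort)
    L = len(spec.percentiles)
    data_curves = np.zeros((L, 2, len(grid)))
    valid = np.zeros((L, 2), dtype=bool)
    masks = np.zeros((L, 2, n))
    for l, pct in enumerate(spec.percentiles):
        idx1, idx2 = dichotomize_by_percentile(x, pct)
        for g, idx in enumerate((idx1, idx2)):
            if len(idx) == 0:
                logger.warning("empty group at percentile %s; term skipped", pct)
                continue
            sub = cohort.iloc[idx]
            if (sub["mets_at_diag"] == 0).sum() == 0:
                logger.warning(
                    "all patients metastatic at diagnosis at percentile %s; skipped", pct
                )
                continue
            curve, _ = make_dmfs_dataset(sub, grid)
            data_curves[l, g] = curve.survival
            valid[l, g] = True
            masks[l, g, idx] = 1.0 / len(idx)
    return _ThresholdData(grid, data_curves, valid, masks, x)


# ---------------------------------------------------------------------------
# Shift-tabulated model curves


class _ShiftTable:
    """Survival curves tabulated over a grid of log-parameter shifts.

    ``G(t=0..)`` rows are linear in the quadrature weights, so curves for an
    arbitrary per-patient shift are linear interpolations between tabulated
    rows; group curves then reduce to one matrix product per objective call.
    """

    def __init__(self, ev: SurvivalEvaluator, times0: np.ndarray, target: str,
                 delta_grid: np.ndarray):
        self.delta = delta_grid
        if target == "alpha":
            profile = ev.alpha_profile(times0)  # (n_a, n_t)
            weights = np.stack([ev.alpha_weights(d) for d in delta_grid])
            self.table = weights @ profile  # (n_delta, n_t)
        else:
            self.table = ev.mu_profile(times0, delta_grid)

    def per_patient(self, deltas: np.ndarray) -> np.ndarray:
        """Interpolated unconditional curves, shape (n_patients, n_t)."""
        lo, hi = self.delta[0], self.delta[-1]
        h = self.delta[1] - self.delta[0]
        pos = np.clip((deltas - lo) / h, 0.0, len(self.delta) - 1.0)
        i = np.minimum(pos.astype(int), len(self.delta) - 2)
        f = (pos - i)[:, None]
        return self.table[i] * (1.0 - f) + self.table[i + 1] * f


def _shift_grid(spec: FitSpec, target_scale: float, x_max: float, n: int = 240):
    """Tabulation range for covariate-induced shifts, padded well beyond the
    Latin-hypercube box so unconstrained Nelder-Mead steps stay on-table."""
    b_lo, b_hi = spec.free.get("b", (spec.effect.b, spec.effect.b))
    c_lo, c_hi = spec.free.get("c", (spec.effect.c, spec.effect.c))
    pad_b = 1.5 * (b_hi - b_lo) + 0.75 * max(abs(b_lo), abs(b_hi))
    c_corners = (c_lo - abs(c_lo) - 0.5, c_hi + abs(c_hi) + 0.5, 0.0)
    corners = [0.0]
    for b in (b_lo - pad_b, b_hi + pad_b):
        # threshold form shifts by b*scale regardless of x, linear forms by
        # b*scale*x (+ intercept c for the pure linear form)
        for x in (0.0, x_max, 1.0):
            base = b * target_scale * x
            if spec.effect.form == "linear":
                corners.extend(base + c for c in c_corners)
            else:
                corners.append(base)
        corners.append(b * target_scale)
    lo, hi = min(corners), max(corners)
    pad = 0.1 * (hi - lo) + 1e-6
    return np.linspace(lo - pad, hi + pad, n)


# ---------------------------------------------------------------------------
# Objective builders


def _nm_minimize(spec: FitSpec, fun, rng_seed):
    names = list(spec.free)
    starts = lhs_initial_conditions(spec.free, spec.n_starts, rng_seed)
    options = dict(xatol=1e-6, fatol=1e-10, maxfev=400 * len(names))
    options.update(spec.nm_options)
    best = None
    start_fvals = []
    n_eval_total = 0
    for start in starts:
        x0 = np.array([_to_internal(n, start[n]) for n in names])

        def wrapped(x):
            params = {n: _from_internal(n, v) for n, v in zip(names, x)}
            val = fun(params)
            return val if np.isfinite(val) else 1e12

        try:
            res = minimize(wrapped, x0, method="Nelder-Mead", options=options)
        except Exception:  # pragma: no cover - defensive
            logger.exception("start %s abandoned", start)
            continue
        start_fvals.append(float(res.fun))
        n_eval_total += int(res.nfev)
        if best is None or res.fun < best[0].fun:
            best = (res, start)
    if best is None:
        raise RuntimeError("all optimization starts failed")
    res, start = best
    estimates = {
        n: _from_internal(n, v) for n, v in zip(names, res.x)
    }
    return FitResult(
        estimates=estimates,
        fval=float(res.fun),
        n_evaluations=n_eval_total,
        converged=bool(res.success),
        initial_point=start,
        start_fvals=start_fvals,
    )


def _grouped_objective(spec: FitSpec, data: _GroupedData):
    """Objective over per-level curves; fast paths when only the location of
    the target parameter moves (covariate b coefficients)."""
    free = set(spec.free)
    eff = spec.effect
    loc_only = free <= {"b", "c", "dif"} | {f"b_{lv}" for lv in data.levels} and eff is not None
    base_pop = spec.pop
    # One evaluator (and cached integral workspace) per level grid.  The
    # alpha grid must span every shift Nelder-Mead may visit.
    shift_hint = 0.0
    if eff is not None and eff.target == "alpha":
        scale = abs(base_pop.log_alpha_pop + eff.dif)
        lvl = max((abs(int(lv)) for lv in data.levels if lv != "all"), default=1)
        b_mag = max(
            (max(abs(lo), abs(hi)) for n, (lo, hi) in spec.free.items()
             if n == "b" or n.startswith("b_")),
            default=abs(eff.b or 0.0),
        )
        lvl_factor = lvl if eff.minimal_categorical else 1
        shift_hint = 2.0 + 2.5 * b_mag * scale * lvl_factor
    elif free & {"log_alpha_pop"}:
        shift_hint = 4.0
    ev = SurvivalEvaluator(
        base_pop, alpha_shift_range=(-shift_hint, shift_hint), **spec.evaluator_opts
    )
    times0 = {lv: np.concatenate(([0.0], data.grids[lv])) for lv in data.levels}
    profiles = {}
    if loc_only and eff.target == "alpha":
        profiles = {lv: ev.alpha_profile(times0[lv]) for lv in data.levels}

    def curve_for(pop, effect, lv, rebuild):
        if effect is None:
            delta_a = delta_m = 0.0
        else:
            s = effect.shift(np.asarray([lv if lv != "all" else np.nan]),
                             base_pop.log_alpha_pop if effect.target == "alpha"
                             else base_pop.log_mu_pop)[0]
            delta_a, delta_m = (s, 0.0) if effect.target == "alpha" else (0.0, s)
        if rebuild:
            ev_l = SurvivalEvaluator(
                pop, alpha_shift_range=(-shift_hint, shift_hint), **spec.evaluator_opts
            )
            g = ev_l.unconditional(times0[lv], delta_a, delta_m)[0]
        elif lv in profiles:
            g = ev.alpha_weights(delta_a) @ profiles[lv]
        else:
            # location shifts on the cached evaluator (pop == base_pop)
            da = delta_a + (pop.log_alpha_pop - base_pop.log_alpha_pop)
            dm = delta_m + (pop.log_mu_pop - base_pop.log_mu_pop)
            g = ev.unconditional(times0[lv], da, [dm])[0]
        return g

    scale = 100.0 if spec.m_scale == "percent" else 1.0

    def fun(params):
        pop, effect = _apply_params(spec, params)
        rebuild = any(
            getattr(pop, k) != getattr(base_pop, k) for k in ("omega_alpha", "omega_mu")
        )
        total = 0.0
        for lv in data.levels:
            g = curve_for(pop, effect, lv, rebuild)
            if g[0] <= 0:
                return np.inf
            model_s = g[1:] / g[0]
            total += float(np.sum((data.survival[lv] - model_s) ** 2))
            if spec.objective == "ss_mdiag":
                total += ((data.m_diag[lv] - (1.0 - g[0])) * scale * spec.lambda_) ** 2
        return total

    return fun


def _threshold_objective(spec: FitSpec, data: _ThresholdData):
    eff = spec.effect
    target_scale = abs(
        (spec.pop.log_alpha_pop if eff.target == "alpha" else spec.pop.log_mu_pop)
        + eff.dif
    )
    delta_grid = _shift_grid(spec, target_scale, float(data.x.max()))
    ev = SurvivalEvaluator(
        spec.pop,
        alpha_shift_range=(
            (float(delta_grid[0]), float(delta_grid[-1]))
            if eff.target == "alpha"
            else (0.0, 0.0)
        ),
        **spec.evaluator_opts,
    )
    times0 = np.concatenate(([0.0], data.times))
    table = _ShiftTable(ev, times0, eff.target, delta_grid)
    base = (
        spec.pop.log_alpha_pop if eff.target == "alpha" else spec.pop.log_mu_pop
    )
    flat_masks = data.masks.reshape(-1, data.masks.shape[-1])  # (L*2, n)

    def fun(params):
        _, effect = _apply_params(spec, params)
        deltas = effect.shift(data.x, base)
        per_patient = table.per_patient(deltas)  # (n, n_t+1)
        g = flat_masks @ per_patient  # (L*2, n_t+1)
        g0 = g[:, 0]
        ok = data.valid.reshape(-1) & (g0 > 0)
        model = np.where(
            ok[:, None], g[:, 1:] / np.where(g0 > 0, g0, 1.0)[:, None], 0.0
        )
        model = model.reshape(data.data_curves.shape)
        return objective_multithreshold(
            data.data_curves, model, valid=ok.reshape(data.valid.shape)
        )

    return fun


def fit_parameters(spec: FitSpec, cohort: pd.DataFrame, rng_seed=None) -> FitResult:
    """Estimate the free parameters of ``spec`` from a cohort table.

    Dispatches on the spec: population-parameter fits and categorical-effect
    fits minimize per-level curve objectives; continuous-covariate fits
    minimize the multi-threshold objective.
    """
    if spec.objective == "multithreshold":
        if spec.effect is None:
            raise ValueError("multithreshold objective requires a covariate effect")
        data = _prepare_thresholds(cohort, spec.effect.covariate, spec)
        fun = _threshold_objective(spec, data)
    else:
        covariate = (
            spec.effect.covariate
            if spec.effect is not None and spec.effect.form == "categorical"
            else None
        )
        data = _prepare_grouped(cohort, covariate, spec)
        fun = _grouped_objective(spec, data)
    return _nm_minimize(spec, fun, rng_seed)


def bootstrap_uncertainty(
    spec: FitSpec, cohort: pd.DataFrame, n_boot: int = 100, rng_seed=None
) -> dict[str, dict[str, float]]:
    """Nonparametric bootstrap uncertainty of a fit on observed data.

    Resamples patients with replacement, refits, and summarizes each free
    parameter by the relative SE (SD of bootstrap estimates over the point
    estimate, %) and the 2.5/97.5 percentile interval.  This is the
    package's chosen uncertainty route for single-cohort (clinical) fits,
    where replicate simulation studies are not available.
    """
    ss = np.random.SeedSequence(rng_seed)
    point = fit_parameters(spec, cohort, rng_seed=ss.spawn(1)[0])
    rows = []
    for k in range(n_boot):
        child = np.random.SeedSequence(entropy=rng_seed, spawn_key=(1, k))
        rng = np.random.default_rng(child)
        sample = cohort.sample(n=len(cohort), replace=True, random_state=rng.integers(2**31))
        try:
            rows.append(fit_parameters(spec, sample, rng_seed=child).estimates)
        except Exception:
            logger.exception("bootstrap replicate %d failed", k)
    boot = pd.DataFrame(rows)
    out = {}
    for name in spec.free:
        est = point.estimates[name]
        sd = float(boot[name].std(ddof=1))
        lo, hi = np.percentile(boot[name], [2.5, 97.5])
        out[name] = {
            "estimate": est,
            "rse_percent": 100.0 * sd / abs(est) if est != 0 else float("inf"),
            "ci95": (float(lo), float(hi)),
        }
    return out


def select_covariate_model(
    cohort: pd.DataFrame, candidates: list[FitSpec], rng_seed=None
) -> list[tuple[FitSpec, FitResult | None]]:
    """Fit every candidate effect model and rank by minimized objective.

    Failed candidates are kept in the output with a None result rather than
    aborting the selection.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.spawn(len(candidates))
    results = []
    for spec, child in zip(candidates, seeds):
        try:
            results.append((spec, fit_parameters(spec, cohort, child)))
        except Exception:
            logger.exception("candidate %s failed", spec)
            results.append((spec, None))
    return sorted(
        results, key=lambda pair: pair[1].fval if pair[1] is not None else np.inf
    )
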