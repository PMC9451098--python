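"""Population-level relapse model.

Individual growth and dissemination parameters are lognormal across patients,

    log alpha_i = log alpha_pop + [covariate shift] + eta_alpha,   eta_alpha ~ N(0, omega_alpha^2)
    log mu_i    = log mu_pop    + [covariate shift] + eta_mu,      eta_mu    ~ N(0, omega_mu^2)

and the diagnosis volume V_diag is lognormal (specified on the cm^3 scale and
converted with 1 cm^3 = 1e9 cells, truncated below the carrying capacity).
The population survival function S(t) = P[TTR > t] is reported conditional on
no visible metastasis at diagnosis, with the metastatic-at-diagnosis fraction
m_diag returned separately.

Because the expected metastasis count is linear in mu, conditioning on
(alpha, V_diag) gives

    P[TTR > t | alpha, V_diag] = F_mu( 1 / I(t_diag + min(t, tau_vis) - tau_vis) )

with F_mu the lognormal CDF of mu, so S(t) reduces to a two-dimensional
quadrature over log alpha (Gauss-Hermite) and log V_diag (Gauss-Legendre in
CDF space of the truncated distribution).  A Monte-Carlo route over simulated
patients is provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import exp1, ndtr, ndtri, roots_legendre

from . import core
from ._expint import exp1_fast

CELLS_PER_CM3 = 1e9

#: Base parameter values used throughout the synthetic identifiability studies.
SYNTHETIC_BASE = dict(
    log_alpha_pop=math.log(0.005),
    omega_alpha=1.0,
    log_mu_pop=math.log(7e-12),
    omega_mu=2.2,
)

#: Growth parameters calibrated from literature radiographic growth data,
#: used for clinical-like fits (dissemination parameters estimated from data).
CLINICAL_LITERATURE = dict(log_alpha_pop=-3.521, omega_alpha=0.827)


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects, random-effect SDs and model constants.

    ``vdiag_log_mean``/``vdiag_log_sd`` are the log-scale location and scale
    of the diagnosis volume distribution in cm^3 (median exp(3.196) ~ 24.4
    cm^3 by default).
    """

    log_alpha_pop: float = SYNTHETIC_BASE["log_alpha_pop"]
    omega_alpha: float = SYNTHETIC_BASE["omega_alpha"]
    log_mu_pop: float = SYNTHETIC_BASE["log_mu_pop"]
    omega_mu: float = SYNTHETIC_BASE["omega_mu"]
    vdiag_log_mean: float = 3.196
    vdiag_log_sd: float = 1.711
    carrying_capacity: float = core.DEFAULT_CARRYING_CAPACITY
    v_vis: float = field(default_factory=core.visible_volume_cells)

    def __post_init__(self) -> None:
        for name in ("omega_alpha", "omega_mu", "vdiag_log_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.v_vis < self.carrying_capacity:
            raise ValueError("v_vis must be below the carrying capacity")

    @property
    def vdiag_log_mean_cells(self) -> float:
        return self.vdiag_log_mean + math.log(CELLS_PER_CM3)

    def with_updates(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CovariateEffect:
    """Effect of one covariate on log alpha_pop or log mu_pop.

    Forms (x the covariate value, base = log parameter + ``dif``, s = |base|):

    - ``categorical``: reference level unchanged; level k shifted by b_k * s
      (with b_k = b * k when ``minimal_categorical`` is set).
    - ``threshold``: shift b * s for x > c, none otherwise.
    - ``linear``: shift b * s * x + c for all x.
    - ``threshold_linear``: shift b * s * x for x > c, none otherwise.

    ``dif`` is an additive offset of the target log fixed effect used when a
    covariate model is estimated on top of a reference fit.
    """

    covariate: str
    target: str  # "alpha" or "mu"
    form: str  # "categorical" | "threshold" | "linear" | "threshold_linear"
    b: float | None = None
    b_k: dict | None = None
    c: float = 0.0
    dif: float = 0.0
    reference_level: int = 1
    minimal_categorical: bool = False

    def __post_init__(self) -> None:
        if self.target not in ("alpha", "mu"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.form not in ("categorical", "threshold", "linear", "threshold_linear"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "categorical" and self.b_k is None and (
            self.b is None or not self.minimal_categorical
        ):
            raise ValueError("categorical form needs b_k, or b with minimal_categorical")
        if self.form != "categorical" and self.b is None:
            raise ValueError(f"form {self.form!r} needs a coefficient b")

    def shift(self, x, log_base: float):
        """Covariate-induced shift of the log parameter (vectorized over x).

        The returned shift includes ``dif``; the random effect is *not* added
        here (it is added at sampling time).
        """
        x = np.asarray(x)
        base = log_base + self.dif
        scale = abs(base)
        if self.form == "categorical":
            lv = x.astype(int)
            out = np.zeros(lv.shape, dtype=float)
            nonref = lv != self.reference_level
            if self.minimal_categorical:
                out[nonref] = self.b * lv[nonref] * scale
            else:
                bk = np.zeros(out.shape)
                for level, b in self.b_k.items():
                    bk[lv == int(level)] = b
                known = ~nonref
                for level in self.b_k:
                    known |= lv == int(level)
                if not known.all():
                    raise ValueError(
                        f"unknown level(s) {sorted(set(lv[~known].tolist()))} "
                        f"for covariate {self.covariate!r}"
                    )
                out = bk * scale
        elif self.form == "threshold":
            out = np.where(x > self.c, self.b * scale, 0.0)
        elif self.form == "linear":
            out = self.b * scale * x.astype(float) + self.c
        else:  # threshold_linear
            out = np.where(x > self.c, self.b * scale * x.astype(float), 0.0)
        return out + self.dif


@dataclass
class SurvivalCurve:
    """A survival curve conditional on no metastasis at diagnosis."""

    times: np.ndarray
    survival: np.ndarray
    m_diag: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have the same shape")


def apply_covariate_effect(log_base: float, effect: CovariateEffect, x) -> float:
    """Log parameter after applying one covariate effect (no random effect)."""
    return float(log_base + effect.shift(np.asarray([x]), log_base)[0])


def combined_shifts(
    pop: PopulationParams, effects: list[CovariateEffect], covariates
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient shifts (delta_log_alpha, delta_log_mu) from all effects.

    ``covariates`` maps covariate name -> array of per-patient values
    (a pandas DataFrame works).
    """
    if not effects:
        return np.zeros(1), np.zeros(1)
    n = len(np.asarray(covariates[effects[0].covariate]))
    d_alpha = np.zeros(n)
    d_mu = np.zeros(n)
    for eff in effects:
        x = np.asarray(covariates[eff.covariate])
        base = pop.log_alpha_pop if eff.target == "alpha" else pop.log_mu_pop
        if eff.target == "alpha":
            d_alpha += eff.shift(x, base)
        else:
            d_mu += eff.shift(x, base)
    return d_alpha, d_mu


def sample_vdiag_cells(pop: PopulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Diagnosis volumes in cells, lognormal truncated to (1, K)."""
    m, s = pop.vdiag_log_mean_cells, pop.vdiag_log_sd
    hi = math.log(pop.carrying_capacity) * (1.0 - 1e-9)
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(m, s, size=max(n - got, 16))
        ok = draw[(draw > 0.0) & (draw < hi)]
        take = min(len(ok), n - got)
        out[got : got + take] = ok[:take]
        got += take
    return np.exp(out)


def sample_individual_arrays(
    pop: PopulationParams,
    effects: list[CovariateEffect],
    covariates,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of (alpha, mu, v_diag) for n patients."""
    if effects:
        d_alpha, d_mu = combined_shifts(pop, effects, covariates)
        if len(d_alpha) != n:
            raise ValueError("covariate arrays must have length n")
    else:
        d_alpha = d_mu = np.zeros(n)
    log_alpha = pop.log_alpha_pop + d_alpha + rng.normal(0.0, pop.omega_alpha, n)
    log_mu = pop.log_mu_pop + d_mu + rng.normal(0.0, pop.omega_mu, n)
    v_diag = sample_vdiag_cells(pop, n, rng)
    return np.exp(log_alpha), np.exp(log_mu), v_diag


def sample_individual(
    pop: PopulationParams,
    effects: list[CovariateEffect] | None = None,
    covariates: dict | None = None,
    rng_seed=None,
) -> core.IndividualParams:
    """Draw one virtual patient (scalar convenience wrapper)."""
    rng = np.random.default_rng(rng_seed)
    cov = {k: np.asarray([v]) for k, v in (covariates or {}).items()}
    alpha, mu, v_diag = sample_individual_arrays(pop, effects or [], cov, 1, rng)
    growth = core.GompertzParams.from_alpha(float(alpha[0]), pop.carrying_capacity)
    return core.IndividualParams(growth=growth, mu=float(mu[0]), v_diag=float(v_diag[0]))


class SurvivalEvaluator:
    """Semi-analytic evaluation of the population survival function.

    The mu dimension is integrated exactly through the lognormal CDF; the
    diagnosis-volume dimension by Gauss-Legendre in CDF space of the
    truncated log-volume distribution.  The log alpha dimension uses a dense
    fixed grid with Gaussian weights rather than Gauss-Hermite nodes: the
    integrand has a kink in alpha wherever the visibility time tau_vis(alpha)
    crosses a grid time (the cure plateau sets in), which defeats
    high-order global quadrature, while a dense composite rule is robust to
    it.  The fixed grid has a second payoff: shifting log alpha_pop (a
    covariate effect) only changes the weight vector, so curves for many
    alpha shifts reuse one precomputed grid (see :meth:`alpha_profile`).
    """

    def __init__(
        self,
        pop: PopulationParams,
        n_v_nodes: int = 32,
        alpha_step: float = 1.0 / 16.0,
        alpha_span: float = 6.5,
        alpha_shift_range: tuple[float, float] = (0.0, 0.0),
    ):
        self.pop = pop
        self.a = math.log(pop.carrying_capacity)
        om = pop.omega_alpha
        lo = pop.log_alpha_pop - alpha_span * om + min(alpha_shift_range[0], 0.0)
        hi = pop.log_alpha_pop + alpha_span * om + max(alpha_shift_range[1], 0.0)
        n_a = int(math.ceil((hi - lo) / (alpha_step * om))) + 1
        self._lnalpha = np.linspace(lo, hi, n_a)
        # log V_diag nodes: Gauss-Legendre in CDF space of the truncated normal
        m, s = pop.vdiag_log_mean_cells, pop.vdiag_log_sd
        vhi = self.a * (1.0 - 1e-9)
        f_lo, f_hi = ndtr((0.0 - m) / s), ndtr((vhi - m) / s)
        u, wu = roots_legendre(n_v_nodes)
        u01 = 0.5 * (u + 1.0)
        self._lnv = m + s * ndtri(f_lo + u01 * (f_hi - f_lo))
        self._v_w = 0.5 * wu  # renormalized truncated density integrates to 1
        self._e1_a = exp1(self.a)
        self._integral_cache: dict[bytes, np.ndarray] = {}

    def alpha_weights(self, delta_alpha: float = 0.0) -> np.ndarray:
        """Normalized N(log alpha_pop + delta, omega^2) weights on the grid."""
        pop = self.pop
        z = (self._lnalpha - pop.log_alpha_pop - delta_alpha) / pop.omega_alpha
        w = np.exp(-0.5 * z * z)
        return w / w.sum()

    def _neg_ln_integral(self, times: np.ndarray) -> np.ndarray:
        """-ln I(t_diag + min(t, tau_vis) - tau_vis) over (alpha, v, t).

        +inf entries mean "no metastasis can be visible by t" (s <= 0).
        Relapses all occur within tau_vis of diagnosis because seeding stops
        at resection, hence the clamp of t at tau_vis.  Cached per time grid:
        fitting evaluates many parameter shifts on a fixed grid.
        """
        key = times.tobytes()
        cached = self._integral_cache.get(key)
        if cached is not None:
            return cached
        pop = self.pop
        beta = np.exp(self._lnalpha) / self.a  # (n_a,)
        t_diag = -np.log1p(-self._lnv[None, :] / self.a) / beta[:, None]
        tau_vis = -math.log1p(-math.log(pop.v_vis) / self.a) / beta  # (n_a,)
        t_eff = np.minimum(times[None, :], tau_vis[:, None]) - tau_vis[:, None]
        s = t_diag[:, :, None] + t_eff[:, None, :]  # (n_a, n_v, n_t)
        pos = s > 0
        u = self.a * np.exp(-beta[:, None, None] * np.where(pos, s, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            i_val = (
                pop.carrying_capacity
                / beta[:, None, None]
                * (exp1_fast(u) - self._e1_a)
            )
            neg_ln_i = np.where(
                pos & (i_val > 0), -np.log(np.maximum(i_val, 1e-300)), np.inf
            )
        if len(self._integral_cache) > 16:
            self._integral_cache.clear()
        self._integral_cache[key] = neg_ln_i
        return neg_ln_i

    def alpha_profile(
        self, times: np.ndarray, delta_mu: float = 0.0
    ) -> np.ndarray:
        """Matrix R with R[i, t] = P[no visible met by t | log alpha = grid_i].

        G(t; delta_alpha) = alpha_weights(delta_alpha) @ R, so survival curves
        for arbitrary shifts of log alpha_pop cost one dot product each.
        """
        pop = self.pop
        times = np.asarray(times, dtype=float)
        neg_ln_i = self._neg_ln_integral(times)
        z = (neg_ln_i - (pop.log_mu_pop + delta_mu)) / pop.omega_mu
        return np.einsum("avt,v->at", ndtr(z), self._v_w)

    def mu_profile(
        self, times: np.ndarray, delta_mu: np.ndarray, delta_alpha: float = 0.0
    ) -> np.ndarray:
        """G(t; delta_mu) for a vector of log mu_pop shifts, shape (n_mu, n_t)."""
        pop = self.pop
        times = np.asarray(times, dtype=float)
        neg_ln_i = self._neg_ln_integral(times)
        w2 = self.alpha_weights(delta_alpha)[:, None] * self._v_w[None, :]
        dmu = np.atleast_1d(np.asarray(delta_mu, dtype=float))
        out = np.empty((len(dmu), len(times)))
        for k, d in enumerate(dmu):
            z = (neg_ln_i - (pop.log_mu_pop + d)) / pop.omega_mu
            out[k] = np.einsum("av,avt->t", w2, ndtr(z))
        return out

    def unconditional(
        self,
        times: np.ndarray,
        delta_alpha: float = 0.0,
        delta_mu: np.ndarray | float = 0.0,
    ) -> np.ndarray:
        """G(t) = P[no visible metastasis by t since diagnosis] (unconditional).

        ``delta_alpha`` is a scalar shift of log alpha_pop; ``delta_mu`` may
        be a vector of shifts of log mu_pop, in which case the result has
        shape (len(delta_mu), len(times)).  m_diag = 1 - G(0).
        """
        return self.mu_profile(times, delta_mu, delta_alpha)

    def curve(
        self,
        times: np.ndarray,
        delta_alpha: float = 0.0,
        delta_mu: float = 0.0,
    ) -> SurvivalCurve:
        """Conditional survival curve S(t) = G(t)/G(0) plus m_diag."""
        times = np.asarray(times, dtype=float)
        grid = np.concatenate(([0.0], times))
        g = self.unconditional(grid, delta_alpha, delta_mu)[0]
        g0 = g[0]
        if g0 <= 0:
            raise ValueError("all patients metastatic at diagnosis (G(0) = 0)")
        return SurvivalCurve(times=times, survival=g[1:] / g0, m_diag=1.0 - g0)


def _design_shifts(pop, effects, covariate_design):
    if not effects or covariate_design is None:
        return np.zeros(1), np.zeros(1)
    return combined_shifts(pop, effects, covariate_design)


def model_survival(
    pop: PopulationParams,
    effects: list[CovariateEffect] | None = None,
    covariate_design=None,
    time_grid: np.ndarray | None = None,
    evaluator: SurvivalEvaluator | None = None,
) -> SurvivalCurve:
    """Population DMFS curve S(t), conditional on no metastasis at diagnosis.

    ``covariate_design`` maps covariate names to per-patient values; the
    curve averages the conditional model over those patients.  Deterministic
    for fixed inputs.
    """
    if time_grid is None or len(np.asarray(time_grid)) == 0:
        raise ValueError("time_grid must be a nonempty array of times")
    times = np.asarray(time_grid, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("time_grid must be nonnegative and nondecreasing")
    d_alpha, d_mu = _design_shifts(pop, effects or [], covariate_design)
    ev = evaluator or SurvivalEvaluator(
        pop, alpha_shift_range=(float(d_alpha.min()), float(d_alpha.max()))
    )
    grid = np.concatenate(([0.0], times))
    pairs = np.column_stack([d_alpha, d_mu])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    weights = counts / counts.sum()
    g = np.zeros(len(grid))
    uniq_da = np.unique(uniq[:, 0])
    for da in uniq_da:
        sel = uniq[:, 0] == da
        gs = ev.unconditional(grid, delta_alpha=da, delta_mu=uniq[sel, 1])
        g += weights[sel] @ gs
    g0 = g[0]
    if g0 <= 0:
        raise ValueError("all patients metastatic at diagnosis (G(0) = 0)")
    return SurvivalCurve(times=times, survival=g[1:] / g0, m_diag=1.0 - g0)


def monte_carlo_survival(
    pop: PopulationParams,
    effects: list[CovariateEffect] | None = None,
    covariate_design=None,
    time_grid: np.ndarray | None = None,
    n: int = 100_000,
    rng_seed=None,
) -> SurvivalCurve:
    """Monte-Carlo estimate of the DMFS curve by simulating n patients.

    Independent cross-check of :func:`model_survival`; survival is the
    fraction of patients without metastasis at diagnosis whose TTR exceeds t.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    times = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(rng_seed)
    effects = effects or []
    if effects:
        if covariate_design is None:
            raise ValueError("covariate effects require a covariate_design")
        cov = {k: np.asarray(v) for k, v in dict(covariate_design).items()}
        m = len(next(iter(cov.values())))
        if m != n:
            idx = rng.integers(0, m, size=n)
            cov = {k: v[idx] for k, v in cov.items()}
    else:
        cov = {}
    alpha, mu, v_diag = sample_individual_arrays(pop, effects, cov, n, rng)
    ttr, mets = core.ttr_vectorized(alpha, mu, v_diag, pop.v_vis, pop.carrying_capacity)
    ok = ~mets
    if not ok.any():
        raise ValueError("all simulated patients metastatic at diagnosis")
    surv = (ttr[ok][None, :] > times[:, None]).mean(axis=1)
    return SurvivalCurve(times=times, survival=surv, m_diag=float(mets.mean()))
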