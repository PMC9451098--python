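"""Single-patient kinetics of primary tumor growth and metastatic relapse.

The primary tumor follows Gompertz growth from one cell,

    V(t) = exp((alpha/beta) * (1 - exp(-beta*t))),

with ``alpha`` the specific growth rate at V = 1 cell (day^-1), ``beta`` the
exponential decay rate of the specific growth rate, and carrying capacity
K = exp(alpha/beta) fixed (1e12 cells by default).  Cells disseminate at rate
d(t) = mu * V(t) (per-cell per-day probability ``mu``), so the expected number
of metastases seeded by time t is N(t) = mu * I(t) with I(t) the integral of
V.  A metastasis becomes visible ``tau_vis`` days after seeding (the time for
one cell to reach the visibility volume, a 5 mm sphere by default), and the
primary is diagnosed (and resected) when it reaches ``v_diag`` cells.  The
time to distant relapse (TTR) measured from diagnosis is the first time a
metastasis becomes visible; patients whose expected seeded count at diagnosis
is below one never relapse (TTR = +infinity).

All quantities here are deterministic closed forms: I(t) is expressed through
the exponential integral E1 and inverted exactly for first-passage times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1

from ._expint import exp1_fast, inv_exp1

DEFAULT_CARRYING_CAPACITY = 1e12
DEFAULT_VIS_DIAMETER_MM = 5.0
DEFAULT_CELLS_PER_MM3 = 1e6


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth parameters for one tumor.

    ``alpha`` and ``beta`` are linked to the carrying capacity by
    K = exp(alpha/beta); use :meth:`from_alpha` to derive beta from a fixed K.
    """

    alpha: float
    beta: float
    carrying_capacity: float = DEFAULT_CARRYING_CAPACITY

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.carrying_capacity > 1:
            raise ValueError("carrying_capacity must be > 1")

    @classmethod
    def from_alpha(
        cls, alpha: float, carrying_capacity: float = DEFAULT_CARRYING_CAPACITY
    ) -> "GompertzParams":
        return cls(alpha, beta_from_alpha(alpha, carrying_capacity), carrying_capacity)

    @property
    def log_k(self) -> float:
        """alpha/beta, the natural log of the asymptotic cell count."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class IndividualParams:
    """One virtual patient: growth kinetics, dissemination, diagnosis size."""

    growth: GompertzParams
    mu: float
    v_diag: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 1 < self.v_diag < self.growth.carrying_capacity:
            raise ValueError(
                "v_diag must satisfy 1 < v_diag < carrying_capacity, "
                f"got {self.v_diag}"
            )


@dataclass(frozen=True)
class TTROutcome:
    """Relapse outcome for one patient.

    ``ttr`` is days since diagnosis until the first metastasis reaches the
    visibility threshold; +infinity when no metastasis was seeded before
    diagnosis, and 0.0 (with ``mets_at_diagnosis`` set) when a metastasis is
    already visible at diagnosis.
    """

    ttr: float
    mets_at_diagnosis: bool
    t_diag: float
    tau_vis: float


def beta_from_alpha(alpha: float, carrying_capacity: float = DEFAULT_CARRYING_CAPACITY) -> float:
    """Decay rate beta such that exp(alpha/beta) equals the carrying capacity."""
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not carrying_capacity > 1:
        raise ValueError(f"carrying_capacity must be > 1, got {carrying_capacity}")
    return alpha / math.log(carrying_capacity)


def gompertz_volume(t, growth: GompertzParams):
    """Tumor cell count V(t) after t days of growth from a single cell."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    a = growth.log_k
    out = np.exp(a * -np.expm1(-growth.beta * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def time_to_volume(v, growth: GompertzParams):
    """Days for the tumor to grow from one cell to ``v`` cells (inverse of V)."""
    v_arr = np.asarray(v, dtype=float)
    a = growth.log_k
    if np.any(v_arr < 1):
        raise ValueError("v must be >= 1")
    if np.any(np.log(v_arr) >= a):
        raise ValueError("v must be below the carrying capacity (finite time)")
    out = -np.log1p(-np.log(v_arr) / a) / growth.beta
    return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


def visible_volume_cells(
    diameter_mm: float = DEFAULT_VIS_DIAMETER_MM,
    cells_per_mm3: float = DEFAULT_CELLS_PER_MM3,
) -> float:
    """Cell count of a sphere of the given diameter (1 mm^3 = 1e6 cells)."""
    if not diameter_mm > 0:
        raise ValueError("diameter must be > 0")
    return math.pi / 6.0 * diameter_mm**3 * cells_per_mm3


def cumulative_dissemination_integral(t, growth: GompertzParams, *, fast: bool = False):
    """I(t) = integral_0^t V(s) ds, so that N(t) = mu * I(t).

    Closed form (K/beta) * (E1(a e^{-beta t}) - E1(a)) with a = ln K.
    Returns 0 for t <= 0 (no seeding before the first cell exists).
    """
    t_arr = np.asarray(t, dtype=float)
    a = growth.log_k
    beta = growth.beta
    e1 = exp1_fast if fast else exp1
    arg = a * np.exp(-beta * np.maximum(t_arr, 0.0))
    out = np.exp(a) / beta * (e1(arg) - e1(np.asarray(a, dtype=float)))
    out = np.where(t_arr <= 0, 0.0, np.maximum(out, 0.0))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def dissemination_inverse(i_target, growth: GompertzParams):
    """Time s at which I(s) reaches ``i_target`` (exact inverse via E1)."""
    i_arr = np.asarray(i_target, dtype=float)
    a = growth.log_k
    beta = growth.beta
    y = beta * i_arr * np.exp(-a) + exp1(a)
    u = inv_exp1(y)
    out = np.log(a / u) / beta
    return float(out) if np.isscalar(i_target) or i_arr.ndim == 0 else out


def individual_ttr(p: IndividualParams, v_vis: float | None = None) -> TTROutcome:
    """Time to distant relapse for one patient.

    A relapse happens when the expected visible-metastasis count
    N_vis(t) = mu * I(t - tau_vis) first reaches 1 after diagnosis; if fewer
    than one metastasis was seeded by diagnosis (mu * I(t_diag) < 1) the
    patient never relapses.
    """
    if v_vis is None:
        v_vis = visible_volume_cells()
    g = p.growth
    if not v_vis < g.carrying_capacity:
        raise ValueError("v_vis must be below the carrying capacity")
    t_diag = time_to_volume(p.v_diag, g)
    tau_vis = time_to_volume(v_vis, g)
    if p.mu == 0.0:
        return TTROutcome(math.inf, False, t_diag, tau_vis)
    n_at_diag = p.mu * cumulative_dissemination_integral(t_diag, g)
    mets_at_diag = (
        p.mu * cumulative_dissemination_integral(t_diag - tau_vis, g) >= 1.0
    )
    if n_at_diag < 1.0:
        return TTROutcome(math.inf, False, t_diag, tau_vis)
    s_star = dissemination_inverse(1.0 / p.mu, g)
    ttr = s_star - t_diag + tau_vis
    if mets_at_diag:
        return TTROutcome(0.0, True, t_diag, tau_vis)
    return TTROutcome(max(ttr, 0.0), False, t_diag, tau_vis)


def ttr_vectorized(
    alpha: np.ndarray,
    mu: np.ndarray,
    v_diag: np.ndarray,
    v_vis: float,
    carrying_capacity: float = DEFAULT_CARRYING_CAPACITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Relapse times for arrays of patients.

    Returns ``(ttr, mets_at_diagnosis)``; ttr is +inf for cured patients and
    0.0 for patients metastatic at diagnosis.  Identical model as
    :func:`individual_ttr`, evaluated with the fast E1 table.
    """
    alpha = np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    v_diag = np.asarray(v_diag, dtype=float)
    a = math.log(carrying_capacity)
    beta = alpha / a
    ln_vd = np.log(v_diag)
    ln_vv = math.log(v_vis)
    if np.any(ln_vd >= a) or ln_vv >= a:
        raise ValueError("diagnosis/visibility volumes must be below K")
    t_diag = -np.log1p(-ln_vd / a) / beta
    tau_vis = -np.log1p(-ln_vv / a) / beta
    e1_a = exp1(a)
    k_over_beta = carrying_capacity / beta

    def integral(s):
        val = k_over_beta * (exp1_fast(a * np.exp(-beta * np.maximum(s, 0.0))) - e1_a)
        return np.where(s <= 0, 0.0, np.maximum(val, 0.0))

    with np.errstate(divide="ignore"):
        n_diag = mu * integral(t_diag)
        mets = mu * integral(t_diag - tau_vis) >= 1.0
        cured = n_diag < 1.0
        relapse = ~cured & ~mets
    ttr = np.full(alpha.shape, np.inf)
    ttr[mets] = 0.0
    if np.any(relapse):
        y = (beta[relapse] / (mu[relapse] * carrying_capacity)) + e1_a
        u = inv_exp1(y)
        s_star = np.log(a / u) / beta[relapse]
        ttr[relapse] = np.maximum(
            s_star - t_diag[relapse] + tau_vis[relapse], 0.0
        )
    return ttr, mets
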