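"""Literature-based parameter derivation.

Radiographic growth studies report kidney tumors growing approximately
linearly in diameter over the interval between a normal image and diagnosis.
Given an initial diameter d0 (mm or any consistent length unit), a linear
diameter growth rate alpha_l (same unit per day) and the elapsed time t
(days), the Gompertz specific growth rate at one cell that reproduces the
same diameter change over t days (with carrying capacity K) is

    alpha = -(ln K / t) * ln(1 - 3 * ln((d0 + alpha_l t) / d0) / ln K).

The factor 3 converts the diameter ratio to a cell-count (volume) ratio, and
the derivation assumes macroscopic growth started shortly before the normal
image, i.e. the tumor is ~1 cell at the start of the observation window: the
returned alpha is exactly the one whose one-cell Gompertz trajectory
accumulates the observed volume fold-change ((d0 + alpha_l t)/d0)^3 over t
days.
Population summaries of per-patient alphas feed the default growth priors
(log alpha_pop = -3.521, omega_alpha = 0.827 with the published cohort
distributions).
"""

from __future__ import annotations

import math

import numpy as np


def alpha_from_linear_growth(
    d0: float, alpha_l: float, t: float, carrying_capacity: float = 1e12
):
    """Gompertz alpha matching linear diameter growth d0 -> d0 + alpha_l*t.

    Vectorized over the three data arguments.  Raises when the implied
    volume change is too fast for a Gompertz tumor with this carrying
    capacity (argument of the outer log nonpositive).
    """
    d0 = np.asarray(d0, dtype=float)
    alpha_l = np.asarray(alpha_l, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(d0 <= 0):
        raise ValueError("d0 must be > 0")
    if np.any(t_arr <= 0):
        raise ValueError("t must be > 0")
    if np.any(alpha_l < 0):
        raise ValueError("alpha_l must be >= 0")
    ln_k = math.log(carrying_capacity)
    inner = 1.0 - 3.0 * np.log((d0 + alpha_l * t_arr) / d0) / ln_k
    if np.any(inner <= 0):
        raise ValueError(
            "growth too fast for Gompertz kinetics with this carrying capacity"
        )
    out = -(ln_k / t_arr) * np.log(inner)
    return float(out) if out.ndim == 0 else out


def fit_lognormal_summary(samples) -> dict:
    """Lognormal MLE on the log scale with standard-error-based RSEs.

    Returns ``log_mean``, ``log_sd`` (MLE of location and scale of
    log(samples)) and their relative standard errors ``rse_log_mean``,
    ``rse_log_sd`` (SE / estimate, normal theory: SE(mean) = s/sqrt(n),
    SE(sd) = s/sqrt(2n)).
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(x <= 0):
        raise ValueError("samples must be > 0")
    logs = np.log(x)
    n = len(logs)
    m = float(np.mean(logs))
    s = float(np.std(logs))  # MLE (ddof=0)
    se_m = s / math.sqrt(n)
    se_s = s / math.sqrt(2 * n)
    return {
        "log_mean": m,
        "log_sd": s,
        "rse_log_mean": abs(se_m / m) if m != 0 else math.inf,
        "rse_log_sd": se_s / s,
    }
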