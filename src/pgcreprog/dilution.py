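"""Replication-dilution model of CpG dyad methylation states.

A CpG dyad is fully methylated (M, both strands), hemimethylated (H, one
strand), or unmethylated (U).  Semiconservative replication hands each
daughter one parental strand; maintenance methyltransferase restores the
nascent strand opposite a methylated template with probability ``p_m``,
de novo activity methylates a nascent strand opposite an unmethylated
template with probability ``p_d``, and active removal strips each
methylated cytosine independently with probability ``p_a`` per division.
With maintenance off (p_m = 0) and no other activity, the methylated-
cytosine fraction f = f_M + f_H/2 halves exactly every division — the
passive-dilution signature of germline demethylation.

The population expectation over both daughters makes one division a fixed
3×3 stochastic map of the (M, H, U) distribution; ``fit`` recovers the
rates from observed state counts at successive timepoints by multinomial
maximum likelihood (grid search plus local refinement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import ConfigurationError


@dataclass(frozen=True)
class DyadDynamicsParams:
    """Maintenance efficiency, de novo rate, active-removal rate."""

    p_maintenance: float
    p_denovo: float = 0.0
    p_active: float = 0.0

    def __post_init__(self):
        for name, p in (
            ("p_maintenance", self.p_maintenance),
            ("p_denovo", self.p_denovo),
            ("p_active", self.p_active),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} outside [0, 1]: {p}")


def _as_dist(dist) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.shape != (3,):
        raise ConfigurationError("distribution must have three entries (M, H, U)")
    if (d < -1e-12).any() or abs(d.sum() - 1.0) > 1e-9:
        raise ConfigurationError("distribution must be a probability simplex point")
    return d


def _step_arrays(fM, fH, fU, pm, pdn, pa):
    """One division, vectorised over parameter/state arrays.

    Replication with maintenance/de novo first (expectation over both
    daughters), then active removal of each methylated cytosine.
    """
    # replication phase
    M = fM * pm + fH * 0.5 * pm
    H = fM * (1.0 - pm) + fH * (0.5 * (1.0 - pm) + 0.5 * pdn) + fU * pdn
    U = fH * 0.5 * (1.0 - pdn) + fU * (1.0 - pdn)
    # active removal: M loses 0/1/2 meCs, H loses 0/1
    M2 = M * (1.0 - pa) ** 2
    H2 = M * 2.0 * pa * (1.0 - pa) + H * (1.0 - pa)
    U2 = U + M * pa**2 + H * pa
    total = M2 + H2 + U2
    return M2 / total, H2 / total, U2 / total


def step(dist, params: DyadDynamicsParams) -> np.ndarray:
    """Apply one cell division to an (M, H, U) distribution."""
    fM, fH, fU = _as_dist(dist)
    return np.array(
        _step_arrays(
            fM, fH, fU, params.p_maintenance, params.p_denovo, params.p_active
        )
    )


def trajectory(dist, params: DyadDynamicsParams, n_steps: int) -> np.ndarray:
    """Iterated divisions; row 0 is the initial distribution unchanged."""
    if n_steps < 0:
        raise ConfigurationError("n_steps must be >= 0")
    out = np.empty((n_steps + 1, 3))
    out[0] = _as_dist(dist)
    for i in range(n_steps):
        out[i + 1] = step(out[i], params)
    return out


def methylated_fraction(dist) -> float:
    """Fraction of methylated cytosines: f_M + f_H / 2."""
    d = _as_dist(dist)
    return float(d[0] + 0.5 * d[1])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _predict_batch(initial, divisions, pm, pdn, pa):
    """Predicted distributions at each later timepoint for parameter arrays."""
    fM = np.full(pm.shape, initial[0])
    fH = np.full(pm.shape, initial[1])
    fU = np.full(pm.shape, initial[2])
    preds = []
    for d in divisions:
        for _ in range(int(d)):
            fM, fH, fU = _step_arrays(fM, fH, fU, pm, pdn, pa)
        preds.append((fM.copy(), fH.copy(), fU.copy()))
    return preds


def _loglik_batch(counts, preds):
    """Multinomial log-likelihood (with coefficient) per parameter vector."""
    ll = 0.0
    for c, (fM, fH, fU) in zip(counts[1:], preds):
        n = c.sum()
        const = gammaln(n + 1) - gammaln(c + 1).sum()
        term = const
        for ci, p in zip(c, (fM, fH, fU)):
            if ci > 0:
                with np.errstate(divide="ignore"):
                    term = term + ci * np.log(p)
        ll = ll + term
    return ll


@dataclass
class FitResult:
    params: DyadDynamicsParams
    log_likelihood: float
    pm_profile: pd.DataFrame  # likelihood surface slice along p_maintenance
    grid_step: float


def fit(
    counts,
    divisions,
    grid_step: float = 0.02,
    refine: bool = True,
    fixed: dict | None = None,
) -> FitResult:
    """Fit dyad dynamics to (M, H, U) counts observed at timepoints.

    ``counts`` is a (T, 3) array of dyad-state counts, T >= 2;
    ``divisions`` the T−1 cell divisions between consecutive timepoints.
    The first timepoint's empirical distribution is the initial condition;
    later timepoints enter the multinomial likelihood.  A full grid over
    the free parameters (default step 0.02) is evaluated vectorised, then
    the optimum is polished by bounded Nelder–Mead.  ``fixed`` may pin any
    of ``p_maintenance``/``p_denovo``/``p_active``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ConfigurationError("counts must be a (T, 3) array of M, H, U counts")
    if counts.shape[0] < 2:
        raise ConfigurationError("at least two timepoints are required")
    if (counts < 0).any():
        raise ConfigurationError("negative counts")
    if (counts.sum(axis=1) == 0).any():
        raise ConfigurationError("a timepoint has zero total counts")
    divisions = np.asarray(divisions, dtype=int)
    if divisions.shape != (counts.shape[0] - 1,):
        raise ConfigurationError("need one divisions entry per timepoint interval")
    if (divisions < 0).any():
        raise ConfigurationError("divisions must be >= 0")
    fixed = dict(fixed or {})
    names = ("p_maintenance", "p_denovo", "p_active")
    unknown = set(fixed) - set(names)
    if unknown:
        raise ConfigurationError(f"unknown fixed parameters: {sorted(unknown)}")

    initial = counts[0] / counts[0].sum()
    axis = np.arange(0.0, 1.0 + 1e-12, grid_step)
    grids = [
        np.asarray([fixed[name]], dtype=float) if name in fixed else axis
        for name in names
    ]
    pm, pdn, pa = (g.ravel() for g in np.meshgrid(*grids, indexing="ij"))
    preds = _predict_batch(initial, divisions, pm, pdn, pa)
    ll = _loglik_batch(counts, preds)
    ll = np.asarray(ll, dtype=float)
    best = int(np.nanargmax(ll))
    x0 = np.array([pm[best], pdn[best], pa[best]])
    best_ll = float(ll[best])

    # profile of the likelihood along p_m (max over the other two params)
    prof = pd.DataFrame({"p_maintenance": pm, "log_likelihood": ll})
    pm_profile = (
        prof.groupby("p_maintenance", sort=True)["log_likelihood"]
        .max()
        .reset_index()
    )

    if refine:
        free = [i for i, name in enumerate(names) if name not in fixed]
        if free:

            def neg_ll(x):
                full = x0.copy()
                full[free] = np.clip(x, 0.0, 1.0)
                p = _predict_batch(
                    initial,
                    divisions,
                    np.array([full[0]]),
                    np.array([full[1]]),
                    np.array([full[2]]),
                )
                return -float(_loglik_batch(counts, p)[0])

            res = minimize(
                neg_ll,
                x0[free],
                method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * len(free),
                options={"xatol": 1e-5, "fatol": 1e-8},
            )
            if np.isfinite(res.fun) and -res.fun >= best_ll:
                x0[free] = np.clip(res.x, 0.0, 1.0)
                best_ll = -float(res.fun)

    params = DyadDynamicsParams(*[float(v) for v in x0])
    return FitResult(params, best_ll, pm_profile, grid_step)
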