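"""Monod kinetics: nonlinear fitting, derived competition traits, contrasts.

The Monod model relates specific growth rate to the external concentration S
of the limiting nutrient,

    mu(S) = mu_max * S / (S + K_s)

with mu_max the maximum specific growth rate (day^-1) and K_s the
half-saturation constant (μg/l of the limiting element).  Two derived traits
summarize competitive ability:

* the initial slope mu_max / K_s with K_s expressed in μM — the affinity of
  the Monod curve near zero substrate (day^-1 μM^-1); and
* R* = K_s * D / (mu_max - D), the substrate concentration at which growth
  balances a loss (dilution) rate D; in resource-competition theory the
  strain with the lowest R* excludes its competitors at equilibrium.

Pairwise parameter contrasts across strain x microbiome-state groups use
Welch-style t statistics on the fitted parameters with Benjamini–Hochberg
control of the false discovery rate within each parameter x nutrient family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError, InsufficientDataError, UndefinedRStarError

__all__ = [
    "MOLAR_MASS",
    "MonodFit",
    "monod_mu",
    "fit_monod",
    "fit_monod_groups",
    "initial_slope",
    "r_star",
    "contrast_parameters",
    "summary_table",
]

#: Molar masses of the limiting elements, g/mol (element basis: the
#: concentrations are μg/l of N or of P, not of nitrate or phosphate).
MOLAR_MASS: dict[str, float] = {"C": 12.011, "N": 14.007, "P": 30.974}

_FTOL = 1e-10
_MAX_NFEV = 500
_LOG_FLOOR = np.log(1e-9)  # lower bound on both parameters via log-space clip


def monod_mu(S, mu_max: float, k_s: float):
    """Monod growth rate mu_max * S / (S + K_s); vectorized over ``S``."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DomainError("substrate concentration S must be >= 0")
    if mu_max <= 0 or k_s <= 0:
        raise DomainError("mu_max and K_s must be positive")
    out = mu_max * S / (S + k_s)
    return float(out) if out.ndim == 0 else out


@dataclass
class MonodFit:
    """Fitted Monod parameters for one strain x state x nutrient group."""

    strain: str
    state: str
    nutrient: str
    mu_max: float
    mu_max_se: float
    k_s: float
    k_s_se: float
    covariance: np.ndarray  # 2x2, order (mu_max, k_s)
    rss: float
    n_points: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def group(self) -> tuple[str, str, str]:
        return (self.strain, self.state, self.nutrient)

    def label(self) -> str:
        return f"{self.state} {self.strain}"


def _default_init(S: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Deterministic starting values: mu_max0 = max observed rate; K_s0 =
    smallest S at which the rate reaches half of mu_max0 (median S fallback)."""
    mu_max0 = max(float(np.max(mu)), 1e-6)
    half = mu_max0 / 2.0
    above = S[mu >= half]
    k_s0 = float(np.min(above[above > 0])) if np.any(above > 0) else float(np.median(S))
    if k_s0 <= 0:
        k_s0 = max(float(np.median(S)), 1e-6)
    return mu_max0, k_s0


def fit_monod(
    S: Sequence[float],
    mu_hat: Sequence[float],
    se: Sequence[float] | None = None,
    init: tuple[float, float] | None = None,
    weighting: str = "none",
    strain: str = "",
    state: str = "",
    nutrient: str = "",
) -> MonodFit:
    """Least-squares Monod fit of growth rate against substrate concentration.

    The fit is unweighted by default; per-point standard errors may be used
    for inverse-variance weighting with ``weighting="inverse_variance"``.
    Both parameters are kept positive via a log reparameterization.  The
    parameter covariance is the Jacobian-based (Gauss–Newton) covariance at
    the optimum scaled by the residual variance RSS/(n-2).
    """
    S = np.asarray(S, dtype=float)
    mu = np.asarray(mu_hat, dtype=float)
    if S.size != mu.size:
        raise ValueError("S and mu_hat must have equal length")
    if S.size < 3:
        raise InsufficientDataError("Monod fit needs >= 3 points")
    if np.unique(S).size < 2:
        raise InsufficientDataError("Monod fit needs >= 2 distinct S values")
    if np.any(S < 0):
        raise DomainError("substrate concentrations must be >= 0")

    flags: list[str] = []
    if np.ptp(mu) < 1e-12:
        flags.append("flat_response")
        warnings.warn(
            "growth rates are constant across S; K_s is unidentifiable",
            stacklevel=2,
        )

    if weighting == "inverse_variance":
        if se is None:
            raise ValueError("inverse_variance weighting requires per-point SEs")
        se_arr = np.asarray(se, float)
        w = 1.0 / np.clip(se_arr, np.max(se_arr) * 1e-3 + 1e-12, None)
    elif weighting == "none":
        w = np.ones_like(mu)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    mu_max0, k_s0 = init if init is not None else _default_init(S, mu)
    x0 = np.log([max(mu_max0, 1e-9), max(k_s0, 1e-9)])

    def resid(x: np.ndarray) -> np.ndarray:
        m, k = np.exp(np.clip(x, _LOG_FLOOR, 50.0))
        return w * (mu - m * S / (S + k))

    res = optimize.least_squares(
        resid, x0, method="trf", ftol=_FTOL, xtol=1e-12, gtol=1e-12,
        max_nfev=_MAX_NFEV,
    )
    converged = bool(res.status > 0)
    if not converged:
        warnings.warn("Monod optimizer did not converge", stacklevel=2)
    m_hat, k_hat = np.exp(np.clip(res.x, _LOG_FLOOR, 50.0))

    # Jacobian of the model in natural parameters at the optimum
    denom = S + k_hat
    J = np.column_stack([w * S / denom, w * (-m_hat * S / denom**2)])
    r = resid(res.x)
    rss = float(np.sum(r**2))
    dof = S.size - 2
    s2 = rss / dof if dof > 0 else np.nan
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
        flags.append("singular_jacobian")
    # numerical symmetrization
    cov = (cov + cov.T) / 2.0
    se_m = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_k = float(np.sqrt(max(cov[1, 1], 0.0)))

    return MonodFit(
        strain=strain, state=state, nutrient=nutrient,
        mu_max=float(m_hat), mu_max_se=se_m, k_s=float(k_hat), k_s_se=se_k,
        covariance=cov, rss=rss, n_points=int(S.size),
        converged=converged, flags=flags,
    )


def fit_monod_groups(
    growth: pd.DataFrame, weighting: str = "none"
) -> list[MonodFit]:
    """Fit the Monod model to every (strain, state, nutrient) group of a
    growth-estimate table (columns concentration, mu_hat, se)."""
    fits = []
    for (strain, state, nutrient), sub in growth.groupby(
        ["strain", "state", "nutrient"], sort=True
    ):
        fits.append(
            fit_monod(
                sub["concentration"], sub["mu_hat"], se=sub["se"],
                weighting=weighting, strain=strain, state=state,
                nutrient=nutrient,
            )
        )
    return fits


def initial_slope(mu_max: float, k_s: float, molar_mass: float) -> float:
    """Affinity mu_max / K_s with K_s converted from μg/l to μM.

    ``molar_mass`` is the element's molar mass in g/mol, so
    K_s[μg/l] / molar_mass[g/mol] is μmol/l and the result is day^-1 μM^-1.
    Equals the derivative d mu/dS at S = 0 expressed per μM.
    """
    if molar_mass <= 0:
        raise DomainError("molar mass must be positive")
    if k_s <= 0:
        raise DomainError("K_s must be positive")
    return mu_max / (k_s / molar_mass)


def r_star(mu_max: float, k_s: float, D: float = 0.2) -> float:
    """Break-even substrate concentration R* = K_s D / (mu_max - D) in μg/l.

    Solves mu(S) = D for S.  Undefined when mu_max <= D: the strain washes
    out at that dilution rate.
    """
    if D <= 0:
        raise DomainError("dilution rate D must be positive")
    if k_s <= 0:
        raise DomainError("K_s must be positive")
    if mu_max <= D:
        raise UndefinedRStarError(
            f"mu_max={mu_max:.4g} <= D={D:.4g}: strain cannot persist"
        )
    return k_s * D / (mu_max - D)


_PARAM_ATTRS = {"mu_max": ("mu_max", "mu_max_se"), "k_s": ("k_s", "k_s_se")}


def contrast_parameters(
    fits: Sequence[MonodFit],
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    parameters: Sequence[str] = ("mu_max", "k_s"),
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Pairwise t-tests on fitted parameters with FDR control.

    ``pairs`` lists ((strain, state), (strain, state)) comparisons; by
    default every within-nutrient pair of groups is compared.  For each
    parameter the difference of estimates is tested with
    t = diff / sqrt(se1^2 + se2^2), df = n1 + n2 - 4 (two parameters
    estimated per group), two-sided p.  P-values are Benjamini–Hochberg
    adjusted within one family per parameter x nutrient.
    """
    by_group = {(f.strain, f.state, f.nutrient): f for f in fits}
    nutrients = sorted({f.nutrient for f in fits})
    rows = []
    for nutrient in nutrients:
        groups = sorted(
            (f.strain, f.state) for f in fits if f.nutrient == nutrient
        )
        if pairs is None:
            use_pairs = [
                (groups[i], groups[j])
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            ]
        else:
            use_pairs = [p for p in pairs if p[0] in groups and p[1] in groups]
        for (g1, g2) in use_pairs:
            f1 = by_group[(g1[0], g1[1], nutrient)]
            f2 = by_group[(g2[0], g2[1], nutrient)]
            for param in parameters:
                attr, se_attr = _PARAM_ATTRS[param]
                diff = getattr(f1, attr) - getattr(f2, attr)
                se_diff = float(
                    np.hypot(getattr(f1, se_attr), getattr(f2, se_attr))
                )
                df = f1.n_points + f2.n_points - 4
                if se_diff == 0:
                    if diff != 0:
                        warnings.warn(
                            "zero SEs with nonzero difference: infinite t",
                            stacklevel=2,
                        )
                        tstat, p = np.inf * np.sign(diff), 0.0
                    else:
                        tstat, p = 0.0, 1.0
                else:
                    tstat = diff / se_diff
                    p = 2.0 * float(stats.t.sf(abs(tstat), df))
                rows.append(
                    dict(
                        parameter=param, nutrient=nutrient,
                        group_1=f"{g1[1]} {g1[0]}", group_2=f"{g2[1]} {g2[0]}",
                        estimate_diff=diff, se_diff=se_diff, t=float(tstat),
                        df=int(df), p=float(p),
                        family=f"{param}:{nutrient}",
                    )
                )
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adjusted"] = []
        return out
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_adjusted"] = multipletests(
            out.loc[idx, "p"].to_numpy(), method=fdr_method
        )[1]
    return out


def summary_table(
    fits: Sequence[MonodFit],
    dilution_rate: float = 0.2,
    molar_mass: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Trait summary per group: Monod parameters with SEs, initial slope,
    and R* at the stated dilution rate (NaN when mu_max <= D)."""
    mm = dict(MOLAR_MASS)
    if molar_mass:
        mm.update(molar_mass)
    rows = []
    for f in sorted(fits, key=lambda f: (f.nutrient, f.strain, f.state)):
        try:
            rs = r_star(f.mu_max, f.k_s, D=dilution_rate)
        except UndefinedRStarError:
            rs = np.nan
        rows.append(
            dict(
                strain=f.strain, state=f.state, nutrient=f.nutrient,
                mu_max=f.mu_max, mu_max_se=f.mu_max_se,
                k_s=f.k_s, k_s_se=f.k_s_se,
                initial_slope=initial_slope(f.mu_max, f.k_s, mm[f.nutrient]),
                r_star=rs, n_points=f.n_points, converged=f.converged,
            )
        )
    return pd.DataFrame(rows)
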