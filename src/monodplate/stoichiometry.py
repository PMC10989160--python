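"""Cellular C/N/P quotas, molar elemental ratios, and trait trade-off fits.

A cell quota Q is the amount of an element bound per cell.  With particulate
element concentrations in μg of element per liter of filtered culture and
cell densities in cells/ml,

    Q [fmol/cell] = (conc / M) [μmol/l] / (density * 1000) [cells/l] * 1e9

where M is the element's molar mass (g/mol).  Because fmol/cell is already a
molar amount per cell, ratios of quotas are molar elemental ratios directly.

Filter blanks (ultrapure-water filtrations) are subtracted per element before
quota computation.  Quotas rest on technical filter replicates only, so they
are summarized by mean and SD without inferential tests; quotas measured on
cultures carrying a microbiome are flagged as overestimates because the
associated bacteria contribute particulate mass but are not counted.
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateRegressionError,
    DomainError,
    InsufficientDataError,
)
from .kinetics import MOLAR_MASS

__all__ = [
    "RatioSet",
    "TradeoffFit",
    "blank_correct",
    "quota",
    "elemental_ratios",
    "quota_table",
    "tradeoff_regression",
]


class RatioSet(NamedTuple):
    """Molar elemental ratios; satisfies C:P = C:N x N:P."""

    N_to_P: float
    C_to_N: float
    C_to_P: float


class TradeoffFit(NamedTuple):
    """OLS fit of an N-limitation trait against the matching P trait."""

    trait: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def blank_correct(measurements: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean filter blank, per element, from sample measurements.

    ``measurements`` needs columns ``element``, ``particulate_ug_per_l`` and
    ``is_blank``.  Returns the non-blank rows with corrected concentrations;
    values driven below zero are clamped to 0 with a warning.  Every element
    present must have at least one blank.
    """
    required = {"element", "particulate_ug_per_l", "is_blank"}
    missing = required - set(measurements.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    blanks = measurements[measurements["is_blank"]]
    samples = measurements[~measurements["is_blank"]].copy()
    for element in samples["element"].unique():
        eb = blanks.loc[blanks["element"] == element, "particulate_ug_per_l"]
        if eb.empty:
            raise ConfigurationError(f"no filter blanks for element {element!r}")
        mask = samples["element"] == element
        samples.loc[mask, "particulate_ug_per_l"] -= eb.mean()
    neg = samples["particulate_ug_per_l"] < 0
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} blank-corrected value(s) below zero; clamped to 0",
            stacklevel=2,
        )
        samples.loc[neg, "particulate_ug_per_l"] = 0.0
    return samples


def quota(
    particulate_ug_per_l: float, cell_density_per_ml: float, molar_mass: float
) -> float:
    """Cell quota in fmol of element per cell (see module docstring)."""
    if cell_density_per_ml <= 0:
        raise DomainError("cell density must be positive")
    if molar_mass <= 0:
        raise DomainError("molar mass must be positive")
    if particulate_ug_per_l < 0:
        raise DomainError("particulate concentration must be >= 0")
    umol_per_l = particulate_ug_per_l / molar_mass
    cells_per_l = cell_density_per_ml * 1000.0
    return umol_per_l / cells_per_l * 1e9


def elemental_ratios(q_c: float, q_n: float, q_p: float) -> RatioSet:
    """Molar N:P, C:N and C:P ratios from quotas in fmol/cell."""
    if q_c <= 0 or q_n <= 0 or q_p <= 0:
        raise DomainError("all quotas must be positive to form ratios")
    return RatioSet(N_to_P=q_n / q_p, C_to_N=q_c / q_n, C_to_P=q_c / q_p)


def quota_table(
    measurements: pd.DataFrame,
    cell_counts: pd.DataFrame,
    molar_mass: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per strain x state x element quota summary.

    ``measurements``: element, particulate_ug_per_l, replicate, is_blank,
    strain, state (blank rows need no strain/state).  ``cell_counts``:
    strain, state, cells_per_ml.  Technical replicates are summarized by
    mean and SD.  Rows for xenic cultures carry ``overestimate_flag=True``
    (uncounted microbiome cells contribute particulate mass).
    """
    mm = dict(MOLAR_MASS)
    if molar_mass:
        mm.update(molar_mass)
    corrected = blank_correct(measurements)
    counts = cell_counts.set_index(["strain", "state"])["cells_per_ml"]
    rows = []
    for (strain, state, element), sub in corrected.groupby(
        ["strain", "state", "element"], sort=True
    ):
        try:
            density = float(counts.loc[(strain, state)])
        except KeyError:
            raise ConfigurationError(
                f"no cell count for culture ({strain}, {state})"
            )
        qs = np.array(
            [
                quota(c, density, mm[element])
                for c in sub["particulate_ug_per_l"]
            ]
        )
        rows.append(
            dict(
                strain=strain, state=state, element=element,
                q_fmol_per_cell=float(qs.mean()),
                sd=float(qs.std(ddof=1)) if qs.size > 1 else 0.0,
                n_replicates=int(qs.size), cell_density_per_ml=density,
                overestimate_flag=(state == "xenic"),
            )
        )
    return pd.DataFrame(rows)


def tradeoff_regression(x, y, trait: str = "") -> TradeoffFit:
    """OLS line, Pearson r, and two-sided slope p-value for y against x.

    Used to ask whether N-limitation traits (K_s, mu_max, quota) trade off
    against the corresponding P-limitation traits across cultures.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("trade-off regression needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("zero variance in x")
    res = stats.linregress(x, y)
    return TradeoffFit(
        trait=trait, slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), n=int(x.size),
    )
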