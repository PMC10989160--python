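"""Synthetic plate-reader data with known ground truth.

The generator emulates the structure of an N/P-limitation plate assay:
nutrient gradients of the limiting element, triplicate wells inoculated at
5000 cells/ml, daily fluorescence readings, media-control baseline wells,
per-culture lag phases, carrying capacities that scale with nutrient supply,
and multiplicative (lognormal) measurement noise.

The latent trajectory of a growth well is a logistic curve whose rate is the
Monod rate at the well's total substrate concentration,

    mu = mu_max * S_tot / (S_tot + K_s),      S_tot = S + background_S
    K' = min(B + q_f * S_tot, K_max)          (carrying capacity, RFU)
    L(t) = K' / (1 + (K'/L0 - 1) * exp(-mu (t - lag))),   L0 = B + F0

flat at L0 before the lag and flat throughout when the yield ceiling K' does
not exceed L0.  Early-phase interval rates of ln L therefore equal mu up to
the logistic saturation term, which is exactly the regime the growth-rate
pipeline extracts.  Observations are F = L * exp(eps), eps ~ N(0, sigma^2)
independent per time point.

Each well draws from its own random stream keyed by a stable hash of the
well's identity and the master seed, so adding wells to a configuration
never perturbs the draws of existing wells.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import MOLAR_MASS
from .plate import PlateSet, WellSeries

__all__ = [
    "N_GRADIENT",
    "P_GRADIENT",
    "KineticTruth",
    "SimulationConfig",
    "simulate_well",
    "simulate_plate",
    "simulate_quota_samples",
]

#: Supplied N levels, μg/l N as nitrate (totals; the lowest level is the
#: medium background itself).
N_GRADIENT: tuple[float, ...] = (8.0, 40.5, 87.0, 425.0, 2760.0, 14150.0, 30500.0)
#: Supplied P levels, μg/l P as phosphate (totals).
P_GRADIENT: tuple[float, ...] = (1.1, 9.6, 18.7, 47.6, 100.0, 171.1, 309.5, 1551.6, 3030.0)

#: Default fluorescence yield per unit of limiting element, RFU per (μg/l).
#: Anchored on quota arithmetic: with ~4e-4 RFU per (cell/ml) of phycocyanin
#: signal and quotas of ~1.3 fmol P and ~48 fmol N per cell, one μg/l of
#: element supports ~2.5e4 cells/ml (P) or ~1.5e3 cells/ml (N).
DEFAULT_YIELD = {"P": 100.0, "N": 0.6}
DEFAULT_K_MAX = 25000.0


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth growth parameters for one strain x state culture."""

    mu_max: float  # day^-1
    k_s: float  # μg/l of the limiting element
    lag: float = 0.0  # days
    yield_rfu_per_ug: float | None = None  # q_f; nutrient default if None
    k_max_rfu: float = DEFAULT_K_MAX


@dataclass
class SimulationConfig:
    """Full description of a synthetic plate run.

    Defaults reproduce the assay design: triplicate wells, 5000 cells/ml
    inocula, daily readings for 25 days, lognormal noise with sigma = 0.03,
    and the printed N or P gradient (totals, so ``background_s`` = 0).
    """

    truths: Mapping[tuple[str, str], KineticTruth]
    nutrient: str = "P"
    gradient: tuple[float, ...] | None = None
    background_s: float = 0.0
    replicates: int = 3
    schedule: tuple[float, ...] = tuple(float(d) for d in range(26))
    baseline_rfu: float = 10.0
    initial_cells_per_ml: float = 5000.0
    f0_rfu: float = 2.0  # fluorescence equivalent of 5000 cells/ml
    noise_sigma: float = 0.03
    n_controls: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient is None:
            self.gradient = N_GRADIENT if self.nutrient == "N" else P_GRADIENT
        self.gradient = tuple(float(g) for g in self.gradient)
        if any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def yield_for(self, truth: KineticTruth) -> float:
        if truth.yield_rfu_per_ug is not None:
            return truth.yield_rfu_per_ug
        return DEFAULT_YIELD[self.nutrient]


def _well_rng(seed: int, *identity) -> np.random.Generator:
    """Random stream keyed by the master seed and the well's identity."""
    tag = "|".join(str(x) for x in identity)
    digest = hashlib.sha256(tag.encode()).digest()
    key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _latent_logistic(
    t: np.ndarray, mu: float, lag: float, l0: float, cap: float
) -> np.ndarray:
    out = np.full_like(t, l0, dtype=float)
    if cap <= l0 or mu <= 0:
        return out
    tt = t - lag
    grow = tt > 0
    out[grow] = cap / (1.0 + (cap / l0 - 1.0) * np.exp(-mu * tt[grow]))
    return out


def simulate_well(
    config: SimulationConfig,
    strain: str,
    state: str,
    concentration: float,
    replicate: int,
    is_control: bool = False,
) -> WellSeries:
    """Simulate one well of the plate (treatment or media control)."""
    t = np.asarray(config.schedule, float)
    b = config.baseline_rfu
    if is_control:
        latent = np.full_like(t, b)
    else:
        truth = config.truths[(strain, state)]
        s_tot = concentration + config.background_s
        mu = truth.mu_max * s_tot / (s_tot + truth.k_s) if s_tot > 0 else 0.0
        cap = min(b + config.yield_for(truth) * s_tot, truth.k_max_rfu)
        l0 = b + config.f0_rfu
        if cap <= l0:
            warnings.warn(
                f"well ({strain}, {state}, {concentration:g}): yield ceiling "
                "below inoculum signal; trajectory stays flat",
                stacklevel=2,
            )
        latent = _latent_logistic(t, mu, truth.lag, l0, cap)
    rng = _well_rng(
        config.seed, config.nutrient, strain, state,
        f"{concentration:.6g}", replicate, int(is_control),
    )
    if config.noise_sigma > 0:
        f = latent * np.exp(rng.normal(0.0, config.noise_sigma, size=t.size))
    else:
        f = latent.copy()
    well_id = (
        f"{config.nutrient}_ctrl_r{replicate}"
        if is_control
        else f"{config.nutrient}_{strain}_{state}_c{concentration:g}_r{replicate}"
    )
    return WellSeries(
        well_id=well_id,
        strain=strain,
        state=state,
        nutrient=config.nutrient,
        concentration=float(concentration),
        replicate=int(replicate),
        is_control=is_control,
        times=t,
        fluorescence=f,
    )


def simulate_plate(config: SimulationConfig) -> PlateSet:
    """One WellSeries per (strain, state, gradient level, replicate), plus
    media-control wells sharing the baseline and noise model."""
    wells = []
    for (strain, state) in sorted(config.truths):
        for conc in config.gradient:
            for rep in range(1, config.replicates + 1):
                wells.append(
                    simulate_well(config, strain, state, conc, rep)
                )
    for rep in range(1, config.n_controls + 1):
        wells.append(
            simulate_well(
                config, "media", "control", 0.0, rep, is_control=True
            )
        )
    return PlateSet(
        wells=wells,
        nutrient_assayed=config.nutrient,
        gradient=list(config.gradient),
        metadata={"seed": config.seed, "noise_sigma": config.noise_sigma},
    )


def simulate_quota_samples(
    true_quotas: Mapping[str, float],
    cell_density_per_ml: float,
    strain: str = "strain",
    state: str = "axenic",
    noise_cv: float = 0.05,
    blank_sd_frac: float = 0.01,
    n_blanks: int = 2,
    seed: int = 0,
    molar_mass: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic particulate C/N/P filter measurements plus cell counts.

    ``true_quotas`` maps elements to ground-truth quotas in fmol/cell.  The
    particulate concentration of a filter replicate is the deterministic
    value Q * (cells/l) * M / 1e9 perturbed by a relative error
    eta ~ N(0, noise_cv^2); blanks are |N(0, blank_sd_frac * signal)|.
    Replicate counts follow the assay: 2 filters for P, 3 for C and for N.

    Returns ``(measurements, cell_counts)`` ready for
    :func:`monodplate.stoichiometry.quota_table`.
    """
    if cell_density_per_ml <= 0:
        raise ValueError("cell density must be positive")
    mm = dict(MOLAR_MASS)
    if molar_mass:
        mm.update(molar_mass)
    n_reps = {"C": 3, "N": 3, "P": 2}
    rng = _well_rng(seed, "quota", strain, state)
    rows = []
    for element in sorted(true_quotas):
        q = float(true_quotas[element])
        if q <= 0:
            raise ValueError(f"true quota for {element} must be positive")
        signal = q * cell_density_per_ml * 1000.0 * mm[element] / 1e9
        for rep in range(1, n_reps.get(element, 3) + 1):
            eta = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            rows.append(
                dict(
                    element=element, replicate=rep, is_blank=False,
                    strain=strain, state=state,
                    particulate_ug_per_l=signal * (1.0 + eta),
                )
            )
        for rep in range(1, n_blanks + 1):
            blank = (
                abs(rng.normal(0.0, blank_sd_frac * signal))
                if blank_sd_frac > 0
                else 0.0
            )
            rows.append(
                dict(
                    element=element, replicate=rep, is_blank=True,
                    strain="", state="", particulate_ug_per_l=blank,
                )
            )
    measurements = pd.DataFrame(rows)
    cell_counts = pd.DataFrame(
        [dict(strain=strain, state=state, cells_per_ml=cell_density_per_ml)]
    )
    return measurements, cell_counts
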