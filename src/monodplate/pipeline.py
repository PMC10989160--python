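"""End-to-end drivers chaining the pipeline stages.

``run_pipeline`` takes a plate (real or simulated) straight to the
Table-1-style trait summary: interval rates -> top-k growth estimates with
the zero-growth gate -> per-group Monod fits -> derived traits (initial
slope, R*) -> pairwise parameter contrasts with FDR control.  All stages are
deterministic, so a fixed simulation seed yields byte-identical result
tables.
"""

from __future__ import annotations

import pandas as pd

from .config import RunConfig
from .growth import estimate_growth
from .kinetics import (
    MonodFit,
    contrast_parameters,
    fit_monod_groups,
    summary_table,
)
from .plate import PlateSet

__all__ = ["PipelineResult", "run_pipeline"]


class PipelineResult(dict):
    """Mapping of result-kind name to DataFrame (growth_estimates,
    monod_fits, contrasts), with the fitted models on ``.fits``."""

    fits: list[MonodFit]


def run_pipeline(plate: PlateSet, config: RunConfig | None = None) -> PipelineResult:
    cfg = config or RunConfig()
    growth = estimate_growth(
        plate,
        k=cfg.top_k,
        alpha=cfg.alpha,
        subtract_control_baseline=cfg.subtract_control_baseline,
        aggregate=cfg.aggregate,
    )
    fits = fit_monod_groups(growth, weighting=cfg.weighting)
    summary = summary_table(
        fits, dilution_rate=cfg.dilution_rate, molar_mass=cfg.molar_mass
    )
    contrasts = contrast_parameters(fits, fdr_method=cfg.fdr_method)
    result = PipelineResult(
        growth_estimates=growth, monod_fits=summary, contrasts=contrasts
    )
    result.fits = fits
    return result
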