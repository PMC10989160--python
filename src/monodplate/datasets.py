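"""Published resource-competition traits for four *Microcystis* strains.

Reported Monod parameters (mu_max, K_s with standard errors), derived traits
(initial slope, R* at D = 0.2 day^-1), and cellular C/N/P quotas with molar
ratios for *Microcystis aeruginosa* PCC 7806 (wild type and the
microcystin-deficient ΔmcyB mutant), PCC 9701, and NIES-843, each grown
axenically and with a lake-derived microbiome (xenic).  Values are printed
literature values at their published precision; they serve as realistic
ground-truth inputs for the synthetic generator and as a consistency check
for the derived-trait formulas.

Units: mu_max day^-1; K_s and R* μg/l of the limiting element; initial slope
day^-1 μM^-1; quotas fmol/cell; ratios molar.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["microcystis_traits"]

_ROWS = [
    # strain, state,
    # mu_max_P, se, k_s_P, se, slope_P, q_p, q_p_sd, p_star,
    # mu_max_N, se, k_s_N, se, slope_N, q_n, q_n_sd, n_star,
    # q_c, q_c_sd, n_to_p, c_to_n, c_to_p
    ("PCC 7806 dmcyB", "axenic",
     0.55, 0.01, 3.58, 0.75, 4.77, 1.27, 0.07, 2.0,
     0.60, 0.04, 290.57, 100.11, 0.029, 28.86, 2.57, 145.3,
     176.14, 13.79, 22.72, 6.10, 138.70),
    ("PCC 7806 dmcyB", "xenic",
     0.49, 0.01, 1.72, 0.42, 8.91, 0.85, 0.05, 1.2,
     0.47, 0.03, 66.75, 25.29, 0.099, 48.22, 3.27, 49.4,
     263.6, 14.26, 56.71, 5.47, 310.03),
    ("PCC 7806", "axenic",
     0.48, 0.01, 0.92, 0.16, 16.16, 0.88, 0.38, 0.7,
     0.58, 0.04, 233.13, 83.95, 0.035, 48.1, 2.87, 122.7,
     367.44, 23.97, 54.96, 7.64, 419.84),
    ("PCC 7806", "xenic",
     0.47, 0.01, 0.63, 0.12, 23.08, 0.72, 0.05, 0.5,
     0.43, 0.03, 63.28, 27.84, 0.094, 44.89, 2.33, 55.0,
     309.22, 16.14, 62.73, 6.89, 432.09),
    ("PCC 9701", "axenic",
     0.54, 0.02, 5.35, 1.34, 3.11, 1.89, 0.14, 3.1,
     0.58, 0.03, 342.09, 112.68, 0.024, 94.16, 6.86, 180.0,
     587.91, 59.63, 49.81, 6.24, 311.01),
    ("PCC 9701", "xenic",
     0.58, 0.02, 7.11, 1.50, 2.55, 3.41, 0.31, 3.7,
     0.58, 0.03, 133.64, 39.25, 0.061, 157.44, 11.43, 70.3,
     849.97, 62.65, 46.12, 5.40, 248.97),
    ("NIES-843", "axenic",
     0.54, 0.01, 4.01, 0.90, 4.17, 3.24, 0.41, 2.4,
     0.54, 0.03, 371.77, 92.89, 0.020, 53.33, 4.15, 218.7,
     304.92, 26.95, 16.47, 5.72, 94.18),
    ("NIES-843", "xenic",
     0.55, 0.01, 3.94, 0.87, 4.31, 2.61, 0.27, 2.3,
     0.48, 0.02, 121.44, 29.81, 0.055, 55.12, 5.66, 86.7,
     305.29, 29.98, 21.11, 5.54, 116.92),
]

_COLUMNS = [
    "strain", "state",
    "mu_max_P", "mu_max_P_se", "k_s_P", "k_s_P_se", "initial_slope_P",
    "q_p", "q_p_sd", "p_star",
    "mu_max_N", "mu_max_N_se", "k_s_N", "k_s_N_se", "initial_slope_N",
    "q_n", "q_n_sd", "n_star",
    "q_c", "q_c_sd", "n_to_p", "c_to_n", "c_to_p",
]


def microcystis_traits() -> pd.DataFrame:
    """Published trait table, one row per strain x microbiome-state culture."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
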