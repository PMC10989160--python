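#!/usr/bin/env python
"""N-vs-P trait trade-off regressions across the eight cultures.

Regresses each culture's fitted N-limitation trait (K_s, mu_max, quota)
against the corresponding P-limitation trait.  A negative, significant
slope would indicate a trade-off between N and P competitive ability;
positive non-significant correlations mean no evidence for one.
"""

from pathlib import Path

import pandas as pd

from monodplate.plate import write_results
from monodplate.stoichiometry import tradeoff_regression

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fits = pd.read_csv(ROOT / "results" / "monod_fits.csv",
                       float_precision="round_trip")
    wide = fits.pivot(index=["strain", "state"], columns="nutrient",
                      values=["mu_max", "k_s"])
    quotas = pd.read_csv(ROOT / "results" / "quotas.csv",
                         float_precision="round_trip")
    qwide = quotas.pivot(index=["strain", "state"], columns="element",
                         values="q_fmol_per_cell")

    rows = []
    for trait, x, y in [
        ("k_s", wide[("k_s", "P")], wide[("k_s", "N")]),
        ("mu_max", wide[("mu_max", "P")], wide[("mu_max", "N")]),
        ("quota", qwide["P"], qwide["N"]),
    ]:
        fit = tradeoff_regression(x.to_numpy(), y.to_numpy(), trait=trait)
        rows.append(fit._asdict())
        verdict = "trade-off" if (fit.slope < 0 and fit.p < 0.05) else \
            "no trade-off evidence"
        print(f"{trait:>7}: slope {fit.slope:8.3f}  r {fit.r:+.2f}  "
              f"p {fit.p:.3f}  -> {verdict}")
    write_results({"tradeoffs": pd.DataFrame(rows)}, ROOT / "results")


if __name__ == "__main__":
    main()
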