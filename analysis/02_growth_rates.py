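#!/usr/bin/env python
"""Interval growth rates, top-five estimates, and the zero-growth gate.

For each simulated plate: per-well log-ratio rates over consecutive daily
readings, the mean of the five highest rates per well (+- SE), and the
pooled ln(F)-slope comparison against media controls that classifies each
treatment as growing or not.  Prints the lowest concentration supporting
growth per culture.  Note the generator's latent model grows (slowly)
wherever the Monod rate is positive, so with enough reading days the gate
legitimately detects growth even at the background nutrient level; real
nutrient-starved cells can fail to grow at all there.
"""

from pathlib import Path

import pandas as pd

from monodplate.growth import estimate_growth, min_growth_concentration
from monodplate.plate import read_plate, write_results

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = {}
    for nutrient in ("P", "N"):
        plate = read_plate(ROOT / "scratch" / f"plate_{nutrient}.csv")
        growth = estimate_growth(plate)
        tables[f"growth_estimates_{nutrient}"] = growth
        print(f"\n{nutrient} plate: minimum concentration with growth (ug/l)")
        for (strain, state), sub in growth.groupby(["strain", "state"]):
            mgc = min_growth_concentration(sub)
            print(f"  {state:>6} {strain:<16} {mgc}")
    write_results(tables, ROOT / "results")


if __name__ == "__main__":
    main()
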