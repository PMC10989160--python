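#!/usr/bin/env python
"""Simulate the P- and N-limitation plate assays for all eight cultures.

Ground-truth Monod parameters come from the published trait table (four
strains x axenic/xenic), so the synthetic plates mimic the real experiment:
the printed nutrient gradients, triplicate wells seeded at 5000 cells/ml,
daily phycocyanin readings for 25 days, media-control wells, and 3%
multiplicative measurement noise.  Plates are written to scratch/ (they are
bulky); downstream scripts derive the small result tables from them.
"""

import argparse
from pathlib import Path

from monodplate.datasets import microcystis_traits
from monodplate.plate import write_plate
from monodplate.simulate import KineticTruth, SimulationConfig, simulate_plate

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def truths_for(nutrient: str):
    traits = microcystis_traits()
    return {
        (row["strain"], row["state"]): KineticTruth(
            mu_max=row[f"mu_max_{nutrient}"], k_s=row[f"k_s_{nutrient}"]
        )
        for _, row in traits.iterrows()
    }


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    SCRATCH.mkdir(exist_ok=True)
    for nutrient in ("P", "N"):
        cfg = SimulationConfig(
            truths=truths_for(nutrient), nutrient=nutrient, seed=args.seed
        )
        plate = simulate_plate(cfg)
        path = SCRATCH / f"plate_{nutrient}.csv"
        write_plate(plate, path)
        print(
            f"{nutrient}: {len(plate.wells)} wells "
            f"({len(cfg.gradient)} levels x {cfg.replicates} replicates x "
            f"8 cultures + {cfg.n_controls} controls) -> {path}"
        )


if __name__ == "__main__":
    main()
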