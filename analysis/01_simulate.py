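#!/usr/bin/env python
"""Generate the synthetic study analysed by the downstream drivers.

Writes a complete dataset with known ground truth to results/data/: a
100-variant panel (quarter each complete-LoF, partial, wt-like and
gain-of-function), 15 mini-array plates (8 sentinels x 12 replicates per
variant/sentinel, 1536 spots per plate), the calibration dilution series,
plate-reader growth curves (8 wells per variant, 4-min sampling), and a
2000-strain SDL screen with 20 planted sensitive strains.
"""

import argparse
from pathlib import Path

from simap import pipeline
from simap.config import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = RunConfig().with_seed(args.seed)
    study = pipeline.simulate_study(cfg.simulation, include_sdl=True)
    outdir = RESULTS / "data"
    pipeline.write_study(study, outdir)
    cfg.echo(outdir)

    truth = study["truth"]
    n_path = int(truth[~truth["variant_id"].isin(("wt", "vector"))]["pathogenic"].sum())
    print(f"wrote synthetic study to {outdir}")
    print(f"  {cfg.simulation.n_variants} variants ({n_path} pathogenic at truth), "
          f"{len(study['layouts'])} mini-array plates, "
          f"{study['growth_curves']['well_id'].nunique()} growth-curve wells")
    print(f"  SDL screen: {cfg.simulation.n_strains} strains, "
          f"{cfg.simulation.n_sensitive} planted sensitive strains")


if __name__ == "__main__":
    main()
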