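#!/usr/bin/env python
"""Generate the three synthetic datasets used by the downstream analyses.

Writes a two-group climate table (28 + 8 occurrence sites, 19 collinear
variables, a latent shift on the dominant axis), a 12-site morphology
table with sexual dimorphism and a quadratic climate dependence, and a
7-locus phased sequence dataset (74 diploid individuals, deep split, no
migration).  Sequence data are bulky and go under scratch/data; the two
small tables go to results/data.
"""

from pathlib import Path

import numpy as np

from divaxes.synthetic import (
    ClimateGenSpec,
    MorphoGenSpec,
    SampleDesign,
    generate_climate_occurrences,
    generate_morphology,
    simulate_multilocus_dataset,
    study_locus_specs,
)

SEED = 20260928
RESULTS = Path(__file__).resolve().parents[1] / "results" / "data"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    climate = generate_climate_occurrences(
        ClimateGenSpec(n_per_group=(28, 8), shift_vector=(2.0, 1.5, 0.0),
                       noise_sd=0.5, seed=SEED)
    )
    climate.to_csv(RESULTS / "climate.csv", index=False)
    print(f"climate: {len(climate)} sites x {climate.shape[1] - 2} variables")

    rng = np.random.default_rng(SEED)
    xs = np.linspace(-2.5, 2.5, 12) + rng.normal(scale=0.1, size=12)
    sites = tuple(
        (f"site{i + 1:02d}", "group1" if i < 8 else "group2", float(x))
        for i, x in enumerate(xs)
    )
    morphology = generate_morphology(
        MorphoGenSpec(sites=sites, n_per_site=7, seed=SEED)
    )
    morphology.to_csv(RESULTS / "morphology.csv", index=False)
    print(f"morphology: {len(morphology)} individuals at {len(sites)} sites")

    ds = simulate_multilocus_dataset(
        study_locus_specs(),
        SampleDesign(n_individuals=(48, 26), n_populations=(2, 2)),
        split_time=2.0,
        seed=SEED,
        outdir=SCRATCH,
    )
    print(f"sequences: {len(ds.loci)} loci for {len(ds.sample_sheet)} individuals "
          f"-> {SCRATCH}")


if __name__ == "__main__":
    main()
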