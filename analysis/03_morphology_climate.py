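#!/usr/bin/env python
"""Morphology analyses on the simulated trait table.

Log10 transforms, the wing-on-tarsus structural-size index, factorial
geography×sex ANOVAs, and the four-model climate regression suite ranked
by AICc with Akaike weights.  Reports land in results/morpho.
"""

from pathlib import Path

import pandas as pd

from divaxes import pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = {
        "seed": 20260928,
        "morphology": {"csv": str(ROOT / "results" / "data" / "morphology.csv")},
    }
    out = ROOT / "results" / "morpho"
    pipeline.run_morpho(cfg, out)
    anova = pd.read_csv(out / "morpho_anova.tsv", sep="\t")
    models = pd.read_csv(out / "morpho_models.tsv", sep="\t")
    print(anova.to_string(index=False))
    print()
    winners = models.loc[models.groupby("trait")["weight"].idxmax()]
    print(winners[["trait", "model", "r_squared", "weight"]].to_string(index=False))


if __name__ == "__main__":
    main()
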