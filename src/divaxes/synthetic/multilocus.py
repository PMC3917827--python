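"""Multilocus phased datasets under a shared two-deme IM history.

Each locus is simulated independently under the same demography (free
recombination between loci, none within), with marker-appropriate
inheritance scalars, and sequences are dealt out to diploid individuals:

* mtDNA — 1 sequence per individual;
* autosomal — 2 phased sequences per individual;
* Z-linked — 2 for males, 1 for females (avian ZW: males are ZZ).

Sequence ids are ``<individual>_a`` / ``<individual>_b``; the
accompanying sample sheet maps individuals to populations and groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import IMParams, simulate_im_locus

__all__ = [
    "LocusSpec",
    "SampleDesign",
    "MultilocusDataset",
    "simulate_multilocus_dataset",
    "study_locus_specs",
    "write_fasta",
]

GENOME_SCALARS = {"mtDNA": 0.25, "autosomal": 1.0, "Z": 0.75}


@dataclass(frozen=True)
class LocusSpec:
    name: str
    genome: str  # "mtDNA" | "autosomal" | "Z"
    theta: float
    locus_length: int

    def __post_init__(self) -> None:
        if self.genome not in GENOME_SCALARS:
            raise ValueError(f"unknown genome class {self.genome!r}")

    @property
    def inheritance_scalar(self) -> float:
        return GENOME_SCALARS[self.genome]


def study_locus_specs() -> list[LocusSpec]:
    """A 7-locus design: one mtDNA protein-coding region, five autosomal
    introns and one Z-linked intron, with lengths typical of passerine
    sequencing panels."""
    return [
        LocusSpec("mtATP", "mtDNA", 5.0, 800),
        LocusSpec("intronA", "autosomal", 2.0, 327),
        LocusSpec("intronB", "autosomal", 2.0, 516),
        LocusSpec("intronC", "autosomal", 2.0, 580),
        LocusSpec("intronD", "autosomal", 2.0, 566),
        LocusSpec("intronE", "autosomal", 2.0, 419),
        LocusSpec("locusZ", "Z", 2.0, 299),
    ]


@dataclass(frozen=True)
class SampleDesign:
    """Individuals per group, their sub-populations and sex ratio."""

    n_individuals: tuple[int, int] = (48, 26)
    n_populations: tuple[int, int] = (2, 2)
    prop_male: float = 0.5
    group_names: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        for n, p in zip(self.n_individuals, self.n_populations):
            if n < p or p < 1:
                raise ValueError("each population needs at least one individual")


@dataclass
class MultilocusDataset:
    sample_sheet: pd.DataFrame
    loci: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    """locus name -> (sequence_ids, sequences)"""


def _build_sample_sheet(design: SampleDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for g, (n_ind, n_pop, gname) in enumerate(
        zip(design.n_individuals, design.n_populations, design.group_names)
    ):
        for i in range(n_ind):
            idx += 1
            rows.append(
                {
                    "individual": f"ind{idx:03d}",
                    "population": f"{gname}_pop{i % n_pop + 1}",
                    "group": gname,
                    "sex": "male" if rng.random() < design.prop_male else "female",
                }
            )
    return pd.DataFrame(rows)


def _copies(genome: str, sex: str) -> int:
    if genome == "mtDNA":
        return 1
    if genome == "autosomal":
        return 2
    return 2 if sex == "male" else 1  # Z-linked; males are the homogametic sex


def simulate_multilocus_dataset(
    locus_specs: list[LocusSpec],
    design: SampleDesign = SampleDesign(),
    *,
    split_time: float = 2.0,
    mig_12: float = 0.0,
    mig_21: float = 0.0,
    ancestral_size: float = 1.0,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> MultilocusDataset:
    """Simulate every locus and deal sequences out to individuals.

    With ``outdir`` set, writes one wrapped FASTA per locus plus a
    ``samples.tsv`` sheet; identical seeds give byte-identical files.
    """
    if not locus_specs:
        raise ValueError("need at least one locus")
    names = [ls.name for ls in locus_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names")

    master = np.random.SeedSequence(seed)
    sheet_rng = np.random.default_rng(master.spawn(1)[0])
    sheet = _build_sample_sheet(design, sheet_rng)
    locus_seeds = master.spawn(len(locus_specs))

    n1 = design.n_individuals[0]
    per_group = [sheet.iloc[:n1], sheet.iloc[n1:]]

    ds = MultilocusDataset(sample_sheet=sheet)
    for ls, ss in zip(locus_specs, locus_seeds):
        counts = []
        ids: list[str] = []
        for grp in per_group:
            total = 0
            for _, ind in grp.iterrows():
                c = _copies(ls.genome, ind["sex"])
                total += c
                for copy in "ab"[:c]:
                    ids.append(f"{ind['individual']}_{copy}")
            counts.append(total)
        params = IMParams(
            theta=ls.theta,
            split_time=split_time,
            mig_12=mig_12,
            mig_21=mig_21,
            n_samples=(counts[0], counts[1]),
            locus_length=ls.locus_length,
            inheritance_scalar=ls.inheritance_scalar,
            ancestral_size=ancestral_size,
            seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
        )
        sim = simulate_im_locus(params)
        ds.loci[ls.name] = (ids, sim.alignment)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, (ids, seqs) in ds.loci.items():
            write_fasta(outdir / f"{name}.fasta", ids, seqs)
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return ds


def write_fasta(
    path: str | Path, ids: list[str], seqs: list[str], wrap: int = 60
) -> None:
    """Write a FASTA file with lines wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for sid, seq in zip(ids, seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
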