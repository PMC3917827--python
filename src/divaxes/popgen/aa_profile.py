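"""Amino-acid profiles of protein-coding alignments.

Sequences are translated with the vertebrate mitochondrial code and
codon positions where the amino acid varies (non-synonymous segregating
codons) are tabulated; positions whose amino-acid sets are disjoint
between the two groups are counted as group-diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .alignment import LocusAlignment, PopPartition

__all__ = ["AAProfile", "AASite", "aa_profile", "VERTEBRATE_MITO_TABLE"]

VERTEBRATE_MITO_TABLE = 2  # NCBI translation table id


@dataclass
class AASite:
    codon_position: int  # 1-based
    amino_acids: tuple[str, ...]
    group_freqs: dict[str, dict[str, float]]
    diagnostic: bool


@dataclass
class AAProfile:
    sites: list[AASite] = field(default_factory=list)

    @property
    def n_segregating(self) -> int:
        return len(self.sites)

    @property
    def n_diagnostic(self) -> int:
        return sum(s.diagnostic for s in self.sites)


def _translate(seq: str, table: int) -> str:
    return str(Seq(seq).translate(table=table))


def aa_profile(
    aln: LocusAlignment,
    partition: PopPartition,
    frame: int = 0,
    table: int = VERTEBRATE_MITO_TABLE,
) -> AAProfile:
    """Tabulate non-synonymous segregating codons between two groups.

    The coding region starts at ``frame`` (0-based offset into the
    alignment) and must cover whole codons.  Internal stop codons
    trigger a warning naming the position; they are tolerated because
    mtDNA alignments commonly end on incomplete-stop quirks.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    length = aln.alignment_length - frame
    if length < 3 or length % 3 != 0:
        raise ValueError(
            f"coding region of length {length} from frame {frame} does not "
            "divide into codons"
        )
    pops = partition.populations(aln.sequence_ids)
    labels = np.unique(pops)
    if labels.size != 2:
        raise ValueError("amino-acid profiling expects exactly two groups")

    proteins = []
    for sid, seq in zip(aln.sequence_ids, aln.sequences):
        coding = seq[frame:]
        if "-" in coding or "N" in coding:
            raise ValueError(f"{sid}: gaps/ambiguity inside the coding region")
        aa = _translate(coding, table)
        stop = aa.find("*")
        if 0 <= stop < len(aa) - 1:
            warnings.warn(
                f"{sid}: internal stop codon at codon {stop + 1}", stacklevel=2
            )
        proteins.append(aa)
    prot = np.array([list(p) for p in proteins], dtype="<U1")

    profile = AAProfile()
    for pos in range(prot.shape[1]):
        col = prot[:, pos]
        aas = sorted(set(col))
        if len(aas) < 2:
            continue
        freqs: dict[str, dict[str, float]] = {}
        sets = []
        for lab in labels:
            sub = col[pops == lab]
            vals, counts = np.unique(sub, return_counts=True)
            freqs[str(lab)] = {
                str(v): float(c) / sub.size for v, c in zip(vals, counts)
            }
            sets.append(set(vals))
        profile.sites.append(
            AASite(
                codon_position=pos + 1,
                amino_acids=tuple(aas),
                group_freqs=freqs,
                diagnostic=not (sets[0] & sets[1]),
            )
        )
    return profile
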