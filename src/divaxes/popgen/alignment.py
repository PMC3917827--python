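"""Locus alignments and population partitions.

An alignment is a set of equal-length DNA sequences plus a boolean mask
of analyzed columns.  The default site policy is complete deletion:
every column containing a gap ('-') or an ambiguous base ('N') is
excluded from all statistics, so the analyzed length L is the gap-free
alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = ["LocusAlignment", "PopPartition", "read_alignment", "partition_from_sheet"]

_VALID = set("ACGTN-")


@dataclass
class LocusAlignment:
    name: str
    sequence_ids: list[str]
    sequences: list[str]
    site_policy: str = "complete"
    _matrix: np.ndarray | None = field(default=None, repr=False)
    _mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"{self.name}: need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.name}: ragged sequence lengths {sorted(lengths)}")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError(f"{self.name}: duplicate sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _VALID
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")
        if self.site_policy not in ("complete", "all"):
            raise ValueError(f"unknown site policy {self.site_policy!r}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = np.array(
                [list(s) for s in self.sequences], dtype="<U1"
            )
        return self._matrix

    @property
    def mask(self) -> np.ndarray:
        """Boolean analyzed-site mask over alignment columns."""
        if self._mask is None:
            m = self.matrix
            if self.site_policy == "complete":
                self._mask = ~np.any((m == "-") | (m == "N"), axis=0)
            else:
                self._mask = np.ones(m.shape[1], dtype=bool)
        return self._mask

    @property
    def L(self) -> int:
        """Number of analyzed sites."""
        return int(self.mask.sum())

    def analyzed_matrix(self) -> np.ndarray:
        """(n × L) character matrix restricted to analyzed columns."""
        return self.matrix[:, self.mask]

    def subset(self, ids: list[str]) -> "LocusAlignment":
        """Alignment restricted to the given sequence ids (mask rebuilt)."""
        lookup = {sid: i for i, sid in enumerate(self.sequence_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"{self.name}: unknown sequence ids {missing}")
        return LocusAlignment(
            name=self.name,
            sequence_ids=list(ids),
            sequences=[self.sequences[lookup[s]] for s in ids],
            site_policy=self.site_policy,
        )


def read_alignment(
    path: str | Path, name: str | None = None, site_policy: str = "complete"
) -> LocusAlignment:
    """Read a FASTA alignment; lowercase input is uppercased."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return LocusAlignment(
        name=name or path.stem,
        sequence_ids=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
        site_policy=site_policy,
    )


@dataclass
class PopPartition:
    """Maps sequence ids to populations and populations to groups."""

    seq_to_pop: dict[str, str]
    pop_to_group: dict[str, str] = field(default_factory=dict)

    def populations(self, ids: list[str]) -> np.ndarray:
        missing = [s for s in ids if s not in self.seq_to_pop]
        if missing:
            raise KeyError(f"sequences not in partition: {missing[:5]}")
        return np.array([self.seq_to_pop[s] for s in ids])

    def groups(self, ids: list[str]) -> np.ndarray:
        pops = self.populations(ids)
        missing = sorted({p for p in pops if p not in self.pop_to_group})
        if missing:
            raise KeyError(f"populations without group: {missing}")
        return np.array([self.pop_to_group[p] for p in pops])


def partition_from_sheet(
    sheet: pd.DataFrame, sequence_ids: list[str], level: str = "population"
) -> PopPartition:
    """Build a partition from a sample sheet for the given sequences.

    Sequence ids are matched to individuals by stripping a trailing
    ``_a``/``_b`` phase suffix; ``level`` chooses whether populations in
    the partition are the sheet's populations (with groups above them)
    or the groups themselves.
    """
    if level not in ("population", "group"):
        raise ValueError("level must be 'population' or 'group'")
    by_ind = sheet.set_index("individual")
    seq_to_pop: dict[str, str] = {}
    pop_to_group: dict[str, str] = {}
    for sid in sequence_ids:
        ind = sid.rsplit("_", 1)[0] if sid.endswith(("_a", "_b")) else sid
        if ind not in by_ind.index:
            raise KeyError(f"sequence {sid!r}: individual {ind!r} not in sheet")
        row = by_ind.loc[ind]
        pop = str(row[level])
        seq_to_pop[sid] = pop
        pop_to_group[pop] = str(row["group"])
    return PopPartition(seq_to_pop, pop_to_group)
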