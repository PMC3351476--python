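"""Sequence alignments and the flat-file formats around them.

An :class:`Alignment` is a rectangular block of nucleotide sequences, one per
sampled individual (the study design sequences a single inferred haplotype
per individual, so sequences are haploid). All statistics operate on the
"effective" columns that contain only unambiguous bases in every sequence
(complete deletion of gap/ambiguous columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass
class Alignment:
    """Equal-length nucleotide sequences over the alphabet {A,C,G,T,-,N}."""

    ids: list[str]
    seqs: list[str]

    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if not self.seqs:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        if len(self.seqs[0]) < 1:
            raise ValueError("alignment length must be >= 1")
        raw = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.seqs), -1)
        self._codes = _CODE[raw]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def codes(self) -> np.ndarray:
        """(n, length) int8 matrix; A,C,G,T -> 0..3, anything else -> -1."""
        return self._codes

    def effective_site_indices(self) -> np.ndarray:
        """0-based indices of columns free of gaps/ambiguity in all rows."""
        return np.flatnonzero((self._codes >= 0).all(axis=0))

    def site_data(self) -> "SiteData":
        idx = self.effective_site_indices()
        return SiteData(
            codes=np.ascontiguousarray(self._codes[:, idx]),
            L_eff=int(idx.size),
            positions=idx.astype(float),
        )

    def subset(self, ids: list[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"sequence ids not in alignment: {missing}")
        return Alignment(ids=list(ids), seqs=[self.seqs[index[s]] for s in ids])


@dataclass(frozen=True)
class SiteData:
    """Matrix view consumed by every statistic.

    ``codes`` holds one small-integer allele code per (sequence, column);
    columns may be a subset of the locus (e.g. only segregating sites from a
    simulation), in which case ``L_eff`` is still the full number of analyzed
    sites and absent columns are implicitly monomorphic. ``positions`` gives
    each column's coordinate in bp (or site index) for spatial statistics.
    """

    codes: np.ndarray
    L_eff: int
    positions: np.ndarray

    @property
    def n(self) -> int:
        return self.codes.shape[0]


def as_site_data(aln) -> SiteData:
    """Coerce an Alignment / SimulatedLocus / SiteData to SiteData."""
    if isinstance(aln, SiteData):
        return aln
    return aln.site_data()


def read_fasta(path: str | Path) -> Alignment:
    """Read one aligned FASTA file (wrapped lines and case are tolerated)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment(
        ids=[r.id for r in records], seqs=[str(r.seq).upper() for r in records]
    )


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sequence_id<TAB>population`` -> mapping."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, pop = line.split("\t")[:2]
            popmap[sid] = pop
    return popmap


def write_popmap(popmap: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, pop in popmap.items():
            fh.write(f"{sid}\t{pop}\n")


def split_populations(aln: Alignment, popmap: dict[str, str]) -> dict[str, Alignment]:
    """Split an alignment into per-population alignments.

    Sequences absent from the population map are dropped.
    """
    groups: dict[str, list[str]] = {}
    for sid in aln.ids:
        pop = popmap.get(sid)
        if pop is not None:
            groups.setdefault(pop, []).append(sid)
    return {pop: aln.subset(ids) for pop, ids in groups.items()}
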