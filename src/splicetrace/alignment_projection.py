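"""Projecting intron positions onto a protein multiple alignment.

Two homologous genes that inherited an intron from their common ancestor carry
it at the same position of the encoded protein — and hence, once the proteins
are aligned, in the same alignment column with the same phase.  This module
maps per-gene intron positions (codon index + phase) to alignment columns and
groups junctions shared across sequences, the comparison that supports
duplication-origin inference across paralogs.

The alignment itself is an input (aligned FASTA); this package never builds
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import AlignmentFormatError, ConsistencyError, IdError
from .gene_models import IntronPosition

GAP = "-"


@dataclass
class Msa:
    """A protein multiple alignment: parallel ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IdError(f"duplicate alignment ids: {dupes}")
        if not self.rows:
            raise AlignmentFormatError("alignment is empty")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment rows, lengths {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise IdError(f"sequence id {seq_id!r} not in alignment") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


@dataclass(frozen=True)
class ProjectedJunction:
    """One intron projected into the alignment frame."""

    column: int  # 1-based alignment column of the host residue
    phase: int
    intron_rank: int


#: JunctionMap: per sequence id, its projected junctions ordered by intron rank
JunctionMap = dict[str, list[ProjectedJunction]]


@dataclass
class SharedJunction:
    """A junction occupied by ≥2 sequences at (nearly) the same column and phase."""

    column: int  # anchor = minimum member column
    phase: int
    supporters: set[str] = field(default_factory=set)
    support: float = 0.0


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`."""
    from Bio import AlignIO

    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    return Msa(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln])


def write_alignment(msa: Msa, path: str | Path) -> None:
    from .gene_models import write_fasta

    write_fasta(zip(msa.ids, msa.rows), path)


def residue_to_column(msa: Msa, seq_id: str) -> dict[int, int]:
    """Strictly increasing map: 1-based residue index -> 1-based alignment column."""
    row = msa.row(seq_id)
    mapping: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            res += 1
            mapping[res] = col
    return mapping


def project_junctions(
    msa: Msa, introns: Mapping[str, Sequence[IntronPosition]]
) -> JunctionMap:
    """Map each sequence's intron positions to alignment columns.

    The phase travels unchanged; the column is that of the codon-index
    residue.  A codon index beyond the ungapped sequence length means the
    gene model and the aligned protein disagree and raises
    :class:`ConsistencyError`.
    """
    jm: JunctionMap = {}
    for seq_id, positions in introns.items():
        r2c = residue_to_column(msa, seq_id)
        nres = len(r2c)
        projected = []
        for pos in sorted(positions, key=lambda p: p.intron_rank):
            if not 1 <= pos.codon_index <= nres:
                raise ConsistencyError(
                    f"{seq_id}: intron codon index {pos.codon_index} outside "
                    f"protein of length {nres}"
                )
            projected.append(ProjectedJunction(
                column=r2c[pos.codon_index], phase=pos.phase,
                intron_rank=pos.intron_rank,
            ))
        jm[seq_id] = projected
    return jm


def call_shared_junctions(
    jm: JunctionMap,
    shift_tolerance: int = 0,
    require_same_phase: bool = True,
    n_eligible: int | None = None,
) -> list[SharedJunction]:
    """Group junctions from distinct sequences occupying the same column.

    Junctions are grouped greedily left-to-right: the leftmost ungrouped
    junction seeds a group (its column is the anchor), and every junction
    within ``shift_tolerance`` columns of the anchor — with equal phase when
    ``require_same_phase`` — joins it.  Each junction belongs to at most one
    group; only groups supported by at least two distinct sequences are
    reported.  ``support`` divides by ``n_eligible`` (default: number of
    sequences present in the junction map).
    """
    if shift_tolerance < 0:
        raise ValueError("shift_tolerance must be >= 0")
    denom = n_eligible if n_eligible is not None else len(jm)
    entries = sorted(
        ((pj.column, pj.phase, seq_id, pj.intron_rank)
         for seq_id, pjs in jm.items() for pj in pjs),
        key=lambda e: (e[0], e[1], e[2], e[3]),
    )
    used = [False] * len(entries)
    shared: list[SharedJunction] = []
    for i, (col, phase, seq_id, _) in enumerate(entries):
        if used[i]:
            continue
        used[i] = True
        members = {seq_id}
        for k in range(i + 1, len(entries)):
            c2, p2, s2, _ = entries[k]
            if c2 - col > shift_tolerance:
                break
            if used[k]:
                continue
            if require_same_phase and p2 != phase:
                continue
            used[k] = True
            members.add(s2)
        if len(members) >= 2:
            shared.append(SharedJunction(
                column=col, phase=phase, supporters=members,
                support=len(members) / denom if denom else 0.0,
            ))
    return shared


def junction_map_table(jm: JunctionMap) -> "pandas.DataFrame":  # noqa: F821
    """Flatten a JunctionMap into a tidy table (id, intron_rank, column, phase)."""
    import pandas as pd

    rows = [
        {"id": sid, "intron_rank": pj.intron_rank,
         "column": pj.column, "phase": pj.phase}
        for sid, pjs in jm.items() for pj in pjs
    ]
    return pd.DataFrame(rows, columns=["id", "intron_rank", "column", "phase"])
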