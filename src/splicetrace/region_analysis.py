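"""Reference-anchored analyses of functional regions and sites.

All operations here are phrased in the coordinates of a single *reference*
sequence (for the PRPS family, human PRPS1): named loop windows (FLAG, PP
loop, catalytic flexible loop, regulatory flexible loop, R5P loop) and named
residue sets (catalytic, dimer-interface, allosteric).  Given a protein MSA
containing the reference, the module

* projects regions into alignment columns,
* detects long lineage-specific insertions inside loop windows — the
  "non-homologous regions" (NHRs) characteristic of non-catalytic PRPS
  paralogs,
* tabulates residue correspondences for a residue set (e.g. which residues a
  paralog carries opposite the catalytic D171/K194/R196/N200/T225),
* scores per-region conservation,
* measures how strongly the differences between two paralogs concentrate in
  a window (e.g. the N-terminal 95 residues), and
* finds upstream in-frame alternative translation starts on transcripts
  (N-terminal leader peptides).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .alignment_projection import GAP, Msa, residue_to_column
from .errors import (
    AnnotationError,
    BoundsError,
    ConsistencyError,
    UndefinedFractionError,
)
from .gene_models import ProteinRecord
from .orf_annotation import TranscriptRecord, _blosum62

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class RegionSet:
    """Named windows and residue sets in reference coordinates (1-based)."""

    reference_id: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    residue_sets: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (s, e) in self.regions.items():
            if not (1 <= s <= e):
                raise BoundsError(f"region {name!r}: bad interval [{s},{e}]")
        for name, members in self.residue_sets.items():
            positions = [p for p, _ in members]
            if len(set(positions)) != len(positions):
                raise BoundsError(f"residue set {name!r}: duplicate positions")


_SET_ITEM = re.compile(r"^([A-Z])(\d+)$")


def load_region_set(path: str | Path, reference_id: str) -> RegionSet:
    """Load a RegionSet TSV: columns name, kind(region|set), value.

    Region values are ``start-end`` (1-based inclusive); set values are
    comma-separated residue tokens like ``D171,K194``.
    """
    regions: dict[str, tuple[int, int]] = {}
    sets: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, kind, value = line.split("\t")[:3]
            if kind == "region":
                s, e = value.split("-")
                regions[name] = (int(s), int(e))
            elif kind == "set":
                members = []
                for token in value.split(","):
                    m = _SET_ITEM.match(token.strip())
                    if not m:
                        raise BoundsError(f"set {name!r}: bad residue token {token!r}")
                    members.append((int(m.group(2)), m.group(1)))
                sets[name] = members
            else:
                raise BoundsError(f"unknown kind {kind!r} for entry {name!r}")
    return RegionSet(reference_id=reference_id, regions=regions, residue_sets=sets)


def default_region_set(reference_id: str = "PRPS1_HUMAN") -> RegionSet:
    """The packaged human-PRPS1 defaults (editable; see data/prps1_regions.tsv)."""
    with resources.as_file(
        resources.files("splicetrace.data") / "prps1_regions.tsv"
    ) as p:
        return load_region_set(p, reference_id)


@dataclass(frozen=True)
class InsertionCall:
    """A run of residues a sequence holds where the reference is gapped."""

    sequence_id: str
    region_name: str
    length: int
    columns: tuple[int, int]
    flank_anchored: bool


@dataclass
class RegionConservation:
    """Identity of each target vs the reference over one region's columns."""

    region_name: str
    per_target: dict[str, float]
    mean: float


@dataclass
class DifferenceConcentration:
    """How many of the differences between two proteins fall inside a window."""

    pair: tuple[str, str]
    total_differences: int
    window: tuple[int, int]
    in_window: int
    fraction: float
    mask: tuple[str, ...] = ()


@dataclass(frozen=True)
class LeaderPeptide:
    """An upstream in-frame start and the N-terminal extension it encodes."""

    transcript_id: str
    canonical_start: int
    alt_start: int
    leader_aa: int
    leader_sequence: str


def project_regions(msa: Msa, rs: RegionSet) -> dict[str, tuple[int, int]]:
    """Map each region to its [first-residue column, last-residue column]."""
    r2c = residue_to_column(msa, rs.reference_id)
    nres = len(r2c)
    out = {}
    for name, (s, e) in rs.regions.items():
        if e > nres:
            raise BoundsError(
                f"region {name!r} [{s},{e}] exceeds reference length {nres}"
            )
        out[name] = (r2c[s], r2c[e])
    return out


def detect_insertions(
    msa: Msa,
    rs: RegionSet,
    min_insertion: int = 10,
    gap_merge: int = 2,
    flank_len: int = 5,
) -> list[InsertionCall]:
    """Find NHR-style insertions: ≥ ``min_insertion`` residues carried by a
    sequence in columns where the reference is gapped, inside a region window.

    Insertion runs separated by at most ``gap_merge`` non-insertion columns
    are merged.  ``flank_anchored`` requires ≥ ``flank_len`` columns on each
    side of the run where both reference and target are aligned (non-gap).
    """
    if min_insertion < 1:
        raise ValueError("min_insertion must be >= 1")
    spans = project_regions(msa, rs)
    ref_row = msa.row(rs.reference_id)
    calls: list[InsertionCall] = []
    for seq_id in msa.ids:
        if seq_id == rs.reference_id:
            continue
        row = msa.row(seq_id)
        for name, (c1, c2) in spans.items():
            ins_cols = [
                c for c in range(c1, c2 + 1)
                if ref_row[c - 1] == GAP and row[c - 1] != GAP
            ]
            if not ins_cols:
                continue
            groups: list[list[int]] = [[ins_cols[0]]]
            for c in ins_cols[1:]:
                if c - groups[-1][-1] - 1 <= gap_merge:
                    groups[-1].append(c)
                else:
                    groups.append([c])
            for grp in groups:
                if len(grp) < min_insertion:
                    continue
                left = sum(
                    1 for c in range(1, grp[0])
                    if ref_row[c - 1] != GAP and row[c - 1] != GAP
                )
                right = sum(
                    1 for c in range(grp[-1] + 1, msa.ncol + 1)
                    if ref_row[c - 1] != GAP and row[c - 1] != GAP
                )
                calls.append(InsertionCall(
                    sequence_id=seq_id, region_name=name, length=len(grp),
                    columns=(grp[0], grp[-1]),
                    flank_anchored=left >= flank_len and right >= flank_len,
                ))
    return calls


def residue_correspondence(
    msa: Msa,
    rs: RegionSet,
    set_name: str,
    targets: Sequence[str],
    strict: bool = False,
) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate what each target carries opposite a reference residue set.

    One row per (reference position, target): the target's residue and its own
    1-based position in the same alignment column (or gap), whether it is
    conserved (identical) and whether it is similar (positive BLOSUM62 score).
    A reference residue differing from the set's expectation warns, or raises
    :class:`ConsistencyError` when ``strict``.
    """
    import pandas as pd

    if set_name not in rs.residue_sets:
        raise KeyError(f"unknown residue set {set_name!r}")
    r2c = residue_to_column(msa, rs.reference_id)
    ref_row = msa.row(rs.reference_id)
    blosum = _blosum62()
    rows = []
    for pos, expected in rs.residue_sets[set_name]:
        if pos > len(r2c):
            raise BoundsError(f"set position {pos} exceeds reference length {len(r2c)}")
        col = r2c[pos]
        ref_res = ref_row[col - 1]
        if ref_res != expected:
            msg = (f"reference {rs.reference_id} has {ref_res}{pos}, "
                   f"expected {expected}{pos}")
            if strict:
                raise ConsistencyError(msg)
            warnings.warn(msg, stacklevel=2)
        for tid in targets:
            trow = msa.row(tid)
            tres = trow[col - 1]
            if tres == GAP:
                rows.append((pos, ref_res, tid, None, None, False, False))
            else:
                tpos = sum(1 for ch in trow[:col] if ch != GAP)
                similar = blosum.get((ref_res, tres), 0.0) > 0
                rows.append((pos, ref_res, tid, tpos, tres,
                             tres == ref_res, similar))
    return pd.DataFrame(rows, columns=[
        "ref_position", "ref_residue", "target_id",
        "target_position", "target_residue", "conserved", "similar",
    ])


def region_conservation(
    msa: Msa, rs: RegionSet, targets: Sequence[str]
) -> list[RegionConservation]:
    """Per-region identity of each target vs the reference.

    Identity is computed over region columns where the reference is not
    gapped; a gap in the target counts as a mismatch.
    """
    spans = project_regions(msa, rs)
    ref_row = msa.row(rs.reference_id)
    out = []
    for name, (c1, c2) in spans.items():
        cols = [c for c in range(c1, c2 + 1) if ref_row[c - 1] != GAP]
        per = {}
        for tid in targets:
            row = msa.row(tid)
            matches = sum(1 for c in cols if row[c - 1] == ref_row[c - 1])
            per[tid] = matches / len(cols)
        out.append(RegionConservation(
            region_name=name, per_target=per,
            mean=sum(per.values()) / len(per) if per else 0.0,
        ))
    return out


def _global_pair_alignment(a: str, b: str, gap_open: float = 11.0,
                           gap_extend: float = 1.0) -> tuple[str, str]:
    """End-gap-free global alignment of two proteins; returns gapped strings."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def difference_concentration(
    a: ProteinRecord,
    b: ProteinRecord,
    window: tuple[int, int] = (1, 95),
    mask: Sequence[str] = (),
    rs: RegionSet | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> DifferenceConcentration:
    """Fraction of a↔b difference events falling in a window of ``a``.

    The pair is globally aligned (end gaps free).  A difference event is a
    mismatch column, or one maximal indel run counted once — so a long NHR
    indel weighs the same as a single substitution.  Columns inside masked
    regions (projected from ``rs``, whose reference must be ``a``) are
    excluded before counting.  Events are assigned to ``a`` coordinates;
    indel runs to the nearest preceding ``a`` residue.
    """
    if window[0] < 1 or window[1] > len(a.residues) or window[0] > window[1]:
        raise BoundsError(f"window {window} outside 1..{len(a.residues)}")
    if mask and rs is None:
        raise ValueError("mask names given without a RegionSet")
    if rs is not None and mask and rs.reference_id != a.id:
        raise ConsistencyError(
            f"mask regions are on {rs.reference_id!r} but first protein is {a.id!r}"
        )
    ga, gb = _global_pair_alignment(a.residues, b.residues, gap_open, gap_extend)

    mask_ivals = [rs.regions[name] for name in mask] if mask else []
    cols = []  # (a_char, b_char, apos_last_consumed)
    apos = 0
    for ca, cb in zip(ga, gb):
        if ca != GAP:
            apos += 1
        cols.append((ca, cb, apos))

    def masked(ca: str, apos: int) -> bool:
        for s, e in mask_ivals:
            if ca != GAP and s <= apos <= e:
                return True
            if ca == GAP and s <= apos <= e - 1:
                return True
        return False

    kept = [(ca, cb, apos) for ca, cb, apos in cols if not masked(ca, apos)]

    events: list[int] = []  # a-position of each difference event
    i = 0
    while i < len(kept):
        ca, cb, apos = kept[i]
        if ca != GAP and cb != GAP:
            if ca != cb:
                events.append(apos)
            i += 1
        elif ca == GAP:
            run_pos = max(1, apos)
            while i < len(kept) and kept[i][0] == GAP:
                i += 1
            events.append(run_pos)
        else:  # gap in b: the run's first column consumes an a residue
            run_pos = apos
            while i < len(kept) and kept[i][1] == GAP and kept[i][0] != GAP:
                i += 1
            events.append(run_pos)

    if not events:
        raise UndefinedFractionError(
            f"{a.id} and {b.id} show no differences; fraction undefined"
        )
    in_window = sum(1 for p in events if window[0] <= p <= window[1])
    return DifferenceConcentration(
        pair=(a.id, b.id), total_differences=len(events), window=window,
        in_window=in_window, fraction=in_window / len(events),
        mask=tuple(mask),
    )


def detect_leader(
    tx: TranscriptRecord, canonical_start: int
) -> list[LeaderPeptide]:
    """Upstream in-frame ATGs with no intervening in-frame stop.

    Results are ordered furthest-upstream first; ``leader_aa`` counts the
    extension residues (including the alternative initiator methionine) and
    ``leader_sequence`` is their translation.  Only ATG starts are considered.
    """
    seq = tx.residues
    if seq[canonical_start:canonical_start + 3] != "ATG":
        raise AnnotationError(
            f"{tx.id}: no ATG at claimed canonical start {canonical_start}"
        )
    alt_starts = []
    k = canonical_start - 3
    while k >= 0:
        codon = seq[k:k + 3]
        if codon in _STOPS:
            break
        if codon == "ATG":
            alt_starts.append(k)
        k -= 3
    leaders = []
    for alt in sorted(alt_starts):
        ext = seq[alt:canonical_start]
        leaders.append(LeaderPeptide(
            transcript_id=tx.id,
            canonical_start=canonical_start,
            alt_start=alt,
            leader_aa=len(ext) // 3,
            leader_sequence=str(Seq(ext).translate()),
        ))
    return leaders
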