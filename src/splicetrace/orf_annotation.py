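"""Homology-based annotation of candidate proteins from assembled transcripts.

Transcripts are scanned for open reading frames in all six frames, and each
candidate ORF is scored against a panel of trusted reference proteins with a
local (Smith–Waterman) aligner under affine gap penalties.  The best-scoring
ORF becomes the transcript's annotation; acceptance requires minimum score,
identity and reference coverage.  No E-values are computed — there is no
database size in this setting — so score + identity + coverage stand in for
search significance.

The local aligner is implemented here explicitly (rather than shelling out to
an external search tool) so that its tie-breaking is deterministic and fully
specified: among equal-scoring alignments prefer the earlier query start,
then the earlier reference start, then fewer gapped columns.  A gap of length
k costs ``gap_open + k * gap_extend`` (the existence/extension convention of
common search tools; defaults 11/1 with BLOSUM62).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Seq import Seq

from .errors import AlphabetError
from .gene_models import ProteinRecord

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptRecord:
    """An assembled transcript (mRNA) sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise AlphabetError(f"transcript {self.id!r} is empty")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise AlphabetError(f"transcript {self.id!r}: non-DNA symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfCall:
    """One ORF: frame in {+1,+2,+3,-1,-2,-3}, ATG offset, end past the stop.

    ``start``/``end`` are 0-based offsets into the frame's reading sequence
    (the transcript itself for + frames, its reverse complement for − frames).
    ``partial3`` marks ORFs running off the 3' end without a stop codon.
    """

    frame: int
    start: int
    end: int
    protein: str
    partial3: bool = False


@dataclass
class LocalAlignmentResult:
    """Optimal local alignment: score, identity over all columns, spans, path.

    ``column_pairs`` lists 1-based (query_pos, ref_pos) per column with None
    on the gapped side.  Identity is identical pairs divided by the total
    number of alignment columns (gap columns included).
    """

    score: float
    identity: float
    query_span: tuple[int, int] | None
    ref_span: tuple[int, int] | None
    column_pairs: list[tuple[int | None, int | None]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.column_pairs


@dataclass
class AnnotationThresholds:
    """Acceptance cutoffs for transcript annotation (repository defaults)."""

    score_min: float = 100.0
    identity_min: float = 0.30
    coverage_min: float = 0.60
    min_aa: int = 150


@dataclass
class AnnotatedProtein:
    """A transcript's best ORF, its best panel match, and the accept decision."""

    protein: ProteinRecord
    orf: OrfCall
    best_reference: str
    score: float
    identity: float
    coverage: float
    accepted: bool


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    # unknown residue X is neutral: contributes nothing either way
    for a in _AA_ALPHABET:
        table[(a, "X")] = 0.0
        table[("X", a)] = 0.0
    return table


def _translate_frame(seq: str, offset: int) -> str:
    usable = len(seq) - offset
    usable -= usable % 3
    if usable <= 0:
        return ""
    return str(Seq(seq[offset:offset + usable]).translate())


def find_orfs(
    tx: TranscriptRecord, min_aa: int = 1, all_starts: bool = False
) -> list[OrfCall]:
    """Scan all six frames for ATG-initiated ORFs of at least ``min_aa`` residues.

    Within one stop-bounded segment of a frame only the 5'-most ATG is
    reported unless ``all_starts`` is set.  ORFs reaching the end of the
    transcript without a stop are reported with ``partial3=True``.  Output is
    sorted longest protein first.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    revcomp = str(Seq(tx.residues).reverse_complement())
    calls: list[OrfCall] = []
    for frame in (1, 2, 3, -1, -2, -3):
        seq = tx.residues if frame > 0 else revcomp
        offset = abs(frame) - 1
        n_codons = (len(seq) - offset) // 3
        codons = [seq[offset + 3 * i: offset + 3 * i + 3] for i in range(n_codons)]
        seg_start = 0  # codon index opening the current stop-bounded segment
        starts_in_segment: list[int] = []
        for ci, codon in enumerate(codons + ["TAA"]):  # sentinel closes last segment
            is_sentinel = ci == len(codons)
            if codon in _STOPS:
                for si in starts_in_segment:
                    protein = "".join(
                        "X" if "N" in c else str(Seq(c).translate())
                        for c in codons[si:ci]
                    )
                    if len(protein) >= min_aa:
                        calls.append(OrfCall(
                            frame=frame,
                            start=offset + 3 * si,
                            end=offset + 3 * ci + (0 if is_sentinel else 3),
                            protein=protein,
                            partial3=is_sentinel,
                        ))
                    if not all_starts:
                        break
                seg_start = ci + 1
                starts_in_segment = []
            elif codon == "ATG":
                if all_starts or not starts_in_segment:
                    starts_in_segment.append(ci)
        del seg_start
    frame_order = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}
    calls.sort(key=lambda c: (-len(c.protein), frame_order[c.frame], c.start))
    return calls


def align_local(
    query: str,
    reference: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignmentResult:
    """Optimal local alignment under affine gaps, with deterministic tie-breaks.

    Raises :class:`AlphabetError` on non-amino-acid symbols.  Returns an empty
    result (score 0) when no positively scoring pair exists.
    """
    if not query or not reference:
        raise AlphabetError("align_local requires non-empty sequences")
    for label, s in (("query", query), ("reference", reference)):
        bad = set(s) - _AA_ALPHABET
        if bad:
            raise AlphabetError(f"{label}: non-amino-acid symbols {sorted(bad)}")
    score = matrix if matrix is not None else _blosum62()

    n, m = len(query), len(reference)
    NEG = float("-inf")
    BIGKEY = (1 << 30, 1 << 30, 1 << 30)
    # per-state matrices: value, tie-break key (qstart, rstart, gap_columns),
    # and backpointer (prev_state or 'new'); states: 0=M, 1=X(gap in ref), 2=Y(gap in query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    kM = [[BIGKEY] * (m + 1) for _ in range(n + 1)]
    kX = [[BIGKEY] * (m + 1) for _ in range(n + 1)]
    kY = [[BIGKEY] * (m + 1) for _ in range(n + 1)]
    bM = [[None] * (m + 1) for _ in range(n + 1)]
    bX = [[None] * (m + 1) for _ in range(n + 1)]
    bY = [[None] * (m + 1) for _ in range(n + 1)]

    best = 0.0
    best_key = BIGKEY
    best_cell = None
    open_cost = gap_open + gap_extend  # first gapped column pays existence + extension

    for i in range(1, n + 1):
        qi = query[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        kMi, kXi, kYi = kM[i], kX[i], kY[i]
        kMp, kXp, kYp = kM[i - 1], kX[i - 1], kY[i - 1]
        for j in range(1, m + 1):
            s = score[(qi, reference[j - 1])]
            # M: align qi with rj, continuing from any state or starting fresh
            val, key, bp = s, (i, j, 0), "new"
            for prev_val, prev_key, prev_state in (
                (Mp[j - 1], kMp[j - 1], 0),
                (Xp[j - 1], kXp[j - 1], 1),
                (Yp[j - 1], kYp[j - 1], 2),
            ):
                if prev_val == NEG:
                    continue
                cand = prev_val + s
                if cand > val or (cand == val and prev_key < key):
                    val, key, bp = cand, prev_key, prev_state
            if val > 0:
                Mi[j], kMi[j], bM[i][j] = val, key, bp
                if val > best or (
                    val == best
                    and best_cell is not None
                    and (key, i, j) < (best_key, best_cell[0], best_cell[1])
                ) or (val == best and best_cell is None):
                    best, best_key, best_cell = val, key, (i, j)
            # X: qi against a gap (gap column in reference)
            xo = Mp[j] - open_cost if Mp[j] != NEG else NEG
            xe = Xp[j] - gap_extend if Xp[j] != NEG else NEG
            if xo != NEG or xe != NEG:
                ko = (kMp[j][0], kMp[j][1], kMp[j][2] + 1)
                ke = (kXp[j][0], kXp[j][1], kXp[j][2] + 1)
                if xo > xe or (xo == xe and ko <= ke):
                    Xi[j], kXi[j], bX[i][j] = xo, ko, 0
                else:
                    Xi[j], kXi[j], bX[i][j] = xe, ke, 1
            # Y: gap column in query
            yo = Mi[j - 1] - open_cost if Mi[j - 1] != NEG else NEG
            ye = Yi[j - 1] - gap_extend if Yi[j - 1] != NEG else NEG
            if yo != NEG or ye != NEG:
                ko = (kMi[j - 1][0], kMi[j - 1][1], kMi[j - 1][2] + 1)
                ke = (kYi[j - 1][0], kYi[j - 1][1], kYi[j - 1][2] + 1)
                if yo > ye or (yo == ye and ko <= ke):
                    Yi[j], kYi[j], bY[i][j] = yo, ko, 0
                else:
                    Yi[j], kYi[j], bY[i][j] = ye, ke, 2

    if best_cell is None or best <= 0:
        return LocalAlignmentResult(score=0.0, identity=0.0,
                                    query_span=None, ref_span=None)

    # traceback from the best M cell
    pairs: list[tuple[int | None, int | None]] = []
    i, j = best_cell
    state = 0
    while True:
        if state == 0:
            pairs.append((i, j))
            bp = bM[i][j]
            i, j = i - 1, j - 1
            if bp == "new":
                break
            state = bp
        elif state == 1:
            pairs.append((i, None))
            state = bX[i][j]
            i -= 1
        else:
            pairs.append((None, j))
            state = bY[i][j]
            j -= 1
    pairs.reverse()

    matches = sum(
        1 for qp, rp in pairs
        if qp is not None and rp is not None and query[qp - 1] == reference[rp - 1]
    )
    qpos = [qp for qp, _ in pairs if qp is not None]
    rpos = [rp for _, rp in pairs if rp is not None]
    return LocalAlignmentResult(
        score=best,
        identity=matches / len(pairs),
        query_span=(qpos[0], qpos[-1]),
        ref_span=(rpos[0], rpos[-1]),
        column_pairs=pairs,
    )


def annotate_transcript(
    tx: TranscriptRecord,
    panel: list[ProteinRecord],
    thresholds: AnnotationThresholds | None = None,
) -> AnnotatedProtein | None:
    """Pick the ORF best matching the reference panel and apply acceptance cutoffs.

    Returns None when no ORF of sufficient length aligns with positive score.
    Coverage is the aligned reference span divided by reference length.
    """
    if not panel:
        raise ValueError("reference panel must be non-empty")
    th = thresholds or AnnotationThresholds()
    best: tuple[float, OrfCall, ProteinRecord, LocalAlignmentResult] | None = None
    for orf in find_orfs(tx, min_aa=th.min_aa):
        for ref in panel:
            aln = align_local(orf.protein, ref.residues)
            if aln.is_empty:
                continue
            if best is None or aln.score > best[0]:
                best = (aln.score, orf, ref, aln)
    if best is None:
        return None
    score, orf, ref, aln = best
    coverage = (aln.ref_span[1] - aln.ref_span[0] + 1) / len(ref.residues)
    accepted = (
        score >= th.score_min
        and aln.identity >= th.identity_min
        and coverage >= th.coverage_min
    )
    return AnnotatedProtein(
        protein=ProteinRecord(id=f"{tx.id}|orf", residues=orf.protein, taxon=tx.taxon),
        orf=orf,
        best_reference=ref.id,
        score=score,
        identity=aln.identity,
        coverage=coverage,
        accepted=accepted,
    )
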