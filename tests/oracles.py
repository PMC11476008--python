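"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: the local-alignment
oracle enumerates every monotone set of aligned residue pairs, the ORF oracle
re-scans frames positionally, and the junction-grouping oracle builds
equality classes directly.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


def enumerate_local_alignments(query: str, reference: str, score,
                               gap_open: float = 11.0,
                               gap_extend: float = 1.0) -> float:
    """Best local-alignment score by exhaustive enumeration (sequences <= 8).

    A local alignment is a non-empty monotone set of aligned index pairs;
    between consecutive pairs each skipped stretch in either sequence is one
    affine gap run costing open + len * extend.  No terminal gaps.
    """
    n, m = len(query), len(reference)
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            for ri in combinations(range(m), k):
                s = 0.0
                for t in range(k):
                    s += score[(query[qi[t]], reference[ri[t]])]
                    if t:
                        dq = qi[t] - qi[t - 1] - 1
                        dr = ri[t] - ri[t - 1] - 1
                        if dq:
                            s -= gap_open + dq * gap_extend
                        if dr:
                            s -= gap_open + dr * gap_extend
                if s > best:
                    best = s
    return best


def orf_scan(seq: str, min_aa: int):
    """Positional six-frame ORF scan: (frame, start, end, protein, partial3)."""
    out = set()
    rc = str(Seq(seq).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        pos = off
        claimed_from = -1  # positions before this belong to a reported ORF
        while pos + 3 <= len(s):
            if s[pos:pos + 3] == "ATG" and pos >= claimed_from:
                end = pos
                partial = True
                while end + 3 <= len(s):
                    if s[end:end + 3] in _STOPS:
                        partial = False
                        break
                    end += 3
                stop_end = end + 3 if not partial else end
                aa = "".join(
                    "X" if "N" in s[p:p + 3] else str(Seq(s[p:p + 3]).translate())
                    for p in range(pos, end, 3)
                )
                if len(aa) >= min_aa:
                    out.add((frame, pos, stop_end, aa, partial))
                claimed_from = stop_end  # only 5'-most ATG per segment
            pos += 3
    return out


def group_junctions_exact(jm: dict) -> set:
    """Equality-class grouping at tolerance 0 with matching phase: the set of
    (column, phase, frozenset(supporters)) shared by >= 2 sequences."""
    classes: dict[tuple, set] = {}
    for sid, pjs in jm.items():
        for pj in pjs:
            classes.setdefault((pj.column, pj.phase), set()).add(sid)
    return {
        (col, phase, frozenset(ids))
        for (col, phase), ids in classes.items() if len(ids) >= 2
    }
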