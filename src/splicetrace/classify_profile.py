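"""Homolog classification, clade presence/absence profiles, duplication support.

Each protein in the family alignment is summarised as a feature vector —
loop-insertion lengths, conservation of the catalytic and dimer-interface
residue sets, intron presence — and classified by an ordered rule list into
the homolog classes observed across Amorphea:

* ``CLASS_I_PRPS``: intact catalytic set, no loop insertions (classical,
  allosterically regulated PRPS; e.g. PRPS1/PRPS2);
* ``CLASS_I_RETROCOPY``: same but intronless (e.g. PRPS1L1);
* ``CLASS_II_PRPS``: intact catalytic set but poorly conserved dimer
  interfaces (bent and/or parallel);
* ``PRPSAP_LIKE``: long insertion in the catalytic flexible loop plus a
  degraded catalytic set (the NHR-bearing non-catalytic paralogs);
* ``PRS5_LIKE``: long insertion in the regulatory flexible loop (fungal-type
  Prs5 orthologs; may additionally carry CF-loop insertions, hence this rule
  fires first).

Class calls aggregate into a clade-by-class presence/absence profile, and
duplication origin is scored by comparing a putative child set's identity to
a candidate parent clade versus an outgroup, with bootstrap support and
shared-junction counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .alignment_projection import JunctionMap, Msa, call_shared_junctions
from .errors import ConsistencyError, MappingError
from .gene_models import IntronPosition
from .region_analysis import (
    RegionSet,
    detect_insertions,
    residue_correspondence,
)

CLASSES = (
    "CLASS_I_PRPS",
    "CLASS_II_PRPS",
    "PRPSAP_LIKE",
    "PRS5_LIKE",
    "CLASS_I_RETROCOPY",
    "UNCLASSIFIED",
)


@dataclass
class FeatureVector:
    """Per-sequence diagnostic features feeding the classifier."""

    id: str
    cf_loop_insertion_len: int = 0
    reg_loop_insertion_len: int = 0
    catalytic_conservation: float = 1.0
    bent_interface_conservation: float = 1.0
    parallel_interface_conservation: float = 1.0
    allosteric_conservation: float = 1.0
    intronless: bool | None = None  # None = unknown (no gene model supplied)


@dataclass
class HomologClass:
    """A class call plus the rules that produced it."""

    label: str
    rationale: list[str] = field(default_factory=list)


@dataclass
class ClassifyThresholds:
    """Rule cutoffs (repository defaults; every report should echo them)."""

    ins_min: int = 10          # residues: minimum NHR-style insertion
    cat_low: float = 0.4       # catalytic set conserved at/below this = degraded
    cat_high: float = 0.8      # at/above this = intact (>= 4/5 of the classic set)
    iface_low: float = 0.5     # either dimer interface at/below this = poorly conserved


@dataclass
class DuplicationSupport:
    """Evidence that a child gene set arose from a candidate parent clade."""

    child_set: tuple[str, ...]
    parent_candidate_set: tuple[str, ...]
    outgroup_set: tuple[str, ...]
    mean_parent_identity: float
    mean_outgroup_identity: float
    delta: float
    shared_junction_count: int
    bootstrap_support: float


def _set_conservation(msa: Msa, rs: RegionSet, set_name: str,
                      targets: Sequence[str]) -> dict[str, float]:
    """Fraction of a residue set conserved (identical to reference) per target."""
    if set_name not in rs.residue_sets:
        return {t: 1.0 for t in targets}
    table = residue_correspondence(msa, rs, set_name, targets)
    out = {}
    for tid, sub in table.groupby("target_id"):
        out[str(tid)] = float(sub["conserved"].mean())
    return {t: out.get(t, 1.0) for t in targets}


def extract_features(
    msa: Msa,
    rs: RegionSet,
    introns: Mapping[str, Sequence[IntronPosition]] | None = None,
    min_insertion: int = 10,
    cf_region: str = "CF_loop",
    reg_region: str = "regulatory_loop",
) -> list[FeatureVector]:
    """Assemble one feature vector per aligned sequence.

    Insertion lengths come from :func:`detect_insertions` (largest call per
    region), conservation fractions from residue-set correspondence against
    the reference.  ``intronless`` is None for sequences without a gene model.
    """
    if introns:
        unknown = set(introns) - set(msa.ids)
        if unknown:
            raise ConsistencyError(f"intron map ids not in alignment: {sorted(unknown)}")
    calls = detect_insertions(msa, rs, min_insertion=min_insertion)
    ins: dict[tuple[str, str], int] = {}
    for c in calls:
        key = (c.sequence_id, c.region_name)
        ins[key] = max(ins.get(key, 0), c.length)
    cat = _set_conservation(msa, rs, "catalytic", msa.ids)
    bent = _set_conservation(msa, rs, "bent_dimer", msa.ids)
    para = _set_conservation(msa, rs, "parallel_dimer", msa.ids)
    allo = _set_conservation(msa, rs, "allosteric", msa.ids)
    vectors = []
    for sid in msa.ids:
        if introns is None or sid not in introns:
            intronless = None
        else:
            intronless = len(introns[sid]) == 0
        vectors.append(FeatureVector(
            id=sid,
            cf_loop_insertion_len=ins.get((sid, cf_region), 0),
            reg_loop_insertion_len=ins.get((sid, reg_region), 0),
            catalytic_conservation=cat[sid],
            bent_interface_conservation=bent[sid],
            parallel_interface_conservation=para[sid],
            allosteric_conservation=allo[sid],
            intronless=intronless,
        ))
    return vectors


def classify(
    fv: FeatureVector, thresholds: ClassifyThresholds | None = None
) -> HomologClass:
    """Ordered-rule class call; deterministic and total."""
    th = thresholds or ClassifyThresholds()
    if fv.reg_loop_insertion_len >= th.ins_min:
        return HomologClass("PRS5_LIKE", [
            f"regulatory-loop insertion {fv.reg_loop_insertion_len} >= {th.ins_min}",
        ])
    if (fv.cf_loop_insertion_len >= th.ins_min
            and fv.catalytic_conservation <= th.cat_low):
        return HomologClass("PRPSAP_LIKE", [
            f"CF-loop insertion {fv.cf_loop_insertion_len} >= {th.ins_min}",
            f"catalytic conservation {fv.catalytic_conservation:.2f} <= {th.cat_low}",
        ])
    if fv.catalytic_conservation >= th.cat_high:
        iface = min(fv.bent_interface_conservation,
                    fv.parallel_interface_conservation)
        if iface <= th.iface_low:
            return HomologClass("CLASS_II_PRPS", [
                f"catalytic conservation {fv.catalytic_conservation:.2f} >= {th.cat_high}",
                f"min interface conservation {iface:.2f} <= {th.iface_low}",
            ])
        rationale = [
            f"catalytic conservation {fv.catalytic_conservation:.2f} >= {th.cat_high}",
        ]
        if fv.intronless is True:
            return HomologClass("CLASS_I_RETROCOPY",
                                rationale + ["intronless gene model"])
        return HomologClass("CLASS_I_PRPS", rationale)
    return HomologClass("UNCLASSIFIED", [])


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV taxon -> clade (header optional)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
                continue
            taxon, clade = line.split("\t")[:2]
            out[taxon] = clade
    return out


def build_profile(
    classified: Sequence[tuple[str, str, HomologClass]],
    taxon_map: Mapping[str, str],
    tree: "dendropy.Tree | None" = None,  # noqa: F821
) -> "pandas.DataFrame":  # noqa: F821
    """Clade × class count matrix (presence = count >= 1).

    ``classified`` rows are (sequence id, taxon, class call).  Every taxon
    must be mapped to a clade; an optional tree orders clade rows by the
    first matching tip/node label.
    """
    import pandas as pd

    unmapped = sorted({t for _, t, _ in classified if t not in taxon_map})
    if unmapped:
        raise MappingError(f"taxa missing from taxon map: {unmapped}")
    clades = sorted({taxon_map[t] for _, t, _ in classified}) or []
    counts = pd.DataFrame(0, index=clades, columns=list(CLASSES), dtype=int)
    for _, taxon, call in classified:
        counts.loc[taxon_map[taxon], call.label] += 1
    if tree is not None and len(counts):
        order = []
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            if label in counts.index and label not in order:
                order.append(label)
        order += [c for c in counts.index if c not in order]
        counts = counts.loc[order]
    counts.index.name = "clade"
    return counts


def _mean_pairwise_identity(
    group_a: Mapping[str, str], group_b: Mapping[str, str]
) -> tuple[float, list[float]]:
    """Mean global identity over all cross pairs; identity = matches over
    columns where both sequences are aligned (end-gap-free global alignment)."""
    from .region_analysis import _global_pair_alignment

    values = []
    for a in group_a.values():
        for b in group_b.values():
            ga, gb = _global_pair_alignment(a, b)
            both = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
            matches = sum(1 for x, y in both if x == y)
            values.append(matches / len(both) if both else 0.0)
    return (sum(values) / len(values) if values else 0.0), values


def duplication_support(
    child: Mapping[str, str],
    parent_candidates: Mapping[str, str],
    outgroup: Mapping[str, str],
    jm: JunctionMap | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> DuplicationSupport:
    """Does the child set look descended from the parent clade?

    Positive ``delta`` (mean child↔parent identity minus mean child↔outgroup
    identity) supports an origin inside the parent clade; ``bootstrap_support``
    is the fraction of pair-resampled replicates with delta > 0.  When a
    junction map is supplied, junctions shared child↔parent at tolerance 0
    and equal phase are counted as corroborating gene-structure evidence.
    """
    import numpy as np

    if not child or not parent_candidates or not outgroup:
        raise ValueError("child, parent and outgroup sets must be non-empty")
    mean_parent, parent_vals = _mean_pairwise_identity(child, parent_candidates)
    mean_out, out_vals = _mean_pairwise_identity(child, outgroup)

    shared = 0
    if jm is not None:
        sub = {k: v for k, v in jm.items() if k in child or k in parent_candidates}
        for sj in call_shared_junctions(sub, shift_tolerance=0,
                                        require_same_phase=True):
            if sj.supporters & set(child) and sj.supporters & set(parent_candidates):
                shared += 1

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        p = rng.choice(parent_vals, size=len(parent_vals), replace=True).mean()
        o = rng.choice(out_vals, size=len(out_vals), replace=True).mean()
        if p - o > 0:
            hits += 1
    return DuplicationSupport(
        child_set=tuple(child),
        parent_candidate_set=tuple(parent_candidates),
        outgroup_set=tuple(outgroup),
        mean_parent_identity=mean_parent,
        mean_outgroup_identity=mean_out,
        delta=mean_parent - mean_out,
        shared_junction_count=shared,
        bootstrap_support=hits / n_boot if n_boot else 0.0,
    )
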