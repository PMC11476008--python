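"""Gene-family simulator with a known evolutionary history.

Generates a PRPS-like gene family evolving on a clade tree: per-branch
amino-acid substitution, intron gain/loss, and scripted events — gene
duplication, loop-window insertion (NHR), degradation of a residue set
(catalytic or interface), retrotransposition to an intronless copy, and
addition of an upstream in-frame leader start.  Every derived file (genomic
sequence, exon table, transcript, protein, true alignment) is mutually
consistent by construction, and the ground truth (classes, junction homology,
event log) is recorded so that every analysis stage of the package can be
tested against a known answer.

Model choices, deliberately simple:

* substitutions act at the amino-acid level (the codon is re-drawn
  synonymously for the new residue); with probability ``blosum_bias`` the
  replacement is drawn from BLOSUM62-positive neighbours of the old residue,
  otherwise uniformly from the other 19;
* residues belonging to any named residue set are protected from random
  substitution — a cartoon of purifying selection at functional sites — and
  change only through explicit ``degrade`` events, which force non-identical,
  BLOSUM62-non-positive replacements;
* insertions are codon-aligned (no frameshifts) and confined to named region
  windows; no other indels occur, so the true alignment is exact;
* intron gain/loss counts are Poisson per branch; the per-site substitution
  probability on a branch of length d is 1 − exp(−d·rate).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from .alignment_projection import Msa
from .classify_profile import ClassifyThresholds, FeatureVector, classify
from .errors import ConfigError
from .gene_models import (
    EXON_TABLE_COLUMNS,
    GeneModel,
    GenomicSequence,
    IntronPosition,
    ProteinRecord,
    write_fasta,
)
from .orf_annotation import TranscriptRecord, _blosum62

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")


def _codon_table() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


_CODONS = _codon_table()
_NONSTOP_CODONS = sorted(c for cs in _CODONS.values() for c in cs)


def _blosum_groups() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per residue: BLOSUM62-positive neighbours and non-positive replacements."""
    b = _blosum62()
    pos, neg = {}, {}
    for a in _AA20:
        pos[a] = [x for x in _AA20 if x != a and b[(a, x)] > 0]
        neg[a] = [x for x in _AA20 if x != a and b[(a, x)] <= 0]
    return pos, neg


_BLOSUM_POS, _BLOSUM_NEG = _blosum_groups()


@dataclass
class EventSpec:
    """One scripted event on a named branch of the clade tree."""

    branch: str
    kind: str  # duplication | insertion | degrade | retrocopy | leader
    gene: str
    new_gene: str | None = None
    region: str | None = None
    length: int = 0
    residue_set: str | None = None
    fraction: float = 0.0
    leader_aa: int = 0


@dataclass
class SimulationConfig:
    """Everything that defines one simulated family (fully seed-reproducible)."""

    seed: int = 0
    clade_tree: str = (
        "((Holozoa:0.10,Holomycota:0.10)Opisthokonta:0.08,"
        "Amoebozoa:0.30)Amorphea;"
    )
    n_taxa_per_clade: int = 2
    taxon_branch_length: float = 0.05
    ancestral_protein_length: int = 320
    intron_set: tuple[tuple[int, int], ...] = ((45, 0), (102, 1), (171, 2), (240, 0))
    substitution_rate: float = 1.0
    blosum_bias: float = 0.5
    intron_gain_rate: float = 0.0
    intron_loss_rate: float = 0.0
    intron_length: int = 84
    utr5_codons: int = 10
    utr3_length: int = 30
    flank_length: int = 25
    root_gene: str = "PRPS"
    regions: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "FLAG": (31, 45),
        "regulatory_loop": (92, 108),
        "CF_loop": (128, 144),
        "PP_loop": (170, 174),
        "R5P_loop": (213, 228),
    })
    residue_sets: dict[str, list[int]] = field(default_factory=lambda: {
        "catalytic": [171, 194, 196, 200, 225],
        "bent_dimer": [50, 54, 58, 62, 66, 70],
        "parallel_dimer": [250, 254, 258, 262, 266, 270],
        "allosteric": [280, 284, 288, 292],
    })
    events: list[EventSpec] = field(default_factory=list)

    def validate(self) -> None:
        L = self.ancestral_protein_length
        if L < 50:
            raise ConfigError("ancestral_protein_length must be >= 50")
        for name, (s, e) in self.regions.items():
            if not (1 <= s <= e <= L):
                raise ConfigError(f"region {name!r} [{s},{e}] outside 1..{L}")
        for name, positions in self.residue_sets.items():
            if any(not 2 <= p <= L for p in positions):
                raise ConfigError(f"residue set {name!r} has positions outside 2..{L}")
        for ci, ph in self.intron_set:
            if not (1 <= ci <= L and ph in (0, 1, 2)):
                raise ConfigError(f"intron ({ci},{ph}) invalid for length {L}")
        if self.substitution_rate < 0 or self.intron_gain_rate < 0 \
                or self.intron_loss_rate < 0:
            raise ConfigError("rates must be >= 0")
        for ev in self.events:
            if ev.kind not in {"duplication", "insertion", "degrade",
                               "retrocopy", "leader"}:
                raise ConfigError(f"unknown event kind {ev.kind!r}")
            if ev.kind == "insertion" and ev.region not in self.regions:
                raise ConfigError(f"insertion event references unknown region {ev.region!r}")
            if ev.kind == "degrade":
                if ev.residue_set not in self.residue_sets:
                    raise ConfigError(f"degrade references unknown set {ev.residue_set!r}")
                if not 0 < ev.fraction <= 1:
                    raise ConfigError(f"degrade fraction {ev.fraction} outside (0,1]")
            if ev.kind in {"duplication", "retrocopy"} and not ev.new_gene:
                raise ConfigError(f"{ev.kind} event needs new_gene")
            if ev.kind == "leader" and not ev.leader_aa >= 1:
                raise ConfigError("leader event needs leader_aa >= 1")


def default_config(seed: int = 0, **overrides: Any) -> SimulationConfig:
    """The stock Amorphea scenario: an opisthokont duplication producing an
    NHR-bearing, catalytically degraded paralog (PRPSAP-like), a fungal
    duplicate with a regulatory-loop insertion (Prs5-like), a holozoan
    retrocopy, and an N-terminal leader on the paralog."""
    cfg = SimulationConfig(seed=seed, events=[
        EventSpec(branch="Opisthokonta", kind="duplication",
                  gene="PRPS", new_gene="AP"),
        EventSpec(branch="Opisthokonta", kind="insertion",
                  gene="AP", region="CF_loop", length=25),
        EventSpec(branch="Opisthokonta", kind="degrade",
                  gene="AP", residue_set="catalytic", fraction=0.8),
        EventSpec(branch="Holomycota", kind="duplication",
                  gene="PRPS", new_gene="Prs5"),
        EventSpec(branch="Holomycota", kind="insertion",
                  gene="Prs5", region="regulatory_loop", length=25),
        EventSpec(branch="Holozoa", kind="retrocopy",
                  gene="PRPS", new_gene="PRPS_retro"),
        EventSpec(branch="Holozoa", kind="leader", gene="AP", leader_aa=29),
    ])
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def paralog_pair_config(seed: int = 0) -> SimulationConfig:
    """A jawed-vertebrate-style paralog pair (AP1/AP2 pattern): AP2 arises by
    duplication from AP1 and acquires rapid N-terminal divergence, an NHR in
    the catalytic flexible loop and a fully degraded catalytic set; both
    carry upstream in-frame leaders (29 and 12 residues)."""
    cfg = SimulationConfig(
        seed=seed, clade_tree="(Vertebrata:0.02)Gnathostomata;",
        n_taxa_per_clade=1, taxon_branch_length=0.0, root_gene="AP1")
    taken = {p for ps in cfg.residue_sets.values() for p in ps}
    cfg.residue_sets["nterm_block"] = [
        p for p in range(2, 92) if p not in taken][:30]
    cfg.events = [
        EventSpec(branch="Gnathostomata", kind="duplication",
                  gene="AP1", new_gene="AP2"),
        EventSpec(branch="Gnathostomata", kind="degrade", gene="AP2",
                  residue_set="nterm_block", fraction=0.9),
        EventSpec(branch="Gnathostomata", kind="degrade", gene="AP2",
                  residue_set="catalytic", fraction=1.0),
        EventSpec(branch="Gnathostomata", kind="insertion", gene="AP2",
                  region="CF_loop", length=25),
        EventSpec(branch="Gnathostomata", kind="leader", gene="AP1",
                  leader_aa=29),
        EventSpec(branch="Gnathostomata", kind="leader", gene="AP2",
                  leader_aa=12),
    ]
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML.

    The document is a mapping of config fields; ``events`` is a list of
    mappings with :class:`EventSpec` fields, ``regions`` maps names to
    ``[start, end]`` pairs, ``intron_set`` is a list of ``[codon, phase]``
    pairs.  Omitted fields keep their defaults.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = SimulationConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"{path}: unknown config field {key!r}")
        if key == "events":
            value = [EventSpec(**e) for e in value]
        elif key == "regions":
            value = {k: (int(v[0]), int(v[1])) for k, v in value.items()}
        elif key == "residue_sets":
            value = {k: [int(p) for p in v] for k, v in value.items()}
        elif key == "intron_set":
            value = tuple((int(a), int(b)) for a, b in value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@dataclass
class _Intron:
    uid: str
    host_key: tuple
    phase: int


@dataclass
class _Gene:
    name: str
    aas: list[str]
    codons: list[str]
    keys: list[tuple]
    introns: list[_Intron]
    leader_codons: list[str] = field(default_factory=list)
    insertions: list[tuple[str, int]] = field(default_factory=list)  # (region, len)
    degraded: dict[str, float] = field(default_factory=dict)
    retro: bool = False


@dataclass
class SimulatedFamily:
    """All artefacts of one simulation plus its ground truth."""

    config: SimulationConfig
    genomes: dict[str, GenomicSequence]
    models: list[GeneModel]
    transcripts: dict[str, TranscriptRecord]
    canonical_starts: dict[str, int]
    proteins: dict[str, ProteinRecord]
    alignment: Msa
    region_set: "RegionSet"  # noqa: F821
    truth: dict[str, Any]

    def intron_positions(self) -> dict[str, list[IntronPosition]]:
        """Ground-truth intron positions per sequence id."""
        out = {}
        for sid, junctions in self.truth["junctions"].items():
            out[sid] = [
                IntronPosition(intron_rank=i + 1, codon_index=ci, phase=ph)
                for i, (_, ci, ph) in enumerate(junctions)
            ]
        return out


def _parse_tree(newick: str):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = set()
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label:
            labels.add(label.replace(" ", "_"))
    return tree, labels


def _node_label(node) -> str:
    label = node.taxon.label if node.taxon else node.label
    return (label or "").replace(" ", "_")


def _substitute(gene: _Gene, p: float, protected: set[int],
                bias: float, rng: np.random.Generator) -> int:
    """Random substitutions on mutable sites; returns the number applied."""
    n_sub = 0
    for i in range(1, len(gene.aas)):  # position 0 (Met/ATG) is immutable
        key = gene.keys[i]
        if key[1] == -1 and (key[0] + 1) in protected:
            continue
        if rng.random() >= p:
            continue
        old = gene.aas[i]
        if old not in _AA20:
            continue
        pool = _BLOSUM_POS[old] if (rng.random() < bias and _BLOSUM_POS[old]) \
            else _BLOSUM_NEG[old]
        new = pool[rng.integers(len(pool))]
        gene.aas[i] = new
        gene.codons[i] = _CODONS[new][rng.integers(len(_CODONS[new]))]
        n_sub += 1
    return n_sub


def _random_protein(L: int, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    aas = ["M"] + [_AA20[rng.integers(20)] for _ in range(L - 1)]
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aas]
    codons[0] = "ATG"
    return aas, codons


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[rng.integers(4)] for _ in range(n))


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Run the simulation; fully reproducible from ``cfg.seed``."""
    from .region_analysis import RegionSet

    cfg.validate()
    tree, labels = _parse_tree(cfg.clade_tree)
    for ev in cfg.events:
        if ev.branch not in labels:
            raise ConfigError(f"event branch {ev.branch!r} not in clade tree")

    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestral_protein_length
    protected = {p for ps in cfg.residue_sets.values() for p in ps}
    ancestral_aas, ancestral_codons = _random_protein(L, rng)
    root_gene = _Gene(
        name=cfg.root_gene,
        aas=ancestral_aas,
        codons=ancestral_codons,
        keys=[(i, -1, 0) for i in range(L)],
        introns=[
            _Intron(uid=f"anc_{k}", host_key=(ci - 1, -1, 0), phase=ph)
            for k, (ci, ph) in enumerate(cfg.intron_set)
        ],
    )

    counters = {"event": 0, "gain": 0}
    event_log: list[dict[str, Any]] = []

    def apply_branch(genes: list[_Gene], length: float, label: str) -> None:
        p = 1.0 - float(np.exp(-length * cfg.substitution_rate))
        for gene in genes:
            n = _substitute(gene, p, protected, cfg.blosum_bias, rng)
            if n:
                event_log.append({"branch": label, "gene": gene.name,
                                  "kind": "substitutions", "count": n})
            for _ in range(rng.poisson(cfg.intron_gain_rate)):
                pos = int(rng.integers(1, 3 * len(gene.aas)))
                ci, ph = pos // 3 + 1, pos % 3
                counters["gain"] += 1
                gene.introns.append(_Intron(
                    uid=f"gain_{counters['gain']}",
                    host_key=gene.keys[ci - 1], phase=ph,
                ))
                event_log.append({"branch": label, "gene": gene.name,
                                  "kind": "intron_gain", "codon_index": ci,
                                  "phase": ph})
            for _ in range(rng.poisson(cfg.intron_loss_rate)):
                if gene.introns:
                    lost = gene.introns.pop(int(rng.integers(len(gene.introns))))
                    event_log.append({"branch": label, "gene": gene.name,
                                      "kind": "intron_loss", "intron": lost.uid})

    def apply_events(genes: list[_Gene], label: str) -> None:
        for ev in cfg.events:
            if ev.branch != label:
                continue
            by_name = {g.name: g for g in genes}
            if ev.gene not in by_name:
                raise ConfigError(
                    f"event on branch {label!r} references gene {ev.gene!r} "
                    f"not present there"
                )
            gene = by_name[ev.gene]
            if ev.kind == "duplication":
                dup = copy.deepcopy(gene)
                dup.name = ev.new_gene
                genes.append(dup)
            elif ev.kind == "retrocopy":
                retro = copy.deepcopy(gene)
                retro.name = ev.new_gene
                retro.introns = []
                retro.retro = True
                genes.append(retro)
            elif ev.kind == "insertion":
                s, e = cfg.regions[ev.region]
                anchors = [i for i, k in enumerate(gene.keys)
                           if k[1] == -1 and s - 1 <= k[0] <= e - 2]
                if not anchors:
                    raise ConfigError(f"region {ev.region!r} has no anchor residues")
                at = anchors[int(rng.integers(len(anchors)))]
                counters["event"] += 1
                eid = counters["event"]
                new_aas = [_AA20[rng.integers(20)] for _ in range(ev.length)]
                new_codons = [_CODONS[a][rng.integers(len(_CODONS[a]))]
                              for a in new_aas]
                new_keys = [(gene.keys[at][0], eid, k) for k in range(ev.length)]
                gene.aas[at + 1:at + 1] = new_aas
                gene.codons[at + 1:at + 1] = new_codons
                gene.keys[at + 1:at + 1] = new_keys
                gene.insertions.append((ev.region, ev.length))
            elif ev.kind == "degrade":
                positions = cfg.residue_sets[ev.residue_set]
                n_target = int(round(ev.fraction * len(positions)))
                chosen = list(rng.choice(positions, size=n_target, replace=False))
                for pos in sorted(int(p) for p in chosen):
                    idx = gene.keys.index((pos - 1, -1, 0))
                    old = gene.aas[idx]
                    pool = _BLOSUM_NEG.get(old) or [a for a in _AA20 if a != old]
                    new = pool[rng.integers(len(pool))]
                    gene.aas[idx] = new
                    gene.codons[idx] = _CODONS[new][rng.integers(len(_CODONS[new]))]
                gene.degraded[ev.residue_set] = max(
                    gene.degraded.get(ev.residue_set, 0.0),
                    n_target / len(positions),
                )
            elif ev.kind == "leader":
                pool = [c for c in _NONSTOP_CODONS if c != "ATG"]
                gene.leader_codons = ["ATG"] + [
                    pool[rng.integers(len(pool))] for _ in range(ev.leader_aa - 1)
                ]
            event_log.append({"branch": label, **asdict(ev)})

    # evolve down the clade tree, then add per-taxon terminal branches
    taxa_genes: list[tuple[str, str, list[_Gene]]] = []  # (clade, taxon, genes)
    node_genes: dict[int, list[_Gene]] = {id(tree.seed_node): [root_gene]}
    apply_events(node_genes[id(tree.seed_node)], _node_label(tree.seed_node))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_set = node_genes[id(node.parent_node)]
            genes = copy.deepcopy(parent_set)
            label = _node_label(node)
            apply_branch(genes, node.edge.length or 0.0, label)
            apply_events(genes, label)
            node_genes[id(node)] = genes
        if node.is_leaf():
            clade = _node_label(node)
            for t in range(1, cfg.n_taxa_per_clade + 1):
                taxon = f"{clade}_t{t}"
                tg = copy.deepcopy(node_genes[id(node)])
                apply_branch(tg, cfg.taxon_branch_length, taxon)
                taxa_genes.append((clade, taxon, tg))

    # realise sequences, gene models, transcripts
    genomes: dict[str, GenomicSequence] = {}
    models: list[GeneModel] = []
    transcripts: dict[str, TranscriptRecord] = {}
    canonical_starts: dict[str, int] = {}
    proteins: dict[str, ProteinRecord] = {}
    truth_class: dict[str, str] = {}
    truth_junctions: dict[str, list[tuple[str, int, int]]] = {}
    truth_leaders: dict[str, int] = {}
    truth_insertions: dict[str, list[tuple[str, int]]] = {}
    taxon_to_clade: dict[str, str] = {}
    key_rows: dict[str, dict[tuple, str]] = {}

    reference_id = None
    for clade, taxon, genes in taxa_genes:
        taxon_to_clade[taxon] = clade
        for gene in genes:
            sid = f"{taxon}|{gene.name}"
            if reference_id is None and gene.name == cfg.root_gene:
                reference_id = sid
            protein = "".join(gene.aas)
            proteins[sid] = ProteinRecord(id=sid, residues=protein,
                                          source_gene=sid, taxon=taxon)
            key_rows[sid] = dict(zip(gene.keys, gene.aas))

            # intron bookkeeping: cds offset of intron i = 3*host_index + phase
            placed = []
            for intr in gene.introns:
                host = gene.keys.index(intr.host_key)
                placed.append((3 * host + intr.phase, intr))
            placed.sort(key=lambda x: x[0])
            truth_junctions[sid] = [
                (intr.uid, off // 3 + 1, off % 3) for off, intr in placed
            ]
            truth_insertions[sid] = list(gene.insertions)
            truth_leaders[sid] = len(gene.leader_codons)

            # ground-truth class from the event history, not from the sequence
            fv = FeatureVector(
                id=sid,
                cf_loop_insertion_len=sum(
                    n for r, n in gene.insertions if r == "CF_loop"),
                reg_loop_insertion_len=sum(
                    n for r, n in gene.insertions if r == "regulatory_loop"),
                catalytic_conservation=1.0 - gene.degraded.get("catalytic", 0.0),
                bent_interface_conservation=1.0 - gene.degraded.get("bent_dimer", 0.0),
                parallel_interface_conservation=1.0 - gene.degraded.get(
                    "parallel_dimer", 0.0),
                allosteric_conservation=1.0 - gene.degraded.get("allosteric", 0.0),
                intronless=len(gene.introns) == 0,
            )
            truth_class[sid] = classify(fv, ClassifyThresholds()).label

            # assemble locus on the + strand, then maybe flip
            cds = "".join(gene.codons) + "TAA"
            utr5_codons = []
            pool = [c for c in _NONSTOP_CODONS if c != "ATG"]
            for _ in range(cfg.utr5_codons - 1):
                utr5_codons.append(pool[rng.integers(len(pool))])
            utr5 = "".join(utr5_codons) + "TAA"  # in-frame stop just upstream
            leader = "".join(gene.leader_codons)
            utr3 = _random_dna(cfg.utr3_length, rng)
            transcripts[sid] = TranscriptRecord(
                id=sid, residues=utr5 + leader + cds + utr3, taxon=taxon)
            canonical_starts[sid] = len(utr5) + len(leader)

            intron_seqs = {
                intr.uid: "GT" + _random_dna(cfg.intron_length - 4, rng) + "AG"
                for _, intr in placed
            }
            cds_start = cfg.flank_length + len(utr5) + len(leader)
            pre_parts, exon_bounds = [], []
            prev = 0
            genome_cursor = cds_start
            for off, intr in placed:
                pre_parts.append(cds[prev:off])
                exon_bounds.append((genome_cursor, genome_cursor + (off - prev)))
                genome_cursor += (off - prev) + cfg.intron_length
                pre_parts.append(intron_seqs[intr.uid])
                prev = off
            pre_parts.append(cds[prev:])
            exon_bounds.append((genome_cursor, genome_cursor + len(cds) - prev))
            locus = (
                _random_dna(cfg.flank_length, rng) + utr5 + leader
                + "".join(pre_parts) + utr3
                + _random_dna(cfg.flank_length, rng)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genome_id = f"{sid}_locus"
            if strand == "-":
                from Bio.Seq import Seq

                locus_out = str(Seq(locus).reverse_complement())
                n = len(locus)
                exons = [(n - e, n - s) for s, e in exon_bounds]
            else:
                locus_out = locus
                exons = exon_bounds
            genomes[genome_id] = GenomicSequence(
                id=genome_id, residues=locus_out, taxon=taxon)
            from .gene_models import ExonInterval

            models.append(GeneModel(
                gene_id=sid, taxon=taxon, strand=strand, genome_id=genome_id,
                exons=[ExonInterval(start=s, end=e, rank=i + 1)
                       for i, (s, e) in enumerate(exons)],
            ))

    # true alignment from homology keys
    all_keys = sorted({k for row in key_rows.values() for k in row})
    ids = sorted(key_rows)
    rows = ["".join(key_rows[sid].get(k, "-") for k in all_keys) for sid in ids]
    alignment = Msa(ids=ids, rows=rows)

    region_set = RegionSet(
        reference_id=reference_id,
        regions=dict(cfg.regions),
        residue_sets={
            name: [(p, ancestral_aas[p - 1]) for p in sorted(positions)]
            for name, positions in cfg.residue_sets.items()
        },
    )

    truth = {
        "reference_id": reference_id,
        "ancestral_protein": "".join(ancestral_aas),
        "classes": truth_class,
        "junctions": truth_junctions,
        "leaders": truth_leaders,
        "insertions": truth_insertions,
        "taxon_to_clade": taxon_to_clade,
        "events": event_log,
    }
    return SimulatedFamily(
        config=cfg, genomes=genomes, models=models, transcripts=transcripts,
        canonical_starts=canonical_starts, proteins=proteins,
        alignment=alignment, region_set=region_set, truth=truth,
    )


def write_fixture_files(fam: SimulatedFamily, out_dir: str | Path) -> dict[str, str]:
    """Write the family as plain-text fixtures; returns a manifest of hashes.

    Re-running with the same config produces byte-identical files (the
    manifest stores per-file SHA-256 plus a hash of the config itself).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_fasta(sorted((g.id, g.residues) for g in fam.genomes.values()),
                out / "genomes.fasta")
    write_fasta(sorted((p.id, p.residues) for p in fam.proteins.values()),
                out / "proteins.fasta")
    write_fasta(sorted((t.id, t.residues) for t in fam.transcripts.values()),
                out / "transcripts.fasta")
    write_fasta(zip(fam.alignment.ids, fam.alignment.rows),
                out / "alignment.fasta")

    with open(out / "models.tsv", "w") as fh:
        fh.write("\t".join(EXON_TABLE_COLUMNS) + "\n")
        for m in sorted(fam.models, key=lambda m: m.gene_id):
            for e in m.exons:
                fh.write("\t".join(map(str, (
                    m.gene_id, m.taxon, m.genome_id, m.strand,
                    e.start, e.end, e.rank))) + "\n")

    with open(out / "regions.tsv", "w") as fh:
        fh.write("name\tkind\tvalue\n")
        for name, (s, e) in fam.region_set.regions.items():
            fh.write(f"{name}\tregion\t{s}-{e}\n")
        for name, members in fam.region_set.residue_sets.items():
            tokens = ",".join(f"{aa}{p}" for p, aa in members)
            fh.write(f"{name}\tset\t{tokens}\n")

    with open(out / "taxon_map.tsv", "w") as fh:
        fh.write("taxon\tclade\n")
        for taxon, clade in sorted(fam.truth["taxon_to_clade"].items()):
            fh.write(f"{taxon}\t{clade}\n")

    with open(out / "clade_tree.nwk", "w") as fh:
        fh.write(fam.config.clade_tree.strip() + "\n")

    with open(out / "canonical_starts.tsv", "w") as fh:
        fh.write("transcript_id\tcanonical_start\n")
        for sid, start in sorted(fam.canonical_starts.items()):
            fh.write(f"{sid}\t{start}\n")

    with open(out / "truth.json", "w") as fh:
        json.dump(fam.truth, fh, indent=1, sort_keys=True, default=list)

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(fam.config), sort_keys=True, default=list).encode()
    ).hexdigest()
    manifest = {"config_sha256": cfg_hash}
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json":
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
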