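"""Exon–intron gene models: parsing, splice-site checks, translation, intron phases.

A :class:`GeneModel` is the unit of gene-structure comparison: a strand-aware,
ordered list of exon intervals on a genomic sequence.  From it we derive the
spliced CDS, the encoded protein, the donor/acceptor dinucleotides of every
intron, and — central to the whole package — the position of every intron
expressed as a (codon index, phase) pair on the protein.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open.  Residue and codon indices are
1-based, matching the D171-style numbering used when discussing catalytic
residues.  Intron *phase* is the number of nucleotides of the split codon
contributed by the upstream exon (0, 1 or 2); a phase-0 intron is attached to
the residue immediately following the junction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    DegenerateIntronError,
    FrameError,
    ParseError,
    PartialModelError,
    PseudogeneError,
    UnknownReferenceError,
)

log = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_STOP_CODONS = {"TAA", "TAG", "TGA"}

#: exon-table dialect column order (TSV, one row per exon)
EXON_TABLE_COLUMNS = (
    "gene_id",
    "taxon",
    "genome_id",
    "strand",
    "exon_start",
    "exon_end",
    "rank",
)


@dataclass
class GenomicSequence:
    """A DNA sequence (genome, contig or locus) restricted to {A,C,G,T,N}."""

    id: str
    residues: str
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise AlphabetError(f"genomic sequence {self.id!r} is empty")
        bad = set(self.residues) - _DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"genomic sequence {self.id!r} contains non-DNA symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonInterval:
    """One exon: [start, end) on the genome, rank 1-based in transcript order."""

    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(f"exon interval start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceJunctionCheck:
    """Donor/acceptor dinucleotides of one intron and their class.

    ``canonical`` means GT..AG, ``noncanonical`` GC..AG, anything else
    (including N-containing dinucleotides) is ``other``.
    """

    intron_rank: int
    donor: str
    acceptor: str
    klass: str


@dataclass(frozen=True)
class IntronPosition:
    """Intron located on the protein: 1-based codon index plus phase 0/1/2."""

    intron_rank: int
    codon_index: int
    phase: int


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally traceable to the gene encoding it."""

    id: str
    residues: str
    source_gene: str | None = None
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"protein {self.id!r} is empty")
        if "*" in self.residues:
            raise AlphabetError(f"protein {self.id!r} contains an internal stop symbol")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """Strand-aware ordered exon structure of one gene on one genomic sequence.

    ``exons`` are kept in transcript (5'→3' of the mRNA) order: genomic-start
    ascending on the + strand, descending on the − strand.  ``partial_flag``
    marks models whose spliced CDS is incomplete (no start/stop, or frame
    broken); such models parse fine but are excluded from junction analysis
    by default.
    """

    gene_id: str
    taxon: str
    strand: str
    genome_id: str
    exons: list[ExonInterval] = field(default_factory=list)
    partial_flag: bool = False
    corroborated: bool | None = None  # transcript support supplied by the user

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ParseError(f"gene {self.gene_id!r}: exon ranks not consecutive from 1")
        starts = [e.start for e in self.exons]
        if self.strand == "+" and starts != sorted(starts):
            raise ParseError(f"gene {self.gene_id!r}: + strand exons not in ascending order")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ParseError(f"gene {self.gene_id!r}: - strand exons not in descending order")
        for a, b in zip(sorted(self.exons, key=lambda e: e.start), sorted(self.exons, key=lambda e: e.start)[1:]):
            if a.end > b.start:
                raise ParseError(f"gene {self.gene_id!r}: overlapping exons {a} / {b}")

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)

    def total_exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_cds(self, genome: GenomicSequence) -> str:
        """Spliced coding sequence read off the coding strand, 5'→3'."""
        if any(e.end > len(genome) for e in self.exons):
            raise UnknownReferenceError(
                f"gene {self.gene_id!r}: exon exceeds genome {genome.id!r} length"
            )
        parts = [genome.residues[e.start:e.end] for e in self.exons]
        if self.strand == "-":
            parts = [str(Seq(p).reverse_complement()) for p in parts]
        return "".join(parts)


def _validate_cds(cds: str) -> bool:
    """True when the CDS looks complete: ATG start, in-frame, stop-terminated."""
    return (
        len(cds) % 3 == 0
        and len(cds) >= 6
        and cds[:3] == "ATG"
        and cds[-3:] in _STOP_CODONS
    )


def parse_gene_models(
    path: str | Path,
    genome_index: Mapping[str, GenomicSequence],
) -> list[GeneModel]:
    """Parse gene models from the exon-table TSV dialect or from GFF3.

    The exon-table dialect has a header row with columns
    ``gene_id  taxon  genome_id  strand  exon_start  exon_end  rank``
    (0-based half-open exon coordinates, 1-based rank in transcript order).
    GFF3 input must carry exon features with a ``gene_id`` attribute (``Parent``
    accepted as fallback); ranks are taken from a ``rank`` attribute when
    present, otherwise assigned from genomic order and strand.

    Models whose spliced CDS is not a complete ORF are returned with
    ``partial_flag=True`` and a logged warning rather than rejected.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(512)
    if head.startswith("##gff-version") or path.suffix.lower() in {".gff", ".gff3"}:
        grouped = _read_gff3(path)
    else:
        grouped = _read_exon_table(path)

    models: list[GeneModel] = []
    for (gene_id, taxon, genome_id, strand), exons in grouped:
        if genome_id not in genome_index:
            raise UnknownReferenceError(
                f"gene {gene_id!r}: unknown genome id {genome_id!r}"
            )
        model = GeneModel(gene_id=gene_id, taxon=taxon, strand=strand,
                          genome_id=genome_id, exons=exons)
        cds = model.spliced_cds(genome_index[genome_id])
        if not _validate_cds(cds):
            model.partial_flag = True
            log.warning("gene %s: incomplete CDS, flagged partial", gene_id)
        models.append(model)
    return models


def _read_exon_table(path: Path):
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(EXON_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    grouped = []
    for key, sub in df.groupby(["gene_id", "taxon", "genome_id", "strand"], sort=False):
        exons = []
        for line_no, row in sub.iterrows():
            start, end = int(row.exon_start), int(row.exon_end)
            if start >= end:
                raise ParseError(
                    f"{path} line {line_no + 2}: exon start {start} >= end {end}"
                )
            exons.append(ExonInterval(start=start, end=end, rank=int(row["rank"])))
        exons.sort(key=lambda e: e.rank)
        grouped.append((tuple(key), exons))
    return grouped


def _read_gff3(path: Path):
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    by_gene: dict[tuple, list] = {}
    for feat in db.features_of_type("exon", order_by="start"):
        gene_id = feat.attributes.get("gene_id", feat.attributes.get("Parent", [None]))[0]
        if gene_id is None:
            raise ParseError(f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id/Parent")
        taxon = feat.attributes.get("taxon", [""])[0]
        key = (gene_id, taxon, feat.seqid, feat.strand)
        rank = feat.attributes.get("rank", [None])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        by_gene.setdefault(key, []).append(
            (feat.start - 1, feat.end, None if rank is None else int(rank))
        )
    grouped = []
    for key, raw in by_gene.items():
        strand = key[3]
        if all(r[2] is not None for r in raw):
            raw.sort(key=lambda r: r[2])
        else:
            raw.sort(key=lambda r: r[0], reverse=(strand == "-"))
        exons = [
            ExonInterval(start=s, end=e, rank=i + 1)
            for i, (s, e, _) in enumerate(raw)
        ]
        grouped.append((key, exons))
    return grouped


def classify_splice_sites(
    model: GeneModel, genome: GenomicSequence
) -> list[SpliceJunctionCheck]:
    """Donor/acceptor dinucleotides for every intron, read on the coding strand.

    Canonical GT..AG and non-canonical GC..AG are recognised; everything else —
    including dinucleotides containing N, which trigger a warning — is ``other``.
    """
    checks = []
    for rank in range(1, len(model.exons)):
        up, down = model.exons[rank - 1], model.exons[rank]
        if model.strand == "+":
            lo, hi = up.end, down.start
        else:
            lo, hi = down.end, up.start
        if hi - lo < 4:
            raise DegenerateIntronError(
                f"gene {model.gene_id!r}: intron {rank} is {hi - lo} nt (< 4)"
            )
        segment = genome.residues[lo:hi]
        if model.strand == "-":
            segment = str(Seq(segment).reverse_complement())
        donor, acceptor = segment[:2], segment[-2:]
        if donor == "GT" and acceptor == "AG":
            klass = "canonical"
        elif donor == "GC" and acceptor == "AG":
            klass = "noncanonical"
        else:
            klass = "other"
            if "N" in donor + acceptor:
                warnings.warn(
                    f"gene {model.gene_id}: N in splice dinucleotide of intron {rank}",
                    stacklevel=2,
                )
        checks.append(SpliceJunctionCheck(intron_rank=rank, donor=donor,
                                          acceptor=acceptor, klass=klass))
    return checks


def spliced_protein(model: GeneModel, genome: GenomicSequence) -> ProteinRecord:
    """Translate the spliced CDS under the standard nuclear code.

    The terminal stop is removed; an internal stop raises
    :class:`PseudogeneError` and an out-of-frame CDS :class:`FrameError`.
    """
    if model.partial_flag:
        raise PartialModelError(f"gene {model.gene_id!r} is partial; cannot translate")
    cds = model.spliced_cds(genome)
    if len(cds) % 3 != 0:
        raise FrameError(f"gene {model.gene_id!r}: CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise PseudogeneError(f"gene {model.gene_id!r}: internal stop codon")
    return ProteinRecord(id=model.gene_id, residues=aa,
                         source_gene=model.gene_id, taxon=model.taxon)


def intron_positions(model: GeneModel) -> list[IntronPosition]:
    """Intron positions as (codon index, phase) from cumulative exon lengths.

    Phase is ``cumlen % 3``; the host codon index is ``cumlen // 3 + 1``,
    which for phase 0 is the residue immediately following the junction.
    """
    if model.partial_flag:
        raise PartialModelError(f"gene {model.gene_id!r} is partial; no intron positions")
    positions = []
    cum = 0
    for rank in range(1, len(model.exons)):
        cum += len(model.exons[rank - 1])
        positions.append(
            IntronPosition(intron_rank=rank, codon_index=cum // 3 + 1, phase=cum % 3)
        )
    return positions


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA into (id, sequence, description) tuples."""
    from Bio import SeqIO

    return [(r.id, str(r.seq), r.description) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
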