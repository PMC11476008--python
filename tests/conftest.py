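"""Shared fixtures: hand-built gene constructions and simulated families."""

from __future__ import annotations

import pytest

from Bio.Seq import Seq

from splicetrace.gene_models import ExonInterval, GeneModel, GenomicSequence
from splicetrace.synthetic_data import default_config, simulate_family


def build_gene(
    cds: str,
    intron_offsets: list[int],
    gene_id: str = "g1",
    strand: str = "+",
    intron_seq: str | None = None,
    flank: str = "ACGTACGTAC",
):
    """Construct a (GeneModel, GenomicSequence) pair from a CDS and the CDS
    offsets at which introns interrupt it.  The + strand locus is built first;
    for '-' the genome is reverse-complemented and coordinates are mirrored,
    so both strands describe the same transcript."""
    intron = intron_seq or ("GT" + "ATCG" * 10 + "AG")
    parts, bounds = [], []
    cursor = len(flank)
    prev = 0
    for off in intron_offsets:
        parts.append(cds[prev:off])
        bounds.append((cursor, cursor + off - prev))
        cursor += off - prev + len(intron)
        parts.append(intron)
        prev = off
    parts.append(cds[prev:])
    bounds.append((cursor, cursor + len(cds) - prev))
    locus = flank + "".join(parts) + flank
    if strand == "-":
        n = len(locus)
        locus = str(Seq(locus).reverse_complement())
        bounds = [(n - e, n - s) for s, e in bounds]
    genome = GenomicSequence(id=f"{gene_id}_locus", residues=locus)
    model = GeneModel(
        gene_id=gene_id, taxon="taxonA", strand=strand, genome_id=genome.id,
        exons=[ExonInterval(start=s, end=e, rank=i + 1)
               for i, (s, e) in enumerate(bounds)],
    )
    return model, genome


@pytest.fixture(scope="session")
def family():
    """One stock simulated family at default divergence."""
    return simulate_family(default_config(seed=11))


@pytest.fixture(scope="session")
def family_rate0():
    """Same scenario with substitution silenced: proteins differ only by events."""
    return simulate_family(default_config(
        seed=11, substitution_rate=0.0, taxon_branch_length=0.0))
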