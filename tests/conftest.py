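import pytest

from tcscensus.io import DomainAssignment, GeneRecord, GenomeAnnotation


def make_annotation(genes, domains=(), genome_id="g1"):
    """genes: iterable of (gene_id, contig, start, end[, coding]);
    domains: iterable of (gene_id, accession)."""
    recs = []
    for g in genes:
        gid, contig, start, end = g[:4]
        coding = g[4] if len(g) > 4 else True
        recs.append(
            GeneRecord(gene_id=gid, genome_id=genome_id, contig_id=contig,
                       start=start, end=end, is_protein_coding=coding)
        )
    doms = [DomainAssignment(gene_id=g, pfam_accession=a) for g, a in domains]
    return GenomeAnnotation(genome_id=genome_id, genes=recs, domains=doms)


@pytest.fixture
def toy_annotation():
    """Five genes on one contig: an adjacent kinase/regulator pair, one
    distant (orphan) kinase, a hybrid next to the pair, and a decoy."""
    return make_annotation(
        genes=[
            ("gA", "c1", 1, 1000),
            ("gB", "c1", 1201, 2200),
            ("gC", "c1", 2401, 3400),
            ("gD", "c1", 20001, 21000),
            ("gE", "c1", 40001, 41000),
        ],
        domains=[
            ("gA", "PF02518"),   # HPK
            ("gB", "PF00072"),   # RR
            ("gC", "PF02518"),   # hybrid
            ("gC", "PF00072"),
            ("gD", "PF02518"),   # orphan HPK
            ("gE", "PF02518"),   # decoy: HATPase + gyrase B
            ("gE", "PF00204"),
        ],
    )
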