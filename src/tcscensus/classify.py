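"""Pfam-rule classification of genes into two-component-system classes.

Histidine protein kinases (HPKs) are recognized by their HATPase-family
domains, response regulators (RRs) by the phosphoreceiver (REC) domain
PF00072, and hybrid kinases by carrying both on one gene. Three HATPase-like
decoys — DNA gyrase B (PF00204), HSP90 (PF00183) and MutL (PF13941) — are
excluded outright: a gene carrying any of them is removed from the census
even if it also carries kinase or receiver domains.

Counting contract: a hybrid contributes to both the HPK and the RR tallies,
so ``n_hpk = #HPK_ONLY + #HYBRID`` and ``n_rr = #RR_ONLY + #HYBRID``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd

from .io import GenomeAnnotation, normalize_pfam_accession

__all__ = ["TCSClass", "PfamRuleSet", "TCSGeneCall", "GenomeCounts", "classify_gene", "classify_genome", "calls_to_frame"]

DEFAULT_HATPASE_PFAMS = frozenset(
    {"PF02518", "PF13581", "PF13589", "PF14501", "PF07536", "PF07730"}
)
DEFAULT_RR_PFAMS = frozenset({"PF00072"})
DEFAULT_EXCLUSION_PFAMS = frozenset({"PF00204", "PF00183", "PF13941"})


class TCSClass(str, Enum):
    HPK_ONLY = "HPK_ONLY"
    RR_ONLY = "RR_ONLY"
    HYBRID = "HYBRID"
    EXCLUDED = "EXCLUDED"
    NON_TCS = "NON_TCS"

    @property
    def is_tcs(self) -> bool:
        """True for the classes counted as TCS genes (HPK, RR, hybrid)."""
        return self in (TCSClass.HPK_ONLY, TCSClass.RR_ONLY, TCSClass.HYBRID)


@dataclass(frozen=True)
class PfamRuleSet:
    """The three disjoint Pfam sets driving classification.

    Defaults: HATPase set = {PF02518 HATPase_c, PF13581 HATPase_c_2, PF13589
    HATPase_c_3, PF14501 HATPase_c_5, PF07536 HWE_HK, PF07730 HisKA_3};
    receiver set = {PF00072 Response_reg}; exclusion set = {PF00204 gyrase B,
    PF00183 HSP90, PF13941 MutL}.
    """

    hatpase_pfams: frozenset[str] = DEFAULT_HATPASE_PFAMS
    rr_pfams: frozenset[str] = DEFAULT_RR_PFAMS
    exclusion_pfams: frozenset[str] = DEFAULT_EXCLUSION_PFAMS

    def __post_init__(self) -> None:
        h, r, x = map(frozenset, (self.hatpase_pfams, self.rr_pfams, self.exclusion_pfams))
        object.__setattr__(self, "hatpase_pfams", h)
        object.__setattr__(self, "rr_pfams", r)
        object.__setattr__(self, "exclusion_pfams", x)
        if h & r or h & x or r & x:
            raise ValueError("hatpase, rr, and exclusion Pfam sets must be pairwise disjoint")

    @classmethod
    def from_config(cls, cfg: dict) -> "PfamRuleSet":
        """Build from a config mapping with optional keys ``hatpase_pfams``,
        ``rr_pfams``, ``exclusion_pfams`` (raw accessions are normalized)."""
        def norm(key, default):
            raw = cfg.get(key)
            if raw is None:
                return default
            return frozenset(normalize_pfam_accession(a) for a in raw)

        return cls(
            hatpase_pfams=norm("hatpase_pfams", DEFAULT_HATPASE_PFAMS),
            rr_pfams=norm("rr_pfams", DEFAULT_RR_PFAMS),
            exclusion_pfams=norm("exclusion_pfams", DEFAULT_EXCLUSION_PFAMS),
        )


@dataclass(frozen=True)
class TCSGeneCall:
    """Classification of one gene, with position copied for downstream work."""

    gene_id: str
    tcs_class: TCSClass
    triggering_pfams: frozenset[str]
    start: int
    contig_id: str = ""


class GenomeCounts(NamedTuple):
    n_hpk: int
    n_rr: int
    n_hybrid: int


def classify_gene(
    domains_for_gene: Iterable[str], rules: PfamRuleSet | None = None
) -> tuple[TCSClass, frozenset[str]]:
    """Classify one gene from its (canonical) Pfam accessions.

    Exclusion takes precedence over everything; otherwise the class follows
    from which of the kinase/receiver sets the gene's domains intersect.
    Duplicate domains count once (set semantics: genes are counted, not
    domain copies).
    """
    rules = rules or PfamRuleSet()
    doms = frozenset(domains_for_gene)
    excl = doms & rules.exclusion_pfams
    if excl:
        return TCSClass.EXCLUDED, excl
    hat = doms & rules.hatpase_pfams
    rec = doms & rules.rr_pfams
    if hat and rec:
        return TCSClass.HYBRID, hat | rec
    if hat:
        return TCSClass.HPK_ONLY, hat
    if rec:
        return TCSClass.RR_ONLY, rec
    return TCSClass.NON_TCS, frozenset()


def classify_genome(
    annotation: GenomeAnnotation, rules: PfamRuleSet | None = None
) -> tuple[list[TCSGeneCall], GenomeCounts]:
    """Classify every gene in a genome and tally HPK/RR/hybrid counts.

    EXCLUDED genes appear in the call list but contribute to no count.
    Hybrids are counted on both the HPK and RR sides.
    """
    rules = rules or PfamRuleSet()
    by_gene = annotation.domains_by_gene()
    calls: list[TCSGeneCall] = []
    n_hpk_only = n_rr_only = n_hybrid = 0
    for gene in annotation.genes:
        cls, trig = classify_gene(by_gene.get(gene.gene_id, ()), rules)
        calls.append(
            TCSGeneCall(
                gene_id=gene.gene_id,
                tcs_class=cls,
                triggering_pfams=trig,
                start=gene.start,
                contig_id=gene.contig_id,
            )
        )
        if cls is TCSClass.HPK_ONLY:
            n_hpk_only += 1
        elif cls is TCSClass.RR_ONLY:
            n_rr_only += 1
        elif cls is TCSClass.HYBRID:
            n_hybrid += 1
    counts = GenomeCounts(n_hpk=n_hpk_only + n_hybrid, n_rr=n_rr_only + n_hybrid, n_hybrid=n_hybrid)
    return calls, counts


def calls_to_frame(calls: Iterable[TCSGeneCall]) -> pd.DataFrame:
    """Per-gene call table (TSV-ready): gene_id, class, triggering pfams, position."""
    return pd.DataFrame(
        [
            (c.gene_id, c.tcs_class.value, ",".join(sorted(c.triggering_pfams)), c.start, c.contig_id)
            for c in calls
        ],
        columns=["gene_id", "tcs_class", "triggering_pfams", "start", "contig_id"],
    )
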