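"""Synthetic annotated genomes, cohorts, and proteome transects.

Every pipeline stage is testable without external genome downloads: the
generators here emit the same GFF3/TSV dialects the readers consume, plus a
ground-truth record of what was planted. Three generators:

* :func:`generate_genome` — one annotated genome with paired two-component
  systems laid out as adjacent genes, planted orphan kinases/regulators
  isolated beyond the orphan threshold, hybrid genes, and exclusion-rule
  decoys (HATPase plus gyrase-B domains) among dummy-domain filler genes.
* :func:`generate_cohort` — copiotroph/oligotroph cohorts with planted
  per-lifestyle HPK-density distributions, either as summary rows (fast,
  for power studies) or as full genomes.
* :func:`generate_transect` — station/depth samples whose spectral counts
  follow y = a·x^b with lognormal noise against phosphate x.

All generators are deterministic functions of (spec, seed). Layout
feasibility is verified post hoc against the orphan rule with an
independent quadratic scan; an unsatisfiable spec raises instead of
silently violating the planted structure.

Default cohort and transect parameters encode the study conditions used by
the test suite: copiotroph HPK density 1.4 vs oligotroph 0.8 per 100 genes
(sd 0.2, 40 genomes per group), and a transect with a = 3, b = −0.8,
log-noise sd 0.1, n = 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import TCSClass
from .io import DomainAssignment, GeneRecord, GenomeAnnotation, GenomeMetadata
from .stats import GenomeTCSSummary

__all__ = [
    "GenomeSpec",
    "GenomeSimulation",
    "CohortSimulation",
    "TransectSimulation",
    "generate_genome",
    "generate_cohort",
    "generate_transect",
]

# filler-gene domains come from a pool disjoint from every rule-set pfam
DUMMY_PFAM_POOL = tuple(f"PF{90000 + i}" for i in range(20))

HPK_PFAM = "PF02518"
RR_PFAM = "PF00072"
EXCLUSION_PFAM = "PF00204"

DEFAULT_ORPHAN_MULTIPLIER = 4.0


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic genome."""

    genome_id: str = "synthetic"
    n_genes: int = 200
    mean_gene_length: int = 1000
    intergenic_gap: int = 200
    n_paired_systems: int = 3
    n_orphan_hpk: int = 1
    n_orphan_rr: int = 1
    n_hybrid: int = 1
    n_excluded_decoys: int = 1
    n_contigs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_paired_systems,
            self.n_orphan_hpk,
            self.n_orphan_rr,
            self.n_hybrid,
            self.n_excluded_decoys,
            self.n_contigs,
        )
        if any(c < 0 for c in counts) or self.n_genes < 1 or self.n_contigs < 1:
            raise ValueError("all GenomeSpec counts must be non-negative (n_genes, n_contigs >= 1)")
        if self.mean_gene_length < 100 or self.intergenic_gap < 0:
            raise ValueError("mean_gene_length >= 100 and intergenic_gap >= 0 required")


@dataclass
class GenomeSimulation:
    """A generated genome plus the ground truth planted into it."""

    annotation: GenomeAnnotation
    classes: dict[str, TCSClass]
    orphan_flags: dict[str, bool]  # TCS genes only
    expected_summary: GenomeTCSSummary
    spec: GenomeSpec


def _gene_lengths(rng: np.random.Generator, n: int, mean: int) -> np.ndarray:
    """Truncated normal gene lengths around the mean (sd 12%, clipped ±50%)."""
    raw = rng.normal(mean, 0.12 * mean, size=n)
    return np.clip(raw, 0.5 * mean, 1.5 * mean).astype(int)


def _brute_force_orphans(
    genes: list[GeneRecord],
    classes: dict[str, TCSClass],
    multiplier: float,
) -> dict[str, bool]:
    """Quadratic all-pairs orphan scan over realized coordinates.

    Kept independent of :mod:`tcscensus.orphans` so generated ground truth
    never relies on the code path it validates.
    """
    coding = [g.length for g in genes if g.is_protein_coding]
    avg = sum(coding) / len(coding)
    threshold = multiplier * avg
    tcs = [g for g in genes if classes[g.gene_id].is_tcs]
    flags: dict[str, bool] = {}
    for g in tcs:
        nearest = math.inf
        for h in tcs:
            if h.gene_id != g.gene_id and h.contig_id == g.contig_id:
                nearest = min(nearest, abs(h.start - g.start))
        flags[g.gene_id] = nearest > threshold
    return flags


def generate_genome(spec: GenomeSpec) -> GenomeSimulation:
    """Generate one annotated genome with planted TCS architecture.

    Paired systems are adjacent HPK+RR genes (hybrids are attached to pair
    blocks when any exist, else placed standalone and hence orphaned);
    planted orphans sit isolated behind filler-gene buffers sized so their
    nearest TCS start exceeds four average gene lengths. Decoy genes carry
    an exclusion pfam alongside a HATPase pfam. The realized layout is
    verified against the orphan rule before emission.
    """
    rng = np.random.default_rng(spec.seed)

    # blocks of co-located TCS genes; buffers of filler genes isolate them
    blocks: list[list[TCSClass]] = []
    pair_blocks = [[TCSClass.HPK_ONLY, TCSClass.RR_ONLY] for _ in range(spec.n_paired_systems)]
    for i in range(spec.n_hybrid):
        if pair_blocks:
            pair_blocks[i % len(pair_blocks)].append(TCSClass.HYBRID)
        else:
            blocks.append([TCSClass.HYBRID])  # standalone hybrid: an orphan
    blocks = pair_blocks + blocks
    blocks += [[TCSClass.HPK_ONLY]] * spec.n_orphan_hpk
    blocks += [[TCSClass.RR_ONLY]] * spec.n_orphan_rr

    # worst-case spacing per slot is 0.5*mean + gap; buffer overshoots the
    # threshold (4 average gene lengths) by 2x to absorb length variation
    min_spacing = 0.5 * spec.mean_gene_length + spec.intergenic_gap
    buffer_slots = math.ceil(2 * DEFAULT_ORPHAN_MULTIPLIER * spec.mean_gene_length / min_spacing)

    n_tcs = sum(len(b) for b in blocks)
    # decoys replace filler genes in place (they are not TCS neighbors, so
    # their position — buffer or leftover — cannot break planted distances)
    n_filler = spec.n_genes - n_tcs
    n_buffers_needed = buffer_slots * len(blocks)
    if n_filler < n_buffers_needed or n_filler < spec.n_excluded_decoys:
        raise ValueError(
            f"unsatisfiable spec: need {n_buffers_needed} filler genes to isolate "
            f"{len(blocks)} TCS blocks plus {spec.n_excluded_decoys} decoy slots, "
            f"but only {n_filler} available (n_genes={spec.n_genes})"
        )

    order = rng.permutation(len(blocks))
    # lay out the genome as: [buffer] block [buffer] block ... + leftover fillers
    layout: list[TCSClass | str] = []
    contig_break_points: list[int] = []  # layout indices where a new contig may start
    for bi in order:
        layout.extend(["filler"] * buffer_slots)
        contig_break_points.append(len(layout))
        layout.extend(blocks[bi])
    leftover = n_filler - n_buffers_needed
    layout.extend(["filler"] * leftover)
    # decoys dropped into filler positions
    filler_idx = [i for i, x in enumerate(layout) if x == "filler"]
    for i in rng.choice(len(filler_idx), size=spec.n_excluded_decoys, replace=False):
        layout[filler_idx[int(i)]] = "decoy"

    # contig assignment: cut only at pre-block buffer boundaries
    cuts: list[int] = []
    if spec.n_contigs > 1:
        usable = [p for p in contig_break_points if 0 < p < len(layout)]
        n_cuts = min(spec.n_contigs - 1, len(usable))
        if n_cuts:
            step = max(1, len(usable) // (n_cuts + 1))
            cuts = sorted(set(usable[step - 1 :: step][:n_cuts]))

    lengths = _gene_lengths(rng, len(layout), spec.mean_gene_length)
    genes: list[GeneRecord] = []
    domains: list[DomainAssignment] = []
    classes: dict[str, TCSClass] = {}
    contig_no, pos = 0, 1
    boundaries = set(cuts)
    for i, item in enumerate(layout):
        if i in boundaries:
            contig_no += 1
            pos = 1
        gid = f"{spec.genome_id}_g{i:05d}"
        length = int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=spec.genome_id,
                contig_id=f"{spec.genome_id}_c{contig_no}",
                start=pos,
                end=pos + length - 1,
                strand=strand,
            )
        )
        pos += length + spec.intergenic_gap

        if item == "filler":
            classes[gid] = TCSClass.NON_TCS
            if rng.random() < 0.5:
                acc = DUMMY_PFAM_POOL[int(rng.integers(len(DUMMY_PFAM_POOL)))]
                domains.append(DomainAssignment(gid, acc))
        elif item == "decoy":
            classes[gid] = TCSClass.EXCLUDED
            domains.append(DomainAssignment(gid, HPK_PFAM))
            domains.append(DomainAssignment(gid, EXCLUSION_PFAM))
        elif item is TCSClass.HPK_ONLY:
            classes[gid] = TCSClass.HPK_ONLY
            domains.append(DomainAssignment(gid, HPK_PFAM))
        elif item is TCSClass.RR_ONLY:
            classes[gid] = TCSClass.RR_ONLY
            domains.append(DomainAssignment(gid, RR_PFAM))
        elif item is TCSClass.HYBRID:
            classes[gid] = TCSClass.HYBRID
            domains.append(DomainAssignment(gid, HPK_PFAM))
            domains.append(DomainAssignment(gid, RR_PFAM))

    annotation = GenomeAnnotation(genome_id=spec.genome_id, genes=genes, domains=domains)

    orphan_flags = _brute_force_orphans(genes, classes, DEFAULT_ORPHAN_MULTIPLIER)
    # post-hoc verification of the planted structure
    gene_by_layout = {i: g.gene_id for i, g in enumerate(genes)}
    li = 0
    for bi in order:
        li += buffer_slots
        block = blocks[bi]
        orphan_block = len(block) == 1
        for _ in block:
            gid = gene_by_layout[li]
            if orphan_flags[gid] != orphan_block:
                raise ValueError(
                    f"unsatisfiable spec: planted gene {gid} realized as "
                    f"{'orphan' if orphan_flags[gid] else 'non-orphan'}, intended otherwise"
                )
            li += 1

    n_hybrid = sum(1 for c in classes.values() if c is TCSClass.HYBRID)
    n_hpk = sum(1 for c in classes.values() if c is TCSClass.HPK_ONLY) + n_hybrid
    n_rr = sum(1 for c in classes.values() if c is TCSClass.RR_ONLY) + n_hybrid
    n_orphan_hpk = sum(
        1 for gid, f in orphan_flags.items() if f and classes[gid] in (TCSClass.HPK_ONLY, TCSClass.HYBRID)
    )
    n_orphan_rr = sum(
        1 for gid, f in orphan_flags.items() if f and classes[gid] in (TCSClass.RR_ONLY, TCSClass.HYBRID)
    )
    npc = annotation.n_protein_coding
    expected = GenomeTCSSummary(
        genome_id=spec.genome_id,
        n_hpk=n_hpk,
        n_rr=n_rr,
        n_hybrid=n_hybrid,
        n_orphan_hpk=n_orphan_hpk,
        n_orphan_rr=n_orphan_rr,
        n_protein_coding=npc,
        hpk_per_100_genes=100.0 * n_hpk / npc,
        rr_hpk_ratio=(n_rr / n_hpk) if n_hpk > 0 and n_rr > 0 else None,
        pct_hybrid=(100.0 * n_hybrid / n_hpk) if n_hpk > 0 else None,
    )
    return GenomeSimulation(
        annotation=annotation,
        classes=classes,
        orphan_flags=orphan_flags,
        expected_summary=expected,
        spec=spec,
    )


@dataclass
class CohortSimulation:
    """Planted copiotroph/oligotroph cohort."""

    summaries: list[GenomeTCSSummary]
    metadata: list[GenomeMetadata]
    planted_means: dict[str, float]
    planted_sd: float
    realized_means: dict[str, float]
    genomes: list[GenomeSimulation] = field(default_factory=list)


# lifestyle -> (HPK density per 100 genes, protein-coding gene count mean/sd)
DEFAULT_GROUP_MEANS = {"copiotroph": 1.4, "oligotroph": 0.8}
DEFAULT_GENOME_SIZES = {"copiotroph": (4000, 400), "oligotroph": (1700, 200)}


def generate_cohort(
    n_per_group: int = 40,
    group_means: dict[str, float] | None = None,
    sd: float = 0.2,
    genome_size_dist: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    full_genomes: bool = False,
    dataset: str = "marine",
) -> CohortSimulation:
    """Generate a cohort with planted per-lifestyle HPK densities.

    Per genome, a target density is drawn from the group's normal
    distribution (truncated at 0.05), the protein-coding gene count from
    the group's genome-size distribution, and the HPK count is the rounded
    product — so realized densities differ from targets by integer
    rounding, exactly as in real genomes. With ``full_genomes=True`` each
    genome is also materialized via :func:`generate_genome` (smaller gene
    counts are advisable there).
    """
    group_means = dict(DEFAULT_GROUP_MEANS if group_means is None else group_means)
    genome_size_dist = dict(DEFAULT_GENOME_SIZES if genome_size_dist is None else genome_size_dist)
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be > 0")
    if any(m > 100 for m in group_means.values()):
        raise ValueError("infeasible density: more than 100 HPK per 100 genes")
    rng = np.random.default_rng(seed)
    summaries: list[GenomeTCSSummary] = []
    metadata: list[GenomeMetadata] = []
    genomes: list[GenomeSimulation] = []
    realized: dict[str, list[float]] = {g: [] for g in group_means}
    for lifestyle, mean_density in sorted(group_means.items()):
        size_mu, size_sd = genome_size_dist.get(lifestyle, (2500, 300))
        for i in range(n_per_group):
            gid = f"{lifestyle}_{i:03d}"
            npc = max(50, int(rng.normal(size_mu, size_sd)))
            density = max(0.05, rng.normal(mean_density, sd))
            n_hpk = max(0, round(density * npc / 100.0))
            n_hybrid = round(0.2 * n_hpk) if lifestyle == "copiotroph" else 0
            n_rr = max(0, round(n_hpk * float(rng.normal(1.0, 0.05))))
            if full_genomes:
                n_pairs = max(n_hpk - n_hybrid - 1, 0)
                sim = generate_genome(
                    GenomeSpec(
                        genome_id=gid,
                        n_genes=npc,
                        n_paired_systems=n_pairs,
                        n_orphan_hpk=n_hpk - n_hybrid - n_pairs,
                        n_orphan_rr=max(n_rr - n_hybrid - n_pairs, 0),
                        n_hybrid=n_hybrid,
                        n_excluded_decoys=1,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
                genomes.append(sim)
                summary = sim.expected_summary
            else:
                summary = GenomeTCSSummary(
                    genome_id=gid,
                    n_hpk=n_hpk,
                    n_rr=n_rr,
                    n_hybrid=n_hybrid,
                    n_orphan_hpk=min(1, n_hpk - n_hybrid),
                    n_orphan_rr=min(1, max(n_rr - n_hybrid, 0)),
                    n_protein_coding=npc,
                    hpk_per_100_genes=100.0 * n_hpk / npc,
                    rr_hpk_ratio=(n_rr / n_hpk) if n_hpk > 0 and n_rr > 0 else None,
                    pct_hybrid=(100.0 * n_hybrid / n_hpk) if n_hpk > 0 else None,
                )
            summaries.append(summary)
            realized[lifestyle].append(summary.hpk_per_100_genes)
            metadata.append(
                GenomeMetadata(
                    genome_id=gid,
                    phylum="Proteobacteria" if lifestyle == "copiotroph" else "Cyanobacteria",
                    genus=lifestyle.capitalize(),
                    habitat="marine",
                    lifestyle=lifestyle,
                    dataset=dataset,
                    genome_size_bp=int(npc * 1200),
                )
            )
    return CohortSimulation(
        summaries=summaries,
        metadata=metadata,
        planted_means=group_means,
        planted_sd=sd,
        realized_means={g: float(np.mean(v)) for g, v in realized.items()},
        genomes=genomes,
    )


@dataclass
class TransectSimulation:
    """Planted power-law transect of spectral counts vs phosphate."""

    abundance: pd.DataFrame
    environment: pd.DataFrame
    a: float
    b: float
    noise_sd_log: float


def generate_transect(
    a: float = 3.0,
    b: float = -0.8,
    noise_sd_log: float = 0.1,
    phosphate_range: tuple[float, float] = (0.01, 3.0),
    n_samples: int = 50,
    seed: int = 0,
) -> TransectSimulation:
    """Station/depth samples with y = a·x^b × exp(N(0, noise_sd_log)).

    Phosphate values are log-spaced across the range (mimicking surface-to-
    nutricline gradients); samples are assigned to synthetic stations and
    depths for realism, neither of which enters the fit.
    """
    if a <= 0:
        raise ValueError("prefactor a must be > 0")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    lo, hi = phosphate_range
    if lo <= 0 or hi <= lo:
        raise ValueError("phosphate_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    x = np.geomspace(lo, hi, n_samples)
    noise = rng.normal(0.0, noise_sd_log, size=n_samples) if noise_sd_log > 0 else np.zeros(n_samples)
    y = a * x**b * np.exp(noise)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    stations = [f"station_{i % 5 + 1}" for i in range(n_samples)]
    depths = np.round(rng.uniform(5, 250, size=n_samples), 1)
    abundance = pd.DataFrame(
        {"sample_id": sample_ids, "station": stations, "depth_m": depths, "spectral_count": y}
    )
    environment = pd.DataFrame({"sample_id": sample_ids, "phosphate_uM": x})
    return TransectSimulation(
        abundance=abundance, environment=environment, a=a, b=b, noise_sd_log=noise_sd_log
    )
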