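"""Positional detection of orphan two-component-system genes.

Bacterial TCS pairs are typically co-located in one operon; a TCS gene far
from every other TCS gene is an "orphan" and a candidate participant in
cross-talking regulatory networks. The genome is treated as linearized, per
contig, with no circular wraparound. Distance is measured start-to-start,
and a gene is an orphan when its nearest TCS neighbor on the same contig is
strictly farther than ``multiplier`` (default 4) average gene lengths, the
average taken over protein-coding genes. A contig's sole TCS gene has
infinite nearest-neighbor distance and is always an orphan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .classify import TCSClass, TCSGeneCall
from .io import GenomeAnnotation

__all__ = ["OrphanCall", "average_gene_length", "find_orphans", "genome_track", "track_to_bed"]


@dataclass(frozen=True)
class OrphanCall:
    gene_id: str
    is_orphan: bool
    nearest_tcs_distance_bp: float  # math.inf when no other TCS gene on contig
    threshold_bp: float


def average_gene_length(annotation: GenomeAnnotation) -> float:
    """Arithmetic mean of (end − start + 1) over protein-coding genes."""
    lengths = [g.length for g in annotation.genes if g.is_protein_coding]
    if not lengths:
        raise ValueError(f"genome {annotation.genome_id}: no protein-coding genes")
    return sum(lengths) / len(lengths)


def find_orphans(
    calls: Sequence[TCSGeneCall],
    annotation: GenomeAnnotation,
    multiplier: float = 4.0,
) -> list[OrphanCall]:
    """Flag each TCS gene as orphan or not by nearest start-to-start distance.

    Only genes called HPK_ONLY, RR_ONLY, or HYBRID count as TCS genes —
    EXCLUDED decoys and NON_TCS genes are neither candidates nor neighbors.
    The orphan test is strict: exactly at threshold is not an orphan.
    Nearest neighbors are found with a single pass over per-contig sorted
    starts; distances to the left and right sorted neighbor suffice since
    starts are totally ordered on the line.
    """
    if multiplier <= 0:
        raise ValueError(f"multiplier must be > 0, got {multiplier}")
    threshold = multiplier * average_gene_length(annotation)

    tcs = [c for c in calls if c.tcs_class.is_tcs]
    by_contig: dict[str, list[TCSGeneCall]] = {}
    for c in tcs:
        by_contig.setdefault(c.contig_id, []).append(c)

    out: list[OrphanCall] = []
    for contig_calls in by_contig.values():
        contig_calls.sort(key=lambda c: (c.start, c.gene_id))
        n = len(contig_calls)
        for i, c in enumerate(contig_calls):
            nearest = math.inf
            if i > 0:
                nearest = min(nearest, c.start - contig_calls[i - 1].start)
            if i < n - 1:
                nearest = min(nearest, contig_calls[i + 1].start - c.start)
            out.append(
                OrphanCall(
                    gene_id=c.gene_id,
                    is_orphan=nearest > threshold,
                    nearest_tcs_distance_bp=nearest,
                    threshold_bp=threshold,
                )
            )
    order = {c.gene_id: i for i, c in enumerate(calls)}
    out.sort(key=lambda o: order[o.gene_id])
    return out


def genome_track(
    calls: Iterable[TCSGeneCall], orphan_calls: Iterable[OrphanCall]
) -> pd.DataFrame:
    """Ordered per-contig track of TCS genes for number-line plots or BED export.

    One row per TCS gene, sorted by (contig, start), with its class and
    orphan flag.
    """
    orphan_by_id = {o.gene_id: o.is_orphan for o in orphan_calls}
    rows = [
        (c.contig_id, c.start, c.gene_id, c.tcs_class.value, orphan_by_id.get(c.gene_id, False))
        for c in calls
        if c.tcs_class.is_tcs
    ]
    df = pd.DataFrame(rows, columns=["contig_id", "start", "gene_id", "tcs_class", "is_orphan"])
    return df.sort_values(["contig_id", "start"], kind="mergesort").reset_index(drop=True)


def track_to_bed(track: pd.DataFrame, annotation: GenomeAnnotation, path) -> None:
    """Write the TCS track as BED (0-based half-open), class+orphan in the name."""
    ends = {g.gene_id: g.end for g in annotation.genes}
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            name = f"{row.gene_id}|{row.tcs_class}|{'orphan' if row.is_orphan else 'paired'}"
            score = 500 if row.is_orphan else 0
            fh.write(f"{row.contig_id}\t{row.start - 1}\t{ends[row.gene_id]}\t{name}\t{score}\n")
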