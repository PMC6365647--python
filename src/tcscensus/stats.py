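"""Per-genome repertoire summaries and cohort-level statistics.

The per-genome quantities mirror the normalized statistics used to compare
signaling repertoires across genomes of very different sizes:

* ``hpk_per_100_genes`` — histidine kinases (hybrids included) per 100
  protein-coding genes, the streamlining-robust HPK density;
* ``rr_hpk_ratio`` — response regulators over histidine kinases; ratios are
  undefined (carried as missing, never 0) when a genome has zero HPKs or
  zero RRs, and such genomes are excluded from ratio-based analyses only;
* ``pct_hybrid`` — percentage of HPKs that are hybrid kinases.

Cohort comparisons use Student's pooled-variance t test, one-way ANOVA, and
percentile-bootstrap confidence intervals for group means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import GenomeCounts, TCSClass, TCSGeneCall
from .io import GenomeAnnotation
from .orphans import OrphanCall

__all__ = [
    "GenomeTCSSummary",
    "CohortResult",
    "summarize_genome",
    "summaries_to_frame",
    "aggregate",
    "two_sample_ttest",
    "one_way_anova",
    "bootstrap_ci",
    "dataset_statistics",
]

SUMMARY_METRICS = (
    "n_hpk",
    "n_rr",
    "n_hybrid",
    "n_orphan_hpk",
    "n_orphan_rr",
    "n_protein_coding",
    "hpk_per_100_genes",
    "rr_hpk_ratio",
    "pct_hybrid",
)


@dataclass(frozen=True)
class GenomeTCSSummary:
    genome_id: str
    n_hpk: int
    n_rr: int
    n_hybrid: int
    n_orphan_hpk: int
    n_orphan_rr: int
    n_protein_coding: int
    hpk_per_100_genes: float
    rr_hpk_ratio: float | None  # None when n_hpk == 0 or n_rr == 0
    pct_hybrid: float | None  # None when n_hpk == 0


@dataclass(frozen=True)
class CohortResult:
    """Outcome of a cohort comparison (t test or ANOVA) with bootstrap CIs."""

    test_name: str
    group_labels: tuple[str, ...]
    group_ns: tuple[int, ...]
    group_means: tuple[float, ...]
    ci_low: tuple[float, ...] | None
    ci_high: tuple[float, ...] | None
    statistic: float | None
    df: tuple[float, ...]
    p_value: float | None

    def summary(self) -> str:
        lines = [f"{self.test_name}: statistic={self.statistic}, df={self.df}, p={self.p_value}"]
        for i, lab in enumerate(self.group_labels):
            ci = ""
            if self.ci_low is not None and self.ci_high is not None:
                ci = f" [95% CI {self.ci_low[i]:.4g}, {self.ci_high[i]:.4g}]"
            lines.append(f"  {lab}: n={self.group_ns[i]}, mean={self.group_means[i]:.4g}{ci}")
        return "\n".join(lines)


def summarize_genome(
    calls: Sequence[TCSGeneCall],
    orphan_calls: Sequence[OrphanCall],
    annotation: GenomeAnnotation,
    counts: GenomeCounts | None = None,
) -> GenomeTCSSummary:
    """Fold per-gene calls and orphan flags into one genome's summary row.

    Hybrid genes are counted in both ``n_hpk`` and ``n_rr`` and, when
    orphaned, in both orphan tallies.
    """
    npc = annotation.n_protein_coding
    if npc == 0:
        raise ValueError(f"genome {annotation.genome_id}: zero protein-coding genes")
    cls_by_id = {c.gene_id: c.tcs_class for c in calls}
    if counts is None:
        n_hybrid = sum(1 for c in calls if c.tcs_class is TCSClass.HYBRID)
        n_hpk = sum(1 for c in calls if c.tcs_class is TCSClass.HPK_ONLY) + n_hybrid
        n_rr = sum(1 for c in calls if c.tcs_class is TCSClass.RR_ONLY) + n_hybrid
        counts = GenomeCounts(n_hpk, n_rr, n_hybrid)
    n_orphan_hpk = sum(
        1
        for o in orphan_calls
        if o.is_orphan and cls_by_id[o.gene_id] in (TCSClass.HPK_ONLY, TCSClass.HYBRID)
    )
    n_orphan_rr = sum(
        1
        for o in orphan_calls
        if o.is_orphan and cls_by_id[o.gene_id] in (TCSClass.RR_ONLY, TCSClass.HYBRID)
    )
    return GenomeTCSSummary(
        genome_id=annotation.genome_id,
        n_hpk=counts.n_hpk,
        n_rr=counts.n_rr,
        n_hybrid=counts.n_hybrid,
        n_orphan_hpk=n_orphan_hpk,
        n_orphan_rr=n_orphan_rr,
        n_protein_coding=npc,
        hpk_per_100_genes=100.0 * counts.n_hpk / npc,
        rr_hpk_ratio=(counts.n_rr / counts.n_hpk) if counts.n_hpk > 0 and counts.n_rr > 0 else None,
        pct_hybrid=(100.0 * counts.n_hybrid / counts.n_hpk) if counts.n_hpk > 0 else None,
    )


def summaries_to_frame(summaries: Sequence[GenomeTCSSummary]) -> pd.DataFrame:
    """One row per genome; undefined ratios become NaN."""
    df = pd.DataFrame(
        [
            (
                s.genome_id,
                s.n_hpk,
                s.n_rr,
                s.n_hybrid,
                s.n_orphan_hpk,
                s.n_orphan_rr,
                s.n_protein_coding,
                s.hpk_per_100_genes,
                np.nan if s.rr_hpk_ratio is None else s.rr_hpk_ratio,
                np.nan if s.pct_hybrid is None else s.pct_hybrid,
            )
            for s in summaries
        ],
        columns=("genome_id",) + SUMMARY_METRICS,
    )
    return df


def aggregate(
    summaries: pd.DataFrame,
    grouping: str,
    metric: str,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group mean/median/n for one summary metric.

    ``grouping`` is a metadata field (lifestyle, phylum, genus, dataset, …)
    or a column already present on the summary frame. Genomes with missing
    metric values are dropped from the aggregate and counted in
    ``n_dropped``.
    """
    if metric not in SUMMARY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {SUMMARY_METRICS}")
    df = summaries
    if grouping not in df.columns:
        if metadata is None:
            raise ValueError(f"grouping column {grouping!r} absent and no metadata given")
        df = df.merge(metadata[["genome_id", grouping]], on="genome_id", how="left")
    rows = []
    for label, grp in df.groupby(grouping, dropna=False):
        vals = grp[metric].dropna()
        rows.append(
            {
                "group": label,
                "n_used": len(vals),
                "n_dropped": len(grp) - len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "median": vals.median() if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean; reproducible under seed."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap_ci requires n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def two_sample_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    tails: str = "two",
    labels: tuple[str, str] = ("A", "B"),
    ci_seed: int | None = None,
    n_boot: int = 2_000,
) -> CohortResult:
    """Student's pooled-variance two-sample t test.

    ``tails="one"`` reports the one-sided p in the direction of the observed
    difference (half the two-sided p). Degenerate input with zero variance
    in both groups and equal means yields t = 0, p = 1.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    if tails == "one":
        p = p / 2.0
    cis = None, None
    if ci_seed is not None:
        lo_a, hi_a = bootstrap_ci(a, n_boot=n_boot, seed=ci_seed)
        lo_b, hi_b = bootstrap_ci(b, n_boot=n_boot, seed=ci_seed + 1)
        cis = (lo_a, lo_b), (hi_a, hi_b)
    return CohortResult(
        test_name=f"student_t_{tails}_tailed",
        group_labels=labels,
        group_ns=(a.size, b.size),
        group_means=(float(a.mean()), float(b.mean())),
        ci_low=cis[0],
        ci_high=cis[1],
        statistic=t,
        df=(float(df),),
        p_value=p,
    )


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    ci_seed: int | None = None,
    n_boot: int = 2_000,
) -> CohortResult:
    """One-way fixed-effects ANOVA with standard (k−1, N−k) degrees of freedom.

    All-constant input makes F undefined; it is reported as missing with a
    warning rather than raised, since flat cohorts are a legitimate
    degenerate outcome on real data.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    labels = tuple(labels) if labels is not None else tuple(f"group{i}" for i in range(len(arrs)))
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    if all(a.var(ddof=1) == 0 for a in arrs) and len({a.mean() for a in arrs}) == 1:
        warnings.warn("ANOVA on identical constant groups: F undefined, reported as missing")
        f = p = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*arrs)
        f, p = float(f), float(p)
        if math.isnan(f):
            warnings.warn("ANOVA F undefined on degenerate input; reported as missing")
            f = p = None
    cis = None, None
    if ci_seed is not None:
        lows, highs = [], []
        for i, a in enumerate(arrs):
            lo, hi = bootstrap_ci(a, n_boot=n_boot, seed=ci_seed + i)
            lows.append(lo)
            highs.append(hi)
        cis = tuple(lows), tuple(highs)
    return CohortResult(
        test_name="one_way_anova",
        group_labels=labels,
        group_ns=tuple(a.size for a in arrs),
        group_means=tuple(float(a.mean()) for a in arrs),
        ci_low=cis[0],
        ci_high=cis[1],
        statistic=f,
        df=(float(k - 1), float(n_total - k)),
        p_value=p,
    )


def dataset_statistics(summaries: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Survey-level statistics for a genome collection.

    Computes the headline numbers of a TCS census: overall mean HPK density,
    per-dataset mean RR/HPK ratio (ratio-undefined genomes excluded), per-
    phylum mean HPK density, per-genus summary table, and the maximum HPK
    count. Used both for reporting on real supplementary exports and for
    synthetic cohorts.
    """
    df = summaries.merge(metadata, on="genome_id", how="left")
    out: dict = {
        "n_genomes": int(len(df)),
        "mean_hpk_per_100_genes": float(df["hpk_per_100_genes"].mean()),
        "max_n_hpk": int(df["n_hpk"].max()),
        "rr_hpk_ratio_by_dataset": {
            str(k): float(v)
            for k, v in df.groupby("dataset")["rr_hpk_ratio"].mean().dropna().items()
        },
        "hpk_per_100_genes_by_phylum": {
            str(k): float(v)
            for k, v in df.groupby("phylum")["hpk_per_100_genes"].mean().dropna().items()
            if k
        },
        "genus_table": aggregate(df, "genus", "hpk_per_100_genes").to_dict("records")
        if "genus" in df.columns
        else [],
        "rr_hpk_ratio_by_genus": {
            str(k): float(v)
            for k, v in df.groupby("genus")["rr_hpk_ratio"].mean().dropna().items()
            if k
        },
    }
    return out
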