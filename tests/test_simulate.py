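import dataclasses

import numpy as np
import pytest

from tcscensus.classify import (
    DEFAULT_EXCLUSION_PFAMS,
    DEFAULT_HATPASE_PFAMS,
    DEFAULT_RR_PFAMS,
    TCSClass,
    classify_genome,
)
from tcscensus.io import write_genome_annotation
from tcscensus.orphans import find_orphans
from tcscensus.simulate import (
    DUMMY_PFAM_POOL,
    GenomeSpec,
    generate_cohort,
    generate_genome,
    generate_transect,
)
from tcscensus.stats import summarize_genome, two_sample_ttest


def test_planted_labels_recovered_through_pipeline():
    spec = GenomeSpec(n_genes=200, n_paired_systems=2, n_orphan_hpk=1,
                      n_orphan_rr=1, n_hybrid=1, n_excluded_decoys=1, seed=13)
    sim = generate_genome(spec)
    calls, counts = classify_genome(sim.annotation)
    assert {c.gene_id: c.tcs_class for c in calls} == sim.classes
    orphans = find_orphans(calls, sim.annotation)
    assert {o.gene_id: o.is_orphan for o in orphans} == sim.orphan_flags
    summary = summarize_genome(calls, orphans, sim.annotation, counts)
    assert summary == sim.expected_summary


def test_hybrid_counts_on_both_sides_of_ground_truth():
    base = GenomeSpec(n_genes=200, n_hybrid=0, seed=2)
    with_h = dataclasses.replace(base, n_hybrid=1)
    s0 = generate_genome(base).expected_summary
    s1 = generate_genome(with_h).expected_summary
    assert s1.n_hpk == s0.n_hpk + 1 and s1.n_rr == s0.n_rr + 1


def test_same_seed_byte_identical_files(tmp_path):
    for i, sub in enumerate(("a", "b")):
        d = tmp_path / sub
        d.mkdir()
        sim = generate_genome(GenomeSpec(n_genes=150, seed=21))
        write_genome_annotation(sim.annotation, d / "g.tsv", d / "d.tsv")
    assert (tmp_path / "a/g.tsv").read_bytes() == (tmp_path / "b/g.tsv").read_bytes()
    assert (tmp_path / "a/d.tsv").read_bytes() == (tmp_path / "b/d.tsv").read_bytes()


def test_unsatisfiable_spec_raises():
    with pytest.raises(ValueError, match="unsatisfiable"):
        generate_genome(GenomeSpec(n_genes=20, n_paired_systems=5, seed=0))


def test_filler_pfams_disjoint_from_rule_sets():
    rule_pfams = DEFAULT_HATPASE_PFAMS | DEFAULT_RR_PFAMS | DEFAULT_EXCLUSION_PFAMS
    assert not set(DUMMY_PFAM_POOL) & rule_pfams
    sim = generate_genome(GenomeSpec(n_genes=150, seed=8))
    filler_doms = {
        d.pfam_accession
        for d in sim.annotation.domains
        if sim.classes[d.gene_id] is TCSClass.NON_TCS
    }
    assert filler_doms <= set(DUMMY_PFAM_POOL)


def test_decoys_carry_exclusion_plus_hatpase():
    sim = generate_genome(GenomeSpec(n_genes=150, n_excluded_decoys=2, seed=9))
    by_gene = sim.annotation.domains_by_gene()
    decoys = [g for g, c in sim.classes.items() if c is TCSClass.EXCLUDED]
    assert len(decoys) == 2
    for g in decoys:
        assert by_gene[g] & DEFAULT_EXCLUSION_PFAMS and by_gene[g] & DEFAULT_HATPASE_PFAMS


def test_multi_contig_layout_keeps_ground_truth():
    sim = generate_genome(GenomeSpec(n_genes=300, n_contigs=4, seed=17))
    assert len(sim.annotation.contigs) == 4
    calls, _ = classify_genome(sim.annotation)
    assert {o.gene_id: o.is_orphan for o in find_orphans(calls, sim.annotation)} == sim.orphan_flags


def test_cohort_planted_contrast_is_detectable():
    sim = generate_cohort(n_per_group=40, sd=0.2, seed=5)
    dens = {}
    for lifestyle in ("copiotroph", "oligotroph"):
        dens[lifestyle] = [
            s.hpk_per_100_genes
            for s, m in zip(sim.summaries, sim.metadata)
            if m.lifestyle == lifestyle
        ]
    res = two_sample_ttest(dens["copiotroph"], dens["oligotroph"])
    assert res.p_value < 1e-10
    assert abs(sim.realized_means["copiotroph"] - 1.4) < 0.15
    assert abs(sim.realized_means["oligotroph"] - 0.8) < 0.15


def test_cohort_sd_zero_realizes_planted_means_up_to_rounding():
    sim = generate_cohort(n_per_group=20, sd=0.0, seed=3)
    # integer rounding against ~1700-4000 genes perturbs density by <0.05
    assert sim.realized_means["copiotroph"] == pytest.approx(1.4, abs=0.05)
    assert sim.realized_means["oligotroph"] == pytest.approx(0.8, abs=0.05)


def test_cohort_full_genomes_round_trip():
    sim = generate_cohort(
        n_per_group=2,
        group_means={"copiotroph": 1.2, "oligotroph": 0.7},
        genome_size_dist={"copiotroph": (400, 20), "oligotroph": (300, 20)},
        seed=11,
        full_genomes=True,
    )
    assert len(sim.genomes) == 4
    for g in sim.genomes:
        calls, counts = classify_genome(g.annotation)
        orphans = find_orphans(calls, g.annotation)
        assert summarize_genome(calls, orphans, g.annotation, counts) == g.expected_summary


def test_cohort_infeasible_density_errors():
    with pytest.raises(ValueError, match="infeasible"):
        generate_cohort(group_means={"copiotroph": 150.0, "oligotroph": 0.8}, seed=0)
    with pytest.raises(ValueError, match="> 0"):
        generate_cohort(group_means={"copiotroph": -1.0, "oligotroph": 0.8}, seed=0)


def test_transect_determinism_and_validation():
    t1 = generate_transect(seed=7)
    t2 = generate_transect(seed=7)
    assert t1.abundance.equals(t2.abundance) and t1.environment.equals(t2.environment)
    with pytest.raises(ValueError):
        generate_transect(a=0.0, seed=0)
    with pytest.raises(ValueError):
        generate_transect(n_samples=2, seed=0)
    with pytest.raises(ValueError):
        generate_transect(phosphate_range=(0.0, 1.0), seed=0)


def test_transect_counts_follow_planted_law():
    sim = generate_transect(a=2.0, b=-0.5, noise_sd_log=0.0, n_samples=10, seed=0)
    x = sim.environment["phosphate_uM"].to_numpy()
    y = sim.abundance["spectral_count"].to_numpy()
    assert np.allclose(y, 2.0 * x**-0.5)
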