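import math

import numpy as np
import pytest

from tcscensus.classify import TCSClass, TCSGeneCall, classify_genome
from tcscensus.orphans import average_gene_length, find_orphans, genome_track
from tcscensus.simulate import GenomeSpec, generate_genome

from conftest import make_annotation


def _calls(starts, contig="c1", cls=TCSClass.HPK_ONLY):
    return [
        TCSGeneCall(gene_id=f"t{i}", tcs_class=cls, triggering_pfams=frozenset({"PF02518"}),
                    start=s, contig_id=contig)
        for i, s in enumerate(starts)
    ]


def _uniform_annotation(n=20, length=1000, gap=0):
    """n protein-coding genes of identical length -> average exactly `length`."""
    genes, pos = [], 1
    for i in range(n):
        genes.append((f"f{i}", "c1", pos, pos + length - 1))
        pos += length + gap
    return make_annotation(genes)


def brute_force_orphans(calls, threshold):
    """Quadratic all-pairs oracle: orphan iff min start distance on the
    same contig strictly exceeds the threshold."""
    tcs = [c for c in calls if c.tcs_class.is_tcs]
    flags = {}
    for c in tcs:
        dists = [abs(c.start - o.start) for o in tcs
                 if o.gene_id != c.gene_id and o.contig_id == c.contig_id]
        flags[c.gene_id] = (min(dists) if dists else math.inf) > threshold
    return flags


def test_average_gene_length_identical():
    assert average_gene_length(_uniform_annotation(10, 1000)) == 1000.0


def test_average_gene_length_two_point_mean():
    ann = make_annotation([("a", "c1", 1, 900), ("b", "c1", 2000, 3099)])  # 900, 1100 bp
    assert average_gene_length(ann) == 1000.0


def test_average_gene_length_skips_noncoding():
    ann = make_annotation([("a", "c1", 1, 1000), ("rna", "c1", 2001, 2100, False)])
    assert average_gene_length(ann) == 1000.0


def test_average_gene_length_requires_coding_genes():
    ann = make_annotation([("rna", "c1", 1, 100, False)])
    with pytest.raises(ValueError):
        average_gene_length(ann)


@pytest.mark.parametrize(
    "starts, expected_orphans",
    [
        # avg gene length 1000 -> threshold 4000 (strict)
        ([1, 3501], set()),                      # 3500 <= 4000: neither
        ([1, 4002], {"t0", "t1"}),               # 4001 > 4000: both
        ([1, 3001, 9001], {"t2"}),               # min distances 3000/3000/6000
    ],
)
def test_orphan_threshold_arithmetic(starts, expected_orphans):
    ann = _uniform_annotation(20, 1000)
    calls = _calls(starts)
    out = find_orphans(calls, ann, multiplier=4.0)
    assert {o.gene_id for o in out if o.is_orphan} == expected_orphans
    for o in out:
        assert o.threshold_bp == 4000.0


def test_sole_tcs_gene_on_contig_is_orphan():
    ann = _uniform_annotation(10, 1000)
    out = find_orphans(_calls([500]), ann)
    assert out[0].is_orphan and out[0].nearest_tcs_distance_bp == math.inf


def test_contigs_are_independent():
    # same starts on different contigs: no cross-contig neighbors
    ann = _uniform_annotation(10, 1000)
    calls = _calls([1], contig="c1") + [
        TCSGeneCall("x", TCSClass.RR_ONLY, frozenset({"PF00072"}), start=10, contig_id="c2")
    ]
    out = {o.gene_id: o for o in find_orphans(calls, ann)}
    assert out["t0"].is_orphan and out["x"].is_orphan


def test_excluded_genes_are_not_neighbors():
    ann = _uniform_annotation(20, 1000)
    calls = _calls([1, 9001]) + [
        TCSGeneCall("decoy", TCSClass.EXCLUDED, frozenset({"PF00204"}), start=9500, contig_id="c1")
    ]
    out = {o.gene_id: o for o in find_orphans(calls, ann)}
    assert "decoy" not in out  # not a candidate
    assert out["t1"].is_orphan  # and not a neighbor either


def test_multiplier_must_be_positive():
    ann = _uniform_annotation(5, 1000)
    with pytest.raises(ValueError):
        find_orphans(_calls([1]), ann, multiplier=0)


def test_matches_brute_force_oracle_on_random_genomes():
    """Sorted single-pass nearest neighbor == quadratic all-pairs scan."""
    rng = np.random.default_rng(42)
    ann = _uniform_annotation(30, 1000)
    for _ in range(300):
        n = int(rng.integers(1, 12))
        starts = sorted(int(s) for s in rng.integers(1, 60_000, size=n))
        contigs = rng.choice(["c1", "c2"], size=n)
        calls = [
            TCSGeneCall(f"t{i}", TCSClass.HPK_ONLY, frozenset({"PF02518"}),
                        start=s, contig_id=str(c))
            for i, (s, c) in enumerate(zip(starts, contigs))
        ]
        mult = float(rng.uniform(0.5, 6.0))
        got = {o.gene_id: o.is_orphan for o in find_orphans(calls, ann, multiplier=mult)}
        assert got == brute_force_orphans(calls, mult * 1000.0)


def test_orphan_monotonicity_under_insertion():
    """Adding a TCS gene can only shrink nearest distances: never converts
    a non-orphan into an orphan."""
    rng = np.random.default_rng(7)
    ann = _uniform_annotation(30, 1000)
    for _ in range(100):
        starts = sorted(int(s) for s in rng.integers(1, 50_000, size=5))
        calls = _calls(starts)
        before = {o.gene_id: o.is_orphan for o in find_orphans(calls, ann)}
        extra = calls + [TCSGeneCall("new", TCSClass.RR_ONLY, frozenset({"PF00072"}),
                                     start=int(rng.integers(1, 50_000)), contig_id="c1")]
        after = {o.gene_id: o.is_orphan for o in find_orphans(extra, ann)}
        for gid, was_orphan in before.items():
            if not was_orphan:
                assert not after[gid]


def test_genome_track_sorted_and_round_trip():
    ann = _uniform_annotation(20, 1000)
    calls = _calls([9001, 1, 3001])  # deliberately out of order
    out = find_orphans(calls, ann)
    track = genome_track(calls, out)
    assert list(track["start"]) == sorted(track["start"])
    assert genome_track([], []).empty


def test_track_positions_equal_planted_positions():
    sim = generate_genome(GenomeSpec(genome_id="trk", n_genes=150, seed=11))
    calls, _ = classify_genome(sim.annotation)
    out = find_orphans(calls, sim.annotation)
    track = genome_track(calls, out)
    planted = {g.gene_id: g.start for g in sim.annotation.genes
               if sim.classes[g.gene_id].is_tcs}
    assert dict(zip(track["gene_id"], track["start"])) == planted
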