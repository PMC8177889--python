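import numpy as np
import pytest
from Bio.Seq import Seq

from hydroprofiler import _seq
from hydroprofiler.refdb import CATEGORIES
from hydroprofiler.simulate import (
    CommunityDesign,
    GeneFeature,
    SyntheticGenome,
    generate_condition_samples,
    generate_genome,
    generate_reference_and_decoys,
    knockout_genome,
    reverse_translate,
    simulate_reads,
)


def test_reverse_translate_roundtrip():
    rng = np.random.default_rng(0)
    protein = "MKLVFAWYCDEGHINPQRST"
    dna = reverse_translate(protein, rng)
    assert len(dna) == 3 * len(protein)
    assert str(Seq(dna).translate()) == protein


def test_generate_reference_shape_and_decoys():
    db, decoys = generate_reference_and_decoys(3, (100, 150), 2, seed=5)
    assert len(db.entries) == 15
    cats = {e.activity_category for e in db.entries}
    assert cats == set(CATEGORIES)
    assert all(100 <= len(e.protein_seq) <= 150 for e in db.entries)
    # decoys share no 8-mer with any entry
    entry_kmers = set()
    for e in db.entries:
        s = e.protein_seq
        entry_kmers |= {s[i : i + 8] for i in range(len(s) - 7)}
    for _, d in decoys:
        dk = {d[i : i + 8] for i in range(len(d) - 7)}
        assert entry_kmers.isdisjoint(dk)


def test_generate_reference_deterministic():
    a, da = generate_reference_and_decoys(2, 100, 1, seed=9)
    b, db_ = generate_reference_and_decoys(2, 100, 1, seed=9)
    assert [e.protein_seq for e in a.entries] == [e.protein_seq for e in b.entries]
    assert da == db_


def test_generate_genome_embeds_translatable_cds(small_genome, small_reference):
    db, _ = small_reference
    proteins = {e.entry_id: e.protein_seq for e in db.entries}
    assert len(small_genome.features) == 3
    for f in small_genome.features:
        cds = small_genome.cds_sequence(f)
        assert str(Seq(cds).translate()) == proteins[f.entry_id]


def test_genome_rejects_overlapping_features():
    with pytest.raises(ValueError, match="overlap"):
        SyntheticGenome(
            genome_id="g",
            sequence="A" * 100,
            features=(
                GeneFeature("a", 0, 30, "+"),
                GeneFeature("b", 20, 50, "+"),
            ),
        )


def test_knockout_removes_hydrogenase_keeps_others():
    g = generate_genome(
        10_000,
        [("h1", "M" * 60, "hydrogenase"), ("d1", "K" * 60, "decoy")],
        seed=3,
        genome_id="g",
    )
    ko = knockout_genome(g)
    assert ko.is_knockout
    assert len(ko.sequence) == len(g.sequence) - 180
    assert [f.entry_id for f in ko.features] == ["d1"]
    # preserved decoy CDS still translates to its protein
    f = ko.features[0]
    assert str(Seq(ko.cds_sequence(f)).translate()) == "K" * 60
    with pytest.raises(ValueError, match="already a knockout"):
        knockout_genome(ko)


def test_simulate_reads_pair_count_and_truth(small_genome):
    reads = simulate_reads(small_genome, fold_coverage=2.0, read_length=100, error_rate=0.0, seed=1)
    expected = round(2.0 * len(small_genome) / 200)
    assert len(reads) == expected
    assert set(reads.truth) == set(reads.read_ids())
    # error-free mates reconstruct the fragment: mate1 = fragment[:r],
    # mate2 = revcomp(fragment[r:])
    for rid, s1, q1, s2, q2 in reads.records[:20]:
        gid, start, _ = reads.truth[rid]
        assert gid == small_genome.genome_id
        frag = small_genome.sequence[start : start + 200]
        assert s1 == frag[:100]
        assert s2 == str(Seq(frag[100:]).reverse_complement())
        assert q1 == q2 == "I" * 100


def test_simulate_reads_error_rate():
    g = generate_genome(50_000, [], seed=11, genome_id="bg")
    reads = simulate_reads(g, fold_coverage=4.0, read_length=100, error_rate=0.02, seed=2)
    mismatches = 0
    bases = 0
    for rid, s1, _, s2, _ in reads.records:
        _, start, _ = reads.truth[rid]
        frag = g.sequence[start : start + 200]
        m2 = str(Seq(frag[100:]).reverse_complement())
        mismatches += sum(a != b for a, b in zip(s1, frag[:100]))
        mismatches += sum(a != b for a, b in zip(s2, m2))
        bases += 200
    rate = mismatches / bases
    assert 0.015 < rate < 0.025


def test_truth_overlapped_entry(small_genome):
    reads = simulate_reads(small_genome, 5.0, 100, 0.0, seed=4)
    feats = small_genome.features
    hit_any = 0
    for rid in reads.read_ids():
        _, start, entry = reads.truth[rid]
        overlaps = [
            f.entry_id
            for f in feats
            if min(f.end, start + 200) - max(f.start, start) > 0
        ]
        if entry is None:
            assert overlaps == []
        else:
            assert entry in overlaps
            hit_any += 1
    assert hit_any > 0


def test_community_design_validation():
    with pytest.raises(ValueError, match="sum to"):
        CommunityDesign(
            members=(("a", (0.5, 0.5)), ("b", (0.6, 0.5))),
            groups=("g1", "g2"),
            samples_per_group=1,
            read_pairs_per_sample=10,
        )


def test_generate_condition_samples_structure():
    g1 = generate_genome(5_000, [("h1", "A" * 60)], seed=1, genome_id="m1")
    g2 = generate_genome(5_000, [], seed=2, genome_id="m2")
    host = generate_genome(5_000, [], seed=3, genome_id="host")
    design = CommunityDesign(
        members=(("m1", (0.4, 0.7)), ("m2", (0.6, 0.3))),
        groups=("mock", "case"),
        samples_per_group=2,
        read_pairs_per_sample=500,
        host_fraction=0.1,
        seed=99,
    )
    samples, truth = generate_condition_samples(design, [g1, g2], host)
    assert sorted(samples) == ["case_01", "case_02", "mock_01", "mock_02"]
    assert truth["groups"]["mock_01"] == "mock"
    for sid, rs in samples.items():
        assert len(rs) == 500
        sources = {gid for gid, _, _ in rs.truth.values()}
        assert sources <= {"m1", "m2", "host"}
    exp = truth["expected_category_fraction"]
    assert set(exp) == {"mock", "case"}
    # m1 carries an entry whose id prefix is not a category name -> all zero
    assert all(v == 0.0 for v in exp["mock"].values())


def test_generate_condition_samples_deterministic():
    g = generate_genome(5_000, [], seed=1, genome_id="m")
    host = generate_genome(5_000, [], seed=2, genome_id="h")
    design = CommunityDesign(
        members=(("m", (1.0, 1.0)),),
        groups=("a", "b"),
        samples_per_group=1,
        read_pairs_per_sample=100,
        seed=5,
    )
    s1, _ = generate_condition_samples(design, [g], host)
    s2, _ = generate_condition_samples(design, [g], host)
    assert s1["a_01"].records == s2["a_01"].records
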