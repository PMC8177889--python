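import math

import numpy as np
import pytest

from _oracles import bit_and_evalue, oracle_best_hit, six_frames
from hydroprofiler.refdb import ActivityCategory, HydrogenaseEntry, MetalClass, ReferenceDB
from hydroprofiler.search import (
    Hit,
    SearchParams,
    filter_host_reads,
    quality_filter,
    read_hits,
    search_reads,
    six_frame_translate,
    write_hits,
)
from hydroprofiler.simulate import ReadSet, generate_genome, simulate_reads

AAS = "ACDEFGHIKLMNPQRSTVWY"
NTS = "ACGT"


def _random_db(rng, n_entries, min_len=40, max_len=80):
    cats = list(ActivityCategory)
    entries = []
    for i in range(n_entries):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(AAS[j] for j in rng.integers(0, 20, size=length))
        entries.append(
            HydrogenaseEntry(
                entry_id=f"e{i:02d}",
                protein_seq=seq,
                metal_class=MetalClass.NIFE,
                activity_category=cats[i % len(cats)],
            )
        )
    return ReferenceDB(entries=tuple(entries))


def _readset(seqs):
    qual = {i: "I" * len(s) for i, s in enumerate(seqs)}
    records = []
    for i in range(0, len(seqs) - 1, 2):
        records.append((f"r{i // 2:03d}", seqs[i], qual[i], seqs[i + 1], qual[i + 1]))
    return ReadSet(records=records)


def test_six_frame_matches_biopython():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(3, 120))
        dna = "".join(NTS[j] for j in rng.integers(0, 4, size=n))
        assert six_frame_translate(dna) == six_frames(dna)


def test_six_frame_worked_examples():
    assert six_frame_translate("ATGAAA") == ["MK", "*", "E", "FH", "F", "S"]
    assert six_frame_translate("ATG") == ["M", "", "", "H", "", ""]
    with pytest.raises(ValueError):
        six_frame_translate("AT")


def test_six_frame_n_renders_x():
    assert six_frame_translate("ATNGGG")[0] == "XG"


def test_search_params_validation():
    with pytest.raises(ValueError):
        SearchParams(seed_length=5)
    with pytest.raises(ValueError):
        SearchParams(evalue_cutoff=0.0)
    with pytest.raises(ValueError):
        SearchParams(scoring_matrix="PAM250")


def test_search_matches_bruteforce_oracle():
    """Reported raw score equals the exhaustive seeded-alignment optimum."""
    rng = np.random.default_rng(20_240_101)
    params = SearchParams(evalue_cutoff=1e12, search_space=1.0)
    for trial in range(60):
        db = _random_db(rng, int(rng.integers(2, 6)))
        entries = [(e.entry_id, e.protein_seq) for e in db.active_entries]
        seqs = []
        for _ in range(8):
            n = int(rng.integers(30, 61))
            seqs.append("".join(NTS[j] for j in rng.integers(0, 4, size=n)))
        # plant one read derived from an entry so hits actually occur
        src = entries[0][1]
        from hydroprofiler.simulate import reverse_translate

        seqs[0] = reverse_translate(src[:20], rng)
        reads = _readset(seqs)
        hits = {h.read_id: h for h in search_reads(reads, db, params)}
        for rid, s1, _, s2, _ in reads.records:
            for mate, seq in ((f"{rid}/1", s1), (f"{rid}/2", s2)):
                expected = oracle_best_hit(seq, entries)
                got = hits.get(mate)
                if expected is None:
                    assert got is None, f"spurious hit for {mate}"
                    continue
                best, winners = expected
                assert got is not None, f"missing hit for {mate} (best={best})"
                assert got.raw_score == best
                # ties break to the lexicographically smallest entry id
                assert got.entry_id == winners[0]
                bit, ev = bit_and_evalue(best, 1.0)
                assert got.bit_score == pytest.approx(bit)
                assert got.evalue == pytest.approx(ev)


def test_search_default_search_space_and_cutoff():
    rng = np.random.default_rng(7)
    db = _random_db(rng, 3)
    entries = [(e.entry_id, e.protein_seq) for e in db.active_entries]
    ref_residues = sum(len(p) for _, p in entries)
    from hydroprofiler.simulate import reverse_translate

    read = reverse_translate(db.active_entries[1].protein_seq[5:35], rng)
    reads = _readset([read, read])
    hits = search_reads(reads, db, SearchParams())
    assert hits, "a 30-residue exact translation must pass the 0.001 cutoff"
    for h in hits:
        bit, ev = bit_and_evalue(h.raw_score, ref_residues * (len(read) // 3))
        assert h.evalue == pytest.approx(ev)
        assert h.evalue <= 0.001


def test_search_respects_exclusions():
    rng = np.random.default_rng(8)
    db = _random_db(rng, 2)
    from hydroprofiler.refdb import apply_exclusions
    from hydroprofiler.simulate import reverse_translate

    target = db.active_entries[0]
    read = reverse_translate(target.protein_seq[:30], rng)
    reads = _readset([read, read])
    assert any(h.entry_id == target.entry_id for h in search_reads(reads, db))
    curated = apply_exclusions(db, [target.entry_id])
    assert all(h.entry_id != target.entry_id for h in search_reads(reads, curated))


def test_quality_filter():
    good = ("a", "ACGT" * 20, "I" * 80, "ACGT" * 20, "I" * 80)
    low_q = ("b", "ACGT" * 20, "#" * 80, "ACGT" * 20, "I" * 80)
    short = ("c", "ACGT", "IIII", "ACGT" * 20, "I" * 80)
    rs = ReadSet(records=[good, low_q, short], truth={"a": ("g", 0, None), "b": ("g", 1, None), "c": ("g", 2, None)})
    out = quality_filter(rs, min_mean_quality=20.0, min_length=50)
    assert [r[0] for r in out.records] == ["a"]
    assert set(out.truth) == {"a"}


def test_host_filter_removes_host_reads():
    host = generate_genome(30_000, [], seed=1, genome_id="host")
    other = generate_genome(30_000, [], seed=2, genome_id="other")
    host_reads = simulate_reads(host, 1.0, 100, 0.005, seed=3)
    other_reads = simulate_reads(other, 1.0, 100, 0.005, seed=4)
    merged = ReadSet(
        records=host_reads.records + other_reads.records,
        truth={**host_reads.truth, **other_reads.truth},
    )
    out = filter_host_reads(merged, host)
    kept_sources = {out.truth[rid][0] for rid in (r[0] for r in out.records)}
    assert kept_sources == {"other"}
    assert len(out) == len(other_reads)


def test_hits_roundtrip(tmp_path):
    hits = [
        Hit("r1/1", "e1", 2, 5, 60.0, 22.5, 1e-4),
        Hit("r0/2", "e2", -3, 0, 48.0, 18.0, 9e-4),
    ]
    p = tmp_path / "hits.tsv"
    write_hits(hits, p)
    back = read_hits(p)
    assert [h.read_id for h in back] == ["r0/2", "r1/1"]
    assert back[1].frame == 2
    assert back[1].raw_score == 60.0
    assert back[0].evalue == pytest.approx(9e-4)
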