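"""Study-level compositions of the pipeline stages.

These functions wire the synthetic-data generator through QC, search,
curation and profiling exactly as the stages compose on real data, and are
the backbone of the validation suite:

* :func:`decoy_validation_study` -- the in-silico knockout experiment: decoy
  entries planted in the reference must be excluded by the twofold rule while
  every genuine entry is retained;
* :func:`enrichment_study` -- a two-group community with a planted fold-change
  in uptake-hydrogenase carrier abundance, recovered by the category-level
  Mann-Whitney chain;
* :func:`search_validation` -- truth-map accuracy of the translated search
  (in-CDS assignment, spurious-hit floor on hydrogenase-free reads).

Fixture parameters default to the study conditions described in
``docs/methods.md``; all randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curate import CurationReport, count_hits, curate_database
from .profile import (
    CategoryProfile,
    GroupComparisonResult,
    NormalizedTable,
    PSEUDO_VALUE_MURINE,
    aggregate_categories,
    build_hit_table,
    compare_groups,
    normalize_hit_table,
)
from .refdb import CATEGORIES, ReferenceDB
from .search import SearchParams, filter_host_reads, quality_filter, search_reads
from .simulate import (
    CommunityDesign,
    ReadSet,
    SyntheticGenome,
    generate_condition_samples,
    generate_genome,
    generate_reference_and_decoys,
    knockout_genome,
    simulate_reads,
    with_decoy_entries,
)
from ._seq import encode_dna, decode_dna, revcomp_codes

__all__ = [
    "DecoyStudyResult",
    "EnrichmentStudyResult",
    "decoy_validation_study",
    "enrichment_study",
    "search_validation",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one master seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping substring occurrences."""
    count = 0
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _revcomp(seq: str) -> str:
    return decode_dna(revcomp_codes(encode_dna(seq)))


# --- decoy curation study ----------------------------------------------------


@dataclass
class DecoyStudyResult:
    db: ReferenceDB  # reference including planted decoy entries
    curated_db: ReferenceDB
    report: CurationReport
    true_ids: frozenset[str]
    decoy_ids: frozenset[str]
    genomes: list[SyntheticGenome]
    knockouts: list[SyntheticGenome]
    knockout_cds_occurrences: int  # excised CDSs found in knockout genomes (expect 0)
    wt_mapped_reads: int
    ko_mapped_reads: int

    @property
    def excluded_ids(self) -> frozenset[str]:
        return self.report.excluded_ids


def decoy_validation_study(
    seed: int,
    n_per_category: int = 2,
    n_decoys: int = 3,
    n_genomes: int = 5,
    genome_length: int = 50_000,
    fold_coverage: float = 50.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    protein_length: int | tuple[int, int] = (200, 400),
    params: SearchParams | None = None,
) -> DecoyStudyResult:
    """Run the in-silico knockout decoy validation end to end.

    Genomes carry both genuine hydrogenase CDSs and decoy genes; the decoy
    proteins are also planted in the reference as if they were annotated
    hydrogenases.  Reads simulated from the wild-type and hydrogenase-free
    (knockout) genomes are searched against that reference and the twofold
    rule is applied.  Decoy entries keep recruiting reads in the knockout
    dataset while genuine entries recruit nothing, so relative recruitment
    flags exactly the decoys.
    """
    seeds = _child_seeds(seed, 2 + 3 * n_genomes)
    db_true, decoys = generate_reference_and_decoys(
        n_per_category, protein_length, n_decoys, seeds[0]
    )
    db = with_decoy_entries(db_true, decoys)
    true_ids = frozenset(e.entry_id for e in db_true.entries)
    decoy_ids = frozenset(d for d, _ in decoys)

    # distribute true entries and decoy genes across the genomes
    items_per_genome: list[list[tuple[str, str, str]]] = [[] for _ in range(n_genomes)]
    for i, e in enumerate(db_true.entries):
        items_per_genome[i % n_genomes].append((e.entry_id, e.protein_seq, "hydrogenase"))
    for i, (did, pseq) in enumerate(decoys):
        items_per_genome[i % n_genomes].append((did, pseq, "decoy"))

    genomes = [
        generate_genome(genome_length, items, seeds[1 + g], genome_id=f"genome_{g + 1}")
        for g, items in enumerate(items_per_genome)
    ]
    knockouts = [knockout_genome(g) for g in genomes]

    # exhaustive scan: no excised CDS may survive anywhere in its knockout genome
    occurrences = 0
    for g, ko in zip(genomes, knockouts):
        for f in g.features:
            if f.role != "hydrogenase":
                continue
            segment = g.sequence[f.start : f.end]
            occurrences += _count_occurrences(ko.sequence, segment)
            occurrences += _count_occurrences(ko.sequence, _revcomp(segment))

    wt_hits = []
    ko_hits = []
    for g, ko, s_wt, s_ko in zip(
        genomes,
        knockouts,
        seeds[1 + n_genomes : 1 + 2 * n_genomes],
        seeds[1 + 2 * n_genomes :],
    ):
        wt_reads = simulate_reads(g, fold_coverage, read_length, error_rate, s_wt)
        ko_reads = simulate_reads(ko, fold_coverage, read_length, error_rate, s_ko)
        wt_hits.extend(search_reads(wt_reads, db, params))
        ko_hits.extend(search_reads(ko_reads, db, params))

    wt_counts = count_hits(wt_hits)
    ko_counts = count_hits(ko_hits)
    report, curated = curate_database(wt_counts, ko_counts, db)
    return DecoyStudyResult(
        db=db,
        curated_db=curated,
        report=report,
        true_ids=true_ids,
        decoy_ids=decoy_ids,
        genomes=genomes,
        knockouts=knockouts,
        knockout_cds_occurrences=occurrences,
        wt_mapped_reads=len(wt_hits),
        ko_mapped_reads=len(ko_hits),
    )


# --- planted enrichment study ------------------------------------------------


@dataclass
class EnrichmentStudyResult:
    db: ReferenceDB
    results: list[GroupComparisonResult]
    profile: CategoryProfile
    norm: NormalizedTable
    truth_summary: dict
    planted_category: str
    host_pairs_total: int
    host_pairs_removed: int
    mapped_reads_total: int

    def result_for(self, category: str) -> GroupComparisonResult:
        for r in self.results:
            if r.category == category:
                return r
        raise KeyError(category)

    @property
    def host_removal_fraction(self) -> float:
        return self.host_pairs_removed / self.host_pairs_total if self.host_pairs_total else 1.0


def enrichment_study(
    seed: int,
    samples_per_group: int = 6,
    read_pairs_per_sample: int = 20_000,
    planted_fold: float = 4.0,
    planted_category: str = "uptake",
    n_per_category: int = 8,
    protein_length: tuple[int, int] = (150, 450),
    genome_length: int = 50_000,
    read_length: int = 100,
    error_rate: float = 0.005,
    host_fraction: float = 0.05,
    planted_abundance: float = 0.03,
    carrier_abundance: float = 0.15,
    pseudo_value: float = PSEUDO_VALUE_MURINE,
    params: SearchParams | None = None,
) -> EnrichmentStudyResult:
    """Two-group community with a planted carrier fold-change, profiled end to end.

    One carrier genome per activity category (each holding that category's
    reference entries), one hydrogenase-free background genome that absorbs
    the abundance shift, and a host genome contributing ``host_fraction`` of
    read pairs.  The planted carrier's abundance is ``planted_fold`` times
    higher in the second group.  Samples run through quality filtering, host
    decontamination, translated search, and the category-level group
    comparison.
    """
    if planted_category not in {c.value for c in CATEGORIES}:
        raise ValueError(f"unknown category {planted_category!r}")
    boosted = planted_abundance * planted_fold
    others_total = carrier_abundance * (len(CATEGORIES) - 1)
    bg_a = 1.0 - planted_abundance - others_total
    bg_b = 1.0 - boosted - others_total
    if bg_b <= 0 or bg_a <= 0:
        raise ValueError("carrier abundances leave no room for the background genome")

    seeds = _child_seeds(seed, 4 + len(CATEGORIES))
    db, _ = generate_reference_and_decoys(n_per_category, protein_length, 0, seeds[0])

    genomes = []
    members = []
    by_cat: dict[str, list] = {c.value: [] for c in CATEGORIES}
    for e in db.entries:
        by_cat[e.activity_category.value].append((e.entry_id, e.protein_seq, "hydrogenase"))
    for ci, cat in enumerate(CATEGORIES):
        g = generate_genome(
            genome_length, by_cat[cat.value], seeds[1 + ci], genome_id=f"carrier_{cat.value}"
        )
        genomes.append(g)
        if cat.value == planted_category:
            members.append((g.genome_id, (planted_abundance, boosted)))
        else:
            members.append((g.genome_id, (carrier_abundance, carrier_abundance)))
    background = generate_genome(
        genome_length, [], seeds[1 + len(CATEGORIES)], genome_id="background"
    )
    genomes.append(background)
    members.append(("background", (bg_a, bg_b)))
    host = generate_genome(
        genome_length, [], seeds[2 + len(CATEGORIES)], genome_id="host"
    )

    design = CommunityDesign(
        members=tuple(members),
        groups=("mock", "case"),
        samples_per_group=samples_per_group,
        read_pairs_per_sample=read_pairs_per_sample,
        read_length=read_length,
        error_rate=error_rate,
        host_fraction=host_fraction,
        seed=seeds[3 + len(CATEGORIES)],
    )
    samples, truth_summary = generate_condition_samples(design, genomes, host)

    per_sample_counts: dict[str, dict[str, int]] = {}
    host_total = 0
    host_removed = 0
    mapped_total = 0
    for sid, reads in samples.items():
        filtered = quality_filter(reads)
        truth = filtered.truth or {}
        host_ids = {rid for rid, (gid, _, _) in truth.items() if gid == "host"}
        host_total += len(host_ids)
        cleaned = filter_host_reads(filtered, host)
        remaining = {r[0] for r in cleaned.records}
        host_removed += len(host_ids - remaining)
        hits = search_reads(cleaned, db, params)
        mapped_total += len(hits)
        per_sample_counts[sid] = count_hits(hits)

    table = build_hit_table(per_sample_counts, truth_summary["groups"], entry_ids=db.active_ids)
    norm = normalize_hit_table(table)
    profile = aggregate_categories(norm, db)
    results = compare_groups(norm, db, pseudo_value=pseudo_value)
    return EnrichmentStudyResult(
        db=db,
        results=results,
        profile=profile,
        norm=norm,
        truth_summary=truth_summary,
        planted_category=planted_category,
        host_pairs_total=host_total,
        host_pairs_removed=host_removed,
        mapped_reads_total=mapped_total,
    )


# --- search validation -------------------------------------------------------


def search_validation(
    seed: int,
    n_per_category: int = 2,
    protein_length: tuple[int, int] = (200, 400),
    genome_length: int = 50_000,
    fold_coverage: float = 20.0,
    read_length: int = 100,
    params: SearchParams | None = None,
) -> dict:
    """Truth-map validation of the translated search on a standard fixture.

    Measures (a) the fraction of error-free mates fully contained in a
    hydrogenase CDS that are assigned to their source entry, and (b) the
    fraction of read pairs from hydrogenase-free (knockout) genomes that
    produce any hit at all -- the spurious-homology floor.
    """
    seeds = _child_seeds(seed, 7)
    db, _ = generate_reference_and_decoys(n_per_category, protein_length, 0, seeds[0])
    entries = list(db.entries)
    half = (len(entries) + 1) // 2
    g1 = generate_genome(
        genome_length,
        [(e.entry_id, e.protein_seq) for e in entries[:half]],
        seeds[1],
        genome_id="fixture_1",
    )
    g2 = generate_genome(
        genome_length,
        [(e.entry_id, e.protein_seq) for e in entries[half:]],
        seeds[2],
        genome_id="fixture_2",
    )

    in_cds = 0
    correct = 0
    ko_pairs = 0
    ko_hit_pairs = 0
    for g, s_wt, s_ko in ((g1, seeds[3], seeds[4]), (g2, seeds[5], seeds[6])):
        reads = simulate_reads(g, fold_coverage, read_length, error_rate=0.0, seed=s_wt)
        hits = {h.read_id: h for h in search_reads(reads, db, params)}
        for rid, (gid, start, _) in (reads.truth or {}).items():
            spans = ((f"{rid}/1", start, start + read_length),
                     (f"{rid}/2", start + read_length, start + 2 * read_length))
            for mate_id, lo, hi in spans:
                for f in g.features:
                    if f.start <= lo and hi <= f.end:
                        in_cds += 1
                        h = hits.get(mate_id)
                        if h is not None and h.entry_id == f.entry_id:
                            correct += 1
                        break

        ko = knockout_genome(g)
        ko_reads = simulate_reads(ko, fold_coverage, read_length, error_rate=0.0, seed=s_ko)
        ko_hits = search_reads(ko_reads, db, params)
        ko_pairs += len(ko_reads)
        ko_hit_pairs += len({h.read_id.rsplit("/", 1)[0] for h in ko_hits})

    return {
        "in_cds_mates": in_cds,
        "in_cds_correctly_assigned": correct,
        "in_cds_accuracy": correct / in_cds if in_cds else float("nan"),
        "knockout_pairs": ko_pairs,
        "knockout_pairs_with_hit": ko_hit_pairs,
        "knockout_pair_hit_rate": ko_hit_pairs / ko_pairs if ko_pairs else float("nan"),
    }
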