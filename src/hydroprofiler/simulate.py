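"""Synthetic data generation: reference proteins, genomes, knockouts, reads.

This module stands in for the raw material of a hydrogenase profiling study:

* random annotated reference proteins plus *decoy* proteins guaranteed to
  share no long exact substring with any real entry;
* synthetic genomes embedding reverse-translated coding sequences at random
  non-overlapping positions on either strand;
* in-silico knockout genomes with every hydrogenase CDS excised (the
  hydrogenase-free datasets used for decoy-based reference curation);
* 100 bp-style paired-end reads with uniform substitution errors and a full
  per-read ground-truth map;
* condition-stratified communities (two groups of samples with prescribed
  per-genome abundances and a host-read contamination fraction).

Every generator is deterministic under a fixed seed.  Coordinates are 0-based
half-open throughout.  The error model is substitution-only with flat quality
strings: sufficient to exercise a translated homology search, while indels,
quality decay and GC bias are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _seq
from .refdb import (
    AMINO_ACIDS,
    CATEGORIES,
    ActivityCategory,
    HydrogenaseEntry,
    MetalClass,
    ReferenceDB,
)

__all__ = [
    "GeneFeature",
    "SyntheticGenome",
    "CommunityDesign",
    "ReadSet",
    "generate_reference_and_decoys",
    "generate_genome",
    "knockout_genome",
    "simulate_reads",
    "generate_condition_samples",
    "reverse_translate",
    "with_decoy_entries",
]

_DECOY_KMER = 8  # decoys must share no exact substring of this length with entries


@dataclass(frozen=True)
class GeneFeature:
    """A CDS placement on a synthetic genome (0-based, half-open)."""

    entry_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    role: str = "hydrogenase"  # "hydrogenase" | "decoy" | "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.entry_id}: invalid interval [{self.start},{self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"{self.entry_id}: CDS length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.entry_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SyntheticGenome:
    genome_id: str
    sequence: str
    features: tuple[GeneFeature, ...] = ()
    is_knockout: bool = False

    def __post_init__(self) -> None:
        last = 0
        for f in sorted(self.features, key=lambda f: f.start):
            if f.start < last:
                raise ValueError(f"{self.genome_id}: overlapping features at {f.entry_id}")
            if f.end > len(self.sequence):
                raise ValueError(f"{self.genome_id}: feature {f.entry_id} beyond genome end")
            last = f.end
        if self.is_knockout and any(f.role == "hydrogenase" for f in self.features):
            raise ValueError(f"{self.genome_id}: knockout genome retains hydrogenase features")

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_sequence(self, feature: GeneFeature) -> str:
        """The coding-strand CDS (reverse-complemented for '-' features)."""
        seg = self.sequence[feature.start : feature.end]
        if feature.strand == "-":
            seg = _seq.decode_dna(_seq.revcomp_codes(_seq.encode_dna(seg)))
        return seg


@dataclass(frozen=True)
class CommunityDesign:
    """Two-group sampling design for condition-stratified communities.

    ``members`` maps each genome id to its relative abundance in each of the
    two groups (per-group abundances must each sum to 1).
    """

    members: tuple[tuple[str, tuple[float, float]], ...]
    groups: tuple[str, str]
    samples_per_group: int
    read_pairs_per_sample: int
    read_length: int = 100
    error_rate: float = 0.005
    host_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError("exactly two condition groups are required")
        for gi in range(2):
            total = sum(ab[gi] for _, ab in self.members)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"group {self.groups[gi]!r} abundances sum to {total}, expected 1"
                )
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0 <= self.host_fraction < 1:
            raise ValueError("host_fraction must be in [0, 1)")


@dataclass
class ReadSet:
    """Paired reads with optional per-pair ground truth.

    ``records`` holds ``(read_id, mate1_seq, mate1_qual, mate2_seq,
    mate2_qual)`` tuples; ``truth`` maps read_id to ``(source_genome_id,
    fragment_start, overlapped_entry_id_or_None)``.
    """

    records: list[tuple[str, str, str, str, str]]
    truth: dict[str, tuple[str, int, str | None]] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def read_ids(self) -> list[str]:
        return [r[0] for r in self.records]


# --- proteins and reference ------------------------------------------------

def _draw_length(rng: np.random.Generator, protein_length: int | tuple[int, int]) -> int:
    if isinstance(protein_length, tuple):
        lo, hi = protein_length
        return int(rng.integers(lo, hi + 1))
    return int(protein_length)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def generate_reference_and_decoys(
    n_per_category: int,
    protein_length: int | tuple[int, int],
    n_decoys: int,
    seed: int,
    max_retries: int = 100,
) -> tuple[ReferenceDB, list[tuple[str, str]]]:
    """Random annotated reference plus decoy proteins.

    The database holds ``n_per_category`` entries for each of the five
    activity categories.  Decoys are random proteins sharing no exact
    substring of >= 8 residues with any reference entry, so any read
    recruitment they receive from hydrogenase-free sequence is genuine
    decoy signal rather than residual homology.

    ``protein_length`` may be a single length or an inclusive ``(lo, hi)``
    range sampled per entry.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    min_len = protein_length[0] if isinstance(protein_length, tuple) else protein_length
    if min_len < 50:
        raise ValueError("protein_length must be >= 50")
    rng = np.random.default_rng(seed)
    metals = [MetalClass.NIFE, MetalClass.FEFE, MetalClass.FE]
    entries: list[HydrogenaseEntry] = []
    for ci, cat in enumerate(CATEGORIES):
        for k in range(n_per_category):
            entries.append(
                HydrogenaseEntry(
                    entry_id=f"{cat.value}_{k + 1:02d}",
                    protein_seq=_random_protein(rng, _draw_length(rng, protein_length)),
                    metal_class=metals[(ci * n_per_category + k) % 3],
                    activity_category=cat,
                    source_label="synthetic",
                )
            )
    entry_kmers: set[str] = set()
    for e in entries:
        entry_kmers |= _kmers(e.protein_seq, _DECOY_KMER)

    decoys: list[tuple[str, str]] = []
    for d in range(n_decoys):
        for _attempt in range(max_retries):
            cand = _random_protein(rng, _draw_length(rng, protein_length))
            if entry_kmers.isdisjoint(_kmers(cand, _DECOY_KMER)):
                decoys.append((f"decoy_{d + 1:02d}", cand))
                break
        else:
            raise RuntimeError(
                f"could not generate decoy {d + 1} distinct from all entries "
                f"after {max_retries} attempts"
            )
    return ReferenceDB(entries=tuple(entries), version_tag=f"synthetic-seed{seed}"), decoys


def with_decoy_entries(
    db: ReferenceDB, decoys: Iterable[tuple[str, str]]
) -> ReferenceDB:
    """Append decoy proteins to a reference as if they were annotated entries.

    This emulates unreliable (e.g. mis-annotated) catalogue entries: the decoy
    curation procedure is expected to find and exclude exactly these.
    """
    extra = tuple(
        HydrogenaseEntry(
            entry_id=did,
            protein_seq=pseq,
            metal_class=MetalClass.NIFE,
            activity_category=CATEGORIES[i % len(CATEGORIES)],
            source_label="decoy",
        )
        for i, (did, pseq) in enumerate(decoys)
    )
    return ReferenceDB(
        entries=db.entries + extra,
        excluded_ids=db.excluded_ids,
        version_tag=db.version_tag,
    )


# --- genomes ---------------------------------------------------------------

def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly random synonymous codons (seeded)."""
    codons = []
    for aa in protein:
        options = _seq.BACK_CODONS.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def generate_genome(
    background_length: int,
    proteins_to_embed: Sequence[tuple],
    seed: int,
    genome_id: str = "genome",
    max_retries: int = 1000,
) -> SyntheticGenome:
    """Random genome with each protein embedded once as a CDS.

    ``proteins_to_embed`` items are ``(id, protein)`` or ``(id, protein,
    role)``; role defaults to ``"hydrogenase"``.  Each CDS is placed at a
    random non-overlapping position on a random strand; the rest of the
    genome is uniform random nucleotide background.
    """
    items = [(t[0], t[1], t[2] if len(t) > 2 else "hydrogenase") for t in proteins_to_embed]
    total_aa = sum(len(p) for _, p, _ in items)
    if background_length < 3 * total_aa:
        raise ValueError("background_length must be >= 3x total embedded protein length")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=background_length).astype(np.int8)

    placed: list[tuple[int, int]] = []
    features: list[GeneFeature] = []
    for pid, protein, role in items:
        cds = reverse_translate(protein, rng)
        n = len(cds)
        for _attempt in range(max_retries):
            start = int(rng.integers(0, background_length - n + 1))
            end = start + n
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise RuntimeError(
                f"could not place CDS for {pid!r} without overlap after {max_retries} tries"
            )
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cds_codes = _seq.encode_dna(cds)
        if strand == "-":
            cds_codes = _seq.revcomp_codes(cds_codes)
        codes[start:end] = cds_codes
        placed.append((start, end))
        features.append(GeneFeature(pid, start, end, strand, role=role))

    features.sort(key=lambda f: f.start)
    return SyntheticGenome(
        genome_id=genome_id,
        sequence=_seq.decode_dna(codes),
        features=tuple(features),
    )


def knockout_genome(genome: SyntheticGenome) -> SyntheticGenome:
    """Excise every hydrogenase CDS; keep other features, coordinates shifted."""
    if genome.is_knockout:
        raise ValueError(f"{genome.genome_id} is already a knockout genome")
    removed = sorted(
        (f for f in genome.features if f.role == "hydrogenase"), key=lambda f: f.start
    )
    kept = sorted(
        (f for f in genome.features if f.role != "hydrogenase"), key=lambda f: f.start
    )
    pieces: list[str] = []
    pos = 0
    for f in removed:
        pieces.append(genome.sequence[pos : f.start])
        pos = f.end
    pieces.append(genome.sequence[pos:])
    new_seq = "".join(pieces)

    shifted: list[GeneFeature] = []
    for f in kept:
        shift = sum(len(r) for r in removed if r.end <= f.start)
        shifted.append(replace(f, start=f.start - shift, end=f.end - shift))
    return SyntheticGenome(
        genome_id=f"{genome.genome_id}__hydfree",
        sequence=new_seq,
        features=tuple(shifted),
        is_knockout=True,
    )


# --- reads -----------------------------------------------------------------

def _fragment_pairs(
    codes: np.ndarray,
    n_pairs: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform abutting-mate fragments: returns (starts, mate1, mate2) codes."""
    L = len(codes)
    r = read_length
    if 2 * r > L:
        raise ValueError("fragment (2x read length) longer than genome")
    starts = rng.integers(0, L - 2 * r + 1, size=n_pairs)
    frag = codes[starts[:, None] + np.arange(2 * r)]
    m1 = np.ascontiguousarray(frag[:, :r])
    m2 = np.ascontiguousarray(frag[:, : r - 1 : -1])  # reversed far half
    m2 = 3 - m2  # complement (synthetic genomes contain no N)
    if error_rate > 0:
        for m in (m1, m2):
            mask = rng.random(m.shape) < error_rate
            shift = rng.integers(1, 4, size=m.shape)
            m[mask] = (m[mask] + shift[mask]) % 4
    return starts, m1, m2


def _rows_to_strings(arr: np.ndarray) -> list[str]:
    chars = _seq._NT_CHARS[arr]
    buf = chars.tobytes()
    n, r = arr.shape
    return [buf[i * r : (i + 1) * r].decode("ascii") for i in range(n)]


def _overlapped_entry(
    features: Sequence[GeneFeature], frag_start: int, frag_len: int
) -> str | None:
    """Entry id of the feature with the largest overlap with the fragment."""
    best: str | None = None
    best_len = 0
    for f in features:
        ov = min(f.end, frag_start + frag_len) - max(f.start, frag_start)
        if ov > best_len:
            best_len = ov
            best = f.entry_id
    return best


def _make_readset(
    genome: SyntheticGenome,
    n_pairs: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    id_prefix: str,
    start_index: int = 0,
) -> ReadSet:
    codes = _seq.encode_dna(genome.sequence)
    starts, m1, m2 = _fragment_pairs(codes, n_pairs, read_length, error_rate, rng)
    qual = "I" * read_length
    s1 = _rows_to_strings(m1)
    s2 = _rows_to_strings(m2)
    records = []
    truth = {}
    frag_len = 2 * read_length
    for i in range(n_pairs):
        rid = f"{id_prefix}:{start_index + i:07d}"
        records.append((rid, s1[i], qual, s2[i], qual))
        truth[rid] = (
            genome.genome_id,
            int(starts[i]),
            _overlapped_entry(genome.features, int(starts[i]), frag_len),
        )
    return ReadSet(records=records, truth=truth)


def simulate_reads(
    genome: SyntheticGenome,
    fold_coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> ReadSet:
    """Simulate paired-end reads to the requested fold coverage.

    The number of pairs is ``round(fold_coverage * genome_length /
    (2 * read_length))``; fragments are uniform over placements, mate 2 is
    the reverse complement of the fragment's far half, and substitution
    errors are applied per base at ``error_rate``.
    """
    if fold_coverage <= 0:
        raise ValueError("fold_coverage must be > 0")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    n_pairs = int(round(fold_coverage * len(genome) / (2 * read_length)))
    rng = np.random.default_rng(seed)
    return _make_readset(genome, n_pairs, read_length, error_rate, rng, genome.genome_id)


def _expected_category_fractions(
    members: Sequence[tuple[str, float]],
    genome_by_id: Mapping[str, SyntheticGenome],
    read_length: int,
    host_fraction: float,
) -> dict[str, float]:
    """Expected fraction of all read pairs whose fragment overlaps each category.

    Computed from feature footprints (placements whose 2x-read fragment
    overlaps the feature by >= 1 nt), scaled by member abundance and the
    non-host fraction.  Window overlap between nearby same-category features
    is ignored; synthetic genomes place features sparsely.
    """
    frag = 2 * read_length
    out: dict[str, float] = {c.value: 0.0 for c in CATEGORIES}
    for gid, ab in members:
        g = genome_by_id[gid]
        n_place = len(g) - frag + 1
        if n_place <= 0:
            continue
        for f in g.features:
            if f.role != "hydrogenase":
                continue
            cat = f.entry_id.split("_")[0]
            if cat not in out:
                continue
            lo = max(0, f.start - frag + 1)
            hi = min(f.end - 1, len(g) - frag)
            count = max(0, hi - lo + 1)
            out[cat] += ab * count / n_place
    return {c: v * (1.0 - host_fraction) for c, v in out.items()}


def generate_condition_samples(
    design: CommunityDesign,
    genomes: Sequence[SyntheticGenome],
    host_genome: SyntheticGenome,
) -> tuple[dict[str, ReadSet], dict]:
    """Per-sample read sets for a two-group community design.

    Each sample draws a binomial number of host-contamination pairs, then
    splits the remaining pairs across member genomes by that group's
    abundances (multinomial).  Sample ids are ``{group}_{k}``; the returned
    truth summary carries the group map and expected per-category read
    fractions per group.
    """
    genome_by_id = {g.genome_id: g for g in genomes}
    for gid, _ in design.members:
        if gid not in genome_by_id:
            raise ValueError(f"community member {gid!r} has no genome")

    n_samples = 2 * design.samples_per_group
    children = np.random.SeedSequence(design.seed).spawn(n_samples)
    samples: dict[str, ReadSet] = {}
    groups_map: dict[str, str] = {}
    si = 0
    for gi, group in enumerate(design.groups):
        probs = np.array([ab[gi] for _, ab in design.members])
        for k in range(design.samples_per_group):
            sample_id = f"{group}_{k + 1:02d}"
            rng = np.random.default_rng(children[si])
            si += 1
            n_host = int(rng.binomial(design.read_pairs_per_sample, design.host_fraction))
            counts = rng.multinomial(design.read_pairs_per_sample - n_host, probs)
            records: list[tuple[str, str, str, str, str]] = []
            truth: dict[str, tuple[str, int, str | None]] = {}
            offset = 0
            for (gid, _), n in zip(design.members, counts):
                if n == 0:
                    continue
                rs = _make_readset(
                    genome_by_id[gid],
                    int(n),
                    design.read_length,
                    design.error_rate,
                    rng,
                    id_prefix=sample_id,
                    start_index=offset,
                )
                records.extend(rs.records)
                truth.update(rs.truth or {})
                offset += int(n)
            if n_host:
                rs = _make_readset(
                    host_genome,
                    n_host,
                    design.read_length,
                    design.error_rate,
                    rng,
                    id_prefix=sample_id,
                    start_index=offset,
                )
                records.extend(rs.records)
                truth.update(rs.truth or {})
            samples[sample_id] = ReadSet(records=records, truth=truth)
            groups_map[sample_id] = group

    truth_summary = {
        "groups": groups_map,
        "expected_category_fraction": {
            group: _expected_category_fractions(
                [(gid, ab[gi]) for gid, ab in design.members],
                genome_by_id,
                design.read_length,
                design.host_fraction,
            )
            for gi, group in enumerate(design.groups)
        },
    }
    return samples, truth_summary
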