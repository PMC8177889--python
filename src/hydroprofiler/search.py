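"""Read QC, host decontamination, and translated six-frame homology search.

The search assigns each mate of a read pair independently to at most one
reference entry (best-hit policy), mimicking the read-level counting of a
translated aligner run with a reporting e-value cutoff.  Each mate is
translated in all six frames; exact 4-residue seeds shared with the active
reference entries are extended without gaps under BLOSUM62, and the best
local segment is scored.  Scores are converted to bit scores with fixed
ungapped Karlin-Altschul constants, and a hit is reported only when its
e-value is at or below the cutoff (0.001 by default, following standard
translated-search practice for short-read functional profiling).

Because queries are at most ~33 translated residues, extension runs to the
query/subject bounds by default rather than stopping on an X-drop; this makes
the reported raw score exactly the optimum over all ungapped local alignments
that contain a seed, which is both cheap at this scale and easy to verify
against exhaustive enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels, _seq
from .refdb import ReferenceDB
from .simulate import ReadSet, SyntheticGenome

__all__ = [
    "SearchParams",
    "Hit",
    "quality_filter",
    "filter_host_reads",
    "six_frame_translate",
    "search_reads",
    "write_hits",
    "read_hits",
]

FRAMES = (1, 2, 3, -1, -2, -3)

HIT_COLUMNS = (
    "read_id",
    "entry_id",
    "frame",
    "alignment_start",
    "raw_score",
    "bit_score",
    "evalue",
)


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the translated search.

    ``karlin_lambda`` and ``karlin_k`` are the published ungapped BLOSUM62
    constants; the e-value they produce is a calibrated monotone transform of
    the raw score, and the reporting cutoff is the operative contract.
    ``search_space`` (effective residues: reference residues x query
    residues) is recomputed per query unless given explicitly.
    """

    seed_length: int = 4
    min_bit_score: float = 0.0
    evalue_cutoff: float = 0.001
    scoring_matrix: str = "BLOSUM62"
    karlin_lambda: float = 0.318
    karlin_k: float = 0.13
    search_space: float | None = None
    xdrop: int | None = None  # None: extend to bounds (exact seeded optimum)

    def __post_init__(self) -> None:
        if self.seed_length < 3:
            raise ValueError("seed_length must be >= 3")
        if self.seed_length != _kernels.SEED_LEN:
            raise ValueError(f"only seed_length={_kernels.SEED_LEN} is implemented")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.scoring_matrix != "BLOSUM62":
            raise ValueError("only the BLOSUM62 scoring matrix is available")


@dataclass(frozen=True)
class Hit:
    """Best assignment of one mate to one reference entry."""

    read_id: str
    entry_id: str
    frame: int
    alignment_start: int
    raw_score: float
    bit_score: float
    evalue: float


def quality_filter(
    reads: ReadSet, min_mean_quality: float = 20.0, min_length: int = 50
) -> ReadSet:
    """Keep pairs where both mates meet mean-quality and length thresholds.

    Quality is phred+33; a pair is dropped whenever either mate fails, since
    an unreliable mate compromises the fragment.  Input order is preserved.
    """
    kept = []
    for rec in reads.records:
        _, s1, q1, s2, q2 = rec
        ok = True
        for s, q in ((s1, q1), (s2, q2)):
            if len(s) < min_length:
                ok = False
                break
            mean_q = sum(q.encode("ascii")) / len(q) - 33.0
            if mean_q < min_mean_quality:
                ok = False
                break
        if ok:
            kept.append(rec)
    truth = None
    if reads.truth is not None:
        ids = {r[0] for r in kept}
        truth = {k: v for k, v in reads.truth.items() if k in ids}
    return ReadSet(records=kept, truth=truth)


def filter_host_reads(
    reads: ReadSet,
    host_genome: SyntheticGenome | str,
    kmer_length: int = 21,
    min_shared_kmers: int = 10,
) -> ReadSet:
    """Drop pairs where either mate shares >= ``min_shared_kmers`` exact
    k-mers (either strand) with the host genome.

    K-mers are compared in canonical (strand-symmetric) form, so reads from
    either strand of the host are removed.  With 100 bp mates, 21-mers and a
    threshold of 10 shared k-mers, host reads survive only if sequencing
    errors destroy nearly every window, while non-host reads essentially
    never share 10 exact 21-mers with an unrelated genome.
    """
    if not reads.records:
        return ReadSet(records=[], truth={} if reads.truth is not None else None)
    host_seq = host_genome.sequence if isinstance(host_genome, SyntheticGenome) else host_genome
    if kmer_length > min(len(r[1]) for r in reads.records):
        raise ValueError("kmer_length exceeds read length")
    host_set = _kernels.build_host_kmer_set(_seq.encode_dna(host_seq), kmer_length)
    seqs: list[str] = []
    for _, s1, _, s2, _ in reads.records:
        seqs.append(s1)
        seqs.append(s2)
    concat, offsets = _seq.encode_many(seqs)
    shared = _kernels.host_shared_kmers(
        concat, offsets, host_set, kmer_length, min_shared_kmers
    )
    shared = shared.reshape(-1, 2)
    keep = (shared < min_shared_kmers).all(axis=1)
    kept = [rec for rec, k in zip(reads.records, keep) if k]
    truth = None
    if reads.truth is not None:
        ids = {r[0] for r in kept}
        truth = {k: v for k, v in reads.truth.items() if k in ids}
    return ReadSet(records=kept, truth=truth)


def six_frame_translate(dna: str) -> list[str]:
    """Translate all six reading frames of ``dna``.

    Frames are ordered +1, +2, +3 (forward) then -1, -2, -3 (reverse
    complement).  Trailing partial codons are dropped; stop codons render
    '*'; codons containing N render 'X'.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = _seq.encode_dna(dna)
    rev = _seq.revcomp_codes(fwd)
    out = []
    for strand in (fwd, rev):
        for off in range(3):
            out.append(_seq.decode_protein(_seq.translate_codes(strand[off:])))
    return out


def _mate_queries(reads: ReadSet) -> tuple[list[str], list[str]]:
    """Flatten pairs into independent single-end queries (read-level counting)."""
    ids: list[str] = []
    seqs: list[str] = []
    for rid, s1, _, s2, _ in reads.records:
        ids.append(f"{rid}/1")
        seqs.append(s1)
        ids.append(f"{rid}/2")
        seqs.append(s2)
    return ids, seqs


def search_reads(
    reads: ReadSet, db: ReferenceDB, params: SearchParams | None = None
) -> list[Hit]:
    """Assign each mate its best hydrogenase entry under the e-value cutoff.

    Each mate is searched independently and contributes at most one hit
    (highest bit score; ties break to the lowest e-value, then the
    lexicographically smallest entry id).  Excluded reference entries are
    never searched, so a curated database automatically constrains the
    assignment universe.
    """
    params = params or SearchParams()
    active = db.active_entries
    if not active:
        raise ValueError("reference database has no active entries")
    # active_entries is sorted by entry_id, so entry-index order is lexicographic
    proteins = [_seq.encode_protein(e.protein_seq) for e in active]
    ref_concat, entry_starts, seed_start, seed_hits = _kernels.build_seed_index(proteins)
    ref_residues = int(entry_starts[-1])

    ids, seqs = _mate_queries(reads)
    if not seqs:
        return []
    concat, offsets = _seq.encode_many(seqs)
    xdrop = 0 if params.xdrop is None else int(params.xdrop)
    scores, ents, frames, rstarts = _kernels.search_batch(
        concat,
        offsets,
        _seq.CODON_AA,
        _seq.BLOSUM62.astype(np.int64),
        ref_concat,
        entry_starts,
        seed_start,
        seed_hits,
        xdrop,
    )

    ln2 = math.log(2.0)
    ln_k = math.log(params.karlin_k)
    lengths = np.diff(offsets)
    hits: list[Hit] = []
    for i in range(len(seqs)):
        if ents[i] < 0:
            continue
        raw = float(scores[i])
        bit = (params.karlin_lambda * raw - ln_k) / ln2
        if bit < params.min_bit_score:
            continue
        space = (
            params.search_space
            if params.search_space is not None
            else ref_residues * (int(lengths[i]) // 3)
        )
        evalue = space * math.pow(2.0, -bit)
        if evalue <= params.evalue_cutoff:
            hits.append(
                Hit(
                    read_id=ids[i],
                    entry_id=active[int(ents[i])].entry_id,
                    frame=int(frames[i]),
                    alignment_start=int(rstarts[i]),
                    raw_score=raw,
                    bit_score=bit,
                    evalue=evalue,
                )
            )
    return hits


def write_hits(hits: Sequence[Hit], path: str | Path) -> None:
    """Write hits as a 7-column TSV, stably sorted by (read_id, entry_id)."""
    rows = sorted(hits, key=lambda h: (h.read_id, h.entry_id))
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in rows:
            fh.write(
                f"{h.read_id}\t{h.entry_id}\t{h.frame}\t{h.alignment_start}\t"
                f"{h.raw_score:g}\t{h.bit_score:.4f}\t{h.evalue:.6g}\n"
            )


def read_hits(path: str | Path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != HIT_COLUMNS:
            raise ValueError(f"unexpected hit table header: {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            hits.append(
                Hit(
                    read_id=parts[0],
                    entry_id=parts[1],
                    frame=int(parts[2]),
                    alignment_start=int(parts[3]),
                    raw_score=float(parts[4]),
                    bit_score=float(parts[5]),
                    evalue=float(parts[6]),
                )
            )
    return hits
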