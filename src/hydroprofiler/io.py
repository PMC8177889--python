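"""On-disk formats: paired FASTQ, genome FASTA, feature BED, group tables.

Reading goes through Biopython's parsers; writing uses plain text emitters
(the formats are line-oriented and the writers are on hot paths).  Feature
coordinates are BED-style 0-based half-open with a strand column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import GeneFeature, ReadSet, SyntheticGenome

__all__ = [
    "write_fastq_pair",
    "read_fastq_pair",
    "write_genome_fasta",
    "read_genome_fasta",
    "write_features_bed",
    "read_features_bed",
    "write_groups_tsv",
    "read_groups_tsv",
]


def write_fastq_pair(reads: ReadSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` and ``<prefix>_2.fastq``."""
    p1 = Path(f"{prefix}_1.fastq")
    p2 = Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rid, s1, q1, s2, q2 in reads.records:
            f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
    return p1, p2


def read_fastq_pair(path1: str | Path, path2: str | Path) -> ReadSet:
    """Read two mate files into a ReadSet; ids are paired positionally.

    A trailing ``/1`` or ``/2`` mate suffix is stripped from the stored id.
    """
    records = []
    with open(path1) as h1, open(path2) as h2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2), strict=True
        ):
            rid = t1.split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            records.append((rid, s1, q1, s2, q2))
    return ReadSet(records=records, truth=None)


def write_genome_fasta(genome: SyntheticGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_genome_fasta(
    path: str | Path, features: tuple[GeneFeature, ...] = (), is_knockout: bool = False
) -> SyntheticGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one genome record, got {len(records)}")
    rec = records[0]
    return SyntheticGenome(
        genome_id=rec.id,
        sequence=str(rec.seq).upper(),
        features=features,
        is_knockout=is_knockout,
    )


def write_features_bed(genome: SyntheticGenome, path: str | Path) -> None:
    """BED6-style: chrom, start, end, name, score (role), strand."""
    with open(path, "w") as fh:
        for f in genome.features:
            fh.write(
                f"{genome.genome_id}\t{f.start}\t{f.end}\t{f.entry_id}\t{f.role}\t{f.strand}\n"
            )


def read_features_bed(path: str | Path) -> tuple[GeneFeature, ...]:
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, role, strand = line.split("\t")[:6]
        feats.append(
            GeneFeature(entry_id=name, start=int(start), end=int(end), strand=strand, role=role)
        )
    return tuple(feats)


def write_groups_tsv(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in sorted(groups):
            fh.write(f"{sid}\t{groups[sid]}\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))
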