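"""Activity-annotated hydrogenase reference database.

Hydrogenases are grouped by active-site metal content ([NiFe], [FeFe], [Fe])
and by predicted biochemical activity (uptake, evolving, bidirectional,
bifurcating, sensory).  This module models a reference of annotated
hydrogenase proteins in the style of the public HydDB catalogue: a FASTA
file of protein sequences plus a tab-separated metadata table mapping each
entry to its metal class and activity category.  Classification is taken
from the metadata as-is; no sequence-based re-classification is performed.

Curation (see :mod:`hydroprofiler.curate`) marks unreliable entries as
excluded rather than deleting them, so the provenance of the full reference
is preserved while downstream search and profiling only ever see the active
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

__all__ = [
    "MetalClass",
    "ActivityCategory",
    "CATEGORIES",
    "HydrogenaseEntry",
    "ReferenceDB",
    "load_reference",
    "validate_reference",
    "apply_exclusions",
    "write_reference",
    "read_exclusion_list",
    "write_exclusion_list",
]

#: The 20 canonical amino acids; 'X' (unknown residue) is additionally allowed.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

METADATA_COLUMNS = ("entry_id", "metal_class", "activity_category", "source_label")


class MetalClass(str, Enum):
    """Active-site metal content of a hydrogenase."""

    NIFE = "NiFe"
    FEFE = "FeFe"
    FE = "Fe"


class ActivityCategory(str, Enum):
    """Predicted biochemical activity of a hydrogenase."""

    UPTAKE = "uptake"
    EVOLVING = "evolving"
    BIDIRECTIONAL = "bidirectional"
    BIFURCATING = "bifurcating"
    SENSORY = "sensory"


#: Canonical category order used for tables and reports.
CATEGORIES: tuple[ActivityCategory, ...] = tuple(ActivityCategory)


def _normalize_token(token: str) -> str:
    """Strip brackets and case so '[NiFe]' and 'nife' match the same enum."""
    return token.strip().strip("[]").lower()


_METAL_LOOKUP = {_normalize_token(m.value): m for m in MetalClass}
_CATEGORY_LOOKUP = {_normalize_token(c.value): c for c in ActivityCategory}


def parse_metal_class(token: str) -> MetalClass:
    try:
        return _METAL_LOOKUP[_normalize_token(token)]
    except KeyError:
        raise ValueError(f"unknown metal class token: {token!r}") from None


def parse_activity_category(token: str) -> ActivityCategory:
    try:
        return _CATEGORY_LOOKUP[_normalize_token(token)]
    except KeyError:
        raise ValueError(f"unknown activity category token: {token!r}") from None


@dataclass(frozen=True)
class HydrogenaseEntry:
    """One annotated reference protein."""

    entry_id: str
    protein_seq: str
    metal_class: MetalClass
    activity_category: ActivityCategory
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise ValueError(f"entry {self.entry_id!r}: empty protein sequence")
        bad = set(self.protein_seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"entry {self.entry_id!r}: invalid residues {sorted(bad)!r} "
                "(only the 20 canonical amino acids plus 'X' are accepted)"
            )


@dataclass(frozen=True)
class ReferenceDB:
    """A collection of hydrogenase entries with a curation exclusion set.

    Iteration yields *active* (non-excluded) entries in entry-id order.
    """

    entries: tuple[HydrogenaseEntry, ...]
    excluded_ids: frozenset[str] = frozenset()
    version_tag: str = ""

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate entry ids: {sorted(dupes)}")
        unknown = self.excluded_ids - set(ids)
        if unknown:
            raise ValueError(f"excluded_ids not in database: {sorted(unknown)}")

    @property
    def entry_ids(self) -> tuple[str, ...]:
        return tuple(e.entry_id for e in self.entries)

    @property
    def active_entries(self) -> tuple[HydrogenaseEntry, ...]:
        return tuple(
            sorted(
                (e for e in self.entries if e.entry_id not in self.excluded_ids),
                key=lambda e: e.entry_id,
            )
        )

    @property
    def active_ids(self) -> tuple[str, ...]:
        return tuple(e.entry_id for e in self.active_entries)

    def __iter__(self) -> Iterator[HydrogenaseEntry]:
        return iter(self.active_entries)

    def __len__(self) -> int:
        return len(self.entries) - len(self.excluded_ids)

    def get(self, entry_id: str) -> HydrogenaseEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def category_of(self) -> dict[str, ActivityCategory]:
        """Map every entry id (active or excluded) to its activity category."""
        return {e.entry_id: e.activity_category for e in self.entries}


def load_reference(
    fasta_source: str | Path | TextIO,
    metadata_source: str | Path | TextIO,
    version_tag: str = "",
) -> ReferenceDB:
    """Load a reference from a protein FASTA and its TSV metadata table.

    Every FASTA record id must appear exactly once in the metadata and vice
    versa; mismatches, unknown category/metal tokens, duplicate ids, and
    malformed sequences all raise ``ValueError`` naming the offender.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record id: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    meta: dict[str, tuple[MetalClass, ActivityCategory, str]] = {}
    close = False
    if isinstance(metadata_source, (str, Path)):
        handle: TextIO = open(metadata_source)
        close = True
    else:
        handle = metadata_source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != METADATA_COLUMNS[:3]:
            raise ValueError(
                f"metadata header must start with {METADATA_COLUMNS[:3]}, got {header!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"metadata line {lineno}: expected >=3 columns")
            entry_id, metal_tok, cat_tok = parts[0], parts[1], parts[2]
            source = parts[3] if len(parts) > 3 else ""
            if entry_id in meta:
                raise ValueError(f"duplicate metadata entry id: {entry_id!r}")
            meta[entry_id] = (
                parse_metal_class(metal_tok),
                parse_activity_category(cat_tok),
                source,
            )
    finally:
        if close:
            handle.close()

    missing_meta = sorted(set(seqs) - set(meta))
    missing_fasta = sorted(set(meta) - set(seqs))
    if missing_meta or missing_fasta:
        raise ValueError(
            "FASTA/metadata id mismatch: "
            f"missing from metadata {missing_meta}, missing from FASTA {missing_fasta}"
        )

    entries = tuple(
        HydrogenaseEntry(
            entry_id=eid,
            protein_seq=seqs[eid],
            metal_class=meta[eid][0],
            activity_category=meta[eid][1],
            source_label=meta[eid][2],
        )
        for eid in sorted(seqs)
    )
    return ReferenceDB(entries=entries, version_tag=version_tag)


def validate_reference(db: ReferenceDB) -> list[str]:
    """Report invariant violations without raising.

    Because :class:`HydrogenaseEntry` and :class:`ReferenceDB` validate on
    construction, a db built through this module is always clean; this check
    exists for databases assembled by hand or deserialized from elsewhere.
    """
    issues: list[str] = []
    seen: set[str] = set()
    for e in db.entries:
        if e.entry_id in seen:
            issues.append(f"{e.entry_id}: duplicate entry_id")
        seen.add(e.entry_id)
        # object.__setattr__ bypasses cannot be ruled out for frozen dataclasses
        if not e.protein_seq:
            issues.append(f"{e.entry_id}: empty protein sequence")
        else:
            bad = set(e.protein_seq) - _VALID_RESIDUES
            if bad:
                issues.append(f"{e.entry_id}: invalid residues {sorted(bad)}")
        if not isinstance(e.metal_class, MetalClass):
            issues.append(f"{e.entry_id}: metal_class not in enum")
        if not isinstance(e.activity_category, ActivityCategory):
            issues.append(f"{e.entry_id}: activity_category not in enum")
    for eid in sorted(db.excluded_ids - set(seen)):
        issues.append(f"{eid}: excluded id not present in database")
    return issues


def apply_exclusions(db: ReferenceDB, ids: Iterable[str]) -> ReferenceDB:
    """Return a db with ``ids`` added to the exclusion set (idempotent)."""
    ids = frozenset(ids)
    unknown = ids - set(db.entry_ids)
    if unknown:
        raise ValueError(f"cannot exclude unknown entry ids: {sorted(unknown)}")
    return replace(db, excluded_ids=db.excluded_ids | ids)


def write_reference(
    db: ReferenceDB, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write all entries (active and excluded) as FASTA + TSV metadata."""
    with open(fasta_path, "w") as fa:
        for e in sorted(db.entries, key=lambda e: e.entry_id):
            fa.write(f">{e.entry_id}\n{e.protein_seq}\n")
    with open(metadata_path, "w") as tsv:
        tsv.write("\t".join(METADATA_COLUMNS) + "\n")
        for e in sorted(db.entries, key=lambda e: e.entry_id):
            tsv.write(
                f"{e.entry_id}\t{e.metal_class.value}\t"
                f"{e.activity_category.value}\t{e.source_label}\n"
            )


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read one entry id per line; blank lines and '#' comments are ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def write_exclusion_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))
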