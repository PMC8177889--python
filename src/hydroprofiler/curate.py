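"""Decoy-based reference curation (in-silico knockout validation).

A reference entry is reliable only if reads recruit to it from hydrogenase-
containing sequence, not from hydrogenase-free sequence.  The validation
simulates reads from wild-type genomes and from knockout genomes with every
hydrogenase CDS excised, maps both read sets against the reference, and
compares per-entry *relative* recruitment (per-dataset fraction of all
hydrogenase-mapped reads).  Entries whose relative recruitment from the
hydrogenase-free dataset is twofold or greater than from the wild-type
dataset are excluded from the classification.

Relative abundance is defined over hydrogenase-mapped reads within each
dataset, which makes the rule invariant to sequencing depth.  The twofold
boundary is inclusive.  Zero conventions: an entry recruiting reads only
from hydrogenase-free sequence is exactly the failure mode the rule targets
and is excluded; an entry recruiting nothing in either dataset is merely
untested and retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refdb import ReferenceDB, apply_exclusions
from .search import Hit

__all__ = ["CurationReport", "count_hits", "curate_database"]

REPORT_COLUMNS = (
    "entry_id",
    "wt_count",
    "ko_count",
    "wt_relative",
    "ko_relative",
    "enrichment_ratio",
    "excluded",
)


@dataclass(frozen=True)
class CurationReport:
    """Per-entry recruitment comparison between wild-type and knockout datasets."""

    table: pd.DataFrame  # columns REPORT_COLUMNS, one row per entry
    fold_threshold: float

    @property
    def excluded_ids(self) -> frozenset[str]:
        t = self.table
        return frozenset(t.loc[t["excluded"], "entry_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, fold_threshold: float = 2.0) -> "CurationReport":
        t = pd.read_csv(path, sep="\t")
        if tuple(t.columns) != REPORT_COLUMNS:
            raise ValueError(f"unexpected curation report columns: {tuple(t.columns)}")
        return cls(table=t, fold_threshold=fold_threshold)


def count_hits(hits: Sequence[Hit]) -> dict[str, int]:
    """Summarize best hits into per-entry read counts.

    The upstream best-hit contract guarantees at most one hit per read;
    a duplicate read id indicates a violated contract and raises.
    """
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for h in hits:
        if h.read_id in seen:
            raise ValueError(f"duplicate read id in hit list: {h.read_id!r}")
        seen.add(h.read_id)
        counts[h.entry_id] = counts.get(h.entry_id, 0) + 1
    return counts


def curate_database(
    wt_counts: Mapping[str, int],
    ko_counts: Mapping[str, int],
    db: ReferenceDB,
    fold_threshold: float = 2.0,
) -> tuple[CurationReport, ReferenceDB]:
    """Apply the twofold decoy-enrichment rule and return the curated database.

    ``wt_counts``/``ko_counts`` are per-entry read counts from the
    hydrogenase-containing and hydrogenase-free datasets.  An entry is
    excluded iff its knockout-dataset relative recruitment is
    ``fold_threshold`` times or more its wild-type relative recruitment
    (with the zero conventions described in the module docstring).
    """
    known = set(db.entry_ids)
    for name, counts in (("wt", wt_counts), ("ko", ko_counts)):
        unknown = set(counts) - known
        if unknown:
            raise ValueError(f"{name} counts reference unknown entries: {sorted(unknown)}")
    wt_total = sum(wt_counts.values())
    ko_total = sum(ko_counts.values())
    if wt_total <= 0 or ko_total <= 0:
        raise ValueError(
            "both datasets must have at least one hydrogenase-mapped read "
            f"(wt={wt_total}, ko={ko_total})"
        )

    rows = []
    for eid in sorted(db.entry_ids):
        wt_c = int(wt_counts.get(eid, 0))
        ko_c = int(ko_counts.get(eid, 0))
        wt_rel = wt_c / wt_total
        ko_rel = ko_c / ko_total
        if wt_rel > 0:
            ratio = ko_rel / wt_rel
        elif ko_rel > 0:
            ratio = np.inf
        else:
            ratio = 0.0
        rows.append(
            {
                "entry_id": eid,
                "wt_count": wt_c,
                "ko_count": ko_c,
                "wt_relative": wt_rel,
                "ko_relative": ko_rel,
                "enrichment_ratio": ratio,
                "excluded": bool(ratio >= fold_threshold),
            }
        )
    table = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    report = CurationReport(table=table, fold_threshold=fold_threshold)
    curated = apply_exclusions(db, report.excluded_ids)
    return report, curated
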