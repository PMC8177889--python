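"""Category abundance profiling and group comparison.

Per-sample best-hit counts are assembled into a sample x entry table,
normalized to each sample's total hydrogenase-mapped reads, aggregated into
the five activity categories, and compared between two condition groups.

The unit of comparison is the reference sequence: for each activity
category, each reference sequence contributes one point per group -- its
per-entry average normalized abundance across that group's samples, with
zero averages replaced by a small pseudo-value (presets: 0.05 for the
murine-style analysis, 0.0005 for the human-style analysis).  The two
groups' vectors of per-entry averages are compared with a two-sided
Mann-Whitney U test (exact by enumeration for small samples, normal
approximation with tie and continuity corrections otherwise), Bonferroni-
corrected across the categories actually testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .refdb import CATEGORIES, ReferenceDB

__all__ = [
    "HitTable",
    "NormalizedTable",
    "CategoryProfile",
    "GroupComparisonResult",
    "MWUResult",
    "PSEUDO_VALUE_MURINE",
    "PSEUDO_VALUE_HUMAN",
    "build_hit_table",
    "normalize_hit_table",
    "aggregate_categories",
    "per_entry_group_averages",
    "mann_whitney_u",
    "bonferroni_adjust",
    "compare_groups",
    "comparison_frame",
]

#: Pseudo-value substituted for zero per-entry group averages.
PSEUDO_VALUE_MURINE = 0.05
PSEUDO_VALUE_HUMAN = 0.0005

#: Largest pooled sample size for which the exact permutation p is computed.
EXACT_ENUMERATION_LIMIT = 16


@dataclass(frozen=True)
class HitTable:
    """Raw sample x entry read counts with per-sample group labels."""

    counts: pd.DataFrame  # index: sample ids (sorted); columns: entry ids (sorted)
    groups: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.groups.index):
            raise ValueError("counts rows and group labels must cover the same samples")


@dataclass(frozen=True)
class NormalizedTable:
    """Per-entry fractions of each sample's hydrogenase-mapped reads."""

    fractions: pd.DataFrame
    groups: pd.Series
    totals: pd.Series  # per-sample hydrogenase-mapped read counts
    zero_samples: tuple[str, ...]  # samples with no mapped reads at all


@dataclass(frozen=True)
class CategoryProfile:
    """Per-sample normalized abundance of each activity category."""

    abundances: pd.DataFrame  # samples x 5 categories
    totals: pd.Series


@dataclass(frozen=True)
class MWUResult:
    U: float
    p_value: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class GroupComparisonResult:
    category: str
    group_means: dict[str, np.ndarray]  # group -> per-entry averages (pseudo-substituted)
    n_entries: int
    U: float
    p_raw: float
    p_bonferroni: float
    pseudo_value: float
    testable: bool


def build_hit_table(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    groups: Mapping[str, str],
    entry_ids: Sequence[str] | None = None,
) -> HitTable:
    """Assemble per-sample entry counts into a dense table.

    ``entry_ids`` fixes the column universe (pass the curated database's
    active ids so never-hit entries appear as structural zero columns);
    otherwise the union of observed entries is used.  Rows and columns are
    sorted for stable output.
    """
    missing = sorted(set(per_sample_counts) - set(groups))
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    if entry_ids is None:
        universe: set[str] = set()
        for counts in per_sample_counts.values():
            universe |= set(counts)
        entry_ids = sorted(universe)
    else:
        entry_ids = sorted(entry_ids)
        for sid, counts in per_sample_counts.items():
            unknown = set(counts) - set(entry_ids)
            if unknown:
                raise ValueError(f"sample {sid!r} counts unknown entries: {sorted(unknown)}")
    sample_ids = sorted(per_sample_counts)
    data = np.zeros((len(sample_ids), len(entry_ids)), dtype=np.int64)
    col = {e: j for j, e in enumerate(entry_ids)}
    for i, sid in enumerate(sample_ids):
        for eid, c in per_sample_counts[sid].items():
            data[i, col[eid]] = c
    counts = pd.DataFrame(data, index=sample_ids, columns=list(entry_ids))
    grp = pd.Series({s: groups[s] for s in sample_ids}, name="group")
    return HitTable(counts=counts, groups=grp)


def normalize_hit_table(table: HitTable) -> NormalizedTable:
    """Divide each sample's counts by its total hydrogenase-mapped reads.

    All-zero samples stay all-zero and are flagged in ``zero_samples``.
    """
    totals = table.counts.sum(axis=1)
    denom = totals.replace(0, 1)
    fractions = table.counts.div(denom, axis=0).astype(float)
    zero = tuple(totals.index[totals == 0])
    return NormalizedTable(
        fractions=fractions, groups=table.groups, totals=totals, zero_samples=zero
    )


def aggregate_categories(norm: NormalizedTable, db: ReferenceDB) -> CategoryProfile:
    """Sum per-entry fractions into the five activity categories."""
    cat_of = db.category_of()
    missing = [e for e in norm.fractions.columns if e not in cat_of]
    if missing:
        raise ValueError(f"entries without an activity category: {missing}")
    data = pd.DataFrame(
        0.0, index=norm.fractions.index, columns=[c.value for c in CATEGORIES]
    )
    for eid in norm.fractions.columns:
        data[cat_of[eid].value] += norm.fractions[eid]
    return CategoryProfile(abundances=data, totals=norm.totals)


def per_entry_group_averages(
    norm: NormalizedTable,
    pseudo_value: float,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> dict[str, pd.Series]:
    """Per-entry mean normalized abundance within each group.

    Any mean exactly equal to zero is replaced by ``pseudo_value``.  The
    substitution happens after averaging (not per sample), so an entry seen
    in any sample of a group keeps its true small average.
    """
    grp = pd.Series(groups) if groups is not None else norm.groups
    labels = list(dict.fromkeys(grp[s] for s in norm.fractions.index))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    out: dict[str, pd.Series] = {}
    for g in labels:
        samples = [s for s in norm.fractions.index if grp[s] == g]
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        means = norm.fractions.loc[samples].mean(axis=0)
        means[means == 0.0] = pseudo_value
        out[g] = means
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``x`` (average ranks for ties).  For
    pooled sizes up to 16 the p-value is exact, computed by enumerating all
    C(n+m, n) group labelings of the pooled values; the permutation
    distribution of U is symmetric about nm/2, so the two-sided p is the
    probability of a deviation from nm/2 at least as large as observed.
    Larger samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    U = float(ranks[:n].sum() - n * (n + 1) / 2)
    mu = n * m / 2.0

    if n + m <= EXACT_ENUMERATION_LIMIT:
        dev = abs(U - mu)
        offset = n * (n + 1) / 2
        count = 0
        total = 0
        for c in combinations(range(n + m), n):
            u = ranks[list(c)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                count += 1
        return MWUResult(U=U, p_value=count / total, method="exact")

    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return MWUResult(U=U, p_value=1.0, method="normal")
    cc = 0.5 if U != mu else 0.0
    z = (abs(U - mu) - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MWUResult(U=U, p_value=p, method="normal")


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Bonferroni correction: p -> min(1, m * p)."""
    ps = list(p_values)
    for p in ps:
        if not (0 < p <= 1):
            raise ValueError(f"p-value outside (0, 1]: {p}")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def compare_groups(
    norm: NormalizedTable,
    db: ReferenceDB,
    pseudo_value: float = PSEUDO_VALUE_MURINE,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> list[GroupComparisonResult]:
    """Per-category two-group comparison of per-entry average abundances.

    For each activity category, the two groups' vectors of per-entry
    averages (one value per reference sequence, zeros pseudo-substituted)
    are compared with :func:`mann_whitney_u`; p-values are Bonferroni-
    adjusted across the testable categories.  A category with no entries in
    the table is reported as untestable and does not count toward the
    correction factor.
    """
    cat_of = db.category_of()
    missing = [e for e in norm.fractions.columns if e not in cat_of]
    if missing:
        raise ValueError(f"entries without an activity category: {missing}")
    averages = per_entry_group_averages(norm, pseudo_value, groups)
    (g1, means1), (g2, means2) = averages.items()

    partial: list[GroupComparisonResult] = []
    raw_ps: list[float] = []
    for cat in CATEGORIES:
        entries = [e for e in norm.fractions.columns if cat_of[e] == cat]
        if not entries:
            partial.append(
                GroupComparisonResult(
                    category=cat.value,
                    group_means={g1: np.array([]), g2: np.array([])},
                    n_entries=0,
                    U=float("nan"),
                    p_raw=float("nan"),
                    p_bonferroni=float("nan"),
                    pseudo_value=pseudo_value,
                    testable=False,
                )
            )
            continue
        xv = means1[entries].to_numpy()
        yv = means2[entries].to_numpy()
        res = mann_whitney_u(xv, yv)
        partial.append(
            GroupComparisonResult(
                category=cat.value,
                group_means={g1: xv, g2: yv},
                n_entries=len(entries),
                U=res.U,
                p_raw=res.p_value,
                p_bonferroni=float("nan"),  # filled below
                pseudo_value=pseudo_value,
                testable=True,
            )
        )
        raw_ps.append(res.p_value)

    adjusted = bonferroni_adjust(raw_ps) if raw_ps else []
    out: list[GroupComparisonResult] = []
    ai = 0
    for r in partial:
        if r.testable:
            out.append(
                GroupComparisonResult(
                    category=r.category,
                    group_means=r.group_means,
                    n_entries=r.n_entries,
                    U=r.U,
                    p_raw=r.p_raw,
                    p_bonferroni=adjusted[ai],
                    pseudo_value=r.pseudo_value,
                    testable=True,
                )
            )
            ai += 1
        else:
            out.append(r)
    return out


def comparison_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results for TSV/JSON export."""
    rows = []
    for r in results:
        rows.append(
            {
                "category": r.category,
                "n_entries": r.n_entries,
                "U": r.U,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "pseudo_value": r.pseudo_value,
                "testable": r.testable,
            }
        )
    return pd.DataFrame(rows)
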