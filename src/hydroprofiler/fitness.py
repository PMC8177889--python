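"""Colonization-fitness analytics for competition experiments.

Implements the statistics used to evaluate bacterial fitness in animal
colonization experiments:

* CFU/g estimation from serial-dilution plate counts;
* limit-of-detection substitution (sub-LOD samples set to 10 CFU/g, the
  plating detection floor, so log-scale statistics stay defined);
* the competitive index (CI): output ratio of two co-inoculated strains
  corrected by their inoculum ratio, oriented so CI > 1 reads as a
  wild-type advantage;
* geometric-mean summaries with t-based 95% confidence intervals on the
  log scale;
* paired Student's t-test of log-transformed abundances;
* relative expression by the comparative Ct method (2^-ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CfuMeasurement",
    "CompetitiveIndexRecord",
    "QpcrRecord",
    "PairedTTestResult",
    "DEFAULT_LOD_CFU_PER_G",
    "cfu_per_gram",
    "apply_lod",
    "competitive_index",
    "competitive_index_record",
    "geometric_mean_ci95",
    "paired_log_t_test",
    "relative_expression_ddct",
    "simulate_competition_cohort",
    "read_cfu_measurements",
]

#: CFU/g assigned to samples below the plating limit of detection.
DEFAULT_LOD_CFU_PER_G = 10.0

COMPARTMENTS = ("colon", "cecum", "other")

CFU_COLUMNS = (
    "animal_id",
    "compartment",
    "strain_label",
    "colony_count",
    "dilution_exponent",
    "plated_volume_ml",
    "homogenate_volume_ml",
    "sample_mass_g",
)


@dataclass(frozen=True)
class CfuMeasurement:
    """One plate count from a 10-fold serial dilution of intestinal content."""

    animal_id: str
    compartment: str
    strain_label: str
    colony_count: int
    dilution_exponent: int  # plate holds 10^-exponent of the homogenate
    plated_volume_ml: float
    homogenate_volume_ml: float
    sample_mass_g: float

    def __post_init__(self) -> None:
        if self.colony_count < 0:
            raise ValueError("colony_count must be >= 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.sample_mass_g <= 0:
            raise ValueError("sample_mass_g must be > 0")

    @property
    def below_lod(self) -> bool:
        return self.colony_count == 0


@dataclass(frozen=True)
class CompetitiveIndexRecord:
    """Inoculum-corrected fitness ratio for one animal (and compartment)."""

    animal_id: str
    wt_out: float
    mut_out: float
    wt_in: float
    mut_in: float
    ci: float
    log10_ci: float
    compartment: str = "other"


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    target_ct: float
    reference_ct: float
    group: str  # "control" or "treated"

    def __post_init__(self) -> None:
        for ct in (self.target_ct, self.reference_ct):
            if not (0 < ct < 45):
                raise ValueError(f"cycle number out of range (0, 45): {ct}")
        if self.group not in ("control", "treated"):
            raise ValueError("group must be 'control' or 'treated'")


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p_value: float
    df: int
    degenerate: bool  # zero variance of non-zero paired differences


def cfu_per_gram(m: CfuMeasurement) -> float:
    """CFU per gram of sample from one serial-dilution plate count.

    colonies x 10^dilution / plated volume gives CFU/ml of homogenate;
    scaling by homogenate volume and sample mass yields CFU/g.
    """
    if m.plated_volume_ml <= 0:
        raise ValueError("plated_volume_ml must be > 0")
    return (
        m.colony_count
        * 10.0**m.dilution_exponent
        / m.plated_volume_ml
        * m.homogenate_volume_ml
        / m.sample_mass_g
    )


def apply_lod(
    values: Sequence[float], lod_value: float = DEFAULT_LOD_CFU_PER_G
) -> np.ndarray:
    """Replace every value below the limit of detection (including 0) by it."""
    if lod_value <= 0:
        raise ValueError("lod_value must be > 0")
    v = np.asarray(values, dtype=float).copy()
    v[v < lod_value] = lod_value
    return v


def competitive_index(
    wt_out: float, mut_out: float, wt_in: float, mut_in: float
) -> tuple[float, float]:
    """Competitive index: (wt/mut) output ratio over (wt/mut) inoculum ratio.

    CI > 1 means a wild-type advantage.  Apply :func:`apply_lod` first; zero
    counts are rejected here because the index is undefined without the LOD
    convention.
    """
    for name, v in (("wt_out", wt_out), ("mut_out", mut_out), ("wt_in", wt_in), ("mut_in", mut_in)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0 after LOD substitution, got {v}")
    ci = (wt_out / mut_out) / (wt_in / mut_in)
    return ci, math.log10(ci)


def competitive_index_record(
    animal_id: str,
    wt_out: float,
    mut_out: float,
    wt_in: float,
    mut_in: float,
    compartment: str = "other",
    lod_value: float = DEFAULT_LOD_CFU_PER_G,
) -> CompetitiveIndexRecord:
    """Build a per-animal CI record, applying LOD substitution to the outputs."""
    wt_o, mut_o = apply_lod([wt_out, mut_out], lod_value)
    ci, log_ci = competitive_index(wt_o, mut_o, wt_in, mut_in)
    return CompetitiveIndexRecord(
        animal_id=animal_id,
        wt_out=float(wt_o),
        mut_out=float(mut_o),
        wt_in=wt_in,
        mut_in=mut_in,
        ci=ci,
        log10_ci=log_ci,
        compartment=compartment,
    )


def geometric_mean_ci95(values: Sequence[float]) -> tuple[float, float, float]:
    """Geometric mean with a t-based 95% confidence interval on the log scale."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    if len(v) < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    logs = np.log(v)
    mean = logs.mean()
    sd = logs.std(ddof=1)
    half = stats.t.ppf(0.975, len(v) - 1) * sd / math.sqrt(len(v))
    return math.exp(mean), math.exp(mean - half), math.exp(mean + half)


def paired_log_t_test(
    a: Sequence[float], b: Sequence[float]
) -> PairedTTestResult:
    """Paired Student's t-test of log-transformed values.

    The test runs on differences ln(a_i) - ln(b_i) with n - 1 degrees of
    freedom, two-sided.  When all paired differences are identical the t
    statistic is undefined: identical samples report (t=0, p=1), while a
    constant non-zero ratio is flagged ``degenerate`` with p reported as 0
    rather than inventing a finite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    d = np.log(a) - np.log(b)
    n = len(d)
    sd = d.std(ddof=1)
    # a constant ratio leaves only float rounding in d; treat that as zero spread
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0))):
        if np.allclose(d, 0):
            return PairedTTestResult(t=0.0, p_value=1.0, df=n - 1, degenerate=False)
        t = math.inf if d[0] > 0 else -math.inf
        return PairedTTestResult(t=t, p_value=0.0, df=n - 1, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTTestResult(t=float(t), p_value=float(p), df=n - 1, degenerate=False)


def relative_expression_ddct(records: Sequence[QpcrRecord]) -> pd.Series:
    """Per-sample fold change by the comparative Ct method.

    dCt = target Ct - reference Ct per sample; ddCt subtracts the control
    group's mean dCt; fold change = 2^-ddCt (controls average to fold 1).
    """
    controls = [r for r in records if r.group == "control"]
    if not controls:
        raise ValueError("at least one control sample is required")
    control_mean = float(np.mean([r.target_ct - r.reference_ct for r in controls]))
    folds = {
        r.sample_id: 2.0 ** -((r.target_ct - r.reference_ct) - control_mean)
        for r in records
    }
    return pd.Series(folds, name="fold_change")


def simulate_competition_cohort(
    n_animals: int,
    log10_ci: float,
    sigma_log10: float,
    seed: int,
    inoculum_cfu: float = 5e8,
    output_scale_cfu_per_g: float = 1e7,
) -> list[CompetitiveIndexRecord]:
    """Synthetic competition cohort with a log-normal fitness effect.

    Each animal's CI is drawn log-normally around ``log10_ci`` with
    between-animal spread ``sigma_log10``; output abundances are constructed
    to realize that CI under an equal inoculum.
    """
    rng = np.random.default_rng(seed)
    log_cis = rng.normal(log10_ci, sigma_log10, size=n_animals)
    total = rng.lognormal(math.log(output_scale_cfu_per_g), 0.5, size=n_animals)
    records = []
    for i in range(n_animals):
        ratio = 10.0 ** log_cis[i]
        mut_out = total[i] / (1 + ratio)
        wt_out = total[i] - mut_out
        records.append(
            competitive_index_record(
                animal_id=f"animal_{i + 1:02d}",
                wt_out=wt_out,
                mut_out=mut_out,
                wt_in=inoculum_cfu,
                mut_in=inoculum_cfu,
            )
        )
    return records


def read_cfu_measurements(path: str | Path) -> list[CfuMeasurement]:
    """Read a long-format TSV of plate counts (columns as in CFU_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CFU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    return [
        CfuMeasurement(
            animal_id=str(r.animal_id),
            compartment=str(r.compartment),
            strain_label=str(r.strain_label),
            colony_count=int(r.colony_count),
            dilution_exponent=int(r.dilution_exponent),
            plated_volume_ml=float(r.plated_volume_ml),
            homogenate_volume_ml=float(r.homogenate_volume_ml),
            sample_mass_g=float(r.sample_mass_g),
        )
        for r in df.itertuples()
    ]
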