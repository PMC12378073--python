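"""Domain types, CSV ingestion, censoring rules and descriptive statistics.

Breast-milk contaminant surveys report left-censored concentrations: any
sample below the analytical limit of detection (LOD) is a *non-detect*.
This module holds the record types for concentration measurements and the
infant cohort, the substitution rules used to turn a censored series into
numbers, exact-binomial detection summaries, and the nonparametric group
comparisons used for demographic covariates.

Units are fixed package-wide: concentrations in ng/mL, milk intake rates
(FIR) in mL per kg body weight per day, doses in ng per kg body weight per
day. Readers reject other unit declarations rather than converting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


class FormatError(ValidationError):
    """Raised when an input file does not have the expected layout."""


class CensoringRule(str, Enum):
    """How non-detects enter summary statistics.

    ``exclude`` drops them; ``zero``, ``half_lod`` and ``lod`` substitute
    0, LOD/2 and LOD respectively. For any dataset with at least one
    non-detect the rule means obey
    mean(exclude) >= mean(lod) >= mean(half_lod) >= mean(zero).
    """

    EXCLUDE = "exclude"
    ZERO = "zero"
    HALF_LOD = "half_lod"
    LOD = "lod"


#: Age strata used throughout: label -> inclusive day range.
AGE_GROUPS: tuple[str, ...] = ("0-2m", "2-4m", "4-6m")
_AGE_CUTOFFS = ((0, 60), (61, 120), (121, 180))


def age_group_of(age_days: int) -> str:
    """Map an age in days to its stratum (0-2 m: <=60 d; 2-4 m: 61-120 d;
    4-6 m: 121-180 d)."""
    if not 0 <= age_days <= 180:
        raise ValidationError(f"age_days {age_days} outside supported 0-180 range")
    for label, (lo, hi) in zip(AGE_GROUPS, _AGE_CUTOFFS):
        if lo <= age_days <= hi:
            return label
    raise ValidationError(f"age_days {age_days} not classifiable")  # pragma: no cover


@dataclass(frozen=True)
class AnalyteSpec:
    """Reference constants for one analyte.

    Parameters
    ----------
    name : analyte identifier, e.g. ``"MEL"`` or ``"CYA"``.
    tdi : tolerable daily intake, ng per kg body weight per day.
    lod, loq : limits of detection / quantification, ng/mL.
    """

    name: str
    tdi: float
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if self.tdi <= 0:
            raise ValidationError(f"{self.name}: tdi must be > 0, got {self.tdi}")
        if not 0 < self.lod < self.loq:
            raise ValidationError(
                f"{self.name}: require 0 < lod < loq, got lod={self.lod} loq={self.loq}"
            )


#: The study's analytes with the most conservative TDIs (ng/kg bw/day) and
#: the method's detection/quantification limits (ng/mL).
MEL = AnalyteSpec("MEL", tdi=3150.0, lod=90.0, loq=270.0)
CYA = AnalyteSpec("CYA", tdi=2500.0, lod=100.0, loq=310.0)
DEFAULT_SPECS: dict[str, AnalyteSpec] = {"MEL": MEL, "CYA": CYA}


@dataclass(frozen=True)
class ConcentrationRecord:
    """One sample's measured value for one analyte.

    ``censored`` is true iff the value is absent (non-detect reported as an
    empty cell) or a reported value lies below the analyte's LOD.
    """

    sample_id: str
    analyte: str
    value: float | None
    censored: bool

    def __post_init__(self) -> None:
        if self.value is None and not self.censored:
            raise ValidationError(f"{self.sample_id}: absent value must be censored")
        if self.value is not None and self.value < 0:
            raise ValidationError(
                f"{self.sample_id}: negative concentration {self.value}"
            )


@dataclass(frozen=True)
class InfantRecord:
    """One infant: age, body weight, milk intake rate and age stratum.

    ``sample_id`` optionally links the infant to their mother's milk sample.
    """

    infant_id: str
    age_days: int
    body_weight: float  # kg
    fir: float  # mL per kg bw per day
    age_group: str = ""
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError(f"{self.infant_id}: body_weight must be > 0")
        if self.fir <= 0:
            raise ValidationError(f"{self.infant_id}: fir must be > 0")
        expected = age_group_of(self.age_days)
        if self.age_group == "":
            object.__setattr__(self, "age_group", expected)
        elif self.age_group != expected:
            raise ValidationError(
                f"{self.infant_id}: age_group {self.age_group!r} inconsistent with "
                f"age_days {self.age_days} (expected {expected!r})"
            )


@dataclass(frozen=True)
class SummaryStats:
    """Detection frequency and moments of one analyte's series (Table-1 style)."""

    analyte: str
    n_total: int
    n_below_lod: int
    detection_pct: float
    detection_ci: tuple[float, float]  # percent, exact binomial 95%
    mean: float
    sd: float
    min: float
    max: float
    rule: CensoringRule


@dataclass(frozen=True)
class GroupComparison:
    """Per-group descriptives plus a nonparametric (or chi-square) test."""

    grouping_variable: str
    group_means: dict[str, tuple[float, float]]  # group -> (mean, sd)
    statistic: float
    p_value: float
    test_name: str
    counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# CSV ingestion


def load_concentrations(
    path: str | Path, specs: Mapping[str, AnalyteSpec]
) -> list[ConcentrationRecord]:
    """Read a concentration CSV (columns sample_id, analyte, value).

    An empty value cell is a non-detect; a reported value below the
    analyte's LOD is also flagged censored. Unknown analytes and negative
    values are rejected.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte": str})
    required = {"sample_id", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[ConcentrationRecord] = []
    for row in df.itertuples(index=False):
        analyte = row.analyte
        if analyte not in specs:
            raise ValidationError(f"{path}: unknown analyte {analyte!r}")
        if pd.isna(row.value):
            records.append(ConcentrationRecord(row.sample_id, analyte, None, True))
            continue
        value = float(row.value)
        if value < 0:
            raise ValidationError(
                f"{path}: negative concentration {value} for sample {row.sample_id}"
            )
        records.append(
            ConcentrationRecord(
                row.sample_id, analyte, value, censored=value < specs[analyte].lod
            )
        )
    return records


def load_cohort(path: str | Path, default_fir: float = 150.0) -> list[InfantRecord]:
    """Read a cohort CSV (infant_id, age_days, body_weight_kg,
    fir_ml_per_kg_day[, sample_id]).

    A missing FIR column or cell falls back to ``default_fir`` (mL/kg/day),
    the conventional intake of an exclusively breastfed infant.
    """
    df = pd.read_csv(path, dtype={"infant_id": str})
    required = {"infant_id", "age_days", "body_weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_fir = "fir_ml_per_kg_day" in df.columns
    has_sid = "sample_id" in df.columns
    infants = []
    for row in df.itertuples(index=False):
        fir = getattr(row, "fir_ml_per_kg_day", None) if has_fir else None
        if fir is None or pd.isna(fir):
            fir = default_fir
        sid = getattr(row, "sample_id", None) if has_sid else None
        if sid is not None and pd.isna(sid):
            sid = None
        infants.append(
            InfantRecord(
                infant_id=row.infant_id,
                age_days=int(row.age_days),
                body_weight=float(row.body_weight_kg),
                fir=float(fir),
                sample_id=None if sid is None else str(sid),
            )
        )
    return infants


def write_concentrations(
    records: Iterable[ConcentrationRecord], path: str | Path
) -> None:
    """Write records in the same CSV dialect ``load_concentrations`` reads
    (non-detects as empty cells)."""
    lines = ["sample_id,analyte,value"]
    for r in records:
        cell = "" if r.value is None else repr(float(r.value))
        lines.append(f"{r.sample_id},{r.analyte},{cell}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort(infants: Iterable[InfantRecord], path: str | Path) -> None:
    lines = ["infant_id,age_days,body_weight_kg,fir_ml_per_kg_day,sample_id"]
    for inf in infants:
        sid = inf.sample_id or ""
        lines.append(
            f"{inf.infant_id},{inf.age_days},{repr(float(inf.body_weight))},"
            f"{repr(float(inf.fir))},{sid}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Censoring rules and summaries


def apply_censoring_rule(
    records: Sequence[ConcentrationRecord],
    rule: CensoringRule | str,
    spec: AnalyteSpec,
) -> np.ndarray:
    """Turn a censored series into numbers under the given rule.

    ``exclude`` returns only uncensored values (order preserved); the
    substitution rules replace each non-detect by 0, LOD/2 or LOD.
    """
    rule = CensoringRule(rule)
    analytes = {r.analyte for r in records}
    if len(analytes) > 1:
        raise ValidationError(f"mixed analytes in one series: {sorted(analytes)}")
    if analytes and next(iter(analytes)) != spec.name:
        raise ValidationError(
            f"records are {analytes.pop()!r} but spec is {spec.name!r}"
        )
    sub = {
        CensoringRule.ZERO: 0.0,
        CensoringRule.HALF_LOD: spec.lod / 2.0,
        CensoringRule.LOD: spec.lod,
    }
    out: list[float] = []
    for r in records:
        if not r.censored:
            out.append(float(r.value))  # type: ignore[arg-type]
        elif rule is not CensoringRule.EXCLUDE:
            out.append(sub[rule])
    return np.asarray(out, dtype=float)


def detection_ci(n_detected: int, n_total: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) equal-tailed binomial CI for the detection
    frequency, in percent."""
    ci = stats.binomtest(n_detected, n_total).proportion_ci(
        confidence_level=level, method="exact"
    )
    return (100.0 * ci.low, 100.0 * ci.high)


def summarize(
    records: Sequence[ConcentrationRecord],
    rule: CensoringRule | str = CensoringRule.EXCLUDE,
    spec: AnalyteSpec | None = None,
) -> SummaryStats:
    """Detection frequency with its exact 95% CI, and mean/SD/min/max of the
    rule-transformed series (sample SD, n-1 denominator)."""
    if len(records) == 0:
        raise ValidationError("summarize requires at least one record")
    rule = CensoringRule(rule)
    analyte = records[0].analyte
    if spec is None:
        spec = DEFAULT_SPECS.get(analyte)
        if spec is None:
            raise ValidationError(f"no AnalyteSpec available for {analyte!r}")
    n_total = len(records)
    n_below = sum(r.censored for r in records)
    pct = 100.0 * (n_total - n_below) / n_total
    ci = detection_ci(n_total - n_below, n_total)
    values = apply_censoring_rule(records, rule, spec)
    if values.size == 0:
        mean = sd = vmin = vmax = float("nan")
    else:
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        vmin = float(np.min(values))
        vmax = float(np.max(values))
    return SummaryStats(
        analyte=analyte,
        n_total=n_total,
        n_below_lod=n_below,
        detection_pct=pct,
        detection_ci=ci,
        mean=mean,
        sd=sd,
        min=vmin,
        max=vmax,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Group comparisons


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    grouping_variable: str = "group",
) -> GroupComparison:
    """Nonparametric comparison of a numeric variable across groups.

    Two groups: two-sided Mann-Whitney U (exact when untied and small,
    tie-corrected normal approximation otherwise, no continuity
    correction). Three or more: Kruskal-Wallis. Per-group mean +/- SD is
    reported alongside, mirroring how survey tables present covariates.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValidationError("values and labels must have equal length")
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    groups = [values[labels == g] for g in uniq]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group must be non-empty")
    gm = {
        str(g): (float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
        for g, v in zip(uniq, groups)
    }
    if len(groups) == 2:
        res = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided", use_continuity=False
        )
        test = "mann-whitney-u"
    else:
        res = stats.kruskal(*groups)
        test = "kruskal-wallis"
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        grouping_variable=grouping_variable,
        group_means=gm,
        statistic=float(res.statistic),
        p_value=p,
        test_name=test,
    )


def tdi_exceedance_test(
    edi_values: Sequence[float],
    spec: AnalyteSpec,
    reference_pct: float = 0.0,
) -> GroupComparison:
    """Count infants whose EDI exceeds the TDI and, when a non-degenerate
    reference proportion is given, test the observed exceedance proportion
    against it with a chi-square goodness-of-fit test.

    With the default reference of 0% the chi-square expectation is
    degenerate, so only the counts are reported (statistic and p are NaN).
    """
    edi = np.asarray(edi_values, dtype=float)
    if edi.size == 0:
        raise ValidationError("empty EDI series")
    n = int(edi.size)
    k = int(np.sum(edi > spec.tdi))
    counts = {"exceeding": k, "not_exceeding": n - k, "n": n}
    if not 0.0 < reference_pct < 100.0:
        statistic = p = float("nan")
    else:
        p_ref = reference_pct / 100.0
        expected = np.array([n * p_ref, n * (1.0 - p_ref)])
        res = stats.chisquare([k, n - k], f_exp=expected)
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        grouping_variable=f"EDI>{spec.tdi} ({spec.name})",
        group_means={},
        statistic=statistic,
        p_value=p,
        test_name="chi-square",
        counts=counts,
    )
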