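"""Deterministic exposure risk: EDI, hazard quotient and hazard index.

The estimated daily intake of a contaminant through breast milk is

    EDI_i = C_i * FIR_i        [ng / kg bw / day]

with C_i the milk concentration (ng/mL) and FIR_i the infant's milk intake
rate (mL/kg bw/day); a group's EDI is the arithmetic mean of its infants'
EDIs (the dose is already normalised per kg body weight, so summing across
infants would be dimensionally wrong). The hazard quotient HQ = EDI / TDI
screens a single contaminant against its tolerable daily intake, and the
hazard index HI = HQ_MEL + HQ_CYA screens the mixture: HI > 1 flags a
potential non-carcinogenic risk, HI < 1 none.

Published risk tables round HQ to two decimals and sum the *rounded* HQs
into the printed HI; both that display convention (half-up) and the raw
unrounded values are carried side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .data import (
    AGE_GROUPS,
    AnalyteSpec,
    CensoringRule,
    ConcentrationRecord,
    InfantRecord,
    ValidationError,
    apply_censoring_rule,
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (0.025 -> 0.03),
    the convention of printed risk tables, unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RiskResult:
    """EDI/HQ per analyte plus HI for one scope (an age group or infant).

    ``hq``/``hi`` are unrounded; ``hq_display``/``hi_display`` follow the
    2-decimal half-up convention with HI summed over rounded HQs.
    ``at_risk`` uses the raw HI with a strict threshold (HI > 1).
    """

    scope: str
    n: int
    edi: dict[str, float]
    hq: dict[str, float]
    hq_display: dict[str, float]
    hi: float
    hi_display: float
    at_risk: bool
    edi_median: dict[str, float]
    hq_median: dict[str, float]


def compute_edi(concentration: float, fir: float) -> float:
    """Per-infant estimated daily intake: concentration (ng/mL) x intake
    rate (mL/kg bw/day) -> ng/kg bw/day."""
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    if fir <= 0:
        raise ValidationError(f"fir must be > 0, got {fir}")
    return concentration * fir


def compute_hq(edi: float, spec: AnalyteSpec) -> float:
    """Hazard quotient EDI/TDI (dimensionless, unrounded)."""
    if edi < 0:
        raise ValidationError(f"negative EDI {edi}")
    return edi / spec.tdi


def compute_hi(hqs: Sequence[float]) -> float:
    """Hazard index: the sum of hazard quotients across analytes."""
    if len(hqs) == 0:
        raise ValidationError("HI requires at least one HQ")
    return float(np.sum(np.asarray(hqs, dtype=float)))


def display_hq(hq: float) -> float:
    return round_half_up(hq, 2)


def display_hi(hqs: Sequence[float]) -> float:
    """Printed-table HI: sum of the display-rounded HQs, re-quantised to
    two decimals to absorb float noise."""
    return round_half_up(compute_hi([display_hq(h) for h in hqs]), 2)


def _group_concentration_series(
    infants: Sequence[InfantRecord],
    records: Sequence[ConcentrationRecord],
    spec: AnalyteSpec,
    rule: CensoringRule,
    resample_seed: int,
) -> list[tuple[InfantRecord, float]]:
    """Pair each infant with a concentration for one analyte.

    Infants whose ``sample_id`` matches a record use their own mother's
    sample (rule-substituted if censored; dropped under ``exclude``).
    Unlinked infants draw from the empirical distribution of the
    rule-transformed series, deterministically under ``resample_seed``.
    """
    by_sample = {r.sample_id: r for r in records}
    pool = apply_censoring_rule(records, rule, spec)
    if pool.size == 0:
        raise ValidationError(
            f"{spec.name}: no usable concentrations under rule {rule.value!r}"
        )
    rng = np.random.default_rng(resample_seed)
    pairs: list[tuple[InfantRecord, float]] = []
    for inf in infants:
        rec = by_sample.get(inf.sample_id) if inf.sample_id else None
        if rec is not None:
            vals = apply_censoring_rule([rec], rule, spec)
            if vals.size == 0:
                continue  # censored mother sample under exclude
            pairs.append((inf, float(vals[0])))
        else:
            pairs.append((inf, float(rng.choice(pool))))
    return pairs


def risk_table(
    cohort: Sequence[InfantRecord],
    concentrations: Mapping[str, Sequence[ConcentrationRecord]],
    specs: Mapping[str, AnalyteSpec],
    rule: CensoringRule | str = CensoringRule.EXCLUDE,
    resample_seed: int = 0,
) -> list[RiskResult]:
    """Per-age-group EDI, HQ and HI table (one row per stratum).

    For each group and analyte the group EDI is the mean of per-infant
    C x FIR over the infants contributing a usable concentration under the
    censoring rule; the group median is reported alongside.
    """
    rule = CensoringRule(rule)
    for analyte in concentrations:
        if analyte not in specs:
            raise ValidationError(f"analyte {analyte!r} has no AnalyteSpec")
    rows: list[RiskResult] = []
    for group in AGE_GROUPS:
        infants = [i for i in cohort if i.age_group == group]
        if not infants:
            raise ValidationError(f"age group {group} is empty")
        edi: dict[str, float] = {}
        edi_med: dict[str, float] = {}
        hq: dict[str, float] = {}
        hq_disp: dict[str, float] = {}
        hq_med: dict[str, float] = {}
        for analyte, records in concentrations.items():
            spec = specs[analyte]
            pairs = _group_concentration_series(
                infants, records, spec, rule, resample_seed
            )
            if not pairs:
                raise ValidationError(
                    f"{group}/{analyte}: no infants with usable concentrations"
                )
            edis = np.array([compute_edi(c, inf.fir) for inf, c in pairs])
            edi[analyte] = float(np.mean(edis))
            edi_med[analyte] = float(np.median(edis))
            hq[analyte] = compute_hq(edi[analyte], spec)
            hq_disp[analyte] = display_hq(hq[analyte])
            hq_med[analyte] = compute_hq(edi_med[analyte], spec)
        hi = compute_hi(list(hq.values()))
        rows.append(
            RiskResult(
                scope=group,
                n=len(infants),
                edi=edi,
                hq=hq,
                hq_display=hq_disp,
                hi=hi,
                hi_display=display_hi(list(hq.values())),
                at_risk=hi > 1.0,
                edi_median=edi_med,
                hq_median=hq_med,
            )
        )
    return rows


def individual_risk(
    infant: InfantRecord,
    concentration: Mapping[str, float],
    specs: Mapping[str, AnalyteSpec],
) -> RiskResult:
    """Risk result for a single infant given per-analyte concentrations."""
    edi = {a: compute_edi(c, infant.fir) for a, c in concentration.items()}
    hq = {a: compute_hq(e, specs[a]) for a, e in edi.items()}
    hi = compute_hi(list(hq.values()))
    return RiskResult(
        scope=infant.infant_id,
        n=1,
        edi=edi,
        hq=hq,
        hq_display={a: display_hq(h) for a, h in hq.items()},
        hi=hi,
        hi_display=display_hi(list(hq.values())),
        at_risk=hi > 1.0,
        edi_median=dict(edi),
        hq_median=dict(hq),
    )
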