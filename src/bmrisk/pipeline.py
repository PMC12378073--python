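"""End-to-end orchestration: data -> summaries -> deterministic risk ->
Monte Carlo -> report bundle.

A run writes a self-describing bundle: descriptive summaries per analyte,
grouped comparisons across age strata, the deterministic risk table (CSV +
JSON, display and raw precision), the Monte Carlo report, a human-readable
Markdown report with the verdict line, and a manifest (seed, config hash,
versions) sufficient to reproduce the bundle. Any stage failure aborts the
run with a stage-labelled error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .config import PipelineConfig
from .data import (
    AGE_GROUPS,
    AnalyteSpec,
    CensoringRule,
    ConcentrationRecord,
    InfantRecord,
    apply_censoring_rule,
    compare_groups,
    load_cohort,
    load_concentrations,
    summarize,
    tdi_exceedance_test,
)
from .montecarlo import (
    DistributionSpec,
    McResult,
    SimulationConfig,
    fit_distribution,
    risk_verdict,
    simulate_hq,
)
from .risk import RiskResult, risk_table
from .synthetic import fixture_dir

log = logging.getLogger("bmrisk")


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the stage that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    out_dir: Path
    summaries: dict[str, object]
    comparisons: dict[str, object]
    risk_rows: list[RiskResult]
    mc_result: McResult
    verdict: dict[str, object]
    manifest: dict[str, object]


def _load_inputs(
    config: PipelineConfig,
) -> tuple[dict[str, list[ConcentrationRecord]], list[InfantRecord]]:
    if config.fixture == "paper":
        base = fixture_dir()
        conc_path, cohort_path = base / "concentrations.csv", base / "cohort.csv"
    else:
        conc_path, cohort_path = config.concentrations_path, config.cohort_path
    records = load_concentrations(conc_path, config.analytes)
    by_analyte: dict[str, list[ConcentrationRecord]] = {}
    for r in records:
        by_analyte.setdefault(r.analyte, []).append(r)
    cohort = load_cohort(cohort_path, default_fir=config.default_fir)
    return by_analyte, cohort


def _simulation_config(
    config: PipelineConfig,
    by_analyte: Mapping[str, Sequence[ConcentrationRecord]],
    cohort: Sequence[InfantRecord],
) -> SimulationConfig:
    """Use configured distributions when given; otherwise fit them from the
    data (normal for concentrations, lognormal for FIR)."""
    conc: dict[str, DistributionSpec] = {}
    for analyte, records in by_analyte.items():
        key = f"concentration:{analyte}"
        if key in config.distributions:
            conc[analyte] = config.distributions[key]
        else:
            values = apply_censoring_rule(
                records, config.censoring_rule, config.analytes[analyte]
            )
            conc[analyte] = fit_distribution(values, "normal")
    fir = config.distributions.get("fir")
    intake = config.distributions.get("intake")
    bw = config.distributions.get("bw")
    if fir is None and intake is None:
        fir = fit_distribution([i.fir for i in cohort], "lognormal")
    return SimulationConfig(
        concentration=conc,
        fir=fir,
        intake=intake,
        bw=bw,
        n_iterations=config.n_iterations,
        seed=config.seed,
        percentiles=config.percentiles,
    )


def _risk_rows_json(rows: Sequence[RiskResult], display: bool) -> list[dict]:
    out = []
    for r in rows:
        analytes = sorted(r.edi)
        row: dict[str, object] = {"age_group": r.scope, "n": r.n}
        for a in analytes:
            if display:
                row[f"edi_{a.lower()}"] = round(r.edi[a], 2)
                row[f"hq_{a.lower()}"] = r.hq_display[a]
            else:
                row[f"edi_{a.lower()}"] = r.edi[a]
                row[f"hq_{a.lower()}"] = r.hq[a]
                row[f"edi_median_{a.lower()}"] = r.edi_median[a]
                row[f"hq_median_{a.lower()}"] = r.hq_median[a]
        row["hi"] = r.hi_display if display else r.hi
        if not display:
            row["at_risk"] = r.at_risk
        out.append(row)
    return out


def _mc_json(result: McResult) -> dict:
    def summ(s) -> dict:
        return {
            "mean": s.mean,
            "sd": s.sd,
            "percentiles": {str(p): v for p, v in s.percentiles.items()},
            "p95": s.p95,
            "exceedance_prob": s.exceedance_prob,
            "degenerate": s.degenerate,
            "sensitivity": [
                {
                    "variable": e.variable,
                    "rank_correlation": e.rank_correlation,
                    "contribution": e.contribution,
                }
                for e in s.sensitivity
            ],
        }

    return {
        "n_iterations": result.n_iterations,
        "seed": result.seed,
        "hq": {a: summ(s) for a, s in result.per_analyte.items()},
        "hi": summ(result.hi),
    }


def _write_plots(result: McResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for analyte, draws in result.hq_draws.items():
        axes[0].hist(draws, bins=60, alpha=0.6, label=analyte, density=True)
        xs = np.sort(draws)
        axes[1].plot(xs, np.linspace(0, 1, xs.size), label=analyte)
    axes[0].set_xlabel("HQ")
    axes[0].set_ylabel("density")
    axes[0].legend()
    axes[1].set_xlabel("HQ")
    axes[1].set_ylabel("cumulative probability")
    axes[1].axhline(0.95, ls="--", c="grey", lw=0.8)
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "hq_distribution.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ReportBundle:
    """Run every stage and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run_pipeline(config, out)
    except Exception as exc:
        # remove partial outputs before propagating
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in out.glob("*"):
                if p.is_file():
                    p.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("pipeline", str(exc)) from exc


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def _run_pipeline(config: PipelineConfig, out: Path) -> ReportBundle:
    by_analyte, cohort = _stage("load")(_load_inputs)(config)
    analytes = sorted(by_analyte)
    for a in analytes:
        n_cens = sum(r.censored for r in by_analyte[a])
        log.info(
            "%s: %d samples, %d censored (< LOD), rule=%s",
            a,
            len(by_analyte[a]),
            n_cens,
            config.censoring_rule.value,
        )
    log.info(
        "cohort: %d infants; simulation seed=%d iterations=%d",
        len(cohort),
        config.seed,
        config.n_iterations,
    )

    # Table-1-like descriptive summaries
    summaries = {}
    for a in analytes:
        s = _stage("summarize")(summarize)(
            by_analyte[a], config.censoring_rule, config.analytes[a]
        )
        summaries[a] = {
            "n_total": s.n_total,
            "n_below_lod": s.n_below_lod,
            "detection_pct": s.detection_pct,
            "detection_ci_95": list(s.detection_ci),
            "mean": s.mean,
            "sd": s.sd,
            "min": s.min,
            "max": s.max,
            "rule": s.rule.value,
        }

    # Table-3-like deterministic risk
    rows = _stage("risk")(risk_table)(
        cohort,
        by_analyte,
        config.analytes,
        config.censoring_rule,
        resample_seed=config.resample_seed,
    )

    # Table-2-like grouped comparisons: per-infant EDIs across age strata,
    # plus the TDI exceedance count/test per analyte.
    comparisons: dict[str, object] = {}
    per_infant_edi: dict[str, dict[str, list[float]]] = {a: {} for a in analytes}
    by_sample = {
        a: {r.sample_id: r for r in by_analyte[a]} for a in analytes
    }
    for a in analytes:
        values, labels = [], []
        edi_all: list[float] = []
        for inf in cohort:
            rec = by_sample[a].get(inf.sample_id) if inf.sample_id else None
            if rec is None:
                continue
            v = apply_censoring_rule([rec], config.censoring_rule, config.analytes[a])
            if v.size == 0:
                continue
            values.append(float(v[0]))
            labels.append(inf.age_group)
            edi_all.append(float(v[0]) * inf.fir)
        comp = _stage("compare")(compare_groups)(values, labels, f"{a} by age group")
        exc = _stage("compare")(tdi_exceedance_test)(edi_all, config.analytes[a])
        comparisons[a] = {
            "age_group_test": {
                "test": comp.test_name,
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "group_mean_sd": comp.group_means,
            },
            "tdi_exceedance": exc.counts,
        }

    # Monte Carlo
    sim_cfg = _stage("mc")(_simulation_config)(config, by_analyte, cohort)
    mc = _stage("mc")(simulate_hq)(sim_cfg, config.analytes)
    verdict = risk_verdict(mc)

    # ---- write bundle
    writer = _stage("write")(_write_bundle)
    manifest = writer(config, out, summaries, comparisons, rows, mc, verdict)
    return ReportBundle(
        out_dir=out,
        summaries=summaries,
        comparisons=comparisons,
        risk_rows=rows,
        mc_result=mc,
        verdict=verdict,
        manifest=manifest,
    )


def _write_bundle(
    config: PipelineConfig,
    out: Path,
    summaries: dict,
    comparisons: dict,
    rows: list[RiskResult],
    mc: McResult,
    verdict: dict,
) -> dict:
    canonical = yaml.safe_dump(config.raw, sort_keys=True)
    manifest = {
        "bmrisk_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config.raw,
        "versions": {
            "numpy": np.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summaries, indent=2))
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
    display_rows = _risk_rows_json(rows, display=True)
    raw_rows = _risk_rows_json(rows, display=False)
    (out / "risk_table.json").write_text(json.dumps(display_rows, indent=2))
    (out / "risk_table_raw.json").write_text(json.dumps(raw_rows, indent=2))
    header = list(display_rows[0].keys())
    csv_lines = [",".join(header)] + [
        ",".join(str(row[h]) for h in header) for row in display_rows
    ]
    (out / "risk_table.csv").write_text("\n".join(csv_lines) + "\n")
    (out / "mc_report.json").write_text(json.dumps(_mc_json(mc), indent=2))
    (out / "verdict.json").write_text(json.dumps(verdict, indent=2))
    if config.plots:
        _write_plots(mc, out)
    (out / "report.md").write_text(_markdown_report(summaries, display_rows, verdict))
    return manifest


def _markdown_report(summaries: dict, display_rows: list[dict], verdict: dict) -> str:
    lines = ["# Breast-milk contaminant risk report", "", "## Detection summary", ""]
    for a, s in summaries.items():
        lo, hi = s["detection_ci_95"]
        lines.append(
            f"- {a}: {s['n_total'] - s['n_below_lod']}/{s['n_total']} detected "
            f"({s['detection_pct']:.1f}%, 95% CI {lo:.1f}-{hi:.1f}%)"
        )
    lines += ["", "## Deterministic risk (per age group)", ""]
    header = list(display_rows[0].keys())
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for row in display_rows:
        lines.append("| " + " | ".join(str(row[h]) for h in header) + " |")
    lines += [
        "",
        "## Probabilistic risk",
        "",
        f"Verdict: **{verdict['classification']}** "
        f"(95th-percentile HI {verdict['p95_hi']:.4g}; per-analyte P95 HQ: "
        + ", ".join(f"{a}={v:.4g}" for a, v in verdict["p95_hq"].items())
        + ")",
        "",
    ]
    return "\n".join(lines)
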