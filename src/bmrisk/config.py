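"""YAML pipeline configuration: schema, validation, unit policing.

Validation collects *all* problems rather than failing on the first, and
rejects unit-annotated strings instead of silently converting — a TDI
written as ``"0.2 mg/kg"`` is an error whose message suggests the correct
ng/kg/day number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .data import AnalyteSpec, CensoringRule
from .montecarlo import DistributionSpec

_TOP_KEYS = {
    "analytes",
    "censoring_rule",
    "inputs",
    "fixture",
    "default_fir_ml_per_kg_day",
    "simulation",
    "resample_seed",
    "plots",
    "log_level",
    "generator",  # accepted so a fixture_config.yaml round-trips
}
_ANALYTE_KEYS = {"tdi_ng_per_kg_day", "lod_ng_per_ml", "loq_ng_per_ml"}
_SIM_KEYS = {"n_iterations", "seed", "percentiles", "distributions"}
_DIST_KEYS = {"family", "loc", "scale", "lower"}

#: unit multipliers to ng for mass-per-kg annotations we can recognise
_UNIT_TO_NG = {"ng": 1.0, "ug": 1e3, "µg": 1e3, "mg": 1e6, "g": 1e9}
_UNIT_RE = re.compile(
    r"^\s*([0-9.eE+-]+)\s*(ng|ug|µg|mg|g)\s*/\s*kg(?:\s*/?\s*(?:bw)?\s*/?\s*(?:day|d))?\s*$"
)


@dataclass
class PipelineConfig:
    """Validated configuration for one end-to-end run."""

    analytes: dict[str, AnalyteSpec]
    censoring_rule: CensoringRule = CensoringRule.EXCLUDE
    concentrations_path: Path | None = None
    cohort_path: Path | None = None
    fixture: str | None = None  # "paper" selects the packaged emulation fixture
    default_fir: float = 150.0
    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    resample_seed: int = 0
    plots: bool = False
    log_level: str = "INFO"
    raw: dict[str, Any] = field(default_factory=dict, repr=False)


def _check_number(
    value: Any, key: str, errors: list[str], positive: bool = True
) -> float | None:
    if isinstance(value, bool) or not isinstance(value, (int, float, str)):
        errors.append(f"{key}: expected a number, got {value!r}")
        return None
    if isinstance(value, str):
        m = _UNIT_RE.match(value)
        if m:
            number, unit = float(m.group(1)), m.group(2)
            suggested = number * _UNIT_TO_NG[unit]
            errors.append(
                f"{key}: unit-annotated value {value!r} not accepted; this "
                f"package uses ng/kg/day — write {suggested:g}"
            )
        else:
            try:
                return _check_number(float(value), key, errors, positive)
            except ValueError:
                errors.append(f"{key}: expected a number, got {value!r}")
        return None
    v = float(value)
    if positive and v <= 0:
        errors.append(f"{key}: must be > 0, got {v}")
        return None
    return v


def _parse_distribution(
    name: str, node: Any, errors: list[str]
) -> DistributionSpec | None:
    if not isinstance(node, Mapping):
        errors.append(f"simulation.distributions.{name}: expected a mapping")
        return None
    unknown = set(node) - _DIST_KEYS
    if unknown:
        errors.append(
            f"simulation.distributions.{name}: unknown keys {sorted(unknown)}"
        )
    family = node.get("family")
    if family not in ("normal", "lognormal", "point"):
        errors.append(
            f"simulation.distributions.{name}: family must be normal, "
            f"lognormal or point, got {family!r}"
        )
        return None
    loc = node.get("loc")
    if not isinstance(loc, (int, float)) or isinstance(loc, bool):
        errors.append(f"simulation.distributions.{name}: loc must be a number")
        return None
    scale = node.get("scale", 0.0)
    if not isinstance(scale, (int, float)) or isinstance(scale, bool) or scale < 0:
        errors.append(
            f"simulation.distributions.{name}: scale must be a number >= 0"
        )
        return None
    lower = node.get("lower")
    if lower is not None and not isinstance(lower, (int, float)):
        errors.append(f"simulation.distributions.{name}: lower must be a number")
        return None
    return DistributionSpec(
        str(family), float(loc), float(scale), None if lower is None else float(lower)
    )


def validate_config_dict(doc: Any) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a parsed YAML document; returns (config, errors). The config
    is None whenever errors is non-empty."""
    errors: list[str] = []
    if not isinstance(doc, Mapping):
        return None, ["config root must be a mapping"]
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")

    analytes: dict[str, AnalyteSpec] = {}
    node = doc.get("analytes")
    if not isinstance(node, Mapping) or not node:
        errors.append("analytes: required mapping of analyte name -> constants")
    else:
        for name, spec in node.items():
            if not isinstance(spec, Mapping):
                errors.append(f"analytes.{name}: expected a mapping")
                continue
            missing = _ANALYTE_KEYS - set(spec)
            for key in sorted(missing):
                errors.append(f"analytes.{name}: missing required key {key}")
            extra = set(spec) - _ANALYTE_KEYS
            if extra:
                errors.append(f"analytes.{name}: unknown keys {sorted(extra)}")
            tdi = _check_number(spec.get("tdi_ng_per_kg_day"), f"analytes.{name}.tdi_ng_per_kg_day", errors) if "tdi_ng_per_kg_day" in spec else None
            lod = _check_number(spec.get("lod_ng_per_ml"), f"analytes.{name}.lod_ng_per_ml", errors) if "lod_ng_per_ml" in spec else None
            loq = _check_number(spec.get("loq_ng_per_ml"), f"analytes.{name}.loq_ng_per_ml", errors) if "loq_ng_per_ml" in spec else None
            if tdi is not None and lod is not None and loq is not None:
                if lod >= loq:
                    errors.append(f"analytes.{name}: require lod < loq")
                else:
                    analytes[str(name)] = AnalyteSpec(str(name), tdi, lod, loq)

    rule = CensoringRule.EXCLUDE
    if "censoring_rule" in doc:
        try:
            rule = CensoringRule(doc["censoring_rule"])
        except ValueError:
            errors.append(
                f"censoring_rule: {doc['censoring_rule']!r} not one of "
                f"{[r.value for r in CensoringRule]}"
            )

    conc_path = cohort_path = None
    fixture = doc.get("fixture")
    inputs = doc.get("inputs")
    if (inputs is None) == (fixture is None):
        errors.append("exactly one of 'inputs' or 'fixture' must be given")
    if inputs is not None:
        if not isinstance(inputs, Mapping):
            errors.append("inputs: expected mapping with concentrations and cohort")
        else:
            for key in ("concentrations", "cohort"):
                if key not in inputs:
                    errors.append(f"inputs.{key}: required path missing")
            extra = set(inputs) - {"concentrations", "cohort"}
            if extra:
                errors.append(f"inputs: unknown keys {sorted(extra)}")
            conc_path = Path(inputs["concentrations"]) if "concentrations" in inputs else None
            cohort_path = Path(inputs["cohort"]) if "cohort" in inputs else None
    if fixture is not None and fixture != "paper":
        errors.append(f"fixture: unknown preset {fixture!r} (only 'paper')")

    default_fir = 150.0
    if "default_fir_ml_per_kg_day" in doc:
        v = _check_number(
            doc["default_fir_ml_per_kg_day"], "default_fir_ml_per_kg_day", errors
        )
        if v is not None:
            default_fir = v

    n_iter, seed = 10_000, 0
    percentiles: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)
    distributions: dict[str, DistributionSpec] = {}
    sim = doc.get("simulation")
    if sim is not None:
        if not isinstance(sim, Mapping):
            errors.append("simulation: expected a mapping")
        else:
            extra = set(sim) - _SIM_KEYS
            if extra:
                errors.append(f"simulation: unknown keys {sorted(extra)}")
            if "n_iterations" in sim:
                if (
                    isinstance(sim["n_iterations"], bool)
                    or not isinstance(sim["n_iterations"], int)
                    or sim["n_iterations"] < 1
                ):
                    errors.append("simulation.n_iterations: must be an integer >= 1")
                else:
                    n_iter = int(sim["n_iterations"])
            if "seed" in sim:
                if isinstance(sim["seed"], bool) or not isinstance(sim["seed"], int):
                    errors.append("simulation.seed: must be an integer")
                else:
                    seed = int(sim["seed"])
            if "percentiles" in sim:
                ps = sim["percentiles"]
                if not isinstance(ps, list) or any(
                    not isinstance(p, (int, float)) or not 0 < p < 100 for p in ps
                ):
                    errors.append("simulation.percentiles: list of numbers in (0,100)")
                else:
                    percentiles = tuple(float(p) for p in ps)
            if "distributions" in sim and isinstance(sim["distributions"], Mapping):
                for name, dnode in sim["distributions"].items():
                    d = _parse_distribution(str(name), dnode, errors)
                    if d is not None:
                        distributions[str(name)] = d
            elif "distributions" in sim:
                errors.append("simulation.distributions: expected a mapping")

    resample_seed = 0
    if "resample_seed" in doc:
        if isinstance(doc["resample_seed"], bool) or not isinstance(doc["resample_seed"], int):
            errors.append("resample_seed: must be an integer")
        else:
            resample_seed = int(doc["resample_seed"])

    plots = bool(doc.get("plots", False))
    log_level = str(doc.get("log_level", "INFO"))

    if errors:
        return None, errors
    return (
        PipelineConfig(
            analytes=analytes,
            censoring_rule=rule,
            concentrations_path=conc_path,
            cohort_path=cohort_path,
            fixture=fixture,
            default_fir=default_fir,
            n_iterations=n_iter,
            seed=seed,
            percentiles=percentiles,
            distributions=distributions,
            resample_seed=resample_seed,
            plots=plots,
            log_level=log_level,
            raw=dict(doc),
        ),
        [],
    )


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Load and validate a YAML config file, collecting all errors."""
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"{path}: cannot parse ({exc})"]
    config, errors = validate_config_dict(doc)
    if config is not None:
        # resolve relative input paths against the config file's directory
        base = Path(path).parent
        if config.concentrations_path and not config.concentrations_path.is_absolute():
            config.concentrations_path = base / config.concentrations_path
        if config.cohort_path and not config.cohort_path.is_absolute():
            config.cohort_path = base / config.cohort_path
        for key, p in (
            ("inputs.concentrations", config.concentrations_path),
            ("inputs.cohort", config.cohort_path),
        ):
            if p is not None and not p.exists():
                errors.append(f"{key}: file not found: {p}")
        if errors:
            return None, errors
    return config, errors
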