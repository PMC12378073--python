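"""Monte Carlo propagation of exposure-factor uncertainty to HQ/HI.

Concentrations are modelled as (zero-truncated) normal variables — survey
values scatter roughly symmetrically around the mean — while body weight
and milk intake rate are lognormal, the usual choice for positively skewed
biological exposure factors. Each iteration draws every input
independently, forms EDI = C x FIR and HQ = EDI/TDI per analyte and
HI = sum of HQs, and the 95th percentile of the resulting HQ distribution
is the probabilistic risk readout.

Sensitivity follows the rank-correlation convention of spreadsheet risk
tools: each input's Spearman correlation with the output, and its squared
correlation normalised over inputs as a contribution-to-variance.

All randomness flows from one master seed through named substreams, so a
simulation is bit-reproducible from its config alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import AnalyteSpec, ValidationError


class ConfigurationError(ValueError):
    """Raised when a simulation config is incomplete or inconsistent."""


_FAMILIES = ("normal", "lognormal", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """One input variable's distribution.

    ``loc``/``scale`` are on the family's natural scale for ``normal`` and
    ``point`` (scale ignored for point); for ``lognormal`` they are the
    mean and SD of log-values. ``lower`` truncates by redraw (concentration
    inputs default to a lower bound of 0 at simulation time).
    """

    family: str
    loc: float
    scale: float = 0.0
    lower: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.scale < 0:
            raise ConfigurationError(f"scale must be >= 0, got {self.scale}")

    def mean(self) -> float:
        """Untruncated mean on the natural scale."""
        if self.family == "lognormal":
            return math.exp(self.loc + self.scale**2 / 2.0)
        return self.loc


def fit_distribution(values: Sequence[float], family: str) -> DistributionSpec:
    """Moment fit: normal -> sample mean/SD; lognormal -> mean/SD of
    log-values; point -> the single repeated value."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("fitting requires at least 2 values")
    if family == "point":
        if not np.all(x == x[0]):
            raise ValidationError("point family requires identical values")
        return DistributionSpec("point", float(x[0]))
    if family == "normal":
        return DistributionSpec("normal", float(np.mean(x)), float(np.std(x, ddof=1)))
    if family == "lognormal":
        if np.any(x <= 0):
            raise ValidationError("lognormal fit requires strictly positive values")
        lx = np.log(x)
        return DistributionSpec(
            "lognormal", float(np.mean(lx)), float(np.std(lx, ddof=1))
        )
    raise ConfigurationError(f"unknown family {family!r}")


def sample(
    spec: DistributionSpec,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` values; truncated families redraw below ``lower``.

    Identical seed (or generator state) gives an identical series.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.family == "point":
        return np.full(n, spec.loc, dtype=float)
    if spec.scale == 0.0:  # degenerate fit: behaves as a point mass
        value = spec.loc if spec.family == "normal" else math.exp(spec.loc)
        return np.full(n, value, dtype=float)
    if spec.family == "normal":
        draw = lambda k: rng.normal(spec.loc, spec.scale, size=k)  # noqa: E731
    else:  # lognormal
        draw = lambda k: rng.lognormal(spec.loc, spec.scale, size=k)  # noqa: E731
    out = draw(n)
    if spec.lower is not None:
        bad = out < spec.lower
        guard = 0
        while np.any(bad):
            out[bad] = draw(int(bad.sum()))
            bad = out < spec.lower
            guard += 1
            if guard > 10_000:  # pragma: no cover - pathological truncation
                raise ValidationError(
                    f"truncation at {spec.lower} rejects nearly all draws"
                )
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs and knobs for one HQ simulation.

    ``concentration`` maps analyte -> DistributionSpec (ng/mL). Intake can
    be given either directly as ``fir`` (mL/kg bw/day) or as ``intake``
    (mL/day) together with ``bw`` (kg), in which case FIR = intake / bw
    per draw.
    """

    concentration: Mapping[str, DistributionSpec]
    fir: DistributionSpec | None = None
    intake: DistributionSpec | None = None
    bw: DistributionSpec | None = None
    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not self.concentration:
            raise ConfigurationError("at least one concentration spec required")
        if any(not 0.0 < p < 100.0 for p in self.percentiles):
            raise ConfigurationError("percentiles must lie in (0, 100)")
        if self.fir is None and (self.intake is None or self.bw is None):
            raise ConfigurationError(
                "provide either a fir spec or both intake and bw specs"
            )
        if self.fir is not None and self.intake is not None:
            raise ConfigurationError("fir and intake/bw are mutually exclusive")


@dataclass(frozen=True)
class SensitivityEntry:
    variable: str
    rank_correlation: float
    contribution: float  # normalised squared rank correlation


@dataclass(frozen=True)
class HqSummary:
    """Summary of one simulated output (an analyte's HQ, or the HI)."""

    mean: float
    sd: float
    percentiles: dict[float, float]
    p95: float
    exceedance_prob: float  # fraction of draws with value > 1
    degenerate: bool  # true when the draws are (numerically) constant
    sensitivity: tuple[SensitivityEntry, ...]


@dataclass(frozen=True)
class McResult:
    """Full simulation output, including the raw draws for downstream use."""

    per_analyte: dict[str, HqSummary]
    hi: HqSummary
    n_iterations: int
    seed: int
    input_draws: dict[str, np.ndarray]
    hq_draws: dict[str, np.ndarray]
    hi_draws: np.ndarray


def sensitivity_analysis(
    input_draws: Mapping[str, np.ndarray],
    output_draws: np.ndarray,
) -> list[SensitivityEntry]:
    """Spearman rank correlation of each input with the output and its
    contribution to variance (squared rho normalised over inputs), sorted
    by absolute contribution, largest first.

    A constant output yields all-zero correlations (degenerate case).
    """
    out = np.asarray(output_draws, dtype=float)
    if out.size < 10:
        raise ValidationError("need at least 10 draws for sensitivity analysis")
    entries: list[tuple[str, float]] = []
    degenerate = np.all(out == out[0])
    for name, draws in input_draws.items():
        x = np.asarray(draws, dtype=float)
        if x.size != out.size:
            raise ValidationError(f"{name}: length {x.size} != output {out.size}")
        if degenerate or np.all(x == x[0]):
            rho = 0.0
        else:
            rho = float(stats.spearmanr(x, out).statistic)
            if math.isnan(rho):
                rho = 0.0
        entries.append((name, rho))
    total = sum(r * r for _, r in entries)
    result = [
        SensitivityEntry(name, rho, (rho * rho / total) if total > 0 else 0.0)
        for name, rho in entries
    ]
    result.sort(key=lambda e: abs(e.contribution), reverse=True)
    return result


def _summarize_output(
    draws: np.ndarray,
    percentiles: Sequence[float],
    inputs: Mapping[str, np.ndarray],
) -> HqSummary:
    pct = {float(p): float(np.percentile(draws, p)) for p in percentiles}
    degenerate = bool(np.all(draws == draws[0]))
    sens = (
        tuple(sensitivity_analysis(inputs, draws)) if draws.size >= 10 else tuple()
    )
    return HqSummary(
        mean=float(np.mean(draws)),
        sd=0.0 if degenerate or draws.size < 2 else float(np.std(draws, ddof=1)),
        percentiles=pct,
        p95=float(np.percentile(draws, 95.0)),
        exceedance_prob=float(np.mean(draws > 1.0)),
        degenerate=degenerate,
        sensitivity=sens,
    )


def simulate_hq(
    config: SimulationConfig, specs: Mapping[str, AnalyteSpec]
) -> McResult:
    """Run the simulation: draw all inputs, form HQ per analyte and HI.

    Substreams are spawned from the master seed in a fixed (sorted
    variable name) order, so results are bit-identical for a given config
    regardless of insertion order.
    """
    for analyte in config.concentration:
        if analyte not in specs:
            raise ConfigurationError(f"no AnalyteSpec for analyte {analyte!r}")
    var_specs: dict[str, DistributionSpec] = {
        f"concentration:{a}": s for a, s in config.concentration.items()
    }
    if config.fir is not None:
        var_specs["fir"] = config.fir
    else:
        var_specs["intake"] = config.intake  # type: ignore[assignment]
        var_specs["bw"] = config.bw  # type: ignore[assignment]

    names = sorted(var_specs)
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    n = config.n_iterations
    draws: dict[str, np.ndarray] = {}
    for name, child in zip(names, children):
        spec = var_specs[name]
        if name.startswith("concentration:") and spec.lower is None:
            spec = DistributionSpec(spec.family, spec.loc, spec.scale, lower=0.0)
        draws[name] = sample(spec, n, rng=np.random.Generator(np.random.PCG64(child)))

    fir = draws["fir"] if "fir" in draws else draws["intake"] / draws["bw"]
    hq_draws: dict[str, np.ndarray] = {}
    per_analyte: dict[str, HqSummary] = {}
    for analyte in config.concentration:
        c = draws[f"concentration:{analyte}"]
        hq = c * fir / specs[analyte].tdi
        hq_draws[analyte] = hq
        rel_inputs = {
            k: v
            for k, v in draws.items()
            if k == f"concentration:{analyte}" or not k.startswith("concentration:")
        }
        per_analyte[analyte] = _summarize_output(hq, config.percentiles, rel_inputs)
    hi_draws = np.sum(np.vstack(list(hq_draws.values())), axis=0)
    hi = _summarize_output(hi_draws, config.percentiles, draws)
    return McResult(
        per_analyte=per_analyte,
        hi=hi,
        n_iterations=n,
        seed=config.seed,
        input_draws=draws,
        hq_draws=hq_draws,
        hi_draws=hi_draws,
    )


def percentile_bootstrap_se(
    draws: np.ndarray, q: float, n_boot: int = 200, seed: int = 0
) -> float:
    """Monte Carlo standard error of the q-th percentile, by bootstrap
    resampling of the draws (used for simulation tolerances)."""
    rng = np.random.default_rng(seed)
    draws = np.asarray(draws, dtype=float)
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = np.percentile(rng.choice(draws, size=draws.size, replace=True), q)
    return float(np.std(est, ddof=1))


def risk_verdict(result: McResult) -> dict[str, object]:
    """Classify the simulated risk: "below threshold" iff every analyte's
    95th-percentile HQ and the 95th-percentile HI are strictly below 1,
    otherwise "potential concern" (the boundary counts as concern)."""
    p95s = {a: s.p95 for a, s in result.per_analyte.items()}
    worst = max(max(p95s.values()), result.hi.p95)
    classification = "below threshold" if worst < 1.0 else "potential concern"
    return {
        "classification": classification,
        "p95_hq": p95s,
        "p95_hi": result.hi.p95,
        "exceedance_prob": {
            a: s.exceedance_prob for a, s in result.per_analyte.items()
        },
        "hi_exceedance_prob": result.hi.exceedance_prob,
    }
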