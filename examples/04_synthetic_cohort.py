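"""Generate a synthetic censored dataset and cohort from scratch.

Calibrates the concentration location so the analytic censored fraction
matches a 77%/84% detection target, draws 100 censored samples per
analyte plus a 20/15/15 infant cohort, and solves intake rates so the
group EDIs hit the published targets exactly - then verifies the
round trip through the CSV readers.
"""

import tempfile
from pathlib import Path

from bmrisk import DEFAULT_SPECS, load_cohort, load_concentrations, summarize
from bmrisk.synthetic import paper_fixture, write_fixture

fixture = paper_fixture(seed=2024)
print("calibrated concentration locations (ng/mL):")
for name, gen in sorted(fixture.params.analytes.items()):
    print(f"  {name}: location {gen.mean:.2f}, sd-parameter {gen.sd_param}, LOD {gen.lod}")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture(fixture, Path(tmp))
    records = load_concentrations(paths["concentrations"], DEFAULT_SPECS)
    by_analyte: dict[str, list] = {}
    for r in records:
        by_analyte.setdefault(r.analyte, []).append(r)
    for analyte in sorted(by_analyte):
        s = summarize(by_analyte[analyte])
        print(f"{analyte}: {s.n_below_lod}/100 non-detects -> detection {s.detection_pct:.0f}%")
    cohort = load_cohort(paths["cohort"])
    sizes = {}
    for infant in cohort:
        sizes[infant.age_group] = sizes.get(infant.age_group, 0) + 1
    print(f"cohort strata: {sizes}")

print("\ngroup EDIs achieved by the intake-rate calibration (ng/kg bw/day):")
for group, per in fixture.achieved_edis.items():
    print(f"  {group}: " + ", ".join(f"{a}={v:.2f}" for a, v in sorted(per.items())))
print(
    "\nThe non-detect counts are exact by construction (stratified draw\n"
    "conditioned on the observed pattern) and the group EDIs match the\n"
    "published table to solver precision."
)
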