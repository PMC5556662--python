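"""Config-driven orchestration: simulate → cohort → identify → estimate → benchmark.

A run is described by a :class:`RunConfig` (YAML-loadable).  ``run_pipeline``
executes all stages, writes every output file under the output directory
and records a machine-readable manifest (config hash, seed, stage row
counts, per-algorithm numerators, content hash per output file).  Reruns
with an identical config are bit-identical, manifest included.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .algorithms import get_algorithms
from .cohort import CohortSpec, build_cohort
from .data import get_site, read_claims_tables
from .errors import ConfigError
from .incidence import STANDARD_POPULATIONS, compare_to_registry, stratified_results
from .model import ClaimsIncidenceModel, DEFAULT_SITES
from .simulate import SimulationConfig, generate_population, generate_registry_benchmark

log = logging.getLogger("claimsinc")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Exactly one of ``input_dir`` (pre-existing claims tables) and
    ``simulation`` (a :class:`SimulationConfig`) must be set.
    """

    out_dir: str
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    algorithms: str | Sequence[str] = "all"
    sites: Sequence[str] = DEFAULT_SITES
    strata: Sequence[str] = ("overall",)
    standard: str = "esp1976"
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigError("set exactly one of input_dir and simulation")
        get_algorithms(self.algorithms)  # validates labels
        for s in self.sites:
            get_site(s)
        if self.standard not in STANDARD_POPULATIONS:
            raise ConfigError(f"unknown standard population {self.standard!r}")
        if self.seed is not None and self.simulation is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: expected a mapping")
        if "simulation" in payload and payload["simulation"] is not None:
            payload["simulation"] = SimulationConfig.from_dict(payload["simulation"])
        if "cohort" in payload and isinstance(payload["cohort"], dict):
            c = dict(payload["cohort"])
            if "reference_date" in c and isinstance(c["reference_date"], str):
                c["reference_date"] = dt.date.fromisoformat(c["reference_date"])
            payload["cohort"] = CohortSpec(**c)
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc

    def canonical_dict(self) -> dict:
        d = {
            "input_dir": self.input_dir,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "cohort": {
                "reference_date": self.cohort.reference_date.isoformat(),
                "required_years": self.cohort.required_years,
                "max_gap_days": self.cohort.max_gap_days,
            },
            "algorithms": list(self.algorithms)
            if not isinstance(self.algorithms, str)
            else self.algorithms,
            "sites": list(self.sites),
            "strata": list(self.strata),
            "standard": self.standard,
            "seed": self.seed,
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed
        if config.seed is not None
        else (config.simulation.seed if config.simulation else None),
        "stages": {},
        "files": {},
    }

    truth = None
    if config.simulation is not None:
        tables, truth = generate_population(config.simulation)
        tables.write(out / "claims")
        truth.to_csv(out / "claims" / "ground_truth.csv", index=False)
        benchmark = generate_registry_benchmark(truth, tables.persons)
        benchmark.to_csv(out / "benchmark.csv", index=False)
        log.info("simulate: %d persons, %d outpatient dx", len(tables.persons), len(tables.outpatient))
    else:
        tables = read_claims_tables(config.input_dir)
        benchmark_path = Path(config.input_dir) / "benchmark.csv"
        benchmark = pd.read_csv(benchmark_path) if benchmark_path.exists() else None
        truth_path = Path(config.input_dir) / "ground_truth.csv"
        truth = pd.read_csv(truth_path, dtype=str) if truth_path.exists() else None
    manifest["stages"]["claims"] = {
        "persons": len(tables.persons),
        "spells": len(tables.spells),
        "outpatient_dx": len(tables.outpatient),
        "inpatient_dx": len(tables.inpatient),
        "procedures": len(tables.procedures),
    }

    cohort = build_cohort(tables, config.cohort)
    cohort.frame.to_csv(out / "cohort.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(cohort.exclusions, indent=2))
    manifest["stages"]["cohort"] = {
        "eligible": len(cohort),
        "exclusions": cohort.exclusions,
    }
    log.info("cohort: %d eligible, %s excluded", len(cohort), cohort.exclusions)

    model = ClaimsIncidenceModel(
        tables,
        cohort_spec=config.cohort,
        sites=config.sites,
        standard=STANDARD_POPULATIONS[config.standard],
    )
    model._cohort = cohort
    fit = model.fit(algorithms=config.algorithms, strata=config.strata)
    fit.to_csv(out)
    manifest["stages"]["identify"] = {"cases": len(fit.cases)}
    ov = fit.results[fit.results["stratum_type"] == "overall"]
    manifest["numerators"] = {
        site: {
            row["algorithm_label"]: int(row["numerator"])
            for _, row in ov[ov["site"] == site].iterrows()
        }
        for site in ov["site"].unique()
    }
    log.info("identify: %d incident cases across %d site-algorithm cells",
             len(fit.cases), len(ov))

    if benchmark is not None:
        comparison = compare_to_registry(fit.results, benchmark)
        comparison.to_csv(out / "benchmark_comparison.csv", index=False)
        manifest["stages"]["benchmark"] = {"rows": len(comparison)}
    if truth is not None:
        validation = fit.validate(truth)
        validation.to_csv(out / "validation.csv", index=False)
        manifest["stages"]["validation"] = {"rows": len(validation)}

    for path in sorted(out.rglob("*.csv")) + sorted(out.glob("*.json")):
        if path.name == "manifest.json":
            continue
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def sensitivity_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the three denominator regimes: main, min1y, per-lookback.

    ``main`` uses the configured cohort rule (7 years by default); ``min1y``
    relaxes it to 1 year; ``per_lookback`` rebuilds the cohort per lookback
    length L with ``required_years = L``, giving algorithm-specific
    denominators.  Identification itself is unchanged; only the eligible
    person set (and hence numerators and denominators) varies.
    """
    out = Path(config.out_dir)
    if config.simulation is not None:
        tables, _ = generate_population(config.simulation)
    else:
        tables = read_claims_tables(config.input_dir)
    specs = get_algorithms(config.algorithms)
    std = STANDARD_POPULATIONS[config.standard]

    def fit_with(spec_cohort: CohortSpec, selected=None) -> pd.DataFrame:
        cohort = build_cohort(tables, spec_cohort)
        from .algorithms import identify_grid

        chosen = selected or specs
        cases = identify_grid(tables, cohort, config.sites, chosen)
        cells = [
            (get_site(s).name, a.label)
            for s in config.sites
            for a in chosen
            if not (a.require_surgery_confirm and not get_site(s).surgery_classes)
        ]
        return stratified_results(cases, cohort, std, config.strata, cells)

    regimes: dict[str, pd.DataFrame] = {}
    regimes["main"] = fit_with(config.cohort)
    regimes["min1y"] = fit_with(dataclasses.replace(config.cohort, required_years=1))

    per_parts = []
    for L in sorted({s.lookback_years for s in specs}):
        sel = [s for s in specs if s.lookback_years == L]
        per_parts.append(
            fit_with(dataclasses.replace(config.cohort, required_years=L), sel)
        )
    regimes["per_lookback"] = pd.concat(per_parts, ignore_index=True)

    out.mkdir(parents=True, exist_ok=True)
    for name, df in regimes.items():
        df.to_csv(out / f"results_{name}.csv", index=False)
    return regimes
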