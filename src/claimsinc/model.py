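"""Model/Results interface over the full identification-and-estimation stack.

``ClaimsIncidenceModel`` is built from claims tables (read from CSV, passed
in memory, or simulated); ``fit()`` applies the selected identification
algorithms and returns a ``ClaimsIncidenceResults`` carrying the incident
cases, stratified crude and age-standardised cumulative incidences, the
exclusion tally, and ``summary()``/``compare()``/``validate()`` methods.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .algorithms import AlgorithmSpec, get_algorithms, identify_grid
from .cohort import CohortResult, CohortSpec, build_cohort, site_denominator
from .data import ClaimsTables, get_site, read_claims_tables
from .incidence import (
    ESP1976,
    StandardPopulation,
    compare_to_registry,
    round_report,
    stratified_results,
    validation_metrics,
)

DEFAULT_SITES = ("breast", "prostate", "colorectal")


class ClaimsIncidenceModel:
    """Incident-cancer-case ascertainment on longitudinal claims data.

    Parameters
    ----------
    tables:
        The five claims tables.
    cohort_spec:
        Continuous-insurance eligibility rule (default: 7 years with gaps
        of at most 28 days, assessed on 2013-01-01).
    sites:
        Cancer entities to analyse.
    standard:
        Standard population for direct age standardisation.
    """

    def __init__(
        self,
        tables: ClaimsTables,
        cohort_spec: CohortSpec | None = None,
        sites: Sequence[str] = DEFAULT_SITES,
        standard: StandardPopulation = ESP1976,
    ):
        self.tables = tables
        self.cohort_spec = cohort_spec or CohortSpec()
        self.sites = tuple(sites)
        self.standard = standard
        self._cohort: CohortResult | None = None

    @classmethod
    def from_csv(cls, directory: str | Path, **kwargs) -> "ClaimsIncidenceModel":
        return cls(read_claims_tables(directory), **kwargs)

    @classmethod
    def from_simulation(cls, config=None, **kwargs) -> "ClaimsIncidenceModel":
        """Build from a synthetic population; ground truth is kept on the model."""
        from .simulate import SimulationConfig, generate_population

        config = config or SimulationConfig()
        tables, truth = generate_population(config)
        model = cls(tables, **kwargs)
        model.ground_truth = truth
        model.simulation_config = config
        return model

    @property
    def cohort(self) -> CohortResult:
        if self._cohort is None:
            self._cohort = build_cohort(self.tables, self.cohort_spec)
        return self._cohort

    def fit(
        self,
        algorithms: str | Sequence[str] | Sequence[AlgorithmSpec] = "all",
        strata: Sequence[str] = ("overall",),
    ) -> "ClaimsIncidenceResults":
        specs = get_algorithms(algorithms)
        cases = identify_grid(self.tables, self.cohort, self.sites, specs)
        cells = [
            (get_site(s).name, a.label)
            for s in self.sites
            for a in specs
            if not (a.require_surgery_confirm and not get_site(s).surgery_classes)
        ]
        results = stratified_results(cases, self.cohort, self.standard, strata, cells)
        return ClaimsIncidenceResults(self, specs, cases, results, strata)


class ClaimsIncidenceResults:
    """Fit output: incident cases plus stratified incidence estimates.

    Attributes
    ----------
    cases:
        One row per person × site × algorithm accepted as incident.
    results:
        site × algorithm × stratum table with numerator, denominator,
        crude (CCI) and age-standardised (ACI) cumulative incidence per
        100,000 (unrounded; ``summary()`` rounds for display).
    """

    def __init__(self, model, specs, cases: pd.DataFrame, results: pd.DataFrame, strata):
        self.model = model
        self.algorithms = specs
        self.cases = cases
        self.results = results
        self.strata = tuple(strata)
        self.cohort = model.cohort
        self.exclusions = model.cohort.exclusions

    def numerators(self) -> pd.DataFrame:
        """Case counts per site × algorithm (overall stratum)."""
        ov = self.results[self.results["stratum_type"] == "overall"]
        return ov.pivot(index="algorithm_label", columns="site", values="numerator")

    def summary(self) -> str:
        """Per-site table of numerators, CCI and ACI per 100,000."""
        lines = []
        labels = [a.label for a in self.algorithms]
        ov = self.results[self.results["stratum_type"] == "overall"]
        lines.append("Incident cancer cases and cumulative incidences per 100,000")
        spec = self.model.cohort_spec
        lines.append(
            f"Cohort: {len(self.cohort):,} persons with >= {spec.required_years} y "
            f"continuous insurance (gaps <= {spec.max_gap_days} d) on {spec.reference_date}"
        )
        for site_name in self.model.sites:
            site = get_site(site_name)
            denom = site_denominator(self.cohort, site)
            lines.append("")
            lines.append(f"{site.name.title()} — denominator n = {denom:,}")
            lines.append(f"{'Algorithm':<12}{'Num.':>8}{'CCI':>10}{'ACI':>10}")
            sub = ov[ov["site"] == site.name].set_index("algorithm_label")
            for label in labels:
                if label not in sub.index:
                    lines.append(f"{label:<12}{'N/A':>8}{'N/A':>10}{'N/A':>10}")
                    continue
                r = sub.loc[label]
                lines.append(
                    f"{label:<12}{int(r['numerator']):>8}"
                    f"{round_report(r['cci']):>10.1f}{round_report(r['aci']):>10.1f}"
                )
        return "\n".join(lines)

    def compare(self, registry: pd.DataFrame) -> pd.DataFrame:
        """Percent differences of claims ACI against a registry table."""
        return compare_to_registry(self.results, registry)

    def validate(self, ground_truth: pd.DataFrame | None = None) -> pd.DataFrame:
        """Sensitivity/PPV per site × algorithm against ground truth."""
        if ground_truth is None:
            ground_truth = getattr(self.model, "ground_truth", None)
        if ground_truth is None:
            raise ValueError("no ground-truth table available")
        rows = []
        for site_name in self.model.sites:
            site = get_site(site_name)
            for spec in self.algorithms:
                if spec.require_surgery_confirm and not site.surgery_classes:
                    continue
                m = validation_metrics(
                    self.cases, ground_truth, self.cohort, site, spec.label
                )
                rows.append({"site": site.name, "algorithm_label": spec.label, **m})
        return pd.DataFrame(rows)

    def to_csv(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "cases": directory / "cases.csv",
            "results": directory / "results.csv",
        }
        self.cases.to_csv(paths["cases"], index=False)
        self.results.to_csv(paths["results"], index=False)
        return paths

    def plot_benchmark(self, registry: pd.DataFrame, site: str, ax=None):
        from .plotting import benchmark_bar

        return benchmark_bar(self, registry, site, ax=ax)
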