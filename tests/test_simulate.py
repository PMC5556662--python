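"""Synthetic-population generator: determinism, invariants, calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from claimsinc.data import SITES
from claimsinc.errors import ConfigError
from claimsinc.simulate import (
    CodingModel,
    EnrollmentModel,
    SimulationConfig,
    SiteDiseaseModel,
    generate_population,
    generate_registry_benchmark,
    sample_recurrence_latency,
)


def zero_disease_config(n=400, seed=1, **coding_overrides):
    disease = {
        name: SiteDiseaseModel(
            hazard_by_age=((0, 0.0),),
            prevalence_at_start=0.0,
            recurrence_prob=0.0,
            recurrence_latency_mean_q=8.0,
            case_fatality_per_quarter=0.0,
        )
        for name in ("BREAST", "PROSTATE", "COLORECTAL")
    }
    coding_kwargs = {"suspected_only_rate": 0.0, "stray_code_rate": 0.0}
    coding_kwargs.update(coding_overrides)
    coding = CodingModel(**coding_kwargs)
    return SimulationConfig(n_persons=n, seed=seed, disease=disease, coding=coding)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            CodingModel(p_index_coded=1.2)
        with pytest.raises(ConfigError):
            EnrollmentModel(p_full_span=-0.1)
        with pytest.raises(ConfigError):
            SimulationConfig(sex_female_prob=2.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_persons=10, seed=5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg

    def test_shipped_default_config_matches_code_defaults(self):
        from pathlib import Path

        path = Path(__file__).resolve().parents[1] / "examples" / "default_sim.yaml"
        assert SimulationConfig.from_yaml(path) == SimulationConfig()


class TestGeneratorContracts:
    def test_zero_hazard_no_cancer_diagnoses(self):
        tables, truth = generate_population(zero_disease_config())
        cancer = tables.outpatient["icd_code"].str.upper().str.slice(0, 3).isin(
            {p for s in SITES.values() for p in s.icd_prefixes}
        )
        assert not cancer.any()
        assert tables.inpatient.empty and tables.procedures.empty
        assert (truth["case_type"] == "NONE").all()

    def test_determinism_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_persons=300, seed=11)
        for d in ("a", "b"):
            tables, truth = generate_population(cfg)
            tables.write(tmp_path / d)
            truth.to_csv(tmp_path / d / "ground_truth.csv", index=False)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        t1, _ = generate_population(SimulationConfig(n_persons=300, seed=1))
        t2, _ = generate_population(SimulationConfig(n_persons=300, seed=2))
        assert not t1.outpatient.equals(t2.outpatient)

    def test_events_belong_to_generated_persons(self, default_sim):
        _, tables, truth = default_sim
        pids = set(tables.persons["person_id"])
        for df in (tables.spells, tables.outpatient, tables.inpatient,
                   tables.procedures):
            assert set(df["person_id"]) <= pids
        assert set(truth["person_id"]) == pids
        assert len(truth) == 3 * len(pids)

    def test_no_event_outside_coverage_or_after_death(self, default_sim):
        _, tables, _ = default_sim
        first_spell = (
            pd.to_datetime(tables.spells.groupby("person_id")["start"].min())
        )
        death = tables.persons.set_index("person_id")["death_date"]
        oq = tables.outpatient.copy()
        oq["year"] = oq["quarter"].str.slice(0, 4).astype(int)
        start_year = first_spell.dt.year.reindex(oq["person_id"]).to_numpy()
        assert (oq["year"].to_numpy() >= start_year).all()
        dq = death.reindex(oq["person_id"]).to_numpy()
        has_death = dq != ""
        death_q = (
            pd.to_datetime(pd.Series(dq[has_death])).dt.year * 4
            + (pd.to_datetime(pd.Series(dq[has_death])).dt.month - 1) // 3
        ).to_numpy()
        ev_q = (
            oq["year"].to_numpy()[has_death] * 4
            + (oq["quarter"].str.slice(5, 6).astype(int).to_numpy()[has_death] - 1)
        )
        assert (ev_q <= death_q).all()

    def test_incident_2013_label_iff_2013_onset(self, default_sim):
        _, _, truth = default_sim
        has_onset = truth["true_onset_quarter"] != ""
        year = truth.loc[has_onset, "true_onset_quarter"].str.slice(0, 4).astype(int)
        lbl = truth.loc[has_onset, "case_type"]
        assert ((year == 2013) == (lbl == "INCIDENT_2013")).all()
        assert (truth.loc[~has_onset, "case_type"].isin(["NONE", "SUSPECTED_ONLY"])).all()


class TestCalibration:
    def test_incident_fraction_matches_closed_form(self):
        h = 8e-4
        cfg = SimulationConfig.perfect_coding(n_persons=20_000, seed=9, hazard=h)
        _, truth = generate_population(cfg)
        # exact single-onset model: disease-free 2006-2012, onset in 2013
        p = (1 - h) ** 28 * (1 - (1 - h) ** 4)
        n = cfg.n_persons  # every person is sex-eligible for >= 1 site
        count = (
            truth[truth["site"] != "BREAST"]  # both-sex site: colorectal + prostate
            .groupby("site")["case_type"]
            .apply(lambda s: (s == "INCIDENT_2013").sum())
        )
        # colorectal applies to everyone: cleanest binomial comparison
        k = int(count["COLORECTAL"])
        lo, hi = stats.binom.interval(0.999, n, p)
        assert lo <= k <= hi

    def test_suspected_only_rate_binomial(self):
        v = 0.05
        cfg = zero_disease_config(n=3000, seed=13, suspected_only_rate=v)
        tables, truth = generate_population(cfg)
        is_breast = tables.outpatient["icd_code"].str.startswith("C50")
        v_only = tables.outpatient[is_breast]
        assert (v_only["certainty"] == "V").all()
        women = tables.persons["sex"] == "F"
        n_disease_free = int(women.sum())  # no disease at all in this config
        k = v_only["person_id"].nunique()
        lo, hi = stats.binom.interval(0.999, n_disease_free, v)
        assert lo <= k <= hi

    def test_recurrence_latency_mean_recovered(self):
        rng = np.random.default_rng(7)
        mean = 8.0
        draws = [sample_recurrence_latency(rng, mean) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(mean, rel=0.05)


class TestRegistryBenchmark:
    def test_zero_incidence_gives_zero_aci(self):
        tables, truth = generate_population(zero_disease_config())
        bench = generate_registry_benchmark(truth, tables.persons)
        assert (bench["aci"].dropna() == 0).all()

    def test_single_state_onsets_zero_elsewhere(self):
        tables, truth = generate_population(
            SimulationConfig(n_persons=2000, seed=21)
        )
        persons = tables.persons.copy()
        persons["state"] = "HB"  # relocate everyone to one state
        bench = generate_registry_benchmark(truth, persons)
        other = bench[(bench["state"] != "HB") & (bench["state"] != "ALL")]
        assert other["aci"].isna().all()  # no residents, no denominator
        hb = bench[(bench["state"] == "HB") & (bench["sex"] == "ALL")
                   & (bench["site"] == "COLORECTAL")]
        allde = bench[(bench["state"] == "ALL") & (bench["sex"] == "ALL")
                      & (bench["site"] == "COLORECTAL")]
        assert hb["aci"].iloc[0] == pytest.approx(allde["aci"].iloc[0])

    def test_hand_built_truth_matches_manual_standardisation(self):
        persons = pd.DataFrame(
            {
                "person_id": ["A", "B", "C", "D"],
                "sex": ["F", "F", "F", "F"],
                "birth_year": ["1950", "1950", "1980", "1980"],  # ages 63, 33
                "state": ["NW", "NW", "NW", "NW"],
                "death_date": ["", "", "", ""],
            }
        )
        truth = pd.DataFrame(
            {
                "person_id": ["A", "C", "D"],
                "site": ["BREAST", "BREAST", "COLORECTAL"],
                "true_onset_quarter": ["2013Q1", "2013Q2", "2013Q3"],
                "case_type": ["INCIDENT_2013", "INCIDENT_2013", "INCIDENT_2013"],
            }
        )
        bench = generate_registry_benchmark(truth, persons)
        # breast, NW: band 60-64 (w 5000) rate 1/2, band 30-34 (w 7000) rate 1/2
        expected = 100_000 * (5000 * 0.5 + 7000 * 0.5) / 100_000
        got = bench[(bench["site"] == "BREAST") & (bench["sex"] == "F")
                    & (bench["state"] == "NW")]["aci"].iloc[0]
        assert got == pytest.approx(expected)
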