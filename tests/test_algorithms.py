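"""Identification rules: index, lookback, confirmation, grid, oracle equivalence."""
import datetime as dt

import pytest

from claimsinc.algorithms import (
    AlgorithmSpec,
    algorithm_grid,
    find_index_quarter,
    get_algorithms,
    identify_grid,
    identify_incident_cases,
    passes_confirmation,
    passes_lookback,
)
from claimsinc.cohort import CohortSpec, build_cohort
from claimsinc.data import (
    BREAST,
    COLORECTAL,
    PROSTATE,
    ClaimsTables,
    InpatientDx,
    OutpatientDx,
    ProcedureRecord,
    Quarter,
)
from claimsinc.errors import ConfigError, IncompatibleAlgorithmError

from conftest import full_coverage_person
from populations import random_population


def outp(q, code="C50.1", cert="G", pid="P1"):
    return OutpatientDx(pid, Quarter.parse(q), code, cert)


class TestAlgorithmGrid:
    def test_exactly_fifteen_with_expected_labels(self):
        grid = algorithm_grid()
        assert len(grid) == 15
        labels = [a.label for a in grid]
        assert labels[:7] == [f"L{i}-C1" for i in range(1, 8)]
        assert set(labels[7:]) == {
            "L1-C4", "L7-C4", "L1-C0", "L7-C0",
            "L1-C1-ed", "L7-C1-ed", "L1-C4-su", "L7-C4-su",
        }

    def test_variant_flags(self):
        by = {a.label: a for a in algorithm_grid()}
        assert by["L7-C4-su"].lookback_years == 7
        assert by["L7-C4-su"].confirmation_quarters == 4
        assert by["L7-C4-su"].require_surgery_confirm
        assert not by["L1-C0"].require_confirmation
        assert not by["L1-C1-ed"].allow_death_confirm
        baseline = by["L1-C1"]
        assert baseline.allow_death_confirm and not baseline.require_surgery_confirm

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(ConfigError):
            AlgorithmSpec("bad", 1, 0)  # C=0 but confirmation required
        with pytest.raises(ConfigError):
            AlgorithmSpec("bad", 1, 1, require_confirmation=False)
        with pytest.raises(ConfigError):
            get_algorithms("L9-C9")


class TestIndexQuarter:
    def test_single_candidate(self):
        assert find_index_quarter([outp("2013Q2")], [], BREAST) == Quarter(2013, 2)

    def test_suspected_marker_never_indexes(self):
        events = [outp("2013Q1", "C61", "V"), outp("2013Q3", "C61", "G")]
        assert find_index_quarter(events, [], PROSTATE) == Quarter(2013, 3)

    def test_earliest_quarter_across_settings(self):
        o = [outp("2013Q3", "C18.2")]
        i = [InpatientDx("P1", dt.date(2013, 2, 1), dt.date(2013, 2, 10),
                         "C18.2", "MAIN_DISCHARGE")]
        assert find_index_quarter(o, i, COLORECTAL) == Quarter(2013, 1)

    def test_ancillary_and_status_post_never_index(self):
        o = [outp("2013Q2", "C50.1", "Z")]
        i = [InpatientDx("P1", dt.date(2013, 5, 1), dt.date(2013, 5, 3),
                         "C50.1", "ANCILLARY")]
        assert find_index_quarter(o, i, BREAST) is None


class TestLookback:
    def test_clean_history_passes(self):
        assert passes_lookback([], [], BREAST, Quarter(2013, 2), 1)

    def test_status_post_counts_in_lookback(self):
        prior = [outp("2012Q4", cert="Z")]
        assert not passes_lookback(prior, [], BREAST, Quarter(2013, 2), 1)

    def test_window_is_4L_quarters(self):
        # ancillary inpatient 7 quarters before the index
        i = [InpatientDx("P1", dt.date(2011, 8, 1), dt.date(2011, 8, 5),
                         "C20", "ANCILLARY")]
        idx = Quarter(2013, 2)
        assert passes_lookback([], i, COLORECTAL, idx, 1)
        assert not passes_lookback([], i, COLORECTAL, idx, 2)


class TestConfirmation:
    def test_status_post_confirms(self):
        spec = get_algorithms("L1-C1")[0]
        conf = [outp("2013Q3", cert="Z")]
        assert passes_confirmation(conf, [], BREAST, Quarter(2013, 2), spec) == "SECOND_DIAGNOSIS"

    def test_same_quarter_diagnosis_never_confirms(self):
        spec = get_algorithms("L1-C1")[0]
        conf = [outp("2013Q2", cert="Z")]
        assert passes_confirmation(conf, [], BREAST, Quarter(2013, 2), spec) is None

    def test_death_in_index_quarter_confirms(self):
        spec = get_algorithms("L1-C1")[0]
        kind = passes_confirmation(
            [], [], BREAST, Quarter(2013, 2), spec, death_date=dt.date(2013, 5, 10)
        )
        assert kind == "DEATH"

    def test_death_excluded_variant(self):
        spec = get_algorithms("L1-C1-ed")[0]
        kind = passes_confirmation(
            [], [], BREAST, Quarter(2013, 2), spec, death_date=dt.date(2013, 5, 10)
        )
        assert kind is None

    def test_confirmation_window_length(self):
        conf = [outp("2014Q4", cert="G")]
        c4 = get_algorithms("L7-C4")[0]
        c1 = get_algorithms("L7-C1")[0]
        idx = Quarter(2013, 4)
        assert passes_confirmation(conf, [], BREAST, idx, c4) == "SECOND_DIAGNOSIS"
        assert passes_confirmation(conf, [], BREAST, idx, c1) is None

    def test_surgery_required_is_necessary_and_sufficient(self):
        spec = get_algorithms("L1-C4-su")[0]
        procs = [ProcedureRecord("P1", dt.date(2013, 8, 1), "LUMPECTOMY")]
        assert passes_confirmation([], [], BREAST, Quarter(2013, 2), spec,
                                   procedures=procs) == "SURGERY"
        # a second diagnosis alone does not satisfy the surgery variant
        conf = [outp("2013Q3", cert="G")]
        assert passes_confirmation(conf, [], BREAST, Quarter(2013, 2), spec) is None

    def test_endoscopy_or_surgery_confirms_colorectal(self):
        spec = get_algorithms("L1-C4-su")[0]
        for pc in ("ENDOSCOPY", "COLORECTAL_SURGERY"):
            procs = [ProcedureRecord("P1", dt.date(2013, 8, 1), pc)]
            assert passes_confirmation([], [], COLORECTAL, Quarter(2013, 2), spec,
                                       procedures=procs) == "SURGERY"

    def test_prostate_surgery_variant_incompatible(self):
        spec = get_algorithms("L1-C4-su")[0]
        with pytest.raises(IncompatibleAlgorithmError):
            passes_confirmation([], [], PROSTATE, Quarter(2013, 2), spec)


class TestIdentifyEngine:
    def cohort_for(self, tables):
        return build_cohort(tables, CohortSpec())

    def test_empty_tables_empty_cases(self):
        tables = ClaimsTables.from_records([full_coverage_person("P1")])
        cases = identify_incident_cases(tables, self.cohort_for(tables), BREAST,
                                        get_algorithms("L1-C1")[0])
        assert cases.empty

    def test_dual_cancer_counted_in_each_entity(self):
        p = full_coverage_person("P1", sex="F")
        events = [
            outp("2013Q1", "C50.1"), outp("2013Q2", "C50.9", "Z"),
            outp("2013Q1", "C18.2"), outp("2013Q2", "C19", "Z"),
        ]
        tables = ClaimsTables.from_records([p], events)
        cases = identify_grid(tables, self.cohort_for(tables),
                              ["breast", "colorectal"], "L1-C1")
        assert set(cases["site"]) == {"BREAST", "COLORECTAL"}
        assert (cases["person_id"] == "P1").all() and len(cases) == 2

    def test_person_never_counted_twice_per_site(self):
        p = full_coverage_person("P1", sex="F")
        events = [outp("2013Q1"), outp("2013Q2"), outp("2013Q3"), outp("2013Q4")]
        tables = ClaimsTables.from_records([p], events)
        cases = identify_incident_cases(tables, self.cohort_for(tables), BREAST,
                                        get_algorithms("L1-C1")[0])
        assert len(cases) == 1
        assert cases["index_quarter"].iloc[0] == "2013Q1"

    def test_sex_incompatible_person_skipped(self):
        p = full_coverage_person("P1", sex="M")
        tables = ClaimsTables.from_records([p], [outp("2013Q1"), outp("2013Q2")])
        cases = identify_incident_cases(tables, self.cohort_for(tables), BREAST,
                                        get_algorithms("L1-C1")[0])
        assert cases.empty

    def test_prostate_surgery_grid_cell_raises_unless_skipped(self):
        p = full_coverage_person("P1", sex="M")
        tables = ClaimsTables.from_records([p])
        cohort = self.cohort_for(tables)
        with pytest.raises(IncompatibleAlgorithmError):
            identify_incident_cases(tables, cohort, PROSTATE,
                                    get_algorithms("L1-C4-su")[0])
        grid_cases = identify_grid(tables, cohort, ["prostate"], "all")
        assert set(grid_cases["algorithm_label"]) <= {
            a.label for a in algorithm_grid() if not a.require_surgery_confirm
        }

    def test_idempotent(self, default_sim, default_sim_cohort):
        _, tables, _ = default_sim
        spec = get_algorithms("L1-C1")[0]
        a = identify_incident_cases(tables, default_sim_cohort, BREAST, spec)
        b = identify_incident_cases(tables, default_sim_cohort, BREAST, spec)
        assert a.equals(b)


class TestOracleEquivalence:
    """The vectorised engine must agree with a brute-force re-derivation."""

    @pytest.mark.parametrize("seed", range(40))
    def test_random_small_populations(self, seed):
        from claimsinc.algorithms import SiteEventIndex
        from oracle import oracle_case_sets

        tables = random_population(seed, n_persons=15)
        cohort = build_cohort(tables, CohortSpec())
        for site in ("BREAST", "PROSTATE", "COLORECTAL"):
            specs = [
                s for s in algorithm_grid()
                if not (s.require_surgery_confirm and site == "PROSTATE")
            ]
            expected = oracle_case_sets(tables, cohort.frame, site, specs)
            ev = SiteEventIndex(tables, site.lower())
            for spec in specs:
                engine = identify_incident_cases(
                    tables, cohort, site.lower(), spec, events=ev
                )
                got = {
                    r["person_id"]: (Quarter.parse(r["index_quarter"]).index,
                                     r["confirm_kind"])
                    for _, r in engine.iterrows()
                }
                assert got == expected[spec.label], f"{site} {spec.label} seed={seed}"


@pytest.fixture(scope="module")
def grid_cases(default_sim, default_sim_cohort):
    _, tables, _ = default_sim
    return identify_grid(tables, default_sim_cohort)


class TestMonotonicity:
    def counts(self, cases, site):
        sub = cases[cases["site"] == site]
        return sub.groupby("algorithm_label")["person_id"].count().to_dict()

    @pytest.mark.parametrize("site", ["BREAST", "PROSTATE", "COLORECTAL"])
    def test_numerator_non_increasing_in_lookback(self, grid_cases, site):
        n = self.counts(grid_cases, site)
        seq = [n.get(f"L{L}-C1", 0) for L in range(1, 8)]
        assert seq == sorted(seq, reverse=True)

    @pytest.mark.parametrize("site", ["BREAST", "PROSTATE", "COLORECTAL"])
    def test_confirmation_ordering(self, grid_cases, site):
        n = self.counts(grid_cases, site)
        for L in (1, 7):
            assert n.get(f"L{L}-C4", 0) >= n.get(f"L{L}-C1", 0)
            assert n.get(f"L{L}-C1", 0) >= n.get(f"L{L}-C1-ed", 0)
            assert n.get(f"L{L}-C0", 0) >= max(
                n.get(f"L{L}-C4", 0), n.get(f"L{L}-C1", 0)
            )

    @pytest.mark.parametrize("site", ["BREAST", "COLORECTAL"])
    def test_surgery_cases_subset_of_c4(self, grid_cases, site):
        sub = grid_cases[grid_cases["site"] == site]
        for L in (1, 7):
            su = set(sub.loc[sub["algorithm_label"] == f"L{L}-C4-su", "person_id"])
            c4 = set(sub.loc[sub["algorithm_label"] == f"L{L}-C4", "person_id"])
            assert su <= c4
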