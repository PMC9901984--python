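"""LR estimation: labeling, counting, smoothing, rollup, and a brute-force oracle."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmindex.icd import parse_icd9
from mmindex.lr import (
    CohortError,
    DiagnosisCount,
    count_diagnoses,
    fit_lr_table,
    label_outcomes,
    raw_lr,
)

from conftest import make_diagnoses, make_outcomes


def brute_force_lr_table(diagnoses, outcomes, horizon_days=183, min_cases=100):
    """Independent recount, straight from the definition.

    Labels each patient, collects each patient's distinct codes, and for
    every code computes prevalence among dead over prevalence among
    alive with the all-die/all-survive smoothing; codes with fewer than
    min_cases carriers pool carriers of observed codes under the parent,
    then under the category.  Dict {canonical: lr}.
    """
    idx = pd.to_datetime(outcomes["index_date"])
    death = pd.to_datetime(outcomes["death_date"])
    status = {}
    for i, pid in enumerate(outcomes["patient_id"]):
        if pd.notna(death.iloc[i]) and (death.iloc[i] - idx.iloc[i]).days < 0:
            continue
        status[pid] = (
            pd.notna(death.iloc[i]) and (death.iloc[i] - idx.iloc[i]).days <= horizon_days
        )
    carriers = {}
    by_pid = dict(zip(outcomes["patient_id"], pd.to_datetime(outcomes["index_date"])))
    for _, row in diagnoses.iterrows():
        pid = row["patient_id"]
        if pid not in status or pd.to_datetime(row["date"]) > by_pid[pid]:
            continue
        canon = parse_icd9(row["code"]).canonical_text
        carriers.setdefault(canon, set()).add(pid)
    N_dead = sum(status.values())
    N_alive = len(status) - N_dead

    def lr_of(patients):
        nd = sum(status[p] for p in patients)
        na = len(patients) - nd
        if na == 0:
            return len(patients) + 1
        if nd == 0:
            return 1 / (len(patients) + 1)
        return (nd / N_dead) / (na / N_alive)

    out = {}
    for canon, pats in carriers.items():
        code = parse_icd9(canon)
        pool = pats
        if len(pats) < min_cases and code.depth > 3:
            chain = []
            node = code.parent()
            while node is not None:
                chain.append(node)
                node = node.parent()
            for ancestor in chain:
                pool = set()
                prefix = ancestor.canonical_text
                for other, other_pats in carriers.items():
                    o = parse_icd9(other)
                    if (
                        o.flavor == code.flavor
                        and o.category == code.category
                        and other.startswith(prefix)
                    ):
                        pool |= other_pats
                if len(pool) >= min_cases or ancestor.depth == 3:
                    break
        out[canon] = lr_of(pool)
    return out


class TestLabelOutcomes:
    def test_death_inside_horizon_is_dead(self):
        out = make_outcomes(1, 0)
        out.loc[0, "death_date"] = out.loc[0, "index_date"] + pd.Timedelta(days=100)
        labels, _ = label_outcomes(out, 183)
        assert labels.iloc[0]

    def test_blank_death_date_means_alive(self):
        labels, _ = label_outcomes(make_outcomes(0, 3), 183)
        assert not labels.any()

    def test_death_after_horizon_is_alive(self):
        out = make_outcomes(1, 0)
        out.loc[0, "death_date"] = out.loc[0, "index_date"] + pd.Timedelta(days=200)
        labels, _ = label_outcomes(out, 183)
        assert not labels.iloc[0]

    def test_death_before_index_excluded_and_reported(self):
        out = make_outcomes(2, 1)
        out.loc[0, "death_date"] = out.loc[0, "index_date"] - pd.Timedelta(days=5)
        labels, excluded = label_outcomes(out, 183)
        assert len(excluded) == 1
        assert out.loc[0, "patient_id"] not in labels.index
        assert len(labels) == 2


class TestCounting:
    def test_repeat_records_count_one_carrier(self, toy_cohort):
        diag, outcomes = toy_cohort
        labels, _ = label_outcomes(outcomes)
        counts = {c.code.canonical_text: c for c in count_diagnoses(diag, labels)}
        # P00000 (dead) has two records of 4275 but contributes once
        assert counts["4275"].n_dead == 2  # P00000 and P00001
        assert counts["4275"].n_alive == 1  # P00003

    def test_direct_tally(self):
        c = DiagnosisCount(parse_icd9("4275"), 20, 45, 100, 900)
        assert c.n_total == 65

    def test_unlabeled_patient_is_error(self, toy_cohort):
        diag, outcomes = toy_cohort
        labels, _ = label_outcomes(outcomes.iloc[1:])
        with pytest.raises(CohortError, match="P00000"):
            count_diagnoses(diag, labels)


class TestRawLR:
    def test_two_sided_formula(self):
        c = DiagnosisCount(parse_icd9("4275"), 20, 45, 100, 900)
        assert raw_lr(c) == pytest.approx(4.0)

    def test_all_die_smoothing(self):
        c = DiagnosisCount(parse_icd9("4275"), 5, 0, 50, 500)
        assert raw_lr(c) == 6.0

    def test_all_survive_smoothing(self):
        c = DiagnosisCount(parse_icd9("4275"), 0, 9, 50, 500)
        assert raw_lr(c) == pytest.approx(0.1)

    def test_equal_prevalence_is_unity(self):
        c = DiagnosisCount(parse_icd9("4275"), 10, 90, 100, 900)
        assert raw_lr(c) == pytest.approx(1.0)

    def test_zero_carriers_error(self):
        c = DiagnosisCount(parse_icd9("4275"), 0, 0, 100, 900)
        with pytest.raises(CohortError):
            raw_lr(c)


def _rollup_cohort():
    """40 carriers of 038.12, 40 of 038.11, 300 of 038.0; plus anchor patients."""
    rows = []
    n_dead, n_alive = 0, 0

    def add(code, nd, na):
        nonlocal n_dead, n_alive
        for _ in range(nd):
            rows.append((True, code))
        for _ in range(na):
            rows.append((False, code))

    add("038.12", 10, 30)
    add("038.11", 5, 35)
    add("038.0", 60, 240)
    add("427.5", 50, 100)
    dead = [r for r in rows if r[0]]
    alive = [r for r in rows if not r[0]]
    # pad with diagnosis-free patients so the cohort has both classes beyond carriers
    outcomes = make_outcomes(len(dead) + 20, len(alive) + 20)
    assignments = []
    pids = outcomes["patient_id"].tolist()
    for i, (_, code) in enumerate(dead):
        assignments.append((pids[i], code))
    for i, (_, code) in enumerate(alive):
        assignments.append((pids[len(dead) + 20 + i], code))
    return make_diagnoses(assignments), outcomes


class TestRollup:
    def test_two_step_rollup_to_category(self):
        """038.12 (40 carriers) -> 038.1 pool (80, still rare) -> 038 pool (380)."""
        diag, outcomes = _rollup_cohort()
        table = fit_lr_table(diag, outcomes, min_cases=100)
        e = table.entries["03812"]
        assert e.rollup_depth == 2
        assert e.source_code == parse_icd9("038")
        # 038 pool: 75 dead + 305 alive carriers; hand recount
        N_dead, N_alive = table.n_dead_total, table.n_alive_total
        assert e.lr == pytest.approx((75 / N_dead) / (305 / N_alive))

    def test_parent_pool_used_when_big_enough(self):
        diag, outcomes = _rollup_cohort()
        table = fit_lr_table(diag, outcomes, min_cases=60)
        e = table.entries["03812"]
        assert e.rollup_depth == 1
        assert e.source_code == parse_icd9("038.1")
        N_dead, N_alive = table.n_dead_total, table.n_alive_total
        assert e.lr == pytest.approx((15 / N_dead) / (65 / N_alive))

    def test_threshold_boundary_keeps_own_lr(self):
        """Exactly min_cases carriers -> no rollup; one fewer -> rollup."""
        diag, outcomes = _rollup_cohort()
        table = fit_lr_table(diag, outcomes, min_cases=40)
        assert table.entries["03812"].rollup_depth == 0  # exactly 40 carriers
        table99 = fit_lr_table(diag, outcomes, min_cases=41)
        assert table99.entries["03812"].rollup_depth >= 1

    def test_raising_min_cases_never_unrolls(self):
        diag, outcomes = _rollup_cohort()
        rolled = []
        for mc in (1, 40, 60, 100, 500):
            table = fit_lr_table(diag, outcomes, min_cases=mc)
            rolled.append(sum(e.rollup_depth > 0 for e in table.entries.values()))
        assert rolled == sorted(rolled)

    def test_depth4_rare_code_rolls_to_category(self):
        diag, outcomes = _rollup_cohort()
        table = fit_lr_table(diag, outcomes, min_cases=1000)
        e = table.entries["4275"]  # 150 carriers, still < 1000
        assert e.rollup_depth == 1
        assert e.source_code == parse_icd9("427")

    def test_category_code_keeps_own_lr_when_rare(self):
        """A rare 3-digit code has no broader within-category concept."""
        outcomes = make_outcomes(2, 8)
        diag = make_diagnoses([("P00000", "486"), ("P00002", "486")])
        table = fit_lr_table(diag, outcomes, min_cases=100)
        e = table.entries["486"]
        assert e.rollup_depth == 0
        assert e.source_code == parse_icd9("486")


def test_record_unit_trigger_counts_rows_not_patients():
    """With min_cases_unit='records', repeat records can avert a rollup."""
    outcomes = make_outcomes(2, 8)
    pids = outcomes["patient_id"].tolist()
    diag = make_diagnoses([(pids[0], "156.8")] * 3 + [(pids[3], "156.0")] * 4)
    by_patients = fit_lr_table(diag, outcomes, min_cases=3)
    assert by_patients.entries["1568"].rollup_depth == 1  # one carrier < 3
    by_records = fit_lr_table(diag, outcomes, min_cases=3, min_cases_unit="records")
    assert by_records.entries["1568"].rollup_depth == 0  # three records >= 3


class TestFitLRTable:
    def test_structural_one_entry_per_code(self, toy_cohort):
        diag, outcomes = toy_cohort
        table = fit_lr_table(diag, outcomes, min_cases=1)
        assert set(table.entries) == {"4275", "5188", "25000"}

    def test_deterministic(self, toy_cohort):
        diag, outcomes = toy_cohort
        t1 = fit_lr_table(diag, outcomes, min_cases=1)
        t2 = fit_lr_table(diag.sample(frac=1, random_state=0), outcomes, min_cases=1)
        assert t1.entries == t2.entries

    def test_degenerate_cohorts_error(self):
        with pytest.raises(CohortError):
            fit_lr_table(make_diagnoses([]), make_outcomes(0, 0))
        diag = make_diagnoses([("P00000", "4275")])
        with pytest.raises(CohortError):
            fit_lr_table(diag, make_outcomes(0, 5))  # zero deaths
        with pytest.raises(CohortError):
            fit_lr_table(diag, make_outcomes(5, 0))  # zero survivors

    def test_diagnoses_after_index_ignored(self):
        outcomes = make_outcomes(2, 3)
        diag = make_diagnoses([("P00000", "4275"), ("P00001", "4275")])
        diag.loc[1, "date"] = pd.Timestamp("2012-01-01") + pd.Timedelta(days=5)
        table = fit_lr_table(diag, outcomes, min_cases=1)
        assert table.entries["4275"].n_total == 1


@st.composite
def small_cohorts(draw):
    n = draw(st.integers(6, 50))
    n_dead = draw(st.integers(1, n - 1))
    codes = ["4275", "42751", "0381", "03812", "03810", "25000", "V667", "E9991"]
    assignments = []
    for i in range(n):
        k = draw(st.integers(0, 3))
        for c in draw(st.lists(st.sampled_from(codes), min_size=k, max_size=k)):
            assignments.append((f"P{i:05d}", c))
    return n_dead, n - n_dead, assignments


@given(small_cohorts(), st.sampled_from([1, 2, 5, 100]))
def test_matches_brute_force_oracle(cohort, min_cases):
    """fit_lr_table agrees with an independent direct recount on small cohorts."""
    n_dead, n_alive, assignments = cohort
    outcomes = make_outcomes(n_dead, n_alive)
    diag = make_diagnoses(assignments)
    if not assignments:
        return
    table = fit_lr_table(diag, outcomes, min_cases=min_cases)
    oracle = brute_force_lr_table(diag, outcomes, min_cases=min_cases)
    assert set(table.entries) == set(oracle)
    for canon, expected in oracle.items():
        got = table.entries[canon].lr
        assert got == pytest.approx(expected), canon
        assert np.isfinite(got) and got > 0
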