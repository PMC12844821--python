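"""Plausibility screen: energy reconciliation, ratio rules, boundaries."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodagg.model import (
    ENERGY_MISMATCH,
    IMPROBABLE_VALUE,
    MISSING_IMAGE_PROXY,
    SFA_GT_FAT,
    SUGARS_GT_CARB,
    NutrientProfile,
)
from foodagg.qc import QCConfig, compute_energy, qc_filter, qc_screen, reason_counts

from conftest import make_record


def reference_energy(p, c, f, fib=0.0, pol=0.0, polyols_within_carb=True):
    """Independent hand-arithmetic oracle for the energy computation."""
    if polyols_within_carb:
        carb_term = max(c - pol, 0.0)
    else:
        carb_term = c
    return 4.0 * p + 4.0 * carb_term + 9.0 * f + 2.0 * fib + 2.4 * pol


class TestComputeEnergy:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            (dict(protein=10, carbohydrate=0, total_fat=0), 40.0),
            (dict(protein=5, total_fat=2, carbohydrate=20, fiber=3, polyols=0), 124.0),
            (dict(protein=0, carbohydrate=0, total_fat=0), 0.0),
        ],
    )
    def test_printed_factor_arithmetic(self, profile, expected):
        assert compute_energy(NutrientProfile(**profile)) == pytest.approx(expected)

    def test_missing_macronutrient_not_computable(self):
        assert compute_energy(NutrientProfile(protein=5, total_fat=2)) is None

    def test_polyols_exceeding_carbohydrate_clamped(self):
        # carb term clamps at 0; polyols still contribute 2.4 kcal/g
        e = compute_energy(NutrientProfile(protein=0, total_fat=0, carbohydrate=2, polyols=5))
        assert e == pytest.approx(2.4 * 5)

    def test_polyols_outside_carbohydrate_config(self):
        cfg = QCConfig(polyols_within_carbohydrate=False)
        e = compute_energy(
            NutrientProfile(protein=0, total_fat=0, carbohydrate=10, polyols=5), cfg
        )
        assert e == pytest.approx(40 + 12.0)

    def test_random_profiles_match_hand_oracle(self):
        rng = random.Random(42)
        for _ in range(100):
            p, c, f = (rng.uniform(0, 30) for _ in range(3))
            fib = rng.choice([0.0, rng.uniform(0, 10)])
            pol = rng.choice([0.0, rng.uniform(0, 2 * c)])  # exercises clamping
            got = compute_energy(
                NutrientProfile(protein=p, carbohydrate=c, total_fat=f, fiber=fib, polyols=pol)
            )
            assert got == pytest.approx(reference_energy(p, c, f, fib, pol), abs=1e-9)


class TestQCScreen:
    def test_energy_mismatch_over_20_percent(self):
        # declared 100, computed 130: relative difference 0.30 > 0.20
        r = make_record("P1", energy=100.0, protein=20.0, carbohydrate=12.5, total_fat=0.0)
        res = qc_screen(r)
        assert res.status == "excluded" and res.reasons == {ENERGY_MISMATCH}
        assert res.energy_rel_diff == pytest.approx(0.30)

    def test_sfa_exceeding_fat(self):
        r = make_record("P1", total_fat=4.0, sfa=5.0)
        assert qc_screen(r).reasons == {SFA_GT_FAT}

    def test_sugars_exceeding_carbohydrate(self):
        r = make_record("P1", carbohydrate=10.0, total_sugars=12.0)
        assert qc_screen(r).reasons == {SUGARS_GT_CARB}

    def test_clean_composite_record_included(self):
        # the 124-kcal profile with consistent declaration and sane ratios
        r = make_record(
            "P1", energy=124.0, protein=5.0, total_fat=2.0, carbohydrate=20.0,
            fiber=3.0, polyols=0.0, sfa=1.0, total_sugars=10.0,
        )
        res = qc_screen(r)
        assert res.status == "included" and not res.reasons

    @pytest.mark.parametrize(
        "nutrients",
        [
            # relative difference exactly 0.20 (declared 412.5, computed 330)
            dict(energy=412.5, protein=10.0, total_fat=10.0, carbohydrate=50.0),
            # ratios exactly 1.0
            dict(total_fat=5.0, sfa=5.0, carbohydrate=8.0, total_sugars=8.0),
        ],
    )
    def test_boundaries_are_strict(self, nutrients):
        assert qc_screen(make_record("P1", **nutrients)).status == "included"

    def test_improbable_value(self):
        r = make_record("P1", protein=150.0)
        assert qc_screen(r).reasons == {IMPROBABLE_VALUE}

    def test_missing_image_flag_passes_through(self):
        r = make_record("P1", image_complete=False)
        assert qc_screen(r).reasons == {MISSING_IMAGE_PROXY}

    def test_incomputable_checks_are_skipped_not_failed(self):
        # nothing declared: every check skips, record stays included
        assert qc_screen(make_record("P1")).status == "included"

    def test_zero_denominators_skip_ratio_checks(self):
        r = make_record("P1", total_fat=0.0, sfa=0.0, carbohydrate=0.0, total_sugars=0.0)
        assert qc_screen(r).status == "included"


class TestQCFilter:
    def test_planted_violations_recovered(self):
        clean = dict(energy=124.0, protein=5.0, total_fat=2.0, carbohydrate=20.0,
                     fiber=3.0, sfa=1.0, total_sugars=10.0)
        records = [make_record(f"C{i}", **clean) for i in range(7)]
        records.insert(2, make_record("V1", energy=100.0, protein=10.0, carbohydrate=10.0, total_fat=10.0))
        records.insert(5, make_record("V2", total_fat=4.0, sfa=5.0))
        records.insert(8, make_record("V3", carbohydrate=10.0, total_sugars=12.0))
        included, results = qc_filter(records)
        assert [r.product_id for r in included] == [f"C{i}" for i in range(7)]
        excluded = {r.product_id: r.reasons for r in results if r.status == "excluded"}
        assert excluded == {
            "V1": {ENERGY_MISMATCH},
            "V2": {SFA_GT_FAT},
            "V3": {SUGARS_GT_CARB},
        }
        assert reason_counts(results) == {ENERGY_MISMATCH: 1, SFA_GT_FAT: 1, SUGARS_GT_CARB: 1}

    def test_empty_input(self):
        assert qc_filter([]) == ([], [])

    def test_shuffle_invariance(self):
        records = [
            make_record("A", energy=100.0, protein=10.0, carbohydrate=10.0, total_fat=10.0),
            make_record("B", total_fat=4.0, sfa=5.0),
            make_record("C", energy=40.0, protein=10.0, carbohydrate=0.0, total_fat=0.0),
        ]
        baseline = {r.product_id for r in qc_filter(records)[1] if r.status == "excluded"}
        shuffled = [records[2], records[0], records[1]]
        assert {r.product_id for r in qc_filter(shuffled)[1] if r.status == "excluded"} == baseline


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    declared=st.floats(10, 500),
    calc_factor=st.floats(0.5, 1.5),
    tol_low=st.floats(0.05, 0.5),
    tol_gap=st.floats(0.01, 0.4),
)
def test_raising_tolerance_never_excludes_more(declared, calc_factor, tol_low, tol_gap):
    """Monotonicity: a laxer energy tolerance can only include more records."""
    p = declared * calc_factor / 4.0  # protein-only profile: computed = declared*calc_factor
    record = make_record("P1", energy=declared, protein=p, carbohydrate=0.0, total_fat=0.0)
    strict = qc_screen(record, QCConfig(energy_tolerance=tol_low))
    lax = qc_screen(record, QCConfig(energy_tolerance=min(tol_low + tol_gap, 0.99)))
    if strict.status == "included":
        assert lax.status == "included"
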