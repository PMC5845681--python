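"""Per-run gait parameter operations against hand-computed values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitkit.core import PawContact, PawLabel
from gaitkit.errors import (
    InsufficientDataError,
    UnsupportedMeasurementError,
    ValidationError,
)
from gaitkit.params import (
    average_speed,
    cadence,
    initial_dual_stance,
    phase_dispersion,
    print_geometry_means,
    print_position,
    run_duration,
    segment_step_cycles,
    stand_index,
    stride_lengths,
    summarize_run,
)
from gaitkit.synth import generate_run

from conftest import contact, make_run


class TestTemporal:
    def test_run_duration_is_exit_minus_enter(self):
        run = make_run([contact("LF", 0.1, 0.3, x=10)], t_exit=2.5)
        assert run_duration(run) == 2.5

    def test_average_speed_span_over_duration(self):
        run = make_run(
            [contact("LF", 0.0, 0.3, x=10), contact("LF", 1.5, 1.8, x=60)], t_exit=2.0
        )
        assert average_speed(run) == pytest.approx(25.0)

    def test_average_speed_degenerate_zero_span(self):
        run = make_run(
            [contact("LF", 0.0, 0.3, x=10), contact("RF", 0.5, 0.8, x=10)], t_exit=2.0
        )
        assert average_speed(run) == 0.0

    def test_average_speed_needs_two_contacts(self):
        run = make_run([contact("LF", 0.0, 0.3, x=10)])
        with pytest.raises(InsufficientDataError):
            average_speed(run)

    def test_cadence_counts_all_paw_contacts(self):
        contacts = [
            contact(p, 0.1 * i, 0.1 * i + 0.05, x=5 + 5 * i)
            for i, p in enumerate(["LF", "RF", "LH", "RH"] * 3)
        ]
        run = make_run(contacts, t_exit=2.0)
        assert cadence(run) == pytest.approx(12 / 2.0 * 60)

    def test_cadence_zero_contacts(self):
        run = make_run([contact("LF", 0.0, 0.1, x=1)], t_exit=2.0)
        run.contacts = []
        assert cadence(run) == 0.0


class TestStepCycles:
    def test_single_cycle_decomposition(self):
        run = make_run(
            [contact("LF", 0.0, 0.3, x=10), contact("LF", 0.5, 0.8, x=24)]
        )
        (cyc,) = segment_step_cycles(run, PawLabel.LF)
        assert cyc.duration == pytest.approx(0.5)
        assert cyc.stand == pytest.approx(0.3)
        assert cyc.swing == pytest.approx(0.2)

    def test_n_prints_give_n_minus_one_cycles(self):
        prints = [contact("RF", 0.4 * k, 0.4 * k + 0.2, x=8 + 14 * k) for k in range(4)]
        assert len(segment_step_cycles(make_run(prints), PawLabel.RF)) == 3

    def test_fewer_than_two_prints_gives_empty_list(self):
        run = make_run([contact("RF", 0.0, 0.2, x=8)])
        assert segment_step_cycles(run, PawLabel.RF) == []

    def test_overlapping_prints_of_same_paw_rejected(self):
        run = make_run(
            [contact("RF", 0.0, 0.6, x=8), contact("RF", 0.5, 0.9, x=22)]
        )
        with pytest.raises(ValidationError, match="overlap"):
            segment_step_cycles(run, PawLabel.RF)


class TestSpatial:
    def test_stride_is_euclidean_distance(self):
        run = make_run(
            [contact("LF", 0.0, 0.2, x=10, y=1), contact("LF", 0.5, 0.7, x=25, y=1)]
        )
        assert stride_lengths(run, PawLabel.LF) == [pytest.approx(15.0)]

    def test_stride_includes_lateral_component(self):
        run = make_run(
            [contact("LF", 0.0, 0.2, x=10, y=1), contact("LF", 0.5, 0.7, x=10, y=4)]
        )
        assert stride_lengths(run, PawLabel.LF) == [pytest.approx(3.0)]

    def test_print_geometry_means(self):
        run = make_run(
            [
                contact("LF", 0.0, 0.2, x=10, length=2.0, area=1.4),
                contact("LF", 0.5, 0.7, x=24, length=2.2, area=1.6),
            ]
        )
        assert print_geometry_means(run, PawLabel.LF) == (
            pytest.approx(2.1),
            pytest.approx(1.5),
        )
        with pytest.raises(InsufficientDataError):
            print_geometry_means(run, PawLabel.RH)


class TestPrintPosition:
    def _run(self, hind_x):
        return make_run(
            [
                contact("RF", 0.0, 0.25, x=50),
                contact("RH", 0.2, 0.45, x=hind_x),
                contact("RF", 0.5, 0.75, x=64),
            ]
        )

    def test_hind_behind_front_is_positive(self):
        assert print_position(self._run(48.5), "right") == [pytest.approx(1.5)]

    def test_hind_on_front_print_is_zero(self):
        assert print_position(self._run(50.0), "right") == [pytest.approx(0.0)]

    def test_overreach_is_negative(self):
        assert print_position(self._run(51.0), "right") == [pytest.approx(-1.0)]


class TestInitialDualStance:
    def _run(self, lf_on, lf_off, rf_off=1.25):
        return make_run(
            [
                contact("LF", lf_on, lf_off, x=40),
                contact("RF", 1.0, rf_off, x=50),
                contact("RF", 1.5, 1.75, x=64),
            ]
        )

    def test_overlap_at_cycle_start(self):
        assert initial_dual_stance(self._run(0.80, 1.15), PawLabel.RF) == [
            pytest.approx(0.15)
        ]

    def test_contralateral_airborne_gives_zero(self):
        assert initial_dual_stance(self._run(0.40, 0.80), PawLabel.RF) == [0.0]

    def test_clipped_to_own_stand(self):
        # LF stays down past RF lift-off: value clips to RF's stand (0.22)
        vals = initial_dual_stance(self._run(0.80, 1.40, rf_off=1.22), PawLabel.RF)
        assert vals == [pytest.approx(0.22)]


class TestStandIndex:
    def _print(self, release):
        series = ((0.0, 0.0), (0.25, 1.5), (0.25 + release, 0.0))
        return contact("LF", 0.0, 0.25 + release, x=10, series=series)

    def test_release_slope_units(self):
        assert stand_index(self._print(0.05)) == pytest.approx(20.0)
        assert stand_index(self._print(0.10)) == pytest.approx(10.0)

    def test_missing_series_is_unsupported(self):
        with pytest.raises(UnsupportedMeasurementError):
            stand_index(contact("LF", 0.0, 0.3, x=10))

    def test_generated_print_matches_closed_form(self):
        run, truth = generate_run(v=35, L=14, d=0.55, release_fraction=0.4)
        c = run.contacts_of(PawLabel.RF)[1]
        assert stand_index(c) == pytest.approx(1 / (0.4 * 0.55 * 0.4), rel=1e-9)


class TestPhaseDispersion:
    def test_formula(self):
        run = make_run(
            [
                contact("RF", 0.0, 0.25, x=8),
                contact("LH", 0.25, 0.5, x=10),
                contact("RF", 0.5, 0.75, x=22),
            ]
        )
        rec = phase_dispersion(run, PawLabel.RF, PawLabel.LH)
        assert rec.values == (pytest.approx(50.0),)
        assert rec.pair_class == "diagonal"

    def test_synchronous_pair_is_zero(self):
        run = make_run(
            [
                contact("RF", 0.0, 0.25, x=8),
                contact("LH", 0.0, 0.25, x=1),
                contact("RF", 0.5, 0.75, x=22),
            ]
        )
        assert phase_dispersion(run, PawLabel.RF, PawLabel.LH).values == (0.0,)

    def test_self_dispersion_identically_zero(self, oracle_run):
        run, _ = oracle_run
        rec = phase_dispersion(run, PawLabel.RF, PawLabel.RF)
        assert all(v == 0.0 for v in rec.values)

    def test_anchor_must_be_front(self, oracle_run):
        run, _ = oracle_run
        with pytest.raises(ValueError, match="front"):
            phase_dispersion(run, PawLabel.LH, PawLabel.RF)

    def test_wrap_folds_into_display_window(self):
        run = make_run(
            [
                contact("RF", 0.0, 0.25, x=8),
                contact("LH", 0.45, 0.7, x=10),
                contact("RF", 0.5, 0.75, x=22),
            ]
        )
        raw = phase_dispersion(run, PawLabel.RF, PawLabel.LH).values[0]
        wrapped = phase_dispersion(run, PawLabel.RF, PawLabel.LH, wrap=True).values[0]
        assert raw == pytest.approx(90.0)
        assert wrapped == pytest.approx(-10.0)


class TestSummarizeRun:
    def test_emits_one_record_per_available_parameter(self, oracle_run):
        run, _ = oracle_run
        recs = summarize_run(run)
        keys = {(r.parameter, r.paw) for r in recs}
        assert ("average_speed", "all") in keys
        for paw in ("LF", "RF", "LH", "RH"):
            assert ("step_cycle", paw) in keys
            assert ("stand_index", paw) in keys
        assert ("print_position", "LF") in keys and ("print_position", "RF") in keys
        assert ("phase_dispersion_diag_RF_LH", "all") in keys
        # no duplicates
        assert len(keys) == len(recs)

    def test_missing_area_series_omits_stand_index_only(self, oracle_run):
        run, _ = oracle_run
        run.contacts = [
            PawContact(
                paw=c.paw, t_contact=c.t_contact, t_liftoff=c.t_liftoff,
                x=c.x, y=c.y, print_length=c.print_length,
                print_area=c.print_area, area_series=None,
            )
            for c in run.contacts
        ]
        recs = summarize_run(run)
        names = {r.parameter for r in recs}
        assert "stand_index" not in names
        assert "step_cycle" in names and "stride_length" in names

    def test_travel_direction_reflection_leaves_parameters_unchanged(
        self, oracle_run, tmp_path
    ):
        from dataclasses import replace
        from gaitkit.core import read_footfall_csv, write_footfall_csv

        run, _ = oracle_run
        mirrored = make_run(
            [replace(c, x=run.walkway_length - c.x) for c in run.contacts],
            t_exit=run.t_exit,
            week=run.week,
        )
        mirrored.animal_id, mirrored.run_id = run.animal_id, run.run_id
        mirrored.group = run.group
        path = tmp_path / "mirrored.csv"
        write_footfall_csv([mirrored], path)
        (back,) = read_footfall_csv(path)
        orig = {(r.parameter, r.paw): r.value for r in summarize_run(run)}
        refl = {(r.parameter, r.paw): r.value for r in summarize_run(back)}
        assert orig.keys() == refl.keys()
        for key, v in orig.items():
            assert refl[key] == pytest.approx(v, abs=5e-3), key


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    v=st.floats(25, 60),
    L=st.floats(11, 16),
    d=st.floats(0.5, 0.7),
)
def test_cycle_decomposition_and_dispersion_bounds_hold(v, L, d):
    """stand + swing == step cycle exactly; dispersion stays in [0, 100)."""
    run, _ = generate_run(v=v, L=L, d=d)
    for paw in PawLabel:
        for cyc in segment_step_cycles(run, paw):
            assert cyc.stand + cyc.swing == cyc.duration
    for anchor in (PawLabel.LF, PawLabel.RF):
        for target in PawLabel:
            for val in phase_dispersion(run, anchor, target).values:
                assert 0.0 <= val < 100.0
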