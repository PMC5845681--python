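"""Synthetic generator: determinism, oracle closure, severity effects."""

import numpy as np
import pandas as pd
import pytest

from gaitkit.core import PawLabel
from gaitkit.errors import ConfigurationError
from gaitkit.params import (
    average_speed,
    cadence,
    phase_dispersion,
    segment_step_cycles,
    stride_lengths,
    summarize_run,
)
from gaitkit.synth import (
    DEFAULT_GROUP_SIZES,
    PhenotypeParams,
    apply_severity,
    draw_cohort,
    effective_severity,
    generate_run,
)


class TestGenerateRun:
    def test_cycle_period_is_stride_over_speed(self, oracle_run):
        run, truth = oracle_run
        assert truth["T"] == pytest.approx(0.4)
        for paw in PawLabel:
            ics = [c.t_contact for c in run.contacts_of(paw)]
            assert np.diff(ics) == pytest.approx(0.4, abs=1e-12)

    def test_stand_and_swing_closed_form(self, oracle_run):
        run, _ = oracle_run
        for paw in PawLabel:
            for cyc in segment_step_cycles(run, paw):
                assert cyc.stand == pytest.approx(0.55 * 0.4, abs=1e-9)
                assert cyc.swing == pytest.approx(0.45 * 0.4, abs=1e-9)

    def test_diagonal_dispersion_matches_phase_offset(self, oracle_run):
        run, _ = oracle_run
        rec = phase_dispersion(run, PawLabel.RF, PawLabel.LH)
        assert len(rec.values) >= 3
        for v in rec.values:
            assert v == pytest.approx(5.0, abs=1e-9)

    def test_walkway_shorter_than_stride_errors(self):
        with pytest.raises(ConfigurationError, match="stride"):
            generate_run(v=35, L=14, d=0.55, walkway_length=10)

    def test_degenerate_duty_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_run(v=35, L=14, d=1.0)

    def test_measured_speed_recovers_injected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.uniform(22, 62)
            run, _ = generate_run(v=v, L=rng.uniform(11, 16), d=rng.uniform(0.5, 0.7))
            assert average_speed(run) == pytest.approx(v, rel=1e-9)

    def test_oracle_closure_on_noiseless_run(self):
        """Every extracted parameter equals its injected closed form."""
        v, L, d = 40.0, 12.5, 0.6
        run, truth = generate_run(v=v, L=L, d=d)
        T = L / v
        for paw in PawLabel:
            for s in stride_lengths(run, paw):
                assert s == pytest.approx(L, abs=1e-9)
            for cyc in segment_step_cycles(run, paw):
                assert cyc.duration == pytest.approx(T, abs=1e-9)
        # cadence: 4 paws stepping at 1/T each, less edge truncation
        assert cadence(run) == pytest.approx(4 * 60 / T, rel=0.12)


class TestSeverityMapping:
    def test_zero_severity_reproduces_baseline_exactly(self, default_params):
        for week in range(7):
            kin = apply_severity(default_params, week, 0.0, "sham_mfb")
            assert kin.v == default_params.baseline_speed_by_week[week]
            assert kin.d == default_params.duty0
            assert kin.phases == default_params.phases

    def test_week_zero_is_unaffected_by_severity(self, default_params):
        kin = apply_severity(default_params, 0, 0.9, "mfb")
        assert kin.v == default_params.baseline_speed_by_week[0]
        assert kin.d == default_params.duty0

    def test_threshold_gates_kinematics_but_not_coordination(self, default_params):
        kin = apply_severity(default_params, 3, 0.4, "striatal")
        base = apply_severity(default_params, 3, 0.0, "sham_striatal")
        assert kin.v == base.v and kin.L == base.L and kin.d == base.d
        assert kin.phases["RH"] != base.phases["RH"]

    def test_stride_strictly_decreases_with_severity(self, default_params):
        """Above threshold, more severity means shorter generated strides."""
        sev = [0.6, 0.7, 0.8, 0.9, 1.0]
        strides = []
        for s in sev:
            kin = apply_severity(default_params, 3, s, "mfb")
            run, _ = generate_run(v=kin.v, L=kin.L, d=kin.d, phases=kin.phases)
            strides.append(np.mean(stride_lengths(run, PawLabel.LF)))
        assert all(a > b for a, b in zip(strides, strides[1:]))

    def test_diagonal_asymmetry_grows_with_delta(self, default_params):
        asyms = []
        for delta in (-0.01, -0.02, -0.04):
            p = PhenotypeParams(delta_diag=delta)
            kin = apply_severity(p, 3, 0.9, "mfb")
            run, _ = generate_run(v=kin.v, L=kin.L, d=kin.d, phases=kin.phases)
            a = np.mean(phase_dispersion(run, PawLabel.LF, PawLabel.RH).values)
            b = np.mean(phase_dispersion(run, PawLabel.RF, PawLabel.LH).values)
            asyms.append(abs(a - b))
        assert asyms[0] < asyms[1] < asyms[2]

    def test_inadmissible_duty_raises_configuration_error(self):
        p = PhenotypeParams(a_duty=1.0)
        with pytest.raises(ConfigurationError):
            apply_severity(p, 3, 1.0, "mfb")


class TestDrawCohort:
    def test_deterministic_for_fixed_seed(self):
        small = {"sham_mfb": 2, "sham_striatal": 0, "mfb": 2, "striatal": 0}
        r1, t1, a1 = draw_cohort(n_per_group=small, weeks=(0, 1), seed=11)
        r2, t2, a2 = draw_cohort(n_per_group=small, weeks=(0, 1), seed=11)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)
        for k in a1:
            pd.testing.assert_frame_equal(a1[k], a2[k])

    def test_group_size_changes_do_not_reshuffle_other_groups(self):
        base = {"sham_mfb": 2, "sham_striatal": 0, "mfb": 2, "striatal": 0}
        grown = dict(base, striatal=2)
        _, t1, _ = draw_cohort(n_per_group=base, weeks=(0,), seed=3)
        _, t2, _ = draw_cohort(n_per_group=grown, weeks=(0,), seed=3)
        t2_sub = t2[t2.animal_id.isin(t1.animal_id)].reset_index(drop=True)
        pd.testing.assert_frame_equal(t1.reset_index(drop=True), t2_sub)

    def test_default_cohort_has_47_animals(self):
        assert sum(DEFAULT_GROUP_SIZES.values()) == 47
        _, truth, anc = draw_cohort(weeks=(0,), seed=2)
        assert truth["animal_id"].nunique() == 47
        assert len(anc["th_counts"]) == 47

    def test_severity_constant_across_weeks(self):
        _, truth, _ = draw_cohort(
            n_per_group={"sham_mfb": 0, "sham_striatal": 0, "mfb": 3, "striatal": 0},
            seed=4,
        )
        per_animal = truth.groupby("animal_id")["severity"].nunique()
        assert (per_animal == 1).all()

    def test_th_coupling_signs(self):
        """More surviving TH+ neurons go with faster, shorter-cycle gait."""
        runs, truth, anc = draw_cohort(
            n_per_group={"sham_mfb": 10, "sham_striatal": 0, "mfb": 20, "striatal": 0},
            weeks=(6,),
            seed=9,
        )
        rows = []
        for run in runs:
            recs = summarize_run(run, parameters={"average_speed", "step_cycle"})
            for r in recs:
                rows.append((run.animal_id, r.parameter, r.paw, r.value))
        df = pd.DataFrame(rows, columns=["animal_id", "parameter", "paw", "value"])
        means = df.groupby(["animal_id", "parameter"])["value"].mean().unstack()
        th = anc["th_counts"].set_index("animal_id")["th_count"]
        merged = means.join(th)
        assert merged["average_speed"].corr(merged["th_count"]) > 0
        assert merged["step_cycle"].corr(merged["th_count"]) < 0

    def test_rotation_and_cylinder_tables_reflect_severity(self):
        _, truth, anc = draw_cohort(weeks=(0,), seed=6)
        rot = anc["rotations"]
        net = (rot.contra_turns - rot.ipsi_turns) / rot.session_minutes
        rot = rot.assign(net=net).groupby(rot.group.values)["net"].mean()
        assert rot["mfb"] > 5.0 > rot["striatal"] > rot["sham_mfb"]
        cyl = anc["cylinder"]
        cyl = cyl[cyl.week == 6]
        pct = 100 * (cyl.left + cyl.both) / (cyl.left + cyl.right + 2 * cyl.both)
        pct = pct.groupby(cyl.group.values).mean()
        assert pct["mfb"] < pct["striatal"] < pct["sham_mfb"]
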