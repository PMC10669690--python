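"""Waveform templates, lesion effects and cohort generation."""

from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError

from gaitdf import (
    CohortConfig,
    LesionEffect,
    WaveformTemplate,
    apply_lesion_effect,
    generate_cohort,
    lesion_profile,
    render_template,
)
from gaitdf.io import write_annotations, write_trajectories
from gaitdf.normalization import extract_step, normalize_step


def interior_extrema(series):
    """Indices (0-based) of strict interior local extrema."""
    out = []
    for i in range(1, len(series) - 1):
        if (series[i] - series[i - 1]) * (series[i + 1] - series[i]) < 0:
            out.append(i)
    return out


class TestRenderTemplate:
    def test_zero_amplitude_is_constant_baseline(self):
        t = WaveformTemplate(pattern="unidirectional", amplitude=0.0, baseline=3.0)
        assert np.array_equal(render_template(t), np.full(100, 3.0))

    @pytest.mark.parametrize("peak", [20, 50, 70, 90])
    def test_unidirectional_single_excursion(self, peak):
        t = WaveformTemplate(
            pattern="unidirectional", amplitude=1.0, baseline=0.0, phase_peak=peak
        )
        s = render_template(t)
        assert int(np.argmax(s)) + 1 == peak
        # exactly one sign change of the first difference
        signs = np.sign(np.diff(s))
        assert int((np.diff(signs) != 0).sum()) == 1
        assert s[0] == pytest.approx(0.0) and s[-1] == pytest.approx(0.0)
        assert s.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("peak,second", [(30, 75), (25, 60), (40, 90)])
    def test_pendular_two_opposite_extrema(self, peak, second):
        t = WaveformTemplate(
            pattern="pendular",
            amplitude=1.0,
            baseline=0.5,
            phase_peak=peak,
            second_extremum_bin=second,
        )
        s = render_template(t)
        ext = interior_extrema(s)
        assert [e + 1 for e in ext] == [peak, second]
        assert s[ext[0]] > t.baseline and s[ext[1]] < t.baseline

    def test_deterministic_in_inputs(self):
        t = WaveformTemplate(pattern="unidirectional", amplitude=2.0, phase_peak=60)
        assert np.array_equal(render_template(t), render_template(t))

    def test_resolution_parameter(self):
        t = WaveformTemplate(pattern="unidirectional", amplitude=1.0, phase_peak=50)
        assert render_template(t, n_bins=37).shape == (37,)
        with pytest.raises(ValueError):
            render_template(t, n_bins=1)

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            WaveformTemplate(pattern="unidirectional", amplitude=-1.0)
        with pytest.raises(ValidationError):
            WaveformTemplate(pattern="unidirectional", amplitude=1.0, phase_peak=101)
        with pytest.raises(ValidationError):
            WaveformTemplate(pattern="unidirectional", amplitude=1.0, phase_peak=1)
        with pytest.raises(ValidationError):
            WaveformTemplate(pattern="pendular", amplitude=1.0, phase_peak=50)
        with pytest.raises(ValidationError):
            WaveformTemplate(
                pattern="pendular", amplitude=1.0, phase_peak=60,
                second_extremum_bin=40,
            )


class TestLesionEffect:
    def test_zero_delta_is_identity(self, rng):
        series = rng.normal(size=100)
        e = LesionEffect(bin_start=10, bin_end=90, delta=0.0)
        assert np.array_equal(apply_lesion_effect(series, e), series)

    def test_exact_span_no_taper(self):
        e = LesionEffect(bin_start=20, bin_end=54, delta=2.0, taper=0.0)
        out = apply_lesion_effect(np.zeros(100), e)
        assert e.n_bins == 35
        affected = out[19:54]
        assert np.all(affected == 2.0)
        assert np.all(out[:19] == 0.0) and np.all(out[54:] == 0.0)

    @pytest.mark.parametrize("start,end,delta", [(1, 1, 3.0), (20, 54, -1.5), (1, 100, 0.7)])
    def test_abs_sum_oracle_no_taper(self, rng, start, end, delta):
        series = rng.normal(size=100)
        e = LesionEffect(bin_start=start, bin_end=end, delta=delta, taper=0.0)
        out = apply_lesion_effect(series, e)
        # direct summation oracle
        expected = abs(delta) * (end - start + 1)
        assert np.abs(out - series).sum() == pytest.approx(expected, rel=1e-12)

    def test_taper_keeps_outside_unchanged_and_bounds_inside(self, rng):
        series = rng.normal(size=100)
        e = LesionEffect(bin_start=30, bin_end=70, delta=2.0, taper=0.5)
        out = apply_lesion_effect(series, e)
        diff = out - series
        assert np.all(diff[:29] == 0.0) and np.all(diff[70:] == 0.0)
        assert diff.max() == pytest.approx(2.0)
        assert np.all(diff >= -1e-12)
        # tapered profile is symmetric about the span centre
        profile = lesion_profile(e)
        inside = profile[29:70]
        assert np.allclose(inside, inside[::-1], atol=1e-12)

    def test_invalid_ranges(self):
        with pytest.raises(ValidationError):
            LesionEffect(bin_start=50, bin_end=40, delta=1.0)
        with pytest.raises(ValidationError):
            LesionEffect(bin_start=0, bin_end=10, delta=1.0)
        e = LesionEffect(bin_start=1, bin_end=10, delta=1.0)
        with pytest.raises(ValueError):
            apply_lesion_effect(np.zeros(50), e)


class TestGenerateCohort:
    def test_counts_default_design(self, default_cohort):
        # 8 groups x 5 animals x 6 steps = 240 annotated steps per (joint, side)
        cohort = default_cohort
        assert len(cohort.trajectories) == 8 * 5 * 3 * 2
        for joint in ("metatarsus", "ankle", "knee"):
            for side in ("left", "right"):
                n_steps = sum(
                    len(cohort.steps_for(t))
                    for t in cohort.trajectories
                    if t.joint == joint and t.side == side
                )
                assert n_steps == 240

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(animals_per_group=2, steps_per_animal=2, seed=7)
        for name in ("a", "b"):
            cohort = generate_cohort(cfg)
            write_trajectories(tmp_path / f"{name}.tsv", cohort.trajectories)
            write_annotations(tmp_path / f"{name}_steps.tsv", cohort.annotations)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (
            (tmp_path / "a_steps.tsv").read_bytes()
            == (tmp_path / "b_steps.tsv").read_bytes()
        )

    def test_distinct_seeds_differ(self):
        cfg7 = CohortConfig(animals_per_group=2, steps_per_animal=2, seed=7)
        cfg8 = cfg7.model_copy(update={"seed": 8})
        ya = generate_cohort(cfg7).trajectories[0].y
        yb = generate_cohort(cfg8).trajectories[0].y
        assert not np.array_equal(ya, yb)

    def test_zero_noise_steps_reproduce_template(self):
        cfg = CohortConfig(
            animals_per_group=2,
            steps_per_animal=3,
            noise_sd_step=0.0,
            noise_sd_animal=0.0,
            lesion_effects={},
            seed=3,
        )
        cohort = generate_cohort(cfg)
        for traj in cohort.trajectories:
            if traj.species != "rat" or traj.joint != "ankle":
                continue
            template = render_template(cfg.template_for(traj.species, traj.joint, traj.side))
            for k, ann in enumerate(cohort.steps_for(traj)):
                curve = normalize_step(extract_step(traj, ann, f"s{k+1}"))
                assert np.abs(curve.y - template).max() < 5e-3

    def test_lesioned_group_mean_matches_template_plus_effect(self):
        effect = LesionEffect(bin_start=20, bin_end=54, delta=2.0, taper=0.0)
        cfg = CohortConfig(
            groups=[("rat", "M", "lesioned")],
            animals_per_group=2,
            steps_per_animal=4,
            noise_sd_step=0.0,
            noise_sd_animal=0.0,
            lesion_effects={"rat:M:metatarsus:left": effect},
            seed=3,
        )
        cohort = generate_cohort(cfg)
        traj = next(
            t for t in cohort.trajectories
            if t.joint == "metatarsus" and t.side == "left"
        )
        expected = render_template(
            cfg.template_for("rat", "metatarsus", "left")
        ) + lesion_profile(effect)
        curve = normalize_step(extract_step(traj, cohort.steps_for(traj)[0]))
        # an untapered effect is a step discontinuity; spline ringing
        # around the two onset edges decays geometrically, so compare a
        # few bins away from them
        edge = np.zeros(100, dtype=bool)
        edge[11:27] = edge[46:61] = True
        assert np.abs((curve.y - expected)[~edge]).max() < 5e-3
        assert curve.y[25:45].mean() - expected[25:45].mean() == pytest.approx(
            0.0, abs=5e-3
        )

    def test_step_noise_sd_recovered_at_fixed_bins(self):
        # >= 500 steps of one animal, zero animal noise: empirical SD at a
        # fixed bin must recover noise_sd_step within 15%
        sd = 0.4
        cfg = CohortConfig(
            groups=[("rat", "M", "control")],
            animals_per_group=2,
            steps_per_animal=300,
            noise_sd_step=sd,
            noise_sd_animal=0.0,
            lesion_effects={},
            seed=9,
        )
        cohort = generate_cohort(cfg)
        traj = next(
            t for t in cohort.trajectories
            if t.joint == "metatarsus" and t.side == "left" and t.animal_id == "rat_M_1"
        )
        curves = [
            normalize_step(extract_step(traj, ann, f"s{k+1}")).y
            for k, ann in enumerate(cohort.steps_for(traj))
        ]
        values = np.stack(curves)
        for b in (10, 50, 90):
            assert values[:, b].std(ddof=1) == pytest.approx(sd, rel=0.15)

    def test_condition_null_groups_exchangeable(self):
        # no lesion effects: day0 and day7 curves of one species/sex share
        # templates and per-animal offsets, so group means agree closely
        cfg = CohortConfig(
            groups=[("mouse", "F", "control"), ("mouse", "F", "lesioned")],
            animals_per_group=3,
            steps_per_animal=10,
            noise_sd_step=0.1,
            noise_sd_animal=0.2,
            lesion_effects={},
            seed=4,
        )
        cohort = generate_cohort(cfg)
        means = {}
        for cond in ("control", "lesioned"):
            curves = []
            for traj in cohort.trajectories:
                if traj.condition != cond or traj.joint != "ankle" or traj.side != "left":
                    continue
                for k, ann in enumerate(cohort.steps_for(traj)):
                    curves.append(normalize_step(extract_step(traj, ann, f"s{k+1}")).y)
            means[cond] = np.stack(curves).mean(axis=0)
        # step noise 0.1 over 30 curves -> SEM ~ 0.018 per bin
        assert np.abs(means["control"] - means["lesioned"]).max() < 0.12

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            CohortConfig(animals_per_group=1)
        with pytest.raises(ValidationError):
            CohortConfig(noise_sd_step=-0.1)
        with pytest.raises(ValidationError):
            CohortConfig(step_duration_range=(0.5, 0.2))
        with pytest.raises(ValidationError):
            CohortConfig(templates={"rat:metatarsus": WaveformTemplate(
                pattern="unidirectional", amplitude=1.0)})
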