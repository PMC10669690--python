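"""Synthetic hindlimb gait generator.

Emulates tunnel-walk landmark recordings at 240 fps: per animal and side,
a sequence of steps whose joint vertical-displacement waveforms follow
species-specific shapes — a single excursion per cycle (*unidirectional*)
or two opposite excursions (*pendular*) — with step-to-step noise,
animal-to-animal template offsets, and, for lesioned sessions, a
localized vertical shift over a contiguous span of cycle bins (the
ground-truth mechanism behind "percent of step cycle changed").

The generator is a pure function of its :class:`CohortConfig` (including
the seed), and emits ground truth (templates, lesion effects) alongside
the trajectories so recovery can be scored without re-deriving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.interpolate import CubicSpline

from .records import (
    CONDITIONS,
    JOINTS,
    N_BINS,
    SESSION_FOR_CONDITION,
    SEXES,
    SIDES,
    SPECIES,
    LandmarkTrajectory,
    StepAnnotation,
    group_code,
)

__all__ = [
    "WaveformTemplate",
    "LesionEffect",
    "CohortConfig",
    "SyntheticCohort",
    "render_template",
    "template_function",
    "apply_lesion_effect",
    "lesion_profile",
    "generate_cohort",
    "default_templates",
    "default_lesion_effects",
    "default_cohort_config",
]


class WaveformTemplate(BaseModel):
    """Noise-free joint vertical-displacement shape over one step cycle.

    ``unidirectional``: a raised-cosine bump peaking at ``phase_peak``
    (one interior extremum).  ``pendular``: a time-warped single-period
    sine with its positive extremum at ``phase_peak`` and its negative
    extremum at ``second_extremum_bin`` (two interior extrema of
    opposite sign relative to ``baseline``).  Bins are on the 1..100
    percent-of-cycle scale; amplitudes in AU.
    """

    pattern: Literal["unidirectional", "pendular"]
    amplitude: float = Field(ge=0.0)
    baseline: float = 0.0
    phase_peak: float = 50.0
    second_extremum_bin: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "WaveformTemplate":
        if not 1 <= self.phase_peak <= N_BINS:
            raise ValueError(f"phase_peak must lie in [1, {N_BINS}]")
        if self.amplitude > 0 and not 2 <= self.phase_peak <= N_BINS - 1:
            raise ValueError(
                "an active template needs an interior peak (2 <= phase_peak <= 99)"
            )
        if self.pattern == "pendular":
            if self.second_extremum_bin is None:
                raise ValueError("pendular template requires second_extremum_bin")
            if not 1 <= self.second_extremum_bin <= N_BINS:
                raise ValueError(f"second_extremum_bin must lie in [1, {N_BINS}]")
            if self.amplitude > 0 and not (
                self.phase_peak < self.second_extremum_bin <= N_BINS - 1
            ):
                raise ValueError(
                    "pendular template requires phase_peak < second_extremum_bin <= 99"
                )
        return self


class LesionEffect(BaseModel):
    """Signed vertical shift applied to a contiguous span of cycle bins.

    ``taper`` is the fraction of the span used for smooth cosine
    ramp-in/out (half at each end); with ``taper = 0`` every affected
    bin is shifted by exactly ``delta`` and the onset is a step edge.
    """

    bin_start: int = Field(ge=1, le=N_BINS)
    bin_end: int = Field(ge=1, le=N_BINS)
    delta: float = 0.0
    taper: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "LesionEffect":
        if self.bin_end < self.bin_start:
            raise ValueError("bin_end must be >= bin_start")
        return self

    @property
    def n_bins(self) -> int:
        return self.bin_end - self.bin_start + 1


def _bin_to_u(b: float) -> float:
    return (b - 1.0) / (N_BINS - 1.0)


def template_function(template: WaveformTemplate):
    """Continuous realization of *template* over normalized time u in [0, 1]."""
    amp, base = template.amplitude, template.baseline
    if amp == 0:
        return lambda u: np.full_like(np.asarray(u, dtype=float), base)
    up = _bin_to_u(template.phase_peak)

    if template.pattern == "unidirectional":
        # piecewise-linear phase warp puts the bump peak at u = up
        def f(u):
            u = np.asarray(u, dtype=float)
            g = np.where(u <= up, 0.5 * u / up, 0.5 + 0.5 * (u - up) / (1.0 - up))
            return base + amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * g))

        return f

    us = _bin_to_u(template.second_extremum_bin)

    def f(u):
        u = np.asarray(u, dtype=float)
        h = np.empty_like(u)
        lo = u <= up
        mid = (u > up) & (u <= us)
        hi = u > us
        h[lo] = 0.25 * u[lo] / up
        h[mid] = 0.25 + 0.5 * (u[mid] - up) / (us - up)
        h[hi] = 0.75 + 0.25 * (u[hi] - us) / (1.0 - us)
        return base + amp * np.sin(2.0 * np.pi * h)

    return f


def render_template(template: WaveformTemplate, n_bins: int = N_BINS) -> np.ndarray:
    """Evaluate *template* on an ``n_bins``-point percent-of-cycle grid."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    u = np.linspace(0.0, 1.0, n_bins)
    return template_function(template)(u)


def _lesion_weight(effect: LesionEffect):
    """Continuous weight profile w(u) in [0, 1] of the affected span."""
    a, b = _bin_to_u(effect.bin_start), _bin_to_u(effect.bin_end)
    span = b - a
    ramp = 0.5 * effect.taper * span

    def w(u):
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        inside = (u >= a) & (u <= b)
        out[inside] = 1.0
        if ramp > 0:
            rise = inside & (u < a + ramp)
            fall = inside & (u > b - ramp)
            out[rise] = 0.5 * (1.0 - np.cos(np.pi * (u[rise] - a) / ramp))
            out[fall] = 0.5 * (1.0 - np.cos(np.pi * (b - u[fall]) / ramp))
        return out

    return w


def lesion_profile(effect: LesionEffect, n_bins: int = N_BINS) -> np.ndarray:
    """Per-bin additive shift (``delta * weight``) on the n_bins grid."""
    u = np.linspace(0.0, 1.0, n_bins)
    return effect.delta * _lesion_weight(effect)(u)


def apply_lesion_effect(series: np.ndarray, effect: LesionEffect) -> np.ndarray:
    """Apply *effect* to a 100-bin series; bins outside the span are unchanged."""
    series = np.asarray(series, dtype=float)
    if series.shape != (N_BINS,):
        raise ValueError(f"series must have exactly {N_BINS} bins")
    return series + lesion_profile(effect, N_BINS)


# ---------------------------------------------------------------------------
# cohort configuration and defaults
# ---------------------------------------------------------------------------

def default_templates() -> dict[str, WaveformTemplate]:
    """Species-specific joint waveform templates, keyed ``species:joint:side``.

    Shapes follow the qualitative species contrast: rat metatarsus and
    ankle move in one direction per cycle while the rat knee is
    pendular; in mice the metatarsus and ankle are pendular and the
    knee unidirectional.  Amplitudes/baselines are free parameters in
    AU (distal joints excursion larger, proximal baseline higher;
    mouse amplitudes about half the rat's).
    """
    by_joint = {
        "rat": {
            "metatarsus": WaveformTemplate(
                pattern="unidirectional", amplitude=3.0, baseline=1.0, phase_peak=70
            ),
            "ankle": WaveformTemplate(
                pattern="unidirectional", amplitude=2.5, baseline=3.0, phase_peak=65
            ),
            "knee": WaveformTemplate(
                pattern="pendular",
                amplitude=1.2,
                baseline=6.0,
                phase_peak=30,
                second_extremum_bin=75,
            ),
        },
        "mouse": {
            "metatarsus": WaveformTemplate(
                pattern="pendular",
                amplitude=1.5,
                baseline=0.5,
                phase_peak=35,
                second_extremum_bin=80,
            ),
            "ankle": WaveformTemplate(
                pattern="pendular",
                amplitude=1.2,
                baseline=1.5,
                phase_peak=30,
                second_extremum_bin=75,
            ),
            "knee": WaveformTemplate(
                pattern="unidirectional", amplitude=0.6, baseline=3.0, phase_peak=60
            ),
        },
    }
    return {
        f"{sp}:{joint}:{side}": by_joint[sp][joint]
        for sp in SPECIES
        for joint in JOINTS
        for side in SIDES
    }


#: Span (bins out of 100) of the lesion-induced shift per
#: (species, sex, joint, side) in the default cohort.  The spans mirror
#: the per-group percent-of-step-cycle-changed structure the analysis is
#: designed to resolve; a span of 0 means no effect.
_DEFAULT_SPANS: dict[tuple[str, str, str, str], int] = {
    ("rat", "M", "metatarsus", "left"): 35,
    ("rat", "M", "metatarsus", "right"): 9,
    ("rat", "F", "metatarsus", "left"): 0,
    ("rat", "F", "metatarsus", "right"): 8,
    ("rat", "M", "ankle", "left"): 63,
    ("rat", "M", "ankle", "right"): 62,
    ("rat", "F", "ankle", "left"): 10,
    ("rat", "F", "ankle", "right"): 22,
    ("rat", "M", "knee", "left"): 9,
    ("rat", "M", "knee", "right"): 4,
    ("rat", "F", "knee", "left"): 8,
    ("rat", "F", "knee", "right"): 42,
    ("mouse", "M", "metatarsus", "left"): 8,
    ("mouse", "M", "metatarsus", "right"): 6,
    ("mouse", "F", "metatarsus", "left"): 4,
    ("mouse", "F", "metatarsus", "right"): 0,
    ("mouse", "M", "ankle", "left"): 18,
    ("mouse", "M", "ankle", "right"): 6,
    ("mouse", "F", "ankle", "left"): 16,
    ("mouse", "F", "ankle", "right"): 2,
    ("mouse", "M", "knee", "left"): 0,
    ("mouse", "M", "knee", "right"): 4,
    ("mouse", "F", "knee", "left"): 22,
    ("mouse", "F", "knee", "right"): 6,
}


def default_lesion_effects(
    delta_rat: float = 1.0, delta_mouse: float = 0.5, taper: float = 0.0
) -> dict[str, LesionEffect]:
    """Lesion effects keyed ``species:sex:joint:side``, spans centred at bin 50."""
    effects: dict[str, LesionEffect] = {}
    for (sp, sex, joint, side), span in _DEFAULT_SPANS.items():
        if span == 0:
            continue
        start = max(1, min(N_BINS - span + 1, 50 - span // 2))
        delta = delta_rat if sp == "rat" else delta_mouse
        effects[f"{sp}:{sex}:{joint}:{side}"] = LesionEffect(
            bin_start=start, bin_end=start + span - 1, delta=delta, taper=taper
        )
    return effects


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort.

    The default is the study design the pipeline targets: eight groups
    (2 species x 2 sexes x control/lesioned), five animals per group,
    the same animals recorded pre-injury (day 0, control) and 7 days
    post-injury (lesioned), six analyzed steps per animal and side,
    240 fps.
    """

    groups: list[tuple[str, str, str]] = Field(
        default_factory=lambda: [
            (sp, sex, cond) for sp in SPECIES for sex in SEXES for cond in CONDITIONS
        ]
    )
    animals_per_group: int = Field(default=5, ge=2)
    steps_per_animal: int = Field(default=6, ge=1)
    fps: float = Field(default=240.0, gt=0)
    step_duration_range: tuple[float, float] = (0.25, 0.5)
    gap_frames: int = Field(default=12, ge=0)
    stride_length: dict[str, float] = Field(
        default_factory=lambda: {"rat": 12.0, "mouse": 6.0}
    )
    noise_sd_step: float = Field(default=0.3, ge=0.0)
    noise_sd_animal: float = Field(default=0.15, ge=0.0)
    templates: dict[str, WaveformTemplate] = Field(default_factory=default_templates)
    lesion_effects: dict[str, LesionEffect] = Field(
        default_factory=default_lesion_effects
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        lo, hi = self.step_duration_range
        if not (0 < lo <= hi):
            raise ValueError("step_duration_range must satisfy 0 < lo <= hi")
        if lo * self.fps < 4:
            raise ValueError("shortest step must span at least 4 frames at this fps")
        for sp, sex, cond in self.groups:
            if sp not in SPECIES or sex not in SEXES or cond not in CONDITIONS:
                raise ValueError(f"invalid group {(sp, sex, cond)!r}")
        for key in self.templates:
            sp, joint, side = key.split(":")
            if sp not in SPECIES or joint not in JOINTS or side not in SIDES:
                raise ValueError(f"invalid template key {key!r}")
        for key in self.lesion_effects:
            sp, sex, joint, side = key.split(":")
            if (
                sp not in SPECIES
                or sex not in SEXES
                or joint not in JOINTS
                or side not in SIDES
            ):
                raise ValueError(f"invalid lesion_effects key {key!r}")
        return self

    def template_for(self, species: str, joint: str, side: str) -> WaveformTemplate:
        return self.templates[f"{species}:{joint}:{side}"]

    def lesion_for(self, species: str, sex: str, joint: str, side: str) -> LesionEffect | None:
        return self.lesion_effects.get(f"{species}:{sex}:{joint}:{side}")


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    return CohortConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Generated trajectories + step annotations + ground truth."""

    config: CohortConfig
    trajectories: list[LandmarkTrajectory]
    annotations: dict[tuple[str, str, str], list[StepAnnotation]]
    ground_truth: dict

    def steps_for(self, traj: LandmarkTrajectory) -> list[StepAnnotation]:
        return self.annotations[(traj.animal_id, traj.session, traj.side)]


def _noise_curve(rng: np.random.Generator, sd: float):
    """Smooth per-step noise: a natural cubic spline through iid per-bin draws."""
    values = rng.normal(0.0, sd, size=N_BINS) if sd > 0 else np.zeros(N_BINS)
    grid = np.linspace(0.0, 1.0, N_BINS)
    spline = CubicSpline(grid, values, bc_type="natural")
    return values, spline


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic cohort, deterministically from ``config``.

    Animals are shared across conditions of the same species x sex (the
    same animal is recorded pre- and post-injury), so per-animal
    template offsets persist from the control to the lesioned session.
    """
    rng = np.random.default_rng(config.seed)
    fps = config.fps

    species_sex = sorted({(sp, sex) for sp, sex, _ in config.groups})
    conditions_for = {
        (sp, sex): [c for c in CONDITIONS if (sp, sex, c) in {tuple(g) for g in config.groups}]
        for sp, sex in species_sex
    }

    trajectories: list[LandmarkTrajectory] = []
    annotations: dict[tuple[str, str, str], list[StepAnnotation]] = {}
    gt_animals: dict[str, dict] = {}

    for sp, sex in species_sex:
        for a in range(config.animals_per_group):
            animal_id = f"{sp}_{sex}_{a + 1}"
            # per-animal template offsets, one per (joint, side, axis)
            offsets = {
                (joint, side): {
                    "y": float(rng.normal(0.0, config.noise_sd_animal)),
                    "x": float(rng.normal(0.0, config.noise_sd_animal)),
                }
                for joint in JOINTS
                for side in SIDES
            }
            gt_animals[animal_id] = {
                "species": sp,
                "sex": sex,
                "offsets": {f"{j}:{s}": o for (j, s), o in offsets.items()},
            }
            for cond in conditions_for[(sp, sex)]:
                session = SESSION_FOR_CONDITION[cond]
                for side in SIDES:
                    # shared step timing for the three joints of this limb
                    durations = rng.uniform(
                        *config.step_duration_range, size=config.steps_per_animal
                    )
                    n_frames = np.maximum(4, np.round(durations * fps).astype(int))
                    starts, cursor = [], 0
                    for n in n_frames:
                        starts.append(cursor)
                        cursor += int(n) + config.gap_frames
                    anns = [
                        StepAnnotation(start_frame=s, end_frame=s + int(n))
                        for s, n in zip(starts, n_frames)
                    ]
                    annotations[(animal_id, session, side)] = anns

                    # per-step smooth noise curves, shared frame grid per joint
                    step_noise = [
                        {
                            "y": _noise_curve(rng, config.noise_sd_step),
                            "x": _noise_curve(rng, config.noise_sd_step),
                        }
                        for _ in range(config.steps_per_animal)
                    ]

                    for joint in JOINTS:
                        template = config.template_for(sp, joint, side)
                        f = template_function(template)
                        effect = (
                            config.lesion_for(sp, sex, joint, side)
                            if cond == "lesioned"
                            else None
                        )
                        w = _lesion_weight(effect) if effect is not None else None
                        stride = config.stride_length[sp]
                        off = offsets[(joint, side)]

                        frames, xs, ys = [], [], []
                        for k, (ann, noise) in enumerate(zip(anns, step_noise)):
                            n = ann.n_frames
                            u = np.linspace(0.0, 1.0, n)
                            y = f(u) + off["y"] + noise["y"][1](u)
                            if w is not None:
                                y = y + effect.delta * w(u)
                            x = stride * u + off["x"] + noise["x"][1](u)
                            frames.append(np.arange(ann.start_frame, ann.end_frame))
                            xs.append(x)
                            ys.append(y)
                        trajectories.append(
                            LandmarkTrajectory(
                                animal_id=animal_id,
                                session=session,
                                species=sp,
                                sex=sex,
                                condition=cond,
                                side=side,
                                joint=joint,
                                fps=fps,
                                frame=np.concatenate(frames),
                                x=np.concatenate(xs),
                                y=np.concatenate(ys),
                            )
                        )

    ground_truth = {
        "seed": config.seed,
        "templates": {
            key: t.model_dump() for key, t in sorted(config.templates.items())
        },
        "lesion_effects": {
            key: e.model_dump() for key, e in sorted(config.lesion_effects.items())
        },
        "noise_sd_step": config.noise_sd_step,
        "noise_sd_animal": config.noise_sd_animal,
        "animals": dict(sorted(gt_animals.items())),
    }
    return SyntheticCohort(
        config=config,
        trajectories=trajectories,
        annotations=annotations,
        ground_truth=ground_truth,
    )
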