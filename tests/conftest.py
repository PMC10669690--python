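from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gaitdf import CohortConfig, NormalizedStepCurve, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_curve(
    x,
    y,
    curve_id="c1",
    animal_id="rat_M_1",
    species="rat",
    sex="M",
    condition="control",
    side="left",
    joint="metatarsus",
) -> NormalizedStepCurve:
    return NormalizedStepCurve(
        curve_id=curve_id,
        animal_id=animal_id,
        species=species,
        sex=sex,
        condition=condition,
        side=side,
        joint=joint,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def random_curves(rng, n, animals=1, **meta):
    """n random curves spread round-robin over `animals` animal ids."""
    curves = []
    for k in range(n):
        curves.append(
            make_curve(
                rng.normal(size=100),
                rng.normal(size=100),
                curve_id=f"c{k}",
                animal_id=f"a{k % animals}",
                **meta,
            )
        )
    return curves


@pytest.fixture(scope="session")
def small_cohort():
    """Two-species cohort small enough for fast I/O tests."""
    cfg = CohortConfig(animals_per_group=2, steps_per_animal=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study design (8 groups x 5 animals x 6 steps)."""
    return generate_cohort(CohortConfig(seed=5))
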