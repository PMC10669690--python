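"""Step extraction and 100-bin step-cycle time normalization.

Each annotated step is cut out of its trajectory and resampled onto the
percent-of-step-cycle axis: normalized time ``u = (t - t0)/(t1 - t0)``
is evaluated at ``u_i = (i - 1)/99`` for bins ``i = 1..100`` through a
cubic *interpolating* spline fitted independently to x(t) and y(t), so
the curve passes through the original samples and both step endpoints
are preserved exactly.  Amplitudes stay in AU — only time is
normalized (an optional amplitude standardization exists but is off by
default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .records import (
    MIN_STEP_FRAMES,
    N_BINS,
    LandmarkTrajectory,
    NormalizedStepCurve,
    StepAnnotation,
    StepSegment,
)

__all__ = [
    "extract_step",
    "normalize_step",
    "normalize_dataset",
    "curves_to_frame",
    "frame_to_curves",
    "write_curves",
    "read_curves",
]

_BIN_U = np.linspace(0.0, 1.0, N_BINS)


def extract_step(
    traj: LandmarkTrajectory, ann: StepAnnotation, step_id: str = "s1"
) -> StepSegment:
    """Cut the frames of ``[start_frame, end_frame)`` out of *traj*.

    Times are seconds, ``t = frame / fps``.
    """
    mask = (traj.frame >= ann.start_frame) & (traj.frame < ann.end_frame)
    n = int(mask.sum())
    if n != ann.n_frames:
        raise ValueError(
            f"annotation [{ann.start_frame}, {ann.end_frame}) expects "
            f"{ann.n_frames} frames but trajectory "
            f"{traj.animal_id}/{traj.session}/{traj.side}/{traj.joint} "
            f"contains {n} of them"
        )
    return StepSegment(
        animal_id=traj.animal_id,
        species=traj.species,
        sex=traj.sex,
        condition=traj.condition,
        side=traj.side,
        joint=traj.joint,
        step_id=step_id,
        t=traj.frame[mask] / traj.fps,
        x=traj.x[mask],
        y=traj.y[mask],
    )


def normalize_step(
    segment: StepSegment,
    bc_type: str = "natural",
    standardize_amplitude: bool = False,
) -> NormalizedStepCurve:
    """Resample one raw step onto the 100-bin step-cycle axis.

    Parameters
    ----------
    segment
        Raw (t, x, y) samples; at least 4, strictly increasing t.
    bc_type
        Spline boundary condition (``"natural"`` by default,
        ``"clamped"`` available).
    standardize_amplitude
        If True, additionally rescale each axis to zero mean / unit SD
        across the 100 bins (off by default; constant axes are left
        at zero after centring).
    """
    t = np.asarray(segment.t, dtype=float)
    if len(t) < MIN_STEP_FRAMES:
        raise ValueError(
            f"step {segment.step_id} of {segment.animal_id}: "
            f"{len(t)} samples, need >= {MIN_STEP_FRAMES} for a cubic spline"
        )
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(
            f"step {segment.step_id} of {segment.animal_id}: timestamps must "
            "be strictly increasing (duplicates present)"
        )
    u = (t - t[0]) / (t[-1] - t[0])
    x = CubicSpline(u, segment.x, bc_type=bc_type)(_BIN_U)
    y = CubicSpline(u, segment.y, bc_type=bc_type)(_BIN_U)
    if standardize_amplitude:
        for arr in (x, y):
            arr -= arr.mean()
            sd = arr.std(ddof=0)
            if sd > 0:
                arr /= sd
    return NormalizedStepCurve(
        curve_id=f"{segment.animal_id}:{segment.condition}:{segment.side}:"
        f"{segment.joint}:{segment.step_id}",
        animal_id=segment.animal_id,
        species=segment.species,
        sex=segment.sex,
        condition=segment.condition,
        side=segment.side,
        joint=segment.joint,
        x=x,
        y=y,
    )


def normalize_dataset(
    pairs: list[tuple[LandmarkTrajectory, list[StepAnnotation]]],
    bc_type: str = "natural",
) -> list[NormalizedStepCurve]:
    """Extract and normalize every annotated step of every trajectory."""
    curves = []
    for traj, anns in pairs:
        for k, ann in enumerate(anns):
            segment = extract_step(traj, ann, step_id=f"s{k + 1}")
            curves.append(normalize_step(segment, bc_type=bc_type))
    return curves


# ---------------------------------------------------------------------------
# tabular representation (one row per curve and bin)
# ---------------------------------------------------------------------------

_CURVE_META = ["curve_id", "animal_id", "species", "sex", "condition", "side", "joint"]


def curves_to_frame(curves: list[NormalizedStepCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "animal_id": c.animal_id,
                    "species": c.species,
                    "sex": c.sex,
                    "condition": c.condition,
                    "side": c.side,
                    "joint": c.joint,
                    "bin": c.bins,
                    "x": c.x,
                    "y": c.y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_curves(table: pd.DataFrame) -> list[NormalizedStepCurve]:
    curves = []
    for _, sub in table.groupby("curve_id", sort=True):
        sub = sub.sort_values("bin")
        meta = {k: sub[k].iloc[0] for k in _CURVE_META}
        curves.append(
            NormalizedStepCurve(
                x=sub["x"].to_numpy(dtype=float),
                y=sub["y"].to_numpy(dtype=float),
                **meta,
            )
        )
    return curves


def write_curves(path, curves: list[NormalizedStepCurve]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gaitdf-curves v1\n")
        curves_to_frame(curves).to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_curves(path) -> list[NormalizedStepCurve]:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": str})
    return frame_to_curves(table)
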