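"""Tabular I/O for landmark trajectories, step annotations and
calibration points, plus the four-point homographic correction.

File formats (all UTF-8, tab-separated, ``#``-prefixed header lines):

Trajectories (``trajectories.tsv``)::

    # gaitdf-trajectories v1
    # fps: 240.0
    # y_axis_direction: up
    animal_id  session  species  sex  condition  side  joint  frame  x  y

``y_axis_direction`` may be ``up`` (native convention: y increases
upward) or ``down`` (image convention); ``down`` files are flipped to
``up`` on read.

Step annotations (``steps.tsv``)::

    # gaitdf-steps v1
    animal_id  session  side  step_id  start_frame  end_frame

Annotations are half-open frame ranges ``[start_frame, end_frame)``
shared by the three joints of that (animal, session, side).

Calibration (JSON): ``{"src": [[x,y]*4], "dst": [[x,y]*4]}``, either at
top level (applied to every trajectory) or nested under ``"left"`` /
``"right"`` for per-camera correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    DegenerateGeometryError,
    FormatError,
    LandmarkTrajectory,
    StepAnnotation,
)

__all__ = [
    "Homography",
    "estimate_homography",
    "apply_homography",
    "read_trajectories",
    "write_trajectories",
    "read_annotations",
    "write_annotations",
    "read_dataset",
    "read_calibration",
]

_TRAJ_COLUMNS = [
    "animal_id", "session", "species", "sex", "condition",
    "side", "joint", "frame", "x", "y",
]
_ANN_COLUMNS = ["animal_id", "session", "side", "step_id", "start_frame", "end_frame"]


# ---------------------------------------------------------------------------
# homography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Homography:
    """3x3 projective transform, normalized so ``H[2, 2] == 1``."""

    H: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("homography matrix must be invertible")
        if H[2, 2] != 0:
            H = H / H[2, 2]
        object.__setattr__(self, "H", H)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.H @ other.H)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of points projectively."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.H.T
        w = hom[:, 2]
        if np.any(w == 0):
            bad = int(np.nonzero(w == 0)[0][0])
            raise ZeroDivisionError(f"point {bad} maps to infinity (w' = 0)")
        return hom[:, :2] / w[:, None]


def _has_collinear_triple(points: np.ndarray, tol: float = 1e-9) -> bool:
    from itertools import combinations

    for i, j, k in combinations(range(len(points)), 3):
        a, b, c = points[i], points[j], points[k]
        area = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        scale = max(np.abs(points).max(), 1.0)
        if area <= tol * scale * scale:
            return True
    return False


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Exact homography from four point correspondences.

    With exactly four correspondences (no three collinear) the eight
    unknowns of H (with ``H[2,2]`` fixed to 1) are determined exactly by
    the 8x8 linear system of the projection equations.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ValueError("estimate_homography requires exactly 4 src and 4 dst points")
    if _has_collinear_triple(src):
        raise DegenerateGeometryError("three of the source points are collinear")
    if _has_collinear_triple(dst):
        raise DegenerateGeometryError("three of the destination points are collinear")

    A = np.zeros((8, 8))
    b = np.zeros(8)
    for k, ((x, y), (xp, yp)) in enumerate(zip(src, dst)):
        A[2 * k] = [x, y, 1, 0, 0, 0, -xp * x, -xp * y]
        b[2 * k] = xp
        A[2 * k + 1] = [0, 0, 0, x, y, 1, -yp * x, -yp * y]
        b[2 * k + 1] = yp
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateGeometryError(f"degenerate correspondence set: {exc}") from exc
    H = np.append(h, 1.0).reshape(3, 3)
    return Homography(H)


def apply_homography(H: Homography, traj: LandmarkTrajectory) -> LandmarkTrajectory:
    """Project every landmark of *traj* through *H*; metadata unchanged."""
    pts = np.column_stack([traj.x, traj.y])
    hom = np.column_stack([pts, np.ones(len(pts))]) @ H.H.T
    w = hom[:, 2]
    if np.any(w == 0):
        bad = int(traj.frame[np.nonzero(w == 0)[0][0]])
        raise ZeroDivisionError(
            f"frame {bad} of {traj.animal_id}/{traj.side}/{traj.joint} "
            "maps to infinity (w' = 0)"
        )
    mapped = hom[:, :2] / w[:, None]
    return LandmarkTrajectory(
        animal_id=traj.animal_id,
        session=traj.session,
        species=traj.species,
        sex=traj.sex,
        condition=traj.condition,
        side=traj.side,
        joint=traj.joint,
        fps=traj.fps,
        frame=traj.frame.copy(),
        x=mapped[:, 0],
        y=mapped[:, 1],
    )


# ---------------------------------------------------------------------------
# trajectory / annotation files
# ---------------------------------------------------------------------------

def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n_header


def write_trajectories(path, trajectories: list[LandmarkTrajectory]) -> None:
    """Write trajectories to the TSV format (y-up convention)."""
    path = Path(path)
    if not trajectories:
        raise ValueError("no trajectories to write")
    fps = {t.fps for t in trajectories}
    if len(fps) != 1:
        raise ValueError(f"trajectories mix frame rates: {sorted(fps)}")
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": t.animal_id,
                    "session": t.session,
                    "species": t.species,
                    "sex": t.sex,
                    "condition": t.condition,
                    "side": t.side,
                    "joint": t.joint,
                    "frame": t.frame,
                    "x": t.x,
                    "y": t.y,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gaitdf-trajectories v1\n")
        fh.write(f"# fps: {fps.pop()!r}\n")
        fh.write("# y_axis_direction: up\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_trajectories(path) -> list[LandmarkTrajectory]:
    """Read a trajectory TSV; raises :class:`FormatError` naming bad rows."""
    path = Path(path)
    meta, n_header = _read_header(path)
    if "fps" not in meta:
        raise FormatError(f"{path}: missing '# fps:' header line")
    try:
        fps = float(meta["fps"])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable fps {meta['fps']!r}") from exc
    y_dir = meta.get("y_axis_direction", "up")
    if y_dir not in ("up", "down"):
        raise FormatError(f"{path}: y_axis_direction must be 'up' or 'down'")

    table = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": str})
    missing = [c for c in _TRAJ_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if y_dir == "down":
        table["y"] = -table["y"]

    trajectories = []
    keys = ["animal_id", "session", "species", "sex", "condition", "side", "joint"]
    for key_vals, sub in table.groupby(keys, sort=True):
        sub = sub.sort_index()
        meta_row = dict(zip(keys, key_vals))
        try:
            trajectories.append(
                LandmarkTrajectory(
                    fps=fps,
                    frame=sub["frame"].to_numpy(),
                    x=sub["x"].to_numpy(dtype=float),
                    y=sub["y"].to_numpy(dtype=float),
                    **meta_row,
                )
            )
        except ValueError as exc:
            # +2: 1-based line numbers plus the column header line
            first = int(sub.index[0]) + n_header + 2
            raise FormatError(
                f"{path}: invalid trajectory starting at line {first}: {exc}"
            ) from exc
    return trajectories


def write_annotations(
    path, annotations: dict[tuple[str, str, str], list[StepAnnotation]]
) -> None:
    path = Path(path)
    rows = []
    for (animal_id, session, side), anns in sorted(annotations.items()):
        for k, ann in enumerate(anns):
            rows.append(
                {
                    "animal_id": animal_id,
                    "session": session,
                    "side": side,
                    "step_id": f"s{k + 1}",
                    "start_frame": ann.start_frame,
                    "end_frame": ann.end_frame,
                }
            )
    table = pd.DataFrame(rows, columns=_ANN_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gaitdf-steps v1\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_annotations(path) -> dict[tuple[str, str, str], list[StepAnnotation]]:
    path = Path(path)
    _, n_header = _read_header(path)
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": str})
    missing = [c for c in _ANN_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out: dict[tuple[str, str, str], list[StepAnnotation]] = {}
    for idx, row in table.iterrows():
        line = int(idx) + n_header + 2
        try:
            ann = StepAnnotation(
                start_frame=int(row["start_frame"]), end_frame=int(row["end_frame"])
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path}: invalid step annotation "
                f"{row['animal_id']}/{row['session']}/{row['side']}/"
                f"{row['step_id']} at line {line}: {exc}"
            ) from exc
        out.setdefault((row["animal_id"], row["session"], row["side"]), []).append(ann)
    return out


def read_dataset(
    traj_path, ann_path
) -> list[tuple[LandmarkTrajectory, list[StepAnnotation]]]:
    """Pair each trajectory with the step annotations of its limb."""
    trajectories = read_trajectories(traj_path)
    annotations = read_annotations(ann_path)
    pairs = []
    for traj in trajectories:
        key = (traj.animal_id, traj.session, traj.side)
        anns = annotations.get(key, [])
        if not anns:
            raise FormatError(
                f"no step annotations for {traj.animal_id}/{traj.session}/{traj.side}"
            )
        pairs.append((traj, anns))
    return pairs


def read_calibration(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read four-point correspondences; returns ``{side: (src, dst)}``.

    A flat ``{"src": ..., "dst": ...}`` file applies to both sides.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)

    def _pair(entry, label):
        src = np.asarray(entry.get("src"), dtype=float)
        dst = np.asarray(entry.get("dst"), dtype=float)
        if src.shape != (4, 2) or dst.shape != (4, 2):
            raise FormatError(
                f"{path}: {label} must provide 4 src and 4 dst points (x, y)"
            )
        return src, dst

    if "src" in data and "dst" in data:
        src, dst = _pair(data, "calibration")
        return {"left": (src, dst), "right": (src, dst)}
    out = {}
    for side in ("left", "right"):
        if side in data:
            out[side] = _pair(data[side], f"camera {side!r}")
    if not out:
        raise FormatError(f"{path}: no calibration entries found")
    return out
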