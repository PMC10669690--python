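"""The dissimilarity factor (DF) between normalized step curves.

For two curves a, b on the 100-bin step-cycle axis,

    DF(a, b) = (1/200) * [ sum_i (x_a(i) - x_b(i))^2
                         + sum_i (y_a(i) - y_b(i))^2 ],   i = 1..100

i.e. the mean of the 200 squared coordinate differences.  Note the
statistic is a mean *squared* difference (no square root), despite
sometimes being described in distance language; the squared form is
implemented verbatim.  DF is symmetric, non-negative, zero iff the
curves coincide at all 200 coordinates, and scales quadratically when
both curves' deviations from a common reference are scaled.

Group DF distributions are built from *cross-animal* pairs only: a step
curve of one animal is compared with every step curve of every other
animal in the group, never with curves of the same animal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import N_BINS, DFRecord, NormalizedStepCurve

__all__ = [
    "dissimilarity_factor",
    "pairwise_df",
    "df_records_to_frame",
    "write_df_records",
    "read_df_records",
]


def _check_comparable(a: NormalizedStepCurve, b: NormalizedStepCurve) -> None:
    if a.joint != b.joint or a.side != b.side:
        raise ValueError(
            f"cannot compare curves of different joint/side: "
            f"{a.joint}/{a.side} vs {b.joint}/{b.side}"
        )


def dissimilarity_factor(a: NormalizedStepCurve, b: NormalizedStepCurve) -> float:
    """Mean of the 200 squared coordinate differences between two curves."""
    _check_comparable(a, b)
    dx = a.x - b.x
    dy = a.y - b.y
    return float((dx @ dx + dy @ dy) / (2 * N_BINS))


def pairwise_df(curves: list[NormalizedStepCurve]) -> list[DFRecord]:
    """DF for every unordered cross-animal pair of *curves*.

    All curves must share joint and side and span at least two distinct
    animals.  For animals u < v with n_u and n_v curves, the output has
    sum over pairs of n_u * n_v records; no self-animal pairs and no
    (a, b)/(b, a) duplicates.
    """
    if not curves:
        raise ValueError("no curves given")
    first = curves[0]
    for c in curves[1:]:
        _check_comparable(first, c)
    animals = {c.animal_id for c in curves}
    if len(animals) < 2:
        raise ValueError(
            "cross-animal DF needs curves from at least 2 distinct animals; "
            f"got only {animals.pop()!r}"
        )

    X = np.stack([c.x for c in curves])
    Y = np.stack([c.y for c in curves])
    ids = np.array([c.animal_id for c in curves])
    records: list[DFRecord] = []
    for i in range(len(curves)):
        dx = X[i + 1 :] - X[i]
        dy = Y[i + 1 :] - Y[i]
        dfs = (np.einsum("ij,ij->i", dx, dx) + np.einsum("ij,ij->i", dy, dy)) / (
            2 * N_BINS
        )
        for off, df in enumerate(dfs):
            j = i + 1 + off
            if ids[j] == ids[i]:
                continue
            a, b = curves[i], curves[j]
            records.append(
                DFRecord(
                    curve_id_a=a.curve_id,
                    curve_id_b=b.curve_id,
                    animal_id_a=a.animal_id,
                    animal_id_b=b.animal_id,
                    group_a=a.group,
                    group_b=b.group,
                    joint=a.joint,
                    side=a.side,
                    df=float(df),
                )
            )
    return records


def df_records_to_frame(records: list[DFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "joint": [r.joint for r in records],
            "side": [r.side for r in records],
            "curve_id_a": [r.curve_id_a for r in records],
            "curve_id_b": [r.curve_id_b for r in records],
            "animal_id_a": [r.animal_id_a for r in records],
            "animal_id_b": [r.animal_id_b for r in records],
            "df": [r.df for r in records],
        }
    )


def write_df_records(path, records: list[DFRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gaitdf-df v1\n")
        df_records_to_frame(records).to_csv(
            fh, sep="\t", index=False, lineterminator="\n"
        )


def read_df_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
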