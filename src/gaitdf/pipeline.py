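"""End-to-end orchestration: simulate/ingest -> calibrate -> normalize ->
DF + bin-wise comparison + group statistics, under one config.

The run is a pure function of the :class:`RunConfig` (including the
seed): the machine-readable report and every intermediate artifact are
byte-identical across reruns.  The report mirrors the per-joint /
per-side structure of a kinematics results table: one bin-wise
percent-of-cycle-changed entry per configured contrast, and per
(joint, side) the group DF distribution summaries with
Kruskal–Wallis/Dunn results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ._version import __version__
from .dissimilarity import pairwise_df, write_df_records
from .io import (
    apply_homography,
    estimate_homography,
    read_calibration,
    read_dataset,
    write_annotations,
    write_trajectories,
)
from .normalization import normalize_dataset, write_curves
from .records import JOINTS, SIDES, NormalizedStepCurve, parse_group_code
from .stats import binwise_compare, kruskal_dunn
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "default_contrasts"]

log = logging.getLogger("gaitdf.pipeline")


def default_contrasts() -> list[tuple[str, str]]:
    """Condition contrasts within species x sex, plus sex contrasts within condition."""
    return [
        ("CMR", "LMR"), ("CFR", "LFR"), ("CMM", "LMM"), ("CFM", "LFM"),
        ("CMR", "CFR"), ("LMR", "LFR"), ("CMM", "CFM"), ("LMM", "LFM"),
    ]


class RunConfig(BaseModel):
    """Configuration of one full analysis run.

    Exactly one input source: a synthetic :class:`CohortConfig`, or
    trajectory + annotation file paths (with optional four-point
    calibration).  ``seed`` drives every random draw; for synthetic
    input it replaces the cohort config's own seed so one number
    governs the whole run.
    """

    synthetic: CohortConfig | None = None
    trajectories: str | None = None
    annotations: str | None = None
    calibration: str | None = None
    joints: list[str] = Field(default_factory=lambda: list(JOINTS))
    sides: list[str] = Field(default_factory=lambda: list(SIDES))
    contrasts: list[tuple[str, str]] = Field(default_factory=default_contrasts)
    axis: str = "y"
    alpha: float = 0.05
    tail: str = "one_sided_auto"
    correction: str | None = None
    animal_means: bool = False
    cross_condition_df: bool = False
    dunn_adjust: str | None = "bonferroni"
    outdir: str | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.synthetic is None) == (self.trajectories is None):
            raise ValueError(
                "exactly one input source required: 'synthetic' or "
                "'trajectories' (+ 'annotations')"
            )
        if self.trajectories is not None and self.annotations is None:
            raise ValueError("file input requires 'annotations'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for j in self.joints:
            if j not in JOINTS:
                raise ValueError(f"unknown joint {j!r}")
        for s in self.sides:
            if s not in SIDES:
                raise ValueError(f"unknown side {s!r}")
        for ga, gb in self.contrasts:
            parse_group_code(ga)
            parse_group_code(gb)
        return self

    def config_hash(self) -> str:
        payload = self.model_dump(exclude={"outdir"})
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2)

    @property
    def binwise(self) -> list[dict]:
        return self.data["binwise"]

    @property
    def df(self) -> list[dict]:
        return self.data["df"]

    def percent_changed(self, joint: str, side: str, contrast: str) -> int:
        for entry in self.binwise:
            if (
                entry["joint"] == joint
                and entry["side"] == side
                and entry["contrast"] == contrast
            ):
                return entry["percent_changed"]
        raise KeyError(f"no bin-wise entry for {joint}/{side}/{contrast}")


def _quartile_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n_pairs": int(len(values)),
        "median": float(med),
        "iqr": [float(q1), float(q3)],
        "mean": float(values.mean()),
    }


def _calibrated(trajectories, calibration_path):
    calib = read_calibration(calibration_path)
    hs = {side: estimate_homography(src, dst) for side, (src, dst) in calib.items()}
    out = []
    for traj in trajectories:
        H = hs.get(traj.side)
        out.append(apply_homography(H, traj) if H is not None else traj)
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full analysis; writes artifacts if an outdir is given.

    Artifacts: ``trajectories.tsv``, ``steps.tsv`` (and
    ``ground_truth.json`` for synthetic input), ``curves.tsv``,
    ``df.tsv``, one ``binwise_<joint>_<side>_<A>_vs_<B>.tsv`` per
    contrast, and ``report.json``.
    """
    outdir = Path(outdir) if outdir is not None else (
        Path(config.outdir) if config.outdir else None
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    ground_truth = None
    if config.synthetic is not None:
        cohort_cfg = config.synthetic.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(cohort_cfg)
        pairs = [(t, cohort.steps_for(t)) for t in cohort.trajectories]
        ground_truth = cohort.ground_truth
        log.info("simulate: %d trajectories", len(cohort.trajectories))
        if outdir is not None:
            write_trajectories(outdir / "trajectories.tsv", cohort.trajectories)
            write_annotations(outdir / "steps.tsv", cohort.annotations)
            with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
                json.dump(ground_truth, fh, sort_keys=True, indent=2)
    else:
        pairs = read_dataset(config.trajectories, config.annotations)
        log.info("ingest: %d trajectories", len(pairs))
        if config.calibration is not None:
            trajs = _calibrated([t for t, _ in pairs], config.calibration)
            pairs = [(t, anns) for t, (_, anns) in zip(trajs, pairs)]
            log.info("calibrate: %d trajectories corrected", len(pairs))

    curves = normalize_dataset(pairs)
    log.info("normalize: %d step curves", len(curves))
    if outdir is not None:
        write_curves(outdir / "curves.tsv", curves)

    by_js: dict[tuple[str, str], list[NormalizedStepCurve]] = {}
    for c in curves:
        if c.joint in config.joints and c.side in config.sides:
            by_js.setdefault((c.joint, c.side), []).append(c)

    # --- DF distributions + KW/Dunn per (joint, side) ---------------------
    df_entries = []
    all_records = []
    for joint in config.joints:
        for side in config.sides:
            group_curves: dict[str, list[NormalizedStepCurve]] = {}
            for c in by_js.get((joint, side), []):
                group_curves.setdefault(c.group, []).append(c)
            distributions: dict[str, np.ndarray] = {}
            summaries: dict[str, dict] = {}
            for group in sorted(group_curves):
                records = pairwise_df(group_curves[group])
                all_records.extend(records)
                values = np.array([r.df for r in records])
                distributions[group] = values
                summaries[group] = _quartile_summary(values)
            if config.cross_condition_df:
                by_ss: dict[tuple[str, str], list[NormalizedStepCurve]] = {}
                for c in by_js.get((joint, side), []):
                    by_ss.setdefault((c.species, c.sex), []).append(c)
                for (sp, sex), cs in sorted(by_ss.items()):
                    if len({c.condition for c in cs}) < 2:
                        continue
                    cross = [
                        r
                        for r in pairwise_df(cs)
                        if r.group_a != r.group_b
                    ]
                    all_records.extend(cross)
                    values = np.array([r.df for r in cross])
                    summaries[cross[0].group] = _quartile_summary(values)
            entry: dict = {"joint": joint, "side": side, "groups": summaries}
            if len(distributions) >= 2:
                result = kruskal_dunn(
                    distributions,
                    alpha=config.alpha,
                    p_adjust=config.dunn_adjust,
                    joint=joint,
                    side=side,
                )
                entry.update(
                    {
                        "kw_H": result.kw_H,
                        "kw_p": result.kw_p,
                        "dunn": {
                            f"{ga}|{gb}": float(result.dunn.loc[ga, gb])
                            for ga, gb in combinations(result.groups, 2)
                        },
                        "normality": {
                            g: (
                                None
                                if v is None
                                else {"statistic": v[0], "p": v[1]}
                            )
                            for g, v in result.normality.items()
                        },
                    }
                )
            df_entries.append(entry)
    log.info("df: %d cross-animal pair records", len(all_records))
    if outdir is not None and all_records:
        write_df_records(outdir / "df.tsv", all_records)

    # --- bin-wise contrasts ----------------------------------------------
    binwise_entries = []
    for joint in config.joints:
        for side in config.sides:
            group_curves = {}
            for c in by_js.get((joint, side), []):
                group_curves.setdefault(c.group, []).append(c)
            for ga, gb in config.contrasts:
                if ga not in group_curves or gb not in group_curves:
                    raise ValueError(
                        f"binwise stage: contrast {ga}:{gb} references a group "
                        f"with no curves at {joint}/{side}"
                    )
                comp = binwise_compare(
                    group_curves[ga],
                    group_curves[gb],
                    axis=config.axis,
                    alpha=config.alpha,
                    tail=config.tail,
                    correction=config.correction,
                    animal_means=config.animal_means,
                )
                table_name = f"binwise_{joint}_{side}_{ga}_vs_{gb}.tsv"
                if outdir is not None:
                    with open(
                        outdir / table_name, "w", encoding="utf-8", newline="\n"
                    ) as fh:
                        fh.write("# gaitdf-binwise v1\n")
                        comp.to_frame().to_csv(
                            fh, sep="\t", index=False, lineterminator="\n"
                        )
                binwise_entries.append(
                    {
                        "joint": joint,
                        "side": side,
                        "contrast": f"{ga}:{gb}",
                        "axis": config.axis,
                        "alpha": config.alpha,
                        "tail": config.tail,
                        "correction": config.correction,
                        "n_a": comp.n_a,
                        "n_b": comp.n_b,
                        "percent_changed": comp.percent_changed,
                        "table": table_name,
                    }
                )
    log.info("binwise: %d contrasts", len(binwise_entries))

    report = RunReport(
        data={
            "provenance": {
                "package": "gaitdf",
                "version": __version__,
                "config_sha256": config.config_hash(),
                "seed": config.seed,
            },
            "config": config.model_dump(exclude={"outdir"}),
            "n_curves": len(curves),
            "binwise": binwise_entries,
            "df": df_entries,
        }
    )
    if ground_truth is not None:
        report.data["ground_truth_file"] = "ground_truth.json"
    if outdir is not None:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            fh.write(report.to_json())
    return report
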