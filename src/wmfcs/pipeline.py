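"""End-to-end orchestration: simulate -> QC -> clean -> FCS -> stats -> report.

A run is fully determined by its configuration and seed; the manifest records
the configuration, seed, subject counts before/after QC and a SHA-256 hash of
every output file, so a rerun from the same manifest reproduces every output
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import connectivity, inference, preprocess, qc, synthetic

log = logging.getLogger("wmfcs")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report", "format_p"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Full-run configuration with the analysis thresholds.

    Defaults follow the published analysis: drop 5 volumes, FD censoring at
    0.5 mm, Euler modified-Z cutoff -3.5, mean-FD cutoff 0.5 mm, outlier
    ratio cutoff 0.3, high-pass 0.01 Hz, TR 2.4 s, BH-FDR at alpha 0.05 with
    family sizes 50 (WW) and 114 (GW).
    """

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    n_drop: int = 5
    fd_threshold: float = 0.5
    euler_threshold: float = -3.5
    mean_fd_max: float = 0.5
    ratio_max: float = 0.3
    highpass_cutoff: float = 0.01
    head_radius: float = 50.0
    alpha: float = 0.05
    family_sizes: dict[str, int] = field(default_factory=lambda: {"WW": 50, "GW": 114})
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        known_cohort = {f.name for f in dataclasses.fields(synthetic.CohortConfig)}
        bad = set(cohort_raw) - known_cohort
        if bad:
            raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
        if "effect_map" in cohort_raw:
            cohort_raw["effect_map"] = tuple(
                (str(n), float(d)) for n, d in cohort_raw["effect_map"]
            )
        if "dose_targets" in cohort_raw:
            cohort_raw["dose_targets"] = tuple(
                (str(a), str(b), float(r)) for a, b, r in cohort_raw["dose_targets"]
            )
        cohort = synthetic.CohortConfig(**cohort_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown run config keys: {sorted(bad)}")
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohort"]["dose_means"] = dict(d["cohort"]["dose_means"])
        d["cohort"]["dose_sds"] = dict(d["cohort"]["dose_sds"])
        return d


def format_p(p: float) -> str:
    """Two-significant-figure p-value rendering (0.0806 -> '0.081')."""
    if not np.isfinite(p):
        return "nan"
    return f"{p:.2g}"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path = "wmfcs_run") -> Path:
    """Execute the full pipeline into ``out_dir``; returns the run directory.

    Stages: simulate cohort -> subject QC -> frame-level cleaning -> FCS ->
    group statistics, dose associations, power and demographics -> report.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = synthetic.simulate_cohort(config.cohort)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    log.info("simulated cohort: %d subjects", len(cohort.records))
    synthetic.records_to_frame(cohort.records).to_csv(
        out / "participants.tsv", sep="\t", index=False
    )
    cohort.scheme.to_tsv(out / "scheme.tsv")

    # QC on the volume-dropped traces (flags index analysed frames)
    try:
        dropped: dict[str, tuple[preprocess.RegionTimeSeries, qc.MotionTrace]] = {}
        fd_map: dict[str, qc.FDSeries] = {}
        for rec in cohort.records:
            ts, trace = preprocess.drop_initial_volumes(
                cohort.series[rec.subject_id],
                cohort.motion[rec.subject_id],
                config.n_drop,
            )
            dropped[rec.subject_id] = (ts, trace)
            fd_map[rec.subject_id] = qc.compute_fd(
                trace, head_radius=config.head_radius, threshold=config.fd_threshold
            )
        qc_report = qc.qc_subjects(
            cohort.records,
            fd_map,
            euler_threshold=config.euler_threshold,
            mean_fd_max=config.mean_fd_max,
            ratio_max=config.ratio_max,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage qc failed: {exc}") from exc
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    included = set(qc_report.loc[qc_report["included"], "subject_id"])
    if not included:
        raise PipelineError(
            "stage qc failed: all subjects excluded; QC summary:\n"
            + qc_report[["subject_id", "exclusion_reasons"]].to_string(index=False)
        )
    log.info("QC kept %d of %d subjects", len(included), len(cohort.records))

    # frame-level cleaning and FCS
    fcs_frames = []
    for rec in cohort.records:
        if rec.subject_id not in included:
            continue
        ts, trace = dropped[rec.subject_id]
        try:
            ts = preprocess.censor_interpolate(
                ts, fd_map[rec.subject_id], threshold=config.fd_threshold
            )
            design = preprocess.build_friston24(trace)
            ts = preprocess.nuisance_regress(ts, design)
            ts = preprocess.highpass(ts, cutoff=config.highpass_cutoff)
            fcs_frames.append(
                connectivity.subject_fcs(ts, cohort.scheme, rec.subject_id)
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stage preprocess/fcs failed for subject {rec.subject_id}: {exc}"
            ) from exc
    fcs = pd.concat(fcs_frames, ignore_index=True)
    fcs.to_csv(out / "fcs.tsv", sep="\t", index=False)

    # statistics
    records_df = synthetic.records_to_frame(cohort.records)
    records_df = records_df[records_df["subject_id"].isin(included)]
    try:
        stats_df = inference.region_group_test(
            fcs, records_df, family_sizes=config.family_sizes, alpha=config.alpha
        )
        demo_df = inference.demographics_table(records_df)
        sig_gw = stats_df.loc[
            (stats_df["family"] == "GW") & stats_df["significant"], "region"
        ].tolist()
        dose_regions = sig_gw or sorted({r for r, _, _ in config.cohort.dose_targets})
        dose_vars = [
            v for v in ("mdrt_brainstem", "mdrt_left_temporal")
            if records_df[v].notna().any()
        ]
        dose_df = (
            inference.dose_association(fcs, records_df, dose_vars, dose_regions)
            if dose_vars and dose_regions
            else pd.DataFrame(
                columns=["region", "dose_variable", "r", "t", "p", "n", "df", "n_excluded"]
            )
        )
        power_rows = [
            {
                "region": row.region,
                "family": row.family,
                "effect_size": (res := inference.posthoc_power_two_sample(
                    row.mean_pre, row.sd_pre, row.n_pre,
                    row.mean_post, row.sd_post, row.n_post,
                    alpha=config.alpha,
                )).effect_size,
                "power": res.power,
            }
            for row in stats_df[stats_df["significant"]].itertuples()
        ]
        power_df = pd.DataFrame(power_rows, columns=["region", "family", "effect_size", "power"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage stats failed: {exc}") from exc

    stats_df.to_csv(out / "table2.tsv", sep="\t", index=False)
    demo_df.to_csv(out / "demographics.tsv", sep="\t", index=False)
    dose_df.to_csv(out / "dose_assoc.tsv", sep="\t", index=False)
    power_df.to_csv(out / "power.tsv", sep="\t", index=False)

    render_report(out, alpha=config.alpha)

    outputs = sorted(
        p.name
        for p in out.iterdir()
        if p.suffix in (".tsv", ".md") and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_subjects": len(cohort.records),
        "n_included": len(included),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def render_report(run_dir: str | Path, alpha: float = 0.05) -> Path:
    """Write a markdown summary of a finished run's statistics tables."""
    run = Path(run_dir)
    needed = ["table2.tsv", "demographics.tsv", "dose_assoc.tsv", "power.tsv"]
    missing = [n for n in needed if not (run / n).exists()]
    if missing:
        raise PipelineError(f"stage report failed: missing tables {missing}")
    stats_df = pd.read_csv(run / "table2.tsv", sep="\t")
    demo_df = pd.read_csv(run / "demographics.tsv", sep="\t")
    dose_df = pd.read_csv(run / "dose_assoc.tsv", sep="\t")

    lines = ["# White-matter FCS analysis report", ""]
    lines += ["## Demographics", ""]
    lines += ["| parameter | pre-RT | post-RT | p |", "|---|---|---|---|"]
    for row in demo_df.itertuples():
        lines.append(f"| {row.parameter} | {row.pre} | {row.post} | {format_p(row.p)} |")
    lines.append("")
    for family, label in (("WW", "WW-FCS (WM-WM)"), ("GW", "GW-FCS (GM-WM)")):
        fam = stats_df[(stats_df["family"] == family) & stats_df["significant"]]
        lines += [f"## Significant regions, {label} (FDR q < {alpha:g})", ""]
        if fam.empty:
            lines += [f"No regions significant in the {family} family.", ""]
            continue
        lines += [
            "| region | pre mean (SD) | post mean (SD) | t | p | p-FDR |",
            "|---|---|---|---|---|---|",
        ]
        for row in fam.itertuples():
            lines.append(
                f"| {row.region} | {row.mean_pre:.2f} ({row.sd_pre:.2f}) | "
                f"{row.mean_post:.2f} ({row.sd_post:.2f}) | {row.t:.2f} | "
                f"{format_p(row.p)} | {format_p(row.p_fdr)} |"
            )
        lines.append("")
    lines += ["## Dose associations (partial correlation)", ""]
    if dose_df.empty:
        lines += ["No dose associations computed.", ""]
    else:
        lines += ["| region | dose variable | r | p | n | df |", "|---|---|---|---|---|---|"]
        for row in dose_df.itertuples():
            lines.append(
                f"| {row.region} | {row.dose_variable} | {row.r:.2f} | "
                f"{format_p(row.p)} | {row.n} | {row.df} |"
            )
        lines.append("")
    path = run / "report.md"
    path.write_text("\n".join(lines))
    return path
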