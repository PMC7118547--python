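"""End-to-end orchestration: simulate → process → analyze → report.

Each stage reads the previous stage's files, so stages can be rerun in
isolation. A run manifest records the config hash, seed, package versions,
and row counts at every stage, reconciling with the exclusion report so the
participant flow is auditable. With a fixed seed the whole pipeline is
deterministic: identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bouts import (
    CutPoints,
    DEFAULT_CATEGORIES,
    classify_intensity,
    detect_sedentary_bouts,
    pattern_table,
    summarize_patterns,
)
from .distributions import Dist
from .errors import (
    CollinearityError,
    ConfigError,
    InsufficientDataError,
    PipelineError,
)
from .io import (
    SF36_ALL,
    check_linkage,
    read_covariates,
    read_epoch_csv,
    read_sleep_diary,
    write_covariates,
    write_epoch_csv,
    write_sleep_diaries,
)
from .models import assign_groups, fit_ancova, run_model_grid
from .synthetic import (
    SleepSchedule,
    SyntheticConfig,
    generate_cohort,
    write_ground_truth,
)
from .wear import (
    WearParams,
    apply_sleep_exclusion,
    detect_nonwear,
    exclusion_report,
    select_valid_days,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run: either synthetic generation or input paths."""

    synthetic: SyntheticConfig | None = None
    epochs_dir: str | None = None
    diary_path: str | None = None
    covariates_path: str | None = None
    wear: WearParams = field(default_factory=WearParams)
    cuts: CutPoints = field(default_factory=CutPoints)
    categories: tuple[int, ...] = DEFAULT_CATEGORIES
    output_dir: str = "sedpatterns_out"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        have_paths = any([self.epochs_dir, self.diary_path, self.covariates_path])
        if self.synthetic is not None and have_paths:
            raise ConfigError("supply either a synthetic config or input paths, not both")
        if self.synthetic is None and not (
            self.epochs_dir and self.diary_path and self.covariates_path
        ):
            raise ConfigError(
                "either a synthetic config or all three input paths are required"
            )
        cats = tuple(self.categories)
        if list(cats) != sorted(cats) or any(c < 1 for c in cats) or len(cats) == 0:
            raise ConfigError("categories must be ascending and >= 1 minute")
        self.wear.validate()
        self.cuts.validate()
        if self.synthetic is not None:
            self.synthetic.validate()
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "synthetic": enc(self.synthetic) if self.synthetic else None,
            "epochs_dir": self.epochs_dir,
            "diary_path": self.diary_path,
            "covariates_path": self.covariates_path,
            "wear": enc(self.wear),
            "cuts": enc(self.cuts),
            "categories": list(self.categories),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        # output location does not affect the science; keep it out of the hash
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def dist(d):
            return Dist(d["family"], dict(d["params"]))

        synth = None
        if raw.get("synthetic"):
            s = dict(raw["synthetic"])
            for key in (
                "sedentary_bout_dist",
                "active_bout_dist",
                "active_intensity_dist",
                "sedentary_count_dist",
                "nonwear_duration_dist",
            ):
                if key in s:
                    s[key] = dist(s[key])
            if "sleep_schedule" in s:
                s["sleep_schedule"] = SleepSchedule(**s["sleep_schedule"])
            synth = SyntheticConfig(**s)
        wear = WearParams(**raw.get("wear", {}))
        cuts = CutPoints(**raw.get("cuts", {}))
        return cls(
            synthetic=synth,
            epochs_dir=raw.get("epochs_dir"),
            diary_path=raw.get("diary_path"),
            covariates_path=raw.get("covariates_path"),
            wear=wear,
            cuts=cuts,
            categories=tuple(raw.get("categories", DEFAULT_CATEGORIES)),
            output_dir=raw.get("output_dir", "sedpatterns_out"),
            seed=int(raw.get("seed", 0)),
        ).validate()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic cohort and write its three CSV dialects + truth."""
    config.validate()
    if config.synthetic is None:
        raise PipelineError("simulate", "no synthetic config supplied")
    out = Path(config.output_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    synth = dataclasses.replace(config.synthetic, seed=config.seed)
    cohort = generate_cohort(synth)
    for pid, series in cohort.series.items():
        write_epoch_csv(series, out / "epochs" / f"{pid}.csv")
        write_ground_truth(series, out / "truth" / f"{pid}.json")
    write_sleep_diaries(cohort.diaries, out / "diary.csv")
    write_covariates(cohort.table, out / "covariates.csv")
    cohort.truth_metrics.to_csv(out / "truth" / "pattern_metrics.csv", index=False)
    return {"n_participants_simulated": len(cohort.series)}


def stage_process(config: PipelineConfig) -> dict:
    """Wear-validate every participant and compute the pattern-summary table."""
    config.validate()
    out = Path(config.output_dir)
    if config.synthetic is not None:
        epochs_dir = out / "epochs"
        diary_path = out / "diary.csv"
        covariates_path = out / "covariates.csv"
    else:
        epochs_dir = Path(config.epochs_dir)
        diary_path = Path(config.diary_path)
        covariates_path = Path(config.covariates_path)
    out.mkdir(parents=True, exist_ok=True)

    diaries = read_sleep_diary(diary_path)
    covariates = read_covariates(covariates_path)
    files = sorted(epochs_dir.glob("*.csv"))
    if not files:
        raise PipelineError("process", f"no epoch CSVs in {epochs_dir}")
    check_linkage(covariates, [f.stem for f in files])

    selections, summaries = {}, []
    for f in files:
        pid = f.stem
        try:
            series = read_epoch_csv(f)
            detect_nonwear(series, config.wear)
            if pid not in diaries:
                raise PipelineError("process", "no sleep diary records", pid)
            apply_sleep_exclusion(series, diaries[pid])
            sel = select_valid_days(series, config.wear)
            selections[pid] = sel
            if not sel.retained:
                continue
            classify_intensity(series, config.cuts)
            bouts = detect_sedentary_bouts(series)
            summaries.append(summarize_patterns(series, bouts, config.categories))
        except PipelineError:
            raise
        except Exception as exc:  # reraise with stage + participant context
            raise PipelineError("process", str(exc), pid) from exc

    report = exclusion_report(selections)
    report.to_csv(out / "exclusion_report.csv", index=False)
    table = pattern_table(summaries, config.categories)
    table.to_csv(out / "pattern_summary.csv", index=False)
    return {
        "n_participants_processed": len(files),
        "n_retained": int(report["retained"].sum()),
        "n_excluded": int((~report["retained"]).sum()),
    }


def analysis_table(config: PipelineConfig) -> pd.DataFrame:
    """Merge pattern summaries with covariates/outcomes for retained participants."""
    out = Path(config.output_dir)
    patterns = pd.read_csv(out / "pattern_summary.csv", dtype={"participant_id": str})
    covariates_path = (
        out / "covariates.csv" if config.synthetic is not None else Path(config.covariates_path)
    )
    cov = read_covariates(covariates_path)
    return patterns.merge(cov, on="participant_id", how="inner")


def stage_analyze(config: PipelineConfig) -> dict:
    """Fit the model grid and the four-group ANCOVA; write long-format results."""
    config.validate()
    out = Path(config.output_dir)
    data = analysis_table(config)

    pct = [f"pct_st_in_bouts_{L}" for L in config.categories]
    freq = [f"bouts_per_sed_hour_{L}" for L in config.categories]
    outcomes = list(SF36_ALL)
    grid = pd.concat(
        [
            run_model_grid(data, outcomes, pct, ["base", "base_mvpa"]),
            run_model_grid(data, outcomes, freq, ["base_st", "base_st_mvpa"]),
        ],
        ignore_index=True,
    )
    grid.to_csv(out / "model_results.csv", index=False)

    groups = assign_groups(data)
    gout = groups.copy()
    gout.to_csv(out / "groups.csv", index=False)

    mean_rows, contrast_rows, ancova_failures = [], [], []
    for include_mvpa in (False, True):
        for outcome in outcomes:
            try:
                res = fit_ancova(data, groups, outcome, include_mvpa=include_mvpa)
            except (CollinearityError, InsufficientDataError) as exc:
                logger.warning("ANCOVA %s (mvpa=%s) skipped: %s", outcome, include_mvpa, exc)
                ancova_failures.append(outcome)
                continue
            for g, m in res.adjusted_means.items():
                mean_rows.append(
                    {
                        "outcome": outcome,
                        "include_mvpa": include_mvpa,
                        "group": g,
                        "adjusted_mean": m,
                        "n": res.group_sizes[g],
                    }
                )
            c = res.contrasts.copy()
            c.insert(0, "outcome", outcome)
            c.insert(1, "include_mvpa", include_mvpa)
            contrast_rows.append(c)
    mean_cols = ["outcome", "include_mvpa", "group", "adjusted_mean", "n"]
    contrast_cols = ["outcome", "include_mvpa", "group1", "group2",
                     "diff", "se", "ci_low", "ci_high", "p"]
    pd.DataFrame(mean_rows, columns=mean_cols).to_csv(out / "ancova_means.csv", index=False)
    (
        pd.concat(contrast_rows, ignore_index=True)
        if contrast_rows
        else pd.DataFrame(columns=contrast_cols)
    ).to_csv(out / "ancova_contrasts.csv", index=False)
    return {
        "n_analysis_rows": len(data),
        "n_model_cells": len(grid),
        "n_model_tests": int(grid["error"].eq("").sum()),
        "n_ancova_failures": len(ancova_failures),
        "st_median_min_per_week": groups.attrs["st_median"],
        "bout_duration_median_min": groups.attrs["dur_median"],
    }


def stage_report(config: PipelineConfig) -> dict:
    """Render a human-readable summary of descriptives and associations."""
    out = Path(config.output_dir)
    for name in ("pattern_summary.csv", "model_results.csv"):
        if not (out / name).exists():
            raise PipelineError("report", f"missing pipeline output {name}")
    lines = ["# Sedentary-pattern analysis report", ""]

    patterns = pd.read_csv(out / "pattern_summary.csv")
    lines.append(f"Retained participants: {len(patterns)}")
    lines.append("")
    lines.append("## Descriptives (mean (SD)) over retained participants")
    lines.append("")
    lines.append("| variable | mean | SD |")
    lines.append("|---|---|---|")
    for c in patterns.columns:
        if c in ("participant_id",):
            continue
        col = pd.to_numeric(patterns[c], errors="coerce")
        lines.append(f"| {c} | {col.mean():.1f} | {col.std(ddof=1):.1f} |")

    grid = pd.read_csv(out / "model_results.csv")
    fitted = grid[grid["error"].isna() | (grid["error"] == "")]
    lines.append("")
    lines.append(
        f"## Associations ({len(fitted)} models fitted, no multiplicity adjustment)"
    )
    lines.append("")
    lines.append("| outcome | exposure | family | B | SE | beta | p |")
    lines.append("|---|---|---|---|---|---|---|")
    for r in fitted.itertuples():
        lines.append(
            f"| {r.outcome} | {r.exposure} | {r.family} | "
            f"{r.B:.3f} | {r.SE:.3f} | {r.beta:.3f} | {r.p:.3g} |"
        )

    means_path = out / "ancova_means.csv"
    if means_path.exists():
        means = pd.read_csv(means_path)
        lines.append("")
        lines.append("## Adjusted means by joint sedentary group (no MVPA adjustment)")
        lines.append("")
        lines.append("| outcome | group | adjusted mean | n |")
        lines.append("|---|---|---|---|")
        for r in means[~means["include_mvpa"]].itertuples():
            lines.append(f"| {r.outcome} | {r.group} | {r.adjusted_mean:.2f} | {r.n} |")

    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return {"report_lines": len(lines)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage and write the reproducibility manifest."""
    config.validate()
    counts: dict = {}
    if config.synthetic is not None:
        counts.update(stage_simulate(config))
    counts.update(stage_process(config))
    counts.update(stage_analyze(config))
    counts.update(stage_report(config))
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "stage_counts": counts,
    }
    out = Path(config.output_dir)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
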