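"""End-to-end pipeline: simulate -> score -> compare -> report.

A run is a pure function of :class:`RunConfig`; the manifest written next
to the outputs (config echo + seed + version) suffices to reproduce it
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .agreement import MethodComparison, bland_altman, compare_all, comparison_table, paired_series
from .cohort import CohortBundle, generate_cohort, read_cohort, write_cohort
from .params import GeneratorParams
from .score import score_cohort
from .urinary import CompletenessRules, ParticipantProfile, UrineRecord, screen_completeness

log = logging.getLogger("dietna")


class CompletenessConfig(BaseModel):
    min_volume: float = 0.5
    creat_per_kg_bounds_male: tuple[float, float] = (14.4, 33.6)
    creat_per_kg_bounds_female: tuple[float, float] = (10.8, 25.2)
    enabled_rules: tuple[str, ...] = ("min_volume", "creatinine_range")

    def rules(self) -> CompletenessRules:
        return CompletenessRules(**self.model_dump())


class RunConfig(BaseModel):
    """Full configuration of a pipeline run."""

    generator: GeneratorParams = Field(default_factory=GeneratorParams)
    completeness: CompletenessConfig = Field(default_factory=CompletenessConfig)
    dashes_per_yes: int = Field(default=2, ge=1, le=2)
    dr15_share: float = Field(default=0.15, ge=0, lt=0.5)
    dr15_mode: str = "share_of_total"
    icc_form: str = "absolute_agreement"
    sensitivity: bool = False
    out_dir: str = "results/run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def screen_cohort(bundle: CohortBundle, rules: CompletenessRules) -> pd.Series:
    """Completeness flags per participant from the urine table."""
    profiles = bundle.profiles.set_index("participant_id")
    flags = {}
    for row in bundle.urine24.itertuples():
        record = UrineRecord(
            participant_id=row.participant_id,
            kind="collection_24h",
            na_conc=row.na_mmol_l,
            k_conc=row.k_mmol_l,
            creat_conc=row.creat_mg_dl,
            volume=row.volume_l,
        )
        p = profiles.loc[row.participant_id]
        profile = ParticipantProfile(
            participant_id=row.participant_id,
            age_y=p["age_y"],
            sex=p["sex"],
            weight_kg=p["weight_kg"],
            height_cm=p["height_cm"],
        )
        complete, _ = screen_completeness(record, profile, rules)
        flags[row.participant_id] = complete
    return pd.Series(flags, name="complete")


@dataclass
class RunBundle:
    """Everything a pipeline run produced, in memory."""

    config: RunConfig
    cohort: CohortBundle
    estimates: pd.DataFrame
    completeness: pd.Series
    comparisons: list[MethodComparison]
    comparisons_sensitivity: list[MethodComparison] = field(default_factory=list)


def run_pipeline(config: RunConfig, out_dir=None) -> RunBundle:
    """Execute all stages and write the output files under ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        bundle = generate_cohort(config.generator)
        write_cohort(bundle, out / "cohort")
        log.info("simulate: %d participants", len(bundle.profiles))

        stage = "score"
        estimates = score_cohort(
            bundle,
            dashes_per_yes=config.dashes_per_yes,
            dr15_share=config.dr15_share,
            dr15_mode=config.dr15_mode,
        )
        estimates.to_csv(out / "estimates.csv", index=False)
        per_method = estimates.groupby("method_id", observed=True).size()
        log.info("score: %d estimate rows (%s)", len(estimates), dict(per_method))

        stage = "screen"
        completeness = screen_cohort(bundle, config.completeness.rules())
        n_incomplete = int((~completeness).sum())
        log.info("screen: %d/%d collections incomplete", n_incomplete, len(completeness))

        stage = "compare"
        comparisons = compare_all(
            estimates, completeness, sensitivity=False, icc_form=config.icc_form
        )
        table = comparison_table(comparisons)
        table.to_csv(out / "comparison_table.csv", index=False)
        sens = []
        if config.sensitivity:
            sens = compare_all(
                estimates, completeness, sensitivity=True, icc_form=config.icc_form
            )
            comparison_table(sens).to_csv(out / "comparison_table_sensitivity.csv", index=False)
        for comp in comparisons:
            pairs, *_ = bland_altman(paired_series(estimates, comp.method_id))
            pairs.to_csv(out / f"bland_altman_{comp.method_id}.csv", index=False)
        log.info("compare: %d methods vs u24", len(comparisons))

        stage = "report"
        run = RunBundle(config, bundle, estimates, completeness, comparisons, sens)
        (out / "report.txt").write_text(render_report(run))
        (out / "report.json").write_text(
            json.dumps(
                {
                    "comparisons": [c.as_dict() for c in comparisons],
                    "comparisons_sensitivity": [c.as_dict() for c in sens],
                },
                indent=2,
                default=float,
            )
        )
        manifest = {
            "dietna_version": __version__,
            "seed": config.generator.seed,
            "config": config.model_dump(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    except Exception as err:  # pragma: no cover - error path context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return run


_REPORT_COLUMNS = [
    ("n", "n", 0),
    ("mean_estimate", "mean", 1),
    ("sd_estimate", "sd", 1),
    ("bias_mean", "bias", 1),
    ("bias_sd", "bias_sd", 1),
    ("p_paired", "p", 3),
    ("pearson_r", "r", 3),
    ("spearman_rho", "rho", 3),
    ("icc", "ICC", 2),
    ("icc_ci_low", "ICC_lo", 2),
    ("icc_ci_high", "ICC_hi", 2),
    ("loa_lower", "LoA_lo", 1),
    ("loa_upper", "LoA_hi", 1),
    ("prop_bias_slope", "beta", 3),
    ("prop_bias_p", "beta_p", 3),
]


def _format_section(comparisons: list[MethodComparison], title: str) -> list[str]:
    lines = [title, "-" * len(title)]
    header = f"{'method':<18}" + "".join(f"{h:>9}" for _, h, _ in _REPORT_COLUMNS) + f"{'class':>11}"
    lines.append(header)
    for c in comparisons:
        cells = []
        for attr, _, nd in _REPORT_COLUMNS:
            value = getattr(c, attr)
            cells.append(f"{value:>9.{nd}f}" if pd.notna(value) else f"{'NA':>9}")
        lines.append(f"{c.method_id:<18}" + "".join(cells) + f"{c.icc_class:>11}")
    return lines


def render_report(run: RunBundle) -> str:
    """Human-readable comparison tables, 1-decimal mg rounding.

    Internal computation is at full precision; this view rounds for
    display only (mg columns to 1 decimal, coefficients to 2-3).
    """
    u24 = run.estimates.loc[run.estimates["method_id"] == "u24", "na_mg_per_day"]
    lines = [
        "Dietary sodium method comparison vs 24-h urine collection",
        "=========================================================",
        f"participants: {len(run.cohort.profiles)}",
        f"incomplete collections: {int((~run.completeness).sum())} "
        f"({100 * (~run.completeness).mean():.1f}%)",
    ]
    if len(u24):
        lines.append(f"mean 24UNa: {u24.mean():.1f} +/- {u24.std(ddof=1):.1f} mg/d (n {len(u24)})")
    lines.append("")
    if run.comparisons:
        lines += _format_section(run.comparisons, "All participants")
    else:
        lines += ["All participants", "----------------", "(no comparisons)"]
    if run.comparisons_sensitivity:
        lines.append("")
        lines += _format_section(
            run.comparisons_sensitivity, "Sensitivity: complete collections only"
        )
    lines.append("")
    lines.append("Note: no multiple-testing correction is applied.")
    return "\n".join(lines) + "\n"
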