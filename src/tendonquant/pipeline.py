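"""Cohort-scale orchestration: quantify a manifest, analyse a cohort table,
and render the results report.

Batch quantification isolates per-section failures: a section that cannot be
read or processed is logged and skipped, and the remaining sections still
produce rows.  The report embeds the fully resolved configuration so a run
can be audited and reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from .config import RunConfig
from .errors import ConfigurationError
from .io import load_manifest_row, read_manifest
from .quantification import SectionMetrics, quantify_section
from .statistics import (
    EARLY_WEEKS,
    CohortAnalysis,
    analyze_cohort,
    cohort_to_long,
)

log = logging.getLogger("tendonquant")

COHORT_COLUMNS = [f.name for f in fields(SectionMetrics)]


def run_quantify(config: RunConfig, root: str | Path = ".") -> tuple[pd.DataFrame, int]:
    """Quantify every manifest row; returns (cohort table, n_failures)."""
    root = Path(root)
    manifest = read_manifest(root / config.manifest)
    rows: list[dict] = []
    failures = 0
    if manifest.empty:
        log.warning("manifest %s is empty; writing header-only cohort", config.manifest)
    for _, row in manifest.iterrows():
        try:
            section = load_manifest_row(row, root)
            metrics = quantify_section(section, config.quant)
            rows.append(metrics.to_row())
            log.info("quantified section %s (%s)", section.section_id, section.stain_kind)
        except Exception as exc:
            failures += 1
            log.warning("section %s failed and was skipped: %s", row["section_id"], exc)
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return cohort, failures


def run_analyze(cohort: pd.DataFrame, config: RunConfig) -> tuple[CohortAnalysis, pd.DataFrame]:
    """Run the statistics stage on a cohort table; returns (analysis, results CSV table)."""
    required = {"section_id", "stain_kind", "group", "week"}
    if not required <= set(cohort.columns):
        raise ConfigurationError(
            f"cohort table lacks columns {sorted(required - set(cohort.columns))}"
        )
    long = cohort_to_long(cohort)
    analysis = analyze_cohort(long, alpha=config.alpha)
    for w in analysis.warnings:
        log.warning("%s", w)
    return analysis, results_table(analysis)


def results_table(analysis: CohortAnalysis) -> pd.DataFrame:
    """Flatten an analysis into one tidy CSV-ready table."""
    rows = []
    for metric, res in analysis.early_anova.items():
        for name, eff in res.effects.items():
            rows.append(
                {
                    "analysis": "early_two_way",
                    "metric": metric,
                    "term": name,
                    "stratum": "",
                    "comparison": "",
                    "ss": eff.ss,
                    "df": eff.df,
                    "F": eff.F,
                    "p": eff.p,
                    "significant": eff.p < analysis.alpha,
                }
            )
    for (metric, wk), pairs in analysis.early_tukey.items():
        for t in pairs:
            rows.append(
                {
                    "analysis": "early_tukey",
                    "metric": metric,
                    "term": "group",
                    "stratum": f"week={wk}",
                    "comparison": f"{t.group_a} vs {t.group_b}",
                    "ss": "",
                    "df": "",
                    "F": "",
                    "p": t.p_adj,
                    "significant": t.reject,
                }
            )
    for metric, res in analysis.late_anova.items():
        for name, eff in res.effects.items():
            rows.append(
                {
                    "analysis": "late_one_way",
                    "metric": metric,
                    "term": name,
                    "stratum": "FL",
                    "comparison": "",
                    "ss": eff.ss,
                    "df": eff.df,
                    "F": eff.F,
                    "p": eff.p,
                    "significant": eff.p < analysis.alpha,
                }
            )
    for metric, pairs in analysis.late_tukey.items():
        for t in pairs:
            rows.append(
                {
                    "analysis": "late_tukey",
                    "metric": metric,
                    "term": "week",
                    "stratum": "FL",
                    "comparison": f"week {t.group_a} vs week {t.group_b}",
                    "ss": "",
                    "df": "",
                    "F": "",
                    "p": t.p_adj,
                    "significant": t.reject,
                }
            )
    return pd.DataFrame(rows)


def _week_markers(analysis: CohortAnalysis, metric: str) -> dict[int, str]:
    """Per-week significance markers: ``#`` = a contrast involving minimal
    loading rejects, ``¤`` = reduced vs full loading rejects."""
    markers: dict[int, str] = {}
    for wk in EARLY_WEEKS:
        pairs = analysis.early_tukey.get((metric, wk), [])
        mark = ""
        if any(t.reject and "ML" in (t.group_a, t.group_b) for t in pairs):
            mark += "#"
        if any(
            t.reject and {t.group_a, t.group_b} == {"RL", "FL"} for t in pairs
        ):
            mark += "¤"
        markers[wk] = mark
    return markers


def _late_markers(analysis: CohortAnalysis, metric: str) -> dict[str, str]:
    """Per-week time markers in late healing: ``a`` = differs from week 3,
    ``b`` = differs from week 12."""
    out: dict[str, str] = {}
    for t in analysis.late_tukey.get(metric, []):
        for ref, sym in (("3", "a"), ("12", "b")):
            if t.reject and ref in (t.group_a, t.group_b):
                other = t.group_b if t.group_a == ref else t.group_a
                out[other] = out.get(other, "") + sym
    return out


def render_report(analysis: CohortAnalysis, config: RunConfig) -> str:
    """Human-readable report: resolved configuration, ANOVA tables, and the
    annotated within-week / across-time Tukey contrasts."""
    lines = ["tendonquant cohort report", "=" * 40, "", "Resolved configuration:"]
    lines += [
        "  " + ln for ln in yaml.safe_dump(config.to_dict(), sort_keys=True).splitlines()
    ]
    lines.append("")
    lines.append("Early healing (weeks 1-3, ML/RL/FL): two-way ANOVA, load x time")
    for metric, res in analysis.early_anova.items():
        lines.append(f"  {metric}:")
        for name, eff in res.effects.items():
            star = " *" if eff.p < analysis.alpha else ""
            lines.append(
                f"    {name:<12s} F({eff.df:.0f},{res.residual_df:.0f}) = "
                f"{eff.F:8.3f}, p = {eff.p:.4g}{star}"
            )
        marks = _week_markers(analysis, metric)
        annotated = ", ".join(
            f"week {wk}: {marks[wk] or '-'}" for wk in sorted(marks)
        )
        lines.append(f"    Tukey within weeks ({'#'}=vs ML, ¤=RL vs FL): {annotated}")
    lines.append("")
    lines.append("Late healing (FL, weeks 3/12/20): one-way ANOVA over time")
    if not analysis.late_anova:
        lines.append("  (skipped: late time points unavailable)")
    for metric, res in analysis.late_anova.items():
        eff = res.effects["week"]
        star = " *" if eff.p < analysis.alpha else ""
        lines.append(
            f"  {metric}: F({eff.df:.0f},{res.residual_df:.0f}) = "
            f"{eff.F:8.3f}, p = {eff.p:.4g}{star}"
        )
        marks = _late_markers(analysis, metric)
        if marks:
            lines.append(
                "    time markers (a=vs week 3, b=vs week 12): "
                + ", ".join(f"week {k}: {v}" for k, v in sorted(marks.items()))
            )
    if analysis.warnings:
        lines.append("")
        lines.append("Warnings:")
        lines += [f"  - {w}" for w in analysis.warnings]
    lines.append("")
    return "\n".join(lines)
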