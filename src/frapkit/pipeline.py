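"""Pipeline orchestration: simulate, quantify, analyze, report.

One seeded config drives the whole chain. Each group's random stream
is derived from the master seed and the group label (not the group's
position), so adding a group to a design never perturbs the draws of
the others. Stage counts (parsed, fit-converged, QC-passed,
post-outlier) are logged per group and are monotone non-increasing
through the pipeline.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .groupstats import (
    ComparisonReport,
    GroupSummary,
    SelectivityProfile,
    TreatmentGroup,
    anova_tukey,
    selectivity_profile,
    summarize_group,
)
from .io import GroupSpec, StudyDesign
from .recovery import CellResult, QCThresholds, quantify_cell
from .simulate import (
    KineticsTruth,
    SimulationSpec,
    calibrate_kinetics_for_thalf,
    simulate_group,
    truth_half_recovery,
)
from .trace import RawTrace

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunArtifacts",
    "group_seed",
    "load_config",
    "run_pipeline",
    "make_report",
]

log = logging.getLogger("frapkit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cell."""


@dataclass(frozen=True)
class PipelineConfig:
    mode: str  # simulate | quantify | analyze | all
    out_dir: Path
    design: StudyDesign
    seed: int = 0
    traces_path: Path | None = None  # input for quantify/analyze
    simulation: dict[str, SimulationSpec] = field(default_factory=dict)
    truth_thalf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "quantify", "analyze", "all"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RunArtifacts:
    """Everything a run produced, for reporting and inspection."""

    config: PipelineConfig
    traces: dict[str, list[RawTrace]] = field(default_factory=dict)
    cell_results: dict[str, list[CellResult]] = field(default_factory=dict)
    summaries: list[GroupSummary] = field(default_factory=list)
    comparisons: ComparisonReport | None = None
    selectivity: SelectivityProfile | None = None
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    truths: dict[str, list[KineticsTruth]] = field(default_factory=dict)


def group_seed(master_seed: int, label: str) -> int:
    """Per-group seed derived from the master seed and the group label."""
    return (int(master_seed) * 1000003 + zlib.crc32(label.encode())) % (2**31)


def _sim_spec_from_mapping(m: dict, seed: int) -> SimulationSpec:
    m = dict(m)
    kin = m.pop("kinetics", None)
    target = m.pop("target_thalf_s", None)
    if kin is not None:
        kinetics = KineticsTruth(**kin)
    elif target is not None:
        kinetics = calibrate_kinetics_for_thalf(
            float(target),
            amplitude_split=float(m.pop("amplitude_split", 0.6)),
            t2_over_t1=float(m.pop("t2_over_t1", 5.0)),
            plateau=float(m.pop("plateau", 0.95)),
            y0=float(m.pop("y0", 0.1)),
        )
    else:
        kinetics = SimulationSpec().kinetics
    m.pop("seed", None)
    return SimulationSpec(kinetics=kinetics, seed=seed, **m)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config (YAML) with its embedded study design."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = fio.read_design(path) if "groups" in doc else None
    if design is None:
        raise fio.DesignError(f"{path}: config needs a 'groups' section")
    seed = int(doc.get("seed", 0))
    sim_cfgs = doc.get("simulation", {}) or {}
    shared = sim_cfgs.get("shared", {}) or {}
    simulation: dict[str, SimulationSpec] = {}
    for g in design.groups:
        if g.label in sim_cfgs or shared:
            merged = {**shared, **(sim_cfgs.get(g.label, {}) or {})}
            simulation[g.label] = _sim_spec_from_mapping(
                merged, seed=group_seed(seed, g.label)
            )
    return PipelineConfig(
        mode=str(doc.get("mode", "all")),
        out_dir=Path(doc.get("out_dir", "frap_run")),
        design=design,
        seed=seed,
        traces_path=Path(doc["traces"]) if doc.get("traces") else None,
        simulation=simulation,
    )


def _simulate_stage(config: PipelineConfig, artifacts: RunArtifacts) -> None:
    all_traces: list[RawTrace] = []
    truth_rows = []
    for g in config.design.groups:
        spec = config.simulation.get(g.label)
        if spec is None:
            raise PipelineError(
                f"simulate: no simulation spec for group {g.label!r}"
            )
        traces, truths = simulate_group(spec, label=g.label)
        artifacts.traces[g.label] = traces
        artifacts.truths[g.label] = truths
        all_traces.extend(traces)
        for tr, truth in zip(traces, truths):
            truth_rows.append(
                (tr.cell_id, truth.y0, truth.a1, truth.t1, truth.a2,
                 truth.t2, truth_half_recovery(truth))
            )
        log.info("simulated group %s: %d cells", g.label, len(traces))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    fio.write_traces(all_traces, out / "traces.tsv")
    import pandas as pd

    pd.DataFrame(
        truth_rows,
        columns=["cell_id", "y0", "A1", "t1", "A2", "t2", "t_half_s"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.12g")


def _assign_groups(
    config: PipelineConfig, traces: list[RawTrace]
) -> dict[str, list[RawTrace]]:
    by_group: dict[str, list[RawTrace]] = {g.label: [] for g in config.design.groups}
    labels = sorted(by_group, key=len, reverse=True)  # longest prefix wins
    for tr in traces:
        for label in labels:
            if tr.cell_id.startswith(label + "."):
                by_group[label].append(tr)
                break
        else:
            log.warning("trace %s matches no design group; skipped", tr.cell_id)
    return by_group


def _quantify_stage(config: PipelineConfig, artifacts: RunArtifacts) -> None:
    thresholds = QCThresholds(
        plateau_max=config.design.plateau_max,
        adj_r2_min=config.design.adj_r2_min,
    )
    if not artifacts.traces:
        # load traces: per-group files if referenced, else one table
        loaded: dict[str, list[RawTrace]] = {}
        per_group = [g for g in config.design.groups if g.traces]
        if per_group:
            for g in config.design.groups:
                if not g.traces:
                    raise PipelineError(
                        f"quantify: group {g.label!r} has no trace file"
                    )
                loaded[g.label] = fio.read_trace_table(g.traces)
        else:
            if config.traces_path is None:
                raise PipelineError("quantify: no trace input configured")
            loaded = _assign_groups(
                config, fio.read_trace_table(config.traces_path)
            )
        artifacts.traces = loaded

    all_results: list[CellResult] = []
    for label, traces in artifacts.traces.items():
        results = []
        for tr in traces:
            try:
                results.append(quantify_cell(tr, thresholds))
            except Exception as exc:
                raise PipelineError(
                    f"quantify: cell {tr.cell_id!r} in group {label!r}: {exc}"
                ) from exc
        artifacts.cell_results[label] = results
        all_results.extend(results)
        counts = {
            "parsed": len(traces),
            "fit_converged": sum(r.fit.converged for r in results),
            "qc_passed": sum(r.qc_pass for r in results),
        }
        artifacts.stage_counts[label] = counts
        log.info(
            "group %s: parsed=%d converged=%d qc_passed=%d",
            label, counts["parsed"], counts["fit_converged"],
            counts["qc_passed"],
        )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    fio.write_cell_results(all_results, config.out_dir / "cells.tsv")


def _analyze_stage(config: PipelineConfig, artifacts: RunArtifacts) -> None:
    if not artifacts.cell_results:
        raise PipelineError("analyze: no per-cell results available")
    design = config.design
    groups: list[TreatmentGroup] = []
    for g in design.groups:
        results = artifacts.cell_results.get(g.label, [])
        vals = [
            r.t_half_s for r in results if r.qc_pass and r.t_half_s is not None
        ]
        if not vals:
            log.error("group %s: no QC-passed cells", g.label)
            continue
        groups.append(
            TreatmentGroup(
                label=g.label, t_half_s=np.asarray(vals), metadata=g.metadata()
            )
        )
        if len(vals) < 10:
            log.warning(
                "group %s has %d QC-passed cells (< 10)", g.label, len(vals)
            )
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts.summaries = [summarize_group(g, alpha=design.alpha) for g in groups]
    for s in artifacts.summaries:
        artifacts.stage_counts.setdefault(s.label, {})["post_outlier"] = (
            s.n_after_outliers
        )
    fio.write_group_summaries(artifacts.summaries, out / "groups.tsv")
    if not groups:
        raise PipelineError("analyze: every group is empty after QC")
    if len(groups) >= 2 and all(g.n >= 2 for g in groups):
        artifacts.comparisons = anova_tukey(groups, alpha=design.alpha)
        fio.write_comparisons(artifacts.comparisons, out / "comparisons.tsv")
        if design.control_label in {g.label for g in groups}:
            artifacts.selectivity = selectivity_profile(
                groups, design.control_label, alpha=design.alpha
            )
            fio.write_selectivity(artifacts.selectivity, out / "selectivity.tsv")


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Run the configured stages and write all result tables.

    ``simulate`` writes traces and truth; ``quantify`` adds the
    per-cell table; ``analyze`` adds group summaries, Tukey-Kramer
    comparisons and, when the control is present, the selectivity
    profile; ``all`` chains the three. Any stage error raises
    :class:`PipelineError` naming the stage (and cell, if relevant).
    """
    artifacts = RunArtifacts(config=config)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode in {"simulate", "all"}:
        _simulate_stage(config, artifacts)
    if config.mode in {"quantify", "analyze", "all"}:
        _quantify_stage(config, artifacts)
    if config.mode in {"analyze", "all"}:
        _analyze_stage(config, artifacts)
    _write_run_log(config, artifacts)
    return artifacts


def _write_run_log(config: PipelineConfig, artifacts: RunArtifacts) -> None:
    from . import __version__

    lines = [
        f"frapkit {__version__}",
        f"mode: {config.mode}",
        f"seed: {config.seed}",
        f"plateau_max: {config.design.plateau_max}",
        f"adj_r2_min: {config.design.adj_r2_min}",
        f"alpha: {config.design.alpha}",
    ]
    for label, counts in artifacts.stage_counts.items():
        parts = " ".join(f"{k}={v}" for k, v in counts.items())
        lines.append(f"group {label}: {parts}")
    (config.out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")


def make_report(artifacts: RunArtifacts, path: str | Path | None = None) -> Path:
    """Render the run as a figure: mean recovery curves per group, a
    bar chart of mean t_half +/- SEM with significance asterisks, and
    the selectivity profile when a control is set.

    Mean recovery curves average normalized curves of QC-passed cells
    at matched frame indices, truncating to the shortest cell in the
    group. Missing sections are skipped with a log note.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = artifacts.config
    if path is None:
        path = config.out_dir / "report.png"
    path = Path(path)

    n_panels = 1 + (artifacts.comparisons is not None) + (
        artifacts.selectivity is not None
    )
    fig, axes = plt.subplots(1, max(n_panels, 2), figsize=(5 * max(n_panels, 2), 4))
    axes = np.atleast_1d(axes)

    ax = axes[0]
    plotted = False
    for label, results in artifacts.cell_results.items():
        curves = [r.curve for r in results if r.qc_pass and r.curve is not None]
        if not curves:
            continue
        n_min = min(c.f_norm.size for c in curves)
        mean_curve = np.mean([c.f_norm[:n_min] for c in curves], axis=0)
        ax.plot(curves[0].time_post_s[:n_min], mean_curve, label=label)
        plotted = True
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("relative fluorescence")
    ax.set_title("mean recovery per group")
    if plotted:
        ax.legend(fontsize=7)
    else:
        ax.text(0.5, 0.5, "no QC-passed cells", ha="center", va="center",
                transform=ax.transAxes)
        log.info("report: no recovery curves to plot")

    ax = axes[1]
    if artifacts.summaries:
        labels = [s.label for s in artifacts.summaries]
        means = [s.mean_s for s in artifacts.summaries]
        sems = [s.sem_s or 0.0 for s in artifacts.summaries]
        bars = ax.bar(labels, means, yerr=sems, capsize=3, color="#88a8c8")
        control = config.design.control_label
        if artifacts.comparisons is not None:
            for bar, s in zip(bars, artifacts.summaries):
                if s.label == control:
                    continue
                try:
                    pair = artifacts.comparisons.pair(s.label, control)
                except KeyError:
                    continue
                if pair.significant:
                    ax.annotate(
                        "*", (bar.get_x() + bar.get_width() / 2,
                              bar.get_height() + (s.sem_s or 0.0)),
                        ha="center", fontsize=14,
                    )
        ax.set_ylabel("mean t$_{1/2}$ (s)")
        ax.set_title("half-recovery time")
        ax.tick_params(axis="x", rotation=45)
    else:
        ax.text(0.5, 0.5, "no group summaries", ha="center", va="center",
                transform=ax.transAxes)
        log.info("report: comparisons section skipped")

    if artifacts.selectivity is not None and len(axes) > 2:
        ax = axes[2]
        prof = artifacts.selectivity
        labels = [e.label for e in prof.entries]
        pcts = [e.percent_of_control for e in prof.entries]
        errs = [e.sem_percent or 0.0 for e in prof.entries]
        bars = ax.bar(labels, pcts, yerr=errs, capsize=3, color="#c8a888")
        for bar, e in zip(bars, prof.entries):
            if e.significant_vs_control:
                ax.annotate(
                    "*", (bar.get_x() + bar.get_width() / 2,
                          bar.get_height() + (e.sem_percent or 0.0)),
                    ha="center", fontsize=14,
                )
        ax.axhline(100.0, ls=":", color="k", lw=0.8)
        ax.set_ylabel("% of control t$_{1/2}$")
        ax.set_title(f"selectivity vs {prof.control_label}")
        ax.tick_params(axis="x", rotation=45)

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
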