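"""Readers and writers for trace tables, study designs and results.

Traces travel as one long-format tab-separated table with columns
``cell_id, frame, time_s, phase, f_roi, f_total, f_bg`` where phase is
``pre`` or ``post``; this is a deliberate standardization of the
per-cell text exports produced by microscope software, not a
reconstruction of any vendor dialect. Designs are YAML. All numeric
output is written at full precision (repr round-trip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import RawTrace

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "SchemaError",
    "DuplicateTimeError",
    "DesignError",
    "read_trace_table",
    "write_traces",
    "read_design",
    "write_cell_results",
    "write_group_summaries",
    "write_comparisons",
    "write_selectivity",
]

TRACE_COLUMNS = ["cell_id", "frame", "time_s", "phase", "f_roi", "f_total", "f_bg"]


class SchemaError(ValueError):
    """Trace table is missing required columns or has bad phase labels."""


class DuplicateTimeError(ValueError):
    """A cell has duplicate (cell_id, time) rows; never silently averaged."""


class DesignError(ValueError):
    """Invalid study-design configuration."""


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of a study design."""

    label: str
    construct: str = ""
    genotype: str = "wild-type"  # or a substitution label, e.g. "N140F"
    saha: bool = False
    saha_um: float | None = None
    inhibitor: str | None = None
    inhibitor_um: float | None = None
    traces: str | None = None  # path reference to the group's trace table

    def metadata(self) -> dict:
        return {
            "construct": self.construct,
            "genotype": self.genotype,
            "saha": self.saha,
            "saha_um": self.saha_um,
            "inhibitor": self.inhibitor,
            "inhibitor_um": self.inhibitor_um,
        }


@dataclass(frozen=True)
class StudyDesign:
    """Groups to compare, the control, and analysis thresholds.

    A warning (not an error) is attached for groups below 10 cells,
    the minimum group size the assay design targets.
    """

    groups: tuple[GroupSpec, ...]
    control_label: str
    plateau_max: float = 1.1
    adj_r2_min: float = 0.95
    alpha: float = 0.05

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DesignError(f"duplicate group labels: {dupes}")
        if self.control_label not in labels:
            raise DesignError(
                f"control_label {self.control_label!r} names no group "
                f"(have {labels})"
            )

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def write_traces(traces: list[RawTrace], path: str | Path) -> None:
    """Serialize traces to the long-format TSV dialect, losslessly."""
    path = Path(path)
    rows = []
    for tr in traces:
        for i in range(tr.n_frames):
            rows.append(
                (
                    tr.cell_id, i, tr.time_s[i],
                    "pre" if i < tr.n_prebleach else "post",
                    tr.f_roi[i], tr.f_total[i], tr.f_bg[i],
                )
            )
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trace_table(path: str | Path) -> list[RawTrace]:
    """Read a long-format trace table into validated traces.

    Rows are grouped by ``cell_id`` (input order of first appearance is
    preserved) and sorted by time within a cell, so interleaved or
    shuffled rows parse identically. Duplicate (cell_id, time) rows and
    cells without prebleach frames are distinct, named errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_phase = set(df["phase"].unique()) - {"pre", "post"}
    if bad_phase:
        raise SchemaError(f"{path}: unknown phase label(s) {sorted(bad_phase)}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s", kind="stable")
        times = sub["time_s"].to_numpy(float)
        if np.any(np.diff(times) == 0):
            raise DuplicateTimeError(
                f"{path}: duplicate time points for cell {cell_id!r}"
            )
        n_pre = int((sub["phase"] == "pre").sum())
        # RawTrace validation raises the named errors for zero prebleach
        # frames, non-monotone time, and non-finite intensities
        traces.append(
            RawTrace(
                cell_id=str(cell_id),
                time_s=times,
                f_roi=sub["f_roi"].to_numpy(float),
                f_total=sub["f_total"].to_numpy(float),
                f_bg=sub["f_bg"].to_numpy(float),
                n_prebleach=n_pre,
            )
        )
    return traces


def _group_from_mapping(label: str, m: dict) -> GroupSpec:
    known = {
        "construct", "genotype", "saha", "saha_um",
        "inhibitor", "inhibitor_um", "traces",
    }
    unknown = set(m) - known
    if unknown:
        raise DesignError(f"group {label!r}: unknown keys {sorted(unknown)}")
    saha = bool(m.get("saha", False)) or m.get("saha_um") is not None
    return GroupSpec(
        label=label,
        construct=str(m.get("construct", "")),
        genotype=str(m.get("genotype", "wild-type")),
        saha=saha,
        saha_um=m.get("saha_um"),
        inhibitor=m.get("inhibitor"),
        inhibitor_um=m.get("inhibitor_um"),
        traces=m.get("traces"),
    )


def read_design(path: str | Path) -> StudyDesign:
    """Read a YAML study design, filling threshold defaults.

    Expected layout::

        control: wt
        alpha: 0.05            # optional
        plateau_max: 1.1       # optional
        adj_r2_min: 0.95       # optional
        groups:
          wt: {construct: BRD4, genotype: wild-type}
          N140F: {construct: BRD4, genotype: N140F}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DesignError(f"{path}: design must be a mapping")
    if "groups" not in doc or "control" not in doc:
        raise DesignError(f"{path}: design needs 'groups' and 'control'")
    raw_groups = doc["groups"]
    if isinstance(raw_groups, dict):
        items = list(raw_groups.items())
    else:  # list form: each item a mapping with a 'label' key
        items = []
        for entry in raw_groups:
            entry = dict(entry)
            items.append((entry.pop("label"), entry))
    groups = tuple(_group_from_mapping(str(k), v or {}) for k, v in items)
    return StudyDesign(
        groups=groups,
        control_label=str(doc["control"]),
        plateau_max=float(doc.get("plateau_max", 1.1)),
        adj_r2_min=float(doc.get("adj_r2_min", 0.95)),
        alpha=float(doc.get("alpha", 0.05)),
    )


def write_cell_results(results, path: str | Path) -> None:
    """Per-cell results TSV: fit parameters, t_half, QC verdict."""
    rows = []
    for r in results:
        f = r.fit
        rows.append(
            {
                "cell_id": r.cell_id, "y0": f.y0, "A1": f.a1, "t1": f.t1,
                "A2": f.a2, "t2": f.t2, "plateau": f.plateau,
                "adj_r2": f.adj_r2, "t_half_s": r.t_half_s,
                "qc_pass": r.qc_pass, "qc_reasons": ";".join(r.qc_reasons),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cell_id", "y0", "A1", "t1", "A2", "t2", "plateau",
            "adj_r2", "t_half_s", "qc_pass", "qc_reasons",
        ],
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def write_group_summaries(summaries, path: str | Path) -> None:
    rows = [
        {
            "label": s.label, "n_before": s.n_before_outliers,
            "n_after": s.n_after_outliers, "mean_s": s.mean_s,
            "sem_s": s.sem_s,
            "removed_values": ";".join(f"{v:.12g}" for v in s.removed_values),
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows, columns=["label", "n_before", "n_after", "mean_s", "sem_s",
                       "removed_values"],
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def write_comparisons(report, path: str | Path) -> None:
    rows = [
        {
            "group_a": p.group_a, "group_b": p.group_b,
            "diff_s": p.mean_diff_s, "q": p.q_statistic,
            "p_adj": p.p_adjusted, "significant": p.significant,
        }
        for p in report.pairs
    ]
    pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff_s", "q", "p_adj",
                       "significant"],
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def write_selectivity(profile, path: str | Path) -> None:
    rows = [
        {
            "label": e.label, "percent": e.percent_of_control,
            "sem_percent": e.sem_percent,
            "significant": e.significant_vs_control,
        }
        for e in profile.entries
    ]
    pd.DataFrame(
        rows, columns=["label", "percent", "sem_percent", "significant"],
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.12g")
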