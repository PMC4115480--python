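"""Group-level statistics for FRAP half-recovery times.

Within each treatment group, outliers are eliminated with the
two-sided Grubbs test (iterated, one value per pass) before the
arithmetic mean and SEM are computed. Groups are then compared by
one-way ANOVA with the Tukey-Kramer multiple-comparison procedure,
which is valid for unequal group sizes, and an inhibitor's selectivity
is summarized as each target's mean t_half expressed as a percentage
of its own untreated wild-type control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TreatmentGroup",
    "GroupSummary",
    "PairComparison",
    "ComparisonReport",
    "SelectivityEntry",
    "SelectivityProfile",
    "MissingControlError",
    "grubbs_critical_value",
    "grubbs_outliers",
    "summarize_group",
    "anova_tukey",
    "selectivity_profile",
]


class MissingControlError(KeyError):
    """The designated control group is absent from the comparison set."""


@dataclass(frozen=True)
class TreatmentGroup:
    """Labeled set of QC-passed per-cell t_half values (seconds)."""

    label: str
    t_half_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.t_half_s, float)
        if vals.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(
                f"group {self.label!r}: t_half values must be positive and finite"
            )
        object.__setattr__(self, "t_half_s", vals)

    @property
    def n(self) -> int:
        return int(self.t_half_s.size)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean_s: float
    sem_s: float | None  # sample SD / sqrt(n); None when n = 1
    n_before_outliers: int
    n_after_outliers: int
    removed_values: tuple[float, ...]


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    mean_diff_s: float  # mean(a) - mean(b)
    q_statistic: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class ComparisonReport:
    anova_f: float
    anova_p: float
    alpha: float
    pairs: tuple[PairComparison, ...]
    degenerate_zero_mse: bool = False

    def pair(self, a: str, b: str) -> PairComparison:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"no comparison for pair ({a!r}, {b!r})")


@dataclass(frozen=True)
class SelectivityEntry:
    label: str
    percent_of_control: float
    sem_percent: float | None
    significant_vs_control: bool


@dataclass(frozen=True)
class SelectivityProfile:
    control_label: str
    entries: tuple[SelectivityEntry, ...]


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    From the t-distribution quantile with n - 2 degrees of freedom at
    tail probability alpha / (2 n):

        G_crit = (n - 1) / sqrt(n) * sqrt(t^2 / (n - 2 + t^2))
    """
    if n < 3:
        raise ValueError("Grubbs critical value requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively remove outliers by the two-sided Grubbs test.

    Each pass computes G = max |x_i - mean| / sd (sample sd, n - 1
    denominator) and removes the single most extreme value if G exceeds
    the critical value at ``alpha``; passes repeat until no removal.
    Nothing is removed when fewer than 3 values remain or when the
    spread is zero. The order of retained values is preserved.

    Returns
    -------
    (retained, removed) : tuple of ndarray
        Retained values in input order, and removed values in removal
        order.
    """
    vals = np.asarray(values, float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Grubbs test requires finite values")
    keep = np.ones(vals.size, dtype=bool)
    removed: list[float] = []
    while keep.sum() >= 3:
        x = vals[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        if g <= grubbs_critical_value(x.size, alpha):
            break
        # map extreme position back to original index
        idx_in_keep = int(np.argmax(dev))
        orig_idx = np.flatnonzero(keep)[idx_in_keep]
        keep[orig_idx] = False
        removed.append(float(vals[orig_idx]))
    return vals[keep], np.asarray(removed, float)


def summarize_group(group: TreatmentGroup, alpha: float = 0.05) -> GroupSummary:
    """Grubbs outlier removal, then arithmetic mean and SEM.

    SEM is the sample standard deviation (n - 1 denominator) divided by
    sqrt(n); it is reported as missing for n = 1.
    """
    retained, removed = grubbs_outliers(group.t_half_s, alpha=alpha)
    n = retained.size
    sem = float(retained.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    return GroupSummary(
        label=group.label,
        mean_s=float(retained.mean()),
        sem_s=sem,
        n_before_outliers=group.n,
        n_after_outliers=int(n),
        removed_values=tuple(removed.tolist()),
    )


def anova_tukey(
    groups: list[TreatmentGroup],
    alpha: float = 0.05,
    remove_outliers: bool = True,
) -> ComparisonReport:
    """One-way ANOVA with Tukey-Kramer all-pairs comparisons.

    The pooled within-group mean square (MSE) with N - k degrees of
    freedom feeds the Tukey-Kramer statistic for each pair (i, j):

        q = |mean_i - mean_j| / sqrt((MSE / 2) (1/n_i + 1/n_j))

    whose adjusted p comes from the studentized-range distribution with
    parameters (k, N - k). The Kramer form of the standard error
    handles unequal group sizes.

    Outlier removal (Grubbs, per group) precedes the ANOVA by default,
    matching the order of the per-group summaries. Groups must have
    n >= 2 after removal.

    Degenerate MSE = 0: pairs with unequal means are reported
    significant with adjusted p = 0 and the report carries a degeneracy
    flag; equal means are never significant.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    samples = []
    for g in groups:
        vals = (
            grubbs_outliers(g.t_half_s, alpha=alpha)[0]
            if remove_outliers
            else np.asarray(g.t_half_s, float)
        )
        if vals.size < 2:
            raise ValueError(
                f"group {g.label!r} has n < 2 after outlier removal"
            )
        samples.append(vals)

    k = len(samples)
    ns = np.array([s.size for s in samples])
    means = np.array([s.mean() for s in samples])
    n_total = int(ns.sum())
    df_within = n_total - k
    sse = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    mse = sse / df_within
    grand = float(np.concatenate(samples).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    df_between = k - 1
    if mse > 0:
        f_stat = (ssb / df_between) / mse
        anova_p = float(stats.f.sf(f_stat, df_between, df_within))
    else:
        f_stat = float("inf") if ssb > 0 else 0.0
        anova_p = 0.0 if ssb > 0 else 1.0

    pairs: list[PairComparison] = []
    idx_pairs = list(itertools.combinations(range(k), 2))
    if mse > 0:
        se = np.array(
            [math.sqrt((mse / 2.0) * (1.0 / ns[i] + 1.0 / ns[j])) for i, j in idx_pairs]
        )
        diffs = np.array([means[i] - means[j] for i, j in idx_pairs])
        q = np.abs(diffs) / se
        p_adj = stats.studentized_range.sf(q, k, df_within)
        p_adj = np.clip(p_adj, 0.0, 1.0)
        for (i, j), d, qv, pv in zip(idx_pairs, diffs, q, p_adj):
            pairs.append(
                PairComparison(
                    group_a=labels[i], group_b=labels[j],
                    mean_diff_s=float(d), q_statistic=float(qv),
                    p_adjusted=float(pv), significant=bool(pv < alpha),
                )
            )
        degenerate = False
    else:
        for i, j in idx_pairs:
            d = float(means[i] - means[j])
            sig = d != 0.0
            pairs.append(
                PairComparison(
                    group_a=labels[i], group_b=labels[j], mean_diff_s=d,
                    q_statistic=float("inf") if sig else 0.0,
                    p_adjusted=0.0 if sig else 1.0, significant=sig,
                )
            )
        degenerate = True

    return ComparisonReport(
        anova_f=float(f_stat), anova_p=anova_p, alpha=alpha,
        pairs=tuple(pairs), degenerate_zero_mse=degenerate,
    )


def selectivity_profile(
    groups: list[TreatmentGroup],
    control_label: str,
    alpha: float = 0.05,
    propagate_control_sem: bool = False,
) -> SelectivityProfile:
    """Percent-of-control profile of mean half-recovery times.

    Each group's post-outlier mean t_half is divided by the control
    group's mean and expressed in percent; the group's SEM is scaled by
    the same factor. Significance versus the control is taken from the
    Tukey-Kramer comparison over the full group set. By default the
    control mean is treated as a constant when scaling error bars; set
    ``propagate_control_sem`` to add the control's relative variance in
    quadrature.
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise MissingControlError(
            f"control group {control_label!r} not among {labels}"
        )
    summaries = {g.label: summarize_group(g, alpha=alpha) for g in groups}
    control = summaries[control_label]
    if control.n_after_outliers < 2:
        raise ValueError("control group needs n >= 2 after outlier removal")
    report = anova_tukey(groups, alpha=alpha)
    entries: list[SelectivityEntry] = []
    for g in groups:
        s = summaries[g.label]
        pct = 100.0 * s.mean_s / control.mean_s
        if s.sem_s is None:
            sem_pct = None
        else:
            sem_pct = 100.0 * s.sem_s / control.mean_s
            if propagate_control_sem and control.sem_s is not None:
                rel = math.hypot(s.sem_s / s.mean_s, control.sem_s / control.mean_s)
                sem_pct = pct * rel
        if g.label == control_label:
            sig = False
            pct = 100.0
        else:
            sig = report.pair(g.label, control_label).significant
        entries.append(
            SelectivityEntry(
                label=g.label, percent_of_control=pct,
                sem_percent=sem_pct, significant_vs_control=sig,
            )
        )
    return SelectivityProfile(control_label=control_label, entries=tuple(entries))
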