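"""Inhibitor selectivity profile across bromodomain targets.

Emulates a BET-inhibitor selectivity experiment: for each of six
bromodomain targets, a wild-type control group and a 1 uM
inhibitor-treated group are simulated; the inhibitor reduces the truth
half-time only for the two BET targets. Each treated group's mean
half-time is expressed as a percentage of its own untreated control,
and significance against the control comes from the Tukey-Kramer
pair. A selective inhibitor shows percent-of-control well below 100
with an asterisk only on its intended targets.
"""

from pathlib import Path

import numpy as np

from frapkit import (
    TreatmentGroup,
    quantify_cell,
    selectivity_profile,
    simulate_group,
)
from frapkit.io import write_selectivity
from frapkit.pipeline import group_seed
from frapkit.simulate import SimulationSpec, calibrate_kinetics_for_thalf

OUT = Path("results/selectivity")
SEED = 55101

TARGETS = {  # target -> (control truth t1/2, inhibitor-sensitive?)
    "BRD3": (5.0, True),
    "BRD4": (6.3, True),
    "TRIM24": (20.7, False),
    "SMARCA2": (3.6, False),
    "CREBBP": (14.9, False),
    "ATAD2": (4.5, False),
}
INHIBITED_FRACTION = 0.4  # treated truth = 40% of control for hits


def quantified_group(label: str, thalf: float, n_cells: int = 12):
    spec = SimulationSpec(
        kinetics=calibrate_kinetics_for_thalf(thalf), n_cells=n_cells,
        duration_s=min(max(40.0, 8.0 * thalf), 170.0),
        seed=group_seed(SEED, label))
    traces, _ = simulate_group(spec, label=label)
    vals = [r.t_half_s for r in map(quantify_cell, traces) if r.qc_pass]
    return TreatmentGroup(label=label, t_half_s=np.asarray(vals))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    print("target      %-of-control  significant   (inhibitor-sensitive?)")
    rows = []
    for target, (thalf, sensitive) in TARGETS.items():
        treated_thalf = thalf * (INHIBITED_FRACTION if sensitive else 1.0)
        control = quantified_group(f"{target}.wt", thalf)
        treated = quantified_group(f"{target}.inh", treated_thalf)
        prof = selectivity_profile([control, treated], control.label)
        entry = next(e for e in prof.entries if e.label == treated.label)
        rows.append(entry)
        flag = "*" if entry.significant_vs_control else " "
        print(f"  {target:10s} {entry.percent_of_control:6.1f}%      {flag}"
              f"             ({'yes' if sensitive else 'no'})")
        write_selectivity(prof, OUT / f"{target}.tsv")
    hits = {e.label.split(".")[0] for e in rows if e.significant_vs_control}
    expected = {t for t, (_, s) in TARGETS.items() if s}
    print(f"flagged: {sorted(hits)}; inhibitor-sensitive truth: "
          f"{sorted(expected)}")


if __name__ == "__main__":
    main()
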