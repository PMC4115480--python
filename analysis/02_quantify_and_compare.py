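"""Quantify the simulated mutant panel and compare groups.

Runs normalization, double-exponential fitting, half-recovery
extraction and QC on every simulated cell from 01, then Grubbs outlier
removal, one-way ANOVA with Tukey-Kramer comparisons, and the summary
figure. Prints the per-group mean half-times next to their simulation
truths and the pairs significant against the wild type.

Run after analysis/01_simulate_mutant_panel.py.
"""

import dataclasses
import importlib.util
import sys
from pathlib import Path

from frapkit import make_report, run_pipeline

spec = importlib.util.spec_from_file_location(
    "mutant_panel", Path(__file__).parent / "01_simulate_mutant_panel.py")
panel = importlib.util.module_from_spec(spec)
spec.loader.exec_module(panel)


def main() -> None:
    traces = panel.OUT / "traces.tsv"
    if not traces.exists():
        sys.exit("run analysis/01_simulate_mutant_panel.py first")
    config = dataclasses.replace(panel.build_config(), mode="analyze",
                                 traces_path=traces, simulation={})
    artifacts = run_pipeline(config)
    print("group means after QC and outlier removal:")
    for s in artifacts.summaries:
        truth = panel.TRUTH_THALF[s.label]
        sem = f"{s.sem_s:.2f}" if s.sem_s is not None else "--"
        print(f"  {s.label:12s} mean {s.mean_s:5.2f} +/- {sem} s "
              f"(truth {truth:.1f} s, n={s.n_after_outliers})")
    print("significant vs wt (Tukey-Kramer, alpha=0.05):")
    for p in artifacts.comparisons.pairs:
        if "wt" in (p.group_a, p.group_b) and p.significant:
            other = p.group_b if p.group_a == "wt" else p.group_a
            print(f"  {other:12s} p_adj = {p.p_adjusted:.2e}")
    fig = make_report(artifacts)
    print(f"tables in {panel.OUT}, figure at {fig}")


if __name__ == "__main__":
    main()
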