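#!/usr/bin/env python
"""Simulate the default local-global recording session.

Generates one run per task variant (xx task with xY|xx deviants, xY task
with xx|xY deviants, both omission variants, and the expected-omission
xxxx block) at a 16-channel desk scale with the default PE1/PE2/PRED
component set, and stores them as HDF5 containers under scratch/recordings/
(binary intermediates; every figure-ready table lands under results/ in the
later steps).  A summary of the simulated ground truth goes to
results/simulation_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hierseq.config import child_seed  # noqa: E402
from hierseq.experiments import REDUCED_ROI_COUNTS, simulate_task_run  # noqa: E402
from hierseq.paradigm import ParadigmConfig  # noqa: E402
from hierseq.synth import default_components, omission_component, write_recording  # noqa: E402

SEED = 20220217
RUNS = [
    ("xx", "xx", "xY|xx", "defaults"),
    ("xY", "xY", "xx|xY", "defaults"),
    ("om_xx", "xx", "x_|xx", "omission"),
    ("om_xY", "xY", "x_|xY", "omission"),
    ("om_block", "omission_block", None, "none"),
]


def main() -> None:
    out_dir = ROOT / "scratch" / "recordings"
    out_dir.mkdir(parents=True, exist_ok=True)
    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    pcfg = ParadigmConfig(n_test_blocks=1)
    rows = []
    for name, task, deviant, comp_kind in RUNS:
        comps = {
            "defaults": default_components(),
            "omission": default_components() + [omission_component()],
            "none": [],
        }[comp_kind]
        rec = simulate_task_run(
            task, deviant, comps, seed=child_seed(SEED, f"run-{name}"),
            paradigm=pcfg, roi_counts=REDUCED_ROI_COUNTS,
        )
        write_recording(rec, out_dir / f"{name}.h5")
        gt = rec.ground_truth
        for comp, grp in gt.groupby("component"):
            rows.append({
                "run": name, "task": task, "deviant": deviant or "n/a",
                "component": comp, "n_events": len(grp),
                "amp_mean": grp["amplitude"].mean(),
                "amp_sd": grp["amplitude"].std(),
            })
        print(f"{name}: {rec.signal.shape[0]} ch x {rec.signal.shape[1]} samples, "
              f"{len(gt)} injected component events")
    summary = pd.DataFrame(rows)
    summary.to_csv(results_dir / "simulation_summary.tsv", sep="\t", index=False)
    print(f"wrote {results_dir / 'simulation_summary.tsv'}")


if __name__ == "__main__":
    main()
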