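#!/usr/bin/env python
"""Depth-dependent activation profiles of the synthetic button-press column.

Simulates the 18-block, 30 s ON/OFF task (270 volumes, TR 4 s) in a single
cortical column at b = 0, 6, 7, 8 s/mm^2, with and without phase
regression, and extracts 20-layer activation profiles (percent signal
change with 95% CI).  Writes results/task_depth_profiles.tsv.

Finding: the noise-free double-peak (deep + superficial) neural profile is
recovered at every b; raising b suppresses the superficial percent change
much more than the deep one (draining-vein bias removed), and phase
regression trims the residual superficial amplitude contributed by the
pial blooming field.
"""

import argparse
from pathlib import Path

import pandas as pd

from layervn.cortex import BlockParadigm, CorticalColumnSpec, simulate_task
from layervn.io import write_tsv
from layervn.layering import (
    assign_equidistant_layers,
    depth_activation_profile,
    layer_average_timeseries,
)
from layervn.preprocess import highpass, make_task_design, phase_regress, unwrap_phase

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise-sd", type=float, default=0.5)
    parser.add_argument("--out-dir", type=Path, default=RESULTS)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    column = CorticalColumnSpec()
    paradigm = BlockParadigm()
    design = make_task_design(paradigm)

    frames = []
    for b in (0.0, 6.0, 7.0, 8.0):
        cts = simulate_task(column, paradigm, vn=b, noise_sd=args.noise_sd,
                            seed=args.seed)
        for use_pr in (False, True):
            mag = cts.magnitude
            if use_pr:
                mag = phase_regress(mag, unwrap_phase(cts.phase))
            mag = highpass(mag, paradigm.TR_s) + mag.mean(axis=1, keepdims=True)
            assign = assign_equidistant_layers(cts.depths)
            layer_ts, _ = layer_average_timeseries(mag, assign)
            prof = depth_activation_profile(layer_ts, design, assign.layer_depths())
            prof.insert(0, "b", b)
            prof.insert(1, "phase_regression", use_pr)
            frames.append(prof)

    table = pd.concat(frames, ignore_index=True)
    write_tsv(table, args.out_dir / "task_depth_profiles.tsv",
              comment="20-layer %BOLD profiles per b value, with/without phase regression")

    pr = table[table.phase_regression]
    for b in (0.0, 7.0):
        sub = pr[pr.b == b]
        sup = sub[sub.depth > 0.7].percent_change.mean()
        deep = sub[(sub.depth > 0.0) & (sub.depth < 0.3)].percent_change.mean()
        print(f"b = {b:g}: mean %change superficial {sup:.3f}, deep {deep:.3f}")
    sup0 = pr[(pr.b == 0.0) & (pr.depth > 0.7)].percent_change.mean()
    sup7 = pr[(pr.b == 7.0) & (pr.depth > 0.7)].percent_change.mean()
    print(f"superficial suppression at b = 7 vs 0: {100 * (1 - sup7 / sup0):.1f}%")


if __name__ == "__main__":
    main()
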