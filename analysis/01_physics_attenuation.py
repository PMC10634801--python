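#!/usr/bin/env python
"""Compartment-wise VN attenuation curves and critical velocities.

Evaluates the IVIM attenuation S/S0 = exp(-b D*) for the capillary,
penetrating-vein, and cortical-artery pools over b = 0..10 s/mm^2, and the
critical velocity of the bipolar pair at the candidate operating points.
Writes results/physics_attenuation.tsv and results/critical_velocities.tsv.

Finding: at the b = 7 s/mm^2 operating point the vein pool retains ~17% of
its signal and the artery pool essentially none, while capillaries retain
>93% — the selectivity that makes a small velocity-nulling gradient a
draining-vein filter rather than a global attenuator.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from layervn.io import write_tsv
from layervn.vascular import attenuation_curve, critical_velocity_from_b

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=RESULTS)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    b_grid = np.round(np.arange(0, 10.25, 0.25), 2)
    table = attenuation_curve(b_grid).reset_index()
    write_tsv(table, args.out_dir / "physics_attenuation.tsv",
              comment="retained intravascular fraction S/S0 = exp(-b D*) per pool")

    vc = pd.DataFrame(
        [(b, critical_velocity_from_b(b)) for b in (6.0, 7.0, 8.0)],
        columns=["b_s_mm2", "critical_velocity_mm_s"],
    )
    write_tsv(vc, args.out_dir / "critical_velocities.tsv",
              comment="v_c from the fixed-G bipolar scaling law, anchored at b=6 -> 16.8 mm/s")

    at7 = table[table.b_s_mm2 == 7.0].iloc[0]
    print("retention at b = 7 s/mm^2:")
    print(f"  capillary {at7['capillary']:.4f}   vein {at7['vein']:.4f}   "
          f"artery {at7['artery']:.2e}")
    print("critical velocities (mm/s):")
    for _, row in vc.iterrows():
        print(f"  b = {row.b_s_mm2:g} -> {row.critical_velocity_mm_s:.1f}")


if __name__ == "__main__":
    main()
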