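#!/usr/bin/env python
"""Layered melanin/agar phantom: T1/T2* concentration dependence, null MTR.

Generates the synthetic phantom (two melanin models at 0.6-3.0 mg/ml plus
agar reference layers), fits T2* from the 4-echo train and T1 from the
MP2RAGE index, computes the MTR map, and regresses each layer summary on
melanin concentration and model.  Expected pattern: a significant negative
T1-concentration slope, a weaker T2* trend, and no MTR modulation.

Writes results/phantom/ (layer_summary.csv, truth.json, summary.json).
"""

import argparse
import json
from pathlib import Path

from nmmt.workflows import PipelineConfig, run_workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    summary = run_workflow("phantom", PipelineConfig(seed=args.seed, out_dir=args.out))
    print(json.dumps(summary, indent=2))
    print()
    print(
        f"T1 falls with melanin concentration (t = {summary['t1_concentration_t']:.2f}, "
        f"p = {summary['t1_concentration_p']:.3g})."
    )
    print(
        "Melanin-minus-agar MTR difference: "
        f"{summary['mtr_melanin_minus_agar']:.3f} percentage points — the melanin "
        "layers carry no MT modulation beyond the agar base."
    )


if __name__ == "__main__":
    main()
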