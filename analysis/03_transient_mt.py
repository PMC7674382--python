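#!/usr/bin/env python
"""Transient MT: sensitivity sweeps, preparation contrast, cohort fit.

Simulates the post-saturation free-pool timeline (fixed set: R1f = R1r =
1/s, f = 10%, krf = 15 Hz; restricted pool saturated, free pool at 5%
saturation), sweeps each parameter over its plausible range, compares
on-resonance inversion against off-resonance saturation for an R1f
difference, and fits the bi-exponential to a noisy 5-subject median
timeline on the 9-delay grid.

Expected pattern: the pool size ratio f and the free-pool R1f dominate the
timeline (f early, R1f late); the exchange rate krf and restricted-pool
R1r barely matter; inversion shows far larger R1-driven contrast than MT
saturation.  Writes results/transient/.
"""

import argparse
from pathlib import Path

from nmmt.workflows import PipelineConfig, run_workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    summary = run_workflow("transient", PipelineConfig(seed=args.seed, out_dir=args.out))
    sp = summary["sweep_spread_max"]
    print("max timeline spread per swept parameter:")
    for name in ("f", "R1f", "krf", "R1r"):
        print(f"  {name:>4}: {sp[name]:.4f}")
    print(
        f"ordering: f ({sp['f']:.3f}) and R1f ({sp['R1f']:.3f}) dominate "
        f"krf ({sp['krf']:.3f}) and R1r ({sp['R1r']:.3f})."
    )
    print(
        f"inversion vs saturation max contrast for an R1f halving: "
        f"{summary['inversion_max_contrast']:.3f} vs {summary['saturation_max_contrast']:.3f}"
    )
    b = summary["biexp"]
    print(
        f"bi-exponential fit of the noisy median timeline: "
        f"lambda = {b['lambda1']:.2f} / {b['lambda2']:.2f} 1/s "
        "(eigen-rates of the generative system: 1.0 / 17.5)"
    )


if __name__ == "__main__":
    main()
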