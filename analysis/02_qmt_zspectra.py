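#!/usr/bin/env python
"""Steady-state qMT: two-pool z-spectrum fits for LC, SN and pons.

Forward-generates z-spectra on the 3-amplitude x 7-offset grid from the
representative ROI parameter sets, then refits the constrained two-pool
model (R1r fixed at 1/s, R1f from the observed-T1 constraint).  The fits
should recover the generative values; the LC shows the smallest
macromolecular pool size ratio f, the SN the largest.

Writes results/qmt_invivo/ (zspec_*.csv, qmt_fit_*.json, qmt_recovery.csv).
"""

import argparse
from pathlib import Path

from nmmt.workflows import PipelineConfig, run_workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--noise-sd", type=float, default=0.0)
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, out_dir=args.out, zspec_noise_sd=args.noise_sd)
    summary = run_workflow("qmt_invivo", cfg)
    print(f"{'ROI':>6} {'f% true':>8} {'f% fit':>8} {'krf true':>9} {'krf fit':>9}")
    for row in summary["recovery"]:
        print(
            f"{row['roi']:>6} {row['f_percent_true']:8.2f} {row['f_percent_fit']:8.2f} "
            f"{row['krf_hz_true']:9.2f} {row['krf_hz_fit']:9.2f}"
        )
    fs = {r["roi"]: r["f_percent_fit"] for r in summary["recovery"]}
    print()
    print(
        f"Pool size ratio ordering: LC ({fs['LC']:.2f}%) < Pons ({fs['Pons']:.2f}%) "
        f"< SN ({fs['SN']:.2f}%) — the LC hyperintensity goes with a lower "
        "macromolecular fraction."
    )


if __name__ == "__main__":
    main()
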