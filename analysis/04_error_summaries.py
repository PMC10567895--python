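#!/usr/bin/env python
"""Grouped error statistics and signed-error plots for both study arms.

Computes MSE (mean signed error), MAE, MAE% and SEE per camera/lens, view
and distance, plus pooled headline numbers, and renders the signed-error
versus distance figure for each arm.
"""

from pathlib import Path

from facefd import summarize
from facefd.evaluation import plot_signed_error
from facefd.io import read_table, write_table

OUT = Path(__file__).resolve().parent.parent / "results"
FIG = OUT / "figures"

for arm in ("dslr", "smartphone"):
    estimates = read_table(OUT / f"estimates_{arm}.csv")
    summary = summarize(estimates, ["camera_name", "view", "fd_true_mm"])
    write_table(OUT / f"summary_{arm}.csv", summary)
    pooled = summarize(estimates)
    print(f"{arm}: pooled over {int(pooled.loc[0, 'n'])} estimates -> "
          f"MSE {pooled.loc[0, 'mse_mm']:.0f} mm, MAE {pooled.loc[0, 'mae_mm']:.0f} mm, "
          f"MAE% {pooled.loc[0, 'mae_pct']:.1f}, SEE {pooled.loc[0, 'see_mm']:.0f} mm")
    short = estimates[estimates["fd_true_mm"] <= 4000.0]
    if len(short):
        p = summarize(short)
        print(f"  1-4 m subset: MAE% {p.loc[0, 'mae_pct']:.1f} over {int(p.loc[0, 'n'])}")
    FIG.mkdir(parents=True, exist_ok=True)
    plot_signed_error(summary, FIG / f"signed_error_{arm}.png")
    print(f"  wrote {OUT / f'summary_{arm}.csv'} and {FIG / f'signed_error_{arm}.png'}")
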