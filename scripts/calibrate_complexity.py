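"""Calibrate under-specified architecture flags against the published
complexity figures (8.84 M parameters, 0.431 TMACs, 0.867 TFLOPs at a
9-channel 144^3 input).

The published description leaves several choices open: the feed-forward
expansion, whether the stride-2 resampling convolutions are dense or
depthwise-separable, the skip-fusion operator, whether decoder levels carry
transformer blocks, normalization, and the bias policy. This script sweeps
exactly those flags, solves the feed-forward expansion against the
parameter count within each structure, and reports the combination that
best reproduces all three figures, with residuals.

Outcome (frozen as the package defaults): separable resampling, additive
fusion, encoder-only transformer blocks, pre-norm on, feed-forward
expansion 2.2625 -> 8.84 M parameters exactly at printed rounding; the MAC
and FLOP totals then come to ~0.456 TMACs / ~0.918 TFLOPs, ~6% above the
published 0.431 / 0.867. No combination in the sweep reproduces all three
printed values simultaneously, so the parameter count (the only
resolution-independent figure) is used as the primary calibration target.

Run:  python scripts/calibrate_complexity.py [--fine]
"""
from __future__ import annotations

import argparse
import itertools
import json

import numpy as np

from tractformer3d import count_macs, count_flops, count_parameters, published_config

TARGET_P = 8.84       # million parameters
TARGET_M = 0.431      # TMACs at 144^3
TARGET_F = 0.867      # TFLOPs at 144^3
DIMS = (144, 144, 144)


def sweep(step: float):
    gammas = np.arange(0.5, 3.5, step)
    rows = []
    for resample, fusion, mirrored, norm in itertools.product(
            ["separable", "dense"], ["add", "concat1", "concat3"],
            [False, True], [True, False]):
        best = None
        for g in gammas:
            try:
                cfg = published_config(ffn_expansion=round(float(g), 4),
                                   resample_mode=resample, skip_fusion=fusion,
                                   decoder_blocks_mirrored=mirrored,
                                   use_norm=norm)
            except ValueError:
                continue
            p = count_parameters(cfg) / 1e6
            if best is None or abs(p - TARGET_P) < abs(best[1] - TARGET_P):
                best = (cfg, p)
        cfg, p = best
        m = count_macs(cfg, DIMS) / 1e12
        f = count_flops(cfg, DIMS) / 1e12
        rows.append({
            "resample": resample, "fusion": fusion, "mirrored": mirrored,
            "norm": norm, "ffn_expansion": cfg.ffn_expansion,
            "params_M": round(p, 4), "tmacs": round(m, 4),
            "tflops": round(f, 4),
            "hits_params": round(p, 2) == TARGET_P,
            "residual": abs(p - TARGET_P) / TARGET_P
            + abs(m - TARGET_M) / TARGET_M + abs(f - TARGET_F) / TARGET_F,
        })
    return sorted(rows, key=lambda r: (not r["hits_params"], r["residual"]))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fine", action="store_true",
                    help="0.0005 expansion grid (slower)")
    args = ap.parse_args()
    rows = sweep(0.0005 if args.fine else 0.005)
    print(f"targets: {TARGET_P} M params, {TARGET_M} TMACs, {TARGET_F} TFLOPs")
    print(json.dumps(rows[:8], indent=2))
    best = rows[0]
    print("\nselected combination:", {k: best[k] for k in
          ("resample", "fusion", "mirrored", "norm", "ffn_expansion")})
    print(f"residuals: params {best['params_M'] - TARGET_P:+.4f} M, "
          f"TMACs {best['tmacs'] - TARGET_M:+.4f}, "
          f"TFLOPs {best['tflops'] - TARGET_F:+.4f}")


if __name__ == "__main__":
    main()
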