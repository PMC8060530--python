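#!/usr/bin/env python
"""Profile the fitted state and contrast the two periods.

Labels every patient-day with its risk profile (feature-activation pattern),
computes per-profile positive-score signatures and prevalences, builds the
per-profile 2x2 period contrasts (Yates chi-square, percent change, pooled
rare-profile CI) and writes all report tables under results/run/report/.
"""

import argparse
from pathlib import Path

from emarisk import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = pipeline.RunConfig(out_dir=args.out, seed=args.seed)
    report = pipeline.cmd_compare(cfg, args.out / "posterior", args.out / "ema.csv")
    print((report / "period_contrasts.txt").read_text())


if __name__ == "__main__":
    main()
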