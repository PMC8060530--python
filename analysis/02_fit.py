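#!/usr/bin/env python
"""Fit the Indian buffet process latent-feature model to the EMA table.

Reads results/run/ema.csv (from 01_simulate.py), assembles per-day
observation vectors with turn-over masks, runs the Gibbs sampler and
serialises the MAP posterior state under results/run/posterior/.
"""

import argparse
import logging
from pathlib import Path

from emarisk import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--verbose", action="store_true")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO if args.verbose else logging.WARNING)

    cfg = pipeline.RunConfig(out_dir=args.out, seed=args.seed)
    post = pipeline.cmd_fit(cfg, args.out / "ema.csv")
    print(f"posterior written to {post}")


if __name__ == "__main__":
    main()
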