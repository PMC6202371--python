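"""Descriptive analysis of the simulated cohort.

Computes unisensory reaching accuracy/precision per condition and the
multisensory bias curves (signed % of disparity, then folded over left/right
directions), and prints the group-level pattern the model analysis builds on:
visual reaches are more precise than proprioceptive ones, and the
proprioceptive pull toward the visual target shrinks as the disparity grows.
Tables go to ``results/descriptives/``.
"""

import argparse
from pathlib import Path

import numpy as np

from periprior.io import RunConfig, read_trials
from periprior.pipeline import bias_percent, fold_directions, unisensory_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path,
                    default=ROOT / "results" / "cohort" / "trials.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "descriptives")
    args = ap.parse_args()

    trials = read_trials(args.trials)
    uni = unisensory_summary(trials)
    bias = bias_percent(trials)
    folded = fold_directions(bias)

    args.out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    for name, df in (("unisensory", uni), ("bias", bias), ("folded", folded)):
        with open(args.out / f"{name}.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# config_hash={cfg.config_hash}\n")
            df.to_csv(fh, index=False, na_rep="NA")

    print("unisensory precision (group mean SD of endpoints, mm):")
    prec = uni.groupby(["visibility", "modality"])["precision_mm"].mean()
    for (vis, mod), v in prec.items():
        print(f"  {vis:9s} {mod:15s} {v:6.1f}")
    print("\nfolded proprioceptive bias (% of disparity, group mean):")
    pp = folded[folded["modality"] == "proprioceptive"]
    for vis, g in pp.groupby("visibility"):
        cells = g.groupby("magnitude_mm")["folded_bias_pct"].mean()
        line = "  ".join(f"|d|={int(k)}: {v:5.1f}" for k, v in cells.items())
        print(f"  {vis:9s} {line}")
    print(f"\ntables -> {args.out}")


if __name__ == "__main__":
    main()
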