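"""Render the report figures from the saved tables.

Bias-vs-disparity curves per visibility condition, model residual curves,
and the fitted-parameter bars (lambda and sigma_c by hand visibility).
PNG output under ``results/figures/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from periprior.viz import plot_bias_curves, plot_fit_scatter, plot_parameter_bars

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=ROOT / "results" / "fits")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "figures")
    args = ap.parse_args()

    bias = pd.read_csv(args.fits / "bias.csv", comment="#")
    residuals = pd.read_csv(args.fits / "residuals.csv", comment="#")
    contrast = pd.read_csv(args.fits / "contrast.csv", comment="#")

    plot_bias_curves(bias, args.out / "bias_curves.png")
    plot_fit_scatter(residuals, args.out / "cp_residuals.png",
                     model="coupling_prior")
    plot_fit_scatter(residuals, args.out / "mle_residuals.png",
                     model="forced_fusion")
    plot_parameter_bars(contrast, args.out / "parameter_bars.png")
    print(f"figures -> {args.out}")


if __name__ == "__main__":
    main()
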