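"""Render the run report: coefficient tables, integration ranges, curves.

Collects the tables written by the earlier steps into results/report.md and
draws the predicted annual death-probability curves (posterior mean with 89%
band) per measure and dataset.
"""

import argparse
from pathlib import Path

import pandas as pd

from capsoc.pipeline import _write_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    _write_report(args.results, None)
    print(f"wrote {args.results / 'report.md'}")

    curves = sorted((args.results / "survival").glob("prediction_*.csv"))
    if curves:
        import matplotlib
        matplotlib.use("Agg")
        matplotlib.rcParams["svg.hashsalt"] = "capsoc"
        import matplotlib.pyplot as plt

        measures = sorted({c.stem.split("__")[0].replace("prediction_", "") for c in curves})
        fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 3.2),
                                 squeeze=False)
        for ax, measure in zip(axes[0], measures):
            for c in curves:
                if not c.stem.startswith(f"prediction_{measure}__"):
                    continue
                label = c.stem.split("__")[1].rsplit("_lag", 1)[0]
                df = pd.read_csv(c)
                ax.plot(df.integration, df.p_mean, label=label)
                ax.fill_between(df.integration, df.p_lo, df.p_hi, alpha=0.2)
            ax.set_title(measure)
            ax.set_xlabel("integration (logit offset)")
        axes[0][0].set_ylabel("annual P(death)")
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(args.results / "prediction_curves.svg", metadata={"Date": None})
        print(f"wrote {args.results / 'prediction_curves.svg'}")


if __name__ == "__main__":
    main()
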