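"""Bar charts of steady-state observables from `prebcr simulate` outputs.

Usage:  python examples/plot_summary.py RUN_DIR [RUN_DIR ...] -o out.png

Each RUN_DIR must contain the summary.json written by the simulate
command; one group of bars per run directory, with between-replicate
standard deviations as error bars.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

PANELS = {
    "receptor aggregation (%)": ["pct_monomer", "pct_dimer", "pct_higher"],
    "ITAM phosphorylation (%)": ["pct_iga_mono", "pct_iga_doubly",
                                 "pct_igb_mono", "pct_igb_doubly"],
    "Lyn (% of pool)": ["pct_lyn_bound", "pct_lyn_activated"],
    "Syk (% of total)": ["pct_syk_bound", "pct_syk_cat_phospho",
                         "pct_syk_linker_phospho"],
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("run_dirs", nargs="+", type=Path)
    ap.add_argument("-o", "--out", default="summary.png")
    args = ap.parse_args()

    summaries = {d.name: pd.read_json(d / "summary.json")
                 for d in args.run_dirs}
    fig, axes = plt.subplots(2, 2, figsize=(11, 7))
    width = 0.8 / len(summaries)
    for ax, (title, cols) in zip(axes.ravel(), PANELS.items()):
        x = np.arange(len(cols))
        for i, (name, s) in enumerate(summaries.items()):
            means = [s.loc[c, "mean"] for c in cols]
            errs = [np.nan_to_num(s.loc[c, "sd_between"]) for c in cols]
            ax.bar(x + i * width, means, width, yerr=errs, capsize=3,
                   label=name)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([c.replace("pct_", "") for c in cols],
                           rotation=20, ha="right", fontsize=8)
        ax.set_title(title, fontsize=10)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
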