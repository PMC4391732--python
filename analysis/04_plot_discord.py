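#!/usr/bin/env python
"""Plot mean +/- SD Robinson-Foulds discord per method, depth and locus count.

Reads results/mean_discord.tsv (produced by 03_run_benchmark.py) and writes
the figure to scratch/discord.png (figures are regenerable binaries and are
kept out of the tracked results).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main():
    table = pd.read_csv(ROOT / "results" / "mean_discord.tsv", sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    offsets = {"concatenation": -0.5, "stem": 0.0, "mdc": 0.5}
    for ax, depth in zip(axes, sorted(table["depth"].unique())):
        sub = table[table["depth"] == depth]
        for method, off in offsets.items():
            cell = sub[sub["method"] == method].sort_values("n_loci")
            x = [i * 3 + off for i in range(len(cell))]
            ax.errorbar(x, cell["mean_rf"], yerr=cell["sd_rf"], fmt="o-",
                        capsize=3, label=method)
        ax.set_xticks([0, 3, 6])
        ax.set_xticklabels(sorted(sub["n_loci"].unique()))
        ax.set_xlabel("loci per matrix")
        ax.set_title(f"depth {depth:g}N")
    axes[0].set_ylabel("mean RF distance to true species tree")
    axes[0].legend()
    fig.tight_layout()
    out = ROOT / "scratch"
    out.mkdir(exist_ok=True)
    fig.savefig(out / "discord.png", dpi=150)
    print(f"wrote {out / 'discord.png'}")


if __name__ == "__main__":
    main()
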