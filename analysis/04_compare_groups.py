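"""Summarise the group comparison: counts, networks, recovery, figures.

Reads the tables written by ``03_run_eeg_pipeline.py`` and reports the
headline count table (exclusive d >= 0.2 edges per subtype x band x
direction with the max-statistic corrected best p), the DMN/ECN/SAL
network aggregation, and how the six planted mood-alpha edges fared
before and after the cross-subtype exclusivity filter.  Also renders the
signed connection matrices as heatmaps.
"""

import argparse
from pathlib import Path

import pandas as pd

PLANTED0 = [(0, 9), (1, 12), (3, 6), (4, 15), (7, 17), (10, 13)]  # 0-based

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/run_seed1"))
args = parser.parse_args()

counts = pd.read_csv(args.run / "count_table.csv")
print("exclusive connection counts (machine twin of the headline table):")
print(counts.to_string(index=False))

nets = pd.read_csv(args.run / "network_counts.csv")
busy = nets[(nets.D_gt_ND + nets.D_lt_ND) > 0]
print("\nnetwork-pair cells with exclusive edges:")
print(busy.to_string(index=False) if not busy.empty else "  none")

comps = pd.read_csv(args.run / "edge_comparisons.tsv", sep="\t")
mood_alpha = comps[(comps.subtype == "mood") & (comps.band == "alpha")]
excl = pd.read_csv(args.run / "exclusive_edges.tsv", sep="\t")
excl_mood_alpha = {
    (r.roi_i, r.roi_j) for r in excl.itertuples()
    if r.subtype == "mood" and r.band == "alpha"
}
print("\nplanted mood-alpha edges:")
for i, j in PLANTED0:
    row = mood_alpha[(mood_alpha.roi_i == i) & (mood_alpha.roi_j == j)].iloc[0]
    survived = "exclusive" if (i, j) in excl_mood_alpha else (
        "flagged, removed by exclusivity" if row.flagged else "not flagged")
    print(f"  ({row.roi_i_label}, {row.roi_j_label}): d = {row.cohens_d:+.2f}, "
          f"t = {row.t:+.2f} -> {survived}")
n_flagged = sum(
    bool(mood_alpha[(mood_alpha.roi_i == i) & (mood_alpha.roi_j == j)].flagged.iloc[0])
    for i, j in PLANTED0
)
print(f"recovered by the d >= 0.2 screen: {n_flagged}/6; "
      f"surviving exclusivity: {len(excl_mood_alpha & set(PLANTED0))}/6")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = args.run / "figures"
    figdir.mkdir(exist_ok=True)
    fig, axes = plt.subplots(2, 4, figsize=(16, 8))
    for col, subtype in enumerate(["mood", "anhedonia", "cognitive", "somatic"]):
        for row, band in enumerate(["alpha", "beta"]):
            mat = pd.read_csv(args.run / f"matrix_{subtype}_{band}.csv", index_col=0)
            ax = axes[row, col]
            ax.imshow(mat.to_numpy(), cmap="bwr", vmin=-1, vmax=1)
            ax.set_title(f"{subtype} / {band}")
            ax.set_xticks(range(18))
            ax.set_xticklabels(mat.columns, rotation=90, fontsize=5)
            ax.set_yticks(range(18))
            ax.set_yticklabels(mat.index, fontsize=5)
    fig.suptitle("Exclusive connection differences (blue D>ND shown +1, red D<ND -1)")
    fig.tight_layout()
    fig.savefig(figdir / "network_matrices.png", dpi=120)
    print(f"figure: {figdir}/network_matrices.png")
except ImportError:
    print("matplotlib unavailable; skipping figures")
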