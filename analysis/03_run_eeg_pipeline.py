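"""Run the full EEG pipeline on a synthetic cohort with planted structure.

Simulates 100 participants' resting EEG (24 channels, 1 kHz, 3 min) with
six alpha-band lagged-coupling edges whose strength is raised for the
mood-depressed group, then filters, epochs, rejects, inverts, extracts
the 18 network ROIs, computes alpha/beta lagged linear connectivity, and
compares depressed vs non-depressed groups per subtype.  Writes the full
table set and a manifest under ``results/run_seed<seed>/``.

Takes a few minutes at full scale (100 participants x 3 min at 1 kHz).
"""

import argparse
from pathlib import Path

from depnet import pipeline, simulate

PLANTED = [(1, 10), (2, 13), (4, 7), (5, 16), (8, 18), (11, 14)]  # 1-based ROI pairs

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n", type=int, default=100)
parser.add_argument("--n-perm", type=int, default=5000)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

edges = tuple(
    simulate.CouplingEdge(roi_i=i, roi_j=j, band="alpha",
                          lag_ms=25.0, strength=0.4, group_contrast=0.5)
    for i, j in PLANTED
)
config = pipeline.RunConfig(
    seed=args.seed,
    cohort=simulate.CohortSpec(n_participants=args.n),
    eeg=simulate.SimEEGSpec(coupling_edges=edges),
    effect_subtype="mood",
    n_permutations=args.n_perm,
)
outdir = args.out / f"run_seed{args.seed}"
manifest = pipeline.run_pipeline(config, outdir)

stages = manifest["stages"]
print(f"simulated {stages['simulated']} participants; "
      f"{stages['excluded']} excluded by the 75% artifact-free rule; "
      f"{stages['retained_after_eeg_qc']} analysed")
print(f"planted: 6 alpha edges for the mood subtype (contrast 0.5)")
print(f"outputs under {outdir}/ (count_table.csv, exclusive_edges.tsv, "
      f"edge_comparisons.tsv, matrix_<subtype>_<band>.csv, qc_report.json)")
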