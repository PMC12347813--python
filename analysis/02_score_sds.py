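"""Score the SDS cohort: totals, subtype means, reliability, demographics.

Reads the simulated item table, applies reverse-keyed scoring, reports
Cronbach's alpha, splits the cohort at the conventional total-score
cutoff of 40 (with the between-group F and partial eta squared), screens
age and sex with Spearman correlations, and assigns per-subtype
depressed / non-depressed groups at the cohort-mean cutoffs.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from depnet import compare, sds

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

records = sds.read_sds_table(args.cohort)
scores = sds.score_cohort(records)
frame = sds.scores_frame(scores)

item_matrix = np.array(
    [[s.scored_items[i] for i in range(1, 21)] for s in scores]
)
alpha = sds.cronbach_alpha(item_matrix)
print(f"scored {len(scores)} participants; Cronbach's alpha = {alpha:.3f}")

totals = frame.sds_total.to_numpy()
clinical = totals >= 40
if 2 <= clinical.sum() <= len(totals) - 2:
    hi, lo = totals[clinical], totals[~clinical]
    t, p, d = compare.edge_ttest(hi, lo)
    F = t**2
    df2 = len(totals) - 2
    eta = compare.partial_eta_squared(F, 1, df2)
    print(f"clinical cutoff 40: {clinical.sum()} above, {(~clinical).sum()} below; "
          f"F(1,{df2}) = {F:.3f}, p = {compare.t_to_p(t, df2):.2e}, "
          f"partial eta^2 = {eta:.3f}")
else:
    F = eta = float("nan")
    print("clinical cutoff split degenerate; F/eta not computed")

ages = [r.age for r in records]
sexes = [r.sex for r in records]
screen = sds.demographic_screen(scores, ages, sexes)
worst = screen.loc[screen.p.idxmin()]
print(f"demographic screen: smallest p = {worst.p:.3f} "
      f"({worst.covariate} vs {worst.variable}); "
      f"max |rho| = {screen.rho.abs().max():.3f}")

assignments = sds.assign_groups(scores)
cutoffs = assignments[0].cutoffs_used
print("subtype-mean cutoffs:", {k: round(v, 3) for k, v in cutoffs.items()})
for s in sds.SUBTYPES:
    n_dep = sum(a.labels[s] == sds.DEPRESSED for a in assignments)
    print(f"  {s:10s} depressed {n_dep:3d} / non-depressed {len(assignments) - n_dep}")

args.out.mkdir(parents=True, exist_ok=True)
frame.to_csv(args.out / "scores.csv", index=False)
sds.assignments_frame(assignments).to_csv(args.out / "groups.csv", index=False)
screen.to_csv(args.out / "demographic_screen.csv", index=False)
(args.out / "sds_summary.json").write_text(json.dumps({
    "cronbach_alpha": alpha,
    "cutoffs": cutoffs,
    "clinical_cutoff_F": float(F),
    "clinical_cutoff_partial_eta_sq": float(eta),
}, indent=1))
print(f"written: {args.out}/scores.csv, groups.csv, demographic_screen.csv, sds_summary.json")
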