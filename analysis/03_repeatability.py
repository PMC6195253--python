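"""Technical repeatability: two-pass image re-counts and sorter
split-samples.

Re-counts isolate pure counting error (the image does not change between
passes); split samples add genuine binomial sampling of which worms end up
in each aliquot.  The analysis also contrasts the observed among-well
variation with the binomial within-well prediction sqrt(p(1-p)/n): with a
few hundred worms per well, sampling error is small next to the biological
variance among plates.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from wormfit.io import read_split_samples
from wormfit.repeatability import (
    recount_analysis,
    split_sample_analysis,
    split_sample_filter,
)
from wormfit.variability import binomial_se, se_ratio

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

import pandas as pd

recounts = pd.read_csv(args.results / "recounts.csv")
rec = recount_analysis(recounts)
print("re-count repeatability (two passes over the same images):")
print(f"  corr total {rec['corr_total']:.4f}, corr GFP {rec['corr_gfp']:.4f}, "
      f"corr p {rec['corr_p']:.4f}")
print(f"  mean |dcount|/avg: total {rec['mean_abs_rel_diff_total_pct']:.2f}%, "
      f"GFP {rec['mean_abs_rel_diff_gfp_pct']:.2f}%")

splits = read_split_samples(args.results / "split_samples.csv")
kept, filt = split_sample_filter(splits)
rep = split_sample_analysis(kept)
print(f"\nsplit samples: kept {filt['n_kept']} of {filt['n_input']} wells "
      f"(n > {filt['min_n']} and {filt['p_lo']} < p < {filt['p_hi']} in both aliquots)")
print(f"  mean |dp| = {rep['mean_abs_dp_pct_points']:.1f} percentage points; "
      f"corr(p_small, p_large) = {rep['corr_p']:.3f}")
print(f"  small aliquot: p = {rep['mean_p_small']:.3f} (SE {rep['se_p_small']:.4f}), "
      f"mean log CI = {rep['mean_log_ci_small']:.3f} (SE {rep['se_log_ci_small']:.4f})")
print(f"  large aliquot: p = {rep['mean_p_large']:.3f} (SE {rep['se_p_large']:.4f})")
nbar_s, nbar_l = rep["mean_n_small"], rep["mean_n_large"]
print(f"  mean aliquot sizes {nbar_s:.0f} / {nbar_l:.0f}: binomial SE ratio "
      f"sqrt(n_large/n_small) = {se_ratio(int(nbar_s), int(nbar_l)):.2f}")
bse = binomial_se(rep["mean_p_small"], int(nbar_s))
print(f"  binomial within-well SE at the small aliquot ({bse:.3f}) vs observed "
      f"among-well SD ({rep['se_p_small'] * np.sqrt(rep['n_wells']):.3f}): "
      "sampling error is the minor component")

with open(args.results / "repeatability.json", "w") as fh:
    json.dump({"recounts": rec, "split_filter": filt, "split_analysis": rep},
              fh, indent=2)
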