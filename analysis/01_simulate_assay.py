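"""Generate the synthetic study inputs: blocked assay counts, sorter
split-samples, and two-pass image re-counts.

Writes results/observations.csv (canonical schema), results/truth.csv,
results/split_samples.csv and results/recounts.csv.  The design mirrors the
full study: 5 blocks x 3 focal strains x 2 competitors x 3 counting methods
x 24 replicates, with by-eye counts absent from one block.
"""

import argparse
from pathlib import Path

from wormfit.io import write_observations
from wormfit.simulate import (
    full_design_config,
    simulate_assay,
    simulate_recounts,
    simulate_split_samples,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
cfg = full_design_config(seed=args.seed)

obs, truth = simulate_assay(cfg)
write_observations(obs, args.out / "observations.csv")
truth.to_csv(args.out / "truth.csv", index=False)
print(f"assay: {len(obs)} plate observations "
      f"({obs['block_id'].nunique()} blocks, "
      f"{obs.groupby(['focal_strain','competitor_strain','method']).ngroups} "
      f"combinations)")

splits, split_truth = simulate_split_samples(cfg, n_wells=336)
splits.to_csv(args.out / "split_samples.csv", index=False)
print(f"splits: {len(splits)} wells, mean small aliquot "
      f"{splits['n_total_small'].mean():.0f} worms, large "
      f"{splits['n_total_large'].mean():.0f}")

recounts = simulate_recounts(cfg, n_images=59)
recounts.to_csv(args.out / "recounts.csv", index=False)
print(f"recounts: {len(recounts)} images counted twice")
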