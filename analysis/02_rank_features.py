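"""Preprocess the synthetic study and rank voxels by stimulus-driven ANOVA F.

Reports how cleanly the univariate ranking separates truly signal-carrying
voxels from noise voxels, and writes the per-voxel F table.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from moviemvpa import anova_f_per_voxel, cut_froi, fixture_config, generate_dataset
from moviemvpa.preprocess import preprocess_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    dataset, truth = generate_dataset(fixture_config(args.seed))
    dataset = preprocess_dataset(dataset)
    ranking = anova_f_per_voxel(dataset.runs)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "voxel": np.arange(ranking.n_voxels),
            "f_stat": ranking.f_stat,
            "p_value": ranking.p_values(),
            "active_truth": truth.active_voxel_mask.astype(int),
        }
    ).to_csv(args.out / "anova_ranking.csv", index=False)

    for frac in (0.05, 0.25):
        k = int(frac * dataset.n_voxels)
        purity = truth.active_voxel_mask[cut_froi(ranking, k)].mean()
        print(f"top {frac:.0%} fROI ({k} voxels): {purity:.1%} inside the true active mask")
    print(
        f"mean F active={ranking.f_stat[truth.active_voxel_mask].mean():.2f}, "
        f"inactive={ranking.f_stat[~truth.active_voxel_mask].mean():.2f} "
        f"(df {ranking.df_between}, {ranking.df_within})"
    )


if __name__ == "__main__":
    main()
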