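"""Generate the moderate-SNR synthetic study and export it as NIfTI runs.

Writes one 4-D volume + label file per run under results/simulated/, plus a
ground-truth summary, so later stages (and any external tool) can ingest the
same dataset through the real-data path.
"""

import argparse
from pathlib import Path

import numpy as np

from moviemvpa import fixture_config, generate_dataset, write_dataset_nifti


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()

    cfg = fixture_config(args.seed)
    dataset, truth = generate_dataset(cfg)
    written = write_dataset_nifti(dataset, args.out)
    np.savetxt(args.out / "active_voxel_mask.txt", truth.active_voxel_mask.astype(int), fmt="%d")

    print(f"wrote {len(written)} files to {args.out}")
    print(
        f"R={dataset.n_runs} runs, C={dataset.n_classes} classes, "
        f"V={dataset.n_voxels} voxels, {truth.active_voxel_mask.sum()} active "
        f"({truth.active_voxel_mask.mean():.0%}), snr={cfg.snr}"
    )


if __name__ == "__main__":
    main()
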