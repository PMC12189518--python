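#!/usr/bin/env python
"""Optional benchmark reproduction on the public 3-channel MI dataset.

The published evaluation runs per-subject 10-fold cross-validation on the
feedback sessions of the BCI Competition IV 2b dataset (nine subjects,
C3/Cz/C4 at 250 Hz, cue codes 769/770) with an ImageNet-pretrained
efficientnet-b0 trunk. Neither the recordings nor the pretrained weights are
bundled or downloaded by this repository; obtain them yourself:

  1. Register and download the GDF files from
     https://www.bbci.de/competition/iv/ and place the feedback-session
     recordings (one or more per subject) under --data-dir.
  2. (Optional) Export published efficientnet-b0 ImageNet weights to an .npz
     keyed by this package's layer paths and pass it as --weights.

Without --weights the trunk is randomly initialised, which reproduces the
"without pretrained weights" ablation condition rather than the headline
configuration.

Usage:
    python scripts/reproduce_bci2b.py --data-dir bci2b/ [--weights w.npz]
        [--subjects 9] [--seed 0] [--out report.json]
"""

from __future__ import annotations

import argparse
import dataclasses


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", required=True)
    parser.add_argument("--weights", default=None)
    parser.add_argument("--subjects", type=int, default=9)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="bci2b_report.json")
    args = parser.parse_args()

    from cdml_eeg import PipelineConfig, TrainConfig, run_experiment

    cfg = PipelineConfig(
        data_dir=args.data_dir,
        n_subjects=args.subjects,
        pretrained=args.weights is not None,
        weights_path=args.weights,
        seed=args.seed,
        train=TrainConfig(seed=args.seed),
    )
    report = run_experiment(cfg)
    report.to_json(args.out)
    for subject, mean in report.per_subject_mean.items():
        print(f"{subject}: {100 * mean:.2f}%")
    print(f"grand mean: {100 * report.grand_mean:.2f}%")


if __name__ == "__main__":
    main()
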