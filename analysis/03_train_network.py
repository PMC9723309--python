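#!/usr/bin/env python
"""Train the minimal 3D CNN on the spectral volumes.

Random 75/12.5/12.5 trial-level partition, one-time augmentation (shift /
zoom / elastic deformation of 33% of training volumes each), class-weighted
cross-entropy with L1+L2 penalties, Adam with the staircase learning-rate
schedule. Prints the layer/parameter summary and writes the per-epoch
metrics log and the trained weights.
"""

import argparse
from pathlib import Path

import numpy as np

from oscimap import net, pipeline, train


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--epochs", type=int, default=10)
    ap.add_argument("--lr", type=float, default=2e-3,
                    help="initial rate of the (scaled-down) staircase schedule")
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with np.load(args.scratch / "volumes.npz") as z:
        volumes, labels = z["volumes"], z["labels"]

    spec = net.ModelSpec(dtype="float32")
    counts = net.count_parameters(spec)
    print("layer parameter counts:", {k: v for k, v in counts.items()
                                      if not k.startswith("total")})
    print(f"trainable parameters: {counts['total']} "
          f"(+{counts['total_with_batchnorm'] - counts['total']} batch-norm)")

    cfg = train.TrainConfig(max_epochs=args.epochs, patience=args.epochs,
                            initial_lr=args.lr, seed=args.seed)
    split = train.partition(len(labels), cfg)
    itr, iva = split.indices("train"), split.indices("val")
    x_train = train.apply_augmentation(volumes[itr], cfg, seed=args.seed)
    model = net.build_model(spec, seed=args.seed)
    model, hist = train.train(model, x_train, labels[itr],
                              volumes[iva], labels[iva], cfg)

    args.outdir.mkdir(parents=True, exist_ok=True)
    hist.to_frame().to_csv(args.outdir / "training_log.tsv", sep="\t", index=False)
    model.save(args.scratch / "model")
    np.save(args.scratch / "split_labels.npy", split.labels)
    print(f"{hist.steps} update steps over {len(hist.epochs)} epochs; "
          f"final val accuracy {hist.val_acc[-1]:.3f}, "
          f"final val loss {hist.val_loss[-1]:.3f}")


if __name__ == "__main__":
    main()
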