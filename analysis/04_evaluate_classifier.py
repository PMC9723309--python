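#!/usr/bin/env python
"""Evaluate the trained classifier on the held-out test trials.

Winner-take-all accuracy (unweighted and balanced), the row-normalized
confusion matrix, and one-vs-rest ROC curves with their areas (the
trapezoidal area equals the Mann-Whitney pairwise probability).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oscimap import evaluate, net


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with np.load(args.scratch / "volumes.npz") as z:
        volumes, labels = z["volumes"], z["labels"]
    split = np.load(args.scratch / "split_labels.npy", allow_pickle=True)
    model = net.Model3DCNN.load(args.scratch / "model")

    idx = np.flatnonzero(split == "test")
    scores = model.predict_proba(volumes[idx])
    table = evaluate.ScoreTable(scores, labels[idx])
    report = evaluate.evaluation_report(table)

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "evaluation.json").write_text(json.dumps(report, indent=1))
    rocs = evaluate.one_vs_rest_roc(table)
    with open(args.outdir / "roc_points.tsv", "w") as f:
        f.write("class\tthreshold\tfp\ttp\n")
        for name, curve in rocs.items():
            for t, fp, tp in zip(curve.thresholds, curve.fp, curve.tp):
                f.write(f"{name}\t{t}\t{fp}\t{tp}\n")

    print(f"test trials: {len(idx)}")
    print(f"accuracy: unweighted {report['accuracy_unweighted']:.3f}, "
          f"balanced {report['accuracy_balanced']:.3f} (chance 0.333)")
    print("per-class accuracy:", {k: round(v, 3)
                                  for k, v in report["per_class_accuracy"].items()})
    print("one-vs-rest AUC:", {k: round(v, 3) for k, v in report["auc"].items()})
    print("confusion matrix rows (true HC, PD_OFF, PD_ON):")
    for row in report["confusion_matrix"]:
        print("  ", [round(v, 3) for v in row])


if __name__ == "__main__":
    main()
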