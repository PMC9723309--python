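#!/usr/bin/env python
"""Associate cluster oscillatory power with the clinical variables.

Median pre-normalization power per subject/state at the cluster electrode
sets and bands, rank-normalized to a standard normal scale, entered in
linear mixed models (ML, by-participant random intercept) with age as
covariate; inference by likelihood-ratio tests on the power term. The
on-medication model relates frontoparietal theta power to the on-off
change in UPDRS motor score, adjusting for age, off-state UPDRS and
education.
"""

import argparse
from pathlib import Path

import pandas as pd

from oscimap import clinstats, pipeline, synth
from oscimap.montage import standard_layout


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    recordings, clinical = synth.read_cohort(args.scratch / "cohort")
    trialsets = pipeline.preprocess_cohort(recordings)
    layout = standard_layout()
    feats = pipeline.power_features(trialsets, layout)
    feats_pd = feats[feats["cohort"].isin(["PD_OFF", "PD_ON"])
                     & feats["state"].isin(["off", "on"])]

    report = clinstats.association_suite(
        feats_pd, clinical,
        off_clusters=("op_beta", "motor_beta", "motor_gamma"),
        on_theta_cluster="fp_theta",
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.outdir / "associations.tsv", sep="\t", index=False)
    report.to_json(args.outdir / "associations.json", orient="records", indent=1)

    pd.set_option("display.width", 160)
    cols = ["outcome", "cluster", "state", "estimate", "se", "chi2", "df", "p"]
    print(report[[c for c in cols if c in report]].to_string(index=False))
    hits = report[(report.get("p", 1) < 0.05)]
    if len(hits):
        print("\nassociations with unadjusted LRT p < 0.05:")
        for _, row in hits.iterrows():
            print(f"  {row['outcome']} ~ {row['cluster']} ({row['state']}): "
                  f"estimate {row['estimate']:+.2f}, chi2(1) = {row['chi2']:.2f}, "
                  f"p = {row['p']:.3f}")


if __name__ == "__main__":
    main()
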