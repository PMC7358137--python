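#!/usr/bin/env python
"""Cross-assay agreement, truth recovery, and pathogenicity classification.

Aligns mini-array and liquid LoF scores by variant, computes the Pearson
correlation matrix, measures recovery of the planted truth (LoF = 1 - f)
per sentinel, and trains a logistic-regression pathogenicity classifier per
sentinel (stratified 70-30 split, fivefold cross-validation) against the
noisy reference labels.

Writes results/pearson.tsv, recovery.tsv, classification.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from simap import evaluate as ev
from simap import pipeline
from simap.config import RunConfig
from simap.errors import SimapError

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    data = RESULTS / "data"
    cfg = RunConfig.from_yaml(data / "run_config.yaml")
    truth = pd.read_csv(data / "truth.tsv", sep="\t")
    ma_scores = pd.read_csv(RESULTS / "miniarray_scores.tsv", sep="\t")
    lq_scores = pd.read_csv(RESULTS / "liquid_scores.tsv", sep="\t")

    # cross-assay agreement, using the most sensitive sentinel's array scores
    best = ma_scores.groupby("sentinel_id")["median_diff"].mean().idxmax()
    matrix = ev.align_scores(
        [pipeline.miniarray_variant_scores(ma_scores, best),
         pipeline.liquid_variant_scores(lq_scores)],
        ["miniarray", "liquid"])
    corr = ev.pearson_matrix(matrix)
    corr.to_csv(RESULTS / "pearson.tsv", sep="\t")
    r = corr.loc["miniarray", "liquid"]
    print(f"solid vs liquid agreement (sentinel {best}): "
          f"r = {r:.3f}, r^2 = {r * r:.3f} over {len(matrix)} variants")

    rows = []
    for sid in sorted(ma_scores["sentinel_id"].unique()):
        sub = pipeline.miniarray_variant_scores(ma_scores, sid).dropna(subset=["lof"])
        rep = ev.recovery_report(sub, truth)["overall"]
        rows.append({"sentinel_id": sid, **rep})
    recovery = pd.DataFrame(rows)
    recovery.to_csv(RESULTS / "recovery.tsv", sep="\t", index=False)
    print("truth recovery per sentinel (RMSE of LoF vs 1-f):")
    print(recovery[["sentinel_id", "n", "rmse", "bias"]].round(3).to_string(index=False))

    labels = truth.set_index("variant_id")["label_observed"].astype(float)
    reports = []
    for sid in sorted(ma_scores["sentinel_id"].unique()):
        sub = pipeline.miniarray_variant_scores(ma_scores, sid).dropna(subset=["lof"])
        y = labels.reindex(sub["variant_id"]).to_numpy()
        try:
            rep = ev.train_pathogenicity_model(sub["lof"], y, split=cfg.split,
                                               seed=cfg.seed, folds=cfg.folds)
        except SimapError as exc:
            print(f"  {sid}: classifier skipped ({exc})")
            continue
        reports.append({"sentinel_id": sid, "accuracy": rep.accuracy,
                        "precision": rep.precision, "sensitivity": rep.sensitivity,
                        "f1": rep.f1, "cv_accuracy": rep.cv_accuracy})
    cls = pd.DataFrame(reports)
    cls.to_csv(RESULTS / "classification.tsv", sep="\t", index=False)
    print("pathogenicity classification per sentinel (70-30 split, 5-fold CV):")
    print(cls.round(3).to_string(index=False))
    print(f"wrote {RESULTS / 'pearson.tsv'}, recovery.tsv, classification.tsv")


if __name__ == "__main__":
    main()
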