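#!/usr/bin/env python
"""Same/different-person verification with five classifiers.

Builds the balanced pair set (every within-subject pair plus an equal
uniform subsample of cross-subject pairs) on the first 30 principal
components, then evaluates L1/L2 distance thresholds and maximum-margin
classifiers (linear, polynomial, RBF kernels) with stratified fivefold
cross-validation.  Writes per-method score tables, ROC curves and a
summary with accuracy and EER.
"""
import argparse
import time
from pathlib import Path

import pandas as pd

from gaituniq.fileio import load_model
from gaituniq.verification import METHODS, build_pair_dataset, count_diff_pairs, cross_validate

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--k", type=int, default=30, help="number of PC features")
    ap.add_argument("--pair-seed", type=int, default=2)
    ap.add_argument("--cv-seed", type=int, default=3)
    args = ap.parse_args()

    model = load_model(RESULTS / "pca_model.npz")
    labels = model.subject_labels
    features = model.scores[:, :args.k]
    dataset = build_pair_dataset(features, labels, seed=args.pair_seed)
    print(f"pair cases: {dataset.n_same} same + {dataset.n_diff} different "
          f"(subsampled from {count_diff_pairs(labels):,}) = {len(dataset)}")

    rows = []
    for method in METHODS:
        t0 = time.time()
        res = cross_validate(dataset, method, folds=5, seed=args.cv_seed)
        rows.append({"method": method, "accuracy": res.accuracy,
                     "eer": res.eer, "folds": res.folds})
        print(f"{method:7s} accuracy {res.accuracy:.4f}  EER {res.eer:.4f}  "
              f"({time.time() - t0:.1f} s)")
        pd.DataFrame({"threshold": res.thresholds, "far": res.far_curve,
                      "frr": res.frr_curve}).to_csv(
            RESULTS / f"roc_{method}.csv", index=False)
        pd.DataFrame({"score": res.scores, "label_same": res.labels,
                      "fold": res.fold_assignment}).to_csv(
            RESULTS / f"scores_{method}.csv", index=False)

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "verification_summary.csv", index=False)
    best = summary.loc[summary.eer.idxmin()]
    print(f"best method: {best.method} (accuracy {best.accuracy:.4f}, "
          f"EER {best.eer:.4f})")
    print(f"wrote {RESULTS / 'verification_summary.csv'}")


if __name__ == "__main__":
    main()
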