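#!/usr/bin/env python
"""PCA of the pooled gait vectors: rank, variance profile, correlations.

Fits the mean-centered PCA, reports the retained rank and the component
counts needed for 90/95/99% of total variance, computes the intra-subject
variance and the intra/explained variance ratio per component, and
correlates the leading component scores with the spatiotemporal gait
parameters (cadence, step length, velocity).
"""
import time
from pathlib import Path

import numpy as np
import pandas as pd

from gaituniq.features import (
    components_for_variance,
    correlate_with_parameters,
    fit_gait_pca,
    intra_subject_variance,
    reorder_components_by_ratio,
    variance_ratio,
)
from gaituniq.fileio import read_gait_vectors, save_model

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    vectors, meta = read_gait_vectors(RESULTS / "gait_vectors.csv",
                                      RESULTS / "cycle_meta.csv")
    labels = meta.subject_id.to_numpy()
    t0 = time.time()
    model = fit_gait_pca(vectors, labels)
    print(f"PCA of {vectors.shape[0]} x {vectors.shape[1]} pool "
          f"in {time.time() - t0:.1f} s")
    print(f"retained {model.n_components} principal components")
    for frac in (0.90, 0.95, 0.99):
        k = components_for_variance(model, frac)
        print(f"  {frac:.0%} of total variance: {k} components")

    intra = intra_subject_variance(model.scores, labels)
    profile = variance_ratio(model.explained_variance, intra)
    order = reorder_components_by_ratio(profile)
    print(f"intra/explained ratio over first 30 components: "
          f"min {profile.ratio[:30].min():.3f}, max {profile.ratio[:30].max():.3f}")
    print(f"most person-stable components (ascending ratio): {order[:6].tolist()}")

    corr = correlate_with_parameters(
        model.scores[:, :8], meta[["cadence", "step_length", "velocity"]])
    strongest = corr.abs().stack().idxmax()
    print(f"strongest PC-parameter correlation: PC{strongest[0] + 1} vs "
          f"{strongest[1]} (r = {corr.loc[strongest]:.2f})")

    save_model(RESULTS / "pca_model.npz", model)
    pd.DataFrame({"explained_variance": profile.explained,
                  "intra_subject_variance": profile.intra,
                  "variance_ratio": profile.ratio}).to_csv(
        RESULTS / "variance_profile.csv", index_label="component")
    corr.to_csv(RESULTS / "pc_parameter_correlations.csv", index_label="component")
    print(f"wrote {RESULTS / 'pca_model.npz'} and variance/correlation tables")


if __name__ == "__main__":
    main()
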