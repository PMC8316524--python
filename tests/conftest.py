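import numpy as np
import pytest

from gaituniq.pipeline import extract_cohort_vectors
from gaituniq.simulate import CohortParams, generate_marker_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject marker cohort at the study's trial/cycle design."""
    params = CohortParams(n_subjects=8, seed=42)
    trials, registry = generate_marker_cohort(params)
    return params, trials, registry


@pytest.fixture(scope="session")
def small_vectors(small_cohort):
    """Gait vectors + per-cycle metadata extracted from the small cohort."""
    _, trials, registry = small_cohort
    vectors, meta = extract_cohort_vectors(trials, registry)
    return vectors, meta


def eer_oracle(scores, labels) -> float:
    """Exhaustive threshold-sweep EER, independent of the package's ROC path.

    Accept a pair iff its score >= threshold; sweep every observed score
    (descending) plus the accept-nothing sentinel, and interpolate the
    FAR/FRR crossing linearly between adjacent thresholds.
    """
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    same = [s for s, l in zip(scores, labels) if l]
    diff = [s for s, l in zip(scores, labels) if not l]
    pts = [(0.0, 1.0)]
    for thr in sorted(set(scores), reverse=True):
        far = sum(1 for s in diff if s >= thr) / len(diff)
        frr = sum(1 for s in same if s < thr) / len(same)
        pts.append((far, frr))
    prev_far, prev_frr = pts[0]
    for far, frr in pts[1:]:
        d = far - frr
        if d == 0:
            return far
        if d > 0:
            alpha = (prev_frr - prev_far) / ((far - prev_far) - (frr - prev_frr))
            return prev_far + alpha * (far - prev_far)
        prev_far, prev_frr = far, frr
    return pts[-1][0]


def random_score_set(rng):
    """A random mixed-tie score/label set for ROC property tests."""
    n_same = int(rng.integers(2, 30))
    n_diff = int(rng.integers(2, 30))
    labels = np.concatenate([np.ones(n_same, bool), np.zeros(n_diff, bool)])
    if rng.random() < 0.5:
        scores = rng.integers(0, 6, size=len(labels)).astype(float)
    else:
        scores = rng.normal(labels.astype(float), 1.0)
    return scores, labels
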