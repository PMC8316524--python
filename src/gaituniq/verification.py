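"""Pairwise same/different-person verification of gait feature vectors.

Verification is posed as binary classification of feature-vector pairs:
every unordered within-subject pair is a "same" case, an equal-sized
uniform subsample of the cross-subject pairs provides the "different"
cases.  Five decision rules are supported:

* ``l1`` / ``l2`` — Manhattan / Euclidean distance of the pair difference,
  thresholded (accept "same" iff distance <= threshold; the threshold is
  chosen on the training folds by maximising accuracy);
* ``linear`` / ``poly`` — maximum-margin classifiers (SVM, C = 1) on the
  elementwise absolute difference;
* ``rbf`` — an RBF-kernel maximum-margin classifier on the signed
  difference, trained with sign symmetrisation (each case augmented by its
  negation) because pair order is arbitrary.

Performance is measured by stratified fivefold cross-validation with
pooled out-of-fold scores, from which FAR/FRR curves and the equal error
rate (EER) are computed.  The EER feeds closed-form population-uniqueness
estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "PairCase",
    "PairDataset",
    "VerificationResult",
    "enumerate_same_pairs",
    "count_diff_pairs",
    "sample_diff_pairs",
    "build_pair_dataset",
    "norm_score",
    "train_pair_classifier",
    "cross_validate",
    "roc_and_eer",
    "uniqueness_estimates",
    "METHODS",
]

METHODS = ("l1", "l2", "linear", "poly", "rbf")


class VerificationError(ValueError):
    """Raised for invalid pair-building or evaluation inputs."""


@dataclass
class PairCase:
    """One labeled feature-difference case."""

    difference: np.ndarray        # signed f1 - f2
    label: bool                   # True = same person
    subject_ids: tuple[str, str]

    def __post_init__(self):
        self.difference = np.asarray(self.difference, dtype=float)
        if self.label != (self.subject_ids[0] == self.subject_ids[1]):
            raise VerificationError("label inconsistent with subject ids")

    @property
    def abs_difference(self) -> np.ndarray:
        return np.abs(self.difference)


@dataclass
class PairDataset:
    """A stack of pair cases with aligned difference matrix and labels."""

    differences: np.ndarray       # (n, k) signed
    labels: np.ndarray            # (n,) bool, True = same
    subject_ids: np.ndarray       # (n, 2) str
    sampling_seed: int | None = None

    def __post_init__(self):
        self.differences = np.asarray(self.differences, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> PairCase:
        return PairCase(self.differences[i], bool(self.labels[i]),
                        (str(self.subject_ids[i, 0]), str(self.subject_ids[i, 1])))

    @property
    def n_same(self) -> int:
        return int(self.labels.sum())

    @property
    def n_diff(self) -> int:
        return int((~self.labels).sum())

    @property
    def abs_differences(self) -> np.ndarray:
        return np.abs(self.differences)


def _group_indices(labels) -> dict:
    labels = np.asarray(labels)
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return groups


def enumerate_same_pairs(features: np.ndarray, labels) -> list[PairCase]:
    """All unordered within-subject pairs; count = sum over subjects C(n_s, 2)."""
    X = np.asarray(features, dtype=float)
    cases = []
    for lab, idx in _group_indices(labels).items():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                cases.append(PairCase(X[idx[a]] - X[idx[b]], True,
                                      (str(lab), str(lab))))
    return cases


def count_diff_pairs(labels) -> int:
    """Number of cross-subject unordered pairs: C(S,2) * t^2 for equal sizes."""
    labels = np.asarray(labels)
    n = len(labels)
    sizes = np.array([len(v) for v in _group_indices(labels).values()])
    return int((n * n - np.sum(sizes * sizes)) // 2)


def _diff_pair_indices(labels) -> np.ndarray:
    """``(total, 2)`` observation index pairs of all cross-subject pairs."""
    groups = list(_group_indices(labels).values())
    blocks = []
    later: list[int] = []
    for g in reversed(groups):
        if later:
            a = np.repeat(g, len(later))
            b = np.tile(later, len(g))
            blocks.append(np.column_stack([a, b]))
        later = g + later
    if not blocks:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(blocks[::-1])


def sample_diff_pairs(features: np.ndarray, labels, n: int, seed: int) -> list[PairCase]:
    """Uniform subsample (without replacement) of the cross-subject pairs.

    Deterministic for a fixed seed; ``n`` equal to the population size
    returns the full enumeration.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    pairs = _diff_pair_indices(labels)
    if n > len(pairs):
        raise VerificationError(
            f"requested {n} different-person pairs, only {len(pairs)} exist")
    rng = np.random.default_rng(seed)
    chosen = pairs[np.sort(rng.choice(len(pairs), size=n, replace=False))]
    return [PairCase(X[a] - X[b], False, (str(labels[a]), str(labels[b])))
            for a, b in chosen]


def build_pair_dataset(
    features: np.ndarray, labels, seed: int, n_diff: int | None = None
) -> PairDataset:
    """Assemble the balanced analysis set: all same pairs + sampled diff pairs.

    ``n_diff`` defaults to the number of same pairs (the balanced design).
    """
    same = enumerate_same_pairs(features, labels)
    if n_diff is None:
        n_diff = len(same)
    diff = sample_diff_pairs(features, labels, n_diff, seed)
    cases = same + diff
    return PairDataset(
        differences=np.array([c.difference for c in cases]),
        labels=np.array([c.label for c in cases]),
        subject_ids=np.array([c.subject_ids for c in cases]),
        sampling_seed=seed,
    )


def norm_score(case: PairCase, p: int) -> float:
    """Manhattan (p=1) or Euclidean (p=2) distance of the pair difference."""
    if p not in (1, 2):
        raise VerificationError("p must be 1 or 2")
    d = case.difference
    return float(np.abs(d).sum()) if p == 1 else float(np.sqrt(np.sum(d * d)))


class PairClassifier:
    """A fitted maximum-margin pair classifier.

    ``decision`` returns a signed margin: positive means the pair is
    predicted to come from the same person.
    """

    def __init__(self, kernel: str, symmetrize: bool = True, C: float = 1.0):
        if kernel not in ("linear", "poly", "rbf"):
            raise VerificationError(f"unknown kernel {kernel!r}")
        self.kernel = kernel
        self.symmetrize = symmetrize
        # inhomogeneous cubic kernel (coef0=1); tight tolerance so the
        # decision function is reproducibly symmetric under pair reversal
        self._svc = SVC(kernel=kernel, C=C, degree=3, gamma="scale",
                        coef0=1.0, tol=1e-5)

    def _features(self, differences: np.ndarray) -> np.ndarray:
        d = np.asarray(differences, dtype=float)
        return d if self.kernel == "rbf" else np.abs(d)

    def fit(self, differences: np.ndarray, labels: np.ndarray) -> "PairClassifier":
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise VerificationError("training set must contain both classes")
        X = self._features(differences)
        if self.kernel == "rbf" and self.symmetrize:
            X = np.concatenate([X, -X])
            y = np.concatenate([y, y])
        self._svc.fit(X, y)
        return self

    def decision(self, differences: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._features(differences))

    def predict(self, differences: np.ndarray) -> np.ndarray:
        return self.decision(differences) > 0


def train_pair_classifier(
    dataset: PairDataset, kernel: str, symmetrize: bool = True, C: float = 1.0
) -> PairClassifier:
    """Fit a maximum-margin classifier on a pair dataset."""
    return PairClassifier(kernel, symmetrize=symmetrize, C=C).fit(
        dataset.differences, dataset.labels)


def _best_threshold(dist: np.ndarray, y: np.ndarray) -> float:
    """Accuracy-maximising acceptance threshold on distances.

    Accept "same" iff distance <= threshold.  Candidates are midpoints of
    adjacent sorted distances plus sentinels; ties break toward the
    smaller threshold.
    """
    order = np.argsort(dist)
    d_sorted = dist[order]
    y_sorted = y[order].astype(int)
    # candidate k = accept the k smallest distances, k = 0..n
    tp = np.concatenate([[0], np.cumsum(y_sorted)])
    fp = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    correct = tp + (fp[-1] - fp)
    # collapse tied distances: threshold must separate distinct values
    uniq_hi = np.concatenate([d_sorted[1:] != d_sorted[:-1], [True]])
    valid_k = np.concatenate([[True], uniq_hi])
    correct = np.where(valid_k, correct, -1)
    k = int(np.argmax(correct))  # argmax takes the first (smallest) maximiser
    if k == 0:
        return float(d_sorted[0] - 1.0) if len(d_sorted) else 0.0
    if k == len(d_sorted):
        return float(d_sorted[-1])
    return float(0.5 * (d_sorted[k - 1] + d_sorted[k]))


@dataclass
class VerificationResult:
    """Cross-validated verification performance of one method."""

    method: str
    scores: np.ndarray            # pooled out-of-fold acceptance scores (higher = same)
    predictions: np.ndarray       # pooled out-of-fold boolean predictions
    labels: np.ndarray
    accuracy: float
    thresholds: np.ndarray        # acceptance-score thresholds of the ROC sweep
    far_curve: np.ndarray
    frr_curve: np.ndarray
    eer: float
    folds: int
    fold_assignment: np.ndarray = field(default=None)


def cross_validate(
    dataset: PairDataset, method: str, folds: int = 5, seed: int = 0
) -> VerificationResult:
    """Stratified k-fold cross-validation of one verification method.

    Folds are stratified by the same/different label; accuracy is the
    pooled out-of-fold correct proportion and the ROC/EER are computed on
    the pooled out-of-fold scores.
    """
    if method not in METHODS:
        raise VerificationError(f"unknown method {method!r}; choose from {METHODS}")
    n = len(dataset)
    if folds < 2 or folds > n:
        raise VerificationError(f"folds must be in [2, {n}], got {folds}")
    y = dataset.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(n)
    preds = np.empty(n, dtype=bool)
    fold_of = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(skf.split(dataset.differences, y.astype(int))):
        fold_of[te] = f
        if method in ("l1", "l2"):
            p = 1 if method == "l1" else 2
            d_all = (np.abs(dataset.differences).sum(axis=1) if p == 1
                     else np.linalg.norm(dataset.differences, axis=1))
            thr = _best_threshold(d_all[tr], y[tr])
            preds[te] = d_all[te] <= thr
            scores[te] = -d_all[te]
        else:
            clf = PairClassifier(method).fit(dataset.differences[tr], y[tr])
            s = clf.decision(dataset.differences[te])
            scores[te] = s
            preds[te] = s > 0
    accuracy = float(np.mean(preds == y))
    thresholds, far, frr, eer = roc_and_eer(scores, y)
    return VerificationResult(
        method=method, scores=scores, predictions=preds, labels=y.copy(),
        accuracy=accuracy, thresholds=thresholds, far_curve=far,
        frr_curve=frr, eer=eer, folds=folds, fold_assignment=fold_of)


def roc_and_eer(scores: np.ndarray, labels: np.ndarray):
    """FAR/FRR curves over all observed score thresholds, and the EER.

    ``scores`` are acceptance scores (higher = more likely same person);
    a pair is accepted iff its score >= threshold.  FAR is the proportion
    of different-person pairs accepted, FRR the proportion of same-person
    pairs rejected.  The EER is read off where FAR = FRR, linearly
    interpolated between the two adjacent thresholds where FAR - FRR
    changes sign.

    Returns ``(thresholds, far, frr, eer)`` with thresholds decreasing
    (loosest first).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise VerificationError("need both same and different pairs for a ROC")
    # roc_curve sweeps thresholds decreasing: fpr == FAR, 1 - tpr == FRR
    far, tpr, thr = roc_curve(y.astype(int), scores, drop_intermediate=False)
    frr = 1.0 - tpr
    d = far - frr
    k = int(np.argmax(d >= 0))
    if d[k] == 0:
        eer = float(far[k])
    else:
        dfar = far[k] - far[k - 1]
        dfrr = frr[k] - frr[k - 1]
        alpha = (frr[k - 1] - far[k - 1]) / (dfar - dfrr)
        eer = float(far[k - 1] + alpha * dfar)
    return thr, far, frr, eer


def uniqueness_estimates(eer: float, population: int):
    """Population-uniqueness arithmetic from a verification EER.

    For a population of ``population`` individuals and one probe sample:

    * ``special_error_bound`` — union bound on the probability of
      misattributing the probe: ``eer * population``;
    * ``special_uniqueness`` — ``1 - eer * population``, the chance the
      probe is unique within the population;
    * ``general_uniqueness`` — ``(1 - eer * population) ** population``,
      the chance every member of the population is unique.
    """
    if not 0.0 <= eer <= 1.0:
        raise VerificationError("eer must be in [0, 1]")
    if population < 1:
        raise VerificationError("population must be >= 1")
    bound = eer * population
    if bound > 1.0:
        raise VerificationError(
            f"eer * population = {bound:.3f} > 1; the union bound degenerates")
    special = 1.0 - bound
    general = special ** population
    return bound, special, general
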