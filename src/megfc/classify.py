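"""Two-scheme cross-validated RBF-SVM classification with stability selection.

Segments (one FC feature vector each) are classified CPS vs SPS with an
RBF-kernel SVM (C = 1.2, gamma = 5).  Feature selection is wrapped in a
14-fold loop under either of two schemes:

* **subsets** — subjects are paired into 16 subsets (one CPS + one SPS
  each, matched by segment-count rank), 2 subsets are held out for
  testing and the remaining 14 run a leave-one-subset-out loop;
* **random** — all training-pool samples are mixed and each of 14
  repetitions draws a random 90/10 split, ignoring subject identity.

Inside each fold, per-feature F-scores are computed on the sub-training
samples only, the top 1% of features is kept, and the SVM is trained on
those features; the held-out fold supplies a validation accuracy.
Features selected in at least 12 of the 14 folds form the *stable set*
(overlap-rate stability selection); the stable features whose mean
F-score exceeds 75% of the maximum are flagged as *strong edges*.  The
final classifier is retrained on the whole training pool restricted to
the stable set and evaluated once on the held-out test subsets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import f_score, select_top_fraction

__all__ = [
    "SubsetPartition",
    "FoldResult",
    "StabilityResult",
    "EvalReport",
    "build_subset_partition",
    "train_rbf_svm",
    "loo_stability_run",
    "random_split_run",
    "overlap_select",
    "flag_strong_edges",
    "finalize_and_evaluate",
    "StabilitySelectedSVC",
]

logger = logging.getLogger(__name__)


@dataclass
class SubsetPartition:
    """Pairing of subjects into subsets plus train/test role assignment."""
    pairs: list[tuple[str, str]]          # (CPS subject, SPS subject) per subset
    test_subsets: tuple[int, ...]         # indices into ``pairs``

    @property
    def n_subsets(self) -> int:
        return len(self.pairs)

    @property
    def training_subsets(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_subsets)
                     if i not in self.test_subsets)

    def subset_of_subject(self) -> dict[str, int]:
        out = {}
        for k, (a, b) in enumerate(self.pairs):
            out[a] = k
            out[b] = k
        return out


@dataclass
class FoldResult:
    """One fold of the selection + training loop."""
    fold_id: int
    selected_features: np.ndarray         # descending F-score, size k
    fscores: np.ndarray                   # F-scores aligned with selection
    validation_accuracy: float


@dataclass
class StabilityResult:
    """Overlap-rate stability selection across folds."""
    occurrence_counts: Counter
    stable_features: np.ndarray           # descending mean F-score
    mean_fscores: np.ndarray              # aligned with stable_features
    threshold: int
    n_folds: int
    strong_flags: np.ndarray = field(default_factory=lambda: np.array([], bool))


@dataclass
class EvalReport:
    """Test-set evaluation with CPS as the positive class."""
    tp: int
    fn: int
    tn: int
    fp: int
    subject_majority_accuracy: float | None = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(1, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / max(1, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / max(1, self.tn + self.fp)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_label=1,
                         subject_ids=None) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive_label
        hit = y_pred == y_true
        rep = cls(tp=int((pos & hit).sum()), fn=int((pos & ~hit).sum()),
                  tn=int((~pos & hit).sum()), fp=int((~pos & ~hit).sum()))
        if subject_ids is not None:
            subject_ids = np.asarray(subject_ids)
            votes = []
            for sid in np.unique(subject_ids):
                m = subject_ids == sid
                majority = Counter(y_pred[m].tolist()).most_common(1)[0][0]
                votes.append(majority == y_true[m][0])
            rep.subject_majority_accuracy = float(np.mean(votes))
        return rep


def build_subset_partition(subject_ids, group_labels, segment_counts,
                           seed=None, n_test: int = 2,
                           test_subsets=None,
                           positive_label="CPS") -> SubsetPartition:
    """Pair subjects across groups by segment-count rank; reserve test subsets.

    Subjects of each group are sorted by their segment counts and paired
    rank-to-rank, so each subset holds one subject per group with roughly
    matched sample sizes.  ``n_test`` subsets (default 2) are chosen by a
    seeded draw unless ``test_subsets`` pins them explicitly.
    """
    subject_ids = np.asarray(subject_ids)
    group_labels = np.asarray(group_labels)
    segment_counts = np.asarray(segment_counts)
    pos = group_labels == positive_label
    if pos.sum() != (~pos).sum():
        raise ValueError(
            f"groups must be equal-sized, got {int(pos.sum())} vs {int((~pos).sum())}"
        )
    order_pos = np.argsort(segment_counts[pos], kind="stable")
    order_neg = np.argsort(segment_counts[~pos], kind="stable")
    pairs = list(zip(subject_ids[pos][order_pos], subject_ids[~pos][order_neg]))
    n_subsets = len(pairs)
    if n_subsets - n_test < 2:
        raise ValueError(
            f"{n_subsets} subsets cannot reserve {n_test} for testing and "
            "leave at least 2 for training"
        )
    if test_subsets is None:
        rng = np.random.default_rng(seed)
        test_subsets = tuple(sorted(
            rng.choice(n_subsets, size=n_test, replace=False).tolist()))
    else:
        test_subsets = tuple(sorted(int(t) for t in test_subsets))
        if any(not 0 <= t < n_subsets for t in test_subsets):
            raise ValueError("test subset index out of range")
    return SubsetPartition(pairs=[(str(a), str(b)) for a, b in pairs],
                           test_subsets=test_subsets)


def train_rbf_svm(X, y, C: float = 1.2, gamma: float = 5.0) -> SVC:
    """Fit the RBF-kernel SVM with the fixed study hyperparameters."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(np.asarray(X), y)
    return clf


def _run_fold(fold_id, X_tr, y_tr, X_va, y_va, k_fraction, C, gamma,
              positive_label) -> FoldResult:
    if np.unique(y_tr).size < 2:
        raise ValueError(f"fold {fold_id}: sub-training set misses a class")
    scores = f_score(X_tr, y_tr, positive_label=positive_label)
    sel = select_top_fraction(scores, k_fraction)
    clf = train_rbf_svm(X_tr[:, sel], y_tr, C=C, gamma=gamma)
    acc = float((clf.predict(X_va[:, sel]) == y_va).mean()) if len(y_va) else float("nan")
    return FoldResult(fold_id=fold_id, selected_features=sel,
                      fscores=scores[sel], validation_accuracy=acc)


def loo_stability_run(X, y, sample_subset_ids, training_subsets,
                      k_fraction: float = 0.01, C: float = 1.2,
                      gamma: float = 5.0, positive_label=1) -> list[FoldResult]:
    """Leave-one-subset-out loop over the training subsets.

    For each held-out subset, F-scores and the top-fraction selection are
    computed on the remaining subsets' samples only, the SVM is trained on
    them, and the held-out subset's segments supply the validation
    accuracy.  Returns one FoldResult per training subset.
    """
    training_subsets = list(training_subsets)
    if len(training_subsets) < 3:
        raise ValueError("need at least 3 training subsets for the loop")
    X = np.asarray(X)
    y = np.asarray(y)
    sample_subset_ids = np.asarray(sample_subset_ids)
    results = []
    for fold_id, held in enumerate(training_subsets):
        va = sample_subset_ids == held
        tr = np.isin(sample_subset_ids, [s for s in training_subsets if s != held])
        results.append(_run_fold(fold_id, X[tr], y[tr], X[va], y[va],
                                 k_fraction, C, gamma, positive_label))
    return results


def random_split_run(X, y, train_frac: float = 0.9, n_reps: int = 14,
                     k_fraction: float = 0.01, seed=None, C: float = 1.2,
                     gamma: float = 5.0, positive_label=1) -> list[FoldResult]:
    """Repeated random sample-level splits of the pooled training samples.

    Each repetition draws a seeded uniform ``train_frac`` split over all
    samples, ignoring subject identity, then selects features and trains
    as in the leave-one-subset-out loop.  A split that leaves a class
    empty is redrawn (and logged).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_reps):
        for attempt in range(100):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if np.unique(y[tr]).size == 2 and len(va) > 0:
                break
            logger.warning("split %d attempt %d left a class empty; redrawn",
                           rep, attempt)
        else:
            raise RuntimeError("could not draw a class-complete split")
        results.append(_run_fold(rep, X[tr], y[tr], X[va], y[va],
                                 k_fraction, C, gamma, positive_label))
    return results


def overlap_select(fold_results: list[FoldResult],
                   threshold: int = 12) -> StabilityResult:
    """Overlap-rate stability selection over fold-wise feature selections.

    A feature is *stable* when it appears in at least ``threshold`` of
    the folds.  Its mean F-score averages the fold F-scores over exactly
    the folds where it was selected (unselected folds never ranked it in
    a comparable context).  Stable features are ordered by descending
    mean F-score.
    """
    if not fold_results:
        raise ValueError("need at least one fold")
    n_folds = len(fold_results)
    if threshold > n_folds:
        raise ValueError(f"threshold {threshold} exceeds the {n_folds} folds")
    counts: Counter = Counter()
    score_sums: Counter = Counter()
    for fr in fold_results:
        for feat, sc in zip(fr.selected_features, fr.fscores):
            counts[int(feat)] += 1
            score_sums[int(feat)] += float(sc)
    stable = [f for f, c in counts.items() if c >= threshold]
    means = np.array([score_sums[f] / counts[f] for f in stable])
    order = np.lexsort((stable, -means)) if stable else np.array([], int)
    return StabilityResult(
        occurrence_counts=counts,
        stable_features=np.asarray(stable, dtype=int)[order],
        mean_fscores=means[order] if stable else np.array([]),
        threshold=threshold, n_folds=n_folds,
    )


def flag_strong_edges(stability: StabilityResult,
                      frac: float = 0.75) -> np.ndarray:
    """Flag stable features whose mean F-score beats ``frac`` of the maximum."""
    if stability.stable_features.size == 0:
        raise ValueError("stable set is empty; nothing to flag")
    flags = stability.mean_fscores > frac * stability.mean_fscores.max()
    stability.strong_flags = flags
    return flags


def finalize_and_evaluate(X_train, y_train, X_test, y_test, stable_features,
                          C: float = 1.2, gamma: float = 5.0,
                          positive_label=1, test_subject_ids=None) -> EvalReport:
    """Retrain on the full training pool over the stable set; score the test set."""
    stable_features = np.asarray(stable_features, dtype=int)
    if stable_features.size == 0:
        raise ValueError(
            "empty stable set: no feature passed the overlap threshold"
        )
    clf = train_rbf_svm(np.asarray(X_train)[:, stable_features], y_train,
                        C=C, gamma=gamma)
    y_pred = clf.predict(np.asarray(X_test)[:, stable_features])
    return EvalReport.from_predictions(y_test, y_pred,
                                       positive_label=positive_label,
                                       subject_ids=test_subject_ids)


class StabilitySelectedSVC(ClassifierMixin, BaseEstimator):
    """RBF SVM over overlap-stable F-score-selected connectivity features.

    scikit-learn classifier wrapping the full training procedure: a
    14-fold selection loop (leave-one-subset-out or repeated random
    splits), overlap-rate stability selection, strong-edge flagging, and
    a final SVM retrained on the stable feature set.

    Parameters
    ----------
    scheme : {"subsets", "random"}
        Fold scheme.  ``"subsets"`` requires ``subset_ids`` at fit time
        (one subset label per sample) and runs leave-one-subset-out;
        ``"random"`` mixes all samples and repeats seeded
        ``train_frac`` splits ``n_reps`` times.
    select_fraction : fraction of features kept per fold (default 0.01).
    overlap_threshold : minimum folds a feature must appear in
        (default 12, against the default 14 folds).
    C, gamma : SVM hyperparameters (defaults 1.2 and 5).
    n_reps, train_frac : random-scheme repetitions and split fraction.
    strong_fraction : strong-edge threshold as a fraction of the top
        mean F-score (default 0.75).
    positive_label : label of the positive (CPS) class, default 1.
    random_state : seed for the random scheme's splits.

    Attributes
    ----------
    fold_results_ : list of FoldResult.
    stability_ : StabilityResult with strong-edge flags.
    selected_features_ : stable feature indices (descending mean F-score).
    svm_ : final fitted ``sklearn.svm.SVC``.
    """

    def __init__(self, scheme: str = "subsets", select_fraction: float = 0.01,
                 overlap_threshold: int = 12, C: float = 1.2,
                 gamma: float = 5.0, n_reps: int = 14, train_frac: float = 0.9,
                 strong_fraction: float = 0.75, positive_label=1,
                 random_state=None):
        self.scheme = scheme
        self.select_fraction = select_fraction
        self.overlap_threshold = overlap_threshold
        self.C = C
        self.gamma = gamma
        self.n_reps = n_reps
        self.train_frac = train_frac
        self.strong_fraction = strong_fraction
        self.positive_label = positive_label
        self.random_state = random_state

    def fit(self, X, y, subset_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.scheme == "subsets":
            if subset_ids is None:
                raise ValueError("scheme='subsets' requires subset_ids")
            subsets = sorted(set(np.asarray(subset_ids).tolist()))
            self.fold_results_ = loo_stability_run(
                X, y, subset_ids, subsets, self.select_fraction,
                self.C, self.gamma, self.positive_label)
        elif self.scheme == "random":
            self.fold_results_ = random_split_run(
                X, y, self.train_frac, self.n_reps, self.select_fraction,
                self.random_state, self.C, self.gamma, self.positive_label)
        else:
            raise ValueError("scheme must be 'subsets' or 'random'")
        self.stability_ = overlap_select(self.fold_results_,
                                         self.overlap_threshold)
        if self.stability_.stable_features.size:
            flag_strong_edges(self.stability_, self.strong_fraction)
        self.selected_features_ = self.stability_.stable_features
        if self.selected_features_.size == 0:
            raise ValueError(
                "empty stable set: no feature reached the overlap threshold "
                f"({self.overlap_threshold}/{self.stability_.n_folds})"
            )
        self.svm_ = train_rbf_svm(X[:, self.selected_features_], y,
                                  C=self.C, gamma=self.gamma)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.svm_.predict(np.asarray(X)[:, self.selected_features_])

    def decision_function(self, X):
        check_is_fitted(self)
        return self.svm_.decision_function(
            np.asarray(X)[:, self.selected_features_])

    def evaluate(self, X, y, subject_ids=None) -> EvalReport:
        """Confusion-based test report with CPS as the positive class."""
        return EvalReport.from_predictions(
            y, self.predict(X), positive_label=self.positive_label,
            subject_ids=subject_ids)
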