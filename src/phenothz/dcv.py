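"""Nested (double) cross-validation for PLS-DA latent-variable selection.

The outer loop splits the samples into five stratified folds and withholds
one fold as the test set.  Within the remaining tuning set, the inner loop
reuses the other four folds: each in turn is held out, models with 1-20
latent variables are trained on the rest, and the LV count that maximizes
the pooled inner overall accuracy (OA) is selected.  The model is refit on
the full tuning set at that LV count and evaluated on the withheld outer
fold.  The whole procedure is repeated with fresh random splits (30 by
default) to estimate the spread of OA; the final reporting model uses the
modal LV count across all selections and is calibrated on all samples.

Centering statistics live inside each PLS fit, so a test-set spectrum never
influences the model that predicts it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import SpectralDataset, RangeSpec, RANGES
from .plsda import PLSModel, fit_plsda, encode_classes, fit_pls

logger = logging.getLogger(__name__)

_REDRAW_STRIDE = 7919  # seed offset between fold re-draws within a repetition


def overall_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Fraction of correctly classified samples."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("label sequences must be non-empty and equal length")
    return sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)


def make_folds(labels: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified random fold assignment (fold id per sample).

    Within each class the sample order is shuffled, classes are concatenated,
    and positions are dealt round-robin, so per-fold class counts differ by
    at most one and fold sizes are as balanced as possible.
    """
    labels = list(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n_samples={n}]")
    rng = np.random.default_rng(seed)
    vocab = sorted(set(labels))
    folds = np.empty(n, dtype=int)
    pos = 0
    for cls in vocab:
        idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        if idx.size < 2:
            logger.warning("class %r has fewer than 2 samples", cls)
        rng.shuffle(idx)
        for i in idx:
            folds[i] = pos % k
            pos += 1
    return folds


def _folds_cover_all_classes(folds: np.ndarray, labels: Sequence, k: int) -> bool:
    classes = set(labels)
    labels = np.asarray(labels, dtype=object)
    return all(set(labels[folds == f]) == classes for f in range(k))


def inner_select_lv(X: np.ndarray, labels: Sequence, inner_folds: np.ndarray,
                    lv_range: Sequence[int] = range(1, 21)) -> int:
    """LV count maximizing pooled inner-CV overall accuracy (ties: smallest).

    Candidates are capped at what the smallest inner training set can
    support, min(n_train - 1, n_variables); an out-of-reach request is
    truncated with a log entry rather than an error.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    fold_ids = np.unique(inner_folds)
    n_train_min = min(int(np.sum(inner_folds != f)) for f in fold_ids)
    cap = min(n_train_min - 1, X.shape[1])
    candidates = [a for a in lv_range if a <= cap]
    if not candidates:
        candidates = [cap]
    if len(candidates) < len(list(lv_range)):
        logger.info("LV candidates truncated to 1..%d (feasibility cap)", cap)

    preds = {a: [None] * len(labels) for a in candidates}
    for f in fold_ids:
        test = np.flatnonzero(inner_folds == f)
        train = np.flatnonzero(inner_folds != f)
        model = fit_plsda(X[train], [labels[i] for i in train], max(candidates))
        for a in candidates:
            for i, lab in zip(test, model.classify(X[test], n_lv=a)):
                preds[a][i] = lab
    oa = {a: overall_accuracy(labels, preds[a]) for a in candidates}
    best = max(oa.values())
    return min(a for a in candidates if oa[a] == best)


@dataclass
class DCVResult:
    """Outcome of the repeated double cross-validation."""

    oa_per_rep: np.ndarray          # (reps,) pooled outer-test OA
    chosen_lv: np.ndarray           # (reps, k) inner selection per outer fold
    correct: np.ndarray             # (reps, n_samples) bool
    sample_ids: list
    seeds: list[int]
    lv_range: tuple[int, int]

    @property
    def mean_oa(self) -> float:
        return float(np.mean(self.oa_per_rep))

    @property
    def min_oa(self) -> float:
        return float(np.min(self.oa_per_rep))

    @property
    def max_oa(self) -> float:
        return float(np.max(self.oa_per_rep))

    @property
    def modal_lv(self) -> int:
        """Most frequent selected LV count across (rep, fold); ties: smallest."""
        values, counts = np.unique(self.chosen_lv.ravel(), return_counts=True)
        return int(values[np.argmax(counts)])  # np.unique sorts ascending

    def per_sample_rates(self) -> dict:
        """Fraction of repetitions in which each sample was classified correctly."""
        rates = self.correct.mean(axis=0)
        return {sid: float(r) for sid, r in zip(self.sample_ids, rates)}

    def summary(self) -> dict:
        return {
            "mean_oa": self.mean_oa,
            "min_oa": self.min_oa,
            "max_oa": self.max_oa,
            "modal_lv": self.modal_lv,
            "n_reps": int(self.oa_per_rep.size),
            "seeds": self.seeds,
        }


def double_cv(X: np.ndarray, labels: Sequence, k: int = 5, reps: int = 30,
              lv_range: Sequence[int] = range(1, 21), base_seed: int = 0,
              sample_ids: Sequence | None = None) -> DCVResult:
    """Repeated nested cross-validation; fully reproducible from ``base_seed``.

    Repetition r draws its folds from seed ``base_seed + r``.  A draw that
    leaves any fold without one of the classes is re-drawn (up to 100
    attempts) so every tuning set sees both classes.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    if sample_ids is None:
        sample_ids = list(range(n))
    lv_list = list(lv_range)

    oas = np.zeros(reps)
    chosen = np.zeros((reps, k), dtype=int)
    correct = np.zeros((reps, n), dtype=bool)
    seeds = []
    for r in range(reps):
        seed_r = base_seed + r
        folds = make_folds(labels, k=k, seed=seed_r)
        attempt = 0
        while not _folds_cover_all_classes(folds, labels, k):
            attempt += 1
            if attempt > 100:
                raise RuntimeError("could not draw folds covering all classes")
            logger.info("rep %d: re-drawing folds (attempt %d)", r, attempt)
            folds = make_folds(labels, k=k, seed=seed_r + attempt * _REDRAW_STRIDE)
        seeds.append(seed_r + attempt * _REDRAW_STRIDE)

        preds: list = [None] * n
        for f in range(k):
            test = np.flatnonzero(folds == f)
            tune = np.flatnonzero(folds != f)
            lv = inner_select_lv(X[tune], [labels[i] for i in tune],
                                 folds[tune], lv_list)
            chosen[r, f] = lv
            lv_fit = min(lv, tune.size - 1, X.shape[1])
            model = fit_plsda(X[tune], [labels[i] for i in tune], lv_fit)
            for i, lab in zip(test, model.classify(X[test])):
                preds[i] = lab
        oas[r] = overall_accuracy(labels, preds)
        correct[r] = np.array([p == t for p, t in zip(preds, labels)])

    return DCVResult(oa_per_rep=oas, chosen_lv=chosen, correct=correct,
                     sample_ids=list(sample_ids), seeds=seeds,
                     lv_range=(min(lv_list), max(lv_list)))


def final_model(X: np.ndarray, labels: Sequence, dcv: DCVResult) -> PLSModel:
    """PLS-DA calibrated on all samples at the modal LV count."""
    lv = min(dcv.modal_lv, len(list(labels)) - 1, np.asarray(X).shape[1])
    return fit_plsda(X, labels, lv)


def per_compound_rates(dcv: DCVResult) -> dict:
    """Per-sample correct-classification rate across repetitions."""
    return dcv.per_sample_rates()


# ---------------------------------------------------------------------------
# Case studies: which compounds enter and how they are labeled.

@dataclass(frozen=True)
class CaseStudySpec:
    name: str
    description: str
    sample_filter: Callable[[object], bool]
    labeler: Callable[[object], str]


CASE_STUDIES = {
    # families: flavonoids vs phenolic acids, all compounds
    "CS1": CaseStudySpec(
        "CS1", "flavonoids vs phenolic acids",
        sample_filter=lambda m: True,
        labeler=lambda m: m.family),
    # among flavonoids: flavonols vs the rest
    "CS2": CaseStudySpec(
        "CS2", "flavonols vs other flavonoids",
        sample_filter=lambda m: m.family == "flavonoid",
        labeler=lambda m: ("flavonol" if m.compound_class == "flavonol"
                           else "other_flavonoid")),
    # among phenolic acids: hydroxycinnamic vs hydroxybenzoic
    "CS3": CaseStudySpec(
        "CS3", "hydroxycinnamic vs hydroxybenzoic acids",
        sample_filter=lambda m: m.family == "phenolic_acid",
        labeler=lambda m: m.compound_class),
}


def case_study_arrays(ds: SpectralDataset,
                      case: str | CaseStudySpec) -> tuple[np.ndarray, list, list]:
    """(X, labels, compound ids) for one case study's sample subset."""
    spec = CASE_STUDIES[case] if isinstance(case, str) else case
    rows = [s for s in ds if spec.sample_filter(s.meta)]
    if not rows:
        raise ValueError(f"case study {spec.name}: no samples selected")
    X = np.vstack([s.absorbance for s in rows])
    labels = [spec.labeler(s.meta) for s in rows]
    ids = [s.meta.compound for s in rows]
    return X, labels, ids
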