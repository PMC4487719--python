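"""Nested 5-fold test evaluation, metrics, Friedman comparison, Fisher projection.

The 5-fold *test* procedure differs from plain cross-validation: the data are
split into five class-stratified parts; for each choice of test part the
remaining four undergo a 4-fold validation rotation (train on three,
validate on one), the fold-trained model with the lowest validation error is
selected, and that model is applied unchanged to the held-out test part.
The subject's score is the mean over the five test rotations, so no test
epoch ever influences training or model selection within its rotation.

Methods are compared across subjects with the nonparametric Friedman test
(methods ranked within each subject), and feature spaces are visualised with
a 3-class Fisher discriminant projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import detect
from .epochs import Epoch, extract_epochs, resolve_onsets
from .features import feature_matrix
from .preprocess import make_surrogate

logger = logging.getLogger(__name__)

METHODS = ("lda_temporal", "lda_spectral", "template")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class FoldReport:
    tp: int
    tn: int
    fp: int
    fn: int
    fold_id: int = 0
    chosen_training_parts: tuple[int, ...] = ()

    @property
    def error(self) -> float:
        return (self.fp + self.fn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def confusion_metrics(predictions, labels, fold_id: int = 0,
                      chosen_training_parts: tuple[int, ...] = ()) -> FoldReport:
    """Confusion counts and derived rates; movement (1) is the positive class."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if len(pred) == 0 or len(pred) != len(y):
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return FoldReport(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        fold_id=fold_id, chosen_training_parts=chosen_training_parts)


@dataclass
class SubjectResult:
    folds: list[FoldReport]
    method: str

    @property
    def mean_error(self) -> float:
        return float(np.mean([f.error for f in self.folds]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([f.sensitivity for f in self.folds]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([f.specificity for f in self.folds]))


# ---------------------------------------------------------------------------
# detectors as fit/predict pairs over abstract items

class LdaDetector:
    """LDA over precomputed feature rows."""

    def fit(self, items, labels):
        return detect.train_lda(np.asarray(items), np.asarray(labels))

    def predict(self, model, items):
        return detect.lda_classify(model, np.asarray(items))


class TemplateDetector:
    """Ensemble-average template + fitted correlation threshold over raw
    temporal-path epoch sample arrays."""

    def fit(self, items, labels):
        labels = np.asarray(labels)
        movement = [s for s, l in zip(items, labels) if l == 1]
        template = detect.build_template(movement)
        r = [detect.template_correlation(template, s) for s in items]
        thr = detect.fit_threshold(r, labels)
        return detect.TemplateModel(template=template, threshold=thr)

    def predict(self, model, items):
        return detect.template_classify(model, items)


def _stratified_parts(labels: np.ndarray, n_parts: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded class-stratified split into ``n_parts`` index arrays."""
    parts: list[list[int]] = [[] for _ in range(n_parts)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for p, chunk in enumerate(np.array_split(idx, n_parts)):
            parts[p].extend(chunk.tolist())
    return [np.sort(np.array(p, dtype=int)) for p in parts]


def five_fold_test(items, labels, detector, seed: int = 0, method: str = "",
                   n_parts: int = 5, shuffle_rotation: bool = False) -> SubjectResult:
    """The nested N-fold test procedure (N = 5).

    ``items`` is indexable per epoch (feature matrix rows, or a list of
    epoch sample arrays for the template detector). Within each test
    rotation the four candidate models come from the 4-fold validation
    rotation over the remaining parts; the candidate with the lowest
    validation error is applied unchanged to the test part. Validation ties
    break toward the lowest validation-part index. ``shuffle_rotation``
    re-draws the rotation order randomly instead of cycling.
    """
    labels = np.asarray(labels)
    items = np.asarray(items) if not isinstance(items, list) else items
    rng = np.random.default_rng(seed)
    parts = _stratified_parts(labels, n_parts, rng)
    for p in parts:
        if len(np.unique(labels[p])) < 2:
            raise ValueError("too few epochs per class to stratify parts")

    def take(idx):
        if isinstance(items, list):
            return [items[i] for i in idx]
        return items[idx]

    rotation = list(range(n_parts))
    if shuffle_rotation:
        rng.shuffle(rotation)
    folds: list[FoldReport] = []
    for fold_id, test_part in enumerate(rotation):
        rest = [p for p in range(n_parts) if p != test_part]
        best = None
        for val_part in rest:
            train_parts = [p for p in rest if p != val_part]
            train_idx = np.concatenate([parts[p] for p in train_parts])
            model = detector.fit(take(train_idx), labels[train_idx])
            val_idx = parts[val_part]
            val_err = confusion_metrics(
                detector.predict(model, take(val_idx)), labels[val_idx]).error
            if best is None or val_err < best[0]:
                best = (val_err, model, tuple(train_parts))
        _, model, chosen = best
        test_idx = parts[test_part]
        folds.append(confusion_metrics(
            detector.predict(model, take(test_idx)), labels[test_idx],
            fold_id=fold_id, chosen_training_parts=chosen))
    return SubjectResult(folds=folds, method=method)


# ---------------------------------------------------------------------------
# cross-subject statistics

def friedman_compare(scores: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across related samples.

    ``scores`` is (n_subjects, k_methods). Methods are ranked within each
    subject (mean ranks on ties); the chi-square statistic with the standard
    tie correction is referred to a chi-square distribution with k-1 degrees
    of freedom. Fully tied data give statistic 0, p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 methods")
    if not np.all(np.isfinite(scores)):
        raise ValueError("missing cells are not allowed")
    n, k = scores.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    rank_sums = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * np.sum(
        (rank_sums - n * (k + 1) / 2.0) ** 2)
    # tie correction
    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (n * k * (k * k - 1))
    if correction <= 0:
        return 0.0, 1.0
    statistic /= correction
    return float(statistic), float(stats.chi2.sf(statistic, k - 1))


def fisher_projection(X: np.ndarray, labels, out_dim: int = 2) -> np.ndarray:
    """Multi-class Fisher discriminant projection, rescaled to [-1, 1].

    Solves the generalized eigenproblem of between-class vs pooled
    within-class scatter and projects onto the leading ``out_dim``
    discriminant directions; each output dimension is then affinely mapped
    to span exactly [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if out_dim > len(classes) - 1:
        raise ValueError("out_dim may not exceed n_classes - 1")
    d = X.shape[1]
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[labels == c]
        muc = Xc.mean(axis=0)
        Sw += (Xc - muc).T @ (Xc - muc)
        Sb += len(Xc) * np.outer(muc - mu, muc - mu)
    if np.linalg.cond(Sw) > detect.COND_LIMIT:
        logger.warning("within-class scatter ill-conditioned; regularizing")
        Sw = Sw + detect.LDA_RIDGE_EPS * np.trace(Sw) / d * np.eye(d)
    from scipy.linalg import eigh
    vals, vecs = eigh(Sb, Sw)
    order = np.argsort(vals)[::-1][:out_dim]
    W = vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    Z = X @ W
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return 2.0 * (Z - lo) / span - 1.0


# ---------------------------------------------------------------------------
# the full study

@dataclass
class StudyReport:
    """Per-subject and aggregate results plus the Friedman comparisons."""

    per_subject: list[dict]                  # one record per subject x task x method
    aggregate: dict                          # group -> method -> metric -> (mean, se)
    friedman: dict                           # group -> comparison -> {statistic, p}
    config: dict = field(default_factory=dict)


def evaluate_subject(recording, seed: int = 0, temporal_mode: str | None = None,
                     regression_until: str = "epoch_end",
                     template_onset_jitter_sd: float = 0.0,
                     methods=METHODS) -> list[dict]:
    """Run the three detection methods on one subject, per movement task.

    Returns one record per (task, method) with the per-fold metrics. The
    temporal-feature mode follows the subject group unless overridden
    (executed features for real/attempted movements, imagery features for
    imaginary ones). ``template_onset_jitter_sd`` optionally degrades the
    template method by cutting its epochs with Gaussian timing jitter,
    emulating the onset uncertainty template matching faces in practice.
    """
    if temporal_mode is None:
        temporal_mode = "imagery" if recording.group == "imaginary" else "executed"
    surrogate = make_surrogate(recording.eeg, recording.channels, recording.fs_eeg)
    resolved = resolve_onsets(recording)
    onsets = np.asarray(resolved.onsets)
    tasks = [recording.task_labels[i] for i in resolved.trial_indices]

    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    records = []
    for t_i, task in enumerate(sorted(set(tasks))):
        sel = np.array([i for i, t in enumerate(tasks) if t == task])
        task_onsets = onsets[sel]
        task_names = [task] * len(sel)
        ep_t = extract_epochs(surrogate, task_onsets, task_names, "temporal",
                              recording.subject_id)
        ep_s = extract_epochs(surrogate, task_onsets, task_names, "spectral",
                              recording.subject_id)
        fold_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(t_i,)).generate_state(1)[0] % (2 ** 31))
        for method in methods:
            if method == "lda_temporal":
                X, y = feature_matrix(ep_t, "temporal", temporal_mode,
                                      regression_until)
                result = five_fold_test(X, y, LdaDetector(), fold_seed, method)
            elif method == "lda_spectral":
                X, y = feature_matrix(ep_s, "spectral")
                result = five_fold_test(X, y, LdaDetector(), fold_seed, method)
            elif method == "template":
                if template_onset_jitter_sd > 0:
                    jit = task_onsets + jitter_rng.normal(
                        0.0, template_onset_jitter_sd, len(task_onsets))
                    ep_j = extract_epochs(surrogate, jit, task_names,
                                          "temporal", recording.subject_id)
                else:
                    ep_j = ep_t
                samples = [e.samples for e in ep_j]
                y = np.array([1 if e.label == "movement" else 0 for e in ep_j])
                result = five_fold_test(samples, y, TemplateDetector(),
                                        fold_seed, method)
            else:
                raise ValueError(f"unknown method {method!r}")
            records.append({
                "subject": recording.subject_id, "group": recording.group,
                "task": task, "method": method,
                "error": result.mean_error,
                "sensitivity": result.mean_sensitivity,
                "specificity": result.mean_specificity,
                "folds": [{"tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn,
                           "error": f.error, "fold_id": f.fold_id,
                           "chosen_training_parts": list(f.chosen_training_parts)}
                          for f in result.folds],
            })
    return records


def _subject_method_scores(records, group, metric="error"):
    """(subjects, methods) matrix of task-averaged scores for one group."""
    subjects = sorted({r["subject"] for r in records if r["group"] == group})
    mat = np.full((len(subjects), len(METHODS)), np.nan)
    for i, s in enumerate(subjects):
        for j, m in enumerate(METHODS):
            vals = [r[metric] for r in records
                    if r["subject"] == s and r["group"] == group and r["method"] == m]
            if vals:
                mat[i, j] = float(np.mean(vals))
    return subjects, mat


def run_study(recordings, seed: int = 0, template_onset_jitter_sd: float = 0.0,
              regression_until: str = "epoch_end") -> StudyReport:
    """Evaluate all three methods on every subject and compare them.

    Per subject and movement task the nested 5-fold test is run for
    lda_temporal, lda_spectral and template matching; scores are averaged
    over the two tasks per subject. Per subject group, methods are compared
    with the Friedman test: first temporal vs spectral features, then the
    better of the two against template matching. Aggregates report
    mean ± standard error (sd/sqrt(n)) across subjects.
    """
    records: list[dict] = []
    for i, rec in enumerate(recordings):
        sub_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(1000 + i,)).generate_state(1)[0] % (2 ** 31))
        records.extend(evaluate_subject(
            rec, seed=sub_seed, regression_until=regression_until,
            template_onset_jitter_sd=template_onset_jitter_sd))

    aggregate: dict = {}
    friedman: dict = {}
    for group in sorted({r["group"] for r in records}):
        subjects, err = _subject_method_scores(records, group, "error")
        aggregate[group] = {}
        for metric in ("error", "sensitivity", "specificity"):
            _, mat = _subject_method_scores(records, group, metric)
            aggregate[group][metric] = {
                m: {"mean": float(np.mean(mat[:, j])),
                    "se": float(np.std(mat[:, j], ddof=1) / np.sqrt(len(subjects)))
                    if len(subjects) > 1 else 0.0}
                for j, m in enumerate(METHODS)}
        friedman[group] = {}
        if len(subjects) >= 2:
            i_t, i_s, i_m = (METHODS.index(m) for m in
                             ("lda_temporal", "lda_spectral", "template"))
            stat, p = friedman_compare(err[:, [i_t, i_s]])
            friedman[group]["temporal_vs_spectral"] = {"statistic": stat, "p": p}
            best = i_s if err[:, i_s].mean() <= err[:, i_t].mean() else i_t
            stat, p = friedman_compare(err[:, [best, i_m]])
            friedman[group]["best_vs_template"] = {
                "statistic": stat, "p": p, "best": METHODS[best]}
    return StudyReport(per_subject=records, aggregate=aggregate,
                       friedman=friedman,
                       config={"seed": seed,
                               "template_onset_jitter_sd": template_onset_jitter_sd,
                               "regression_until": regression_until})
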