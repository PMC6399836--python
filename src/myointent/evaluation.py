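"""Trial-wise leave-one-out cross-validation and reporting.

For each participant the three retained trials per direction define three
folds: fold j trains an LDA on trials {0,1,2} \\ {j} of every class and tests
on trial j of every class, so every retained trial is tested exactly once
and used for training exactly twice.  Window-level decisions are scored as
per-class accuracies per fold, averaged across folds (the class-balanced
convention); pooled confusion counts across folds are kept for reporting.

Also provides the cohort-level summary table across the four feature sets,
the normalized AB/AD-vs-ER/IR torque scatter used to visualize strategy
overlap, and Spearman rank correlations of accuracy against clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import CLASS_ORDER, TaskClass
from .classifier import fit_lda, predict
from .features import FeatureMatrix, FeatureSet, WindowSpec, extract_features
from .preprocessing import (ActiveSegment, JointTorqueSeries,
                            RigidBodyGeometry, compute_joint_torques,
                            max_voluntary_torque, notch_filter, segment_active,
                            select_trials)
from .synthetic import TrialRecording

FUNCTIONAL_ACCURACY = 90.0  # percent; conventional usability cutoff


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K window-decision counts (rows = actual, columns = predicted)."""

    classes: tuple = CLASS_ORDER
    counts: np.ndarray = None
    undefined_classes: list = field(default_factory=list)

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return pct

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.row_percent)

    @property
    def overall_accuracy(self) -> float:
        acc = self.per_class_accuracy
        return float(np.mean(acc[np.isfinite(acc)]))

    def to_frame(self, percent: bool = True, decimals: int | None = None
                 ) -> pd.DataFrame:
        codes = [c.code for c in self.classes]
        data = self.row_percent if percent else self.counts
        if decimals is not None:
            data = np.round(data, decimals)
        return pd.DataFrame(data, index=codes, columns=codes)


def confusion_matrix(actual: Sequence, predicted: Sequence,
                     class_order: Sequence = CLASS_ORDER) -> ConfusionMatrix:
    """Tally window decisions.  Classes absent from ``actual`` are listed in
    ``undefined_classes`` and their accuracy rows are NaN, never silently 0."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    K = len(class_order)
    counts = np.zeros((K, K), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label {a!r} or {p!r} not in class order")
        counts[index[a], index[p]] += 1
    undefined = [c for i, c in enumerate(class_order) if counts[i].sum() == 0]
    return ConfusionMatrix(classes=tuple(class_order), counts=counts,
                           undefined_classes=undefined)


# ---------------------------------------------------------------------------
# participant preparation (preprocessing pipeline)
# ---------------------------------------------------------------------------

@dataclass
class PreparedTrial:
    trial: TrialRecording
    emg_filtered: np.ndarray
    torques: JointTorqueSeries
    segment: ActiveSegment
    mvt: float  # this trial's own MVT in the tested direction


@dataclass
class PreparedParticipant:
    participant_id: str
    by_class: dict            # TaskClass -> [PreparedTrial x 3], acquisition order
    direction_mvt: dict       # TaskClass -> MVT (max over retained trials)
    selection_flags: dict     # TaskClass -> stop-criterion flag
    clinical_scores: Optional[dict]


def prepare_participant(trials: Sequence[TrialRecording],
                        geometry: RigidBodyGeometry,
                        threshold: float = 0.20,
                        notch_fundamental: float = 60.0) -> PreparedParticipant:
    """Run the full preprocessing chain for one participant.

    Per direction: compute joint torques and the 200 ms moving-average MVT
    for every trial, retain the three strongest trials, notch-filter their
    EMG, and segment each retained trial where its primary torque exceeds
    ``threshold`` x the direction-level MVT (max over the retained trials).
    """
    pids = {t.participant_id for t in trials}
    if len(pids) != 1:
        raise ValueError("trials must belong to a single participant")
    by_class: dict = {}
    direction_mvt: dict = {}
    flags: dict = {}
    scores = trials[0].clinical_scores
    for task in CLASS_ORDER:
        cls_trials = sorted([t for t in trials if t.task is task],
                            key=lambda t: t.acquisition_index)
        if len(cls_trials) < 3:
            raise ValueError(
                f"participant {trials[0].participant_id} has "
                f"{len(cls_trials)} trials for {task.code}; need >= 3")
        torque_series = [compute_joint_torques(t.loadcell, geometry, t.fs)
                         for t in cls_trials]
        mvts = [max_voluntary_torque(ts.primary(task), t.fs)[0]
                for ts, t in zip(torque_series, cls_trials)]
        keep, flag = select_trials(mvts)
        flags[task] = flag
        dir_mvt = max(mvts[i] for i in keep)
        if dir_mvt <= 0:
            raise ValueError(f"non-positive MVT for {task.code}")
        direction_mvt[task] = dir_mvt
        prepared = []
        for i in keep:
            t = cls_trials[i]
            emg_f = notch_filter(t.emg.T, t.fs,
                                 fundamental=notch_fundamental).T
            seg = segment_active(torque_series[i], task, dir_mvt, threshold)
            prepared.append(PreparedTrial(trial=t, emg_filtered=emg_f,
                                          torques=torque_series[i],
                                          segment=seg, mvt=mvts[i]))
        by_class[task] = prepared
    return PreparedParticipant(
        participant_id=trials[0].participant_id, by_class=by_class,
        direction_mvt=direction_mvt, selection_flags=flags,
        clinical_scores=scores)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    feature_set: FeatureSet
    fold_class_accuracy: np.ndarray   # (3, 8), percent, NaN if no test windows
    confusion: ConfusionMatrix        # pooled counts across folds
    fold_test_trials: list            # per fold, trial ids tested

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Per-class window accuracy averaged over the three folds (percent)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.fold_class_accuracy, axis=0)

    @property
    def overall_accuracy(self) -> float:
        acc = self.per_class_accuracy
        return float(np.mean(acc[np.isfinite(acc)]))


def _trial_features(prep: PreparedTrial, spec: WindowSpec,
                    feature_set: FeatureSet, deadband: float) -> FeatureMatrix:
    return extract_features(prep.trial, prep.segment, prep.torques, spec,
                            feature_set, emg=prep.emg_filtered,
                            deadband=deadband)


def loocv_trialwise(participant: PreparedParticipant,
                    feature_set: FeatureSet,
                    spec: WindowSpec = WindowSpec(),
                    deadband: float = 0.0,
                    ridge: float | None = None) -> LoocvResult:
    """Three-fold trial-wise leave-one-out cross-validation.

    Requires exactly three retained trials per class.  Every feature-set
    variant sees identical window partitions because segmentation and
    windowing are fixed per trial before extraction.
    """
    for task, preps in participant.by_class.items():
        if len(preps) != 3:
            raise ValueError(f"{task.code}: expected 3 retained trials")
    feats = {task: [_trial_features(p, spec, feature_set, deadband)
                    for p in preps]
             for task, preps in participant.by_class.items()}

    K = len(CLASS_ORDER)
    fold_acc = np.full((3, K), np.nan)
    all_actual: list = []
    all_pred: list = []
    fold_tests = []
    for j in range(3):
        train = FeatureMatrix.concat(
            [feats[task][i] for task in CLASS_ORDER for i in range(3) if i != j])
        model = fit_lda(train, ridge=ridge)
        fold_tests.append([feats[task][j].trial_ids[0]
                           for task in CLASS_ORDER if len(feats[task][j])])
        for k, task in enumerate(CLASS_ORDER):
            test = feats[task][j]
            if len(test) == 0:
                continue
            pred = predict(model, test.values)
            correct = sum(p is task for p in pred)
            fold_acc[j, k] = 100.0 * correct / len(test)
            all_actual.extend(test.labels)
            all_pred.extend(pred)
    return LoocvResult(feature_set=feature_set, fold_class_accuracy=fold_acc,
                       confusion=confusion_matrix(all_actual, all_pred),
                       fold_test_trials=fold_tests)


@dataclass
class ParticipantResult:
    participant_id: str
    results: dict                 # FeatureSet -> LoocvResult
    clinical_scores: Optional[dict]

    def accuracy(self, feature_set: FeatureSet) -> float:
        return self.results[feature_set].overall_accuracy


def evaluate_participant(trials: Sequence[TrialRecording],
                         geometry: RigidBodyGeometry,
                         feature_sets: Sequence[FeatureSet] = tuple(FeatureSet),
                         spec: WindowSpec = WindowSpec(),
                         deadband: float = 0.0,
                         ridge: float | None = None,
                         threshold: float = 0.20) -> ParticipantResult:
    """End-to-end evaluation of one participant across feature sets."""
    prep = prepare_participant(trials, geometry, threshold=threshold)
    results = {fs: loocv_trialwise(prep, fs, spec, deadband, ridge)
               for fs in feature_sets}
    return ParticipantResult(participant_id=prep.participant_id,
                             results=results,
                             clinical_scores=prep.clinical_scores)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_feature_sets(participants: Sequence[ParticipantResult],
                           feature_sets: Sequence[FeatureSet] = tuple(FeatureSet)
                           ) -> pd.DataFrame:
    """Cohort summary: per-class accuracy averaged over participants for each
    feature set, plus an 'Average' row (mean of the eight class rows).

    A companion boolean column ``<set>_functional`` flags cells at or above
    the 90 % usability cutoff.
    """
    if not participants:
        raise ValueError("no participants")
    for p in participants:
        missing = [fs for fs in feature_sets if fs not in p.results]
        if missing:
            raise ValueError(
                f"participant {p.participant_id} missing feature sets "
                f"{[m.name for m in missing]}")
    rows = {}
    for fs in feature_sets:
        acc = np.vstack([p.results[fs].per_class_accuracy
                         for p in participants])
        per_class = np.nanmean(acc, axis=0)
        rows[fs.name] = np.append(per_class, np.mean(per_class))
    table = pd.DataFrame(rows, index=[c.code for c in CLASS_ORDER] + ["Average"])
    for fs in feature_sets:
        table[f"{fs.name}_functional"] = table[fs.name] >= FUNCTIONAL_ACCURACY
    return table


def participant_accuracy_table(participants: Sequence[ParticipantResult],
                               feature_set: FeatureSet) -> pd.DataFrame:
    """Per-participant per-class accuracy breakdown for one feature set."""
    rows = []
    for p in participants:
        acc = p.results[feature_set].per_class_accuracy
        row = {"participant_id": p.participant_id}
        row.update({c.code: acc[i] for i, c in enumerate(CLASS_ORDER)})
        row["overall"] = p.results[feature_set].overall_accuracy
        if p.clinical_scores:
            row.update(p.clinical_scores)
        rows.append(row)
    return pd.DataFrame(rows)


def torque_space_scatter(participant: PreparedParticipant,
                         spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Per-window normalized (AB/AD, ER/IR) torque pairs for the four most
    confused classes.

    Each window of an AB, AD, ER or IR trial contributes its window-mean
    AB/AD torque divided by the MVT of the direction matching its sign
    (AB-MVT when positive, AD-MVT when negative), and likewise for ER/IR.
    """
    four = (TaskClass.AB, TaskClass.AD, TaskClass.ER, TaskClass.IR)
    for task in four:
        if participant.direction_mvt.get(task, 0) <= 0:
            raise ValueError(f"zero MVT for {task.code}")
    rows = []
    for task in four:
        for prep in participant.by_class[task]:
            fm = _trial_features(prep, spec, FeatureSet.TORQUE, 0.0)
            for ab_ad, _, er_ir, _ in fm.values:
                ab_norm = ab_ad / (participant.direction_mvt[TaskClass.AB]
                                   if ab_ad >= 0 else
                                   participant.direction_mvt[TaskClass.AD])
                er_norm = er_ir / (participant.direction_mvt[TaskClass.ER]
                                   if er_ir >= 0 else
                                   participant.direction_mvt[TaskClass.IR])
                rows.append({"class": task.code, "ab_ad_norm": ab_norm,
                             "er_ir_norm": er_norm})
    return pd.DataFrame(rows)


def spearman_correlation(x: Sequence[float], y: Sequence[float]
                         ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of average ranks (ties share their mean
    rank); p uses t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of
    freedom, which is approximate for small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero-variance ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
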