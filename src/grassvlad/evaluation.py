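"""Classification protocols and metrics.

VLAD codes are classified with an RBF-kernel SVM whose hyperparameters are
selected by an inner stratified grid search on the training set only.  Two
evaluation protocols are provided: stratified k-fold cross-validation at the
image level, and patient-wise holdout (patients — never individual images —
are split ~70/30 per class, repeated over several seeded trials) in which no
patient may contribute images to both sides of a split.

Metrics: the image classification rate N_c / N_all; the per-patient score
(fraction of a patient's images classified correctly); and the global patient
classification rate, the mean of patient scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .patches import ImageRecord

DEFAULT_C_GRID = (1.0, 10.0, 100.0)
DEFAULT_WIDTH_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class SplitPlan:
    """Train/test index folds under one protocol."""

    protocol: str
    folds: List[Tuple[np.ndarray, np.ndarray]]
    seed: int
    patient_aware: bool

    def __post_init__(self):
        if self.protocol not in ("kfold", "patient_holdout"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")


def make_split(
    records: Sequence[ImageRecord],
    protocol: str = "kfold",
    seed: int = 0,
    n_folds: int = 5,
    train_frac: float = 0.7,
    n_trials: int = 5,
) -> SplitPlan:
    """Build a split plan over manifest records.

    ``kfold``: seeded stratified k-fold over image labels.
    ``patient_holdout``: ``n_trials`` independent seeded draws; in each draw
    the *patients* of every class are partitioned ~train_frac/(1-train_frac),
    and images follow their patient, so no patient straddles a split.
    """
    labels = np.array([r.label for r in records])
    patients = np.array([r.patient_id for r in records])
    n = len(records)
    if n == 0:
        raise ConfigError("empty record list")
    if protocol == "kfold":
        _, counts = np.unique(labels, return_counts=True)
        if n_folds > counts.min():
            raise ConfigError(
                f"n_folds={n_folds} exceeds smallest class count {counts.min()}"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(n), labels)]
        return SplitPlan("kfold", folds, seed, patient_aware=False)
    if protocol != "patient_holdout":
        raise ConfigError(f"unknown protocol {protocol!r}")
    # Each patient belongs to the class of its first image.
    patient_label: Dict[str, str] = {}
    for r in records:
        patient_label.setdefault(r.patient_id, r.label)
    by_class: Dict[str, List[str]] = {}
    for pid, lab in patient_label.items():
        by_class.setdefault(lab, []).append(pid)
    for lab, pids in by_class.items():
        if len(pids) < 2:
            raise ConfigError(
                f"patient_holdout needs >= 2 patients per class; class {lab!r} has "
                f"{len(pids)}"
            )
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_trials):
        train_patients = set()
        for lab in sorted(by_class):
            pids = sorted(by_class[lab])
            perm = rng.permutation(len(pids))
            n_train = int(round(train_frac * len(pids)))
            n_train = min(max(n_train, 1), len(pids) - 1)
            train_patients.update(pids[i] for i in perm[:n_train])
        tr = np.nonzero(np.isin(patients, sorted(train_patients)))[0]
        te = np.setdiff1d(np.arange(n), tr)
        assert not set(patients[tr]) & set(patients[te]), "patient leakage"
        folds.append((tr, te))
    return SplitPlan("patient_holdout", folds, seed, patient_aware=True)


def train_classifier(
    codes: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    width_grid: Sequence[float] = DEFAULT_WIDTH_GRID,
    inner_folds: int = 3,
) -> SVC:
    """Fit an RBF-kernel SVM with an inner stratified grid search.

    Kernel widths are the grid values scaled by the median pairwise code
    distance delta (gamma = 1 / (2 (s * delta)^2)); C ranges over ``c_grid``.
    Multiclass is handled one-vs-one (SVC default).  Deterministic given seed.
    """
    X = np.asarray(codes, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigError("training needs at least two classes")
    # Median pairwise distance of (a subsample of) the training codes.
    rng = np.random.default_rng(seed)
    sub = X if len(X) <= 500 else X[np.sort(rng.choice(len(X), 500, replace=False))]
    sq = np.sum(sub ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * sub @ sub.T, 0.0)
    iu = np.triu_indices(len(sub), k=1)
    delta = float(np.sqrt(np.median(d2[iu]))) if iu[0].size else 1.0
    if delta <= 0:
        delta = 1.0
    gammas = [1.0 / (2.0 * (s * delta) ** 2) for s in width_grid]
    folds = min(inner_folds, int(counts.min()))
    if folds < 2:
        model = SVC(kernel="rbf", C=10.0, gamma=gammas[2], random_state=seed)
        model.fit(X, y)
        return model
    search = GridSearchCV(
        SVC(kernel="rbf", random_state=seed),
        param_grid={"C": list(c_grid), "gamma": gammas},
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def classification_rate(pred: Sequence, true: Sequence) -> float:
    """N_c / N_all: fraction of correctly classified images."""
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise DataError("predictions and truths must be equal-length and nonempty")
    return float(np.mean(pred == true))


def patient_score(
    pred: Sequence, true: Sequence, patient_ids: Sequence[str]
) -> Dict[str, float]:
    """Per patient: correctly classified images over that patient's images."""
    pred, true = np.asarray(pred), np.asarray(true)
    pids = np.asarray(patient_ids)
    if not (pred.shape == true.shape == pids.shape):
        raise DataError("pred, true and patient_ids must share length")
    scores: Dict[str, float] = {}
    for pid in np.unique(pids):
        mask = pids == pid
        scores[str(pid)] = float(np.mean(pred[mask] == true[mask]))
    return scores


def global_patient_rate(scores: Dict[str, float]) -> float:
    """Mean of patient scores (the global patient classification rate)."""
    if not scores:
        raise DataError("empty patient-score map")
    return float(np.mean(list(scores.values())))


@dataclass
class EvalReport:
    """Per-fold rates, their mean/std, patient metrics and config echo."""

    protocol: str
    fold_rates: List[float]
    confusions: List[List[List[int]]]
    class_names: List[str]
    patient_scores: List[Dict[str, float]]
    global_patient_rates: List[float]
    config: Dict = field(default_factory=dict)
    predictions: List[Dict] = field(default_factory=list)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.fold_rates))

    @property
    def std_rate(self) -> float:
        return float(np.std(self.fold_rates))

    @property
    def mean_global_patient_rate(self) -> float:
        return float(np.mean(self.global_patient_rates))

    def to_dict(self) -> Dict:
        return {
            "protocol": self.protocol,
            "fold_rates": self.fold_rates,
            "mean_rate": self.mean_rate,
            "std_rate": self.std_rate,
            "confusions": self.confusions,
            "class_names": self.class_names,
            "patient_scores": self.patient_scores,
            "global_patient_rates": self.global_patient_rates,
            "mean_global_patient_rate": self.mean_global_patient_rate,
            "config": self.config,
            "predictions": self.predictions,
        }

    def summary(self) -> str:
        lines = [
            f"protocol: {self.protocol}",
            f"folds:    {len(self.fold_rates)}",
            "fold classification rates: "
            + ", ".join(f"{r:.4f}" for r in self.fold_rates),
            f"mean rate: {self.mean_rate:.4f} (std {self.std_rate:.4f})",
            f"mean global patient rate: {self.mean_global_patient_rate:.4f}",
        ]
        return "\n".join(lines)


def evaluate_folds(
    codes_per_fold: List[Tuple[np.ndarray, np.ndarray]],
    records: Sequence[ImageRecord],
    plan: SplitPlan,
    seed: int = 0,
    config: Dict = None,
) -> EvalReport:
    """Train and score one SVM per fold given per-fold (train, test) codes."""
    labels = np.array([r.label for r in records])
    pids = np.array([r.patient_id for r in records])
    class_names = sorted(np.unique(labels))
    fold_rates, confusions, p_scores, g_rates = [], [], [], []
    predictions = []
    for fold_i, ((tr, te), (code_tr, code_te)) in enumerate(
        zip(plan.folds, codes_per_fold)
    ):
        model = train_classifier(code_tr, labels[tr], seed=seed + fold_i)
        pred = model.predict(code_te)
        predictions.extend(
            {"path": records[i].path, "true": str(labels[i]),
             "predicted": str(p), "fold": fold_i,
             "patient_id": records[i].patient_id}
            for i, p in zip(te, pred)
        )
        fold_rates.append(classification_rate(pred, labels[te]))
        confusions.append(
            confusion_matrix(labels[te], pred, labels=class_names).tolist()
        )
        scores = patient_score(pred, labels[te], pids[te])
        p_scores.append(scores)
        g_rates.append(global_patient_rate(scores))
    return EvalReport(
        protocol=plan.protocol,
        fold_rates=fold_rates,
        confusions=confusions,
        class_names=list(class_names),
        patient_scores=p_scores,
        global_patient_rates=g_rates,
        config=config or {},
        predictions=predictions,
    )
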