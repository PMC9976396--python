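"""Per-locus classifier training, locus selection, and model bundles.

Each retained microsatellite locus gets a pair of binary classifiers
(logistic regression and an SVC) fitted on max-normalized length
profiles, with labels inherited from the sample-level mismatch-repair
status (every locus of a dMMR sample is treated as unstable, of a pMMR
sample as stable). Hyperparameters are grid-searched with 3-fold
cross-validated AUC on a fold assignment computed once on the training
sample list and shared by every locus and model kind, so model
comparisons see the same splits regardless of which samples pass the
depth filter at a given locus.

Locus selection is two-stage: coverage (evaluable in a minimum fraction
of training samples) and discriminative power (validation AUC at or
above the floor in *both* models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import IsolationForest, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import SVC, OneClassSVM

from .features import FeatureVector
from .regions import MsLocus, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "UNSTABLE_LABEL",
    "STABLE_LABEL",
    "FINAL_KINDS",
    "OUTLIER_KINDS",
    "ZOO_KINDS",
    "LabeledSample",
    "FittedModel",
    "LocusModelPair",
    "ModelBundle",
    "LocusSkipped",
    "CohortError",
    "split_cohort",
    "assign_folds",
    "select_loci_by_coverage",
    "train_locus_models",
    "instability_score",
    "instability_call",
    "evaluate_locus_auc",
    "select_final_loci",
    "fit_models",
    "train_bundle",
]

UNSTABLE_LABEL = "dMMR"
STABLE_LABEL = "pMMR"

FINAL_KINDS = ("logreg", "svc")
OUTLIER_KINDS = frozenset({"isolation_forest", "lof", "ocsvm"})
ZOO_KINDS = ("logreg", "svc", "random_forest", "naive_bayes",
             "isolation_forest", "lof", "ocsvm")

_C_GRID = [0.01, 0.1, 1.0, 10.0, 100.0]


class LocusSkipped(RuntimeError):
    """A locus cannot be trained/evaluated (class too small or absent)."""


class CohortError(ValueError):
    """Cohort too small or degenerate for the requested operation."""


@dataclass
class LabeledSample:
    """One sample: identifier, dMMR/pMMR label, per-locus feature vectors."""

    sample_id: str
    label: str
    features: dict[str, FeatureVector]

    def __post_init__(self) -> None:
        if self.label not in (UNSTABLE_LABEL, STABLE_LABEL):
            raise ValueError(
                f"{self.sample_id}: label must be {UNSTABLE_LABEL!r} or "
                f"{STABLE_LABEL!r}, got {self.label!r}"
            )

    @property
    def is_unstable(self) -> bool:
        return self.label == UNSTABLE_LABEL


@dataclass
class FittedModel:
    """A fitted estimator plus the hyperparameters the grid search chose."""

    kind: str
    estimator: object
    params: dict


@dataclass
class LocusModelPair:
    """The two final classifiers for one locus plus QC/selection metadata."""

    locus_name: str
    model_logreg: Optional[FittedModel]
    model_svc: Optional[FittedModel]
    auc_logreg: float
    auc_svc: float
    coverage_pass: bool
    retained: bool
    n_train_stable: int = 0
    n_train_unstable: int = 0


@dataclass
class ModelBundle:
    """Everything needed to score new samples: panel, config snapshot, models."""

    panel: list[MsLocus]
    config: PipelineConfig
    pairs: dict[str, LocusModelPair]
    split: dict[str, list[str]]
    baselines: dict[str, np.ndarray] = field(default_factory=dict)
    version: str = "1"
    seed: int = 0

    @property
    def retained_loci(self) -> list[str]:
        return [name for name, pair in self.pairs.items() if pair.retained]


def split_cohort(
    samples: Sequence[LabeledSample], seed: int
) -> tuple[list[LabeledSample], list[LabeledSample], list[LabeledSample]]:
    """Random label-stratified three-way split into near-equal subsets."""
    labels = [s.label for s in samples]
    n_unstable = labels.count(UNSTABLE_LABEL)
    n_stable = labels.count(STABLE_LABEL)
    if min(n_stable, n_unstable) < 3:
        raise CohortError(
            "need >= 3 samples per class to split into train/validation/test; "
            f"got {n_stable} {STABLE_LABEL} and {n_unstable} {UNSTABLE_LABEL} "
            "- collect a larger cohort"
        )
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    subsets = [
        [samples[i] for i in test_idx]
        for _, test_idx in skf.split(np.zeros(len(samples)), labels)
    ]
    for part in subsets:
        part_labels = {s.label for s in part}
        if part_labels != {UNSTABLE_LABEL, STABLE_LABEL}:
            raise CohortError(
                "a split subset lost one class entirely - collect a larger cohort"
            )
    train, validation, test = subsets
    return train, validation, test


def assign_folds(
    samples: Sequence[LabeledSample], kfold: int, seed: int
) -> dict[str, int]:
    """Stratified fold id per sample, computed once and shared across loci/kinds."""
    labels = [s.label for s in samples]
    skf = StratifiedKFold(n_splits=kfold, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(samples)), labels)):
        for i in test_idx:
            fold_of[samples[i].sample_id] = fold
    return fold_of


def select_loci_by_coverage(
    train: Sequence[LabeledSample], panel: list[MsLocus], config: PipelineConfig
) -> list[str]:
    """Loci evaluable (depth filter passed) in >= coverage_fraction of training samples."""
    if not train:
        raise CohortError("empty training set")
    retained = []
    for locus in panel:
        n_pass = sum(
            1 for s in train
            if locus.name in s.features and s.features[locus.name].evaluable
        )
        if n_pass / len(train) >= config.coverage_fraction:
            retained.append(locus.name)
    if not retained:
        raise CohortError("panel incompatible with data: no locus passes coverage")
    return retained


def _locus_matrix(
    samples: Sequence[LabeledSample], locus_name: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix / label vector over samples where the locus is evaluable.

    Labels are inherited from the sample: 1 = unstable (dMMR), 0 = stable.
    """
    rows, y, ids = [], [], []
    for s in samples:
        fv = s.features.get(locus_name)
        if fv is not None and fv.evaluable:
            rows.append(fv.values)
            y.append(1 if s.is_unstable else 0)
            ids.append(s.sample_id)
    if not rows:
        return np.empty((0, 0)), np.empty(0, dtype=int), []
    return np.vstack(rows), np.asarray(y, dtype=int), ids


def _base_estimator(kind: str, seed: int):
    if kind == "logreg":
        # default L2 regularization; strength searched over the C grid
        return LogisticRegression(class_weight="balanced", max_iter=5000)
    if kind == "svc":
        return SVC(class_weight="balanced")
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, class_weight="balanced", random_state=seed
        )
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "isolation_forest":
        return IsolationForest(random_state=seed)
    if kind == "lof":
        return LocalOutlierFactor(novelty=True)
    if kind == "ocsvm":
        return OneClassSVM(nu=0.1)
    raise ValueError(f"unknown model kind {kind!r}")


_GRIDS = {
    "logreg": {"C": _C_GRID},
    "svc": {"kernel": ["linear", "rbf"], "C": _C_GRID},
    "random_forest": {},
    "naive_bayes": {},
}


def train_locus_models(
    train: Sequence[LabeledSample],
    locus_name: str,
    config: PipelineConfig,
    model_kinds: Iterable[str] = FINAL_KINDS,
    fold_of: Optional[dict[str, int]] = None,
) -> dict[str, FittedModel]:
    """Fit the requested model kinds for one locus.

    Supervised kinds are grid-searched by cross-validated AUC on the
    shared fold assignment; outlier kinds see only stable-labeled
    vectors. Raises :class:`LocusSkipped` when a class is too small for
    the k-fold scheme at this locus.
    """
    X, y, ids = _locus_matrix(train, locus_name)
    if X.size == 0:
        raise LocusSkipped(f"{locus_name}: no evaluable training samples")
    k = config.kfold
    n_unstable, n_stable = int(y.sum()), int((1 - y).sum())
    if min(n_stable, n_unstable) < k:
        raise LocusSkipped(
            f"{locus_name}: class with fewer than kfold={k} evaluable samples "
            f"({n_stable} stable, {n_unstable} unstable)"
        )
    if fold_of is None:
        fold_of = assign_folds(train, k, config.seed)
    # restrict the shared folds to the samples evaluable at this locus
    folds = np.array([fold_of[sid] for sid in ids])
    cv = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        if len(set(y[test_idx])) < 2 or len(set(y[train_idx])) < 2:
            raise LocusSkipped(
                f"{locus_name}: shared fold {f} single-class after depth filtering"
            )
        cv.append((train_idx, test_idx))

    fitted: dict[str, FittedModel] = {}
    for kind in model_kinds:
        base = _base_estimator(kind, config.seed)
        if kind in OUTLIER_KINDS:
            # outlier detectors are trained on stable (pMMR) vectors only
            base.fit(X[y == 0])
            fitted[kind] = FittedModel(kind, base, {})
            continue
        grid = _GRIDS[kind]
        if grid:
            search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True)
            search.fit(X, y)
            fitted[kind] = FittedModel(kind, search.best_estimator_, dict(search.best_params_))
        else:
            base.fit(X, y)
            fitted[kind] = FittedModel(kind, base, {})
    return fitted


def instability_score(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Continuous score, higher = more unstable, for any model kind."""
    est = model.estimator
    if model.kind in OUTLIER_KINDS:
        # outlier detectors score "normality"; instability is its negation
        return -est.decision_function(X)
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def instability_call(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Binary unstable call (native class prediction / outlier flag)."""
    pred = model.estimator.predict(X)
    if model.kind in OUTLIER_KINDS:
        return np.asarray(pred == -1, dtype=bool)
    return np.asarray(pred == 1, dtype=bool)


def evaluate_locus_auc(
    models: dict[str, FittedModel],
    validation: Sequence[LabeledSample],
    locus_name: str,
) -> dict[str, float]:
    """Validation AUC per model kind at one locus (labels inherited from samples)."""
    X, y, _ = _locus_matrix(validation, locus_name)
    if X.size == 0 or len(set(y)) < 2:
        raise LocusSkipped(
            f"{locus_name}: validation set single-class or empty after depth filter"
        )
    return {
        kind: float(roc_auc_score(y, instability_score(model, X)))
        for kind, model in models.items()
    }


def select_final_loci(
    aucs: dict[str, tuple[float, float]], config: PipelineConfig
) -> set[str]:
    """Loci whose validation AUC reaches the floor in both final models."""
    return {
        name
        for name, (auc_lr, auc_svc) in aucs.items()
        if min(auc_lr, auc_svc) >= config.locus_auc_min
    }


def fit_models(
    train: Sequence[LabeledSample],
    validation: Sequence[LabeledSample],
    panel: list[MsLocus],
    config: PipelineConfig,
    seed: int,
) -> tuple[dict[str, LocusModelPair], dict[str, np.ndarray]]:
    """Train and select the per-locus model pairs on an explicit train/validation split.

    Returns the pair table (one entry per coverage-passing locus, with
    ``retained`` set by the dual-AUC rule) and, for retained loci, the
    stable training profiles kept as plotting baselines.
    """
    covered = select_loci_by_coverage(train, panel, config)
    fold_of = assign_folds(train, config.kfold, seed)
    pairs: dict[str, LocusModelPair] = {}
    baselines: dict[str, np.ndarray] = {}
    for name in covered:
        try:
            models = train_locus_models(train, name, config, FINAL_KINDS, fold_of)
            aucs = evaluate_locus_auc(models, validation, name)
        except LocusSkipped as exc:
            logger.warning("locus dropped: %s", exc)
            pairs[name] = LocusModelPair(
                name, None, None, float("nan"), float("nan"),
                coverage_pass=True, retained=False,
            )
            continue
        _, y, _ = _locus_matrix(train, name)
        retained = min(aucs["logreg"], aucs["svc"]) >= config.locus_auc_min
        pairs[name] = LocusModelPair(
            name,
            models["logreg"],
            models["svc"],
            aucs["logreg"],
            aucs["svc"],
            coverage_pass=True,
            retained=retained,
            n_train_stable=int((y == 0).sum()),
            n_train_unstable=int((y == 1).sum()),
        )
        if retained:
            stable_rows = [
                s.features[name].values
                for s in train
                if not s.is_unstable
                and name in s.features
                and s.features[name].evaluable
            ]
            if stable_rows:
                baselines[name] = np.vstack(stable_rows)
    return pairs, baselines


def train_bundle(
    samples: Sequence[LabeledSample],
    panel: list[MsLocus],
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> ModelBundle:
    """End-to-end training: split the cohort, fit and select, assemble a bundle."""
    if seed is None:
        seed = config.seed
    train, validation, test = split_cohort(samples, seed)
    pairs, baselines = fit_models(train, validation, panel, config, seed)
    if not any(p.retained for p in pairs.values()):
        raise CohortError("no locus retained: every locus failed coverage or AUC selection")
    split = {
        "train": [s.sample_id for s in train],
        "validation": [s.sample_id for s in validation],
        "test": [s.sample_id for s in test],
    }
    return ModelBundle(
        panel=list(panel), config=config, pairs=pairs, split=split,
        baselines=baselines, seed=seed,
    )
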