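"""Seeded 70-30 train/test harness for binary ICD prediction.

The evaluation design repeatedly splits the cohort 70% train / 30% test
under a list of named seeds (default [1, 0, 250, 500, 750]), fits each
learner on the four geometric parameters only, and records one prediction
per (seed, learner, test patient). A patient drawn into several test sets
accumulates a repetition count; with 135 patients and five seeds this
yields 5 x 40 = 200 predictions per learner.

Learners: random forest (RF), RBF support vector machine (SVM) and a small
multi-layer perceptron (MLP) as the primary trio, plus decision tree (DT),
logistic regression (LR) and gradient-boosted trees (GBT). Kernel, linear
and neural learners see z-scored features (scaler fitted on the training
fold only); tree learners see raw features. All fits are deterministic
given the harness seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import BinaryOutcome, PatientRecord, PredictionRecord
from .zoning import ZoneScheme, default_zone_scheme, profile

DEFAULT_SEEDS = (1, 0, 250, 500, 750)
DEFAULT_ALGORITHMS = ("RF", "SVM", "MLP")
FEATURES = ("ad_mm", "aop_deg", "hsd_mm", "mla_deg")

#: Learners whose features are z-scored on the training fold.
_SCALED = {"SVM", "MLP", "LR"}


@dataclass(frozen=True)
class SplitPlan:
    """Reproducible train/test partitions, one per seed."""

    n: int
    seeds: tuple[int, ...]
    train_fraction: float
    splits: dict[int, tuple[np.ndarray, np.ndarray]] = field(compare=False)

    @property
    def test_size(self) -> int:
        return self.n - round_half_up(self.train_fraction * self.n)


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_split_plan(
    n: int,
    seeds=DEFAULT_SEEDS,
    train_fraction: float = 0.70,
) -> SplitPlan:
    """Partition indices 0..n-1 into train/test once per seed.

    The train size is train_fraction * n rounded half-up (95 of 135 at the
    default fraction). Each seed drives an independent permutation stream.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    seeds = tuple(int(s) for s in seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"duplicate seeds in {seeds}")
    n_train = round_half_up(train_fraction * n)
    splits = {}
    for s in seeds:
        perm = np.random.default_rng(s).permutation(n)
        splits[s] = (np.sort(perm[:n_train]), np.sort(perm[n_train:]))
    return SplitPlan(n=n, seeds=seeds, train_fraction=train_fraction, splits=splits)


def _make_estimator(algorithm: str, seed: int, hyperparameters: dict | None):
    hp = dict(hyperparameters or {})
    if algorithm == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    elif algorithm == "SVM":
        est = SVC(C=hp.pop("C", 1.0), kernel=hp.pop("kernel", "rbf"),
                  gamma=hp.pop("gamma", "scale"), random_state=seed, **hp)
    elif algorithm == "MLP":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (8,)),
            solver=hp.pop("solver", "lbfgs"),
            max_iter=hp.pop("max_iter", 1000),
            random_state=seed, **hp,
        )
    elif algorithm == "DT":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif algorithm == "LR":
        est = LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    elif algorithm == "GBT":
        est = GradientBoostingClassifier(random_state=seed, **hp)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _feature_matrix(records: list[PatientRecord]) -> np.ndarray:
    return np.array([[getattr(r, f) for f in FEATURES] for r in records])


def _labels(records: list[PatientRecord]) -> np.ndarray:
    return np.array([r.binary_outcome.value for r in records])


def train_predict(
    algorithm: str,
    train: list[PatientRecord],
    test: list[PatientRecord],
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> list[BinaryOutcome]:
    """Fit one learner on the training fold and label the test fold."""
    model, labels = fit(algorithm, train, hyperparameters, seed)
    return [BinaryOutcome(l) for l in model.predict(_feature_matrix(test))]


def fit(
    algorithm: str,
    train: list[PatientRecord],
    hyperparameters: dict | None = None,
    seed: int = 0,
):
    y = _labels(train)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single outcome class")
    model = _make_estimator(algorithm, seed, hyperparameters)
    model.fit(_feature_matrix(train), y)
    return model, y


def feature_importance_rank(
    algorithm: str,
    model,
    holdout: list[PatientRecord] | None = None,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Strict importance ranking of the four features for a fitted model.

    Tree learners use impurity importance, logistic regression the absolute
    standardized coefficients, and SVM/MLP permutation importance on a
    held-out set (required for those learners). Ties break on the canonical
    feature order. Returns ``(ranking, raw importance per feature)``; near-
    zero importances flag an uninformative (unstable) ranking.
    """
    est = model.named_steps["model"] if isinstance(model, Pipeline) else model
    if algorithm in ("RF", "DT", "GBT"):
        scores = np.asarray(est.feature_importances_)
    elif algorithm == "LR":
        scores = np.abs(np.asarray(est.coef_).ravel())
    elif algorithm in ("SVM", "MLP"):
        if holdout is None:
            raise ValueError(f"{algorithm} importance needs a held-out set")
        res = permutation_importance(
            model, _feature_matrix(holdout), _labels(holdout),
            n_repeats=20, random_state=seed,
        )
        scores = res.importances_mean
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    order = sorted(range(len(FEATURES)), key=lambda i: (-scores[i], i))
    return [FEATURES[i] for i in order], scores


@dataclass(frozen=True)
class HarnessResult:
    per_prediction: pd.DataFrame           # seed, algorithm, patient_id, labels
    records: list[PredictionRecord]        # aggregated with repetition counts
    importance: dict[str, list[str]]       # algorithm -> ranked features
    importance_scores: dict[str, np.ndarray] = field(compare=False, default=None)

    def total_predictions(self, algorithm: str) -> int:
        frame = self.per_prediction
        return int((frame["algorithm"] == algorithm).sum())


def run_harness(
    cohort: list[PatientRecord],
    plan: SplitPlan | None = None,
    algorithms=DEFAULT_ALGORITHMS,
    hyperparameters: dict | None = None,
    zone_scheme: ZoneScheme | None = None,
    seed: int = 0,
) -> HarnessResult:
    """Run every (seed, algorithm) fit and aggregate per-patient predictions.

    ``seed`` drives learner-internal randomness only; the partitions come
    from the plan's own seed list. Aggregated records carry the patient's
    zone profile, AIDA class, actual binary outcome and repetition count;
    rows merge only when every learner predicted the same label in each
    repetition.
    """
    plan = plan if plan is not None else make_split_plan(len(cohort))
    scheme = zone_scheme if zone_scheme is not None else default_zone_scheme()
    if plan.n != len(cohort):
        raise ValueError(f"plan is for n={plan.n}, cohort has {len(cohort)}")
    hyperparameters = hyperparameters or {}
    rows = []
    importance: dict[str, list[str]] = {}
    scores: dict[str, np.ndarray] = {}
    for algo in algorithms:
        for split_seed in plan.seeds:
            train_ix, test_ix = plan.splits[split_seed]
            train = [cohort[i] for i in train_ix]
            test = [cohort[i] for i in test_ix]
            predicted = train_predict(
                algo, train, test, hyperparameters.get(algo), seed=seed
            )
            for rec, label in zip(test, predicted):
                rows.append(
                    {
                        "seed": split_seed,
                        "algorithm": algo,
                        "patient_id": rec.patient_id,
                        "actual": rec.binary_outcome.value,
                        "predicted": label.value,
                    }
                )
        # rank importances on the last split's folds (refit not needed)
        model, _ = fit(algo, train, hyperparameters.get(algo), seed=seed)
        importance[algo], scores[algo] = feature_importance_rank(
            algo, model, holdout=test, seed=seed
        )
    per_prediction = pd.DataFrame(rows)
    records = _aggregate(cohort, per_prediction, algorithms, scheme)
    return HarnessResult(
        per_prediction=per_prediction,
        records=records,
        importance=importance,
        importance_scores=scores,
    )


def _aggregate(cohort, per_prediction, algorithms, scheme) -> list[PredictionRecord]:
    by_id = {r.patient_id: r for r in cohort}
    wide = per_prediction.pivot_table(
        index=["patient_id", "seed"],
        columns="algorithm",
        values="predicted",
        aggfunc="first",
    ).reset_index()
    records = []
    group_cols = [a for a in ("SVM", "RF", "MLP") if a in algorithms]
    for (pid, *labels), grp in wide.groupby(["patient_id"] + group_cols, sort=True):
        rec = by_id[pid]
        prof = profile(rec, scheme)
        label_of = dict(zip(group_cols, labels))
        records.append(
            PredictionRecord(
                patient_id=pid,
                aida_class=prof.aida_class,
                zone_ad=prof.zone_ad,
                zone_aop=prof.zone_aop,
                zone_mla=prof.zone_mla,
                zone_hsd=prof.zone_hsd,
                asynclitism_type=rec.asynclitism_type,
                actual_outcome=rec.binary_outcome,
                predicted_svm=BinaryOutcome(label_of.get("SVM", "NOICD")),
                predicted_rf=BinaryOutcome(label_of.get("RF", "NOICD")),
                predicted_mlp=BinaryOutcome(label_of.get("MLP", "NOICD")),
                n_predictions=len(grp),
            )
        )
    return records


def importance_grid(result: HarnessResult) -> pd.DataFrame:
    """Per-algorithm importance ranking grid with each feature's position."""
    rows = []
    for algo, ranking in result.importance.items():
        row = {"algorithm": algo}
        for pos, feat in enumerate(ranking, start=1):
            row[feat] = pos
        rows.append(row)
    return pd.DataFrame(rows).set_index("algorithm")
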