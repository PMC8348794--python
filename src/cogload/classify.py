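"""Workload classification with shallow feed-forward networks.

The protocol has three stages: (1) divide the epoch-level feature matrix
into train/validation/test sets under one of four schemes, (2) select a
network architecture by grid search over 1–3 hidden layers and
{1, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90} nodes per layer (the same
width for every layer), averaging validation accuracy over repeated
trainings to wash out weight-initialization noise, and (3) train a 10-member
voting ensemble of the selected architecture, whose majority vote is the
prediction.

Division schemes:

``subject_16_4_4``
    random subject-wise partition into 16 train / 4 validation / 4 test
    subjects — the fully calibration-free setting;
``day1_train_day2_val_test``
    day 1 trains, the first (chronological) half of day 2 validates, the
    second half tests — personal calibration;
``train_1p5_days``
    day 1 plus the first half of day 2 train; the remaining half-day splits
    evenly into validation and test — within-session calibration;
``leave_one_out``
    one fold per subject, that subject tests, the rest train (with a 10%
    stratified validation slice carved from the training pool).

Networks are fully connected with ReLU hidden units and softmax outputs,
trained by Adam on cross-entropy with early stopping on validation accuracy;
inputs are z-scored per feature (fit on the training split only) and the
training rows are permuted before entering the network.  All randomness
derives from one master seed.
"""

from __future__ import annotations


from dataclasses import dataclass


import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .features import BANDS
from .seeds import child_seed

__all__ = [
    "SPLIT_SCHEMES",
    "NODE_GRID",
    "NetConfig",
    "Split",
    "TrainedNet",
    "VotingEnsemble",
    "ClassifierReport",
    "split_data",
    "subset_epochs",
    "train_once",
    "grid_search",
    "train_ensemble",
    "evaluate",
    "default_grid",
    "feature_matrix",
    "PAIRWISE_TASKS",
]

SPLIT_SCHEMES = (
    "subject_16_4_4",
    "day1_train_day2_val_test",
    "train_1p5_days",
    "leave_one_out",
)
NODE_GRID = (1, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90)
PAIRWISE_TASKS = (("L0", "L1"), ("L0", "L2"), ("L0", "L3"), ("L1", "L2"), ("L2", "L3"))
DEFAULT_PAIR = ("L0", "L3")


@dataclass(frozen=True)
class NetConfig:
    """Architecture: 1–3 hidden layers of equal width from the node grid."""

    n_layers: int
    n_nodes: int
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 3:
            raise ValueError("n_layers must be 1..3")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return (self.n_nodes,) * self.n_layers


def default_grid(n_classes: int = 2) -> list[NetConfig]:
    return [NetConfig(l, n, n_classes) for l in (1, 2, 3) for n in NODE_GRID]


@dataclass
class Split:
    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    scheme: str
    fold: object = None  # held-out subject for leave-one-out

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def _half_by_time(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chronological halves within each (subject, condition).

    Rows are in presentation order within a session, but conditions run in
    blocks — halving the raw order would put whole conditions on one side.
    Halving within each condition keeps both halves class-balanced while
    still splitting early from late epochs.
    """
    first, second = [], []
    for _, grp in frame.groupby(["subject", "condition"], sort=False):
        k = len(grp) // 2
        first.append(grp.iloc[:k])
        second.append(grp.iloc[k:])
    return pd.concat(first), pd.concat(second)


def split_data(features: pd.DataFrame, scheme: str, seed: int = 0):
    """Divide epochs into train/validation/test under one of the four schemes.

    Returns a :class:`Split`, or a list of them for ``leave_one_out``.
    Partitions are disjoint at the epoch level, and at the subject level for
    the subject-wise schemes.
    """
    if scheme not in SPLIT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SPLIT_SCHEMES}")
    subjects = sorted(features["subject"].unique())

    if scheme == "subject_16_4_4":
        if len(subjects) < 24:
            raise ValueError(f"subject_16_4_4 needs >= 24 subjects, got {len(subjects)}")
        rng = np.random.default_rng(child_seed(seed, "split", scheme))
        perm = [subjects[i] for i in rng.permutation(len(subjects))]
        tr, va, te = set(perm[:16]), set(perm[16:20]), set(perm[20:24])
        return Split(
            features[features["subject"].isin(tr)],
            features[features["subject"].isin(va)],
            features[features["subject"].isin(te)],
            scheme,
        )

    if scheme in ("day1_train_day2_val_test", "train_1p5_days"):
        day1 = features[features["day"] == 1]
        day2 = features[features["day"] == 2]
        if day2.empty:
            raise ValueError(f"scheme {scheme} needs two days of data")
        first_half, second_half = _half_by_time(day2)
        if scheme == "day1_train_day2_val_test":
            return Split(day1, first_half, second_half, scheme)
        va, te = _half_by_time(second_half)
        return Split(pd.concat([day1, first_half]), va, te, scheme)

    # leave_one_out
    folds = []
    for held in subjects:
        pool = features[features["subject"] != held]
        rng = np.random.default_rng(child_seed(seed, "split", scheme, held))
        # fixed 10% stratified validation slice from the training pool
        val_idx = []
        for _, grp in pool.groupby("condition", sort=True):
            k = max(1, int(round(0.1 * len(grp))))
            val_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
        val_mask = pool.index.isin(val_idx)
        folds.append(
            Split(
                pool[~val_mask],
                pool[val_mask],
                features[features["subject"] == held],
                scheme,
                fold=held,
            )
        )
    return folds


def subset_epochs(
    features: pd.DataFrame,
    criterion: str = "all",
    *,
    subsample_to: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Filter epochs by stimulus/response metadata.

    ``criterion``: ``target`` (target stimuli), ``target+correct`` (target
    stimuli answered correctly, i.e. responded), ``nontarget``, ``correct``
    (correct response regardless of stimulus: responded on targets, silent on
    non-targets), or ``all``.  Optionally subsample to a reference size.
    """
    if criterion == "all":
        out = features
    elif criterion == "target":
        out = features[features["is_target"]]
    elif criterion == "target+correct":
        out = features[features["is_target"] & features["responded"]]
    elif criterion == "nontarget":
        out = features[~features["is_target"]]
    elif criterion == "correct":
        out = features[features["is_target"] == features["responded"]]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if out.empty:
        raise ValueError(f"criterion {criterion!r} selected no epochs")
    if subsample_to is not None and subsample_to < len(out):
        rng = np.random.default_rng(child_seed(seed, "subsample", criterion))
        idx = rng.choice(len(out), size=subsample_to, replace=False)
        out = out.iloc[np.sort(idx)]
    return out


def feature_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract (X, y, columns) from a labelled feature frame.

    Feature columns with any NaN (channels rejected in some session) are
    dropped so every network sees a consistent input dimension.
    """
    cols = [c for c in frame.columns if "_" in c and c.split("_")[0] in BANDS.names]
    X = frame[cols].to_numpy(dtype=float)
    keep = ~np.isnan(X).any(axis=0)
    return X[:, keep], frame["condition"].to_numpy(), [c for c, k in zip(cols, keep) if k]


@dataclass
class TrainedNet:
    """A fitted scaler + network pair with its validation accuracy."""

    scaler: StandardScaler
    net: MLPClassifier
    classes: np.ndarray
    val_accuracy: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def train_once(
    config: NetConfig,
    train: pd.DataFrame,
    validation: pd.DataFrame,
    seed: int,
    *,
    max_epochs: int = 150,
    patience: int = 10,
) -> TrainedNet:
    """Train one network with early stopping on validation accuracy.

    The training rows are permuted with the derived seed before entering the
    network; standardization is fit on the training split only.  Identical
    inputs and seed give identical weights.
    """
    X_tr, y_tr, _ = feature_matrix(train)
    X_va, y_va, _ = feature_matrix(validation)
    classes = np.unique(y_tr)
    if classes.size < 2:
        raise ValueError("training set contains a single class; cannot train")
    rng = np.random.default_rng(child_seed(seed, "permute"))
    perm = rng.permutation(len(X_tr))
    X_tr, y_tr = X_tr[perm], y_tr[perm]

    scaler = StandardScaler().fit(X_tr)
    Xs_tr, Xs_va = scaler.transform(X_tr), scaler.transform(X_va)
    net = MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=5e-3,
        batch_size=min(32, len(Xs_tr)),
        random_state=child_seed(seed, "init"),
        max_iter=1,
        warm_start=False,
    )
    best = (-1.0, None, None)
    stall = 0
    for _ in range(max_epochs):
        net.partial_fit(Xs_tr, y_tr, classes=classes)
        acc = float(np.mean(net.predict(Xs_va) == y_va))
        if acc > best[0] + 1e-12:
            best = (acc, [c.copy() for c in net.coefs_], [b.copy() for b in net.intercepts_])
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    net.coefs_, net.intercepts_ = best[1], best[2]
    return TrainedNet(scaler=scaler, net=net, classes=net.classes_, val_accuracy=best[0])


def grid_search(
    grid: list[NetConfig],
    train: pd.DataFrame,
    validation: pd.DataFrame,
    *,
    repeats: int = 30,
    seed: int = 0,
    max_epochs: int = 150,
) -> tuple[NetConfig, pd.DataFrame]:
    """Mean validation accuracy per architecture over repeated trainings.

    Returns the winning configuration (ties broken toward fewer layers, then
    fewer nodes) and the full accuracy table.
    """
    if not grid:
        raise ValueError("empty architecture grid")
    rows = []
    for config in grid:
        accs = [
            train_once(
                config, train, validation,
                child_seed(seed, "grid", config.n_layers, config.n_nodes, r),
                max_epochs=max_epochs,
            ).val_accuracy
            for r in range(repeats)
        ]
        rows.append(
            {
                "n_layers": config.n_layers,
                "n_nodes": config.n_nodes,
                "mean_val_accuracy": float(np.mean(accs)),
                "sd_val_accuracy": float(np.std(accs)),
            }
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_val_accuracy", "n_layers", "n_nodes"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    best = next(
        c for c in grid if c.n_layers == top["n_layers"] and c.n_nodes == top["n_nodes"]
    )
    return best, table


@dataclass
class VotingEnsemble:
    """Ten identically configured networks; prediction by majority vote.

    Vote ties are resolved by the highest mean class score across members —
    never arbitrarily.
    """

    members: list[TrainedNet]
    config: NetConfig

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")

    @property
    def classes(self) -> np.ndarray:
        return self.members[0].classes

    def mean_scores(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        classes = self.classes
        votes = np.zeros((len(X), classes.size), dtype=int)
        for m in self.members:
            pred = m.predict(X)
            for j, c in enumerate(classes):
                votes[:, j] += pred == c
        top = votes.max(axis=1, keepdims=True)
        tied = (votes == top).sum(axis=1) > 1
        winner = np.argmax(votes, axis=1)
        if tied.any():
            scores = self.mean_scores(X[tied])
            # among vote-tied classes, take the larger mean score
            masked = np.where(votes[tied] == top[tied], scores, -np.inf)
            winner[tied] = np.argmax(masked, axis=1)
        return classes[winner]


def train_ensemble(
    config: NetConfig,
    train: pd.DataFrame,
    validation: pd.DataFrame,
    *,
    n_members: int = 10,
    seed: int = 0,
    max_epochs: int = 150,
) -> VotingEnsemble:
    """Train ``n_members`` networks from derived sub-seeds."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members = [
        train_once(config, train, validation, child_seed(seed, "member", k),
                   max_epochs=max_epochs)
        for k in range(n_members)
    ]
    return VotingEnsemble(members=members, config=config)


@dataclass
class ClassifierReport:
    """Evaluation surfaces for one task (a class pair or the 4-class task)."""

    classes: tuple[str, ...]
    accuracy: float
    confusion: np.ndarray  # rows: true class, columns: predicted
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    recall: float | None = None
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2): false/true positive rate
    config: NetConfig | None = None
    missing_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "missing_classes": list(self.missing_classes),
        }
        if self.roc_points is not None:
            out["roc_points"] = self.roc_points.tolist()
        if self.config is not None:
            out["architecture"] = {
                "n_layers": self.config.n_layers,
                "n_nodes": self.config.n_nodes,
            }
        return out


def _roc(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from positive-class scores.

    Tied scores are collapsed to one threshold, so the curve cuts diagonally
    through tie groups and the trapezoidal area equals the pairwise
    concordance probability (ties counted half).
    """
    order = np.argsort(-scores, kind="mergesort")
    scores, truth = scores[order], truth[order]
    # indices where the score changes: thresholds sit at group boundaries
    last_of_group = np.flatnonzero(np.diff(scores) != 0)
    boundaries = np.concatenate([last_of_group, [scores.size - 1]])
    tps = np.cumsum(truth)[boundaries]
    fps = np.cumsum(~truth)[boundaries]
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate(
    ensemble: VotingEnsemble,
    test: pd.DataFrame,
    classes: tuple[str, ...] | None = None,
) -> ClassifierReport:
    """Score the ensemble on a test set.

    Two-class tasks report sensitivity/specificity/precision/recall with the
    higher-load class as positive, plus the ROC (from ensemble mean scores)
    and its trapezoidal AUC.  The confusion matrix rows sum to the per-class
    test counts.  Classes absent from the test set are reported as missing,
    with their metrics left undefined.
    """
    X, y, _ = feature_matrix(test)
    classes = tuple(classes if classes is not None else ensemble.classes)
    pred = ensemble.predict(X)
    conf = _sk_confusion(y, pred, labels=list(classes))
    accuracy = float(np.trace(conf) / max(conf.sum(), 1))
    missing = tuple(c for c in classes if not np.any(y == c))

    report = ClassifierReport(
        classes=classes,
        accuracy=accuracy,
        confusion=conf,
        config=ensemble.config,
        missing_classes=missing,
    )
    if len(classes) == 2 and not missing:
        pos = classes[1]  # higher-load class
        truth = y == pos
        pred_pos = pred == pos
        tp = int(np.sum(truth & pred_pos))
        tn = int(np.sum(~truth & ~pred_pos))
        fp = int(np.sum(~truth & pred_pos))
        fn = int(np.sum(truth & ~pred_pos))
        scores = ensemble.mean_scores(X)[:, list(ensemble.classes).index(pos)]
        roc, auc = _roc(scores, truth)
        report.sensitivity = tp / (tp + fn) if tp + fn else None
        report.specificity = tn / (tn + fp) if tn + fp else None
        report.precision = tp / (tp + fp) if tp + fp else None
        report.recall = report.sensitivity
        report.auc = auc
        report.roc_points = roc
    return report
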