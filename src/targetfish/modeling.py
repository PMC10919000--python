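"""Per-target classifiers with class balancing and applicability-domain gating.

For each protein target, one classifier is trained per (descriptor kind,
algorithm) combination — five algorithms (decision tree DT, random forest
RF, k-nearest neighbours KNN, support vector machine SVM, Gaussian naive
Bayes GM) times three descriptor spaces (FGP, DSC, FUS) — giving 15 models
per target.  Before fitting, the majority class of the training portion is
undersampled by k-means clustering (k equal to the minority count, one
representative drawn per cluster) so that every training set is exactly
balanced.  Each fitted model carries a distance-based applicability domain:
a query compound outside it is still scored, but its prediction is flagged
as unreliable.

The central estimator, :class:`TargetClassifier`, follows the scikit-learn
fit/predict contract and composes with pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cluster import KMeans
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .curation import ACTIVE, INACTIVE
from .featurization import DSC_LENGTH, FGP_BITS, KINDS

ALGORITHMS = ("DT", "RF", "KNN", "SVM", "GM")

#: algorithms whose decision rule depends on inter-point distances and
#: therefore require standardized continuous features.
_DISTANCE_BASED = {"KNN", "SVM"}


@dataclass
class TargetDataset:
    """Feature matrix, labels and compound IDs for one target in one descriptor space."""

    target_id: str
    X: np.ndarray
    y: np.ndarray  # strings, "active"/"inactive"
    compound_ids: list[str]
    kind: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count does not match label count")
        if len(set(self.y)) < 2:
            raise ValueError(f"target {self.target_id}: both classes must be present")

    def subset(self, idx) -> "TargetDataset":
        idx = np.asarray(idx)
        return TargetDataset(
            self.target_id,
            self.X[idx],
            self.y[idx],
            [self.compound_ids[i] for i in idx],
            self.kind,
        )


def _scaler_for(kind: str):
    """Standardize continuous descriptors only; binary bits already share a scale.

    For DSC the whole matrix is standardized; for FUS only the descriptor
    block (columns beyond the fingerprint) is, the bit block passing
    through untouched; FGP needs no scaling.
    """
    if kind == "DSC":
        return StandardScaler()
    if kind == "FUS":
        return ColumnTransformer(
            [("dsc", StandardScaler(), slice(FGP_BITS, FGP_BITS + DSC_LENGTH))],
            remainder="passthrough",
        )
    return "passthrough"


def _base_estimator(algorithm: str, kind: str, seed: int):
    """Frozen default hyperparameters per algorithm; no feature selection anywhere."""
    if algorithm == "DT":
        est = DecisionTreeClassifier(random_state=seed)
    elif algorithm == "RF":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif algorithm == "KNN":
        est = KNeighborsClassifier(n_neighbors=5)
    elif algorithm == "SVM":
        # Platt sigmoid fitted on training folds maps the SVM margin onto a
        # probability, putting it on the same [0, 1] scale as the others.
        est = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False)
    elif algorithm == "GM":
        est = GaussianNB()
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if algorithm in _DISTANCE_BASED:
        return Pipeline([("scale", _scaler_for(kind)), ("clf", est)])
    return est


# ---------------------------------------------------------------------------
# Class balancing


def balance_by_clustering(majority_features, n_minority: int, seed: int) -> np.ndarray:
    """Pick ``n_minority`` diverse rows of the majority class.

    The majority class is partitioned into ``n_minority`` k-means clusters
    and one member is drawn at random from each, so the retained subset
    spreads over the chemical space of the majority class instead of being
    a blind random sample.  Deterministic given ``seed``.
    """
    X = np.asarray(majority_features, dtype=float)
    n_major = X.shape[0]
    if n_minority > n_major:
        raise ValueError(
            f"cannot select {n_minority} rows from a majority class of {n_major}"
        )
    if n_minority == n_major:
        return np.arange(n_major)
    km = KMeans(n_clusters=n_minority, random_state=seed, n_init=10)
    assign = km.fit_predict(X)
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(n_minority):
        members = np.flatnonzero(assign == c)
        if members.size == 0:  # pragma: no cover - sklearn repairs empty clusters
            continue
        if members.size == 1:
            chosen.append(int(members[0]))
        else:
            chosen.append(int(rng.choice(members)))
    return np.array(sorted(chosen))


def balance_dataset(ds: TargetDataset, seed: int) -> TargetDataset:
    """Undersample the majority class of a dataset to exact class balance."""
    y = ds.y
    n_act = int(np.sum(y == ACTIVE))
    n_inact = int(np.sum(y == INACTIVE))
    if n_act == n_inact:
        return ds
    major_label = ACTIVE if n_act > n_inact else INACTIVE
    n_minor = min(n_act, n_inact)
    major_idx = np.flatnonzero(y == major_label)
    minor_idx = np.flatnonzero(y != major_label)
    keep_major = major_idx[balance_by_clustering(ds.X[major_idx], n_minor, seed)]
    keep = np.sort(np.concatenate([minor_idx, keep_major]))
    return ds.subset(keep)


def make_split(
    ds: TargetDataset, test_fraction: float = 0.30, seed: int = 0
) -> tuple[TargetDataset, TargetDataset]:
    """Stratified train/holdout split; test size = floor(n * fraction).

    Balancing is *not* applied here: it belongs to the training portion only,
    after the split, so the holdout keeps the natural class ratio.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = ds.X.shape[0]
    n_test = int(np.floor(n * test_fraction))
    n_test = max(n_test, 2)  # stratification needs one per class
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=ds.y
    )
    train, test = ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))
    return train, test


# ---------------------------------------------------------------------------
# Applicability domain


class ADRegion:
    """Distance-to-centroid applicability domain for one descriptor space.

    The threshold is ``mean + k * SD`` of the training compounds' distances
    to their centroid.  For binary fingerprints (FGP) the centroid is the
    per-bit majority vote (ties broken toward 0) and the distance is
    Hamming; for continuous descriptors (DSC) features are standardized
    with the training mean/SD and the distance is Euclidean.  The fused
    space (FUS) stores both sub-regions and a point is inside only when it
    is inside both simultaneously.
    """

    def __init__(self, kind: str, k: float = 3.0):
        if kind not in KINDS:
            raise ValueError(f"unknown descriptor kind {kind!r}")
        self.kind = kind
        self.k = k

    def fit(self, X: np.ndarray) -> "ADRegion":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit an applicability domain on no compounds")
        if self.kind == "FUS":
            self.fgp_ = ADRegion("FGP", self.k).fit(X[:, :FGP_BITS])
            self.dsc_ = ADRegion("DSC", self.k).fit(X[:, FGP_BITS:])
            self.n_features_ = X.shape[1]
            return self
        if self.kind == "FGP":
            # majority-vote binary centroid; exact ties (mean == 0.5) -> 0
            self.centroid_ = (X.mean(axis=0) > 0.5).astype(float)
        else:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            self.centroid_ = np.zeros(X.shape[1])  # centroid in standardized space
        d = self._distances(X)
        self.threshold_ = float(d.mean() + self.k * d.std())
        self.n_features_ = X.shape[1]
        return self

    def _distances(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if hasattr(self, "n_features_") and X.shape[1] != self.n_features_:
            raise ValueError("dimension mismatch")
        if self.kind == "FGP":
            return np.abs(X - self.centroid_).sum(axis=1)
        Z = (X - self.mean_) / self.scale_
        return np.linalg.norm(Z, axis=1)

    def contains(self, x: np.ndarray) -> np.ndarray:
        """Boolean in-domain flag(s) for one vector or a matrix of query points."""
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        if x2.shape[1] != self.n_features_:
            raise ValueError(
                f"dimension mismatch: region expects {self.n_features_} features, "
                f"got {x2.shape[1]}"
            )
        if self.kind == "FUS":
            inside = self.fgp_.contains(x2[:, :FGP_BITS]) & self.dsc_.contains(
                x2[:, FGP_BITS:]
            )
        else:
            inside = self._distances(x2) <= self.threshold_
        return inside if np.ndim(x) > 1 else bool(inside[0])

    def to_dict(self) -> dict:
        if self.kind == "FUS":
            return {"kind": "FUS", "k": self.k,
                    "fgp": self.fgp_.to_dict(), "dsc": self.dsc_.to_dict()}
        d = {"kind": self.kind, "k": self.k, "threshold": self.threshold_}
        return d


def fit_ad(train_features: np.ndarray, kind: str, k: float = 3.0) -> ADRegion:
    """Fit a distance-based applicability domain on training features."""
    return ADRegion(kind, k).fit(train_features)


def in_ad(region: ADRegion, x: np.ndarray):
    """Whether a query vector lies inside the applicability domain."""
    return region.contains(x)


# ---------------------------------------------------------------------------
# The per-target estimator


class TargetClassifier(BaseEstimator, ClassifierMixin):
    """A single target-centric model: classifier plus applicability domain.

    Parameters
    ----------
    algorithm : {"DT", "RF", "KNN", "SVM", "GM"}, default="RF"
        Learning algorithm.  KNN and SVM are wrapped with a training-set
        standardizer because their decision rules are distance based.
    kind : {"FGP", "DSC", "FUS"}, default="FGP"
        Descriptor space of the input features; controls the applicability
        domain geometry.
    ad_k : float, default=3.0
        Multiplier in the AD threshold ``mean + ad_k * SD``.
    balance : bool, default=True
        Undersample the majority class by k-means clustering before fitting.
    random_state : int, default=0

    Attributes
    ----------
    classes_ : ndarray of str
        ``["active", "inactive"]`` order as seen by the underlying model.
    estimator_ : fitted scikit-learn classifier
    ad_ : ADRegion
        Fitted applicability domain over the (balanced) training compounds.
    """

    def __init__(
        self,
        algorithm: str = "RF",
        kind: str = "FGP",
        ad_k: float = 3.0,
        balance: bool = True,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.kind = kind
        self.ad_k = ad_k
        self.balance = balance
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if self.balance:
            ds = TargetDataset("_", X, y, [str(i) for i in range(len(y))], self.kind)
            ds = balance_dataset(ds, self.random_state)
            X, y = ds.X, ds.y
        est = _base_estimator(self.algorithm, self.kind, self.random_state)
        self.estimator_ = clone(est).fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.ad_ = ADRegion(self.kind, self.ad_k).fit(X)
        self.n_features_in_ = X.shape[1]
        self.n_train_ = X.shape[0]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = check_array(X, dtype=float)
        return self.estimator_.predict_proba(X)

    def predict_proba_active(self, X) -> np.ndarray:
        """Probability of the active class, shape (n_samples,)."""
        proba = self.predict_proba(X)
        col = int(np.flatnonzero(self.classes_ == ACTIVE)[0])
        return proba[:, col]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = check_array(X, dtype=float)
        return self.estimator_.predict(X)

    def in_ad(self, X) -> np.ndarray:
        check_is_fitted(self, "ad_")
        return self.ad_.contains(np.atleast_2d(np.asarray(X, dtype=float)))


@dataclass
class TrainedTCM:
    """A fitted target-centric model bundled with its provenance."""

    target_id: str
    kind: str
    algorithm: str
    model: TargetClassifier
    seed: int
    n_train: int
    n_test: int
    class_counts: dict
    holdout_metrics: dict

    @property
    def model_id(self) -> str:
        return f"{self.target_id}:{self.kind}_{self.algorithm}"

    def manifest(self) -> dict:
        return {
            "target_id": self.target_id,
            "kind": self.kind,
            "algorithm": self.algorithm,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "class_counts": self.class_counts,
            "holdout_metrics": self.holdout_metrics,
            "ad": self.model.ad_.to_dict(),
        }


def train_tcm(
    train: TargetDataset,
    algorithm: str,
    seed: int = 0,
    test: TargetDataset | None = None,
    ad_k: float = 3.0,
    balance: bool = True,
) -> TrainedTCM:
    """Fit one target-centric model on an already-split training set.

    When a holdout set is supplied, the f1-score (harmonic mean of
    precision and recall, computed on the active class) and accuracy on it
    are stored in the model metadata.
    """
    clf = TargetClassifier(
        algorithm=algorithm, kind=train.kind, ad_k=ad_k,
        balance=balance, random_state=seed,
    ).fit(train.X, train.y)
    metrics: dict = {}
    n_test = 0
    if test is not None:
        pred = clf.predict(test.X)
        metrics["f1"] = float(f1_score(test.y, pred, pos_label=ACTIVE))
        metrics["accuracy"] = float(np.mean(pred == test.y))
        n_test = test.X.shape[0]
    y = train.y
    return TrainedTCM(
        target_id=train.target_id,
        kind=train.kind,
        algorithm=algorithm,
        model=clf,
        seed=seed,
        n_train=clf.n_train_,
        n_test=n_test,
        class_counts={
            ACTIVE: int(np.sum(y == ACTIVE)),
            INACTIVE: int(np.sum(y == INACTIVE)),
        },
        holdout_metrics=metrics,
    )


# ---------------------------------------------------------------------------
# Prediction profiles


@dataclass
class PredictionEntry:
    """One model's prediction for one compound: target, probability, AD flag."""

    target_id: str
    model_id: str
    kind: str
    algorithm: str
    p_active: float
    in_ad: bool


@dataclass
class CompoundProfile:
    """All per-target predictions for one query compound."""

    compound_id: str
    entries: list[PredictionEntry]

    def __len__(self):
        return len(self.entries)


def predict_profile(
    compound_id: str,
    features_by_kind: dict[str, np.ndarray],
    models: list[TrainedTCM],
) -> CompoundProfile:
    """Score one compound against a panel of trained models.

    ``features_by_kind`` maps each descriptor kind appearing among the
    models to that compound's feature vector.  Out-of-domain predictions
    are flagged, never suppressed.
    """
    entries: list[PredictionEntry] = []
    for tcm in models:
        if tcm.kind not in features_by_kind:
            raise ValueError(
                f"model {tcm.model_id} needs descriptor kind {tcm.kind}, "
                f"but only {sorted(features_by_kind)} were provided"
            )
        x = np.atleast_2d(np.asarray(features_by_kind[tcm.kind], dtype=float))
        p = float(tcm.model.predict_proba_active(x)[0])
        inside = bool(tcm.model.in_ad(x)[0])
        entries.append(
            PredictionEntry(
                target_id=tcm.target_id,
                model_id=tcm.model_id,
                kind=tcm.kind,
                algorithm=tcm.algorithm,
                p_active=p,
                in_ad=inside,
            )
        )
    return CompoundProfile(compound_id=compound_id, entries=entries)


# ---------------------------------------------------------------------------
# Persistence


def save_models(models: list[TrainedTCM], out_dir) -> None:
    """One joblib file per model plus a JSON manifest for the whole panel."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tcm in models:
        fname = tcm.model_id.replace(":", "__") + ".joblib"
        joblib.dump(tcm, out / fname)
        entry = tcm.manifest()
        entry["file"] = fname
        manifest.append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_models(model_dir) -> list[TrainedTCM]:
    from pathlib import Path

    model_dir = Path(model_dir)
    with open(model_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return [joblib.load(model_dir / entry["file"]) for entry in manifest]
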