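"""Biomarker assembly and cross-validated alertness-outcome classification.

The feature vector collects the statistically significant network metrics:
per-channel node strength and local efficiency in the late windows of the
alpha and beta bands, global clustering coefficient, and the multilayer
modularity Q — 22 features in the default specification.  Trials of the
two alert-state outcomes (collision vs no collision) are classified with
stratified k-fold cross-validation; standardization is fit inside each
training fold so no test information leaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE1_BIOMARKERS",
    "MULTILAYER_METRICS",
    "FeatureMatrix",
    "CVReport",
    "assemble_features",
    "crossval_evaluate",
    "ablation_singlelayer",
    "embed_2d",
]

#: Metrics computed on the multi-layer network (dropped in the
#: single-layer-only ablation).
MULTILAYER_METRICS = ("Q", "MPC")

#: Default biomarker specification: the significant metric cells.  Entries
#: with ``channels=None`` contribute one global scalar.  ``window=None``
#: marks whole-epoch (multi-layer) metrics.
TABLE1_BIOMARKERS = [
    {"band": "alpha", "window": None, "metric": "Q", "channels": None},
    {"band": "alpha", "window": 4, "metric": "NS",
     "channels": ["Pz", "P4", "T6", "FT7", "CP4"]},
    {"band": "alpha", "window": 4, "metric": "E-loc",
     "channels": ["Fp1", "P3", "P4", "T6", "CP4", "CPz"]},
    {"band": "alpha", "window": 4, "metric": "CC", "channels": None},
    {"band": "beta", "window": 5, "metric": "NS",
     "channels": ["F3", "Fz", "C4", "CP3", "CP4"]},
    {"band": "beta", "window": 5, "metric": "E-loc",
     "channels": ["F3", "P3", "FC4"]},
    {"band": "beta", "window": 5, "metric": "CC", "channels": None},
]

#: Positive class for sensitivity/precision: the collision outcome.
POSITIVE_CLASS = "AS-CE"
NEGATIVE_CLASS = "AS-NC"

_CLASSIFIERS = {
    "svm-linear": lambda seed: SVC(kernel="linear", C=1.0, random_state=seed),
    "svm-rbf": lambda seed: SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed),
    "rf": lambda seed: RandomForestClassifier(n_estimators=500, random_state=seed),
    "knn-3": lambda seed: KNeighborsClassifier(n_neighbors=3),
}


@dataclass
class FeatureMatrix:
    """Trials x features table with class labels and per-column provenance."""

    X: pd.DataFrame
    labels: np.ndarray
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.X):
            raise ValueError("labels length must match row count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def drop_metrics(self, metrics: tuple[str, ...]) -> "FeatureMatrix":
        keep = [
            c for c in self.X.columns
            if self.provenance.get(c, {}).get("metric") not in metrics
        ]
        return FeatureMatrix(
            self.X[keep].copy(), self.labels.copy(),
            {c: self.provenance[c] for c in keep if c in self.provenance},
        )


@dataclass
class CVReport:
    """Per-fold and mean classification scores from stratified k-fold CV."""

    classifier: str
    seed: int
    fold_assignment: np.ndarray
    accuracy: list[float]
    sensitivity: list[float]
    specificity: list[float]
    precision: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.mean_accuracy,
            "sensitivity": self.mean_sensitivity,
            "specificity": self.mean_specificity,
            "precision": self.mean_precision,
        }


def _column_name(band: str, window, metric: str, channel: str) -> str:
    w = f"W{window}" if window is not None else "ALL"
    return f"{band}_{w}_{metric}_{channel}"


def assemble_features(
    metrics: pd.DataFrame, spec: list[dict] | None = None
) -> FeatureMatrix:
    """Pivot a long-form metric table into a trials x features matrix.

    ``metrics`` must hold per-trial rows for both alert-state outcomes with
    columns condition/band/window/trial/channel/metric/value; whole-epoch
    multi-layer metrics (Q, MPC) use window -1 and channel ``"GLOBAL"``.
    ``spec`` defaults to the 22-feature biomarker list.
    """
    if spec is None:
        spec = TABLE1_BIOMARKERS
    if not spec:
        raise ValueError("empty biomarker specification")
    table = metrics[metrics["condition"].isin([POSITIVE_CLASS, NEGATIVE_CLASS])]
    known_channels = set(table["channel"].unique())

    trials = (
        table[["condition", "trial"]]
        .drop_duplicates()
        .sort_values(["condition", "trial"])
        .reset_index(drop=True)
    )
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    for entry in spec:
        band, window, metric = entry["band"], entry["window"], entry["metric"]
        channels = entry["channels"] if entry["channels"] is not None else ["GLOBAL"]
        win_val = -1 if window is None else window
        for ch in channels:
            if ch != "GLOBAL" and ch not in known_channels:
                raise ValueError(f"channel {ch!r} not present in the metric table")
            sel = table[
                (table["band"] == band)
                & (table["window"] == win_val)
                & (table["metric"] == metric)
                & (table["channel"] == ch)
            ]
            cell = sel.set_index(["condition", "trial"])["value"]
            vals = np.array(
                [
                    cell.get((row.condition, row.trial), np.nan)
                    for row in trials.itertuples()
                ]
            )
            name = _column_name(band, window, metric, ch)
            columns[name] = vals
            provenance[name] = {
                "band": band, "window": window, "metric": metric, "channel": ch,
            }
    X = pd.DataFrame(columns)
    X.insert(0, "_trial", trials["trial"])
    labels = trials["condition"].to_numpy()
    X = X.drop(columns="_trial")
    return FeatureMatrix(X, labels, provenance)


def crossval_evaluate(
    fm: FeatureMatrix, classifier: str = "svm-linear", k: int = 5, seed: int = 0
) -> CVReport:
    """Stratified k-fold cross-validation with in-fold standardization.

    Sensitivity is recall of the collision class (AS-CE), specificity the
    recall of the no-collision class, precision the positive predictive
    value of collision calls.  The same seed always yields the same folds
    and report.
    """
    if classifier not in _CLASSIFIERS:
        raise ValueError(
            f"unknown classifier {classifier!r}; options: {sorted(_CLASSIFIERS)}"
        )
    y = fm.labels
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(
            f"every class needs at least k={k} trials "
            f"(have {counts.to_dict()}); use a smaller k"
        )
    X = fm.X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(y), -1)
    acc, sens, spec, prec = [], [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = fold
        model = Pipeline(
            [("scale", StandardScaler()), ("clf", _CLASSIFIERS[classifier](seed))]
        )
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        truth = y[te]
        tp = np.sum((pred == POSITIVE_CLASS) & (truth == POSITIVE_CLASS))
        tn = np.sum((pred == NEGATIVE_CLASS) & (truth == NEGATIVE_CLASS))
        fp = np.sum((pred == POSITIVE_CLASS) & (truth == NEGATIVE_CLASS))
        fn = np.sum((pred == NEGATIVE_CLASS) & (truth == POSITIVE_CLASS))
        acc.append((tp + tn) / len(truth))
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
    return CVReport(classifier, seed, fold_assignment, acc, sens, spec, prec)


def ablation_singlelayer(
    metrics_or_fm, classifier: str = "svm-linear", k: int = 5, seed: int = 0
) -> CVReport:
    """Re-run the classification without multi-layer features.

    Accepts a long-form metric table or a prebuilt :class:`FeatureMatrix`;
    the multilayer metric columns (Q, MPC) are dropped and the identical CV
    protocol is applied.
    """
    fm = (
        metrics_or_fm
        if isinstance(metrics_or_fm, FeatureMatrix)
        else assemble_features(metrics_or_fm)
    )
    return crossval_evaluate(fm.drop_metrics(MULTILAYER_METRICS), classifier, k, seed)


def embed_2d(fm: FeatureMatrix, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of the standardized feature matrix.

    Perplexity is auto-reduced (with a warning) when there are too few
    trials for the requested value.  Returned purely for visualization; no
    cluster-quality claims are attached.
    """
    X = fm.X.to_numpy(dtype=float)
    n = len(X)
    if n < 5:
        raise ValueError("need at least 5 trials for a 2-D embedding")
    max_perp = (n - 1) / 3.0
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} trials; using {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    Xs = StandardScaler().fit_transform(X)
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(Xs)
    return np.asarray(emb)
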