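"""Cell-type assignment: correlation model, classifier, transfer, consensus.

Three independent voices assign a type to each cell or cluster:

* **CAM** (correlation assignment model): Pearson correlation of a cell's
  marker profile against each reference cell-type profile.  The type with
  the highest r above a threshold is assigned; when the top two r values
  lie within ``double_gap`` the cell receives a hyphenated double label
  (best type first, e.g. ``neurons-NPC``), capturing intermediate states.
  Because Pearson correlation is invariant to positive affine transforms,
  raw-scale cells can be compared directly against the [0, 1] reference.
* **RFM**: a random-forest classifier grid-searched by cross-validation
  on an annotated training set.
* **Label transfer**: a kNN vote in the reference data's PCA space, a
  deliberate simplification of anchor-based transfer; the query is
  projected with the reference's scaling and rotation.

Per-cluster frequency tables and a modal consensus combine the voices;
the final annotation applies a user-editable cluster -> label mapping so
expert override stays first-class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .events import EventTable
from .reference import ReferenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CamParams",
    "RfmConfig",
    "critical_r",
    "find_correlation",
    "rfm_train",
    "rfm_predict",
    "transfer_labels",
    "get_annotation",
    "annotate_df",
    "annotate",
]

UNASSIGNED = "unassigned"


def critical_r(n_markers: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson r at significance ``alpha``.

    With ``n`` paired observations (markers) the correlation significance
    test has ``n - 2`` degrees of freedom and the critical value is
    ``t / sqrt(t^2 + n - 2)`` where ``t`` is the two-tailed t quantile.
    For a 13-marker panel at alpha 0.05 this is 0.553: smaller r values
    cannot be distinguished from no correlation.
    """
    if n_markers < 3:
        raise ValueError("n_markers must be >= 3 (df = n - 2 must be positive)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_markers - 2
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(t**2 + df))


# ----------------------------------------------------------------------
# CAM
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CamParams:
    """Assignment thresholds for the correlation model.

    ``min_corr`` is the minimum best-correlation for a cell to be
    assigned (0.553 is the 13-marker significance threshold; 0.1 assigns
    nearly everything); ``double_gap`` is the maximum difference between
    the best and second-best r for a combined double label.
    """

    min_corr: float = 0.553
    double_gap: float = 0.05

    def __post_init__(self) -> None:
        if not -1 <= self.min_corr <= 1:
            raise ValueError("min_corr must be in [-1, 1]")
        if self.double_gap < 0:
            raise ValueError("double_gap must be >= 0")


def find_correlation(
    events: EventTable,
    ref: ReferenceMatrix,
    params: CamParams | None = None,
) -> pd.DataFrame:
    """Per-cell Pearson correlation against every reference profile.

    Returns a frame with columns ``cam_label``, ``cam_r_best``,
    ``cam_r_second``, ``cam_best_type``, ``cam_second_type`` and
    ``cam_flag`` (``zero_variance`` for degenerate cells, ``negative_r``
    when the winning correlation is negative but above ``min_corr``).
    """
    params = params or CamParams()
    shared = [m for m in events.markers if m in ref.markers]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared markers between events and reference, got {len(shared)}"
        )
    if len(shared) < 5:
        warnings.warn(
            f"only {len(shared)} shared markers; correlations will be noisy"
        )
    X = events.intensities[:, [events.marker_index(m) for m in shared]]
    R = ref.values[shared].to_numpy()  # (T, m)
    types = np.asarray(ref.cell_types)

    def standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        sd = np.where(sd > 0, sd, 1.0)
        return (A - mu) / sd, ok

    Xs, x_ok = standardize(X)
    Rs, r_ok = standardize(R)
    if not r_ok.all():
        raise ValueError(
            "reference rows with zero variance over shared markers: "
            + ", ".join(types[~r_ok])
        )
    corr = (Xs @ Rs.T) / len(shared)  # (n, T) Pearson r

    order = np.argsort(-corr, axis=1)
    best, second = order[:, 0], order[:, 1]
    r_best = corr[np.arange(len(corr)), best]
    r_second = corr[np.arange(len(corr)), second]

    labels = np.where(
        r_best < params.min_corr,
        UNASSIGNED,
        np.where(
            (r_best - r_second) <= params.double_gap,
            np.char.add(np.char.add(types[best].astype(str), "-"), types[second].astype(str)),
            types[best].astype(str),
        ),
    )
    flags = np.where(~x_ok, "zero_variance", np.where((r_best < 0) & (labels != UNASSIGNED), "negative_r", ""))
    labels = np.where(x_ok, labels, UNASSIGNED)
    return pd.DataFrame(
        {
            "cam_label": labels,
            "cam_r_best": np.where(x_ok, r_best, np.nan),
            "cam_r_second": np.where(x_ok, r_second, np.nan),
            "cam_best_type": np.where(x_ok, types[best], None),
            "cam_second_type": np.where(x_ok, types[second], None),
            "cam_flag": flags,
        }
    )


# ----------------------------------------------------------------------
# random-forest classifier
# ----------------------------------------------------------------------

@dataclass
class RfmConfig:
    """Grid and validation settings for the random-forest model.

    The default grid matches the common practice for this workflow:
    features per split 5-7, 1500/1800/2000 trees and a 15-18 cap on leaf
    nodes per tree, 80/20 stratified train/holdout split, 3-fold CV on the
    training side.
    """

    features_per_split: Sequence[int] = (5, 6, 7)
    n_trees: Sequence[int] = (1500, 1800, 2000)
    max_nodes: Sequence[int] = (15, 16, 17, 18)
    cv_folds: int = 3
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class RfmModel:
    classifier: RandomForestClassifier
    markers: list[str]
    classes: list[str]
    best_params: dict
    holdout_accuracy: float
    cv_table: pd.DataFrame


def rfm_train(
    events: EventTable,
    labels: Sequence[str],
    config: RfmConfig | None = None,
) -> RfmModel:
    """Grid-searched random forest on annotated events.

    Stratified 80/20 split; the grid is searched by ``cv_folds``-fold CV
    on the training side; the best model is refit and scored on the
    holdout.  "Max nodes" caps the leaf count of each tree.
    """
    config = config or RfmConfig()
    y = np.asarray(labels)
    if len(y) != events.n_events:
        raise ValueError("labels length does not match events")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    small = classes[counts < config.cv_folds]
    if small.size:
        raise ValueError(
            "classes with fewer members than cv_folds: " + ", ".join(map(str, small))
        )
    X = events.intensities
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X,
        y,
        test_size=config.holdout_fraction,
        stratify=y,
        random_state=config.seed,
    )
    grid = {
        "max_features": [min(f, X.shape[1]) for f in config.features_per_split],
        "n_estimators": list(config.n_trees),
        "max_leaf_nodes": list(config.max_nodes),
    }
    search = GridSearchCV(
        RandomForestClassifier(random_state=config.seed),
        grid,
        cv=StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed),
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    best = search.best_estimator_
    acc = float(best.score(X_ho, y_ho))
    cv_table = pd.DataFrame(search.cv_results_)[
        ["param_max_features", "param_n_estimators", "param_max_leaf_nodes", "mean_test_score"]
    ]
    return RfmModel(
        classifier=best,
        markers=list(events.markers),
        classes=list(best.classes_),
        best_params=dict(search.best_params_),
        holdout_accuracy=acc,
        cv_table=cv_table,
    )


def rfm_predict(model: RfmModel, events: EventTable) -> pd.DataFrame:
    """Predict labels and class probabilities for new events."""
    missing = [m for m in model.markers if m not in events.markers]
    if missing:
        raise ValueError("events are missing model markers: " + ", ".join(missing))
    X = events.intensities[:, [events.marker_index(m) for m in model.markers]]
    proba = model.classifier.predict_proba(X)
    labels = np.asarray(model.classes)[proba.argmax(axis=1)]
    out = pd.DataFrame({"rfm_label": labels})
    for i, c in enumerate(model.classes):
        out[f"p_{c}"] = proba[:, i]
    return out


# ----------------------------------------------------------------------
# kNN label transfer in reference PCA space
# ----------------------------------------------------------------------

def transfer_labels(
    reference_events: EventTable,
    reference_labels: Sequence[str],
    query: EventTable,
    k: int = 10,
    n_components: int = 12,
) -> pd.DataFrame:
    """Label the query by an inverse-distance kNN vote in reference PCA space.

    The reference is z-scored and decomposed by PCA; the query is projected
    with the *reference's* scaling and rotation so both live in the same
    space.  This is a deliberate simplification of anchor-based label
    transfer and is validated by planted-label recovery, not by
    equivalence to any anchor implementation.
    """
    y = np.asarray(reference_labels)
    if len(y) != reference_events.n_events:
        raise ValueError("reference_labels length does not match reference_events")
    if k > reference_events.n_events:
        raise ValueError("k exceeds the number of reference events")
    shared = [m for m in reference_events.markers if m in query.markers]
    if len(shared) < 2:
        raise ValueError("need >= 2 shared markers for transfer")
    Xr = reference_events.intensities[:, [reference_events.marker_index(m) for m in shared]]
    Xq = query.intensities[:, [query.marker_index(m) for m in shared]]
    scaler = StandardScaler().fit(Xr)
    pca = PCA(n_components=min(n_components, len(shared))).fit(scaler.transform(Xr))
    Pr = pca.transform(scaler.transform(Xr))
    Pq = pca.transform(scaler.transform(Xq))

    nn = NearestNeighbors(n_neighbors=k).fit(Pr)
    dist, idx = nn.kneighbors(Pq)
    w = 1.0 / np.maximum(dist, 1e-12)
    classes = np.unique(y)
    class_idx = {c: i for i, c in enumerate(classes)}
    votes = np.zeros((len(Pq), len(classes)))
    neigh_class = np.vectorize(class_idx.get)(y[idx])
    for j in range(k):
        np.add.at(votes, (np.arange(len(Pq)), neigh_class[:, j]), w[:, j])
    votes /= votes.sum(axis=1, keepdims=True)
    win = votes.argmax(axis=1)
    return pd.DataFrame(
        {
            "transfer_label": classes[win],
            "transfer_score": votes[np.arange(len(Pq)), win],
        }
    )


# ----------------------------------------------------------------------
# per-cluster summaries, consensus and final annotation
# ----------------------------------------------------------------------

def get_annotation(
    labels: Sequence[str],
    clusters: Sequence,
    top_n: int = 3,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Most frequent labels per cluster for one method.

    Returns one row per cluster with the top label and its frequency plus
    the ``top_n`` ranked labels.  Unassigned cells are excluded from the
    frequencies by default.  Exact frequency ties break alphabetically and
    raise the ``tie`` flag.
    """
    df = pd.DataFrame({"label": np.asarray(labels), "cluster": np.asarray(clusters)})
    if not include_unassigned:
        df = df[df["label"] != UNASSIGNED]
    rows = []
    for cl in pd.unique(np.asarray(clusters)):
        sub = df[df["cluster"] == cl]
        if sub.empty:
            rows.append(dict(cluster=cl, top_label=UNASSIGNED, frequency=0.0,
                             top_labels="", tie=False))
            continue
        freq = sub["label"].value_counts(normalize=True)
        # alphabetical tie-break within equal frequencies
        freq = freq.sort_index().sort_values(ascending=False, kind="stable")
        top = freq.index[0]
        tie = len(freq) > 1 and np.isclose(freq.iloc[0], freq.iloc[1])
        rows.append(
            dict(
                cluster=cl,
                top_label=top,
                frequency=float(freq.iloc[0]),
                top_labels=";".join(freq.index[:top_n]),
                tie=bool(tie),
            )
        )
    return pd.DataFrame(rows)


def annotate_df(
    method_labels: Mapping[str, Sequence[str]],
    clusters: Sequence,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Combine per-method per-cluster top labels into one consensus table.

    The consensus is the modal label across methods; full (1-1-1 style)
    disagreement breaks alphabetically and is flagged for expert review.
    """
    if not method_labels:
        raise ValueError("no method label tables supplied")
    per_method = {
        name: get_annotation(lab, clusters, include_unassigned=include_unassigned)
        .set_index("cluster")["top_label"]
        for name, lab in method_labels.items()
    }
    table = pd.DataFrame(per_method)
    consensus, flags = [], []
    for _, row in table.iterrows():
        counts = row.value_counts()
        counts = counts.sort_index().sort_values(ascending=False, kind="stable")
        consensus.append(counts.index[0])
        flags.append(len(counts) > 1 and counts.iloc[0] == counts.iloc[1])
    table["consensus"] = consensus
    table["review"] = flags
    return table.reset_index().rename(columns={"index": "cluster"})


def annotate(
    events: EventTable,
    clusters: Sequence,
    mapping: Mapping,
    column: str = "final_label",
) -> EventTable:
    """Apply a cluster -> label mapping as the final per-cell annotation.

    The mapping is user-editable: expert overrides of the consensus are
    expected.  Unmapped clusters are an error listing the cluster ids.
    """
    clusters = np.asarray(clusters)
    unmapped = sorted({c for c in pd.unique(clusters) if c not in mapping})
    if unmapped:
        raise KeyError(f"clusters without a label mapping: {unmapped}")
    labels = np.array([mapping[c] for c in clusters], dtype=object)
    out = events.with_obs("cluster", clusters)
    return out.with_obs(column, labels)
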