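"""Unsupervised cell-type classification for MEC units.

Each unit is summarized by 11 features — seven from its firing-rate map
(spatial information, border score, total field area, in-field mean rate,
in-field peak rate, out-of-field mean rate, overall mean rate) and four from
its spatial autocorrelogram (grid score and the first three principal
components of the autocorrelogram population).  Features are z-scored
within a dataset, embedded in two dimensions with UMAP, clustered with
DBSCAN, and the resulting clusters are assigned cell types from their mean
z-scored profiles: the top grid-score cluster is ``grid``, the top
border-score cluster ``border``, the cluster with high firing rate and low
spatial information ``interneuron``, the high-SI low-grid cluster
``aperiodic_spatial``; anything left is ``undefined`` and DBSCAN noise
points stay ``noise``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from . import gridborder, maps

__all__ = [
    "FEATURE_ORDER",
    "FeatureTable",
    "ClusterAssignment",
    "CellTypeClassifier",
    "extract_features",
    "normalize_features",
    "embed_and_cluster",
    "label_clusters",
    "AmbiguousLabelingError",
]

#: Fixed, versioned feature order; changing it is a breaking change.
FEATURE_ORDER = (
    "si", "border_score", "field_area", "infield_mfr", "infield_peak",
    "outfield_mfr", "mfr", "grid_score", "pc1", "pc2", "pc3",
)


class AmbiguousLabelingError(RuntimeError):
    """Two clusters tie on the statistic that decides a cell-type label."""


@dataclass
class FeatureTable:
    """Per-unit 11-feature matrix plus imputation flags."""

    features: pd.DataFrame  # index = unit ids, columns = FEATURE_ORDER
    imputed: pd.DataFrame  # boolean, same shape


@dataclass
class ClusterAssignment:
    unit_ids: list[str]
    cluster_ids: np.ndarray  # -1 = noise
    cell_types: list[str] = dc_field(default_factory=list)
    embedding: np.ndarray | None = None
    cluster_profiles: pd.DataFrame | None = None


def extract_features(traj: maps.Trajectory,
                     spikes: dict[str, maps.SpikeTrain],
                     bin_size: float = 2.0, extent: float | None = None,
                     kernel_bins: int = 10) -> FeatureTable:
    """Compute the 11-entry feature vector for every unit of a session.

    Runs the full map / field / autocorrelogram chain per unit, then a
    population PCA of the autocorrelograms for pc1..pc3.  Undefined grid or
    border scores (silent or field-less units) are imputed to the dataset
    minimum of that feature and flagged.
    """
    if not spikes:
        raise ValueError("no units supplied")
    occ = maps.occupancy_map(traj, bin_size=bin_size, extent=extent)
    duration = traj.duration
    rows: dict[str, dict[str, float]] = {}
    acs: list[gridborder.Autocorrelogram] = []
    for uid, train in spikes.items():
        rmap = maps.rate_map(traj, train, kernel_bins=kernel_bins, occ=occ)
        fields = maps.detect_fields(rmap)
        metrics = maps.rate_metrics(rmap, fields, train, duration, occ=occ)
        ac = gridborder.spatial_autocorrelation(rmap)
        gs = gridborder.grid_score(ac)
        bs = gridborder.border_score(rmap, fields)
        acs.append(ac)
        rows[uid] = {
            "si": metrics.si,
            "border_score": bs.b,
            "field_area": metrics.field_area,
            "infield_mfr": metrics.infield_mfr,
            "infield_peak": metrics.infield_peak,
            "outfield_mfr": metrics.outfield_mfr,
            "mfr": metrics.mfr,
            "grid_score": gs.score,
        }
    scores, _ = gridborder.ac_principal_components(acs, k=3)
    for j, uid in enumerate(rows):
        rows[uid]["pc1"] = scores[j, 0]
        rows[uid]["pc2"] = scores[j, 1]
        rows[uid]["pc3"] = scores[j, 2]
    df = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_ORDER)]
    imputed = df.isna()
    for col in ("grid_score", "border_score"):
        if df[col].isna().any():
            fill = df[col].min()
            if np.isnan(fill):
                fill = 0.0
            df[col] = df[col].fillna(fill)
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"incomplete features after imputation: {missing}")
    return FeatureTable(features=df, imputed=imputed)


def normalize_features(features: pd.DataFrame) -> pd.DataFrame:
    """z-score each feature across the dataset; constant features dropped.

    Each dataset (recording cohort) is normalized independently — call this
    once per dataset, never on a pooled matrix.
    """
    if len(features) < 2:
        raise ValueError("cannot z-score a single-unit dataset")
    sd = features.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(features.columns[~keep])
        warnings.warn(f"constant features dropped: {dropped}")
    kept = features.loc[:, keep]
    return (kept - kept.mean(axis=0)) / sd[keep]


class CellTypeClassifier(ClusterMixin, BaseEstimator):
    """UMAP + DBSCAN cell-type classifier over z-scored unit features.

    Parameters
    ----------
    n_neighbors, min_dist : UMAP neighborhood size and packing (defaults
        15 and 0.1); 2-D embedding with a fixed ``random_state``.
    eps, min_samples : DBSCAN density parameters in the embedded space.
    normalize : z-score the feature matrix inside ``fit`` (set False when
        passing an already-normalized matrix).

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n_units, 2) UMAP coordinates.
    labels_ : DBSCAN cluster ids (-1 = noise).
    cell_types_ : per-unit type strings.
    cluster_profiles_ : mean z-scored SI / grid / border / MFR per cluster.
    """

    def __init__(self, n_neighbors: int = 15, min_dist: float = 0.1,
                 eps: float = 0.5, min_samples: int = 5,
                 normalize: bool = True, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.eps = eps
        self.min_samples = min_samples
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X, y=None):
        import umap

        if isinstance(X, FeatureTable):
            X = X.features
        df = pd.DataFrame(X)
        if len(df) < 10:
            raise ValueError("need at least 10 units for density clustering")
        Z = normalize_features(df) if self.normalize else df
        n_nb = min(self.n_neighbors, len(Z) - 1)
        reducer = umap.UMAP(n_neighbors=n_nb, min_dist=self.min_dist,
                            n_components=2, random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = reducer.fit_transform(Z.to_numpy())
        labels = DBSCAN(eps=self.eps,
                        min_samples=self.min_samples).fit_predict(emb)
        if np.all(labels == -1):
            raise RuntimeError(
                "all units labeled noise; consider a larger eps or a "
                "smaller min_samples")
        self.zmatrix_ = Z
        self.embedding_ = emb
        self.labels_ = labels
        self.cell_types_, self.cluster_profiles_ = _label_from_profiles(
            labels, Z)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# greedy rank-based anchor order; each rule names its deciding statistic
_LABEL_RULES = (
    ("grid", lambda p: p.get("grid_score", p["si"] * 0)),
    ("border", lambda p: p.get("border_score", p["si"] * 0)),
    ("interneuron", lambda p: p["mfr"] - p["si"]),
    ("aperiodic_spatial",
     lambda p: (p["si"] - p.get("grid_score", 0.0)
                - p.get("border_score", 0.0))),
)

_PROFILE_COLS = ("si", "grid_score", "border_score", "mfr")


def _label_from_profiles(labels: np.ndarray, Z: pd.DataFrame,
                         tie_tol: float = 1e-12,
                         undefined_distance: float = 2.5
                         ) -> tuple[list[str], pd.DataFrame]:
    """Cell types from cluster-mean z-profiles.

    One anchor cluster per type is picked by rank: highest mean grid score
    -> grid, highest border score -> border, highest (MFR - SI) ->
    interneuron, highest (SI - grid) -> aperiodic_spatial.  Density
    clustering can split one physiological type across several clusters, so
    each unanchored cluster inherits the type of the nearest anchor profile
    (Euclidean, in z-profile space) when within ``undefined_distance``;
    clusters resembling no anchor stay ``undefined``.
    """
    clusters = sorted(int(c) for c in np.unique(labels) if c != -1)
    cols = [c for c in _PROFILE_COLS if c in Z.columns]
    prof = pd.DataFrame(
        {c: [Z.loc[labels == k, c].mean() for k in clusters] for c in cols},
        index=clusters)
    type_of: dict[int, str] = {}
    remaining = list(clusters)
    for cell_type, stat in _LABEL_RULES:
        if not remaining:
            break
        vals = np.array([float(stat(prof.loc[k])) for k in remaining])
        order = np.argsort(vals)[::-1]
        if len(remaining) > 1 and abs(vals[order[0]] - vals[order[1]]) < tie_tol:
            raise AmbiguousLabelingError(
                f"clusters {remaining[order[0]]} and {remaining[order[1]]} "
                f"tie on the statistic deciding {cell_type!r}")
        type_of[remaining[order[0]]] = cell_type
        remaining.remove(remaining[order[0]])
    anchors = {k: t for k, t in type_of.items()}
    for k in remaining:
        dists = {t: float(np.linalg.norm(prof.loc[k] - prof.loc[a]))
                 for a, t in anchors.items()}
        best = min(dists, key=dists.get)
        type_of[k] = best if dists[best] <= undefined_distance else "undefined"
    cell_types = ["noise" if l == -1 else type_of[int(l)] for l in labels]
    prof.insert(0, "cell_type", [type_of[k] for k in clusters])
    return cell_types, prof


def embed_and_cluster(Z: pd.DataFrame, seed: int = 0,
                      **params) -> ClusterAssignment:
    """Functional wrapper: z-matrix in, cluster ids + embedding out."""
    clf = CellTypeClassifier(normalize=False, random_state=seed, **params)
    clf.fit(Z)
    return ClusterAssignment(unit_ids=list(pd.DataFrame(Z).index),
                             cluster_ids=clf.labels_,
                             cell_types=clf.cell_types_,
                             embedding=clf.embedding_,
                             cluster_profiles=clf.cluster_profiles_)


def label_clusters(assignment: ClusterAssignment,
                   Z: pd.DataFrame) -> ClusterAssignment:
    """Assign cell types to existing clusters from their z-scored profiles."""
    types, prof = _label_from_profiles(assignment.cluster_ids,
                                       pd.DataFrame(Z))
    assignment.cell_types = types
    assignment.cluster_profiles = prof
    return assignment


def classify_session(traj: maps.Trajectory,
                     spikes: dict[str, maps.SpikeTrain],
                     bin_size: float = 2.0, kernel_bins: int = 10,
                     seed: int = 0, **params) -> ClusterAssignment:
    """End-to-end pipeline: features -> z-score -> UMAP -> DBSCAN -> types."""
    table = extract_features(traj, spikes, bin_size=bin_size,
                             kernel_bins=kernel_bins)
    clf = CellTypeClassifier(random_state=seed, **params)
    clf.fit(table.features)
    return ClusterAssignment(unit_ids=list(table.features.index),
                             cluster_ids=clf.labels_,
                             cell_types=clf.cell_types_,
                             embedding=clf.embedding_,
                             cluster_profiles=clf.cluster_profiles_)
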