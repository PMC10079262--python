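"""Per-track feature matrices, embedding, clustering and range selection.

Features with incommensurate units (um/min vs degrees vs um^2) are
standardized by default before PCA or clustering; the unscaled mode is
retained for parity checks. Tracks with undefined (NaN) feature entries
are excluded from embeddings/clusterings with an explicit report, never
imputed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import TracksDataset
from .metrics import MeasureFn, get_measure
from .qc import filter_tracks

__all__ = [
    "FeatureMatrix", "feature_matrix",
    "track_feature_map", "cluster_tracks", "select_tracks",
]


@dataclass
class FeatureMatrix:
    """Tracks x measures matrix with recorded scaling metadata.

    ``values`` rows follow the dataset's (lexicographic) track order;
    ``center``/``scale`` record the per-column standardization so the
    transform is reproducible. Constant columns are centered and given a
    recorded scale of 0 (values left at 0 after centering).
    """

    ids: list[str]
    features: list[str]
    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    scaled: bool
    undefined_ids: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.features)

    def complete(self) -> "FeatureMatrix":
        """Rows with no undefined entries (what embeddings/clusterings use)."""
        keep = ~np.isnan(self.values).any(axis=1)
        return FeatureMatrix(
            ids=[i for i, k in zip(self.ids, keep) if k],
            features=self.features,
            values=self.values[keep],
            center=self.center,
            scale=self.scale,
            scaled=self.scaled,
            undefined_ids=[i for i, k in zip(self.ids, keep) if not k],
        )


def feature_matrix(
    dataset: TracksDataset,
    measures: dict[str, MeasureFn] | list[str],
    scale: bool = True,
) -> FeatureMatrix:
    """Evaluate named measures on every track.

    ``measures`` is either a list of registry names or a mapping
    name -> callable (the custom-measure extension point). With ``scale``,
    columns are standardized to mean 0 / sd 1.
    """
    if isinstance(measures, (list, tuple)):
        measures = {name: get_measure(name) for name in measures}
    if not measures:
        raise ValueError("need at least one measure")
    if dataset.n_tracks == 0:
        raise ValueError("empty dataset")
    ids = list(dataset)
    names = list(measures)
    vals = np.array([
        [float(measures[m](dataset[tid])) for m in names] for tid in ids
    ])
    undefined = [tid for tid, row in zip(ids, vals) if np.isnan(row).any()]
    center = np.zeros(len(names))
    scl = np.ones(len(names))
    if scale:
        center = np.nanmean(vals, axis=0)
        scl = np.nanstd(vals, axis=0, ddof=1) if len(ids) > 1 else np.ones(len(names))
        vals = vals - center
        nonconst = scl > 0
        vals[:, nonconst] /= scl[nonconst]
        scl = np.where(nonconst, scl, 0.0)
    return FeatureMatrix(ids, names, vals, center, scl, scale, undefined)


def _classical_mds(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic classical (Torgerson) MDS on Euclidean distances."""
    d2 = squareform(pdist(x)) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1][:k]
    lam = np.clip(lam[order], 0.0, None)
    return vec[:, order] * np.sqrt(lam)


def _fix_signs(components: np.ndarray, coords: np.ndarray):
    """Sign convention: largest-magnitude loading of each component positive."""
    for i, comp in enumerate(components):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            components[i] = -comp
            coords[:, i] = -coords[:, i]
    return components, coords


def track_feature_map(
    fm: FeatureMatrix, method: str = "pca", k: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Embed tracks into k dimensions from their feature matrix.

    Returns (coords, diagnostics). PCA is bit-reproducible: component
    signs are fixed so each component's largest-magnitude loading is
    positive; diagnostics carry explained-variance fractions and loadings.
    MDS is classical (Torgerson) scaling, also deterministic. Tracks with
    undefined features are excluded and listed in the diagnostics.
    """
    fm = fm.complete()
    if k > len(fm.features):
        raise ValueError(f"k={k} exceeds the {len(fm.features)} features")
    diagnostics: dict = {"method": method, "excluded": fm.undefined_ids}
    if method.lower() == "pca":
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(fm.values)
        comps, coords = _fix_signs(pca.components_, coords)
        diagnostics["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
        diagnostics["loadings"] = pd.DataFrame(
            comps, index=[f"PC{i + 1}" for i in range(k)], columns=fm.features
        )
        cols = [f"PC{i + 1}" for i in range(k)]
    elif method.lower() == "mds":
        coords = _classical_mds(fm.values, k)
        _, coords = _fix_signs(coords.T.copy(), coords)
        cols = [f"dim{i + 1}" for i in range(k)]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=fm.ids, columns=cols), diagnostics


def cluster_tracks(
    fm: FeatureMatrix,
    method: str = "hierarchical",
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.Series, dict]:
    """Cluster tracks in feature space.

    hierarchical: average-linkage agglomeration (deterministic; ties broken
    by the lexicographic id order of the rows). kmeans: best of
    ``n_restarts`` seeded restarts. Returns (labels indexed by id,
    diagnostics with the linkage tree or inertia plus the config used).
    """
    fm = fm.complete()
    n = len(fm.ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} usable tracks")
    diagnostics: dict = {
        "method": method, "k": k, "excluded": fm.undefined_ids,
        "seed": seed, "n_restarts": n_restarts,
    }
    if method == "hierarchical":
        link = hierarchy.linkage(fm.values, method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
        diagnostics["linkage"] = link
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(fm.values)
        diagnostics["inertia"] = float(km.inertia_)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=fm.ids, name="label"), diagnostics


def select_tracks(
    dataset: TracksDataset, measure: MeasureFn | str, lower: float, upper: float
) -> TracksDataset:
    """Tracks whose measure value lies in [lower, upper].

    Composable with any downstream analysis; disjoint ranges partition the
    tracks on which the measure is defined.
    """
    fn = get_measure(measure) if isinstance(measure, str) else measure
    return filter_tracks(dataset, measure=fn, lower=lower, upper=upper)
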