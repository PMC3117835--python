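"""Clustering and principal component analysis of stem-length profiles.

Each species is a point in stem-length space (one integer coordinate per
stem, in base pairs). K-means groups species by profile similarity; PCA on
the covariance of the centered — deliberately unscaled, since all variables
share the same unit — matrix identifies the stems contributing most
variance, and a biplot payload combines scores, loadings and cluster
assignments for any renderer. Partial sequences (rows containing ``~``) are
excluded from PCA by default because their stem lengths are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError, ValidationError
from .stems import StemLengthTable


@dataclass
class ClusterAssignment:
    """K-means result: species -> cluster id, with the achieved objective."""

    assignments: dict[str, int]
    k: int
    wcss: float  # within-cluster sum of squares of the best run


@dataclass
class PcaResult:
    """Loadings, scores and variance shares of a stem-length PCA."""

    loadings: pd.DataFrame  # stems x components, orthonormal columns
    scores: pd.DataFrame  # species x components
    explained_variance_ratio: np.ndarray
    top_stems: list[str]  # top-|loading| stem per component

    @property
    def first_two_share(self) -> float:
        return float(self.explained_variance_ratio[:2].sum())


def _imputed_matrix(table: StemLengthTable) -> pd.DataFrame:
    """Lengths with unknown cells imputed by the per-stem modal length."""
    filled = table.lengths.copy()
    for stem in table.stem_labels:
        modal = table.modal_length(stem)
        filled[stem] = filled[stem].fillna(0 if modal is None else modal)
    return filled


def kmeans_stems(
    table: StemLengthTable, k: int, seed: int = 0, restarts: int = 10
) -> ClusterAssignment:
    """K-means on stem-length profiles; best of ``restarts`` seeded runs.

    Unknown cells are imputed with the stem's modal length so every species
    can be assigned. Deterministic for a given seed.
    """
    X = _imputed_matrix(table)
    if k > len(X):
        raise ParameterError(f"k={k} exceeds the {len(X)} available species")
    if k < 1:
        raise ParameterError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X.to_numpy(dtype=float))
    return ClusterAssignment(
        assignments=dict(zip(X.index, (int(l) for l in labels))),
        k=k,
        wcss=float(km.inertia_),
    )


def wcss_profile(
    table: StemLengthTable, k_range=range(2, 9), seed: int = 0, restarts: int = 10
) -> pd.Series:
    """Within-cluster sum of squares across a range of k (elbow support)."""
    ks = [k for k in k_range if k <= len(table.species)]
    return pd.Series(
        {k: kmeans_stems(table, k, seed=seed, restarts=restarts).wcss for k in ks},
        name="wcss",
    )


def pca_stems(
    table: StemLengthTable, exclude_partial: bool = True, scale: bool = False
) -> PcaResult:
    """Covariance PCA of the stem-length matrix.

    Rows with unknown cells are dropped (PCA does not impute), as are
    partial sequences when ``exclude_partial`` is set. ``scale`` switches to
    correlation (autoscaled) PCA; the default centers only.
    """
    keep = ~table.unknown.any(axis=1)
    if exclude_partial:
        keep &= ~table.partial
    X = table.lengths[keep]
    if len(X) < 2:
        raise ParameterError("PCA needs at least 2 complete species rows")
    if len(X.columns) < 2:
        raise ParameterError("PCA needs at least 2 stems")
    if len(X) <= len(X.columns):
        import warnings

        warnings.warn(
            f"only {len(X)} sequences for {len(X.columns)} stems; "
            "components beyond n-1 are not estimable"
        )
    mat = X.to_numpy(dtype=float)
    if scale:
        sd = mat.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    if np.allclose(mat, mat.mean(axis=0)):
        raise ParameterError("degenerate table: no variance at all")

    pca = PCA()
    scores = pca.fit_transform(mat)
    n_comp = pca.n_components_
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    loadings = pd.DataFrame(
        pca.components_.T, index=X.columns, columns=comp_names
    )
    top = [loadings[c].abs().idxmax() for c in comp_names]
    return PcaResult(
        loadings=loadings,
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        top_stems=top,
    )


def biplot_data(
    pca: PcaResult,
    clusters: ClusterAssignment | None = None,
    outlier_radius: float = 2.5,
) -> dict:
    """Drawing-neutral biplot payload: points, loading arrows, outliers.

    Points carry the species' first-two-component scores and cluster class;
    arrows are per-stem loading vectors. A species is flagged as an outlier
    when its 2-D score distance from the score centroid exceeds
    ``outlier_radius`` times the root-mean-square distance.
    """
    species = list(pca.scores.index)
    cluster_of = {}
    if clusters is not None:
        missing = set(species) - set(clusters.assignments)
        if missing:
            raise ValidationError(
                f"species in PCA but not clustered: {sorted(missing)}"
            )
        cluster_of = clusters.assignments

    xy = pca.scores.iloc[:, :2].to_numpy()
    center = xy.mean(axis=0)
    dists = np.linalg.norm(xy - center, axis=1)
    rms = float(np.sqrt((dists**2).mean())) or 1.0
    outliers = [sp for sp, d in zip(species, dists) if d > outlier_radius * rms]

    points = [
        {
            "species": sp,
            "x": float(xy[i, 0]),
            "y": float(xy[i, 1]),
            "cluster": cluster_of.get(sp),
        }
        for i, sp in enumerate(species)
    ]
    arrows = [
        {
            "stem": stem,
            "dx": float(pca.loadings.iloc[r, 0]),
            "dy": float(pca.loadings.iloc[r, 1]) if pca.loadings.shape[1] > 1 else 0.0,
        }
        for r, stem in enumerate(pca.loadings.index)
    ]
    return {"points": points, "arrows": arrows, "outliers": outliers}
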