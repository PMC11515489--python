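"""Spectral clustering of an omics block with out-of-sample assignment.

Clustering is fit on training patients only; held-out patients receive a
label through a Nystrom extension of the spectral embedding, so the
test set never influences the discovered structure. This is the mechanism
that lets a cluster label act as a covariate in a prediction model
evaluated on held-out data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigError, DegenerateInputError
from .synthetic import OmicsBlock

logger = logging.getLogger(__name__)

#: eigengap below which `choose_k` reports no confident structure
_LOW_CONFIDENCE_GAP = 0.1


@dataclass
class ClusterModel:
    """Fitted spectral-clustering state supporting out-of-sample assignment.

    Holds everything the Nystrom extension needs: the standardization
    statistics, the standardized training matrix, the kernel bandwidth and
    training degrees, the top-k eigenpairs of the symmetric normalized
    affinity operator, the row-normalized training embedding and the
    k-means centroids in spectral space. Cluster indices are relabeled by
    descending cluster size, ties broken by the lower original index.
    """

    k: int
    bandwidth: float
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_points: np.ndarray        # standardized, n x p
    degrees: np.ndarray                # affinity row sums, n
    eigenvalues: np.ndarray            # top k, descending
    eigenvectors: np.ndarray           # n x k, columns match eigenvalues
    embedding: np.ndarray              # row-normalized eigenvector rows
    centroids: np.ndarray              # k x k in spectral space
    training_labels: np.ndarray        # int labels in [0, k)
    feature_space_centroids: np.ndarray  # k x p, fallback assignment targets
    label_map: dict[int, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "k": int(self.k),
            "bandwidth": float(self.bandwidth),
            "feature_names": self.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_points": self.training_points.tolist(),
            "degrees": self.degrees.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "embedding": self.embedding.tolist(),
            "centroids": self.centroids.tolist(),
            "training_labels": self.training_labels.tolist(),
            "feature_space_centroids": self.feature_space_centroids.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(
            k=d["k"], bandwidth=d["bandwidth"], feature_names=d["feature_names"],
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            training_points=np.asarray(d["training_points"], float),
            degrees=np.asarray(d["degrees"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            eigenvectors=np.asarray(d["eigenvectors"], float),
            embedding=np.asarray(d["embedding"], float),
            centroids=np.asarray(d["centroids"], float),
            training_labels=np.asarray(d["training_labels"], int),
            feature_space_centroids=np.asarray(d["feature_space_centroids"], float),
        )


@dataclass
class ClusterAssignment:
    """Per-patient cluster labels produced by a fitted ClusterModel."""

    patient_ids: np.ndarray
    labels: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patient_ids) != len(self.labels):
            raise ConfigError("one label required per patient")
        if self.k is None:
            self.k = int(self.labels.max(initial=0)) + 1
        elif self.labels.size and not (0 <= self.labels.max() < self.k):
            raise ConfigError("labels fall outside the fitted model's label set")


class KChoice(int):
    """Integer cluster count annotated with the eigengap evidence behind it."""

    gaps: np.ndarray
    low_confidence: bool

    def __new__(cls, k: int, gaps: np.ndarray, low_confidence: bool) -> "KChoice":
        obj = super().__new__(cls, k)
        obj.gaps = gaps
        obj.low_confidence = low_confidence
        return obj


def _row_normalize(u: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    return np.divide(u, norms, out=np.zeros_like(u), where=norms > 0)


def _normalized_affinity(x: np.ndarray, bandwidth: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian affinity and its symmetric normalization D^{-1/2} W D^{-1/2}."""
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    np.fill_diagonal(w, 1.0)
    degrees = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    return w * inv_sqrt[:, None] * inv_sqrt[None, :], degrees


def _resolve_bandwidth(x: np.ndarray, bandwidth_rule: str,
                       bandwidth: float | None) -> float:
    if bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ConfigError("fixed bandwidth_rule requires a positive bandwidth")
        return float(bandwidth)
    if bandwidth_rule != "median_heuristic":
        raise ConfigError(f"unknown bandwidth_rule {bandwidth_rule!r}")
    dist = pdist(x)
    sigma = float(np.median(dist))
    if sigma <= 0:
        raise DegenerateInputError(
            "median pairwise distance is zero: rows are (nearly) all identical")
    return sigma


def fit_spectral(block: OmicsBlock, k: int = 2, *,
                 bandwidth_rule: str = "median_heuristic",
                 bandwidth: float | None = None, seed: int = 0,
                 n_init: int = 10) -> ClusterModel:
    """Fit spectral clustering on an omics block.

    Features are standardized internally with this block's means/SDs (the
    training statistics); the Gaussian affinity W_ij = exp(-||xi-xj||^2 /
    (2 sigma^2)) is normalized symmetrically, the top-k eigenvectors are
    row-normalized and clustered with seeded k-means.
    """
    if k < 2:
        raise ConfigError(f"k must be at least 2, got {k}")
    if block.n < k:
        raise ConfigError(f"need at least k={k} rows, got {block.n}")
    std = block if block.standardized else block.standardize()
    x = std.values
    if np.unique(x, axis=0).shape[0] < k:
        raise DegenerateInputError(
            f"fewer than k={k} distinct rows in the block")

    sigma = _resolve_bandwidth(x, bandwidth_rule, bandwidth)
    m, degrees = _normalized_affinity(x, sigma)
    eigvals, eigvecs = np.linalg.eigh(m)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    embedding = _row_normalize(eigvecs)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    raw_labels = km.fit_predict(embedding)

    # relabel by descending cluster size for determinism
    sizes = np.bincount(raw_labels, minlength=k)
    new_order = np.lexsort((np.arange(k), -sizes))
    label_map = {int(old): int(new) for new, old in enumerate(new_order)}
    labels = np.array([label_map[l] for l in raw_labels], dtype=int)
    centroids = km.cluster_centers_[new_order]

    feature_space_centroids = np.vstack(
        [x[labels == c].mean(axis=0) for c in range(k)])

    return ClusterModel(
        k=k, bandwidth=sigma, feature_names=list(block.feature_names),
        feature_means=np.asarray(std.ref_means, float),
        feature_sds=np.asarray(std.ref_sds, float),
        training_points=x, degrees=degrees,
        eigenvalues=eigvals, eigenvectors=eigvecs, embedding=embedding,
        centroids=centroids, training_labels=labels,
        feature_space_centroids=feature_space_centroids, label_map=label_map,
    )


def choose_k(block: OmicsBlock, k_max: int, *,
             bandwidth_rule: str = "median_heuristic",
             bandwidth: float | None = None) -> KChoice:
    """Advisory eigengap heuristic for the number of clusters.

    Returns the k in [2, k_max] maximizing the eigengap lambda_k -
    lambda_{k+1} of the normalized affinity operator. When the largest gap
    is small (no clear structure) the floor k=2 is returned with
    ``low_confidence=True``. The default pipeline uses a fixed k=2.
    """
    if k_max < 2:
        raise ConfigError("k_max must be at least 2")
    if k_max >= block.n:
        raise ConfigError(f"k_max={k_max} must be below the sample count {block.n}")
    std = block if block.standardized else block.standardize()
    sigma = _resolve_bandwidth(std.values, bandwidth_rule, bandwidth)
    m, _ = _normalized_affinity(std.values, sigma)
    eigvals = np.sort(np.linalg.eigvalsh(m))[::-1]
    ks = np.arange(2, k_max + 1)
    gaps = eigvals[ks - 1] - eigvals[ks]
    best = int(ks[np.argmax(gaps)])
    if float(gaps.max()) < _LOW_CONFIDENCE_GAP:
        return KChoice(2, gaps, True)
    return KChoice(best, gaps, False)


def assign_out_of_sample(model: ClusterModel, block: OmicsBlock,
                         strategy: str = "nystrom") -> ClusterAssignment:
    """Assign cluster labels to new patients with a fitted model.

    ``nystrom`` (default): each test point's kernel vector to the training
    points is degree-normalized, projected onto the stored eigenvectors
    scaled by 1/eigenvalue, row-normalized, and assigned to the nearest
    spectral centroid. A test point with an (numerically) all-zero kernel
    vector falls back to the nearest cluster mean in standardized feature
    space. ``feature_centroid``: nearest cluster mean in standardized
    feature space for every point (sensitivity-analysis alternative).
    """
    if list(block.feature_names) != model.feature_names:
        raise ConfigError("test block features do not match the fitted model")
    if block.n == 0:
        return ClusterAssignment(block.patient_ids, np.empty(0, dtype=int), model.k)
    if strategy not in ("nystrom", "feature_centroid"):
        raise ConfigError(f"unknown assignment strategy {strategy!r}")

    x = (block.values - model.feature_means) / model.feature_sds

    if strategy == "feature_centroid":
        d = cdist(x, model.feature_space_centroids)
        return ClusterAssignment(block.patient_ids, np.argmin(d, axis=1), model.k)

    d2 = cdist(x, model.training_points, metric="sqeuclidean")
    kx = np.exp(-d2 / (2.0 * model.bandwidth**2))
    dx = kx.sum(axis=1)
    dead = dx <= 0.0
    labels = np.empty(block.n, dtype=int)

    live = ~dead
    if live.any():
        b = kx[live] / np.sqrt(dx[live, None] * model.degrees[None, :])
        with np.errstate(divide="ignore"):
            inv_eig = 1.0 / model.eigenvalues
        emb = _row_normalize(b @ (model.eigenvectors * inv_eig[None, :]))
        d = cdist(emb, model.centroids)
        labels[live] = np.argmin(d, axis=1)
    if dead.any():
        logger.warning(
            "%d test point(s) had a zero kernel vector; falling back to "
            "nearest feature-space centroid", int(dead.sum()))
        d = cdist(x[dead], model.feature_space_centroids)
        labels[dead] = np.argmin(d, axis=1)

    return ClusterAssignment(block.patient_ids, labels, model.k)
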