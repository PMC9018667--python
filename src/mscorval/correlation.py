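"""Structural correlations from residue-wise clustering of interresidual distances.

For each residue r of an L-residue protein, every entity (each state of each
conformer) is described by the vector of distances from r to all other
residues.  Features whose standard deviation across entities falls below a
significance threshold (default 0.5 A) are discarded as thermal noise.  The
entities are then clustered into K components with a Gaussian mixture model,
yielding a residue-specific clustering vector.  Pairs of clustering vectors
are compared by mutual information (in bits),

    I(X, Y) = sum_{x,y} p(x,y) log2[ p(x,y) / (p(x) p(y)) ],

adjusted so that random clusterings score approximately zero (adjusted
mutual information, AMI).  The L x L AMI matrix A is averaged to the scalar
structural correlation parameter mu in [0, 1]; the residue whose clustering
agrees best with all others is the *key residue* and its clustering vector
is the global state assignment of the bundle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import adjusted_mutual_info_score

from .ensemble import Ensemble

__all__ = [
    "ClusteringVector",
    "CorrelationMatrix",
    "CorrelationResult",
    "CorrelationError",
    "residue_features",
    "cluster_entities",
    "mutual_information",
    "adjusted_mutual_information",
    "correlation_matrix",
    "structural_correlation",
    "key_residue_and_clustering",
    "analyze",
]

DEFAULT_THRESHOLD = 0.5  # A; significance threshold absorbing random thermal motion
DEFAULT_GMM_RESTARTS = 10


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringVector:
    """Per-entity state labels from clustering one residue's distance features."""

    labels: np.ndarray
    residue_index: int | None = None
    informative: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_labels(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def degenerate(self) -> bool:
        return (not self.informative) or self.n_labels < 2


@dataclass
class CorrelationMatrix:
    """Symmetric L x L adjusted-mutual-information matrix A."""

    A: np.ndarray
    n_states: int
    threshold: float
    residue_indices: list[int] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.A.shape[0]


@dataclass
class CorrelationResult:
    matrix: CorrelationMatrix
    mu: float
    mu_raw: float
    key_residue: int
    global_clustering: ClusteringVector
    clusterings: list[ClusteringVector]


def _entity_reference_coords(ensemble: Ensemble, atom_mode: str) -> np.ndarray:
    """(n_entities, L, 3) reference coordinates for all entities."""
    return np.array([e.reference_coords(atom_mode) for e in ensemble.entities()])


def _all_distances(coords: np.ndarray) -> np.ndarray:
    """(n_entities, L, L) pairwise distance tensor."""
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    return np.sqrt(np.sum(diff ** 2, axis=-1))


def residue_features(
    ensemble: Ensemble,
    residue: int,
    threshold: float = DEFAULT_THRESHOLD,
    atom_mode: str = "CA",
) -> np.ndarray:
    """Distance features of one residue: one row per entity, one column per
    retained other residue.

    ``residue`` is a 0-based position in the chain.  Columns whose standard
    deviation across entities is below ``threshold`` are removed; the result
    may have zero columns if no interresidual distance moves significantly.
    """
    L = ensemble.sequence_length
    if not 0 <= residue < L:
        raise CorrelationError(f"residue position {residue} out of range 0..{L - 1}")
    if threshold < 0:
        raise CorrelationError("threshold must be >= 0")
    coords = _entity_reference_coords(ensemble, atom_mode)
    dists = _all_distances(coords)[:, residue, :]  # (n_entities, L)
    feats = np.delete(dists, residue, axis=1)
    keep = feats.std(axis=0) >= threshold if threshold > 0 else np.ones(feats.shape[1], bool)
    return feats[:, keep]


def _gmm_labels(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_restarts: int,
    reg: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Diagonal-covariance Gaussian-mixture EM, vectorized over restarts.

    All restarts run as one batch (means initialized from random distinct
    rows); the restart with the best final log-likelihood provides the
    labels.  Purpose-built because the correlation engine fits one mixture
    per residue per restart — thousands per analysis — where per-fit
    overhead dominates a general-purpose implementation.
    """
    n, d = X.shape
    B = n_restarts
    # k-means++ seeding per restart: spread the initial means apart
    idx = np.empty((B, K), dtype=int)
    for b in range(B):
        chosen = [int(rng.integers(n))]
        for _ in range(K - 1):
            d2 = np.min(
                ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(-1), axis=1
            )
            total = d2.sum()
            if total <= 0:
                chosen.append(int(rng.integers(n)))
            else:
                chosen.append(int(rng.choice(n, p=d2 / total)))
        idx[b] = chosen
    mu = X[idx].astype(float)  # (B, K, d)
    base_var = X.var(axis=0) + reg
    var = np.broadcast_to(base_var, (B, K, d)).copy()
    w = np.full((B, K), 1.0 / K)
    Xsq = X ** 2
    ll_prev = np.full(B, -np.inf)
    R = None
    for _ in range(max_iter):
        diff2 = (X[None, None, :, :] - mu[:, :, None, :]) ** 2  # (B, K, n, d)
        logp = (
            -0.5 * (diff2 / var[:, :, None, :]).sum(-1)
            - 0.5 * np.log(2.0 * np.pi * var).sum(-1)[:, :, None]
            + np.log(np.maximum(w, 1e-300))[:, :, None]
        )  # (B, K, n)
        norm = logsumexp(logp, axis=1)  # (B, n)
        R = np.exp(logp - norm[:, None, :])
        ll = norm.sum(axis=1)
        Nk = R.sum(axis=2)  # (B, K)
        safe = np.maximum(Nk, 1e-12)[:, :, None]
        w = Nk / n
        mu = (R @ X) / safe
        var = np.maximum((R @ Xsq) / safe - mu ** 2, 0.0) + reg
        if np.all(np.abs(ll - ll_prev) < tol * (np.abs(ll) + 1.0)):
            break
        ll_prev = ll
    best = int(np.argmax(ll_prev))
    return np.argmax(R[best], axis=0)


def cluster_entities(
    features: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
    residue_index: int | None = None,
) -> ClusteringVector:
    """Cluster entities into ``n_clusters`` states with a Gaussian mixture model.

    Diagonal covariances are used (features routinely outnumber entities);
    the best of ``n_restarts`` seeded restarts by log-likelihood is kept.
    An empty feature matrix yields a degenerate single-label vector flagged
    as uninformative.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise CorrelationError("feature matrix must be 2-D")
    n = features.shape[0]
    if features.shape[1] == 0:
        return ClusteringVector(np.zeros(n, dtype=int), residue_index, informative=False)
    if n < n_clusters:
        raise CorrelationError(f"cannot form {n_clusters} clusters from {n} entities")
    labels = _gmm_labels(features, n_clusters, np.random.default_rng(int(seed) % (2**31)), n_restarts)
    return ClusteringVector(labels, residue_index, informative=True)


def mutual_information(X: ClusteringVector | np.ndarray, Y: ClusteringVector | np.ndarray) -> float:
    """Mutual information between two clusterings, in bits.

    Empirical plug-in estimate; zero-probability cells contribute zero.
    """
    x = X.labels if isinstance(X, ClusteringVector) else np.asarray(X, dtype=int)
    y = Y.labels if isinstance(Y, ClusteringVector) else np.asarray(Y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("clustering vectors must be 1-D and of equal length")
    n = x.size
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xv.size, yv.size))
    np.add.at(joint, (xi, yi), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, pxy * np.log2(np.where(mask, pxy / (px * py), 1.0)), 0.0)
    return float(terms.sum())


def adjusted_mutual_information(X: ClusteringVector | np.ndarray, Y: ClusteringVector | np.ndarray) -> float:
    """Mutual information adjusted for chance under the fixed-marginals
    permutation model: AMI = (I - E[I]) / (mean(H(X), H(Y)) - E[I]).

    Identical non-degenerate clusterings score 1; a clustering with a single
    label (including the degenerate output of an empty feature matrix) is
    uninformative by convention and scores 0 against anything.
    """
    xcv = X if isinstance(X, ClusteringVector) else ClusteringVector(np.asarray(X, dtype=int))
    ycv = Y if isinstance(Y, ClusteringVector) else ClusteringVector(np.asarray(Y, dtype=int))
    if xcv.labels.shape != ycv.labels.shape:
        raise CorrelationError("clustering vectors must have equal length")
    if xcv.degenerate or ycv.degenerate:
        return 0.0
    return float(adjusted_mutual_info_score(xcv.labels, ycv.labels, average_method="arithmetic"))


def _residue_clusterings(
    ensemble: Ensemble,
    n_states: int,
    threshold: float,
    seed: int,
    atom_mode: str,
    n_restarts: int,
) -> list[ClusteringVector]:
    L = ensemble.sequence_length
    coords = _entity_reference_coords(ensemble, atom_mode)
    dists = _all_distances(coords)
    rng = np.random.default_rng(seed)
    res_seeds = rng.integers(0, 2**31 - 1, size=L)
    clusterings = []
    for r in range(L):
        feats = np.delete(dists[:, r, :], r, axis=1)
        if threshold > 0:
            feats = feats[:, feats.std(axis=0) >= threshold]
        clusterings.append(
            cluster_entities(feats, n_states, seed=int(res_seeds[r]), n_restarts=n_restarts, residue_index=r)
        )
    return clusterings


def correlation_matrix(
    ensemble: Ensemble,
    n_states: int,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    atom_mode: str = "CA",
    n_restarts: int = DEFAULT_GMM_RESTARTS,
    clusterings: list[ClusteringVector] | None = None,
) -> CorrelationMatrix:
    """L x L matrix of pairwise adjusted mutual information between
    residue-specific clusterings.

    Residues whose features are entirely filtered by the significance
    threshold yield zero rows and columns (including the diagonal).
    """
    if n_states < 2:
        raise CorrelationError(
            "at least two states are required for the meaningful extraction of structural correlations"
        )
    n_entities = ensemble.n_conformers * ensemble.n_states
    if n_entities < n_states:
        raise CorrelationError(f"{n_entities} entities cannot support {n_states} clusters")
    if clusterings is None:
        clusterings = _residue_clusterings(ensemble, n_states, threshold, seed, atom_mode, n_restarts)
    L = len(clusterings)
    A = np.zeros((L, L))
    # identical clusterings recur across residues; cache AMI per label pair
    keys = [cv.labels.tobytes() for cv in clusterings]
    cache: dict[tuple[bytes, bytes], float] = {}
    for i in range(L):
        if not clusterings[i].degenerate:
            A[i, i] = 1.0
        for j in range(i + 1, L):
            key = (keys[i], keys[j]) if keys[i] <= keys[j] else (keys[j], keys[i])
            if key not in cache:
                cache[key] = adjusted_mutual_information(clusterings[i], clusterings[j])
            A[i, j] = A[j, i] = cache[key]
    return CorrelationMatrix(A, n_states, threshold, list(ensemble.residue_indices))


def structural_correlation(
    matrix: CorrelationMatrix,
    include_diagonal: bool = False,
    clamp: bool = True,
) -> float:
    """The scalar structural correlation parameter mu: the mean of the AMI
    matrix entries.

    By default the diagonal (self-agreement) is excluded so that mu = 0
    corresponds to the absence of correlated motion; ``include_diagonal``
    restores the literal double sum over all i, j.  Small negative values
    (chance-level anticorrelation) are clamped to 0 unless ``clamp=False``.
    """
    A = matrix.A
    if A.size == 0:
        raise CorrelationError("empty correlation matrix")
    if include_diagonal:
        mu = float(A.mean())
    else:
        if A.shape[0] < 2:
            raise CorrelationError("off-diagonal average needs at least two residues")
        mu = float((A.sum() - np.trace(A)) / (A.shape[0] * (A.shape[0] - 1)))
    return max(mu, 0.0) if clamp else mu


def key_residue_and_clustering(
    matrix: CorrelationMatrix,
    clusterings: list[ClusteringVector],
) -> tuple[int, ClusteringVector]:
    """Residue (0-based position) with maximal mean correlation to all other
    residues, and its clustering vector as the global state assignment.

    Ties break toward the lowest residue position.  If the matrix is all
    zero no residue is informative; the first residue is returned with a
    warning and its (degenerate) clustering.
    """
    A = matrix.A
    L = A.shape[0]
    if L != len(clusterings):
        raise CorrelationError("matrix and clusterings are inconsistent")
    if L < 2:
        return 0, clusterings[0]
    row_mean = (A.sum(axis=1) - np.diag(A)) / (L - 1)
    if np.all(A == 0):
        warnings.warn("all-zero correlation matrix; no informative key residue", stacklevel=2)
        return 0, clusterings[0]
    best = int(np.argmax(row_mean))  # argmax returns the lowest index on ties
    return best, clusterings[best]


def analyze(
    ensemble: Ensemble,
    n_states: int,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    atom_mode: str = "CA",
    include_diagonal: bool = False,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> CorrelationResult:
    """Full correlation analysis of a bundle: matrix, mu, key residue and
    global clustering."""
    clusterings = _residue_clusterings(ensemble, n_states, threshold, seed, atom_mode, n_restarts)
    matrix = correlation_matrix(
        ensemble, n_states, threshold, seed, atom_mode, n_restarts, clusterings=clusterings
    )
    mu_raw = structural_correlation(matrix, include_diagonal=include_diagonal, clamp=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        key, global_cl = key_residue_and_clustering(matrix, clusterings)
    return CorrelationResult(matrix, max(mu_raw, 0.0), mu_raw, key, global_cl, clusterings)
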