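"""Markov state models and time-lagged independent component analysis.

Kinetic similarity between a reference trajectory and a backmapped one is
judged by estimating MSMs over a shared state decomposition (k-means
centroids fit on the reference data only, then frozen) and comparing
implied timescales and eigenvector cosine similarities.  TICA supplies a
slow-coordinate basis when no intuitive collective variables exist.

Estimation choices: transition counts use the sliding window at lag tau;
the model is restricted to the largest strongly connected set of visited
states; the transition matrix is the reversible maximum-likelihood
estimator (fixed-point iteration on the symmetrized count identity);
eigen-decomposition is done in the pi-symmetrized basis for numerical
stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

__all__ = [
    "TransitionModel",
    "TicaModel",
    "TICA",
    "MarkovStateModel",
    "tica_fit",
    "kmeans_discretize",
    "assign_states",
    "msm_estimate",
    "implied_timescales",
    "normalize_timescales",
    "eigenvector_similarity",
]


# ---------------------------------------------------------------------------
# k-means discretization
# ---------------------------------------------------------------------------

def kmeans_discretize(features: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Fit k centroids on ``features`` (n_frames, n_features) and assign states.

    The centroids are meant to be fit once on a designated reference set;
    use :func:`assign_states` to discretize any other series with the same
    frozen centroids.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("empty feature series")
    if features.shape[0] <= k:
        raise ValueError(f"need more samples ({features.shape[0]}) than centroids ({k})")
    seed = int(rng.integers(2**31 - 1)) if isinstance(rng, np.random.Generator) else int(rng)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(features)
    return km.cluster_centers_, km.labels_.astype(np.int64)


def assign_states(features: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid state assignment with frozen centroids."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    d2 = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Reversible MSM on the largest connected set of visited states.

    ``state_ids`` maps the model's internal state index to the global
    centroid index, so models built on a shared centroid set are
    comparable.  ``lag`` is in frames unless ``lag_time`` (physical
    units) is set.
    """

    transition_matrix: np.ndarray
    lag: int
    state_ids: np.ndarray
    counts: np.ndarray
    centroids: np.ndarray | None = None
    lag_time: float | None = None
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors_right: np.ndarray = field(init=False)
    stationary_distribution: np.ndarray = field(init=False)

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        if np.any(T < -1e-12):
            raise ValueError("transition matrix entries must be nonnegative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = T
        # stationary distribution from detailed balance (reversible estimator)
        pi = self._stationary(T)
        self.stationary_distribution = pi
        # symmetrized eigenproblem: S = D^1/2 T D^-1/2 is symmetric for reversible T
        sq = np.sqrt(pi)
        S = (sq[:, None] * T) / sq[None, :]
        S = 0.5 * (S + S.T)
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        self.eigenvalues = vals
        self.eigenvectors_right = vecs / sq[:, None]  # right eigenvectors of T

    @staticmethod
    def _stationary(T: np.ndarray) -> np.ndarray:
        vals, vecs = scipy.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def _count_matrix(dtrajs, n_states: int, lag: int) -> np.ndarray:
    C = np.zeros((n_states, n_states))
    for dtraj in dtrajs:
        dtraj = np.asarray(dtraj, dtype=np.int64)
        if len(dtraj) > lag:
            np.add.at(C, (dtraj[:-lag], dtraj[lag:]), 1.0)
    return C


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    n, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(C > 0), directed=True, connection="strong"
    )
    sizes = np.bincount(labels, weights=C.sum(axis=1) + C.sum(axis=0))
    return np.where(labels == np.argmax(sizes))[0]


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    """Fixed-point iteration for the reversible maximum-likelihood
    transition matrix: x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)."""
    Csym = C + C.T
    c_row = C.sum(axis=1)
    X = Csym.copy()
    X /= X.sum()
    for _ in range(max_iter):
        x_row = X.sum(axis=1)
        q = c_row / x_row
        denom = q[:, None] + q[None, :]
        X_new = np.where(Csym > 0, Csym / denom, 0.0)
        X_new /= X_new.sum()
        if np.abs(X_new - X).max() < tol:
            X = X_new
            break
        X = X_new
    return X / X.sum(axis=1, keepdims=True)


def msm_estimate(dtrajs, lag: int, centroids=None, lag_time: float | None = None) -> TransitionModel:
    """Reversible maximum-likelihood MSM at lag ``lag`` (frames).

    ``dtrajs`` is one integer state sequence or a list of them.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    n_states = int(max(d.max() for d in dtrajs if len(d))) + 1
    C = _count_matrix(dtrajs, n_states, lag)
    if C.sum() == 0:
        raise ValueError(f"no transition pairs at lag {lag}")
    active = _largest_connected_set(C)
    Ca = C[np.ix_(active, active)]
    if len(active) == 1:
        T = np.ones((1, 1))
    else:
        T = _reversible_mle(Ca)
    return TransitionModel(
        transition_matrix=T,
        lag=lag,
        state_ids=active,
        counts=Ca,
        centroids=centroids,
        lag_time=lag_time,
    )


def implied_timescales(model: TransitionModel) -> np.ndarray:
    """t_i = -tau / ln(lambda_i) for nontrivial 0 < lambda_i < 1, descending.

    The stationary eigenvalue is excluded; nonpositive eigenvalues are
    skipped with a warning (they carry no resolvable timescale).
    """
    tau = model.lag_time if model.lag_time is not None else float(model.lag)
    lams = model.eigenvalues[1:]  # drop stationary eigenvalue 1
    keep = (lams > 0) & (lams < 1)
    if np.any(lams <= 0):
        warnings.warn(
            f"{int((lams <= 0).sum())} nonpositive eigenvalue(s) skipped", stacklevel=2
        )
    ts = -tau / np.log(lams[keep])
    return np.sort(ts)[::-1]


def normalize_timescales(target, reference) -> tuple[np.ndarray, float]:
    """Rescale ``target`` so its slowest process matches the reference's.

    Returns (rescaled, factor) with factor = slowest(ref)/slowest(target).
    Pairwise ratios within the target list are preserved exactly.
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(target) == 0 or len(reference) == 0:
        raise ValueError("both timescale lists must be nonempty")
    if target.max() <= 0:
        raise ValueError("slowest target timescale must be positive")
    factor = reference.max() / target.max()
    return target * factor, float(factor)


def cosine_similarity_on_support(va: np.ndarray, vb: np.ndarray) -> float:
    """|cosine| of two vectors already restricted to a shared support."""
    va, vb = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return abs(float(np.dot(va / na, vb / nb)))


def eigenvector_similarity(model_a: TransitionModel, model_b: TransitionModel) -> np.ndarray:
    """|cosine| between paired nontrivial right eigenvectors, restricted to
    mutually occupied states and renormalized there.

    Both models must be built on the same global centroid set; the
    absolute value makes the measure invariant to eigenvector sign.
    """
    mutual, ia, ib = np.intersect1d(model_a.state_ids, model_b.state_ids, return_indices=True)
    if len(mutual) == 0:
        raise ValueError("models share no occupied states")
    n = min(model_a.n_states, model_b.n_states) - 1
    sims = [
        cosine_similarity_on_support(
            model_a.eigenvectors_right[ia, k], model_b.eigenvectors_right[ib, k]
        )
        for k in range(1, n + 1)
    ]
    return np.asarray(sims)


class MarkovStateModel(BaseEstimator):
    """sklearn-style wrapper: ``fit`` on discrete state sequences.

    Fitted attributes: ``model_`` (:class:`TransitionModel`),
    ``timescales_``, ``transition_matrix_``.
    """

    def __init__(self, lag: int = 1, lag_time: float | None = None):
        self.lag = lag
        self.lag_time = lag_time

    def fit(self, X, y=None):
        self.model_ = msm_estimate(X, self.lag, lag_time=self.lag_time)
        self.transition_matrix_ = self.model_.transition_matrix
        self.timescales_ = implied_timescales(self.model_)
        return self


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

@dataclass
class TicaModel:
    """Fitted TICA: projection onto the leading independent components."""

    lag: int
    mean: np.ndarray
    components: np.ndarray  # (n_features, n_components)
    eigenvalues: np.ndarray

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) @ self.components


def tica_fit(features: np.ndarray, lag: int, n_components: int | None = None, epsilon: float = 1e-10) -> TicaModel:
    """Symmetrized time-lagged covariance generalized eigenproblem.

    Solves C_tau v = lambda C_0 v with both covariance matrices estimated
    symmetrically in time, which bounds all eigenvalues within [-1, 1].
    Components are ordered by decreasing eigenvalue; the trivial constant
    direction never appears because data are mean-centered.  A constant
    feature column raises a degenerate-feature error naming the column.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be (n_frames, n_features)")
    if X.shape[0] <= lag:
        raise ValueError(f"series length {X.shape[0]} must exceed lag {lag}")
    var = X.var(axis=0)
    tiny = var <= 1e-20 * max(1.0, float(var.max()))
    if np.any(tiny):
        bad = np.where(tiny)[0]
        raise ValueError(f"constant feature column(s) {bad.tolist()} have zero variance")
    mean = X.mean(axis=0)
    X = X - mean
    A, B = X[:-lag], X[lag:]
    n = A.shape[0]
    C0 = 0.5 * (A.T @ A + B.T @ B) / n
    Ct = 0.5 * (A.T @ B + B.T @ A) / n
    # whiten with a rank-truncated C0
    s, U = np.linalg.eigh(C0)
    keep = s > epsilon * s.max()
    W = U[:, keep] / np.sqrt(s[keep])
    M = W.T @ Ct @ W
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    comps = W @ vecs
    if n_components is not None:
        vals, comps = vals[:n_components], comps[:, :n_components]
    return TicaModel(lag=lag, mean=mean, components=comps, eigenvalues=vals)


class TICA(BaseEstimator, TransformerMixin):
    """sklearn-style transformer for time-lagged ICA.

    Fitted attributes: ``model_``, ``eigenvalues_``, ``components_``.
    """

    def __init__(self, lag: int = 10, n_components: int = 2):
        self.lag = lag
        self.n_components = n_components

    def fit(self, X, y=None):
        self.model_ = tica_fit(X, self.lag, self.n_components)
        self.eigenvalues_ = self.model_.eigenvalues
        self.components_ = self.model_.components
        return self

    def transform(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("TICA is not fitted")
        return self.model_.transform(X)
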