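"""Morphology-based clustering of airway segments.

A Gaussian mixture model is fit by expectation–maximization on the two
morphological features (lumen diameter, wall thickness), pooled over the
complete dataset of all trees. The number of components and the covariance
family are chosen by the Bayesian information criterion in the convention

    BIC = 2·logL − m·ln(n)

under which the best model has the *highest* score. The covariance-family
grid mirrors the classical model-based-clustering families:

=================  =============================================
``spherical-shared``  one isotropic variance shared by all components
``spherical-free``    one isotropic variance per component
``diagonal-free``     axis-aligned covariance per component
``full-shared``       one full covariance shared by all components
``full-free``         full covariance per component ("ellipsoidal,
                      variable volume / shape / orientation")
=================  =============================================

Selected clusters are renamed CL1…CLk in descending order of component mean
lumen diameter, so CL1 is always the large central airway compartment and
CLk the smallest, most distal one.

Features enter on the raw µm scale by default (no standardization); a
covariance floor of 1e-6 times the mean feature variance guards against
singular components arising from duplicated measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .tree_model import Cohort

__all__ = [
    "FAMILIES",
    "FeatureMatrix",
    "ClusterModel",
    "ClusterAssignment",
    "build_feature_matrix",
    "bic_score",
    "fit_gmm",
    "select_model",
    "canonical_relabel",
    "assign_clusters",
]

FAMILIES = (
    "spherical-shared",
    "spherical-free",
    "diagonal-free",
    "full-shared",
    "full-free",
)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FeatureMatrix:
    """Pooled (lumen, wall) features, one row per segment."""

    values: np.ndarray  # (n, 2), µm
    index: tuple[tuple[str, str], ...]  # (subject_id, segment_id) per row

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("feature matrix must be (n, 2)")
        if X.shape[0] < 2:
            raise ValidationError("feature matrix needs at least 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValidationError("feature matrix contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(
    cohort: Cohort, standardize: bool = False
) -> FeatureMatrix:
    """Pool (lumen diameter, wall thickness) rows over all trees."""
    rows, idx = [], []
    for tree, seg in cohort.iter_segments():
        rows.append((seg.lumen_diameter, seg.wall_thickness))
        idx.append((tree.subject_id, seg.segment_id))
    X = np.asarray(rows, dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return FeatureMatrix(values=X, index=tuple(idx))


def bic_score(log_likelihood: float, n_parameters: int, n_observations: int) -> float:
    """BIC in the higher-is-better convention ``2·logL − m·ln(n)``."""
    if n_observations < 2:
        raise ValidationError("BIC requires at least 2 observations")
    return 2.0 * log_likelihood - n_parameters * np.log(n_observations)



def _logsumexp_rows(ld: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp of a (n, k) matrix (fast path, no scipy)."""
    m = ld.max(axis=1)
    return m + np.log(np.exp(ld - m[:, None]).sum(axis=1))

def _n_parameters(k: int, family: str) -> int:
    d = 2
    base = (k - 1) + k * d
    cov = {
        "spherical-shared": 1,
        "spherical-free": k,
        "diagonal-free": k * d,
        "full-shared": d * (d + 1) // 2,
        "full-free": k * d * (d + 1) // 2,
    }[family]
    return base + cov


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x | mean, cov) for 2-D data, vectorized over rows."""
    return _log_gauss_all(X, mean[None, :], cov[None, :, :])[:, 0]


def _log_gauss_all(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log N(x_i | mean_j, cov_j) for 2-D data."""
    a, b, c = covs[:, 0, 0], covs[:, 0, 1], covs[:, 1, 1]
    det = a * c - b * b
    if np.any(det <= 0):
        raise FloatingPointError("singular component covariance")
    dx = X[:, 0, None] - means[None, :, 0]
    dy = X[:, 1, None] - means[None, :, 1]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


@dataclass
class ClusterModel:
    """A fitted Gaussian mixture on (lumen, wall)."""

    k: int
    family: str
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    log_likelihood: float
    ll_trace: np.ndarray  # per-iteration log-likelihood of the winning restart
    n_obs: int
    converged: bool
    seed: int | None = None
    bic_table: dict = field(default_factory=dict)  # (k, family) -> BIC
    cluster_names: tuple[str, ...] | None = None  # set by canonical_relabel

    @property
    def n_parameters(self) -> int:
        return _n_parameters(self.k, self.family)

    @property
    def bic(self) -> float:
        return bic_score(self.log_likelihood, self.n_parameters, self.n_obs)

    def log_responsibilities(self, X: np.ndarray) -> np.ndarray:
        ld = _log_gauss_all(X, self.means, self.covariances) + np.log(self.weights)
        return ld - _logsumexp_rows(ld)[:, None]

    def score(self, X: np.ndarray) -> float:
        ld = _log_gauss_all(X, self.means, self.covariances) + np.log(self.weights)
        return float(_logsumexp_rows(ld).sum())

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "seed": self.seed,
            "cluster_names": list(self.cluster_names) if self.cluster_names else None,
            "bic_table": [
                {"k": k, "family": fam, "bic": v}
                for (k, fam), v in sorted(self.bic_table.items())
            ],
        }


@dataclass(frozen=True)
class ClusterAssignment:
    """Hard labels plus posterior responsibilities, row-aligned to features."""

    index: tuple[tuple[str, str], ...]
    labels: tuple[str, ...]
    responsibilities: np.ndarray  # (n, k), columns ordered as cluster_names
    cluster_names: tuple[str, ...]


def _m_step_cov(
    X: np.ndarray, resp: np.ndarray, means: np.ndarray, nk: np.ndarray, family: str,
    floor: float,
) -> np.ndarray:
    n, _ = X.shape
    k = means.shape[0]
    covs = np.empty((k, 2, 2))
    dx = X[:, None, :] - means[None, :, :]  # (n, k, 2)
    full = np.einsum("nk,nkd,nke->kde", resp, dx, dx) / nk[:, None, None]
    if family == "full-free":
        covs = full
    elif family == "full-shared":
        pooled = np.tensordot(nk, full, axes=1) / n
        covs = np.repeat(pooled[None, :, :], k, axis=0)
    elif family == "diagonal-free":
        for j in range(k):
            covs[j] = np.diag(np.diag(full[j]))
    elif family == "spherical-free":
        for j in range(k):
            covs[j] = np.eye(2) * np.trace(full[j]) / 2.0
    elif family == "spherical-shared":
        pooled = np.tensordot(nk, full, axes=1) / n
        covs = np.repeat((np.eye(2) * np.trace(pooled) / 2.0)[None, :, :], k, axis=0)
    else:
        raise ValidationError(f"unknown covariance family {family!r}")
    covs = covs + floor * np.eye(2)[None, :, :]
    return covs


def _em_once(
    X: np.ndarray,
    k: int,
    family: str,
    rng: np.random.Generator,
    init: str,
    max_iter: int,
    tol: float,
    floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, bool]:
    n = X.shape[0]
    # --- initialization: hard responsibilities from k-means (or random) ---
    if k == 1:
        resp = np.ones((n, 1))
    elif init == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=k, n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X)
        resp = np.zeros((n, k))
        resp[np.arange(n), km.labels_] = 1.0
    else:
        resp = rng.dirichlet(np.ones(k), size=n)
    nk = np.maximum(resp.sum(axis=0), 1e-10)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = _m_step_cov(X, resp, means, nk, family, floor)

    trace = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        ld = _log_gauss_all(X, means, covs) + np.log(weights)
        row_ll = _logsumexp_rows(ld)
        ll = float(row_ll.sum())
        trace.append(ll)
        if ll - prev_ll < tol * (abs(ll) + 1.0) and len(trace) > 1:
            converged = True
            break
        prev_ll = ll
        resp = np.exp(ld - row_ll[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-10)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = _m_step_cov(X, resp, means, nk, family, floor)
    else:
        ld = _log_gauss_all(X, means, covs) + np.log(weights)
        trace.append(float(_logsumexp_rows(ld).sum()))
    return weights, means, covs, trace[-1], np.asarray(trace), converged


def fit_gmm(
    features: FeatureMatrix | np.ndarray,
    k: int,
    family: str = "full-free",
    seed: int = 0,
    n_restarts: int = 10,
    init: str = "kmeans",
    max_iter: int = 200,
    tol: float = 1e-7,
) -> ClusterModel:
    """Fit one Gaussian mixture by seeded multi-restart EM.

    The best restart by final log-likelihood wins; the fit is deterministic
    given ``(seed, n_restarts)``. Singular solutions are prevented by a
    covariance floor of 1e-6 times the mean feature variance.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = X.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of rows ({n})")
    if family not in FAMILIES:
        raise ValidationError(f"unknown covariance family {family!r}")
    floor = 1e-6 * float(np.mean(np.var(X, axis=0)))
    if floor == 0.0:  # all rows identical
        floor = 1e-6
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        try:
            out = _em_once(X, k, family, rng, init, max_iter, tol, floor)
        except FloatingPointError:
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise ValidationError(
            f"EM failed for k={k}, family={family!r}: all restarts degenerate"
        )
    weights, means, covs, ll, trace, converged = best
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations "
            f"(k={k}, family={family!r}); best iterate returned",
            RuntimeWarning,
        )
    return ClusterModel(
        k=k, family=family, weights=weights, means=means, covariances=covs,
        log_likelihood=ll, ll_trace=trace, n_obs=n, converged=converged, seed=seed,
    )


def select_model(
    features: FeatureMatrix | np.ndarray,
    k_range: Iterable[int] = range(1, 10),
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    n_restarts: int = 4,
    **fit_kwargs,
) -> ClusterModel:
    """Scan (k, covariance family) and return the BIC-maximizing mixture.

    Ties are broken toward smaller k, then toward the simpler family (in
    the order of :data:`FAMILIES`). The full BIC table of the scan is kept
    on the returned model.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or not families:
        raise ValidationError("k_range and families must be nonempty")
    for fam in families:
        if fam not in FAMILIES:
            raise ValidationError(f"unknown covariance family {fam!r}")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(k_range) * len(families)))
    table: dict[tuple[int, str], float] = {}
    candidates: list[tuple[float, int, int, ClusterModel]] = []
    errors: list[str] = []
    for k in k_range:
        for fam in families:
            child_seed = int(next(children).generate_state(1)[0] % (2**31 - 1))
            try:
                model = fit_gmm(
                    features, k=k, family=fam, seed=child_seed,
                    n_restarts=n_restarts, **fit_kwargs,
                )
            except ValidationError as exc:
                errors.append(str(exc))
                continue
            table[(k, fam)] = model.bic
            candidates.append((model.bic, -k, -FAMILIES.index(fam), model))
    if not candidates:
        raise ValidationError(
            "model selection failed for every (k, family) pair: " + "; ".join(errors)
        )
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    best = candidates[-1][3]
    best.bic_table = table
    best.seed = seed
    return best


def canonical_relabel(
    model: ClusterModel, features: FeatureMatrix
) -> tuple[ClusterModel, ClusterAssignment]:
    """Rename clusters CL1…CLk by strictly descending mean lumen diameter.

    Exact ties in mean lumen are broken by descending mean wall thickness,
    then by original component index. Returns the reordered model and the
    hard assignment (label = argmax posterior responsibility).
    """
    order = sorted(
        range(model.k),
        key=lambda j: (-model.means[j, 0], -model.means[j, 1], j),
    )
    names = tuple(f"CL{i + 1}" for i in range(model.k))
    relabeled = ClusterModel(
        k=model.k,
        family=model.family,
        weights=model.weights[order],
        means=model.means[order],
        covariances=model.covariances[order],
        log_likelihood=model.log_likelihood,
        ll_trace=model.ll_trace,
        n_obs=model.n_obs,
        converged=model.converged,
        seed=model.seed,
        bic_table=model.bic_table,
        cluster_names=names,
    )
    resp = np.exp(relabeled.log_responsibilities(features.values))
    hard = resp.argmax(axis=1)
    assignment = ClusterAssignment(
        index=features.index,
        labels=tuple(names[j] for j in hard),
        responsibilities=resp,
        cluster_names=names,
    )
    return relabeled, assignment


def assign_clusters(cohort: Cohort, assignment: ClusterAssignment) -> None:
    """Write the assignment's labels back onto the cohort's segments."""
    label_of = dict(zip(assignment.index, assignment.labels))
    for tree, seg in cohort.iter_segments():
        key = (tree.subject_id, seg.segment_id)
        if key in label_of:
            seg.cluster_label = label_of[key]
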