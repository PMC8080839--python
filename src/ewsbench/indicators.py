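"""The thirteen multivariate indicators of resilience loss.

All indicators are statistics of the fluctuations of a stationary
multivariate series.  As a system approaches a zero-eigenvalue bifurcation
its dominant recovery rate slows, which raises lag-1 autocorrelation,
variance, cross-correlation and the mutual information between the series
and its own lagged copy; the indicators differ in how they reduce the
multivariate signal to a scalar.

The catalogue (canonical snake_case names):

================================  =============================================
``degenerate_fingerprinting``     lag-1 AC of the projection on the first
                                  principal component of the covariance PCA
``maf_autocorrelation``           lag-1 AC of the projection on the first
                                  min/max autocorrelation factor (MAF); the
                                  maximum autocorrelation over linear
                                  combinations
``maf_eigenvalue``                smallest MAF eigenvalue (falls toward the
                                  transition)
``mutual_information``            kNN mutual information between the series
                                  and its lag-1 copy
``avg_autocorrelation``           mean per-variable lag-1 AC
``node_max_autocorrelation``      largest per-variable lag-1 AC
``maf_variance``                  variance of the data projected on the first
                                  MAF direction
``node_max_variance``             largest per-variable variance
``avg_variance``                  mean per-variable variance
``pca_variance``                  variance on the first principal component
                                  (largest covariance eigenvalue)
``max_covariance``                largest entry of the covariance matrix
``explained_variance``            largest covariance eigenvalue / trace
``avg_cross_correlation``         mean absolute pairwise Pearson correlation
================================  =============================================

Every indicator has a fixed orientation: all rise toward the transition
except ``maf_eigenvalue``, which falls (the slowest direction's
difference-variance shrinks as its autocorrelation approaches one).
Trend scoring applies the orientation first, so a "performing" indicator
always means a rising oriented signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .errors import (
    CatalogueError,
    DegenerateDataError,
    DimensionError,
    NotApplicableError,
    PreconditionError,
    UndefinedStatisticError,
)
from .simulate import TimeSeriesMatrix

__all__ = [
    "IndicatorValue",
    "MAFDecomposition",
    "lag1_autocorrelation",
    "covariance_matrix",
    "whiten",
    "maf_decomposition",
    "ksg_mutual_information",
    "compute_indicator",
    "compute_all_indicators",
    "list_indicators",
    "orientation",
    "INDICATOR_NAMES",
    "MULTIVARIATE_ONLY",
]

Orientation = Literal["increases_toward_transition", "decreases_toward_transition"]

_ORIENTATIONS: dict[str, Orientation] = {
    "degenerate_fingerprinting": "increases_toward_transition",
    "maf_autocorrelation": "increases_toward_transition",
    "maf_eigenvalue": "decreases_toward_transition",
    "mutual_information": "increases_toward_transition",
    "avg_autocorrelation": "increases_toward_transition",
    "node_max_autocorrelation": "increases_toward_transition",
    "maf_variance": "increases_toward_transition",
    "node_max_variance": "increases_toward_transition",
    "avg_variance": "increases_toward_transition",
    "pca_variance": "increases_toward_transition",
    "max_covariance": "increases_toward_transition",
    "explained_variance": "increases_toward_transition",
    "avg_cross_correlation": "increases_toward_transition",
}

INDICATOR_NAMES: tuple[str, ...] = tuple(_ORIENTATIONS)

#: Indicators that require at least two observed variables.
MULTIVARIATE_ONLY = frozenset(
    {
        "degenerate_fingerprinting",
        "maf_autocorrelation",
        "maf_eigenvalue",
        "maf_variance",
        "pca_variance",
        "explained_variance",
        "avg_cross_correlation",
    }
)


def list_indicators() -> list[str]:
    """Canonical names of all thirteen indicators."""
    return list(INDICATOR_NAMES)


def orientation(name: str) -> Orientation:
    try:
        return _ORIENTATIONS[name]
    except KeyError:
        raise CatalogueError(
            f"unknown indicator {name!r}; valid names: {', '.join(INDICATOR_NAMES)}"
        ) from None


@dataclass(frozen=True)
class IndicatorValue:
    """A single indicator evaluated on one series."""

    name: str
    value: float
    orientation: Orientation
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MAFDecomposition:
    """Min/max autocorrelation factor decomposition.

    ``eigenvalues`` (ascending) are the spectrum of the covariance of the
    first difference of the whitened data; for a stationary series the
    eigenvalue of a direction with lag-1 autocorrelation ``rho`` is
    ``2 (1 - rho)``, so the smallest eigenvalue belongs to the *most*
    autocorrelated — slowest — linear combination.  ``weights`` maps
    original variables to MAF scores (columns, first = slowest); the
    projection of the de-meaned data on ``weights[:, 0]`` is the first MAF
    series.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray


def lag1_autocorrelation(x) -> float:
    """Lag-1 autocorrelation with the global-mean normalisation.

    ``sum((x_t - m)(x_{t+1} - m)) / sum((x_t - m)^2)`` with ``m`` the mean
    over the full series.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise PreconditionError("need at least 3 samples")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise UndefinedStatisticError("lag-1 autocorrelation of a constant series")
    return float(xc[:-1] @ xc[1:] / denom)


def _values(X) -> np.ndarray:
    if isinstance(X, TimeSeriesMatrix):
        return X.values
    v = np.asarray(X, dtype=float)
    return v[:, None] if v.ndim == 1 else v


def covariance_matrix(X) -> np.ndarray:
    """Sample covariance (divisor T-1) of a T x N series."""
    v = _values(X)
    if v.shape[0] < 2:
        raise PreconditionError("need at least 2 samples")
    return np.cov(v, rowvar=False, ddof=1).reshape(v.shape[1], v.shape[1])

_RANK_RTOL = 1e-12


def whiten(X) -> tuple[np.ndarray, np.ndarray]:
    """Standardise-decorrelate-standardise transform.

    Returns ``(Y, W)`` with ``Y = (X - mean) @ W`` and ``cov(Y)`` the
    identity.  If the covariance is rank deficient the null directions are
    dropped with a warning and ``W`` has one column per retained direction.
    """
    v = _values(X)
    C = covariance_matrix(v)
    evals, evecs = np.linalg.eigh(C)
    keep = evals > _RANK_RTOL * max(evals.max(), 1.0)
    if not keep.any():
        raise DegenerateDataError(
            "covariance is identically zero (all variables constant)",
            null_directions=evecs,
        )
    if not keep.all():
        warnings.warn(
            f"covariance rank deficient; dropping {int((~keep).sum())} "
            "null direction(s)",
            stacklevel=2,
        )
    W = evecs[:, keep] / np.sqrt(evals[keep])
    return (v - v.mean(axis=0)) @ W, W


def maf_decomposition(X) -> MAFDecomposition:
    """Min/max autocorrelation factors of a T x N series.

    Whitens the data, takes the covariance of the first difference and
    diagonalises it (eigenvalues ascending).  Algebraically identical to
    the generalised eigenproblem ``cov(dX) v = lambda cov(X) v``; the
    whiten-then-diff route is used because it is numerically symmetric.
    """
    v = _values(X)
    if v.shape[0] < 3:
        raise PreconditionError("need at least 3 samples")
    Y, W = whiten(v)
    D = np.diff(Y, axis=0)
    CD = np.cov(D, rowvar=False, ddof=1).reshape(Y.shape[1], Y.shape[1])
    evals, evecs = np.linalg.eigh(CD)  # ascending
    weights = W @ evecs
    # fix sign convention: largest-magnitude weight positive
    for j in range(weights.shape[1]):
        k = np.argmax(np.abs(weights[:, j]))
        if weights[k, j] < 0:
            weights[:, j] = -weights[:, j]
    return MAFDecomposition(weights=weights, eigenvalues=np.clip(evals, 0.0, None))


def _ksg_jitter(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = a.std(axis=0)
    scale[scale == 0.0] = 1.0
    return a + 1e-10 * scale * rng.standard_normal(a.shape)


def ksg_mutual_information(X, Y, k: int = 3, base: float = 2.0) -> float:
    """Kraskov-Stoegbauer-Grassberger (variant 1) mutual information.

    Nearest-neighbour estimate under the max-norm:
    ``psi(k) + psi(T) - <psi(n_x + 1) + psi(n_y + 1)>`` where ``n_x`` counts
    the samples strictly closer than the k-th joint neighbour in the X
    marginal (and likewise for Y).  No bias correction is applied.  A
    deterministic jitter of amplitude ``1e-10 * sd`` (fixed sub-seed) breaks
    exact ties, which otherwise bias the strict-inequality counts.

    Returns the estimate in units of ``log(base)`` (bits by default).
    """
    x = _values(X)
    y = _values(Y)
    if x.shape[0] != y.shape[0]:
        raise DimensionError(
            f"X and Y must have the same number of rows "
            f"({x.shape[0]} vs {y.shape[0]})"
        )
    T = x.shape[0]
    if T <= k + 1:
        raise PreconditionError(f"need more than k+1={k + 1} paired samples")
    if (x.std(axis=0) == 0.0).any() or (y.std(axis=0) == 0.0).any():
        warnings.warn("constant column(s) in MI input; jitter applied", stacklevel=2)
    rng = np.random.Generator(np.random.PCG64(0x5EED))
    x = _ksg_jitter(x, rng)
    y = _ksg_jitter(y, rng)

    joint = np.hstack([x, y])
    tree_joint = cKDTree(joint)
    # k+1 because the query point itself is returned at distance 0
    eps = tree_joint.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    strict = np.nextafter(eps, 0.0)
    nx = cKDTree(x).query_ball_point(x, strict, p=np.inf, return_length=True) - 1
    ny = cKDTree(y).query_ball_point(y, strict, p=np.inf, return_length=True) - 1
    mi_nats = digamma(k) + digamma(T) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(mi_nats / np.log(base))


def _per_column_ac(v: np.ndarray) -> np.ndarray:
    out = np.empty(v.shape[1])
    for j in range(v.shape[1]):
        try:
            out[j] = lag1_autocorrelation(v[:, j])
        except UndefinedStatisticError:
            warnings.warn(
                f"constant column {j}; contributing autocorrelation 0",
                stacklevel=3,
            )
            out[j] = 0.0
    return out


def _first_pc(C: np.ndarray) -> tuple[float, np.ndarray]:
    evals, evecs = np.linalg.eigh(C)
    return float(evals[-1]), evecs[:, -1]


def _avg_cross_correlation(v: np.ndarray) -> float:
    sd = v.std(axis=0, ddof=1)
    if (sd == 0.0).any():
        warnings.warn("constant column(s); their correlations counted as 0", stacklevel=3)
    N = v.shape[1]
    C = covariance_matrix(v)
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, C / denom, 0.0)
    iu = np.triu_indices(N, k=1)
    return float(np.mean(np.abs(R[iu])))


def compute_indicator(name: str, X) -> IndicatorValue:
    """Evaluate one catalogue indicator on a T x N series.

    Raises
    ------
    CatalogueError
        Unknown ``name``.
    NotApplicableError
        A multivariate-only indicator applied to a single-variable series.
    """
    orient = orientation(name)
    v = _values(X)
    T, N = v.shape
    if N < 2 and name in MULTIVARIATE_ONLY:
        raise NotApplicableError(
            f"{name} requires at least two variables (got {N})"
        )
    details: dict = {}

    if name == "avg_autocorrelation":
        value = float(np.mean(_per_column_ac(v)))
    elif name == "node_max_autocorrelation":
        value = float(np.max(_per_column_ac(v)))
    elif name == "avg_variance":
        value = float(np.mean(v.var(axis=0, ddof=1)))
    elif name == "node_max_variance":
        value = float(np.max(v.var(axis=0, ddof=1)))
    elif name == "max_covariance":
        value = float(covariance_matrix(v).max())
    elif name == "pca_variance":
        value, vec = _first_pc(covariance_matrix(v))
        details["direction"] = vec
    elif name == "explained_variance":
        C = covariance_matrix(v)
        lam, vec = _first_pc(C)
        tr = float(np.trace(C))
        if tr == 0.0:
            raise UndefinedStatisticError("explained variance of constant data")
        value = lam / tr
        details["direction"] = vec
    elif name == "degenerate_fingerprinting":
        _, vec = _first_pc(covariance_matrix(v))
        proj = (v - v.mean(axis=0)) @ vec
        value = lag1_autocorrelation(proj)
        details["direction"] = vec
    elif name == "avg_cross_correlation":
        value = _avg_cross_correlation(v)
    elif name == "mutual_information":
        value = ksg_mutual_information(v[:-1], v[1:])
    elif name in ("maf_autocorrelation", "maf_eigenvalue", "maf_variance"):
        maf = maf_decomposition(v)
        w0 = maf.weights[:, 0]
        details["direction"] = w0
        if name == "maf_eigenvalue":
            value = float(maf.eigenvalues[0])
        else:
            # project raw de-meaned data on the unit-norm first MAF direction
            w_unit = w0 / np.linalg.norm(w0)
            proj = (v - v.mean(axis=0)) @ w_unit
            if name == "maf_autocorrelation":
                value = lag1_autocorrelation(proj)
            else:
                value = float(proj.var(ddof=1))
                details["projection"] = "raw de-meaned data, unit-norm direction"
    else:  # pragma: no cover - catalogue and dispatch kept in sync
        raise CatalogueError(name)

    if not np.isfinite(value):
        raise UndefinedStatisticError(f"{name} evaluated to a non-finite value")
    return IndicatorValue(name=name, value=value, orientation=orient, details=details)


def compute_all_indicators(X, names=None) -> list[IndicatorValue]:
    """Evaluate a set of indicators (default: the full catalogue).

    Multivariate-only indicators are skipped with a warning when the series
    has a single variable.
    """
    v = _values(X)
    results = []
    for name in names or INDICATOR_NAMES:
        if v.shape[1] < 2 and name in MULTIVARIATE_ONLY:
            warnings.warn(f"skipping {name} on single-variable data", stacklevel=2)
            continue
        results.append(compute_indicator(name, v))
    return results
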