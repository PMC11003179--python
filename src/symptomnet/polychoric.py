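"""Two-step maximum-likelihood polychoric correlation estimation.

The polychoric model assumes each pair of ordinal items arises from a
standard bivariate normal latent variable discretized by per-item threshold
vectors.  Estimation is two-step: thresholds from the univariate margins
(``cut_k = Phi^{-1}(cumulative proportion)``), then the latent correlation
``rho`` by maximizing the contingency-table multinomial likelihood with
thresholds held fixed — the de-facto estimator of psychometric network
tooling.

The pairwise matrix assembled from two-step estimates need not be positive
semi-definite; :func:`nearest_psd_repair` fixes that by eigenvalue clipping
with re-scaling to unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .data import MISSING, ItemResponseMatrix
from .errors import DegenerateItemError, EstimationError

#: rho is clamped to this magnitude to keep downstream matrices invertible.
RHO_BOUND = 0.999

# Gauss-Legendre rule for the correlation-integral representation of the
# bivariate normal CDF; 48 nodes give ~1e-14 accuracy for |rho| <= 0.95.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)

# |latent| beyond this is numerically +-infinity (Phi(8.5) == 1 - 1.1e-17).
_CLIP = 8.5


@dataclass
class CorrelationEstimate:
    """A p×p polychoric correlation matrix with estimation metadata."""

    matrix: np.ndarray
    thresholds: list[np.ndarray]
    repaired: bool
    min_eigenvalue_before: float
    pair_n: np.ndarray          # per-pair complete observations
    boundary_pairs: list[tuple[str, str]]
    labels: list[str]

    @property
    def n_effective(self) -> int:
        """Conservative sample size for likelihood-based criteria: the
        minimum per-pair complete-observation count."""
        p = self.matrix.shape[0]
        off = self.pair_n[~np.eye(p, dtype=bool)]
        return int(off.min())


def bvn_cdf(x, y, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF ``P(X <= x, Y <= y)``, vectorized over
    ``x`` and ``y`` (broadcast together) for scalar ``rho``.

    Uses the identity
    ``Phi2(x, y; rho) = Phi(x) Phi(y) + (1/2pi) \\int_0^rho
    exp(-(x^2 - 2 x y r + y^2) / (2 (1 - r^2))) / sqrt(1 - r^2) dr``
    evaluated by Gauss-Legendre quadrature; for ``|rho| > 0.95`` the
    integrand concentrates near ``r = 1`` and the computation falls back to
    scipy's Genz algorithm.
    """
    x = np.clip(np.asarray(x, dtype=float), -_CLIP, _CLIP)
    y = np.clip(np.asarray(y, dtype=float), -_CLIP, _CLIP)
    x, y = np.broadcast_arrays(x, y)
    if abs(rho) >= 1.0:
        raise EstimationError(f"|rho| must be < 1, got {rho}")
    if rho == 0.0:
        return ndtr(x) * ndtr(y)
    if abs(rho) > 0.95:
        mvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        pts = np.stack([x.ravel(), y.ravel()], axis=1)
        return np.asarray(mvn.cdf(pts)).reshape(x.shape)
    # substitute r = rho (t + 1) / 2 over t in [-1, 1]
    r = 0.5 * rho * (_GL_NODES + 1.0)
    w = 0.5 * rho * _GL_WEIGHTS
    xe = x[..., None]
    ye = y[..., None]
    one_m_r2 = 1.0 - r * r
    integrand = np.exp(-(xe * xe - 2.0 * xe * ye * r + ye * ye)
                       / (2.0 * one_m_r2)) / np.sqrt(one_m_r2)
    out = ndtr(x) * ndtr(y) + (integrand * w).sum(axis=-1) / (2.0 * np.pi)
    return np.clip(out, 0.0, 1.0)


def bivariate_rectangle_prob(rho: float, a_lo: float, a_hi: float,
                             b_lo: float, b_hi: float) -> float:
    """Probability that a standard bivariate normal with correlation ``rho``
    lands in ``(a_lo, a_hi] x (b_lo, b_hi]`` (±inf permitted at extremes),
    by four-term inclusion-exclusion of the CDF."""
    if not (a_lo < a_hi and b_lo < b_hi):
        raise EstimationError("rectangle bounds must be increasing")
    xs = np.array([[a_hi, a_lo], [a_hi, a_lo]])
    ys = np.array([[b_hi, b_hi], [b_lo, b_lo]])
    F = bvn_cdf(xs, ys, rho)
    prob = F[0, 0] - F[0, 1] - F[1, 0] + F[1, 1]
    return float(min(max(prob, 0.0), 1.0))


def estimate_thresholds(category_counts: np.ndarray) -> np.ndarray:
    """First-stage threshold estimates from observed category counts.

    ``cut_k = Phi^{-1}(cumulative proportion through category k)`` for
    ``k = 1 .. K-1``.  Empty extreme categories yield ∓inf cuts (handled
    naturally by open-ended rectangles downstream); interior empty
    categories produce tied cuts, broken by an epsilon of 1e-6 with a
    warning.  An item with all observations in one category is degenerate.
    """
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts < 0):
        raise EstimationError("category counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise EstimationError("no observations")
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError(
            "all observations in a single category; correlations with this "
            "item are undefined")
    cum = np.cumsum(counts)[:-1] / total
    with np.errstate(divide="ignore"):
        cuts = ndtri(cum)
    tied = False
    for k in range(1, len(cuts)):
        if np.isfinite(cuts[k]) and cuts[k] <= cuts[k - 1]:
            cuts[k] = cuts[k - 1] + 1e-6
            tied = True
    if tied:
        warnings.warn("interior empty category: tied thresholds broken by "
                      "epsilon 1e-6", stacklevel=2)
    return cuts


def _cell_probs(rho: float, th1: np.ndarray, th2: np.ndarray) -> np.ndarray:
    """All K1×K2 rectangle probabilities at once via double differencing of
    the CDF over the threshold grid padded with ±inf."""
    g1 = np.concatenate(([-np.inf], th1, [np.inf]))
    g2 = np.concatenate(([-np.inf], th2, [np.inf]))
    F = bvn_cdf(g1[:, None], g2[None, :], rho)
    P = np.diff(np.diff(F, axis=0), axis=1)
    return np.clip(P, 0.0, 1.0)


def _neg_loglik(rho: float, table: np.ndarray, th1: np.ndarray,
                th2: np.ndarray) -> float:
    P = _cell_probs(rho, th1, th2)
    mask = table > 0
    return -float(np.sum(table[mask] * np.log(np.maximum(P[mask], 1e-300))))


def polychoric_rho(table: np.ndarray, th1: np.ndarray,
                   th2: np.ndarray) -> float:
    """Second-stage ML estimate of the latent correlation for one item pair.

    Maximizes the multinomial log-likelihood of the contingency ``table``
    over ``rho`` with thresholds held fixed, by derivative-free bounded
    scalar search on ``[-0.999, 0.999]`` (xatol 1e-6).  Estimates within
    5e-4 of the bound are snapped to ±0.999 (a flagged boundary estimate).
    Zero rows/columns are permitted — empty cells contribute nothing.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (len(th1) + 1, len(th2) + 1):
        raise EstimationError(
            f"table shape {table.shape} inconsistent with thresholds "
            f"({len(th1) + 1} x {len(th2) + 1} expected)")
    if table.sum() <= 0:
        raise EstimationError("empty contingency table")
    res = optimize.minimize_scalar(
        _neg_loglik, bounds=(-RHO_BOUND, RHO_BOUND), args=(table, th1, th2),
        method="bounded", options={"xatol": 1e-6, "maxiter": 200})
    rho = float(res.x)
    if RHO_BOUND - abs(rho) < 5e-4:
        rho = np.sign(rho) * RHO_BOUND
    return rho


def is_boundary(rho: float) -> bool:
    return abs(rho) >= RHO_BOUND


def contingency_table(x: np.ndarray, y: np.ndarray, k1: int,
                      k2: int) -> tuple[np.ndarray, int]:
    """Pairwise-complete K1×K2 contingency table and its effective n."""
    ok = (x != MISSING) & (y != MISSING)
    xs, ys = x[ok], y[ok]
    table = np.bincount(xs * k2 + ys, minlength=k1 * k2).reshape(k1, k2)
    return table.astype(float), int(ok.sum())


def polychoric_matrix(data: ItemResponseMatrix) -> CorrelationEstimate:
    """Assemble the full polychoric correlation matrix.

    Thresholds come from each item's own (complete-observation) margin;
    pairwise estimation uses pairwise-complete rows, so each pair keeps its
    maximal n (recorded in ``pair_n``).  If the assembled matrix is
    indefinite it is repaired to PSD and flagged.
    """
    p = data.p
    if p < 2:
        raise EstimationError("need at least 2 items")
    thresholds: list[np.ndarray] = []
    for j, item in enumerate(data.items):
        col = data.values[:, j]
        counts = np.bincount(col[col != MISSING],
                             minlength=item.n_categories)
        try:
            thresholds.append(estimate_thresholds(counts))
        except DegenerateItemError as exc:
            raise DegenerateItemError(
                f"item {item.label!r}: {exc}") from None

    R = np.eye(p)
    pair_n = np.full((p, p), data.n, dtype=np.int64)
    boundary: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            table, n_ij = contingency_table(
                data.values[:, i], data.values[:, j],
                data.items[i].n_categories, data.items[j].n_categories)
            if n_ij == 0:
                raise EstimationError(
                    f"no complete observations for pair "
                    f"({data.items[i].label}, {data.items[j].label})")
            rho = polychoric_rho(table, thresholds[i], thresholds[j])
            R[i, j] = R[j, i] = rho
            pair_n[i, j] = pair_n[j, i] = n_ij
            if is_boundary(rho):
                boundary.append((data.items[i].label, data.items[j].label))

    min_eig = float(np.linalg.eigvalsh(R)[0])
    repaired = False
    if min_eig < 0.0 or boundary:
        R = nearest_psd_repair(R)
        repaired = True
    return CorrelationEstimate(R, thresholds, repaired, min_eig, pair_n,
                               boundary, data.labels)


def nearest_psd_repair(matrix: np.ndarray,
                       floor: float = 1e-6) -> np.ndarray:
    """Repair an indefinite symmetric matrix to a PSD correlation matrix.

    Eigenvalues are clipped at a small positive floor, the matrix is
    reconstructed and rescaled to unit diagonal.  PSD inputs are returned
    unchanged (idempotence), and no entry can leave [-1, 1].
    """
    A = np.asarray(matrix, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise EstimationError("repair requires a symmetric matrix")
    vals, vecs = np.linalg.eigh(A)
    if vals[0] >= 0.0:
        return A.copy()
    vals = np.maximum(vals, floor)
    B = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    B = (B + B.T) / 2.0
    np.fill_diagonal(B, 1.0)
    return B
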