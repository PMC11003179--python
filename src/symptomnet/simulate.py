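"""Latent-Gaussian ordinal data generation from a known sparse network.

The generative model mirrors the assumption behind polychoric correlation:
each respondent draws a latent multivariate-normal vector whose correlation
structure is implied by a known sparse partial-correlation network, and each
item discretizes its latent coordinate through a fixed, strictly increasing
threshold vector.  Latent marginals are standard normal — all scale
information lives in the thresholds (the identification convention of the
polychoric model).

The default study preset emulates a two-cluster symptom questionnaire:
6 posttraumatic-stress (PTS) items scored 0–4 and 10 posttraumatic-growth
(PTG) items scored 0–5, n = 406 respondents, dense positive within-cluster
structure and a handful of signed cross-cluster "bridge" edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Item, ItemResponseMatrix
from .errors import EstimationError, ValidationError

PTS = "PTS"
PTG = "PTG"

SeedLike = "int | np.random.SeedSequence"


@dataclass(frozen=True)
class TrueNetwork:
    """A known partial-correlation network used as simulation ground truth.

    ``weights`` is the p×p symmetric edge-weight matrix of partial
    correlations with an exactly zero diagonal.  The implied precision
    matrix is ``K = I − weights`` (unit diagonal, ``k_ij = −w_ij``) and must
    be positive definite.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]
    communities: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValidationError("weights diagonal must be exactly zero")
        if np.any(np.abs(w) >= 1.0):
            raise ValidationError("all |w_ij| must be < 1")
        if len(self.node_labels) != w.shape[0] or \
                len(self.communities) != w.shape[0]:
            raise ValidationError("labels/communities length mismatch")
        object.__setattr__(self, "weights", w)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def implied_precision(self) -> np.ndarray:
        return np.eye(self.p) - self.weights


@dataclass(frozen=True)
class ItemModel(Item):
    """Item metadata plus the latent thresholds used for discretization."""

    thresholds: np.ndarray = None  # (n_categories - 1,), strictly increasing

    def __post_init__(self) -> None:
        super().__post_init__()
        th = np.asarray(self.thresholds, dtype=float)
        if th.shape != (self.n_categories - 1,):
            raise ValidationError(
                f"item {self.label!r}: need {self.n_categories - 1} "
                f"thresholds, got {th.shape}")
        if np.any(np.diff(th) <= 0):
            raise ValidationError(
                f"item {self.label!r}: thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", th)

    def as_item(self) -> Item:
        return Item(self.label, self.community, self.n_categories)


def build_true_network(p_pts: int, p_ptg: int, within_density: float,
                       n_bridges: int, bridge_signs: tuple[int, ...],
                       weight_range: tuple[float, float] = (0.12, 0.32),
                       seed: SeedLike = 0, *, eig_floor: float = 0.05,
                       shrink: float = 0.9,
                       max_shrink_iter: int = 50) -> TrueNetwork:
    """Construct a sparse two-community partial-correlation network.

    Within each community, ``round(within_density * n_pairs)`` node pairs
    receive a positive weight drawn uniformly from ``weight_range``.
    Exactly ``n_bridges`` cross-community pairs receive a weight with the
    declared sign and magnitude from the same range.  If the implied
    precision matrix ``I − W`` is not comfortably positive definite (its
    smallest eigenvalue must exceed ``eig_floor``), all weights are
    uniformly multiplied by ``shrink`` — preserving the sign pattern — up to
    ``max_shrink_iter`` times; running out of iterations is an error, never
    a silent truncation.
    """
    if p_pts < 2 or p_ptg < 2:
        raise ValidationError("need at least 2 nodes per community")
    if not 0 < within_density <= 1:
        raise ValidationError("within_density must be in (0, 1]")
    if n_bridges > p_pts * p_ptg:
        raise ValidationError("n_bridges exceeds number of cross pairs")
    if len(bridge_signs) != n_bridges:
        raise ValidationError(
            f"bridge_signs has length {len(bridge_signs)}, "
            f"expected n_bridges = {n_bridges}")
    if any(s not in (-1, 1) for s in bridge_signs):
        raise ValidationError("bridge signs must be +1 or -1")
    lo, hi = weight_range
    if not 0 < lo <= hi < 1:
        raise ValidationError("weight_range must satisfy 0 < lo <= hi < 1")

    rng = np.random.default_rng(seed)
    p = p_pts + p_ptg
    labels = tuple([f"PTS{i + 1}" for i in range(p_pts)]
                   + [f"PTG{i + 1}" for i in range(p_ptg)])
    communities = tuple([PTS] * p_pts + [PTG] * p_ptg)
    W = np.zeros((p, p))

    for offset, size in ((0, p_pts), (p_pts, p_ptg)):
        pairs = [(offset + a, offset + b)
                 for a in range(size) for b in range(a + 1, size)]
        n_edges = int(round(within_density * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        for k in chosen:
            i, j = pairs[k]
            W[i, j] = W[j, i] = rng.uniform(lo, hi)

    cross = [(a, p_pts + b) for a in range(p_pts) for b in range(p_ptg)]
    chosen = rng.choice(len(cross), size=n_bridges, replace=False)
    for sign, k in zip(bridge_signs, chosen):
        i, j = cross[k]
        W[i, j] = W[j, i] = sign * rng.uniform(lo, hi)

    for _ in range(max_shrink_iter + 1):
        min_eig = float(np.linalg.eigvalsh(np.eye(p) - W)[0])
        if min_eig > eig_floor:
            break
        W *= shrink
    else:
        raise EstimationError(
            f"could not reach positive definiteness: min eigenvalue "
            f"{min_eig:.4g} <= floor {eig_floor} after "
            f"{max_shrink_iter} shrink iterations")
    return TrueNetwork(W, labels, communities)


def true_network_to_covariance(net: TrueNetwork) -> np.ndarray:
    """Latent correlation matrix implied by a true network.

    Builds the unit-diagonal precision ``K = I − W``, inverts it, and
    rescales the inverse to unit diagonal.  Converting the precision of the
    result back to partial correlations recovers ``net.weights`` exactly
    (up to round-off).
    """
    K = net.implied_precision()
    min_eig = float(np.linalg.eigvalsh(K)[0])
    if min_eig <= 1e-10:
        raise EstimationError(
            f"implied precision numerically singular "
            f"(min eigenvalue {min_eig:.3g})")
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    R = sigma / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def sample_ordinal(cov: np.ndarray, items: list[ItemModel], n: int,
                   seed: SeedLike = 0) -> ItemResponseMatrix:
    """Draw n latent multivariate-normal rows and discretize per item.

    The assigned category is the number of thresholds strictly below the
    latent value, so discretization is monotone by construction.
    """
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    if len(items) != p:
        raise ValidationError(f"{len(items)} items but covariance is {p}x{p}")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise EstimationError("covariance matrix is not positive definite")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, p)) @ L.T
    values = np.empty((n, p), dtype=np.int64)
    for j, item in enumerate(items):
        values[:, j] = np.searchsorted(item.thresholds, latent[:, j],
                                       side="left")
    return ItemResponseMatrix(values, [it.as_item() for it in items])


# Fixed preset thresholds (documented in docs/methods.md): PTS items are
# right-skewed (most mass in low categories), PTG items roughly symmetric
# with a mild shift toward higher growth categories.
PTS_THRESHOLDS = np.array([-0.25, 0.65, 1.45, 2.25])
PTG_THRESHOLDS = np.array([-1.65, -0.95, -0.25, 0.45, 1.35])

DEFAULT_BRIDGE_SIGNS = (1, 1, -1, -1)


def preset_items(p_pts: int = 6, p_ptg: int = 10) -> list[ItemModel]:
    items = [ItemModel(f"PTS{i + 1}", PTS, 5, PTS_THRESHOLDS)
             for i in range(p_pts)]
    items += [ItemModel(f"PTG{i + 1}", PTG, 6, PTG_THRESHOLDS)
              for i in range(p_ptg)]
    return items


def default_study_preset(seed: int, n: int = 406
                         ) -> tuple[TrueNetwork, list[ItemModel],
                                    ItemResponseMatrix]:
    """The default study conditions: 16 nodes (6 PTS + 10 PTG), two dense
    positive within-cluster blocks (density 0.6), four signed bridges (two
    positive, two negative), n = 406 respondents by default."""
    ss = np.random.SeedSequence(seed)
    s_net, s_data = ss.spawn(2)
    net = build_true_network(6, 10, within_density=0.6, n_bridges=4,
                             bridge_signs=DEFAULT_BRIDGE_SIGNS,
                             weight_range=(0.12, 0.32), seed=s_net)
    items = preset_items()
    cov = true_network_to_covariance(net)
    data = sample_ordinal(cov, items, n, seed=s_data)
    return net, items, data


def weak_sparse_preset(seed: int, n: int = 100
                       ) -> tuple[TrueNetwork, list[ItemModel],
                                  ItemResponseMatrix]:
    """A near-empty counterpart to the default preset, used to exercise
    instability: very sparse within-cluster structure (density 0.10), two
    bridges, small n.  Edge weights sit on [0.30, 0.40] — the EBIC
    detection boundary at n = 100 — so the estimated support is non-empty
    but flickers across subsamples (weaker edges would yield an entirely
    empty estimate, for which EI stability is undefined rather than
    low)."""
    ss = np.random.SeedSequence(seed)
    s_net, s_data = ss.spawn(2)
    net = build_true_network(6, 10, within_density=0.10, n_bridges=2,
                             bridge_signs=(1, -1),
                             weight_range=(0.30, 0.40), seed=s_net)
    items = preset_items()
    cov = true_network_to_covariance(net)
    data = sample_ordinal(cov, items, n, seed=s_data)
    return net, items, data
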