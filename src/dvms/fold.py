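"""Permutation folding of configuration points into a reference Voronoi tile.

The Voronoi sites of a wavefunction tile are the Na! Nb! like-spin
permutation images of a reference point x̄. Folding a configuration point
means relabelling its same-spin electrons so it lands in the tile of the
identity image; because relabelling is a permutation, the optimal fold per
spin is a linear assignment problem with squared-distance costs, and the
folded squared distance to x̄ equals the distance to the *nearest*
permutation image of x̄.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .wavefunction import SpinPartition, as_config_array


@dataclass(frozen=True)
class VoronoiSite:
    """Reference configuration point x̄ with a human-readable label."""

    point: np.ndarray  # (N, 3), bohr
    partition: SpinPartition
    label: str = ""

    def __post_init__(self):
        pt = as_config_array(self.point, self.partition)
        if not np.all(np.isfinite(pt)):
            raise ValueError("non-finite site coordinates")
        object.__setattr__(self, "point", pt)

    @property
    def alpha(self) -> np.ndarray:
        return self.point[: self.partition.n_alpha]

    @property
    def beta(self) -> np.ndarray:
        return self.point[self.partition.n_alpha:]


@dataclass(frozen=True)
class FoldResult:
    folded: np.ndarray  # (N, 3)
    alpha_perm: np.ndarray  # folded[i] = x[alpha_perm[i]]
    beta_perm: np.ndarray
    parity: int
    sq_distance: float


def permutation_parity(perm) -> int:
    """+1 for an even permutation, -1 for odd."""
    perm = np.asarray(perm, dtype=int)
    n = perm.size
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("not a permutation")
    seen = np.zeros(n, dtype=bool)
    parity = 1
    for i in range(n):
        if seen[i]:
            continue
        j = i
        length = 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length % 2 == 0:
            parity = -parity
    return parity


def _spin_fold(block: np.ndarray, ref: np.ndarray):
    """Optimal relabelling of one spin block onto a reference block.

    Returns (perm, cost): perm[i] = index into ``block`` assigned to
    reference electron i.
    """
    if block.shape[0] == 0:
        return np.empty(0, dtype=int), 0.0
    cost = cdist(ref, block, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].sum())


def _spin_fold_both(block: np.ndarray, ref: np.ndarray):
    """Optimal relabelling of one spin block plus the cheapest
    opposite-parity alternative (repair by the lowest-cost transposition of
    the optimum -- exact whenever the parity flip is carried by one
    ambiguous pair, the generic case for physical configurations).

    Returns (perm, cost, alt_perm, alt_cost); alt_perm is None when the
    block has fewer than two electrons (no opposite-parity relabelling).
    """
    n = block.shape[0]
    if n == 0:
        return np.empty(0, dtype=int), 0.0, None, np.inf
    cost = cdist(ref, block, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    c0 = float(cost[rows, cols].sum())
    if n < 2:
        return cols, c0, None, np.inf
    A = cost[:, cols]
    d = np.diag(A)
    delta = A + A.T - d[:, None] - d[None, :]
    np.fill_diagonal(delta, np.inf)
    i, j = np.unravel_index(np.argmin(delta), delta.shape)
    alt = cols.copy()
    alt[[i, j]] = alt[[j, i]]
    return cols, c0, alt, c0 + float(delta[i, j])


def best_fold(x, site: VoronoiSite, parity: int | None = None) -> FoldResult:
    """Fold a configuration point into the tile of ``site``.

    Minimizes sum_i ||r_perm(i) - s_i||^2 over all same-spin relabellings,
    independently per spin (the cross-spin assignment is fixed: electrons
    never change spin).

    ``parity`` restricts the overall relabelling parity: +1 folds onto the
    even-permutation images of the site (the images sharing the site's
    wavefunction sign), -1 onto the odd ones. None (default) is the
    unconstrained nearest image.
    """
    part = site.partition
    arr = as_config_array(x, part)
    na = part.n_alpha
    if parity is None:
        pa, ca = _spin_fold(arr[:na], site.alpha)
        pb, cb = _spin_fold(arr[na:], site.beta)
    else:
        pa0, ca0, pa1, ca1 = _spin_fold_both(arr[:na], site.alpha)
        pb0, cb0, pb1, cb1 = _spin_fold_both(arr[na:], site.beta)
        sa = permutation_parity(pa0) if na else 1
        sb = permutation_parity(pb0) if part.n_beta else 1
        best = None
        for (p_a, c_a, s_a) in ((pa0, ca0, sa), (pa1, ca1, -sa)):
            for (p_b, c_b, s_b) in ((pb0, cb0, sb), (pb1, cb1, -sb)):
                if p_a is None or p_b is None:
                    continue
                if s_a * s_b != parity:
                    continue
                if best is None or c_a + c_b < best[0]:
                    best = (c_a + c_b, p_a, p_b)
        if best is None:
            raise ValueError(
                f"no relabelling with parity {parity:+d} exists for this "
                "electron count")
        _, pa, pb = best
        ca = cb = None  # recomputed below from the chosen permutations
        ca = float(np.sum((arr[:na][pa] - site.alpha) ** 2))
        cb = float(np.sum((arr[na:][pb] - site.beta) ** 2))
    folded = np.concatenate([arr[:na][pa], arr[na:][pb]]) if part.n_electrons \
        else arr
    par = (permutation_parity(pa) if na else 1) * \
        (permutation_parity(pb) if part.n_beta else 1)
    return FoldResult(folded=folded, alpha_perm=pa, beta_perm=pb,
                      parity=par, sq_distance=ca + cb)


def even_fold(x, site: VoronoiSite) -> tuple[FoldResult, bool]:
    """Fold onto the even-permutation images of ``site`` (the images inside
    the walker's own sign region).

    Returns (fold, odd_optimum): ``odd_optimum`` flags that the
    unconstrained nearest image was an odd one, i.e. the parity constraint
    actually changed the fold (a diagnostic of how often the naive fold
    would leave the sign region).
    """
    unconstrained = best_fold(x, site)
    if unconstrained.parity == 1:
        return unconstrained, False
    return best_fold(x, site, parity=1), True


def nearest_site(x, sites) -> tuple[int, FoldResult]:
    """Index of the Voronoi site whose permutation images are nearest to
    ``x``, with the corresponding fold. Ties break to the lowest index."""
    sites = list(sites)
    if not sites:
        raise ValueError("need at least one site")
    best = None
    best_i = -1
    for i, s in enumerate(sites):
        f = best_fold(x, s)
        if best is None or f.sq_distance < best.sq_distance:
            best, best_i = f, i
    return best_i, best


class SpinFactoredSites:
    """Fast classifier for site families that are outer products of a few
    alpha-block variants and beta-block variants.

    The squared folded distance to site (i, j) = (alpha variant i, beta
    variant j) separates as d2_alpha(i) + d2_beta(j), so classification
    needs one assignment solve per variant per spin instead of per site.
    """

    def __init__(self, alpha_variants, beta_variants, partition: SpinPartition,
                 labels=None):
        self.alpha_variants = [np.asarray(a, float) for a in alpha_variants]
        self.beta_variants = [np.asarray(b, float) for b in beta_variants]
        self.partition = partition
        self.labels = labels

    @property
    def sites(self) -> list[VoronoiSite]:
        out = []
        for i, a in enumerate(self.alpha_variants):
            for j, b in enumerate(self.beta_variants):
                lab = (self.labels[i * len(self.beta_variants) + j]
                       if self.labels else f"site-{i}{j}")
                out.append(VoronoiSite(np.concatenate([a, b]),
                                       self.partition, lab))
        return out

    def classify(self, X: np.ndarray, parities=None):
        """Nearest-site index for a batch of configurations (W, N, 3).

        ``parities`` (n_sites,) restricts, per site, the parity of the
        relabelling onto that site (+1: even images, -1: odd images); a
        walker of sign s can only occupy images of site S with parity
        s * sign(Psi(S)). None classifies by unconstrained nearest image.

        Returns (site_index (W,), d2 (W, n_sites)); the site index is
        i * n_beta_variants + j, matching ``self.sites`` order.
        """
        X = np.asarray(X, float)
        W = X.shape[0]
        na = self.partition.n_alpha
        nA, nB = len(self.alpha_variants), len(self.beta_variants)
        # per spin variant, best cost at even (0) and odd (1) parity
        ca = np.full((W, nA, 2), np.inf)
        cb = np.full((W, nB, 2), np.inf)
        for w in range(W):
            for i, ref in enumerate(self.alpha_variants):
                p0, c0, p1, c1 = _spin_fold_both(X[w, :na], ref)
                s0 = permutation_parity(p0) if p0 is not None else 1
                ca[w, i, 0 if s0 == 1 else 1] = c0
                if p1 is not None:
                    ca[w, i, 1 if s0 == 1 else 0] = c1
            for j, ref in enumerate(self.beta_variants):
                p0, c0, p1, c1 = _spin_fold_both(X[w, na:], ref)
                s0 = permutation_parity(p0) if p0 is not None else 1
                cb[w, j, 0 if s0 == 1 else 1] = c0
                if p1 is not None:
                    cb[w, j, 1 if s0 == 1 else 0] = c1
        d2 = np.empty((W, nA * nB))
        for i in range(nA):
            for j in range(nB):
                k = i * nB + j
                even = np.minimum(ca[:, i, 0] + cb[:, j, 0],
                                  ca[:, i, 1] + cb[:, j, 1])
                odd = np.minimum(ca[:, i, 0] + cb[:, j, 1],
                                 ca[:, i, 1] + cb[:, j, 0])
                if parities is None:
                    d2[:, k] = np.minimum(even, odd)
                else:
                    d2[:, k] = even if parities[k] == 1 else odd
        return np.argmin(d2, axis=1), d2

    def fold(self, x, site_index: int, parity: int | None = None
             ) -> FoldResult:
        return best_fold(x, self.sites[site_index], parity=parity)
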