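"""Comparative layer: trait extraction, phylogenetic signal, trees.

A distance matrix is reduced to a single quantitative trait per taxon with
classical multidimensional scaling (principal coordinates), and the
phylogenetic signal of that trait against a time-calibrated ultrametric
tree is quantified with five standard indices:

* Abouheif's Cmean -- autocorrelation with the Abouheif proximity matrix
  (product of 1/#direct-descendants over internal nodes on the tip-to-tip
  path), permutation test.
* Moran's I -- autocorrelation with row-standardised 1/patristic-distance
  weights, permutation test (null expectation -1/(n-1)).
* Blomberg's K and K* -- variance ratios standardised by their Brownian
  motion expectation (K uses the phylogenetic GLS mean, K* the arithmetic
  mean), permutation tests.
* Pagel's lambda -- maximum-likelihood branch-length transform under a
  Brownian model, likelihood-ratio test against lambda = 0 (chi-square with
  one df, halved at the boundary).  The search is bounded by positive
  definiteness of the transformed covariance, not hard-capped at 1.

Distance-based tree building (UPGMA, neighbor joining) and Newick I/O round
out the layer.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "pcoa_axis1",
    "morans_i",
    "abouheif_cmean",
    "blomberg_k",
    "pagel_lambda",
    "IndexResult",
    "BlombergResult",
    "LambdaResult",
    "SignalReport",
    "signal_report",
    "upgma",
    "neighbor_joining",
]


class PhyloTree:
    """A rooted tree with labelled tips and branch lengths (time units).

    Thin wrapper over a :class:`dendropy.Tree` adding the matrix views the
    signal indices need (patristic distances, Brownian covariance, Abouheif
    proximities) and an ultrametricity check.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        self._labels = labels

    # -- construction / serialisation -------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from dendropy.utility.error import DataParseError

        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except DataParseError as exc:
            message = str(exc)
            if "Duplicate taxon labels" in message:
                raise ValueError(f"duplicate tip labels: {message}") from None
            raise ValueError(f"malformed Newick: {message}") from None
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True,
                                 real_value_format_specifier=".12g")
        return s.strip()

    def write(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write(self.to_newick() + "\n")

    # -- basic views -------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def _node_depths(self) -> dict:
        depths = {}
        for node in self._tree.preorder_node_iter():
            parent_depth = depths.get(node.parent_node, 0.0)
            depths[node] = parent_depth + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> pd.Series:
        depths = self._node_depths()
        return pd.Series(
            {leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()}
        )

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """All root-to-tip spans equal within relative tolerance."""
        d = self.tip_depths().to_numpy()
        span = d.max()
        if span == 0:
            return True
        return bool((d.max() - d.min()) <= rel_tol * span)

    # -- matrices ----------------------------------------------------------

    def _order_index(self, order) -> list:
        order = list(order) if order is not None else self.tip_labels
        if set(order) != set(self._labels) or len(order) != len(self._labels):
            raise ValueError("order must be a permutation of the tip labels")
        return order

    def vcv(self, order=None) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        order = self._order_index(order)
        pos = {t: i for i, t in enumerate(order)}
        n = len(order)
        depths = self._node_depths()
        C = np.zeros((n, n))
        leafsets = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = pos[node.taxon.label]
                leafsets[node] = [i]
                C[i, i] = depths[node]
                continue
            children = node.child_nodes()
            sets = [leafsets[c] for c in children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            C[i, j] = C[j, i] = depths[node]
            leafsets[node] = [i for s in sets for i in s]
        return C

    def patristic_matrix(self, order=None) -> np.ndarray:
        """Sum of branch lengths along tip-to-tip paths."""
        order = self._order_index(order)
        C = self.vcv(order)
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def abouheif_proximity(self, order=None) -> np.ndarray:
        """A_ij = 1 / product of #direct-descendants over path internal nodes."""
        order = self._order_index(order)
        tips = {leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()}
        ancestors = {}
        for label in order:
            chain = []
            node = tips[label].parent_node
            while node is not None:
                chain.append(node)
                node = node.parent_node
            ancestors[label] = chain
        n = len(order)
        A = np.zeros((n, n))
        for i in range(n):
            chain_i = ancestors[order[i]]
            set_i = {id(nd): k for k, nd in enumerate(chain_i)}
            for j in range(i + 1, n):
                chain_j = ancestors[order[j]]
                for kj, nd in enumerate(chain_j):
                    if id(nd) in set_i:
                        ki = set_i[id(nd)]
                        break
                path_nodes = chain_i[: ki + 1] + chain_j[:kj]
                prod = 1.0
                for nd in path_nodes:
                    prod *= len(nd.child_nodes())
                A[i, j] = A[j, i] = 1.0 / prod
        return A


def read_newick(path) -> PhyloTree:
    return PhyloTree.read(path)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# Trait extraction (classical MDS / principal coordinates)
# ---------------------------------------------------------------------------


def pcoa_axis1(m) -> pd.Series:
    """First principal coordinate of a distance matrix, one value per taxon.

    Classical (Torgerson) scaling: eigen-decomposition of the double-centred
    squared-distance matrix; the leading eigenvector is scaled by the square
    root of its eigenvalue.  The sign is fixed by making the first taxon's
    coordinate non-negative (all downstream indices are invariant to affine
    trait transforms, so the choice is immaterial).
    """
    taxa = list(m.taxa)
    values = m.values
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = float(values[0, 1]) / 2.0
        return pd.Series([half, -half], index=taxa)
    d2 = values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    lead = int(np.argmax(eigval))
    if eigval[lead] <= 1e-12:
        raise ValueError("degenerate configuration: leading eigenvalue <= 0")
    coords = eigvec[:, lead] * math.sqrt(eigval[lead])
    if coords[0] < 0:
        coords = -coords
    return pd.Series(coords, index=taxa)


# ---------------------------------------------------------------------------
# Phylogenetic signal indices
# ---------------------------------------------------------------------------


@dataclass
class IndexResult:
    estimate: float
    p_value: float
    note: str = ""


@dataclass
class BlombergResult:
    k: float
    k_star: float
    p_k: float
    p_k_star: float
    note: str = ""


@dataclass
class LambdaResult:
    lambda_hat: float
    p_value: float
    log_likelihood: float
    note: str = ""


def _align_trait(trait, tree: PhyloTree) -> tuple:
    order = tree.tip_labels
    if isinstance(trait, pd.Series):
        missing = [t for t in order if t not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tips: {missing}")
        x = trait.reindex(order).to_numpy(dtype=float)
    else:
        x = np.array([trait[t] for t in order], dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("trait values must be finite")
    return x, order


def _random_permutations(n: int, b: int, rng: np.random.Generator) -> np.ndarray:
    return np.argsort(rng.random((b, n)), axis=1)


def _autocorrelation(x: np.ndarray, W: np.ndarray) -> float:
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant trait: autocorrelation undefined")
    # W is row-standardised, so sum(W) = n and the n/S0 factor cancels
    return float(z @ W @ z / denom)


def _moran_type_test(x: np.ndarray, W: np.ndarray, n_perm: int,
                     seed: int) -> tuple:
    obs = _autocorrelation(x, W)
    rng = np.random.default_rng(seed)
    perms = _random_permutations(x.size, n_perm, rng)
    Z = x[perms] - x.mean()
    stat = ((Z @ W) * Z).sum(axis=1) / (Z * Z).sum(axis=1)
    p = (np.count_nonzero(stat >= obs) + 1) / (n_perm + 1)
    return obs, float(p)


def _row_standardise(A: np.ndarray) -> np.ndarray:
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    rowsum = W.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("isolated tip: zero row sum in weight matrix")
    return W / rowsum


def morans_i(trait, tree: PhyloTree, n_perm: int = 999, seed: int = 0) -> IndexResult:
    """Moran's I with row-standardised inverse-patristic-distance weights.

    One-sided permutation test (alternative: positive autocorrelation).
    The expectation under random tip permutation is -1/(n-1).
    """
    x, order = _align_trait(trait, tree)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    P = tree.patristic_matrix(order)
    off = ~np.eye(x.size, dtype=bool)
    if (P[off] <= 0).any():
        raise ValueError("zero patristic distance between distinct tips")
    with np.errstate(divide="ignore"):
        A = 1.0 / P
    W = _row_standardise(A)
    obs, p = _moran_type_test(x, W, n_perm, seed)
    return IndexResult(obs, p, note="weights: row-standardised 1/patristic distance")


def abouheif_cmean(trait, tree: PhyloTree, n_perm: int = 999, seed: int = 0) -> IndexResult:
    """Abouheif's Cmean: Moran-type autocorrelation with Abouheif proximities."""
    x, order = _align_trait(trait, tree)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    W = _row_standardise(tree.abouheif_proximity(order))
    obs, p = _moran_type_test(x, W, n_perm, seed)
    return IndexResult(obs, p, note="weights: row-standardised Abouheif proximities")


def blomberg_k(trait, tree: PhyloTree, n_perm: int = 999, seed: int = 0) -> BlombergResult:
    """Blomberg's K and K*, with one-sided permutation tests.

    Both compare the observed ratio of among-tip variance to
    phylogenetically corrected variance against its Brownian-motion
    expectation; K centres the trait on the phylogenetic GLS mean, K* on
    the arithmetic mean.  K ~ 1 under Brownian evolution, < 1 for
    star-like (signal-free) traits.
    """
    x, order = _align_trait(trait, tree)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 tips")
    V = tree.vcv(order)
    try:
        cho = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    Vinv1 = cho_solve(cho, np.ones(n))
    s_inv = float(Vinv1.sum())  # 1' V^-1 1
    trV = float(np.trace(V))
    sumV = float(V.sum())
    expected_k = (trV - n / s_inv) / (n - 1)
    expected_kstar = (trV - sumV / n) / (n - 1)

    def k_stats(X: np.ndarray) -> tuple:
        """Vectorised (K, K*) for trait rows of X."""
        ahat = (X @ Vinv1) / s_inv
        R = X - ahat[:, None]
        mse = np.einsum("bi,bi->b", R, cho_solve(cho, R.T).T) / (n - 1)
        mse0 = (R**2).sum(axis=1) / (n - 1)
        Rm = X - X.mean(axis=1, keepdims=True)
        mse0_star = (Rm**2).sum(axis=1) / (n - 1)
        return (mse0 / mse) / expected_k, (mse0_star / mse) / expected_kstar

    k_obs, kstar_obs = (float(v[0]) for v in k_stats(x[None, :]))
    rng = np.random.default_rng(seed)
    perms = _random_permutations(n, n_perm, rng)
    k_perm, kstar_perm = k_stats(x[perms])
    p_k = (np.count_nonzero(k_perm >= k_obs) + 1) / (n_perm + 1)
    p_kstar = (np.count_nonzero(kstar_perm >= kstar_obs) + 1) / (n_perm + 1)
    return BlombergResult(k_obs, kstar_obs, float(p_k), float(p_kstar))


def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    C = lam * V
    np.fill_diagonal(C, np.diag(V))
    return C


def _lambda_max(V: np.ndarray, cap: float = 3.0) -> float:
    """Largest lambda keeping the transformed covariance positive definite."""

    def pd_ok(lam: float) -> bool:
        try:
            cho_factor(_lambda_cov(V, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    if pd_ok(cap):
        return cap
    lo, hi = (1.0, cap) if pd_ok(1.0) else (0.0, 1.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _bm_loglik(x: np.ndarray, C: np.ndarray) -> float:
    n = x.size
    try:
        cho = cho_factor(C)
    except np.linalg.LinAlgError:
        return -np.inf
    Cinv1 = cho_solve(cho, np.ones(n))
    mu = float(x @ Cinv1 / Cinv1.sum())
    r = x - mu
    q = float(r @ cho_solve(cho, r))
    if q <= 0:
        return -np.inf
    sigma2 = q / n
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def pagel_lambda(trait, tree: PhyloTree) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda with a boundary-corrected LRT.

    Off-diagonal covariances are scaled by lambda; the ML search runs over
    [0, lambda_max] where lambda_max keeps the covariance positive definite
    (this can exceed 1 on ultrametric trees).  The p-value is a likelihood
    ratio test against lambda = 0 using a chi-square with one degree of
    freedom halved at the boundary.
    """
    x, order = _align_trait(trait, tree)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    V = tree.vcv(order)
    lam_max = _lambda_max(V)

    def nll(lam: float) -> float:
        return -_bm_loglik(x, _lambda_cov(V, lam))

    res = optimize.minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-6})
    candidates = [(nll(0.0), 0.0), (nll(lam_max * (1 - 1e-9)), lam_max),
                  (float(res.fun), float(res.x))]
    best_nll, lam_hat = min(candidates)
    if not np.isfinite(best_nll):
        raise ValueError("non-finite likelihood in lambda optimisation "
                         f"(lambda_max={lam_max:.4g}, n={x.size})")
    ll_hat = -best_nll
    ll0 = _bm_loglik(x, _lambda_cov(V, 0.0))
    lrt = 2.0 * (ll_hat - ll0)
    p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return LambdaResult(float(lam_hat), float(p), float(ll_hat),
                        note=f"ML on [0, {lam_max:.4g}], boundary-halved chi2 LRT")


@dataclass
class SignalReport:
    """The five phylogenetic-signal indices for one trait/tree pair."""

    cmean: IndexResult
    morans_i: IndexResult
    blomberg: BlombergResult
    pagel: LambdaResult
    n_permutations: int
    seed: int
    trait_name: str = ""

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "cmean": {"estimate": self.cmean.estimate, "p": self.cmean.p_value},
            "morans_i": {"estimate": self.morans_i.estimate, "p": self.morans_i.p_value},
            "blomberg_k": {"estimate": self.blomberg.k, "p": self.blomberg.p_k},
            "blomberg_k_star": {"estimate": self.blomberg.k_star, "p": self.blomberg.p_k_star},
            "pagel_lambda": {"estimate": self.pagel.lambda_hat, "p": self.pagel.p_value},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @staticmethod
    def _stars(p: float) -> str:
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "NS"

    def to_tsv_row(self) -> str:
        cells = []
        for est, p in [
            (self.cmean.estimate, self.cmean.p_value),
            (self.morans_i.estimate, self.morans_i.p_value),
            (self.blomberg.k, self.blomberg.p_k),
            (self.blomberg.k_star, self.blomberg.p_k_star),
            (self.pagel.lambda_hat, self.pagel.p_value),
        ]:
            cells.append(f"{est:.4f} {self._stars(p)}")
        return "\t".join([self.trait_name] + cells)


def signal_report(trait, tree: PhyloTree, n_perm: int = 999, seed: int = 0,
                  trait_name: str = "") -> SignalReport:
    """Compute all five signal indices for one trait vector."""
    return SignalReport(
        cmean=abouheif_cmean(trait, tree, n_perm, seed),
        morans_i=morans_i(trait, tree, n_perm, seed),
        blomberg=blomberg_k(trait, tree, n_perm, seed),
        pagel=pagel_lambda(trait, tree),
        n_permutations=n_perm,
        seed=seed,
        trait_name=trait_name,
    )


# ---------------------------------------------------------------------------
# Distance-based trees
# ---------------------------------------------------------------------------


def upgma(m) -> PhyloTree:
    """Average-linkage agglomeration; the output tree is ultrametric.

    Merge heights are D/2; at equal minimum distance the pair containing
    the lexicographically smallest member label is merged first, making the
    result deterministic.
    """
    taxa = list(m.taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    # cluster state: id -> (member labels, size, height, newick fragment)
    clusters = {i: ([t], 1, 0.0, t) for i, t in enumerate(taxa)}
    dist = {frozenset((i, j)): float(m.values[i, j])
            for i in range(len(taxa)) for j in range(i + 1, len(taxa))}
    next_id = len(taxa)
    while len(clusters) > 1:
        def sort_key(pair):
            i, j = tuple(pair)
            labs = sorted([min(clusters[i][0]), min(clusters[j][0])])
            return (dist[pair], labs)

        best = min(dist, key=sort_key)
        i, j = tuple(best)
        d = dist[best]
        labels_i, ni, hi, nwk_i = clusters.pop(i)
        labels_j, nj_, hj, nwk_j = clusters.pop(j)
        h = d / 2.0
        newick = f"({nwk_i}:{h - hi:.10g},{nwk_j}:{h - hj:.10g})"
        for other in clusters:
            d_new = (ni * dist.pop(frozenset((i, other)))
                     + nj_ * dist.pop(frozenset((j, other)))) / (ni + nj_)
            dist[frozenset((next_id, other))] = d_new
        dist.pop(best)
        clusters[next_id] = (labels_i + labels_j, ni + nj_, h, newick)
        next_id += 1
    (_, _, _, newick) = next(iter(clusters.values()))
    return PhyloTree.from_newick(newick + ";")


def neighbor_joining(m) -> PhyloTree:
    """Standard neighbor joining (unrooted; negative branches clamped to 0)."""
    import skbio
    from skbio.tree import nj as _nj

    taxa = list(m.taxa)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    sk_dm = skbio.DistanceMatrix(m.values, ids=taxa)
    tree = _nj(sk_dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue())
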