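"""Mixed-effects Bayesian Additive Regression Trees.

A sum of shallow regression trees plus a cluster-level random intercept,

    y_ij = sum_k g_k(x_ij; J_k, M_k) + b_i + eps_ij,   b_i ~ N(0, sigma_b^2),

updated one backfitting sweep at a time so it can sit inside an outer Gibbs
sampler.  Two response modes are supported: ``gaussian`` (residual variance
sigma^2 given a conjugate inverse-gamma update) and ``probit_latent`` (the
response is a latent Gaussian with variance fixed at 1, as in probit data
augmentation; sigma^2 is never updated).

Tree structure follows the canonical BART prior: a node at depth d splits
with probability alpha (1+d)^(-beta); leaf values are i.i.d. N(0, sigma_mu^2);
structures move by Metropolis-Hastings GROW / PRUNE / CHANGE proposals against
the partial residual of the other trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionTree",
    "MixedBartModel",
    "bart_sweep",
    "update_random_intercepts",
    "update_residual_variance",
    "predict",
    "leaf_prior_scale",
]

_LEAF = -1
_DEAD = -9


def leaf_prior_scale(y_range: float, K: int, k_scale: float = 2.0,
                     mode: str = "gaussian") -> float:
    """Prior standard deviation of a single leaf value.

    Gaussian responses are centered, so the sum of K leaves should cover the
    observed range with k_scale prior standard deviations on each side:
    sigma_mu = y_range / (2 k_scale sqrt(K)).  Probit latents live on a fixed
    scale, covered by sigma_mu = 3 / (k_scale sqrt(K)).
    """
    if K < 1:
        raise ValueError("K must be a positive tree count")
    if mode == "gaussian":
        return float(y_range) / (2.0 * k_scale * math.sqrt(K))
    if mode in ("probit", "probit_latent"):
        return 3.0 / (k_scale * math.sqrt(K))
    raise ValueError(f"unknown response mode {mode!r}")


class DecisionTree:
    """Binary tree stored as parallel node arrays.

    Internal nodes carry (feature, threshold); leaves carry a value ``mu``.
    Node slots are append-only; pruned subtrees are tombstoned.
    """

    __slots__ = ("feature", "threshold", "left", "right", "parent",
                 "depth", "mu")

    def __init__(self):
        self.feature = [_LEAF]
        self.threshold = [0.0]
        self.left = [-1]
        self.right = [-1]
        self.parent = [-1]
        self.depth = [0]
        self.mu = [0.0]

    # -- structure queries ----------------------------------------------
    def is_leaf(self, node: int) -> bool:
        return self.feature[node] == _LEAF

    def leaves(self) -> list[int]:
        return [i for i, f in enumerate(self.feature) if f == _LEAF]

    def prunable(self) -> list[int]:
        """Internal nodes whose two children are both leaves."""
        out = []
        for i, f in enumerate(self.feature):
            if f >= 0 and self.feature[self.left[i]] == _LEAF \
                    and self.feature[self.right[i]] == _LEAF:
                out.append(i)
        return out

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f == _LEAF)

    # -- structure edits -------------------------------------------------
    def split(self, node: int, feature: int, threshold: float) -> tuple[int, int]:
        lc, rc = len(self.feature), len(self.feature) + 1
        for child in (lc, rc):
            self.feature.append(_LEAF)
            self.threshold.append(0.0)
            self.left.append(-1)
            self.right.append(-1)
            self.parent.append(node)
            self.depth.append(self.depth[node] + 1)
            self.mu.append(0.0)
        self.feature[node] = feature
        self.threshold[node] = threshold
        self.left[node], self.right[node] = lc, rc
        return lc, rc

    def collapse(self, node: int) -> None:
        lc, rc = self.left[node], self.right[node]
        self.feature[lc] = self.feature[rc] = _DEAD
        self.feature[node] = _LEAF
        self.left[node] = self.right[node] = -1
        self.mu[node] = 0.0

    # -- data routing ----------------------------------------------------
    def assign(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index for every row of X (vectorized traversal)."""
        out = np.zeros(X.shape[0], dtype=np.int64)
        stack = [0]
        while stack:
            node = stack.pop()
            if self.feature[node] == _LEAF:
                continue
            rows = out == node
            go_left = rows & (X[:, self.feature[node]] <= self.threshold[node])
            out[go_left] = self.left[node]
            out[rows & ~go_left] = self.right[node]
            stack.extend((self.left[node], self.right[node]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        mu = np.asarray(self.mu)
        return mu[self.assign(X)]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {k: list(getattr(self, k)) for k in self.__slots__}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        t = cls.__new__(cls)
        for k in cls.__slots__:
            setattr(t, k, list(d[k]))
        return t


class MixedBartModel:
    """Sum-of-trees mean function with a cluster random intercept.

    Parameters
    ----------
    X : training covariate matrix (used to fix the cutpoint grids)
    y : initial response (sets centering offset and the leaf-prior scale)
    n_clusters : total number of clusters indexable by ``clusters`` vectors
    K : number of trees
    mode : 'gaussian' or 'probit_latent'
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_clusters: int,
                 K: int = 50, mode: str = "gaussian", k_scale: float = 2.0,
                 n_cutpoints: int = 100, min_leaf: int = 5,
                 alpha_tree: float = 0.95, beta_tree: float = 2.0,
                 a0: float = 0.001, b0: float = 0.001,
                 rng: np.random.Generator | None = None):
        if mode not in ("gaussian", "probit_latent"):
            raise ValueError(f"unknown response mode {mode!r}")
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.size == 0:
            raise ValueError("empty response")
        self.mode = mode
        self.K = int(K)
        self.min_leaf = int(min_leaf)
        self.alpha_tree = float(alpha_tree)
        self.beta_tree = float(beta_tree)
        self.a0, self.b0 = float(a0), float(b0)
        self.p = X.shape[1]
        self.n_clusters = int(n_clusters)

        # quantile cutpoint grids, fixed for the life of the model
        self.cutpoints = []
        qs = np.linspace(0, 1, n_cutpoints + 2)[1:-1]
        for j in range(self.p):
            grid = np.unique(np.quantile(X[:, j], qs))
            self.cutpoints.append(grid)

        if mode == "gaussian":
            self.offset = float(y.mean())
            y_range = float(y.max() - y.min()) or 1.0
            self.sigma2 = float(np.var(y - self.offset)) or 1.0
        else:
            self.offset = 0.0
            y_range = 6.0
            self.sigma2 = 1.0
        self.sigma_mu = leaf_prior_scale(y_range, self.K, k_scale, mode)

        # random-intercept block: IG(1.5, 1.5*lam_hat) prior on sigma_b^2,
        # the scalar reduction of an inverse-Wishart with 3 degrees of freedom
        self.b = np.zeros(self.n_clusters)
        lam = float(np.var(y - y.mean())) / 4.0 or 0.1
        self.ab_prior = 1.5
        self.bb_prior = 1.5 * lam
        self.sigma_b2 = lam

        self.trees = [DecisionTree() for _ in range(self.K)]
        self.rng = rng or np.random.default_rng()

        # per-call training cache
        self._cache_token: object = None
        self._node_of: list[np.ndarray] | None = None
        self._tree_fit: np.ndarray | None = None
        self._total_fit: np.ndarray | None = None
        self._move_stats = {"grow": [0, 0], "prune": [0, 0], "change": [0, 0]}

    # -- prediction -------------------------------------------------------
    def tree_sum(self, X: np.ndarray) -> np.ndarray:
        out = np.full(X.shape[0], self.offset)
        for t in self.trees:
            out += t.predict(X)
        return out

    def predict(self, X: np.ndarray, clusters: np.ndarray | None = None,
                include_intercepts: bool = False) -> np.ndarray:
        out = self.tree_sum(X)
        if include_intercepts:
            if clusters is None:
                raise ValueError("intercepts requested without cluster indices")
            clusters = np.asarray(clusters)
            known = (clusters >= 0) & (clusters < self.n_clusters)
            add = np.zeros(len(clusters))
            add[known] = self.b[clusters[known]]
            out = out + add  # unknown clusters get the prior-mean 0
        return out

    # -- cache ------------------------------------------------------------
    def _sync_cache(self, X: np.ndarray, token: object) -> None:
        if (token is not None and self._node_of is not None
                and self._cache_token == token):
            return
        self._node_of = [t.assign(X) for t in self.trees]
        self._tree_fit = np.empty((self.K, X.shape[0]))
        for k, t in enumerate(self.trees):
            self._tree_fit[k] = np.asarray(t.mu)[self._node_of[k]]
        self._total_fit = self._tree_fit.sum(axis=0)
        self._cache_token = token

    # -- marginal likelihood of a leaf ------------------------------------
    def _lml(self, n: float, s: float) -> float:
        v = self.sigma2 + n * self.sigma_mu**2
        return 0.5 * math.log(self.sigma2 / v) + \
            self.sigma_mu**2 * s * s / (2.0 * self.sigma2 * v)

    def _p_split(self, depth: int) -> float:
        return self.alpha_tree * (1.0 + depth) ** (-self.beta_tree)

    def _valid_cuts(self, xv: np.ndarray, j: int) -> np.ndarray:
        # c == lo is allowed (left child takes x <= c); c == hi would leave
        # the right child empty.  Binary covariates split at c = 0.
        grid = self.cutpoints[j]
        lo, hi = xv.min(), xv.max()
        return grid[(grid >= lo) & (grid < hi)]

    # -- one MH structure move for tree k ---------------------------------
    def _move(self, k: int, X: np.ndarray, r: np.ndarray) -> None:
        tree = self.trees[k]
        node_of = self._node_of[k]
        rng = self.rng
        single = tree.n_leaves == 1
        u = rng.random()
        p_grow, p_prune = 0.25, 0.25
        if single or u < p_grow:
            move = "grow"
        elif u < p_grow + p_prune:
            move = "prune"
        else:
            move = "change"
        self._move_stats[move][1] += 1

        if move == "grow":
            leaves = tree.leaves()
            leaf = leaves[rng.integers(len(leaves))]
            rows = np.nonzero(node_of == leaf)[0]
            if len(rows) < 2 * self.min_leaf:
                return
            j = int(rng.integers(self.p))
            xv = X[rows, j]
            cuts = self._valid_cuts(xv, j)
            if len(cuts) == 0:
                return
            c = float(cuts[rng.integers(len(cuts))])
            lmask = xv <= c
            nL = int(lmask.sum())
            nR = len(rows) - nL
            if nL < self.min_leaf or nR < self.min_leaf:
                return
            sL = float(r[rows[lmask]].sum())
            s = float(r[rows].sum())
            sR = s - sL
            d = tree.depth[leaf]
            ps, ps1 = self._p_split(d), self._p_split(d + 1)
            log_prior = math.log(ps) + 2 * math.log1p(-ps1) - math.log1p(-ps)
            log_lik = self._lml(nL, sL) + self._lml(nR, sR) - \
                self._lml(len(rows), s)
            parent = tree.parent[leaf]
            pp = tree.prunable()
            n_pp_new = len(pp) + 1 - (1 if parent in pp else 0)
            p_grow_fwd = 1.0 if single else p_grow
            # the uniform (var, cut) proposal matches the uniform rule prior,
            # so those factors cancel; only node-selection terms remain
            log_prop = math.log(p_prune / n_pp_new) - math.log(
                p_grow_fwd / len(leaves))
            if math.log(rng.random() + 1e-300) < log_prior + log_lik + log_prop:
                lc, rc = tree.split(leaf, j, c)
                node_of[rows[lmask]] = lc
                node_of[rows[~lmask]] = rc
                self._move_stats["grow"][0] += 1
        elif move == "prune":
            pp = tree.prunable()
            if not pp:
                return
            node = pp[rng.integers(len(pp))]
            lc, rc = tree.left[node], tree.right[node]
            lrows = np.nonzero(node_of == lc)[0]
            rrows = np.nonzero(node_of == rc)[0]
            rows = np.concatenate([lrows, rrows])
            if len(rows) == 0:
                return
            j = tree.feature[node]
            cuts = self._valid_cuts(X[rows, j], j)
            if len(cuts) == 0:
                return  # reverse grow impossible; keep structure
            sL = float(r[lrows].sum())
            sR = float(r[rrows].sum())
            s = sL + sR
            d = tree.depth[node]
            ps, ps1 = self._p_split(d), self._p_split(d + 1)
            log_prior = math.log(ps) + 2 * math.log1p(-ps1) - math.log1p(-ps)
            log_lik = self._lml(len(lrows), sL) + self._lml(len(rrows), sR) - \
                self._lml(len(rows), s)
            n_leaves_after = tree.n_leaves - 1
            p_grow_rev = 1.0 if n_leaves_after == 1 else p_grow
            log_prop = math.log(p_grow_rev / n_leaves_after) \
                - math.log(p_prune / len(pp))
            if math.log(rng.random() + 1e-300) < -log_prior - log_lik + log_prop:
                tree.collapse(node)
                node_of[rows] = node
                self._move_stats["prune"][0] += 1
        else:  # change
            pp = tree.prunable()
            if not pp:
                return
            node = pp[rng.integers(len(pp))]
            lc, rc = tree.left[node], tree.right[node]
            rows = np.nonzero((node_of == lc) | (node_of == rc))[0]
            if len(rows) < 2 * self.min_leaf:
                return
            j_new = int(rng.integers(self.p))
            cuts_new = self._valid_cuts(X[rows, j_new], j_new)
            if len(cuts_new) == 0:
                return
            c_new = float(cuts_new[rng.integers(len(cuts_new))])
            lmask = X[rows, j_new] <= c_new
            nL = int(lmask.sum())
            nR = len(rows) - nL
            if nL < self.min_leaf or nR < self.min_leaf:
                return
            old_l = node_of[rows] == lc
            sL_old = float(r[rows[old_l]].sum())
            sR_old = float(r[rows[~old_l]].sum())
            nL_old = int(old_l.sum())
            sL = float(r[rows[lmask]].sum())
            sR = sL_old + sR_old - sL
            # rule prior and rule proposal are the same uniform scheme and
            # cancel; the ratio reduces to the marginal-likelihood ratio
            log_lik = (self._lml(nL, sL) + self._lml(nR, sR)
                       - self._lml(nL_old, sL_old)
                       - self._lml(len(rows) - nL_old, sR_old))
            if math.log(rng.random() + 1e-300) < log_lik:
                tree.feature[node] = j_new
                tree.threshold[node] = c_new
                node_of[rows[lmask]] = lc
                node_of[rows[~lmask]] = rc
                self._move_stats["change"][0] += 1

    # -- leaf value draws --------------------------------------------------
    def _draw_leaves(self, k: int, r: np.ndarray) -> None:
        tree = self.trees[k]
        node_of = self._node_of[k]
        leaves = tree.leaves()
        lut = np.full(len(tree.feature), -1, dtype=np.int64)
        lut[leaves] = np.arange(len(leaves))
        compact = lut[node_of]
        counts = np.bincount(compact, minlength=len(leaves)).astype(float)
        sums = np.bincount(compact, weights=r, minlength=len(leaves))
        prec = counts / self.sigma2 + 1.0 / self.sigma_mu**2
        var = 1.0 / prec
        mean = var * sums / self.sigma2
        draws = mean + np.sqrt(var) * self.rng.standard_normal(len(leaves))
        for leaf, val in zip(leaves, draws):
            tree.mu[leaf] = float(val)
        self._tree_fit[k] = draws[compact]

    # -- full sweep --------------------------------------------------------
    def sweep(self, X: np.ndarray, y: np.ndarray, clusters: np.ndarray,
              rng: np.random.Generator | None = None,
              cache_token: object = None) -> "MixedBartModel":
        """One backfitting pass: all K trees, intercepts, then variances."""
        if rng is not None:
            self.rng = rng
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.size == 0:
            raise ValueError("empty response")
        clusters = np.asarray(clusters)
        token = cache_token if cache_token is not None else object()
        self._sync_cache(X, token)
        yc = y - self.offset
        bvec = self.b[clusters]
        for k in range(self.K):
            r = yc - (self._total_fit - self._tree_fit[k]) - bvec
            old = self._tree_fit[k].copy()
            self._move(k, X, r)
            # recompute fit after a possible structural change
            self._tree_fit[k] = np.asarray(self.trees[k].mu)[self._node_of[k]]
            self._draw_leaves(k, r)
            self._total_fit += self._tree_fit[k] - old
        resid = yc - self._total_fit
        self.update_intercepts(resid, clusters)
        if self.mode == "gaussian":
            ssr = float(((resid - self.b[clusters]) ** 2).sum())
            self.sigma2 = _draw_inv_gamma(
                self.a0 + len(y) / 2.0, self.b0 + ssr / 2.0, self.rng)
        return self

    # -- random-intercept block ---------------------------------------------
    def update_intercepts(self, residuals: np.ndarray,
                          clusters: np.ndarray) -> np.ndarray:
        """Draw every b_i from its normal full conditional, then sigma_b^2.

        Clusters absent from ``clusters`` are drawn from the N(0, sigma_b^2)
        prior.  Full-conditional precision is n_i/sigma^2 + 1/sigma_b^2.
        """
        counts = np.bincount(clusters, minlength=self.n_clusters).astype(float)
        sums = np.bincount(clusters, weights=residuals,
                           minlength=self.n_clusters)
        prec = counts / self.sigma2 + 1.0 / self.sigma_b2
        var = 1.0 / prec
        mean = var * sums / self.sigma2
        self.b = mean + np.sqrt(var) * self.rng.standard_normal(self.n_clusters)
        self.sigma_b2 = _draw_inv_gamma(
            self.ab_prior + self.n_clusters / 2.0,
            self.bb_prior + float((self.b ** 2).sum()) / 2.0, self.rng)
        return self.b

    # -- diagnostics ---------------------------------------------------------
    def acceptance_rates(self) -> dict[str, float]:
        return {m: (a / n if n else float("nan"))
                for m, (a, n) in self._move_stats.items()}

    # -- serialization --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "mode": self.mode, "K": self.K, "offset": self.offset,
            "sigma2": self.sigma2, "sigma_mu": self.sigma_mu,
            "sigma_b2": self.sigma_b2, "b": self.b.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        })

    def restore_trees(self, payload: str) -> None:
        d = json.loads(payload)
        self.trees = [DecisionTree.from_dict(t) for t in d["trees"]]
        self.offset = d["offset"]
        self.sigma2 = d["sigma2"]
        self.sigma_mu = d["sigma_mu"]
        self.sigma_b2 = d["sigma_b2"]
        self.b = np.asarray(d["b"])
        self._cache_token = None


def _draw_inv_gamma(shape: float, rate: float,
                    rng: np.random.Generator) -> float:
    return float(rate / rng.gamma(shape))


# ---------------------------------------------------------------------------
# functional surface used by the samplers and tests
# ---------------------------------------------------------------------------

def bart_sweep(model: MixedBartModel, X: np.ndarray, y: np.ndarray,
               clusters: np.ndarray, rng: np.random.Generator,
               cache_token: object = None) -> MixedBartModel:
    """One full backfitting sweep (tree moves, leaf draws, intercepts,
    variance updates); mutates and returns ``model``."""
    return model.sweep(X, y, clusters, rng, cache_token)


def update_random_intercepts(model: MixedBartModel, residuals: np.ndarray,
                             clusters: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    model.rng = rng
    return model.update_intercepts(np.asarray(residuals, float),
                                   np.asarray(clusters))


def update_residual_variance(model: MixedBartModel, residuals: np.ndarray,
                             prior: tuple[float, float],
                             rng: np.random.Generator) -> float:
    """Conjugate draw sigma^2 ~ IG(a0 + n/2, b0 + SSR/2); gaussian mode only."""
    if model.mode != "gaussian":
        raise ValueError("residual variance is fixed at 1 in probit mode")
    a0, b0 = prior
    residuals = np.asarray(residuals, float)
    ssr = float((residuals ** 2).sum())
    model.sigma2 = _draw_inv_gamma(a0 + residuals.size / 2.0,
                                   b0 + ssr / 2.0, rng)
    return model.sigma2


def predict(model: MixedBartModel, X: np.ndarray,
            clusters: np.ndarray | None = None,
            include_intercepts: bool = False) -> np.ndarray:
    return model.predict(np.asarray(X, float), clusters, include_intercepts)
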