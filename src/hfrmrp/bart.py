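"""Probit Bayesian additive regression trees for (possibly weighted) binary data.

A sum-of-trees model f(x) = sum_j g(x; T_j, M_j) with the standard
regularisation prior: P(a node at depth d splits) = alpha * (1 + d)^-beta,
leaf values iid N(0, sigma_mu^2) with sigma_mu = 3 / (k * sqrt(n_trees)) so
the prior mass of f stays in roughly [-3, 3] on the probit scale. Binary
outcomes enter through latent-variable data augmentation: each Bernoulli
trial contributes a N(offset + f(x), 1) latent truncated to the positive or
negative half-line according to its outcome, and the trees are updated by
Metropolis-Hastings grow/prune/change moves given the latent sums.

Rows may carry binomial counts (``trials``, ``successes``); a row with n
trials contributes the sum of its n latent variables, which is exactly the
expanded-record likelihood at a fraction of the cost. Survey microdata is
the special case trials = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

_EPS = 1e-12


class _Node:
    __slots__ = ("var", "cut", "left", "right", "value", "rows", "weight", "depth")

    def __init__(self, rows, depth, weight):
        self.var = -1          # -1 marks a leaf
        self.cut = 0.0
        self.left = None
        self.right = None
        self.value = 0.0
        self.rows = rows       # training-row indices, leaves only
        self.weight = weight   # total trials in this leaf
        self.depth = depth

    @property
    def is_leaf(self):
        return self.var < 0


def _leaves(node, out):
    if node.is_leaf:
        out.append(node)
    else:
        _leaves(node.left, out)
        _leaves(node.right, out)
    return out


def _nog_nodes(node, out):
    """Internal nodes whose children are both leaves (prunable)."""
    if node.is_leaf:
        return out
    if node.left.is_leaf and node.right.is_leaf:
        out.append(node)
    _nog_nodes(node.left, out)
    _nog_nodes(node.right, out)
    return out


def _parent_is_nog(root, leaf):
    """True iff `leaf` has a parent whose other child is also a leaf."""

    def parent_of(nd, target):
        if nd.is_leaf:
            return None
        if nd.left is target or nd.right is target:
            return nd
        return parent_of(nd.left, target) or parent_of(nd.right, target)

    par = parent_of(root, leaf)
    if par is None:
        return False
    sib = par.right if par.left is leaf else par.left
    return sib.is_leaf


def _flatten(root):
    """Compact (var, cut, left, right, value) arrays for storage/prediction."""
    links = {}
    order = []

    def walk(nd):
        idx = len(order)
        order.append(nd)
        if nd.is_leaf:
            links[idx] = (-1, -1)
            return idx
        li = walk(nd.left)
        ri = walk(nd.right)
        links[idx] = (li, ri)
        return idx

    walk(root)
    n = len(order)
    var = np.fromiter((nd.var for nd in order), dtype=np.int32, count=n)
    cut = np.fromiter((nd.cut for nd in order), dtype=np.float64, count=n)
    val = np.fromiter((nd.value for nd in order), dtype=np.float64, count=n)
    left = np.fromiter((links[i][0] for i in range(n)), dtype=np.int32, count=n)
    right = np.fromiter((links[i][1] for i in range(n)), dtype=np.int32, count=n)
    return var, cut, left, right, val


def _eval_flat(tree, X):
    var, cut, left, right, val = tree
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if var[node] < 0:
            out[idx] = val[node]
        else:
            go_left = X[idx, var[node]] <= cut[node]
            stack.append((left[node], idx[go_left]))
            stack.append((right[node], idx[~go_left]))
    return out


def evaluate_forest(forest, X):
    """Sum of flattened trees evaluated at X."""
    total = np.zeros(X.shape[0])
    for tree in forest:
        total += _eval_flat(tree, X)
    return total


@dataclass
class BartSettings:
    """Sampler settings; the defaults are the desk-scale preset."""

    n_trees: int = 50
    n_burn: int = 300
    n_draws: int = 500
    thin: int = 2
    alpha: float = 0.95
    beta: float = 2.0
    k: float = 2.0
    max_cutpoints: int = 100
    p_grow: float = 0.25
    p_prune: float = 0.25


class ProbitBart:
    """MCMC sampler for the probit sum-of-trees model.

    After ``fit``, kept posterior draws of the forest are stored compactly,
    so ``predict_draws`` can evaluate the posterior at arbitrary covariate
    rows; if ``X_pred`` is passed to ``fit`` the prediction draws for that
    grid are computed on the fly and stored in ``pred_draws_``.
    """

    def __init__(self, settings: BartSettings | None = None, seed: int = 0):
        self.settings = settings or BartSettings()
        self.seed = int(seed)
        self.forests_: list | None = None
        self.pred_draws_: np.ndarray | None = None
        self.offset_: float = 0.0

    # -- latent augmentation ------------------------------------------------

    def _sample_latent_sums(self, mean, rng):
        """Sum of truncated-normal latents per row, exact and vectorised."""
        S = np.zeros(self._n)
        if len(self._pos_rows):
            m = mean[self._pos_rows]
            lo = ndtr(-m)                       # P(z < 0)
            u = rng.random(len(m))
            q = np.clip(lo + u * (1.0 - lo), _EPS, 1 - _EPS)
            z = m + ndtri(q)
            np.add.at(S, self._pos_rows, np.maximum(z, 0.0))
        if len(self._neg_rows):
            m = mean[self._neg_rows]
            lo = ndtr(-m)
            u = rng.random(len(m))
            q = np.clip(u * lo, _EPS, 1 - _EPS)
            z = m + ndtri(q)
            np.add.at(S, self._neg_rows, np.minimum(z, 0.0))
        return S

    # -- marginal likelihood ------------------------------------------------

    def _leaf_lml(self, W, R):
        t2 = self._tau2
        return -0.5 * np.log1p(t2 * W) + 0.5 * t2 * R * R / (1.0 + t2 * W)

    def _p_split(self, depth):
        s = self.settings
        return s.alpha * (1.0 + depth) ** (-s.beta)

    # -- proposals ----------------------------------------------------------

    def _valid_cut_range(self, var, rows):
        x = self._X[rows, var]
        lo, hi = x.min(), x.max()
        grid = self._grids[var]
        j0 = np.searchsorted(grid, lo, side="left")
        j1 = np.searchsorted(grid, hi, side="left")
        return grid, j0, j1           # valid cuts are grid[j0:j1]

    def _try_grow(self, root, r, rng):
        s = self.settings
        leaves = _leaves(root, [])
        L = len(leaves)
        leaf = leaves[rng.integers(L)]
        var = int(rng.integers(self._p))
        grid, j0, j1 = self._valid_cut_range(var, leaf.rows)
        if j1 <= j0:
            return False
        cut = float(grid[j0 + rng.integers(j1 - j0)])
        go_left = self._X[leaf.rows, var] <= cut
        rows_l = leaf.rows[go_left]
        rows_r = leaf.rows[~go_left]
        W_l = float(self._trials[rows_l].sum())
        W_r = leaf.weight - W_l
        R_l = float(r[rows_l].sum())
        R = float(r[leaf.rows].sum())
        R_r = R - R_l

        d = leaf.depth
        lp_prior = (
            np.log(self._p_split(d))
            + 2.0 * np.log1p(-self._p_split(d + 1))
            - np.log1p(-self._p_split(d))
        )
        lp_ml = self._leaf_lml(W_l, R_l) + self._leaf_lml(W_r, R_r) - self._leaf_lml(leaf.weight, R)
        # forward: p_grow * (1/L); reverse: p_prune * (1/n_nog(T')). Growing a
        # leaf adds one prunable (nog) node and removes its parent from the
        # nog set iff the parent was nog.
        n_nog_new = len(_nog_nodes(root, [])) + (0 if _parent_is_nog(root, leaf) else 1)
        p_grow_T = 1.0 if root.is_leaf else s.p_grow
        lp_prop = np.log(s.p_prune) - np.log(n_nog_new) - (np.log(p_grow_T) - np.log(L))
        if np.log(rng.random()) < lp_prior + lp_ml + lp_prop:
            leaf.var = var
            leaf.cut = cut
            leaf.left = _Node(rows_l, d + 1, W_l)
            leaf.right = _Node(rows_r, d + 1, W_r)
            leaf.rows = None
            return True
        return False

    def _try_prune(self, root, r, rng):
        s = self.settings
        nogs = _nog_nodes(root, [])
        if not nogs:
            return False
        nd = nogs[rng.integers(len(nogs))]
        rows = np.concatenate([nd.left.rows, nd.right.rows])
        W = nd.left.weight + nd.right.weight
        R_l = float(r[nd.left.rows].sum())
        R_r = float(r[nd.right.rows].sum())
        R = R_l + R_r
        d = nd.depth
        lp_prior = -(
            np.log(self._p_split(d))
            + 2.0 * np.log1p(-self._p_split(d + 1))
            - np.log1p(-self._p_split(d))
        )
        lp_ml = self._leaf_lml(W, R) - self._leaf_lml(nd.left.weight, R_l) - self._leaf_lml(nd.right.weight, R_r)
        # reverse grow must re-pick this leaf among the pruned tree's leaves;
        # the removed split's rule prior cancels against the reverse rule
        # proposal (both uniform over the same support)
        L_pruned = len(_leaves(root, [])) - 1
        p_grow_rev = 1.0 if root is nd else s.p_grow
        lp_prop = (
            np.log(p_grow_rev) - np.log(L_pruned)
            - (np.log(s.p_prune) - np.log(len(nogs)))
        )
        if np.log(rng.random()) < lp_prior + lp_ml + lp_prop:
            nd.var = -1
            nd.left = None
            nd.right = None
            nd.rows = rows
            nd.weight = W
            return True
        return False

    def _try_change(self, root, r, rng):
        nogs = _nog_nodes(root, [])
        if not nogs:
            return False
        nd = nogs[rng.integers(len(nogs))]
        rows = np.concatenate([nd.left.rows, nd.right.rows])
        var = int(rng.integers(self._p))
        grid, j0, j1 = self._valid_cut_range(var, rows)
        if j1 <= j0:
            return False
        cut = float(grid[j0 + rng.integers(j1 - j0)])
        go_left = self._X[rows, var] <= cut
        rows_l, rows_r = rows[go_left], rows[~go_left]
        W = nd.left.weight + nd.right.weight
        W_l = float(self._trials[rows_l].sum())
        R_l_new = float(r[rows_l].sum())
        R_total = float(r[rows].sum())
        old_lml = self._leaf_lml(nd.left.weight, float(r[nd.left.rows].sum())) + self._leaf_lml(
            nd.right.weight, float(r[nd.right.rows].sum())
        )
        new_lml = self._leaf_lml(W_l, R_l_new) + self._leaf_lml(W - W_l, R_total - R_l_new)
        if np.log(rng.random()) < new_lml - old_lml:
            nd.var = var
            nd.cut = cut
            nd.left = _Node(rows_l, nd.depth + 1, W_l)
            nd.right = _Node(rows_r, nd.depth + 1, W - W_l)
            return True
        return False

    # -- main loop ----------------------------------------------------------

    def fit(self, X, successes, trials=None, X_pred=None):
        s = self.settings
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        successes = np.asarray(successes, dtype=np.int64)
        if trials is None:
            trials = np.ones_like(successes)
        trials = np.asarray(trials, dtype=np.int64)
        if (successes < 0).any() or (successes > trials).any():
            raise ValueError("successes must satisfy 0 <= successes <= trials")
        active = trials > 0
        X_act = X[active]
        k_act = successes[active]
        n_act = trials[active]
        self._n, self._p = X_act.shape
        self._X = X_act
        self._trials = n_act.astype(np.float64)

        total_k, total_n = int(k_act.sum()), int(n_act.sum())
        if total_k == 0 or total_k == total_n:
            raise ValueError("constant outcome: all trials share one response")
        pbar = np.clip(total_k / total_n, 1e-6, 1 - 1e-6)
        self.offset_ = float(ndtri(pbar))

        self._tau2 = (3.0 / (s.k * np.sqrt(s.n_trees))) ** 2

        # cutpoint grids: unique values except the max; thin to max_cutpoints
        self._grids = []
        for j in range(self._p):
            u = np.unique(X_act[:, j])
            g = u[:-1]
            if len(g) > s.max_cutpoints:
                idx = np.linspace(0, len(g) - 1, s.max_cutpoints).round().astype(int)
                g = g[np.unique(idx)]
            self._grids.append(g)

        # expansion maps for exact latent sums
        rows = np.arange(self._n)
        self._pos_rows = np.repeat(rows, k_act)
        self._neg_rows = np.repeat(rows, n_act - k_act)

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 97]))
        W0 = float(self._trials.sum())
        trees = [_Node(np.arange(self._n), 0, W0) for _ in range(s.n_trees)]
        row_fit = np.zeros((s.n_trees, self._n))
        fit_train = np.zeros(self._n)

        keep_every = max(int(s.thin), 1)
        n_iter = s.n_burn + s.n_draws * keep_every
        forests = []
        pred = None
        if X_pred is not None:
            X_pred = np.ascontiguousarray(np.asarray(X_pred, dtype=np.float64))
            pred = np.empty((s.n_draws, X_pred.shape[0]), dtype=np.float32)

        for it in range(n_iter):
            S = self._sample_latent_sums(self.offset_ + fit_train, rng)
            for j, root in enumerate(trees):
                f_minus = fit_train - row_fit[j]
                r = S - self._trials * (self.offset_ + f_minus)
                if root.is_leaf:
                    move = "grow"
                else:
                    u = rng.random()
                    move = "grow" if u < s.p_grow else ("prune" if u < s.p_grow + s.p_prune else "change")
                if move == "grow":
                    self._try_grow(root, r, rng)
                elif move == "prune":
                    self._try_prune(root, r, rng)
                else:
                    self._try_change(root, r, rng)
                # resample leaf values
                for leaf in _leaves(root, []):
                    W = leaf.weight
                    R = float(r[leaf.rows].sum())
                    post_var = self._tau2 / (1.0 + self._tau2 * W)
                    post_mean = self._tau2 * R / (1.0 + self._tau2 * W)
                    leaf.value = post_mean + np.sqrt(post_var) * rng.standard_normal()
                    row_fit[j, leaf.rows] = leaf.value
                fit_train = f_minus + row_fit[j]

            if it >= s.n_burn and (it - s.n_burn) % keep_every == 0:
                d = (it - s.n_burn) // keep_every
                forest = [_flatten(t) for t in trees]
                forests.append(forest)
                if pred is not None:
                    pred[d] = ndtr(self.offset_ + evaluate_forest(forest, X_pred))

        self.forests_ = forests
        self.pred_draws_ = pred
        return self

    def predict_draws(self, Xnew):
        """Posterior draws of P(outcome = 1), shape (n_draws, len(Xnew))."""
        if self.forests_ is None:
            raise RuntimeError("model is not fitted")
        Xnew = np.ascontiguousarray(np.asarray(Xnew, dtype=np.float64))
        out = np.empty((len(self.forests_), Xnew.shape[0]), dtype=np.float32)
        for d, forest in enumerate(self.forests_):
            out[d] = ndtr(self.offset_ + evaluate_forest(forest, Xnew))
        return out
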