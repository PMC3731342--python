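"""Strict-molecular-clock dating on codon-position alignments.

Workflow: fit GTR+Gamma(4) branch lengths on a fixed rooted topology
(typically the 3rd-codon-position view, where most change is synonymous),
test the clock by a likelihood-ratio test of node-height vs free branch
lengths (df = n - 2), then rescale node heights so a single calibrated node
matches its age (goat/markhor split, 3.4 Ma in the original design). Node-age
standard errors come from the curvature (observed information) of the
height likelihood, propagated through the calibration rescaling.

Model/Results idiom: :class:`StrictClockModel` ... ``.fit()`` ->
:class:`ClockResults`; ``date()`` -> :class:`Chronogram`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import chi2, gamma as gamma_dist

from .alignio import NucAlignment
from .errors import ConvergenceError, UsageError
from .tree import Node, PhyloTree

NUCS = "ACGT"
NUC_IDX = {c: i for i, c in enumerate(NUCS)}
# GTR exchangeability order, s_GT fixed to 1
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # AC AG AT CG CT (GT ref)



def _clip_grad(g: np.ndarray, cap: float = 1e3) -> np.ndarray:
    """Cap the gradient norm; near-zero branches can produce huge, nearly
    discontinuous derivatives that break the L-BFGS-B line search."""
    norm = float(np.sqrt(np.sum(np.minimum(np.abs(g), 1e100) ** 2)))
    if norm > cap:
        return g * (cap / norm)
    return g


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability gamma categories (mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    upper = gammainc(shape + 1.0, edges[1:] * shape)
    lower = gammainc(shape + 1.0, edges[:-1] * shape)
    return k * (upper - lower)


def gtr_rate_matrix(exch: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalized 4-state GTR generator (one substitution per unit length)."""
    s = np.zeros((4, 4))
    for val, (i, j) in zip(exch, EXCH_PAIRS):
        s[i, j] = s[j, i] = val
    s[2, 3] = s[3, 2] = 1.0
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(pi @ np.diag(q))
    return q / scale


class _NucEngine:
    """GTR+Gamma pruning likelihood over site patterns on a rooted tree."""

    def __init__(self, aln: NucAlignment, tree: PhyloTree, n_cat: int = 4):
        leaf_names = tree.leaf_names()
        if set(leaf_names) != set(aln.ids):
            raise UsageError("tree leaves and alignment ids differ")
        self.tree = tree
        self.n_cat = n_cat
        arr = aln.to_array()[[aln.ids.index(nm) for nm in leaf_names]]
        coded = np.full(arr.shape, -1, dtype=np.int8)
        for c, i in NUC_IDX.items():
            coded[arr == c] = i
        patterns, weights = np.unique(coded.T, axis=0, return_counts=True)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[0]
        counts = np.bincount(coded[coded >= 0].ravel(), minlength=4)
        if counts.min() == 0:
            counts = counts + 1
        self.pi = counts / counts.sum()

        post = tree.postorder()
        self.nodes = post
        self.node_index = {id(n): k for k, n in enumerate(post)}
        self.is_leaf = np.array([n.is_leaf for n in post])
        self.branch_nodes = [k for k, n in enumerate(post) if n.parent is not None]
        self.n_branches = len(self.branch_nodes)
        self.leaf_down = {}
        for k, n in enumerate(post):
            if n.is_leaf:
                states = patterns[:, leaf_names.index(n.name)]
                D = np.zeros((self.n_patterns, 4))
                obs = states >= 0
                D[np.arange(self.n_patterns)[obs], states[obs]] = 1.0
                D[~obs] = 1.0
                self.leaf_down[k] = D
        t0 = np.array([max(post[k].length or 0.0, 1e-6) for k in self.branch_nodes])
        # input trees may carry lengths in years; renormalize implausible
        # totals to a generic starting point in substitutions/site
        if t0.sum() > 10.0:
            t0 = t0 * (0.5 / t0.sum())
        self.t0 = np.clip(t0, 1e-6, 10.0)
        variable = False
        for p in patterns:
            obs = p[p >= 0]
            if obs.size and (obs != obs[0]).any():
                variable = True
                break
        if not variable:
            raise UsageError("degenerate alignment: no variation")

    def loglik(self, exch: np.ndarray, shape: float, t: np.ndarray,
               gradient: bool = False):
        """Mixture log-likelihood; optionally the branch-length gradient.

        The gradient weights per-category branch derivatives by the
        per-pattern posterior category probabilities.
        """
        q = gtr_rate_matrix(exch, self.pi)
        rates = discrete_gamma_rates(shape, self.n_cat)
        sq = np.sqrt(self.pi)
        B = q * (sq[:, None] / sq[None, :])
        lam, U = np.linalg.eigh(0.5 * (B + B.T))
        X = U / sq[:, None]
        Y = U.T * sq[None, :]
        branch_of_node = {k: i for i, k in enumerate(self.branch_nodes)}
        nn = len(self.nodes)
        per_cat = []
        for r in rates:
            down = [None] * nn
            b_cache = [None] * nn
            e_cache = [None] * nn
            M_cache = [None] * nn
            logscale = np.zeros(self.n_patterns)
            for k, node in enumerate(self.nodes):
                if self.is_leaf[k]:
                    down[k] = self.leaf_down[k]
                else:
                    D = None
                    for child in node.children:
                        ck = self.node_index[id(child)]
                        D = M_cache[ck] if D is None else D * M_cache[ck]
                    mx = D.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    down[k] = D / mx[:, None]
                    logscale += np.log(mx)
                if node.parent is not None:
                    tb = t[branch_of_node[k]]
                    e = np.exp(lam * tb * r)
                    b = down[k] @ Y.T
                    M = (b * e[None, :]) @ X.T
                    np.maximum(M, 0.0, out=M)
                    b_cache[k], e_cache[k], M_cache[k] = b, e, M
            per_cat.append(
                (down[-1] @ self.pi, logscale.copy(), down, b_cache, e_cache, M_cache)
            )
        ls = np.stack([c[1] for c in per_cat])
        vals = np.stack([c[0] for c in per_cat])
        ref = ls.max(axis=0)
        scaled = vals * np.exp(ls - ref[None, :])
        site = scaled.mean(axis=0)
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            raise FloatingPointError("non-finite site likelihood")
        lnl = float(self.weights @ (np.log(site) + ref))
        if not gradient:
            return lnl

        grad_t = np.zeros(self.n_branches)
        post_cat = scaled / np.maximum(scaled.sum(axis=0), 1e-300)[None, :]
        for ci, r in enumerate(rates):
            _, _, down, b_cache, e_cache, M_cache = per_cat[ci]
            wcat = self.weights * post_cat[ci]
            upper = [None] * nn
            upper[nn - 1] = np.broadcast_to(self.pi, (self.n_patterns, 4))
            for k in reversed(range(nn)):
                node = self.nodes[k]
                if node.is_leaf:
                    continue
                up = upper[k]
                kids = [self.node_index[id(c)] for c in node.children]
                Ms = [M_cache[c] for c in kids]
                nkid = len(kids)
                prefix = [up]
                for i in range(nkid):
                    prefix.append(prefix[i] * Ms[i])
                suffix = [None] * (nkid + 1)
                suffix[nkid] = np.ones_like(up)
                for i in range(nkid - 1, -1, -1):
                    suffix[i] = suffix[i + 1] * Ms[i]
                for i, ck in enumerate(kids):
                    upre = prefix[i] * suffix[i + 1]
                    mx = upre.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    upre = upre / mx[:, None]
                    e = e_cache[ck]
                    b = b_cache[ck]
                    a = upre @ X
                    den = np.einsum("pi,pi->p", a * e[None, :], b)
                    den = np.maximum(den, 1e-250)
                    num = np.einsum("pi,pi->p", a * (lam * r * e)[None, :], b)
                    with np.errstate(over="ignore", invalid="ignore"):
                        ratio = np.nan_to_num(num / den, nan=0.0,
                                              posinf=1e12, neginf=-1e12)
                    grad_t[branch_of_node[ck]] += float(wcat @ ratio)
                    if not node.children[i].is_leaf:
                        upper[ck] = (a * e[None, :]) @ Y
        return lnl, grad_t


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------
@dataclass
class GTRFit:
    exch: np.ndarray
    shape: float
    pi: np.ndarray
    lnL: float
    branch_lengths: np.ndarray
    tree: PhyloTree
    n_params: int


@dataclass
class ClockTestResult:
    lnL_clock: float
    lnL_free: float
    df: int

    @property
    def statistic(self) -> float:
        return 2.0 * (self.lnL_free - self.lnL_clock)

    @property
    def p(self) -> float:
        return float(chi2.sf(max(self.statistic, 0.0), self.df))


@dataclass
class ClockResults:
    """Strict-clock ML fit: node heights in substitutions/site."""

    tree: PhyloTree  # rooted copy with heights on node.age (subs/site)
    heights: dict[int, float]  # internal-node postorder index -> height
    exch: np.ndarray
    shape: float
    lnL: float
    engine: "_NucEngine" = field(repr=False)
    height_cov: np.ndarray | None = field(default=None, repr=False)
    height_order: list[int] = field(default_factory=list)


@dataclass
class Chronogram:
    """Clock tree with calibrated node ages (years) and standard errors."""

    tree: PhyloTree  # node.age in years
    ages: dict[int, float]
    ses: dict[int, float]
    rate: float  # substitutions per site per year
    calibration: tuple[frozenset, float]

    def node_table(self) -> pd.DataFrame:
        rows = []
        post = self.tree.postorder()
        for k, node in enumerate(post):
            if node.is_leaf:
                continue
            rows.append(
                {
                    "node": k,
                    "clade": ",".join(sorted(self.tree.clade_leafset(node))),
                    "age_years": self.ages[k],
                    "se_years": self.ses[k],
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------
class StrictClockModel:
    """GTR+Gamma strict-clock model on a rooted topology.

    Parameters
    ----------
    aln : NucAlignment
        Typically a 3rd-codon-position view.
    tree : PhyloTree
        Rooted topology (outgroup-rooted); branch lengths, if present, seed
        the optimizer.
    """

    def __init__(self, aln: NucAlignment, tree: PhyloTree, n_cat: int = 4):
        self.aln = aln
        self.tree = tree.copy()
        self.engine = _NucEngine(aln, self.tree, n_cat)
        post = self.engine.nodes
        self.internal = [k for k, n in enumerate(post) if not n.is_leaf]
        self.root_index = len(post) - 1

    @staticmethod
    def _fd_model_grad(f, exch, shape, rel=1e-5):
        """Central differences for the 6 substitution-model parameters."""
        g = np.zeros(6)
        for i in range(5):
            h = exch[i] * rel
            ep, em = exch.copy(), exch.copy()
            ep[i] += h
            em[i] -= h
            g[i] = (f(ep, shape) - f(em, shape)) / (2 * h)
        h = shape * rel
        g[5] = (f(exch, shape + h) - f(exch, shape - h)) / (2 * h)
        return g

    # -------------------------------------------------------- free model
    def fit_free(self, maxiter: int = 500, t_init: np.ndarray | None = None,
                 model_init: tuple | None = None) -> GTRFit:
        """Unconstrained branch lengths (clock alternative).

        Multi-start over deterministic branch-length rescalings; near-zero
        branches make the surface stiff enough that a single start can stall.
        """
        eng = self.engine
        nb = eng.n_branches
        bounds = (
            [(np.log(1e-8), np.log(20.0))] * nb
            + [(np.log(1e-3), np.log(200.0))] * 5
            + [(np.log(0.02), np.log(200.0))]
        )

        def nll(z):
            x = np.exp(z)
            t, exch, shape = x[:nb], x[nb : nb + 5], x[nb + 5]
            try:
                lnl, gt = eng.loglik(exch, shape, t, gradient=True)
            except FloatingPointError:
                return 1e12, np.zeros_like(z)
            gm = self._fd_model_grad(
                lambda e, s: eng.loglik(e, s, t), exch, shape
            )
            g = np.concatenate([gt, gm])
            return -lnl, -_clip_grad(g * x)

        exch0, shape0 = (np.ones(5), 0.5) if model_init is None else model_init
        t_base = eng.t0 if t_init is None else np.clip(t_init, 1e-8, 20.0)
        starts = [t_base] if t_init is not None else [t_base, t_base * 0.3,
                                                     t_base * 3.0]
        best = None
        for ts in starts:
            z0 = np.log(np.clip(np.concatenate([ts, exch0, [shape0]]), 1e-8, None))
            r = minimize(nll, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                         options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
            if best is None or r.fun < best.fun:
                best = r
        res = best
        res.x = np.exp(res.x)
        tree = self.tree.copy()
        post = tree.postorder()
        for i, k in enumerate(eng.branch_nodes):
            post[k].length = float(res.x[i])
        return GTRFit(
            exch=res.x[nb : nb + 5].copy(),
            shape=float(res.x[nb + 5]),
            pi=eng.pi.copy(),
            lnL=float(-res.fun),
            branch_lengths=res.x[:nb].copy(),
            tree=tree,
            n_params=nb + 6,
        )

    # ------------------------------------------------------- clock model
    def _heights_from_x(self, x: np.ndarray) -> np.ndarray:
        """Map (root height, per-node fractions) to heights per node."""
        post = self.engine.nodes
        heights = np.zeros(len(post))
        root_h = x[0]
        frac = {k: x[1 + i] for i, k in enumerate(self.internal) if k != self.root_index}
        heights[self.root_index] = root_h
        for node in self.engine.tree.preorder():
            k = self.engine.node_index[id(node)]
            if node.parent is None or node.is_leaf:
                continue
            pk = self.engine.node_index[id(node.parent)]
            heights[k] = frac[k] * heights[pk]
        return heights

    def _branch_lengths_from_heights(self, heights: np.ndarray) -> np.ndarray:
        eng = self.engine
        t = np.zeros(eng.n_branches)
        for i, k in enumerate(eng.branch_nodes):
            pk = eng.node_index[id(eng.nodes[k].parent)]
            t[i] = max(heights[pk] - heights[k], 1e-10)
        return t

    def _height_grad_to_x(self, x: np.ndarray, heights: np.ndarray,
                          grad_t: np.ndarray) -> np.ndarray:
        """Chain rule: branch-length gradient -> (root height, fractions)."""
        eng = self.engine
        # dlnL/dh_k: + from child branches, - from the branch above k
        gh = np.zeros(len(eng.nodes))
        for i, k in enumerate(eng.branch_nodes):
            pk = eng.node_index[id(eng.nodes[k].parent)]
            gh[pk] += grad_t[i]
            if not eng.nodes[k].is_leaf:
                gh[k] -= grad_t[i]
        # subtree sums of h_k * gh_k over internal nodes (postorder)
        sub = np.zeros(len(eng.nodes))
        for k, node in enumerate(eng.nodes):
            if node.is_leaf:
                continue
            sub[k] = heights[k] * gh[k] + sum(
                sub[eng.node_index[id(c)]] for c in node.children if not c.is_leaf
            )
        g = np.zeros(len(x))
        g[0] = sub[self.root_index] / x[0]
        idx = 1
        for k in self.internal:
            if k == self.root_index:
                continue
            g[idx] = sub[k] / x[idx]
            idx += 1
        return g

    def fit(self, maxiter: int = 500) -> ClockResults:
        """ML node heights under the strict clock, with height covariance."""
        eng = self.engine
        n_int = len(self.internal) - 1  # non-root internal nodes
        nh = 1 + n_int
        # initialize heights by averaging child depths along the input lengths
        branch_of = {k: i for i, k in enumerate(eng.branch_nodes)}
        h0 = np.zeros(len(eng.nodes))
        for k, node in enumerate(eng.nodes):
            if node.is_leaf:
                continue
            h0[k] = float(
                np.mean(
                    [
                        h0[eng.node_index[id(c)]]
                        + eng.t0[branch_of[eng.node_index[id(c)]]]
                        for c in node.children
                    ]
                )
            )
        for node in eng.tree.preorder():  # enforce strict monotonicity
            k = eng.node_index[id(node)]
            if node.parent is None or node.is_leaf:
                continue
            pk = eng.node_index[id(node.parent)]
            h0[k] = min(h0[k], 0.999 * h0[pk])
        fracs0 = np.array(
            [
                np.clip(h0[k] / max(h0[eng.node_index[id(eng.nodes[k].parent)]], 1e-9),
                        1e-3, 1.0 - 1e-3)
                for k in self.internal
                if k != self.root_index
            ]
        )
        x0 = np.concatenate([[max(h0[self.root_index], 1e-4)], fracs0,
                             np.ones(5), [0.5]])
        bounds = (
            [(1e-7, 20.0)] + [(1e-4, 1.0 - 1e-4)] * n_int
            + [(1e-3, 200.0)] * 5 + [(0.02, 200.0)]
        )

        def nll(x):
            heights = self._heights_from_x(x[:nh])
            t = self._branch_lengths_from_heights(heights)
            exch, shape = x[nh : nh + 5], x[nh + 5]
            try:
                lnl, gt = eng.loglik(exch, shape, t, gradient=True)
            except FloatingPointError:
                return 1e12, np.zeros_like(x)
            gx = self._height_grad_to_x(x[:nh], heights, gt)
            gm = self._fd_model_grad(lambda e, s: eng.loglik(e, s, t), exch, shape)
            return -lnl, -_clip_grad(np.concatenate([gx, gm]))

        res = minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
        if not np.isfinite(res.fun):
            raise ConvergenceError("clock fit failed")
        heights = self._heights_from_x(res.x[:nh])
        exch, shape = res.x[nh : nh + 5].copy(), float(res.x[nh + 5])

        # observed information of heights (other parameters held at MLE)
        hvec = heights[self.internal].copy()

        def nll_h(h):
            full = heights.copy()
            full[self.internal] = h
            t = self._branch_lengths_from_heights(full)
            try:
                return -eng.loglik(exch, shape, t)
            except FloatingPointError:
                return 1e12

        cov = _covariance_from_hessian(nll_h, hvec)

        tree = self.tree
        post = eng.nodes
        hdict = {}
        for k in self.internal:
            post[k].age = float(heights[k])
            hdict[k] = float(heights[k])
        for k, n in enumerate(post):
            if n.is_leaf:
                n.age = 0.0
        return ClockResults(
            tree=tree,
            heights=hdict,
            exch=exch,
            shape=shape,
            lnL=float(-res.fun),
            engine=eng,
            height_cov=cov,
            height_order=list(self.internal),
        )


def _covariance_from_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Covariance = inverse of a central-difference Hessian (ridge-guarded)."""
    n = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-8)
    H = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej)
                    + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    # guard against indefiniteness from finite-difference noise
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-8 * max(w.max(), 1.0))
    return (V / w) @ V.T


# --------------------------------------------------------------------------
# spec-level operations
# --------------------------------------------------------------------------
def fit_gtr_gamma(aln: NucAlignment, tree: PhyloTree, maxiter: int = 500) -> GTRFit:
    """ML GTR+Gamma(4) fit with free branch lengths on a fixed topology."""
    return StrictClockModel(aln, tree).fit_free(maxiter=maxiter)


def clock_test(aln: NucAlignment, tree: PhyloTree, maxiter: int = 500) -> ClockTestResult:
    """LRT of the strict clock: heights (n-1) vs free lengths (2n-3)."""
    model = StrictClockModel(aln, tree)
    clock = model.fit(maxiter=maxiter)
    free = model.fit_free(maxiter=maxiter)
    # the clock solution is a feasible point of the free model: polishing
    # from it guarantees lnL_free >= lnL_clock up to optimizer tolerance
    heights = np.zeros(len(model.engine.nodes))
    for k, h in clock.heights.items():
        heights[k] = h
    t_clock = model._branch_lengths_from_heights(heights)
    warm = model.fit_free(maxiter=maxiter, t_init=t_clock,
                          model_init=(clock.exch, clock.shape))
    lnl_free = max(free.lnL, warm.lnL, clock.lnL)
    n = len(aln.ids)
    return ClockTestResult(lnL_clock=clock.lnL, lnL_free=lnl_free, df=n - 2)


def date_tree(
    aln: NucAlignment,
    tree: PhyloTree,
    calibration: tuple,
    maxiter: int = 500,
) -> Chronogram:
    """Strict-clock chronogram with one calibrated node.

    ``calibration`` is (leaf-name collection defining the node as an MRCA,
    age in years). Node heights are rescaled so the calibrated node equals
    its age exactly; SEs propagate through the rescaling by the delta method.
    """
    names, age_years = calibration
    if isinstance(names, str):
        names = [names]
    if age_years <= 0:
        raise UsageError("calibration age must be positive")
    model = StrictClockModel(aln, tree)
    cal_node = model.engine.tree.mrca(names)
    cal_k = model.engine.node_index[id(cal_node)]
    if model.engine.nodes[cal_k].is_leaf:
        raise UsageError("calibration node is a leaf")
    res = model.fit(maxiter=maxiter)
    order = res.height_order
    pos = {k: i for i, k in enumerate(order)}
    h = np.array([res.heights[k] for k in order])
    cov = res.height_cov
    ic = pos[cal_k]
    hc = h[ic]
    if hc <= 0:
        raise UsageError("calibrated node height is zero")
    scale = age_years / hc
    ages, ses = {}, {}
    for k in order:
        i = pos[k]
        ages[k] = float(h[i] * scale)
        if k == cal_k:
            ses[k] = 0.0
        else:
            var = (
                cov[i, i] / hc**2
                + h[i] ** 2 * cov[ic, ic] / hc**4
                - 2.0 * h[i] * cov[i, ic] / hc**3
            )
            ses[k] = float(age_years * np.sqrt(max(var, 0.0)))
    tree_out = res.tree.copy()
    post = tree_out.postorder()
    for k in order:
        post[k].age = ages[k]
    for n in post:
        if n.is_leaf:
            n.age = 0.0
    for n in post:
        if n.parent is not None:
            n.length = (n.parent.age or 0.0) - (n.age or 0.0)
    leafset = frozenset(model.engine.tree.clade_leafset(cal_node))
    return Chronogram(
        tree=tree_out,
        ages=ages,
        ses=ses,
        rate=float(hc / age_years),
        calibration=(leafset, float(age_years)),
    )


def rate_from_calibrated_node(tree: PhyloTree, names, age_years: float) -> float:
    """Per-site per-year rate from a node height (subs/site) and its age."""
    if age_years <= 0:
        raise UsageError("age must be positive")
    node = tree.mrca(names if not isinstance(names, str) else [names])
    if node.age is None or node.age <= 0:
        raise UsageError("node has no positive height")
    return float(node.age / age_years)
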