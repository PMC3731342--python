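"""Branch-wise dN/dS (omega) codon substitution models.

A GY94-style 60-state codon model under the vertebrate mitochondrial code, in
which substitution rates between single-step codons are

    q_ij = pi_j              synonymous transversion
    q_ij = kappa pi_j        synonymous transition
    q_ij = omega pi_j        non-synonymous transversion
    q_ij = omega kappa pi_j  non-synonymous transition

with omega varying over branch *classes* (inter-species, the six deep
branches, the per-haplogroup shallow branches). Each class generator is
scaled so branch lengths are expected substitutions per codon under that
class's own omega. Likelihoods use Felsenstein pruning with site-pattern
compression and analytic gradients (branch lengths via the eigenbasis of the
symmetrized generator; kappa/omega via first-order perturbation of the
matrix exponential).

The fitting interface follows the Model/Results idiom:
``BranchOmegaModel(caln, cat, spec).fit()`` returns a
:class:`BranchOmegaResults` carrying estimates, lnL, #p and AIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from ._codes import (
    N_SENSE,
    NUC_INDEX,
    SENSE_CODONS,
    SINGLE_STEP,
    STEP_IS_SYNONYMOUS,
    STEP_IS_TRANSITION,
)
from .alignio import MISSING, CodonAlignment
from .errors import ConvergenceError, UsageError
from .phylo import BranchCategoryMap
from .tree import PhyloTree

OMEGA_MIN = 1e-4
OMEGA_MAX = 999.0

_CODON_POS_NUC = np.array(
    [[NUC_INDEX[c[k]] for k in range(3)] for c in SENSE_CODONS]
)


# --------------------------------------------------------------------------
# frequencies and rate matrices
# --------------------------------------------------------------------------
def codon_frequencies(caln: CodonAlignment, model: str = "F3x4") -> np.ndarray:
    """Equilibrium sense-codon frequencies from the alignment.

    'F3x4' uses position-specific nucleotide frequencies, 'F61' empirical
    codon frequencies, 'equal' a flat distribution. A small floor keeps every
    sense codon reachable.
    """
    counts = np.bincount(caln.codons[caln.codons >= 0].ravel(), minlength=N_SENSE)
    if model == "equal":
        pi = np.full(N_SENSE, 1.0 / N_SENSE)
    elif model == "F61":
        pi = counts + 0.5
        pi = pi / pi.sum()
    elif model == "F3x4":
        posfreq = np.zeros((3, 4))
        for k in range(3):
            posfreq[k] = np.bincount(_CODON_POS_NUC[:, k], weights=counts, minlength=4)
        posfreq = (posfreq + 0.5) / (posfreq + 0.5).sum(axis=1, keepdims=True)
        pi = np.prod(
            [posfreq[k, _CODON_POS_NUC[:, k]] for k in range(3)], axis=0
        )
        pi = pi / pi.sum()
    else:
        raise UsageError(f"unknown frequency model {model!r}")
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


N_FREQ_PARAMS = {"F3x4": 9, "F61": 59, "equal": 0}


@dataclass
class CodonModelParams:
    """Point in parameter space of the branch-omega codon model."""

    kappa: float
    pi: np.ndarray
    omega_map: dict[str, float]

    def __post_init__(self):
        if self.kappa <= 0:
            raise UsageError("kappa must be positive")
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-12:
            raise UsageError("pi must sum to 1")
        for key, w in self.omega_map.items():
            if not (OMEGA_MIN <= w <= OMEGA_MAX):
                raise UsageError(f"omega[{key}]={w} outside [{OMEGA_MIN}, {OMEGA_MAX}]")


def build_rate_matrix(params: CodonModelParams, omega: float) -> np.ndarray:
    """60x60 generator for one omega class, scaled to one expected
    substitution per codon per unit branch length (under this omega)."""
    rates = np.where(STEP_IS_TRANSITION, params.kappa, 1.0) * np.where(
        STEP_IS_SYNONYMOUS, 1.0, omega
    )
    q = np.where(SINGLE_STEP, rates * params.pi[None, :], 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(params.pi @ np.diag(q))
    return q / scale


# --------------------------------------------------------------------------
# model specifications (the omega-constraint ladders)
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class OmegaModelSpec:
    """A named partition of branch-class keys into shared-omega classes.

    Keys are 'interspecies', 'deep:<tag>' and 'shallow:<hg>'; each inner
    tuple shares one free omega.
    """

    name: str
    classes: tuple[tuple[str, ...], ...]
    description: str = ""

    @property
    def n_omegas(self) -> int:
        return len(self.classes)

    def class_names(self) -> list[str]:
        return ["&".join(c) for c in self.classes]

    def class_index(self) -> dict[str, int]:
        out = {}
        for k, cls in enumerate(self.classes):
            for key in cls:
                if key in out:
                    raise UsageError(f"key {key} in two omega classes of {self.name}")
                out[key] = k
        return out


def _keys(cat: BranchCategoryMap) -> tuple[list[str], list[str]]:
    deep = [f"deep:{t}" for t in cat.deep_tags()]
    shallow = [f"shallow:{t}" for t in cat.shallow_tags()]
    return deep, shallow


def _spec(name: str, classes, description: str = "") -> OmegaModelSpec:
    """Build a spec, dropping classes left empty by the tree at hand."""
    return OmegaModelSpec(name, tuple(c for c in classes if c), description)


def shallow_family(cat: BranchCategoryMap) -> list[tuple[OmegaModelSpec, str | None]]:
    """The shallow-branch model ladder with its printed comparison partners.

    Models: 1w, 2w, 3w, 4w1 (A apart), 4w2 (B apart), 4w3 (A=B vs C=D), 5w
    (A, B, C=D), 6w (all apart). Assumes shallow tags A..D; generalizes to
    any tag set by the same constructions where possible.
    """
    deep, shallow = _keys(cat)
    inter = ["interspecies"]
    sh = {t.split(":", 1)[1]: t for t in shallow}
    tags = sorted(sh)
    ladder: list[tuple[OmegaModelSpec, str | None]] = [
        (_spec("1w", (tuple(inter + deep + shallow),), "single omega"), None),
        (
            _spec(
                "2w",
                (tuple(inter), tuple(deep + shallow)),
                "inter-species != intra-species",
            ),
            "1w",
        ),
        (
            _spec(
                "3w",
                (tuple(inter), tuple(deep), tuple(shallow)),
                "inter-species != deep != shallow",
            ),
            "2w",
        ),
    ]
    if len(tags) == 4:
        a, b, c, d = tags
        ladder += [
            (
                _spec(
                    "4w1",
                    (tuple(inter), tuple(deep), (sh[a],), (sh[b], sh[c], sh[d])),
                    f"shallow {a} != {b}={c}={d}",
                ),
                "3w",
            ),
            (
                _spec(
                    "4w2",
                    (tuple(inter), tuple(deep), (sh[b],), (sh[a], sh[c], sh[d])),
                    f"shallow {b} != {a}={c}={d}",
                ),
                "3w",
            ),
            (
                _spec(
                    "4w3",
                    (tuple(inter), tuple(deep), (sh[a], sh[b]), (sh[c], sh[d])),
                    f"shallow {a}={b} != {c}={d}",
                ),
                "3w",
            ),
            (
                _spec(
                    "5w",
                    (tuple(inter), tuple(deep), (sh[a],), (sh[b],), (sh[c], sh[d])),
                    f"shallow {a} != {b} != {c}={d}",
                ),
                "4w1",
            ),
            (
                _spec(
                    "6w",
                    (tuple(inter), tuple(deep)) + tuple((sh[t],) for t in tags),
                    "all shallow apart",
                ),
                "5w",
            ),
        ]
    return ladder


def deep_family(cat: BranchCategoryMap) -> list[tuple[OmegaModelSpec, str | None]]:
    """The deep-branch ladder: 3w, one 4w_k per deep branch, and 5w (b and y
    apart), each compared against its printed partner."""
    deep, shallow = _keys(cat)
    inter = ["interspecies"]
    ladder: list[tuple[OmegaModelSpec, str | None]] = [
        (
            _spec(
                "3w",
                (tuple(inter), tuple(deep), tuple(shallow)),
                "inter-species != deep != shallow",
            ),
            None,
        )
    ]
    for k, key in enumerate(deep, start=1):
        rest = tuple(x for x in deep if x != key)
        ladder.append(
            (
                _spec(
                    f"4w{k}",
                    (tuple(inter), (key,), rest, tuple(shallow)),
                    f"deep {key.split(':')[1]} apart",
                ),
                "3w",
            )
        )
    tagset = {k.split(":", 1)[1]: k for k in deep}
    if "b" in tagset and "y" in tagset:
        rest = tuple(v for t, v in sorted(tagset.items()) if t not in ("b", "y"))
        ladder.append(
            (
                _spec(
                    "5w",
                    (tuple(inter), (tagset["b"],), (tagset["y"],), rest, tuple(shallow)),
                    "deep b != y != others",
                ),
                f"4w{sorted(tagset).index('y') + 1}" if "y" in tagset else "3w",
            )
        )
    return ladder


def _finite(x: np.ndarray) -> np.ndarray:
    """Clamp non-finite ratio artifacts from extreme parameter regions."""
    return np.nan_to_num(x, nan=0.0, posinf=1e12, neginf=-1e12)


# --------------------------------------------------------------------------
# likelihood engine
# --------------------------------------------------------------------------
class _Engine:
    """Pruning likelihood + analytic gradient on a fixed rooted tree."""

    def __init__(self, caln: CodonAlignment, cat: BranchCategoryMap,
                 spec: OmegaModelSpec, freq_model: str = "F3x4"):
        tree = cat.tree
        leaf_names = tree.leaf_names()
        if set(leaf_names) != set(caln.ids):
            raise UsageError("tree leaves and alignment ids differ")
        self.spec = spec
        self.freq_model = freq_model
        self.pi = codon_frequencies(caln, freq_model)
        self.sqrt_pi = np.sqrt(self.pi)

        # site-pattern compression
        cols = caln.codons[[caln.ids.index(nm) for nm in leaf_names]].T
        patterns, weights = np.unique(cols, axis=0, return_counts=True)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[0]

        # flatten the tree into postorder arrays
        self.tree = tree
        post = tree.postorder()
        self.nodes = post
        self.node_index = {id(n): k for k, n in enumerate(post)}
        self.parent = np.array(
            [self.node_index[id(n.parent)] if n.parent else -1 for n in post]
        )
        self.is_leaf = np.array([n.is_leaf for n in post])
        self.branch_nodes = [k for k, n in enumerate(post) if n.parent is not None]
        self.n_branches = len(self.branch_nodes)

        class_of_key = spec.class_index()
        required = {cat.class_key(frozenset(tree.clade_leafset(n)))
                    for n in post if n.parent is not None}
        missing = required - set(class_of_key)
        if missing:
            raise UsageError(f"spec {spec.name} lacks classes for {sorted(missing)}")
        self.branch_class = np.array(
            [
                class_of_key[cat.class_key(frozenset(tree.clade_leafset(post[k])))]
                for k in self.branch_nodes
            ]
        )
        self.n_classes = spec.n_omegas

        leaf_state = {nm: i for i, nm in enumerate(leaf_names)}
        self.leaf_pattern_state = {}
        self.leaf_down = {}
        npat = self.n_patterns
        for k, n in enumerate(post):
            if n.is_leaf:
                states = patterns[:, leaf_state[n.name]]
                self.leaf_pattern_state[k] = states
                D = np.zeros((npat, N_SENSE))
                obs = states >= 0
                D[np.arange(npat)[obs], states[obs]] = 1.0
                D[~obs] = 1.0
                self.leaf_down[k] = D

        t0 = np.array([max(post[k].length or 0.0, 1e-4) for k in self.branch_nodes])
        # trees may carry lengths in other units (e.g. years from a simulated
        # genealogy); renormalize implausible totals to a generic starting
        # point rather than starting saturated
        if t0.sum() > 20.0:
            t0 = t0 * (1.0 / t0.sum())
        self.t0 = np.clip(t0, 1e-4, 5.0)

        # masks reused for dQ
        self._trans = SINGLE_STEP & STEP_IS_TRANSITION
        self._nonsyn = SINGLE_STEP & ~STEP_IS_SYNONYMOUS

    # ------------------------------------------------------------------
    def _class_matrices(self, kappa: float, omegas: np.ndarray):
        """Eigen-factorizations and perturbation matrices per omega class.

        Returns per class: (lam, X, Y, Vkappa, Vomega) with
        P(t) = X diag(e^{lam t}) Y and V = U^T D^{1/2} dQ D^{-1/2} U.
        """
        out = []
        pi = self.pi
        for c in range(self.n_classes):
            w = omegas[c]
            rates = np.where(self._trans & SINGLE_STEP, kappa, 1.0)
            rates = np.where(SINGLE_STEP, rates, 0.0)
            rates = rates * np.where(self._nonsyn, w, 1.0)
            R = rates * pi[None, :]
            rowsum = R.sum(axis=1)
            scale = float(pi @ rowsum)
            Q = R / scale
            np.fill_diagonal(Q, -rowsum / scale)

            B = Q * (self.sqrt_pi[:, None] / self.sqrt_pi[None, :])
            B = 0.5 * (B + B.T)
            lam, U = np.linalg.eigh(B)
            X = U / self.sqrt_pi[:, None]
            Y = U.T * self.sqrt_pi[None, :]

            def dQ_from(dR):
                drow = dR.sum(axis=1)
                dscale = float(pi @ drow)
                dq = dR / scale - Q * (dscale / scale)
                ddiag = -drow / scale + rowsum * dscale / scale**2
                dq[np.diag_indices_from(dq)] = ddiag
                return dq

            dR_k = np.where(self._trans, R / kappa, 0.0)
            dR_w = np.where(self._nonsyn, R / w, 0.0)
            Vk = Y @ dQ_from(dR_k) @ X
            Vw = Y @ dQ_from(dR_w) @ X
            out.append((lam, X, Y, Vk, Vw))
        return out

    # ------------------------------------------------------------------
    def loglik(self, kappa, omegas, t, gradient=False):
        mats = self._class_matrices(kappa, np.asarray(omegas, dtype=float))
        npat = self.n_patterns
        nn = len(self.nodes)
        down = [None] * nn
        logscale = [None] * nn
        b_cache = [None] * nn
        e_cache = [None] * nn
        M_cache = [None] * nn

        branch_of_node = {k: i for i, k in enumerate(self.branch_nodes)}
        for k in range(nn):
            if self.is_leaf[k]:
                down[k] = self.leaf_down[k]
                logscale[k] = np.zeros(npat)
            else:
                node = self.nodes[k]
                D = None
                ls = np.zeros(npat)
                for child in node.children:
                    ck = self.node_index[id(child)]
                    M = M_cache[ck]
                    D = M if D is None else D * M
                    ls = ls + logscale[ck]
                mx = D.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                D = D / mx[:, None]
                down[k] = D
                logscale[k] = ls + np.log(mx)
            if self.parent[k] >= 0:
                i = branch_of_node[k]
                lam, X, Y, _, _ = mats[self.branch_class[i]]
                e = np.exp(lam * t[i])
                b = down[k] @ Y.T
                M = (b * e[None, :]) @ X.T
                np.maximum(M, 0.0, out=M)
                b_cache[k], e_cache[k], M_cache[k] = b, e, M

        rk = nn - 1  # root is last in postorder
        site = down[rk] @ self.pi
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            bad = int(np.argmin(site))
            raise FloatingPointError(f"non-finite likelihood at site pattern {bad}")
        lnl = float(self.weights @ (np.log(site) + logscale[rk]))
        if not gradient:
            return lnl

        # ---- gradient: preorder uppers -------------------------------
        grad_t = np.zeros(self.n_branches)
        grad_k = 0.0
        grad_w = np.zeros(self.n_classes)
        upper = [None] * nn
        upper[rk] = np.broadcast_to(self.pi, (npat, N_SENSE))
        Gmat_cache = {}
        for k in reversed(range(nn)):  # preorder
            node = self.nodes[k]
            if node.is_leaf:
                continue
            up = upper[k]
            kids = [self.node_index[id(c)] for c in node.children]
            Ms = [M_cache[c] for c in kids]
            nkid = len(kids)
            prefix = [None] * (nkid + 1)
            prefix[0] = up
            for i in range(nkid):
                prefix[i + 1] = prefix[i] * Ms[i]
            suffix = [None] * (nkid + 1)
            suffix[nkid] = np.ones_like(up)
            for i in range(nkid - 1, -1, -1):
                suffix[i] = suffix[i + 1] * Ms[i]
            for i, ck in enumerate(kids):
                upre = prefix[i] * suffix[i + 1]
                mx = upre.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                upre = upre / mx[:, None]
                bi = branch_of_node[ck]
                cls = self.branch_class[bi]
                lam, X, Y, Vk, Vw = mats[cls]
                e = e_cache[ck]
                b = b_cache[ck]
                a = upre @ X
                den = np.einsum("pi,pi->p", a * e[None, :], b)
                den = np.maximum(den, 1e-250)
                # branch length derivative (diagonal in the eigenbasis)
                num_t = np.einsum("pi,pi->p", a * (lam * e)[None, :], b)
                with np.errstate(over="ignore", invalid="ignore"):
                    grad_t[bi] += float(self.weights @ _finite(num_t / den))
                # kappa / omega derivatives via divided differences
                key = (cls, round(float(t[bi]), 14))
                G = Gmat_cache.get(key)
                if G is None:
                    dl = lam[:, None] - lam[None, :]
                    de = e[:, None] - e[None, :]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        G = np.where(np.abs(dl) > 1e-9, de / dl,
                                     t[bi] * e[:, None] * np.ones_like(de))
                    Gmat_cache[key] = G
                num_k = np.einsum("pi,pi->p", a @ (Vk * G), b)
                num_w = np.einsum("pi,pi->p", a @ (Vw * G), b)
                with np.errstate(over="ignore", invalid="ignore"):
                    grad_k += float(self.weights @ _finite(num_k / den))
                    grad_w[cls] += float(self.weights @ _finite(num_w / den))
                if not node.children[i].is_leaf:
                    upper[ck] = (a * e[None, :]) @ Y
        return lnl, grad_t, grad_k, grad_w


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------
@dataclass
class BranchOmegaResults:
    """ML fit of a branch-omega model (alias: FitResult)."""

    model: OmegaModelSpec
    lnL: float
    kappa: float
    omegas: dict[str, float]
    n_params: int
    branch_lengths: dict[frozenset, float]
    converged: bool
    n_iter: int
    freq_model: str

    @property
    def aic(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.n_params

    def omega_by_key(self) -> dict[str, float]:
        """Per branch-class key (e.g. 'shallow:A') -> fitted omega."""
        out = {}
        for cls, w in zip(self.model.classes, self.omegas.values()):
            for key in cls:
                out[key] = w
        return out

    def summary(self) -> str:
        lines = [
            f"Branch-omega codon model: {self.model.name}"
            + (f" ({self.model.description})" if self.model.description else ""),
            f"  lnL      {self.lnL:.2f}",
            f"  #p       {self.n_params}",
            f"  AIC      {self.aic:.2f}",
            f"  kappa    {self.kappa:.4f}",
            f"  freqs    {self.freq_model}",
            f"  converged {self.converged}",
            "  omega estimates:",
        ]
        for name, w in self.omegas.items():
            lines.append(f"    {name:<40s} {w:.4f}")
        return "\n".join(lines)


FitResult = BranchOmegaResults


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------
class BranchOmegaModel:
    """Codon branch-model likelihood for one omega-constraint specification.

    Parameters
    ----------
    caln : CodonAlignment
    cat : BranchCategoryMap
        Branch stratification (carries the outgroup-rooted tree).
    spec : OmegaModelSpec
        Partition of branch classes into shared-omega groups.
    freq_model : str
        'F3x4' (default), 'F61' or 'equal'.
    """

    def __init__(self, caln: CodonAlignment, cat: BranchCategoryMap,
                 spec: OmegaModelSpec, freq_model: str = "F3x4"):
        self.caln = caln
        self.cat = cat
        self.spec = spec
        self.freq_model = freq_model
        self.engine = _Engine(caln, cat, spec, freq_model)

    def loglike(self, kappa: float, omegas, branch_lengths=None) -> float:
        t = self.engine.t0 if branch_lengths is None else np.asarray(branch_lengths)
        return self.engine.loglik(kappa, omegas, t)

    @property
    def n_params(self) -> int:
        return (
            self.engine.n_branches
            + 1
            + self.spec.n_omegas
            + N_FREQ_PARAMS[self.freq_model]
        )

    def fit(
        self,
        omega0: float = 0.2,
        kappa0: float = 4.0,
        starts: tuple[float, ...] = (1.0, 0.5, 0.1),
        stage1_maxiter: int = 25,
        maxiter: int = 2000,
        tol: float = 1e-6,
        t_init: np.ndarray | None = None,
    ) -> BranchOmegaResults:
        """Maximize lnL over branch lengths, kappa and the free omegas.

        Multi-start over ``starts`` multiples of ``omega0`` (short
        exploratory runs), then the best start is polished to |dlnL| < tol.
        """
        eng = self.engine
        nb, nc = eng.n_branches, eng.n_classes
        # optimize multiplicative parameters on the log scale (conditioning)
        bounds = (
            [(np.log(1e-7), np.log(50.0))] * nb
            + [(np.log(0.05), np.log(500.0))]
            + [(np.log(OMEGA_MIN), np.log(OMEGA_MAX))] * nc
        )

        def objective(z):
            x = np.exp(z)
            t, kappa, om = x[:nb], x[nb], x[nb + 1 :]
            try:
                lnl, gt, gk, gw = eng.loglik(kappa, om, t, gradient=True)
            except FloatingPointError:
                return 1e12, np.zeros_like(z)
            g = np.concatenate([gt, [gk], gw]) * x  # chain rule d/dlog
            norm = float(np.sqrt(np.sum(np.minimum(np.abs(g), 1e100) ** 2)))
            if norm > 1e4:  # guard the line search against near-singular ratios
                g = g * (1e4 / norm)
            return -lnl, -g

        def run(z0, niter):
            return minimize(
                objective,
                z0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": niter, "ftol": tol * 1e-4, "gtol": 1e-7},
            )

        t_start = eng.t0 if t_init is None else np.clip(t_init, 1e-7, 50.0)
        stage1 = []
        for mult in starts:
            z0 = np.log(
                np.concatenate(
                    [
                        t_start,
                        [kappa0],
                        np.full(nc, np.clip(mult * omega0, OMEGA_MIN, 10.0)),
                    ]
                )
            )
            stage1.append(run(z0, stage1_maxiter))
        best = min(stage1, key=lambda r: r.fun)
        res = run(best.x, maxiter)
        converged = bool(res.success or res.fun <= best.fun + tol)
        if not converged and not np.isfinite(res.fun):
            raise ConvergenceError(f"model {self.spec.name} failed to converge")

        xfin = np.exp(res.x)
        t = xfin[:nb]
        kappa = float(xfin[nb])
        omegas = {
            name: float(w) for name, w in zip(self.spec.class_names(), xfin[nb + 1 :])
        }
        lengths = {}
        for i, k in enumerate(eng.branch_nodes):
            leafset = frozenset(eng.tree.clade_leafset(eng.nodes[k]))
            lengths[leafset] = float(t[i])
        self._last_tvec = t.copy()  # reused for ladder warm starts
        return BranchOmegaResults(
            model=self.spec,
            lnL=float(-res.fun),
            kappa=kappa,
            omegas=omegas,
            n_params=self.n_params,
            branch_lengths=lengths,
            converged=converged,
            n_iter=int(res.nit),
            freq_model=self.freq_model,
        )


# --------------------------------------------------------------------------
# spec-level operations
# --------------------------------------------------------------------------
def branch_likelihood(
    caln: CodonAlignment,
    tree: PhyloTree,
    cat: BranchCategoryMap,
    spec: OmegaModelSpec,
    params: CodonModelParams,
) -> float:
    """Log-likelihood at fixed parameters (branch lengths from the tree).

    ``params.omega_map`` maps the spec's class names to omega values.
    """
    cat = BranchCategoryMap(tree, cat.category, cat.tag) if tree is not cat.tree else cat
    eng = _Engine(caln, cat, spec, "F3x4")
    eng.pi = params.pi
    eng.sqrt_pi = np.sqrt(params.pi)
    omegas = [params.omega_map[name] for name in spec.class_names()]
    return eng.loglik(params.kappa, omegas, eng.t0)


def fit_model(
    caln: CodonAlignment,
    tree: PhyloTree,
    cat: BranchCategoryMap,
    spec: OmegaModelSpec,
    opts: dict | None = None,
) -> BranchOmegaResults:
    """Functional wrapper over :class:`BranchOmegaModel`.fit."""
    opts = dict(opts or {})
    freq_model = opts.pop("freq_model", "F3x4")
    if tree is not cat.tree:
        cat = BranchCategoryMap(tree, cat.category, cat.tag)
    return BranchOmegaModel(caln, cat, spec, freq_model).fit(**opts)


def lrt(nested: BranchOmegaResults, general: BranchOmegaResults,
        df: int | None = None, tol: float = 1e-3) -> float:
    """Chi-square LRT p-value of a nested model pair."""
    if df is None:
        df = general.n_params - nested.n_params
    if nested.n_params + df != general.n_params:
        raise UsageError("df inconsistent with parameter counts")
    stat = 2.0 * (general.lnL - nested.lnL)
    if stat < -tol:
        raise ConvergenceError(
            f"general model lnL below nested ({general.lnL:.6f} < {nested.lnL:.6f})"
        )
    return float(chi2.sf(max(stat, 0.0), df))


def lrt_from_lnl(lnl_nested: float, lnl_general: float, df: int = 1) -> float:
    """LRT p-value from two log-likelihood values (ledger arithmetic)."""
    return float(chi2.sf(max(2.0 * (lnl_general - lnl_nested), 0.0), df))


def aic(lnl: float, n_params: int) -> float:
    return -2.0 * lnl + 2.0 * n_params


def run_model_ladder(
    caln: CodonAlignment,
    tree: PhyloTree,
    cat: BranchCategoryMap,
    family: str,
    opts: dict | None = None,
) -> pd.DataFrame:
    """Fit the shallow- or deep-branch ladder and tabulate lnL/#p/AIC/LRT.

    Mirrors the layout of the published model-comparison tables: one row per
    model with its comparison partner, plus a best-by-AIC flag. The fitted
    results objects are attached as ``df.attrs['results']``.
    """
    if family not in ("shallow-family", "deep-family", "shallow", "deep"):
        raise UsageError(f"unknown family {family!r}")
    if tree is not cat.tree:
        cat = BranchCategoryMap(tree, cat.category, cat.tag)
    ladder = (
        shallow_family(cat) if family.startswith("shallow") else deep_family(cat)
    )
    results: dict[str, BranchOmegaResults] = {}
    rows = []
    tvecs: dict[str, np.ndarray] = {}
    for spec, partner in ladder:
        fit_opts = dict(opts or {})
        if partner and partner in results:
            # warm-start from the nested partner's fit
            prev = results[partner]
            fit_opts.setdefault("omega0", float(np.mean(list(prev.omegas.values()))))
            fit_opts.setdefault("kappa0", prev.kappa)
            fit_opts.setdefault("t_init", tvecs[partner])
        model = BranchOmegaModel(caln, cat, spec, fit_opts.pop("freq_model", "F3x4"))
        res = model.fit(**fit_opts)
        tvecs[spec.name] = model._last_tvec
        results[spec.name] = res
        p = np.nan
        if partner and partner in results:
            p = lrt(results[partner], res)
        rows.append(
            {
                "model": spec.name,
                "constraint": spec.description,
                "lnL": res.lnL,
                "np": res.n_params,
                "AIC": res.aic,
                "LRT_p": p,
                "vs": partner or "",
            }
        )
    df = pd.DataFrame(rows)
    df["best_AIC"] = df["AIC"] == df["AIC"].min()
    df.attrs["results"] = results
    return df


# --------------------------------------------------------------------------
# brute-force oracle (tests / validation only, tiny instances)
# --------------------------------------------------------------------------
def brute_force_loglik(
    caln: CodonAlignment,
    cat: BranchCategoryMap,
    spec: OmegaModelSpec,
    kappa: float,
    omegas,
    freq_model: str = "F3x4",
) -> float:
    """Likelihood by explicit summation over all internal-state assignments.

    Exponential in the number of internal nodes; use only on <=3-leaf,
    few-codon instances.
    """
    from scipy.linalg import expm

    eng = _Engine(caln, cat, spec, freq_model)
    tree = cat.tree
    post = tree.postorder()
    internal = [n for n in post if not n.is_leaf]
    pi = eng.pi
    params = CodonModelParams(kappa, pi, {})
    class_of = {}
    for i, k in enumerate(eng.branch_nodes):
        class_of[id(eng.nodes[k])] = eng.branch_class[i]
    P = {}
    for node in post:
        if node.parent is None:
            continue
        q = build_rate_matrix(params, float(np.asarray(omegas)[class_of[id(node)]]))
        P[id(node)] = expm(q * max(node.length or 0.0, 1e-4))

    leaf_states = {n.name: None for n in post if n.is_leaf}
    rowidx = {nm: caln.ids.index(nm) for nm in leaf_states}
    lnl = 0.0
    for col in range(caln.n_codons):
        total = 0.0
        for assign in itertools.product(range(N_SENSE), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            term = pi[state[id(tree.root)]]
            for node in post:
                if node.parent is None:
                    continue
                sp = state[id(node.parent)]
                if node.is_leaf:
                    sc = caln.codons[rowidx[node.name], col]
                    if sc == MISSING:
                        term *= 1.0  # marginalized below by summing all states
                        term *= P[id(node)][sp].sum()
                        continue
                else:
                    sc = state[id(node)]
                term *= P[id(node)][sp, sc]
            total += term
        lnl += np.log(total)
    return float(lnl)
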