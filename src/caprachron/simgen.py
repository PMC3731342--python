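"""Synthetic data with the statistical structure of a multi-haplogroup
mitochondrial study.

Within each haplogroup a coalescent genealogy is drawn under exponential
population growth (star-like genealogies at strong growth); haplogroup MRCAs
are grafted onto a fixed deep topology at configured split times, and an
outgroup attaches at the calibration depth. Sequences then evolve along the
genealogy under a codon model with branch-category-specific omega, or under
nucleotide K80/GTR+Gamma (D-loop-like fragments). All times are years, with
an explicit generation-time parameter; every stochastic step takes a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from ._codes import N_SENSE, SENSE_CODONS
from .alignio import CodonAlignment, NucAlignment
from .chronos import discrete_gamma_rates, gtr_rate_matrix
from .codonml import CodonModelParams, build_rate_matrix
from .errors import UsageError
from .phylo import BranchCategoryMap, HaplogroupAssignment, categorize_branches
from .tree import Node, PhyloTree

# Default nucleotide composition per codon position, mitochondrial
# H-strand-coding-like (T, C, A, G order of _codes.NUCS).
_DEFAULT_POS_FREQ = np.array(
    [
        [0.23, 0.26, 0.31, 0.20],
        [0.40, 0.26, 0.19, 0.15],
        [0.25, 0.30, 0.37, 0.08],
    ]
)


@dataclass
class DemographyConfig:
    """Sampling scheme, deep topology and within-haplogroup demography.

    ``splits`` maps frozensets of haplogroup labels to split times (years);
    nesting must be consistent. ``tmrca`` optionally pins each haplogroup's
    MRCA age (years): the simulated within-group genealogy is rescaled to it
    (the study-card behavior); absent entries leave the coalescent TMRCA
    random. Growth rates are per generation.
    """

    samples: dict[str, int]
    splits: dict[frozenset, float]
    outgroup_age: float = 3.4e6
    outgroup_label: str = "markhor"
    pop_size: dict[str, float] = field(default_factory=dict)
    growth: dict[str, float] = field(default_factory=dict)
    tmrca: dict[str, float] = field(default_factory=dict)
    generation_time: float = 2.5
    default_pop_size: float = 100_000.0
    default_growth: float = 5e-4

    def __post_init__(self):
        for g, n in self.samples.items():
            if n < 1:
                raise UsageError(f"sample size for {g} must be >= 1")
        times = sorted(self.splits.items(), key=lambda kv: len(kv[0]))
        for (sa, ta) in times:
            for (sb, tb) in times:
                if sa < sb and not ta < tb:
                    raise UsageError(
                        f"split times must decrease toward the present: "
                        f"{sorted(sb)} at {tb} <= nested {sorted(sa)} at {ta}"
                    )


def study_demography(
    samples: dict[str, int] | None = None,
) -> DemographyConfig:
    """The default four-haplogroup study card.

    Haplogroups A:16, B:13, C:2, D:3 plus one outgroup; C split 840 ka,
    B vs A+D 350 ka, A vs D 200 ka; TMRCAs pinned to the study's point
    estimates (A 90.95, B 41.93, C 77.35, D 32.3 ka); goat/markhor
    calibration depth 3.4 Ma.
    """
    samples = samples or {"A": 16, "B": 13, "C": 2, "D": 3}
    groups = set(samples)
    splits = {}
    if groups == {"A", "B", "C", "D"}:
        splits = {
            frozenset("AD"): 200_000.0,
            frozenset("ABD"): 350_000.0,
            frozenset("ABCD"): 840_000.0,
        }
    else:
        raise UsageError("study card is defined for haplogroups A-D")
    return DemographyConfig(
        samples=samples,
        splits=splits,
        tmrca={"A": 90_950.0, "B": 41_930.0, "C": 77_350.0, "D": 32_300.0},
    )


@dataclass
class EvolveConfig:
    """Substitution process for sequence evolution along a genealogy in years.

    ``rate`` is per nucleotide site per year; codon-model branch lengths are
    3*rate*years (expected substitutions per codon). ``omega`` maps branch
    category keys ('interspecies', 'deep:<tag>' or plain 'deep',
    'shallow:<hg>' or 'shallow') to dN/dS values.
    """

    model: str  # 'codon-GY' | 'gtr-gamma' | 'k80-gamma'
    length: int
    rate: float
    kappa: float = 6.0
    shape: float = 0.5
    omega: dict[str, float] = field(default_factory=dict)
    pi_nuc: np.ndarray | None = None
    exch: np.ndarray | None = None
    n_gamma_cat: int = 8

    def __post_init__(self):
        if self.model not in ("codon-GY", "gtr-gamma", "k80-gamma"):
            raise UsageError(f"unknown model {self.model!r}")
        if self.rate < 0 or self.length <= 0:
            raise UsageError("rate must be >= 0 and length positive")


# --------------------------------------------------------------------------
# genealogy
# --------------------------------------------------------------------------
def _growth_coalescent(n: int, n0: float, r: float, rng) -> Node:
    """Kingman coalescent with backward population size N0*exp(-r*t).

    Times in generations on node.age; exact inversion sampling of the
    inhomogeneous exponential waiting times.
    """
    lineages = [Node(name=i) for i in range(n)]
    for leaf in lineages:
        leaf.age = 0.0
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        pair_rate = k * (k - 1) / 2.0
        e = rng.exponential()
        if r > 0:
            t = np.log(np.exp(r * t) + e * r * n0 / pair_rate) / r
        else:
            t = t + e * n0 / pair_rate
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = Node()
        parent.age = t
        parent.add(lineages[i])
        parent.add(lineages[j])
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(parent)
    return lineages[0]


def _scale_ages(node: Node, factor: float) -> None:
    stack = [node]
    while stack:
        x = stack.pop()
        x.age = x.age * factor
        stack.extend(x.children)


def simulate_genealogy(
    cfg: DemographyConfig, seed: int
) -> tuple[PhyloTree, HaplogroupAssignment]:
    """Time-scaled genealogy (years) plus the leaf haplogroup assignment."""
    rng = np.random.default_rng(seed)
    g = cfg.generation_time
    labels: dict[str, str] = {}
    group_roots: dict[str, Node] = {}
    for grp in sorted(cfg.samples):
        n = cfg.samples[grp]
        n0 = cfg.pop_size.get(grp, cfg.default_pop_size)
        growth = cfg.growth.get(grp, cfg.default_growth)
        root = _growth_coalescent(n, n0, growth, rng)
        _scale_ages(root, g)  # generations -> years
        if grp in cfg.tmrca and root.age > 0:
            _scale_ages(root, cfg.tmrca[grp] / root.age)
        idx = 0
        stack = [root]
        while stack:
            node = stack.pop()
            if not node.children:
                node.name = f"{grp}_{idx}"
                labels[node.name] = grp
                idx += 1
            stack.extend(node.children)
        group_roots[grp] = root

    # graft group MRCAs onto the nested backbone
    clades = sorted(cfg.splits, key=len)
    tops: dict[frozenset, Node] = {frozenset([grp]): root for grp, root in group_roots.items()}
    for clade in clades:
        t_split = cfg.splits[clade]
        members = [key for key in list(tops) if key < clade]
        # keep only maximal members (direct children of this split)
        members = [m for m in members if not any(m < other for other in members)]
        if len(members) < 2:
            raise UsageError(f"split {sorted(clade)} has fewer than two child clades")
        node = Node()
        node.age = t_split
        for m in members:
            child = tops.pop(m)
            if child.age >= t_split:
                raise UsageError(
                    f"clade {sorted(m)} TMRCA {child.age} exceeds split {t_split}"
                )
            node.add(child)
        tops[clade] = node
    if len(tops) != 1:
        raise UsageError("splits do not connect all haplogroups")
    ingroup_root = next(iter(tops.values()))
    root = Node()
    root.age = cfg.outgroup_age
    root.add(ingroup_root)
    out_leaf = Node(name=cfg.outgroup_label)
    out_leaf.age = 0.0
    root.add(out_leaf)
    labels[cfg.outgroup_label] = "outgroup"

    tree = PhyloTree(root)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return tree, HaplogroupAssignment(labels)


# --------------------------------------------------------------------------
# sequence evolution
# --------------------------------------------------------------------------
def _sample_descent(P: np.ndarray, parent_states: np.ndarray, rng) -> np.ndarray:
    """Draw child states codon-by-codon from transition rows of P."""
    child = np.empty_like(parent_states)
    for s in np.unique(parent_states):
        idx = np.nonzero(parent_states == s)[0]
        p = np.maximum(P[s], 0.0)
        child[idx] = rng.choice(P.shape[1], size=idx.size, p=p / p.sum())
    return child


def _expm_spectral(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    sq = np.sqrt(pi)
    B = q * (sq[:, None] / sq[None, :])
    lam, U = np.linalg.eigh(0.5 * (B + B.T))
    X = U / sq[:, None]
    Y = U.T * sq[None, :]
    return (X * np.exp(lam * t)[None, :]) @ Y


def default_codon_pi() -> np.ndarray:
    """F3x4-style codon frequencies from the default mito-like composition."""
    from ._codes import NUC_INDEX

    pos = _DEFAULT_POS_FREQ
    idx = np.array([[NUC_INDEX[c[k]] for k in range(3)] for c in SENSE_CODONS])
    pi = pos[0, idx[:, 0]] * pos[1, idx[:, 1]] * pos[2, idx[:, 2]]
    return pi / pi.sum()


def _omega_for_branch(cfg: EvolveConfig, key: str) -> float:
    if key in cfg.omega:
        return cfg.omega[key]
    cat = key.split(":", 1)[0]
    if cat in cfg.omega:
        return cfg.omega[cat]
    raise UsageError(f"omega map lacks an entry for branch category {key!r}")


def evolve_sequences(
    tree: PhyloTree,
    cfg: EvolveConfig,
    seed: int,
    categories: BranchCategoryMap | None = None,
) -> CodonAlignment | NucAlignment:
    """Evolve sequences along a genealogy whose branch lengths are years.

    Codon mode requires ``categories`` (or a fully categorical 'omega' map
    with 'deep'/'shallow'/'interspecies' defaults); the codon process never
    emits stop codons because the state space is the 60 sense codons.
    """
    rng = np.random.default_rng(seed)
    post = tree.postorder()
    root = post[-1]
    preorder = tree.preorder()

    if cfg.model == "codon-GY":
        pi = default_codon_pi() if cfg.pi_nuc is None else cfg.pi_nuc
        params = CodonModelParams(cfg.kappa, pi, {})
        qcache: dict[float, np.ndarray] = {}
        states = {id(root): rng.choice(N_SENSE, size=cfg.length, p=pi)}
        for node in preorder:
            if node.parent is None:
                continue
            if categories is not None:
                key = categories.class_key(frozenset(tree.clade_leafset(node)))
            else:
                key = "interspecies"
            w = _omega_for_branch(cfg, key)
            if w not in qcache:
                qcache[w] = build_rate_matrix(params, w)
            t_codon = 3.0 * cfg.rate * (node.length or 0.0)
            P = _expm_spectral(qcache[w], pi, t_codon)
            states[id(node)] = _sample_descent(P, states[id(node.parent)], rng)
        leaves = tree.leaves()
        codons = np.stack([states[id(leaf)] for leaf in leaves]).astype(np.int16)
        return CodonAlignment([leaf.name for leaf in leaves], codons)

    # nucleotide modes
    if cfg.model == "k80-gamma":
        pi = np.full(4, 0.25)
        exch = np.array([1.0, cfg.kappa, 1.0, 1.0, cfg.kappa])
    else:
        pi = cfg.pi_nuc if cfg.pi_nuc is not None else np.array([0.33, 0.27, 0.13, 0.27])
        exch = cfg.exch if cfg.exch is not None else np.array([2.0, 8.0, 1.5, 1.0, 12.0])
    q = gtr_rate_matrix(exch, pi)
    rates = discrete_gamma_rates(cfg.shape, cfg.n_gamma_cat)
    site_cat = rng.integers(0, cfg.n_gamma_cat, size=cfg.length)
    states = {id(root): rng.choice(4, size=cfg.length, p=pi)}
    for node in preorder:
        if node.parent is None:
            continue
        t_site = cfg.rate * (node.length or 0.0)
        child = np.empty(cfg.length, dtype=np.int64)
        for c in range(cfg.n_gamma_cat):
            idx = np.nonzero(site_cat == c)[0]
            if idx.size == 0:
                continue
            P = _expm_spectral(q, pi, t_site * rates[c])
            child[idx] = _sample_descent(P, states[id(node.parent)][idx], rng)
        states[id(node)] = child
    leaves = tree.leaves()
    nucmap = np.array(list("ACGT"))
    seqs = ["".join(nucmap[states[id(leaf)]]) for leaf in leaves]
    return NucAlignment([leaf.name for leaf in leaves], seqs)


# --------------------------------------------------------------------------
# the end-to-end study fixture
# --------------------------------------------------------------------------
STUDY_OMEGA = {
    "interspecies": 0.0564,
    "deep:a": 0.2206,
    "deep:b": 0.1483,
    "deep:c": 0.0246,
    "deep:d": 0.0356,
    "deep:x": 0.0001,
    "deep:y": 0.0001,
    "shallow:A": 0.049,
    "shallow:B": 0.345,
    "shallow:C": 0.123,
    "shallow:D": 0.173,
}

#: overall per-site per-year substitution rate of the coding concatenation
STUDY_CODING_RATE = 1.2e-8
#: D-loop per-site per-year rate (fast clock estimated on the HV1 fragment)
STUDY_DLOOP_RATE = 2.73e-7


@dataclass
class StudyFixture:
    genealogy: PhyloTree
    assignment: HaplogroupAssignment
    categories: BranchCategoryMap
    codon_aln: CodonAlignment
    dloop_aln: NucAlignment
    params: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        from .alignio import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.codon_aln.to_nuc_alignment(), outdir / "codon.fasta")
        write_fasta(self.dloop_aln, outdir / "dloop.fasta")
        (outdir / "genealogy.nwk").write_text(self.genealogy.to_newick())
        with open(outdir / "params.yml", "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=False)


def make_study_fixture(
    seed: int,
    n_codons: int = 3500,
    dloop_length: int = 481,
    samples: dict[str, int] | None = None,
    omega: dict[str, float] | None = None,
    coding_rate: float = STUDY_CODING_RATE,
    kappa: float = 6.0,
) -> StudyFixture:
    """Deterministic end-to-end bundle exercising every pipeline stage.

    34 ingroup sequences (A:16, B:13, C:2, D:3) plus one outgroup by
    default; ~3,500 codons of coding sequence with branch-category omegas
    matching the study's point estimates, and a D-loop-like fragment under
    K80+Gamma(alpha=0.22) at the fast D-loop rate.
    """
    ss = np.random.SeedSequence(seed)
    s_gene, s_codon, s_dloop = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    demo = study_demography(samples)
    tree, assignment = simulate_genealogy(demo, s_gene)
    categories = categorize_branches(tree, assignment)
    omega = dict(STUDY_OMEGA if omega is None else omega)
    codon_cfg = EvolveConfig(
        model="codon-GY", length=n_codons, rate=coding_rate, kappa=kappa, omega=omega
    )
    caln = evolve_sequences(categories.tree, codon_cfg, s_codon, categories)
    caln.meta = dict(assignment.labels)
    dloop_cfg = EvolveConfig(
        model="k80-gamma",
        length=dloop_length,
        rate=STUDY_DLOOP_RATE,
        kappa=10.0,
        shape=0.22,
    )
    dloop = evolve_sequences(categories.tree, dloop_cfg, s_dloop)
    dloop.meta = dict(assignment.labels)
    params = {
        "seed": seed,
        "n_codons": n_codons,
        "dloop_length": dloop_length,
        "samples": demo.samples,
        "splits": {"+".join(sorted(k)): v for k, v in demo.splits.items()},
        "tmrca": demo.tmrca,
        "outgroup_age": demo.outgroup_age,
        "generation_time": demo.generation_time,
        "omega": omega,
        "coding_rate": coding_rate,
        "dloop_rate": STUDY_DLOOP_RATE,
        "kappa": kappa,
    }
    return StudyFixture(tree, assignment, categories, caln, dloop, params)
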