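"""Distance-based tree inference and the three-way branch stratification.

Implements K80+Gamma pairwise distances, neighbor joining with deterministic
tie-breaking, Felsenstein bootstrap supports, reference-based haplogroup
assignment, and the shallow / deep / inter-species branch categorization used
by the branch-wise dN/dS models:

* shallow — branches strictly inside a haplogroup's MRCA subtree (tagged with
  that haplogroup),
* deep — internal branches between the all-ingroup MRCA and each haplogroup
  MRCA, including each haplogroup's stem,
* inter-species — branches connecting the outgroup to the ingroup MRCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import NucAlignment
from .errors import UsageError
from .tree import Node, PhyloTree

PURINES = frozenset("AG")

OUTGROUP_LABEL = "outgroup"


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class HaplogroupAssignment:
    """Total mapping leaf -> haplogroup label ('outgroup' roots the tree)."""

    labels: dict[str, str]

    def group(self, label: str) -> list[str]:
        return [k for k, v in self.labels.items() if v == label]

    @property
    def outgroup(self) -> list[str]:
        return self.group(OUTGROUP_LABEL)

    def haplogroups(self) -> list[str]:
        return sorted({v for v in self.labels.values() if v != OUTGROUP_LABEL})


@dataclass
class BranchCategoryMap:
    """Per-branch category over a rooted tree.

    Branches are keyed by the leafset of the node below them. ``tree`` is the
    outgroup-rooted tree the map was built on. Category values are
    'shallow' / 'deep' / 'interspecies'; shallow branches carry their
    haplogroup tag, deep branches a tag naming the haplogroup(s) below them
    (stem of A -> 'a'; composite clades like A+D -> 'x', A+D+B -> 'y' in the
    four-haplogroup layout).
    """

    tree: PhyloTree
    category: dict[frozenset, str]
    tag: dict[frozenset, str]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat in self.category.values():
            out[cat] = out.get(cat, 0) + 1
        return out

    def deep_tags(self) -> list[str]:
        tags = {t for k, t in self.tag.items() if self.category[k] == "deep"}
        return sorted(tags, key=lambda t: (len(t), t))

    def shallow_tags(self) -> list[str]:
        return sorted({t for k, t in self.tag.items() if self.category[k] == "shallow"})

    def class_key(self, leafset: frozenset) -> str:
        """Canonical key 'interspecies' | 'deep:<tag>' | 'shallow:<tag>'."""
        cat = self.category[leafset]
        if cat == "interspecies":
            return cat
        return f"{cat}:{self.tag[leafset]}"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for leafset in sorted(self.category, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "branch": ",".join(sorted(leafset)),
                    "category": self.category[leafset],
                    "tag": self.tag.get(leafset, ""),
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------
def k80_gamma_distance(aln: NucAlignment, shape: float = 0.22) -> DistanceMatrix:
    """Gamma-corrected Kimura two-parameter distances.

    d = (a/2)[(1-2P-Q)^{-1/a} - 1] + (a/4)[(1-2Q)^{-1/a} - 1] with transition
    and transversion proportions P, Q over pairwise non-missing columns.
    Saturated pairs (non-positive power argument) are flagged undefined.
    """
    if shape <= 0:
        raise UsageError("gamma shape must be positive")
    arr = aln.to_array()
    n = aln.n
    valid = (arr == "A") | (arr == "C") | (arr == "G") | (arr == "T")
    purine = (arr == "A") | (arr == "G")
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                raise UsageError(
                    f"no shared complete columns for {aln.ids[i]}/{aln.ids[j]}"
                )
            diff = both & (arr[i] != arr[j])
            ts = (diff & (purine[i] == purine[j])).sum()
            tv = diff.sum() - ts
            P, Q = ts / m, tv / m
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if w1 <= 0 or w2 <= 0:
                undefined.append((aln.ids[i], aln.ids[j]))
                warnings.warn(
                    f"saturated distance for {aln.ids[i]}/{aln.ids[j]} "
                    f"(P={P:.3f}, Q={Q:.3f})"
                )
                dist = np.nan
            else:
                dist = (shape / 2.0) * (w1 ** (-1.0 / shape) - 1.0) + (
                    shape / 4.0
                ) * (w2 ** (-1.0 / shape) - 1.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(aln.ids[:], d, undefined)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------
def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster-id, cluster-id) pair, where a cluster's id is the smallest leaf
    name it contains; negative branch lengths are clamped to zero with the
    deficit moved to the sister branch. Returns an unrooted tree (basal
    trifurcation).
    """
    n = len(dm.ids)
    if n < 3:
        raise UsageError("neighbor joining needs at least 3 sequences")
    if np.isnan(dm.values).any():
        raise UsageError("distance matrix contains undefined entries")
    nodes = [Node(name=i) for i in dm.ids]
    cluster_id = list(dm.ids)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    ids = tuple(sorted((cluster_id[active[a]], cluster_id[active[b]])))
                    if best is None or ids < best[0]:
                        best = (ids, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        vi = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vi, vj = 0.0, dij
        if vj < 0:
            vi, vj = dij, 0.0
        new = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        new.add(nodes[i])
        new.add(nodes[j])
        nodes.append(new)
        cluster_id.append(min(cluster_id[i], cluster_id[j]))
        k = len(nodes) - 1
        newdist = np.zeros(len(nodes))
        for other in active:
            if other in (i, j):
                continue
            newdist[other] = 0.5 * (d[i, other] + d[j, other] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, : k + 1] = newdist[: k + 1]
        d[: k + 1, k] = newdist[: k + 1]
        active = [x for x in active if x not in (i, j)] + [k]

    # final three clusters joined at the basal trifurcation
    i, j, k = sorted(active, key=lambda x: cluster_id[x])
    root = Node()
    nodes[i].length = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for x in (i, j, k):
        root.add(nodes[x])
    return PhyloTree(root)


def bootstrap_support(
    aln: NucAlignment,
    reps: int,
    seed: int,
    shape: float = 0.22,
) -> PhyloTree:
    """Felsenstein column bootstrap on the NJ tree.

    Supports are the percentage of replicate NJ trees containing each original
    bipartition, attached to internal nodes of the point-estimate tree.
    """
    if reps < 1:
        raise UsageError("reps must be >= 1")
    base = nj_tree(k80_gamma_distance(aln, shape))
    counts: dict[frozenset, int] = {p: 0 for p in base.bipartitions()}
    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    length = aln.length
    for _ in range(reps):
        cols = rng.integers(0, length, size=length)
        rep = NucAlignment(aln.ids[:], ["".join(row) for row in arr[:, cols]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                rep_tree = nj_tree(k80_gamma_distance(rep, shape))
            except UsageError:
                continue  # saturated replicate
        parts = rep_tree.bipartitions()
        for p in counts:
            if p in parts:
                counts[p] += 1
    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)
    for node in base.branches():
        if node.is_leaf:
            continue
        side = base.clade_leafset(node)
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / reps
    return base


# --------------------------------------------------------------------------
# haplogroup assignment
# --------------------------------------------------------------------------
def assign_haplogroups(
    query: NucAlignment,
    refs: NucAlignment,
    shape: float = 0.22,
) -> HaplogroupAssignment:
    """Label queries by the smallest NJ clade containing a reference.

    ``refs.meta`` maps reference ids to haplogroup labels (22 reference
    D-loop haplotypes in the original design). A joint NJ tree is built; each
    query takes the label of the smallest clade containing it plus at least
    one reference, by majority when references conflict (with a warning), or
    'unassigned' when the tie cannot be resolved.
    """
    if not query.ids:
        return HaplogroupAssignment({})
    if query.length != refs.length:
        raise UsageError("query and reference alignments must share coordinates")
    missing = [r for r in refs.ids if r not in refs.meta]
    if missing:
        raise UsageError(f"references without labels: {missing}")
    joint = NucAlignment(
        query.ids + refs.ids, query.seqs + refs.seqs, dict(refs.meta)
    )
    tree = nj_tree(k80_gamma_distance(joint, shape))
    out_refs = [r for r in refs.ids if refs.meta[r] == OUTGROUP_LABEL]
    if out_refs:
        tree = tree.root_with_outgroup(out_refs)
    else:
        tree = tree.root_with_outgroup([refs.ids[0]])
    ref_label = dict(refs.meta)
    leaf_node = {leaf.name: leaf for leaf in tree.leaves()}
    labels: dict[str, str] = {}
    for qid in query.ids:
        node = leaf_node[qid].parent
        label = "unassigned"
        while node is not None:
            found = [
                ref_label[nm]
                for nm in tree.clade_leafset(node)
                if nm in ref_label and ref_label[nm] != OUTGROUP_LABEL
            ]
            if found:
                values, counts = np.unique(found, return_counts=True)
                if len(values) > 1:
                    warnings.warn(
                        f"ambiguous clade for {qid}: references {sorted(set(found))}"
                    )
                top = counts.max()
                winners = sorted(values[counts == top])
                label = winners[0] if len(winners) == 1 else "unassigned"
                break
            node = node.parent
        labels[qid] = label
    return HaplogroupAssignment(labels)


# --------------------------------------------------------------------------
# branch categorization
# --------------------------------------------------------------------------
_COMPOSITE_ALIASES = {
    # four-haplogroup layout of the goat tree: A+D and A+D+B backbone clades
    frozenset("AD"): "x",
    frozenset("ABD"): "y",
}


def _composite_tag(groups: frozenset) -> str:
    if groups in _COMPOSITE_ALIASES:
        return _COMPOSITE_ALIASES[groups]
    return "+".join(sorted(groups)).lower()


def categorize_branches(
    tree: PhyloTree, hg: HaplogroupAssignment
) -> BranchCategoryMap:
    """Stratify every branch into shallow / deep / inter-species.

    The tree is rooted at the midpoint of the outgroup stem. Each haplogroup
    must be monophyletic. A haplogroup's stem branch is deep; the pendant
    branch of a single-member haplogroup counts as shallow.
    """
    outgroup = hg.outgroup
    if not outgroup:
        raise UsageError("assignment contains no outgroup leaves")
    rooted = tree.root_with_outgroup(outgroup)
    leaf_names = set(rooted.leaf_names())
    unlabeled = leaf_names - set(hg.labels)
    if unlabeled:
        raise UsageError(f"leaves without haplogroup labels: {sorted(unlabeled)}")

    groups = hg.haplogroups()
    group_leaves = {g: set(hg.group(g)) & leaf_names for g in groups}
    mrca_set: dict[str, frozenset] = {}
    for g in groups:
        members = group_leaves[g]
        clade = rooted.clade_leafset(rooted.mrca(members))
        intruders = clade - members
        if intruders:
            raise UsageError(
                f"haplogroup {g} not monophyletic; intruding leaves: "
                f"{sorted(intruders)}"
            )
        mrca_set[g] = frozenset(clade)

    ingroup = leaf_names - set(outgroup)
    category: dict[frozenset, str] = {}
    tag: dict[frozenset, str] = {}
    for node in rooted.branches():
        clade = rooted.clade_leafset(node)
        key = frozenset(clade)
        if clade <= set(outgroup) or ingroup <= clade:
            category[key] = "interspecies"
            tag[key] = "interspecies"
            continue
        shallow_in = [
            g for g in groups if clade < mrca_set[g] or (len(mrca_set[g]) == 1 and clade == mrca_set[g])
        ]
        if shallow_in:
            category[key] = "shallow"
            tag[key] = shallow_in[0]
        else:
            category[key] = "deep"
            below = frozenset(g for g in groups if mrca_set[g] <= clade)
            if len(below) == 1:
                tag[key] = next(iter(below)).lower()
            else:
                tag[key] = _composite_tag(below)
    return BranchCategoryMap(rooted, category, tag)
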