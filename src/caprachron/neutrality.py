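"""McDonald–Kreitman contingency tables and Tajima's D.

The MK test contrasts synonymous/non-synonymous changes that are *fixed*
between two haplogroups (each group internally monomorphic, no shared
allele) with those *polymorphic* within either group. Under neutrality the
two ratios agree; a Neutrality Index (Pn/Ps)/(Dn/Ds) above 1 indicates an
excess of (typically slightly deleterious) non-synonymous polymorphism.
Tajima's D contrasts pairwise diversity with segregating-site diversity;
negative values signal population expansion or purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, fisher_exact

from ._codes import SENSE_CODONS, translate
from .alignio import MISSING, CodonAlignment, NucAlignment
from .errors import UsageError


# --------------------------------------------------------------------------
# McDonald–Kreitman
# --------------------------------------------------------------------------
@dataclass
class MKContingency:
    """2x2 fixed/polymorphic x synonymous/non-synonymous counts."""

    Ds: int
    Ps: int
    Dn: int
    Pn: int
    codons_analyzed: int = 0
    complex_excluded: int = 0

    def table(self) -> np.ndarray:
        """Rows syn/nonsyn, columns fixed/polymorphic."""
        return np.array([[self.Ds, self.Ps], [self.Dn, self.Pn]], dtype=float)


@dataclass
class MKResult:
    NI: float | None
    alpha: float | None
    fisher_p: float
    G: float | None
    G_williams: float | None
    G_yates: float | None

    @property
    def p_G(self) -> float | None:
        return None if self.G is None else float(chi2.sf(self.G, 1))

    @property
    def p_G_williams(self) -> float | None:
        return None if self.G_williams is None else float(chi2.sf(self.G_williams, 1))

    @property
    def p_G_yates(self) -> float | None:
        return None if self.G_yates is None else float(chi2.sf(self.G_yates, 1))


def _pathway_changes(codon_a: str, codon_b: str):
    """Classify the nucleotide changes between two codons.

    Single-step pairs give one syn/nonsyn call. Multi-step pairs are
    decomposed change-by-change only when every mutational order gives the
    same syn/nonsyn multiset and never crosses a stop codon; otherwise None
    (ambiguous, excluded with a count).
    """
    import itertools

    diffs = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diffs:
        return []
    if len(diffs) == 1:
        return [translate(codon_a) == translate(codon_b)]
    outcomes = set()
    paths = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        calls = []
        ok = True
        for k in order:
            nxt = cur[:k] + codon_b[k] + cur[k + 1 :]
            if nxt not in SENSE_CODONS and translate_or_stop(nxt):
                ok = False
                break
            calls.append(translate(cur) == translate(nxt))
            cur = nxt
        if ok:
            paths.append(calls)
            outcomes.add(tuple(sorted(calls)))
    if len(outcomes) == 1 and paths:
        return list(paths[0])
    return None


def translate_or_stop(codon: str) -> bool:
    """True when the codon is a stop under the vertebrate mito code."""
    return translate(codon) == "*"


def mk_contingency(alnA: CodonAlignment, alnB: CodonAlignment) -> MKContingency:
    """Build the MK 2x2 table between two haplogroup codon alignments.

    Only codon columns complete (non-missing) in every used sequence of both
    groups contribute; this is why the number of codons analyzed differs
    across haplogroup pairs when different individuals lack different genes.
    """
    if alnA.n_codons != alnB.n_codons:
        raise UsageError("alignments do not share codon coordinates")
    if max(alnA.n, alnB.n) < 2:
        raise UsageError("need >= 2 sequences in at least one group")
    A, B = alnA.codons, alnB.codons
    completeA = ~(A == MISSING).any(axis=0)
    completeB = ~(B == MISSING).any(axis=0)
    usable = completeA & completeB
    Ds = Ps = Dn = Pn = 0
    complex_excluded = 0
    for col in np.nonzero(usable)[0]:
        a_states = set(A[:, col].tolist())
        b_states = set(B[:, col].tolist())
        if len(a_states) == 1 and len(b_states) == 1:
            (sa,), (sb,) = a_states, b_states
            if sa == sb:
                continue
            calls = _pathway_changes(SENSE_CODONS[sa], SENSE_CODONS[sb])
            if calls is None:
                complex_excluded += 1
                continue
            for is_syn in calls:
                if is_syn:
                    Ds += 1
                else:
                    Dn += 1
            continue
        # polymorphic within at least one group: count each group's internal
        # changes against its own majority (ancestral proxy) allele
        for states in (a_states, b_states):
            if len(states) == 1:
                continue
            ref = min(states)
            ambiguous = False
            calls_all = []
            for s in states:
                if s == ref:
                    continue
                calls = _pathway_changes(SENSE_CODONS[ref], SENSE_CODONS[s])
                if calls is None:
                    ambiguous = True
                    break
                calls_all.extend(calls)
            if ambiguous:
                complex_excluded += 1
                continue
            for is_syn in calls_all:
                if is_syn:
                    Ps += 1
                else:
                    Pn += 1
    return MKContingency(
        Ds, Ps, Dn, Pn,
        codons_analyzed=int(usable.sum()),
        complex_excluded=complex_excluded,
    )


def _g_statistic(tab: np.ndarray) -> float:
    N = tab.sum()
    E = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / N
    mask = tab > 0
    return float(2.0 * (tab[mask] * np.log(tab[mask] / E[mask])).sum())


def mk_statistics(tab: MKContingency) -> MKResult:
    """NI, alpha, Fisher's exact p and the G-test family for one MK table.

    G_williams divides G by q = 1 + (N/r1+N/r2-1)(N/c1+N/c2-1)/(6N); the
    Yates variant recomputes G on counts shifted 0.5 toward expectation
    (convention-sensitive; reported as such).
    """
    t = tab.table()
    undefined = tab.Ps == 0 or tab.Ds == 0 or tab.Dn == 0
    NI = alpha = None
    if not undefined:
        NI = (tab.Pn / tab.Ps) / (tab.Dn / tab.Ds)
        alpha = 1.0 - NI
    fisher_p = float(fisher_exact(t.astype(int), alternative="two-sided")[1])
    margins_ok = t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0
    if not margins_ok:
        return MKResult(NI, alpha, fisher_p, None, None, None)
    G = _g_statistic(t)
    N = t.sum()
    r, c = t.sum(axis=1), t.sum(axis=0)
    q = 1.0 + ((N / r).sum() - 1.0) * ((N / c).sum() - 1.0) / (6.0 * N)
    E = np.outer(r, c) / N
    shifted = t + np.clip(E - t, -0.5, 0.5)
    G_yates = _g_statistic(shifted)
    return MKResult(NI, alpha, fisher_p, G, G / q, G_yates)


def fisher_exact_enumeration(tab: np.ndarray) -> float:
    """Two-tailed Fisher p by exhaustive enumeration over the margins.

    Sums hypergeometric point probabilities <= the observed table's (with a
    small relative slack for float ties). Independent oracle for the
    scipy-backed p-value in :func:`mk_statistics`.
    """
    tab = np.asarray(tab, dtype=int)
    r1, r2 = tab.sum(axis=1)
    c1, _ = tab.sum(axis=0)
    N = tab.sum()

    def logp(a):
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        return (
            gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(N - c1 + 1)
            - gammaln(N + 1) - gammaln(a + 1) - gammaln(b + 1)
            - gammaln(c + 1) - gammaln(d + 1)
        )

    lo, hi = max(0, c1 - r2), min(c1, r1)
    obs = logp(tab[0, 0])
    total = 0.0
    for a in range(lo, hi + 1):
        lp = logp(a)
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


# --------------------------------------------------------------------------
# Tajima's D
# --------------------------------------------------------------------------
@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float
    D: float | None


def tajimas_d(aln: NucAlignment) -> TajimaResult:
    """Tajima's test statistic with the canonical 1989 constants.

    Only columns free of gaps and Ns contribute. D is undefined (None) when
    there are no segregating sites.
    """
    n = aln.n
    if n < 2:
        raise UsageError("need >= 2 sequences")
    arr = aln.to_array()
    valid = ~((arr == "N") | (arr == "-")).any(axis=0)
    sub = arr[:, valid]
    seg = np.array([len(set(sub[:, j])) > 1 for j in range(sub.shape[1])])
    S = int(seg.sum())
    # mean number of pairwise differences
    total = 0.0
    npairs = n * (n - 1) / 2
    for i in range(n):
        for j in range(i + 1, n):
            total += (sub[i] != sub[j]).sum()
    pi = total / npairs
    if S == 0:
        return TajimaResult(n, 0, pi, None)
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaResult(n, S, pi, float(D))
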