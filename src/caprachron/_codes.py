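"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The table has 60 sense codons: TAA/TAG/AGA/AGG are stops, ATA codes Met and
TGA codes Trp. All codon-indexed arrays in the package follow the ordering of
:data:`SENSE_CODONS`.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_AA = (
    # TTT TTC TTA TTG ... standard table-2 layout over TCAG x TCAG x TCAG
    "FFLLSSSSYY**CCWW"
    "LLLLPPPPHHQQRRRR"
    "IIMMTTTTNNKKSS**"
    "VVVVAAAADDEEGGGG"
)

ALL_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_TO_AA = {c: _AA[i] for i, c in enumerate(ALL_CODONS)}
STOP_CODONS = frozenset(c for c, a in CODON_TO_AA.items() if a == "*")
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

assert N_SENSE == 60
assert STOP_CODONS == {"TAA", "TAG", "AGA", "AGG"}
assert CODON_TO_AA["ATA"] == "M" and CODON_TO_AA["TGA"] == "W"

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a<->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def translate(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) under the vertebrate mito code."""
    return CODON_TO_AA[codon]


def _single_step_tables():
    """Masks over sense-codon pairs differing at exactly one position.

    Returns boolean (60, 60) arrays: single-step, transition (given single
    step), synonymous (given single step).
    """
    single = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    transit = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    synon = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transit[i, j] = is_transition(ci[k], cj[k])
            synon[i, j] = CODON_TO_AA[ci] == CODON_TO_AA[cj]
    return single, transit, synon


SINGLE_STEP, STEP_IS_TRANSITION, STEP_IS_SYNONYMOUS = _single_step_tables()
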