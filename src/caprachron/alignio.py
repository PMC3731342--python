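"""Alignment I/O and codon-alignment construction.

Reads nucleotide alignments of mitochondrial protein-coding genes, strips
initiation/termination codons and inter-gene overlap columns, and produces an
analysis-ready codon matrix under the vertebrate mitochondrial code. Two data
sets are derived from one input: the *smaller* set (rows/columns restricted so
no missing cell remains) and the *larger* set (missing data kept). Coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio import SeqIO

from ._codes import SENSE_CODONS, SENSE_INDEX, STOP_CODONS
from .errors import AlignmentError, DataQualityError, ParseError, UsageError

VALID_CHARS = set("ACGTN-")

#: sentinel codon index for a cell voided by any N or gap in its triplet
MISSING = -1


@dataclass
class NucAlignment:
    """A rectangular nucleotide alignment over {A,C,G,T,N,-}.

    ``meta`` optionally carries a per-sequence haplogroup label.
    """

    ids: list[str]
    seqs: list[str]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_array(self) -> np.ndarray:
        """(n, L) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def subset(self, ids: list[str]) -> "NucAlignment":
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise UsageError(f"unknown ids: {missing}")
        return NucAlignment(
            ids=list(ids),
            seqs=[self.seqs[index[i]] for i in ids],
            meta={i: self.meta[i] for i in ids if i in self.meta},
        )

    def take_columns(self, cols) -> "NucAlignment":
        arr = self.to_array()[:, list(cols)]
        return NucAlignment(self.ids[:], ["".join(r) for r in arr], dict(self.meta))


@dataclass(frozen=True)
class GeneRegion:
    """A gene's column interval [start, end) in the concatenation.

    ``frame`` is the offset from ``start`` to the first complete codon.
    """

    name: str
    start: int
    end: int
    frame: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise UsageError(f"bad interval for {self.name}: [{self.start}, {self.end})")
        if self.frame not in (0, 1, 2):
            raise UsageError(f"frame must be 0/1/2, got {self.frame}")


@dataclass
class CodonAlignment:
    """Codon matrix over the 60 sense codons of the vertebrate mito code.

    ``codons`` is an (n_seq, n_codon) int array of indices into
    :data:`caprachron._codes.SENSE_CODONS`, with :data:`MISSING` for voided
    cells. ``collapsed`` records duplicate-haplotype representatives.
    """

    ids: list[str]
    codons: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)
    provenance: str = "larger"
    collapsed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.codons[self.ids.index(seq_id)]

    def codon_strings(self, seq_id: str) -> list[str]:
        return [SENSE_CODONS[c] if c >= 0 else "---" for c in self.row(seq_id)]

    def subset(self, ids: list[str]) -> "CodonAlignment":
        rows = [self.ids.index(i) for i in ids]
        return CodonAlignment(
            ids=list(ids),
            codons=self.codons[rows].copy(),
            meta={i: self.meta[i] for i in ids if i in self.meta},
            provenance=self.provenance,
            collapsed={},
        )

    def to_nuc_alignment(self) -> NucAlignment:
        seqs = ["".join(self.codon_strings(i)) for i in self.ids]
        return NucAlignment(self.ids[:], seqs, dict(self.meta))


def read_fasta(path) -> NucAlignment:
    """Read an aligned FASTA file; lowercase normalized, U mapped to T."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        for pos, ch in enumerate(seq):
            if ch not in VALID_CHARS:
                raise ParseError(
                    f"illegal character {ch!r} in record {rec.id!r} at column {pos}"
                )
        ids.append(rec.id)
        seqs.append(seq)
    if not ids:
        raise ParseError(f"no FASTA records in {path}")
    return NucAlignment(ids, seqs)


def write_fasta(aln: NucAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_phylip(aln: NucAlignment, path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    width = max(len(i) for i in aln.ids)
    with open(path, "w") as fh:
        fh.write(f" {aln.n} {aln.length}\n")
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f"{sid:<{width}}  {seq}\n")


def read_regions(path) -> list[GeneRegion]:
    """Region config: YAML list (gene/start/end/frame) or 4-column TSV."""
    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        entries = yaml.safe_load(text)
        return [
            GeneRegion(e["gene"], int(e["start"]), int(e["end"]), int(e.get("frame", 0)))
            for e in entries
        ]
    regions = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, start, end, *rest = line.split("\t")
        frame = int(rest[0]) if rest else 0
        regions.append(GeneRegion(gene, int(start), int(end), frame))
    return regions


def build_codon_alignment(
    aln: NucAlignment,
    regions: list[GeneRegion],
    exclusions: list[tuple[int, int]] | None = None,
) -> CodonAlignment:
    """Assemble the codon matrix from per-gene column intervals.

    For each gene, columns in any excluded interval (inter-gene overlaps) are
    removed from both genes sharing them, the remaining length must be a
    multiple of 3, and the first (initiation) and last (termination) codons are
    stripped. Cells containing N or '-' become :data:`MISSING`; an internal
    stop codon raises :class:`DataQualityError` (numt / frameshift signal).
    """
    exclusions = exclusions or []
    excluded_cols = set()
    for s, e in exclusions:
        excluded_cols.update(range(s, e))

    arr = aln.to_array()
    codon_cols: list[list[int]] = []
    gene_of_codon: list[str] = []
    for region in regions:
        cols = [
            c
            for c in range(region.start + region.frame, region.end)
            if c not in excluded_cols
        ]
        if len(cols) % 3 != 0:
            raise UsageError(
                f"gene {region.name}: {len(cols)} columns after exclusions, "
                "not divisible by 3"
            )
        triplets = [cols[i : i + 3] for i in range(0, len(cols), 3)]
        # strip initiation and termination codons
        triplets = triplets[1:-1]
        codon_cols.extend(triplets)
        gene_of_codon.extend([region.name] * len(triplets))

    n_codons = len(codon_cols)
    codons = np.full((aln.n, n_codons), MISSING, dtype=np.int16)
    for j, cols in enumerate(codon_cols):
        sub = arr[:, cols]
        for i in range(aln.n):
            cell = "".join(sub[i])
            if "N" in cell or "-" in cell:
                continue
            if cell in STOP_CODONS:
                raise DataQualityError(
                    f"internal stop codon {cell} in sequence {aln.ids[i]!r}, "
                    f"gene {gene_of_codon[j]}, codon index {j}"
                )
            codons[i, j] = SENSE_INDEX[cell]
    return CodonAlignment(aln.ids[:], codons, dict(aln.meta), provenance="larger")


def _collapse_duplicates(caln: CodonAlignment) -> CodonAlignment:
    """Keep one representative per identical codon row, recording the mapping."""
    seen: dict[bytes, str] = {}
    keep_rows, keep_ids = [], []
    collapsed: dict[str, list[str]] = {}
    for i, sid in enumerate(caln.ids):
        key = caln.codons[i].tobytes()
        if key in seen:
            collapsed.setdefault(seen[key], []).append(sid)
        else:
            seen[key] = sid
            keep_rows.append(i)
            keep_ids.append(sid)
    return CodonAlignment(
        keep_ids,
        caln.codons[keep_rows].copy(),
        {i: caln.meta[i] for i in keep_ids if i in caln.meta},
        provenance=caln.provenance,
        collapsed=collapsed,
    )


def split_small_large(caln: CodonAlignment) -> tuple[CodonAlignment, CodonAlignment]:
    """Derive the gap-free *smaller* and the full *larger* data set.

    Smaller: sequences containing missing cells are dropped, then any column
    still containing a missing cell is dropped. Identical haplotypes are
    collapsed to one representative in both outputs.
    """
    complete = ~(caln.codons == MISSING).any(axis=1)
    ids_small = [sid for sid, ok in zip(caln.ids, complete) if ok]
    small = CodonAlignment(
        ids_small,
        caln.codons[complete].copy(),
        {i: caln.meta[i] for i in ids_small if i in caln.meta},
        provenance="smaller",
    )
    keep_cols = ~(small.codons == MISSING).any(axis=0)
    small.codons = small.codons[:, keep_cols]
    small = _collapse_duplicates(small)
    larger = _collapse_duplicates(replace(caln, provenance="larger"))
    return small, larger


def codon_position_view(caln: CodonAlignment, pos: int) -> NucAlignment:
    """Nucleotide alignment of codon position ``pos`` (1, 2 or 3).

    Missing codons appear as 'N'. Column count equals the codon count.
    """
    if pos not in (1, 2, 3):
        raise UsageError(f"codon position must be 1, 2 or 3, got {pos}")
    lookup = np.array([c[pos - 1] for c in SENSE_CODONS] + ["N"], dtype="U1")
    idx = np.where(caln.codons == MISSING, len(SENSE_CODONS), caln.codons)
    arr = lookup[idx]
    return NucAlignment(caln.ids[:], ["".join(r) for r in arr], dict(caln.meta))
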