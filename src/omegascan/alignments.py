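"""Genetic-code tables, codon alignments and third-position GC diagnostics.

A :class:`CodonAlignment` stores one protein-coding gene as a matrix of
sense-codon state indices over taxa.  Codon states are indexed in a single
fixed order — lexicographic over the nucleotide order T, C, A, G, the
convention used by most codon-model software — so that every downstream
module (rate matrices, pruning likelihoods, simulators) agrees on what
"state 7" means.  Any triplet that is not composed of exactly A/C/G/T
(alignment gaps, Ns, other IUPAC ambiguity codes) is stored as
:data:`MISSING` and is treated as fully ambiguous by the likelihood
machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MISSING",
    "GeneticCode",
    "STANDARD_CODE",
    "CodonAlignment",
    "load_codon_alignment",
    "write_codon_alignment",
    "gc3",
    "delta_gc3",
]

#: Sentinel state for a missing / fully-ambiguous codon.
MISSING: int = -1

#: Nucleotide ordering used for codon-state indices (PAML-style).
NUCLEOTIDE_ORDER = "TCAG"


class StopCodonError(ValueError):
    """An in-frame stop codon was found in a sequence read in strict mode."""


@dataclass(frozen=True, eq=False)  # identity hash: codes are module-level singletons
class GeneticCode:
    """A genetic code: the 64-triplet amino-acid map plus the fixed sense-codon order.

    The sense-codon order is lexicographic over T, C, A, G and is the state
    index convention for every codon matrix in the package.
    """

    name: str
    codon_to_aa: Mapping[str, str]
    sense_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_ncbi_table(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        all_codons = ["".join(c) for c in itertools.product(NUCLEOTIDE_ORDER, repeat=3)]
        stops = frozenset(table.stop_codons)
        sense = tuple(c for c in all_codons if c not in stops)
        mapping = {c: table.forward_table[c] for c in sense}
        return cls(
            name=table.names[0],
            codon_to_aa=mapping,
            sense_codons=sense,
            stop_codons=stops,
            index={c: i for i, c in enumerate(sense)},
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def amino_acid(self, state: int) -> str:
        return self.codon_to_aa[self.sense_codons[state]]

    def codon_nucleotide_indices(self) -> np.ndarray:
        """(n_states, 3) array of nucleotide indices (into T,C,A,G) per codon."""
        nuc = {b: i for i, b in enumerate(NUCLEOTIDE_ORDER)}
        return np.array(
            [[nuc[b] for b in codon] for codon in self.sense_codons], dtype=np.int64
        )

    def third_position_gc(self) -> np.ndarray:
        """Boolean mask over sense codons whose third base is G or C."""
        return np.array([c[2] in "GC" for c in self.sense_codons], dtype=bool)


#: The universal genetic code (61 sense codons, stops TAA/TAG/TGA).
STANDARD_CODE = GeneticCode.from_ncbi_table(1)


@dataclass
class CodonAlignment:
    """An in-frame codon alignment for one gene.

    Attributes
    ----------
    gene_id:
        Identifier for the gene / alignment.
    taxa:
        Ordered, unique taxon names (one per row).
    codons:
        ``(n_taxa, L)`` integer matrix of sense-codon state indices, with
        :data:`MISSING` for gaps/ambiguous codons.
    code:
        The genetic code giving meaning to the state indices.
    """

    gene_id: str
    taxa: tuple[str, ...]
    codons: np.ndarray
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2:
            raise ValueError("codon matrix must be 2-D (taxa x columns)")
        if self.codons.shape[0] != len(self.taxa):
            raise ValueError("row count does not match number of taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"duplicate taxon names in alignment {self.gene_id!r}")
        if self.codons.size and (
            self.codons.max() >= self.code.n_states or self.codons.min() < MISSING
        ):
            raise ValueError("codon state indices out of range")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        """Alignment length in codons."""
        return self.codons.shape[1]

    @property
    def fraction_missing(self) -> float:
        if self.codons.size == 0:
            return 0.0
        return float(np.mean(self.codons == MISSING))

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment {self.gene_id!r}") from None

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxon_index(taxon)]

    def sequence_string(self, taxon: str) -> str:
        """Nucleotide string for one taxon; missing codons rendered as ``---``."""
        states = self.row(taxon)
        sense = self.code.sense_codons
        return "".join("---" if s == MISSING else sense[s] for s in states)

    def subset_taxa(self, keep: Iterable[str]) -> "CodonAlignment":
        keep = [t for t in self.taxa if t in set(keep)]
        idx = [self.taxon_index(t) for t in keep]
        return CodonAlignment(self.gene_id, tuple(keep), self.codons[idx], self.code)

    def log_line(self) -> str:
        return (
            f"gene={self.gene_id} taxa={self.n_taxa} L={self.length} "
            f"missing={100.0 * self.fraction_missing:.1f}%"
        )


def _triplet_state(triplet: str, code: GeneticCode, mask_stops: bool) -> int:
    if any(b not in "ACGT" for b in triplet):
        return MISSING
    if triplet in code.stop_codons:
        if mask_stops:
            return MISSING
        raise StopCodonError(f"in-frame stop codon {triplet!r}")
    return code.index[triplet]


def load_codon_alignment(
    path, code: GeneticCode = STANDARD_CODE, *, mask_stops: bool = False,
    gene_id: str | None = None,
) -> CodonAlignment:
    """Read an in-frame nucleotide FASTA into a :class:`CodonAlignment`.

    Gap characters and ambiguity codes anywhere inside a triplet make the
    whole codon :data:`MISSING`.  In-frame stop codons raise
    :class:`StopCodonError` unless ``mask_stops`` is set, in which case they
    too become missing.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate taxon names in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths in {path}: {sorted(lengths)}")
    (nt_len,) = lengths
    if nt_len % 3 != 0:
        raise ValueError(f"alignment length {nt_len} not divisible by 3 in {path}")
    n_codons = nt_len // 3
    matrix = np.empty((len(records), n_codons), dtype=np.int64)
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper().replace("U", "T")
        for j in range(n_codons):
            try:
                matrix[i, j] = _triplet_state(seq[3 * j : 3 * j + 3], code, mask_stops)
            except StopCodonError as err:
                raise StopCodonError(
                    f"{err} at codon {j + 1} of {rec.id!r} in {path}"
                ) from None
    if gene_id is None:
        import os

        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CodonAlignment(gene_id, tuple(names), matrix, code)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    """Write a codon alignment back to nucleotide FASTA (missing codons as ``---``)."""
    records = [
        SeqRecord(Seq(aln.sequence_string(t)), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def gc3(alignment: CodonAlignment, taxon: str) -> float:
    """GC content at third codon positions for one taxon.

    The denominator counts only non-missing codons.  A row with no usable
    codons has undefined GC3 and returns ``nan`` (so that fully fragmentary
    rows never masquerade as AT-rich).
    """
    states = alignment.row(taxon)
    observed = states[states != MISSING]
    if observed.size == 0:
        return math.nan
    is_gc = alignment.code.third_position_gc()
    return float(np.mean(is_gc[observed]))


def delta_gc3(alignment: CodonAlignment, foreground_tips: Sequence[str]) -> float:
    """Difference of mean GC3: foreground tips minus all remaining tips.

    Taxa whose GC3 is undefined (all codons missing) are excluded from the
    group means; if an entire group is undefined the result is ``nan``.
    """
    fg = set(foreground_tips)
    if not fg:
        raise ValueError("foreground tip set is empty")
    unknown = fg - set(alignment.taxa)
    if unknown:
        raise KeyError(f"foreground tips not in alignment: {sorted(unknown)}")
    bg = [t for t in alignment.taxa if t not in fg]
    if not bg:
        raise ValueError("foreground tips must be a proper subset of taxa")

    def group_mean(taxa: list[str]) -> float:
        vals = [gc3(alignment, t) for t in taxa]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return group_mean(sorted(fg)) - group_mean(bg)
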