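"""Ortholog multiple-sequence-alignment handling.

Alignments are aligned FASTA files of one mitochondrial protein across
mammalian species, with a designated human reference row.  This module reads
and writes them, computes pairwise dissimilarity, and applies the ortholog
dissimilarity filter (sequences more than 50% dissimilar to the human
sequence are discarded; 30% for MT-ATP8).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: default header convention: "<accession> Genus species [rest]"
DEFAULT_SPECIES_REGEX = r"^\S+\s+(\S+\s+\S+)"


class AlignmentFormatError(ValueError):
    """The input is not a valid aligned FASTA (ragged, empty, ...)."""


class ReferenceNotFoundError(KeyError):
    """No record header contains the requested reference identifier."""


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned set of ortholog sequences with a human reference row.

    ``identifiers``, ``species`` and ``sequences`` are parallel tuples; all
    sequences have length ``n_columns`` and ``reference_index`` addresses the
    human row.  ``name`` is the protein (gene) name, e.g. ``MT-ND1``.
    """

    identifiers: tuple[str, ...]
    species: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_index: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("alignment has no records")
        n = len(self.sequences[0])
        for ident, seq in zip(self.identifiers, self.sequences):
            if len(seq) != n:
                raise AlignmentFormatError(
                    f"ragged alignment: record {ident!r} has length "
                    f"{len(seq)}, expected {n}"
                )
        if not (0 <= self.reference_index < len(self.sequences)):
            raise IndexError(
                f"reference_index {self.reference_index} out of range"
            )
        if len(set(self.identifiers)) != len(self.identifiers):
            raise AlignmentFormatError("duplicate record identifiers")

    @property
    def n_records(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.reference_index]

    @property
    def reference_species(self) -> str:
        return self.species[self.reference_index]

    def reference_ungapped_length(self) -> int:
        return sum(c != GAP for c in self.reference_sequence)

    def non_reference_indices(self) -> list[int]:
        """Indices of rows whose species differs from the reference species."""
        ref_sp = self.reference_species
        return [
            i
            for i in range(self.n_records)
            if i != self.reference_index and self.species[i] != ref_sp
        ]


def read_alignment(
    path,
    reference_id: str,
    species_regex: str = DEFAULT_SPECIES_REGEX,
    name: str = "",
) -> ProteinAlignment:
    """Read an aligned FASTA file and designate the reference row.

    ``reference_id`` must occur as a substring of exactly the reference
    record's header (id + description).  Species are parsed from the header
    with ``species_regex`` (one capture group); headers that do not match get
    an empty species string.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    pattern = re.compile(species_regex)
    ids, species, seqs = [], [], []
    ref_index = None
    for i, rec in enumerate(records):
        header = rec.description or rec.id
        ids.append(rec.id)
        m = pattern.search(header)
        species.append(m.group(1) if m else "")
        seqs.append(str(rec.seq).upper())
        if reference_id in header:
            if ref_index is None:
                ref_index = i
    if ref_index is None:
        raise ReferenceNotFoundError(
            f"no record header contains reference id {reference_id!r}"
        )
    return ProteinAlignment(
        identifiers=tuple(ids),
        species=tuple(species),
        sequences=tuple(seqs),
        reference_index=ref_index,
        name=name,
    )


def write_alignment(aln: ProteinAlignment, path) -> None:
    """Write the alignment back to aligned FASTA (header = "id species")."""
    records = [
        SeqRecord(Seq(seq), id=ident, description=sp)
        for ident, sp, seq in zip(aln.identifiers, aln.species, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def dissimilarity(a: str, b: str) -> float:
    """Fraction of compared columns at which two aligned sequences differ.

    Columns gapped in both sequences are excluded from the denominator; a gap
    aligned against a residue counts as a difference.  Two sequences with no
    comparable columns are defined to have dissimilarity 0.
    """
    if len(a) != len(b):
        raise ValueError(
            f"aligned sequences differ in length: {len(a)} vs {len(b)}"
        )
    compared = 0
    differing = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        compared += 1
        if x != y:
            differing += 1
    return differing / compared if compared else 0.0


def filter_orthologs(
    aln: ProteinAlignment, max_dissimilarity: float
) -> ProteinAlignment:
    """Drop rows strictly more dissimilar to the human row than the threshold.

    The reference row is always retained; relative order is preserved.  The
    default threshold in the pipeline is 0.5 (0.3 for MT-ATP8).
    """
    if not 0.0 < max_dissimilarity <= 1.0:
        raise ValueError("max_dissimilarity must be in (0, 1]")
    ref = aln.reference_sequence
    keep = [
        i
        for i in range(aln.n_records)
        if i == aln.reference_index
        or dissimilarity(aln.sequences[i], ref) <= max_dissimilarity
    ]
    return ProteinAlignment(
        identifiers=tuple(aln.identifiers[i] for i in keep),
        species=tuple(aln.species[i] for i in keep),
        sequences=tuple(aln.sequences[i] for i in keep),
        reference_index=keep.index(aln.reference_index),
        name=aln.name,
    )


def filter_report(
    aln: ProteinAlignment, max_dissimilarity: float
) -> pd.DataFrame:
    """Per-record dissimilarity-to-human and keep/discard decision as a table."""
    ref = aln.reference_sequence
    rows = []
    for i in range(aln.n_records):
        d = dissimilarity(aln.sequences[i], ref)
        kept = i == aln.reference_index or d <= max_dissimilarity
        rows.append(
            {
                "identifier": aln.identifiers[i],
                "species": aln.species[i],
                "dissimilarity": d,
                "status": "kept" if kept else "discarded",
            }
        )
    return pd.DataFrame(rows)
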