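"""Compensated Pathogenic Deviation (CPD) calling.

A CPD is a human pathogenic missense variant whose alternative residue is the
wild-type (reference) residue in one or more non-human orthologs.  A
supporting ortholog must additionally conserve the variant's sequence
context: at least 7 of the 10 residues surrounding the variant position
(5 upstream, 5 downstream, in human ungapped coordinates) identical to the
human sequence.  Prevalence of the alternative residue across all non-human
orthologs is reported alongside each call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .msa import GAP, ProteinAlignment

FLANK_HALF_WIDTH = 5
MIN_FLANK_IDENTITY = 7


class ReferenceMismatchError(ValueError):
    """The human residue at the variant column differs from ref_aa."""


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level substitution: gene, 1-based position, ref/alt residue."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref_aa equals alt_aa ({self.ref_aa})")

    def __str__(self) -> str:
        return f"{self.gene}:p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class CPDCall:
    """A positive CPD call with its supporting orthologs.

    ``supporting_species`` holds (identifier, species, flank_identity_count)
    for every non-human row carrying the alternative residue with >= 7/10
    conserved flanks; ``ortholog_fraction`` is the alt-residue prevalence over
    all non-human rows, flank-qualified or not.
    """

    variant: VariantRecord
    supporting_species: tuple[tuple[str, str, int], ...]
    ortholog_fraction: float

    def __post_init__(self) -> None:
        if not self.supporting_species:
            raise ValueError("CPDCall requires at least one supporting species")
        if any(c < MIN_FLANK_IDENTITY for _, _, c in self.supporting_species):
            raise ValueError("supporting species below flank threshold")


def position_to_column(aln: ProteinAlignment, position: int) -> int:
    """Map a 1-based human ungapped position to a 0-based alignment column."""
    if position < 1:
        raise IndexError(f"position must be >= 1, got {position}")
    seen = 0
    for col, residue in enumerate(aln.reference_sequence):
        if residue != GAP:
            seen += 1
            if seen == position:
                return col
    raise IndexError(
        f"position {position} beyond human sequence length {seen}"
    )


def flank_identity(
    aln: ProteinAlignment, record_index: int, position: int
) -> int:
    """Count conserved residues among the 10 human-coordinate flank positions.

    Flank positions running off either protein terminus count as
    non-identical, as do gaps in the target row at a flank column.
    """
    human = aln.sequences[aln.reference_index]
    target = aln.sequences[record_index]
    length = aln.reference_ungapped_length()
    count = 0
    for p in range(position - FLANK_HALF_WIDTH, position + FLANK_HALF_WIDTH + 1):
        if p == position:
            continue
        if p < 1 or p > length:
            continue  # off-terminus slot: non-identical by convention
        col = position_to_column(aln, p)
        if target[col] != GAP and target[col] == human[col]:
            count += 1
    return count


def cpd_prevalence(aln: ProteinAlignment, variant: VariantRecord) -> float:
    """Fraction of non-human rows carrying alt_aa at the variant's column."""
    col = _checked_column(aln, variant)
    others = aln.non_reference_indices()
    if not others:
        return 0.0
    carriers = sum(1 for i in others if aln.sequences[i][col] == variant.alt_aa)
    return carriers / len(others)


def call_cpd(
    aln: ProteinAlignment,
    variant: VariantRecord,
    min_flank_identity: int = MIN_FLANK_IDENTITY,
) -> CPDCall | None:
    """Call a CPD, or return None when no ortholog qualifies.

    The alignment is expected to be pre-filtered by dissimilarity.  A call
    requires >= 1 non-human row carrying alt_aa at the variant column with
    flank identity >= ``min_flank_identity``.
    """
    col = _checked_column(aln, variant)
    supporting = []
    for i in aln.non_reference_indices():
        if aln.sequences[i][col] != variant.alt_aa:
            continue
        flanks = flank_identity(aln, i, variant.position)
        if flanks >= min_flank_identity:
            supporting.append((aln.identifiers[i], aln.species[i], flanks))
    if not supporting:
        return None
    return CPDCall(
        variant=variant,
        supporting_species=tuple(supporting),
        ortholog_fraction=cpd_prevalence(aln, variant),
    )


def _checked_column(aln: ProteinAlignment, variant: VariantRecord) -> int:
    col = position_to_column(aln, variant.position)
    observed = aln.reference_sequence[col]
    if observed != variant.ref_aa:
        raise ReferenceMismatchError(
            f"human residue at {variant.gene} position {variant.position} is "
            f"{observed!r}, variant states ref {variant.ref_aa!r}"
        )
    return col


# ---------------------------------------------------------------------------
# tabular interfaces

VARIANT_COLUMNS = ["gene", "position", "ref_aa", "alt_aa", "label"]


def read_variant_table(path) -> list[VariantRecord]:
    """Read a variant TSV (gene, position, ref_aa, alt_aa[, label])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = set(VARIANT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    return [
        VariantRecord(
            gene=row.gene,
            position=int(row.position),
            ref_aa=str(row.ref_aa),
            alt_aa=str(row.alt_aa),
            label="" if pd.isna(row.label) else str(row.label),
        )
        for row in df.itertuples()
    ]


def screen_variants(
    alignments: dict[str, ProteinAlignment],
    variants: list[VariantRecord],
    min_flank_identity: int = MIN_FLANK_IDENTITY,
) -> pd.DataFrame:
    """Call CPDs for a variant table against per-gene alignments.

    Returns one row per variant with the call outcome, supporting species
    (semicolon-joined "species|identifier|flanks"), and alt prevalence.
    """
    columns = [
        "variant", "gene", "position", "ref_aa", "alt_aa", "label",
        "is_cpd", "n_supporting", "supporting_species", "alt_prevalence",
    ]
    rows = []
    for v in variants:
        if v.gene not in alignments:
            raise KeyError(f"no alignment provided for gene {v.gene}")
        aln = alignments[v.gene]
        call = call_cpd(aln, v, min_flank_identity=min_flank_identity)
        rows.append(
            {
                "variant": str(v),
                "gene": v.gene,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "label": v.label,
                "is_cpd": call is not None,
                "n_supporting": len(call.supporting_species) if call else 0,
                "supporting_species": ";".join(
                    f"{sp}|{ident}|{fl}"
                    for ident, sp, fl in (call.supporting_species if call else ())
                ),
                "alt_prevalence": cpd_prevalence(aln, v),
            }
        )
    return pd.DataFrame(rows, columns=columns)
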