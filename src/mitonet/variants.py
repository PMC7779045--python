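"""Exhaustive nonsynonymous single-nucleotide variant enumeration for mtDNA.

The 13 human mitochondrial protein-coding genes are translated with the
vertebrate mitochondrial code (NCBI translation table 2: TGA=Trp, ATA=Met,
AGA/AGG=stop).  For every codon position each of the three alternative
bases is tested; substitutions that change the encoded amino acid are
emitted.  By default substitutions whose reference or alternative codon is
a stop are excluded from the amino-acid-variation count (stop-gain and
stop-loss are truncation events, not residue changes); the policy is
configurable and recorded in run manifests because the printed total
depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

VERTEBRATE_MITO_TABLE = 2
NUCLEOTIDES = "ACGT"

#: stop-codon substitutions excluded from the nonsynonymous count
POLICY_EXCLUDE_STOPS = "exclude-stops"
#: stop-gain/stop-loss included, amino-acid symbol '*'
POLICY_INCLUDE_STOPS = "include-stops"

MT_GENES_13 = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


class GeneFormatError(ValueError):
    """Input lacks CDS features or a usable gene table."""


@dataclass(frozen=True)
class CodingGene:
    """One protein-coding gene on the mtDNA circle.

    ``cds_sequence`` is the coding strand 5'->3', padded with 'A' to a full
    terminal codon when the annotated feature ends mid-codon (the
    polyadenylation-completed stop), in which case ``incomplete_stop`` is
    True and ``pad_length`` gives the number of padded bases.
    """

    name: str
    cds_sequence: str
    genome_start: int  # 1-based inclusive
    genome_end: int  # 1-based inclusive
    strand: str = "+"
    translation_table: int = VERTEBRATE_MITO_TABLE
    incomplete_stop: bool = False
    pad_length: int = 0

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise GeneFormatError(
                f"{self.name}: CDS length {len(self.cds_sequence)} not a "
                "multiple of 3 after stop completion"
            )
        table = CodonTable.unambiguous_dna_by_id[self.translation_table]
        seq = self.cds_sequence
        for k in range(0, len(seq) - 3, 3):  # internal codons only
            if seq[k:k + 3] in table.stop_codons:
                raise GeneFormatError(
                    f"{self.name}: internal stop codon at codon {k // 3 + 1}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3


@dataclass(frozen=True)
class EnumeratedVariant:
    """A single-nucleotide substitution changing the encoded residue."""

    gene: str
    genome_position: int
    ref_nt: str
    alt_nt: str
    codon_index: int  # 0-based
    ref_aa: str
    alt_aa: str
    protein_position: int  # 1-based


def _complement(nt: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[nt]


def _pad_to_codon(seq: str) -> tuple[str, int]:
    pad = (3 - len(seq) % 3) % 3
    return seq + "A" * pad, pad


def load_genes(source) -> list[CodingGene]:
    """Load protein-coding genes from a GenBank flat file or a gene table.

    GenBank: CDS features are extracted (minus-strand features
    reverse-complemented); features ending mid-codon are padded with 'A' and
    flagged ``incomplete_stop``.  Gene table: TSV with columns name,
    genome_start, genome_end, strand, cds_sequence.
    """
    source = Path(source)
    head = source.read_text()[:5000]
    if head.startswith("LOCUS"):
        return _load_genbank(source)
    return _load_gene_table(source)


def _load_genbank(path) -> list[CodingGene]:
    record = SeqIO.read(str(path), "genbank")
    genes = []
    for feature in record.features:
        if feature.type != "CDS":
            continue
        quals = feature.qualifiers
        name = (quals.get("gene") or quals.get("product") or ["?"])[0]
        raw = str(feature.extract(record.seq)).upper()
        seq, pad = _pad_to_codon(raw)
        table = int((quals.get("transl_table") or [VERTEBRATE_MITO_TABLE])[0])
        genes.append(
            CodingGene(
                name=name,
                cds_sequence=seq,
                genome_start=int(feature.location.start) + 1,
                genome_end=int(feature.location.end),
                strand="+" if feature.location.strand != -1 else "-",
                translation_table=table,
                incomplete_stop=pad > 0,
                pad_length=pad,
            )
        )
    if not genes:
        raise GeneFormatError(f"no CDS features in {path}")
    return genes


def _load_gene_table(path) -> list[CodingGene]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "genome_start", "genome_end", "strand", "cds_sequence"}
    if not required.issubset(df.columns):
        raise GeneFormatError(
            f"gene table missing columns: {sorted(required - set(df.columns))}"
        )
    genes = []
    for row in df.itertuples():
        seq, pad = _pad_to_codon(str(row.cds_sequence).upper())
        genes.append(
            CodingGene(
                name=str(row.name),
                cds_sequence=seq,
                genome_start=int(row.genome_start),
                genome_end=int(row.genome_end),
                strand=str(row.strand),
                incomplete_stop=pad > 0,
                pad_length=pad,
            )
        )
    return genes


def enumerate_nonsyn(
    gene: CodingGene, stop_policy: str = POLICY_EXCLUDE_STOPS
) -> list[EnumeratedVariant]:
    """All single-nucleotide substitutions changing the encoded residue.

    Padded stop-completion bases are never enumerated.  Under the default
    policy any substitution whose reference or alternative codon is a stop
    is excluded; under ``include-stops`` such events are emitted with '*'.
    """
    if stop_policy not in (POLICY_EXCLUDE_STOPS, POLICY_INCLUDE_STOPS):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    table = CodonTable.unambiguous_dna_by_id[gene.translation_table]
    stops = set(table.stop_codons)
    seq = gene.cds_sequence
    real_length = len(seq) - gene.pad_length
    out = []
    for ci in range(gene.n_codons):
        codon = seq[3 * ci:3 * ci + 3]
        ref_is_stop = codon in stops
        for offset in range(3):
            cds_pos = 3 * ci + offset  # 0-based on the coding strand
            if cds_pos >= real_length:
                continue  # padded base, not a genomic position of this CDS
            ref_nt = codon[offset]
            for alt_nt in NUCLEOTIDES:
                if alt_nt == ref_nt:
                    continue
                alt_codon = codon[:offset] + alt_nt + codon[offset + 1:]
                alt_is_stop = alt_codon in stops
                if stop_policy == POLICY_EXCLUDE_STOPS and (
                    ref_is_stop or alt_is_stop
                ):
                    continue
                ref_aa = "*" if ref_is_stop else table.forward_table[codon]
                alt_aa = "*" if alt_is_stop else table.forward_table[alt_codon]
                if ref_aa == alt_aa:
                    continue
                if gene.strand == "+":
                    genome_position = gene.genome_start + cds_pos
                    g_ref, g_alt = ref_nt, alt_nt
                else:
                    genome_position = gene.genome_end - cds_pos
                    g_ref, g_alt = _complement(ref_nt), _complement(alt_nt)
                out.append(
                    EnumeratedVariant(
                        gene=gene.name,
                        genome_position=genome_position,
                        ref_nt=g_ref,
                        alt_nt=g_alt,
                        codon_index=ci,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        protein_position=ci + 1,
                    )
                )
    return out


def total_count(
    genes: list[CodingGene], stop_policy: str = POLICY_EXCLUDE_STOPS
) -> int:
    """Sum of per-gene nonsynonymous counts (overlapping genes independent)."""
    return sum(len(enumerate_nonsyn(g, stop_policy)) for g in genes)


def variants_to_frame(variants: list[EnumeratedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": v.gene,
                "genome_position": v.genome_position,
                "ref_nt": v.ref_nt,
                "alt_nt": v.alt_nt,
                "codon_index": v.codon_index,
                "protein_position": v.protein_position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
            }
            for v in variants
        ]
    )


def translate_cds(seq: str, table: int = VERTEBRATE_MITO_TABLE) -> str:
    """Translate a complete CDS (helper for oracle-style checks)."""
    return str(Seq(seq).translate(table=table))
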