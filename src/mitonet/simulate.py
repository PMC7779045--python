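"""Synthetic fixtures with known ground truth for every analysis module.

Generators produce: star-phylogeny ortholog alignments with planted fixed
"pathogenic" residues (CPDs) and planted co-varying column pairs; ΔΔG tables
with planted disruptive-single / compensated-pair structure; toy
protein-coding genes; and noisy rigid-body trajectories with harmonic
collective modes.  Every generator is deterministic for a fixed seed and
emits the same file formats the analysis readers consume, so pipelines can
be exercised end-to-end through files.

The star phylogeny draws every non-human row independently from the human
(ancestral) row: each column substitutes with probability 1 - exp(-d) for
divergence d (expected substitutions per site), uniformly over the 19 other
residues.  Coupled column pairs co-substitute through a fixed residue
bijection with the given strength.  No indels are simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .compensation import DdgRecord, Mutation
from .cpd import VariantRecord
from .dynamics import Trajectory
from .msa import AA20, ProteinAlignment
from .variants import VERTEBRATE_MITO_TABLE, CodingGene

HUMAN_SPECIES = "Homo sapiens"


@dataclass(frozen=True)
class PlantedCPD:
    variant: VariantRecord
    carrier_ids: tuple[str, ...]
    flank_conservation: float

    @property
    def is_decoy(self) -> bool:
        """Carriers with scrambled flanks below the 7/10 threshold."""
        return self.flank_conservation < 0.7


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth planted by a generator, reproducible from (params, seed)."""

    seed: int
    planted_cpds: tuple[PlantedCPD, ...] = ()
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    planted_compensations: tuple[str, ...] = ()
    mode_variances: tuple[float, ...] = ()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def simulate_alignment(
    n_species: int,
    length: int,
    divergence: float,
    coupled_pairs=(),
    cpd_spec=None,
    seed: int = 0,
    name: str = "SIM1",
) -> tuple[ProteinAlignment, SimulationTruth]:
    """Star-sampled ortholog alignment with planted co-variation and CPDs.

    ``coupled_pairs`` is a list of (column_i, column_j, strength) with
    0-based distinct columns and strength in [0, 1]; ``cpd_spec`` is one
    (position, ref_aa, alt_aa, n_carriers, flank_conservation) tuple or a
    list of them (1-based position).  At a planted CPD column only the
    designated carriers ever hold the alternative residue, so planted truth
    is unambiguous.  Row 0 is the human/ancestral sequence.
    """
    rng = np.random.default_rng(seed)
    if n_species < 2:
        raise ValueError("need at least two species")
    aa = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")
    ancestral = rng.integers(0, 20, size=length)

    pair_maps = []
    for i, j, strength in coupled_pairs:
        if not (0 <= i < length and 0 <= j < length and i != j):
            raise ValueError(f"invalid coupled pair ({i}, {j})")
        if not 0.0 <= strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        partner = rng.permutation(20)
        ancestral[j] = partner[ancestral[i]]
        pair_maps.append((i, j, strength, partner))

    cpd_specs = []
    if cpd_spec is not None:
        specs = cpd_spec if isinstance(cpd_spec, list) else [cpd_spec]
        for position, ref_aa, alt_aa, n_carriers, flank_conservation in specs:
            if not 1 <= position <= length:
                raise ValueError(f"CPD position {position} outside protein")
            if n_carriers >= n_species:
                raise ValueError("n_carriers must be below n_species")
            ancestral[position - 1] = AA20.index(ref_aa)
            cpd_specs.append(
                (position, ref_aa, alt_aa, n_carriers, flank_conservation)
            )

    n_tips = n_species - 1
    p_sub = 1.0 - np.exp(-divergence)
    rows = np.tile(ancestral, (n_tips, 1))
    substitute = rng.random((n_tips, length)) < p_sub
    # uniform exchange over the 19 non-ancestral residues
    shifts = rng.integers(1, 20, size=(n_tips, length))
    rows = np.where(substitute, (rows + shifts) % 20, rows)

    for i, j, strength, partner in pair_maps:
        follow = rng.random(n_tips) < strength
        rows[follow, j] = partner[rows[follow, i]]

    truth_cpds = []
    tip_ids = [f"orth{i + 1:04d}" for i in range(n_tips)]
    for position, ref_aa, alt_aa, n_carriers, flank_conservation in cpd_specs:
        col = position - 1
        alt_idx = AA20.index(alt_aa)
        carriers = rng.choice(n_tips, size=n_carriers, replace=False)
        is_carrier = np.zeros(n_tips, dtype=bool)
        is_carrier[carriers] = True
        # non-carriers never hold the alternative residue at a planted column
        clash = (~is_carrier) & (rows[:, col] == alt_idx)
        rows[clash, col] = ancestral[col]
        rows[carriers, col] = alt_idx
        flank_cols = [
            p - 1
            for p in range(position - 5, position + 6)
            if p != position and 1 <= p <= length
        ]
        for tip in carriers:
            for fc in flank_cols:
                if rng.random() < flank_conservation:
                    rows[tip, fc] = ancestral[fc]
                else:
                    rows[tip, fc] = (
                        ancestral[fc] + rng.integers(1, 20)
                    ) % 20
        truth_cpds.append(
            PlantedCPD(
                variant=VariantRecord(
                    gene=name,
                    position=position,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    label="planted",
                ),
                carrier_ids=tuple(tip_ids[c] for c in sorted(carriers)),
                flank_conservation=flank_conservation,
            )
        )

    sequences = ["".join(aa[ancestral])]
    sequences += ["".join(aa[row]) for row in rows]
    species = [HUMAN_SPECIES] + [
        f"Simulatus sp{i + 1:04d}" for i in range(n_tips)
    ]
    aln = ProteinAlignment(
        identifiers=tuple(["human"] + tip_ids),
        species=tuple(species),
        sequences=tuple(sequences),
        reference_index=0,
        name=name,
    )
    truth = SimulationTruth(
        seed=seed,
        planted_cpds=tuple(truth_cpds),
        planted_pairs=tuple((i, j, s) for i, j, s, _ in pair_maps),
    )
    return aln, truth


def simulate_ddg_table(
    n_pairs: int,
    fraction_compensated: float,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_replicas: int = 10,
) -> tuple[list[DdgRecord], list[DdgRecord], SimulationTruth]:
    """ΔΔG tables with an exact planted number of compensation events.

    Compensated pairs get one clearly disruptive single (|ΔΔG| >= 0.91
    kcal/mol) and a pair ΔΔG within ±0.05; the rest either have two
    tolerated singles or a clearly non-compensatory pair ΔΔG.  Replica noise
    must be small against those 0.05/0.3 kcal/mol margins so every
    classification is unambiguous.
    """
    if not 0.0 <= fraction_compensated <= 1.0:
        raise ValueError("fraction_compensated must be in [0, 1]")
    if noise_sd > 0.012:
        raise ValueError(
            "noise_sd too large for the planted classification margins"
        )
    rng = np.random.default_rng(seed)
    n_comp = int(round(n_pairs * fraction_compensated))
    singles: list[DdgRecord] = []
    doubles: list[DdgRecord] = []
    planted = []

    def draw(target: float) -> tuple[float, tuple[float, ...]]:
        replicas = target + rng.normal(0.0, noise_sd, size=n_replicas)
        return tuple(float(r) for r in replicas)

    for k in range(n_pairs):
        a = Mutation("SIMP1", k + 1, "A", "V")
        b = Mutation("SIMP2", k + 1, "L", "F")
        compensated = k < n_comp
        sign = rng.choice([-1.0, 1.0])
        if compensated:
            t_a = sign * (0.91 + rng.uniform(0.0, 0.5))
            t_b = rng.uniform(-0.3, 0.3)
            t_pair = rng.uniform(-0.04, 0.04)
        elif rng.random() < 0.5:
            # no destabilization to compensate
            t_a = rng.uniform(-0.3, 0.3)
            t_b = rng.uniform(-0.3, 0.3)
            t_pair = rng.uniform(-0.04, 0.04)
        else:
            # disruptive single, clearly non-compensatory pair
            t_a = sign * (0.91 + rng.uniform(0.0, 0.5))
            t_b = rng.uniform(-0.3, 0.3)
            t_pair = sign * (0.4 + rng.uniform(0.0, 1.0))
        singles.append(DdgRecord.from_replicas(a, draw(t_a)))
        singles.append(DdgRecord.from_replicas(b, draw(t_b)))
        doubles.append(DdgRecord.from_replicas((a, b), draw(t_pair)))
        if compensated:
            planted.append(f"{a}+{b}")
    truth = SimulationTruth(seed=seed, planted_compensations=tuple(planted))
    return singles, doubles, truth


def simulate_trajectory(
    n_frames: int,
    n_atoms: int,
    mode_amplitudes=(),
    noise_sd: float = 0.0,
    rigid_drift: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, SimulationTruth]:
    """Harmonic motion along orthonormal collective modes, plus noise.

    Mode k oscillates with amplitude a_k (Å) at k+1 cycles over the
    trajectory, giving a positional variance of a_k^2 along its mode vector
    (recorded in the truth).  With ``rigid_drift`` every frame is composed
    with a random rotation and translation, which the analysis
    superposition must remove.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    n3 = 3 * n_atoms
    base = rng.normal(0.0, 5.0, size=(n_atoms, 3))
    k = len(mode_amplitudes)
    if k > 0:
        raw = rng.normal(size=(n3, k))
        # internal modes only: remove overlap with rigid translations and
        # infinitesimal rotations so superposition does not eat amplitude
        rigid = np.zeros((n3, 6))
        centered = base - base.mean(axis=0)
        for axis in range(3):
            t = np.zeros((n_atoms, 3))
            t[:, axis] = 1.0
            rigid[:, axis] = t.ravel()
            e = np.zeros(3)
            e[axis] = 1.0
            rigid[:, 3 + axis] = np.cross(e, centered).ravel()
        rigid, _ = np.linalg.qr(rigid)
        raw -= rigid @ (rigid.T @ raw)
        modes, _ = np.linalg.qr(raw)
    coords = np.tile(base, (n_frames, 1, 1))
    t = np.arange(n_frames)
    for m, amplitude in enumerate(mode_amplitudes):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal = (
            amplitude
            * np.sqrt(2.0)
            * np.sin(2.0 * np.pi * (m + 1) * t / n_frames + phase)
        )
        coords += signal[:, None, None] * modes[:, m].reshape(1, n_atoms, 3)
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    if rigid_drift:
        from scipy.spatial.transform import Rotation

        for f in range(n_frames):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0.0, 3.0, size=3)
            coords[f] = coords[f] @ rot.T + shift
    truth = SimulationTruth(
        seed=seed,
        mode_variances=tuple(float(a) ** 2 for a in mode_amplitudes),
    )
    return Trajectory(coordinates=coords), truth


def simulate_gene(
    n_codons: int, seed: int = 0, name: str = "SIMG1", genome_start: int = 101
) -> CodingGene:
    """A random protein-coding toy gene valid under the mitochondrial code."""
    from Bio.Data import CodonTable

    rng = np.random.default_rng(seed)
    table = CodonTable.unambiguous_dna_by_id[VERTEBRATE_MITO_TABLE]
    stops = set(table.stop_codons)
    nts = "ACGT"
    codons = []
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(nts), size=3))
        if codon not in stops:
            codons.append(codon)
    codons.append("TAA")
    seq = "".join(codons)
    return CodingGene(
        name=name,
        cds_sequence=seq,
        genome_start=genome_start,
        genome_end=genome_start + len(seq) - 1,
        strand="+",
    )


# ---------------------------------------------------------------------------
# file emission (the analysis readers' formats)


def write_variant_table(variants: list[VariantRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene": v.gene,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "label": v.label,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def write_ddg_tables(
    singles: list[DdgRecord], doubles: list[DdgRecord], singles_path, doubles_path
) -> None:
    import pandas as pd

    def single_row(m: Mutation) -> dict:
        return {
            "protein": m.protein,
            "position": m.position,
            "ref_aa": m.ref_aa,
            "alt_aa": m.alt_aa,
        }

    rows = []
    for rec in singles:
        row = single_row(rec.subject)
        row.update(
            {f"replica{i + 1}": v for i, v in enumerate(rec.replicas)}
            or {"ddg": rec.ddg}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(singles_path, sep="\t", index=False)

    rows = []
    for rec in doubles:
        a, b = rec.subject
        row = single_row(a)
        row.update({f"partner_{k}": v for k, v in single_row(b).items()})
        row.update(
            {f"replica{i + 1}": v for i, v in enumerate(rec.replicas)}
            or {"ddg": rec.ddg}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(doubles_path, sep="\t", index=False)


def write_gene_table(genes: list[CodingGene], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "name": g.name,
                "genome_start": g.genome_start,
                "genome_end": g.genome_end,
                "strand": g.strand,
                "cds_sequence": g.cds_sequence[: len(g.cds_sequence) - g.pad_length],
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)
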