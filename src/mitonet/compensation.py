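"""Energetic classification of variants and variant pairs from ΔΔG tables.

Single mutants whose |ΔΔG| exceeds 0.61 kcal/mol are tagged disruptive;
double mutants with |ΔΔG| below 0.1 kcal/mol are tagged compensatory.  A
compensation event is a pair with at least one disruptive constituent whose
joint ΔΔG is nevertheless compensatory.  Pairs are partitioned into
inter-protein, intra-protein and interface classes (interface = both
positions in a supplied interface-residue set).  ΔΔG values are inputs
(e.g. FoldX output averaged over replicas); this module performs no
free-energy calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

DISRUPTIVE_CUTOFF = 0.61  # kcal/mol, strict: |ddg| > cutoff
COMPENSATORY_CUTOFF = 0.1  # kcal/mol, strict: |ddg| < cutoff


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution located on a protein."""

    protein: str
    position: int
    ref_aa: str
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.protein}:{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class DdgRecord:
    """A free-energy change for a single mutation or a mutation pair.

    ``ddg`` is the mean over replicas when replicas are given.
    """

    subject: Mutation | tuple[Mutation, Mutation]
    ddg: float
    replicas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.replicas:
            mean = sum(self.replicas) / len(self.replicas)
            if not math.isclose(mean, self.ddg, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"ddg {self.ddg} is not the mean of replicas ({mean})"
                )

    @classmethod
    def from_replicas(cls, subject, replicas) -> "DdgRecord":
        return cls(
            subject=subject,
            ddg=mean_replicas(replicas),
            replicas=tuple(replicas),
        )


@dataclass(frozen=True)
class PairClassification:
    """Joint classification of a double mutant and its two singles."""

    pair: tuple[Mutation, Mutation]
    single_calls: tuple[str, str]  # disruptive | tolerated
    pair_call: str  # compensatory | non-compensatory
    klass: str  # inter | intra | interface
    ddg_a: float
    ddg_b: float
    ddg_pair: float

    @property
    def is_compensation_event(self) -> bool:
        return "disruptive" in self.single_calls and (
            self.pair_call == "compensatory"
        )

    @property
    def epistasis(self) -> float:
        """Deviation of the pair ΔΔG from additivity of the singles."""
        return self.ddg_pair - (self.ddg_a + self.ddg_b)


def mean_replicas(replicas) -> float:
    """Arithmetic mean of replica ΔΔG values (kcal/mol)."""
    replicas = list(replicas)
    if not replicas:
        raise ValueError("replica list is empty")
    return float(sum(replicas) / len(replicas))


def classify_single(ddg: float, cutoff: float = DISRUPTIVE_CUTOFF) -> str:
    """'disruptive' iff |ddg| strictly exceeds the cutoff, else 'tolerated'."""
    if not math.isfinite(ddg):
        raise ValueError(f"non-finite ddg: {ddg}")
    return "disruptive" if abs(ddg) > cutoff else "tolerated"


def classify_pair(ddg_pair: float, cutoff: float = COMPENSATORY_CUTOFF) -> str:
    """'compensatory' iff |ddg_pair| is strictly below the cutoff."""
    if not math.isfinite(ddg_pair):
        raise ValueError(f"non-finite ddg: {ddg_pair}")
    return "compensatory" if abs(ddg_pair) < cutoff else "non-compensatory"


class MissingSingleError(KeyError):
    """A double mutant has no matching single-mutant ΔΔG entries."""


def compensation_screen(
    singles: list[DdgRecord],
    doubles: list[DdgRecord],
    interface_residues: set[tuple[str, int]] | None = None,
    disruptive_cutoff: float = DISRUPTIVE_CUTOFF,
    compensatory_cutoff: float = COMPENSATORY_CUTOFF,
) -> list[PairClassification]:
    """Classify every double mutant against its constituent singles.

    A pair is an actionable compensation event when at least one single is
    disruptive and the pair ΔΔG is compensatory; the classification is
    emitted for every pair regardless, so downstream filters can apply
    stricter conventions.
    """
    interface_residues = interface_residues or set()
    by_mut = {r.subject: r for r in singles if isinstance(r.subject, Mutation)}
    out = []
    for rec in doubles:
        if not isinstance(rec.subject, tuple):
            raise ValueError(f"not a pair record: {rec.subject}")
        a, b = rec.subject
        missing = [str(m) for m in (a, b) if m not in by_mut]
        if missing:
            raise MissingSingleError(
                f"pair {a}+{b}: no single-mutant record for "
                + ", ".join(missing)
            )
        ddg_a, ddg_b = by_mut[a].ddg, by_mut[b].ddg
        both_at_interface = (
            (a.protein, a.position) in interface_residues
            and (b.protein, b.position) in interface_residues
        )
        if both_at_interface:
            klass = "interface"
        elif a.protein != b.protein:
            klass = "inter"
        else:
            klass = "intra"
        out.append(
            PairClassification(
                pair=(a, b),
                single_calls=(
                    classify_single(ddg_a, disruptive_cutoff),
                    classify_single(ddg_b, disruptive_cutoff),
                ),
                pair_call=classify_pair(rec.ddg, compensatory_cutoff),
                klass=klass,
                ddg_a=ddg_a,
                ddg_b=ddg_b,
                ddg_pair=rec.ddg,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular interfaces

SINGLE_COLUMNS = ["protein", "position", "ref_aa", "alt_aa"]
PAIR_COLUMNS = SINGLE_COLUMNS + [
    "partner_protein", "partner_position", "partner_ref_aa", "partner_alt_aa",
]


def _record_from_row(row, cols, prefix="") -> Mutation:
    return Mutation(
        protein=str(row[prefix + "protein"]),
        position=int(row[prefix + "position"]),
        ref_aa=str(row[prefix + "ref_aa"]),
        alt_aa=str(row[prefix + "alt_aa"]),
    )


def _ddg_from_row(row, subject) -> DdgRecord:
    replica_cols = [c for c in row.index if c.startswith("replica")]
    if replica_cols:
        return DdgRecord.from_replicas(
            subject, [float(row[c]) for c in replica_cols]
        )
    return DdgRecord(subject=subject, ddg=float(row["ddg"]))


def read_ddg_tables(singles_path, doubles_path):
    """Read single- and double-mutant ΔΔG TSVs.

    Both accept either a ``ddg`` column or ``replica1..replicaN`` columns
    (then ddg = their mean).  Doubles carry ``partner_*`` columns for the
    second mutation.
    """
    singles_df = pd.read_csv(singles_path, sep="\t")
    doubles_df = pd.read_csv(doubles_path, sep="\t")
    singles = [
        _ddg_from_row(row, _record_from_row(row, SINGLE_COLUMNS))
        for _, row in singles_df.iterrows()
    ]
    doubles = [
        _ddg_from_row(
            row,
            (
                _record_from_row(row, SINGLE_COLUMNS),
                _record_from_row(row, PAIR_COLUMNS, prefix="partner_"),
            ),
        )
        for _, row in doubles_df.iterrows()
    ]
    return singles, doubles


def read_interface_set(path) -> set[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r["protein"]), int(r["position"])) for _, r in df.iterrows()
    }


def screen_to_frame(results: list[PairClassification]) -> pd.DataFrame:
    rows = []
    for r in results:
        a, b = r.pair
        rows.append(
            {
                "mutation_a": str(a),
                "mutation_b": str(b),
                "ddg_a": r.ddg_a,
                "ddg_b": r.ddg_b,
                "ddg_pair": r.ddg_pair,
                "call_a": r.single_calls[0],
                "call_b": r.single_calls[1],
                "pair_call": r.pair_call,
                "klass": r.klass,
                "compensation_event": r.is_compensation_event,
                "epistasis": r.epistasis,
            }
        )
    return pd.DataFrame(rows)
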