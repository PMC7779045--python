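"""Residue co-variation scoring across ortholog alignments.

Two independent pairwise scorers are provided:

* ``mi_apc`` — mutual information between columns over the 21-symbol
  alphabet (20 residues + gap), computed from redundancy-weighted
  frequencies with a pseudocount, followed by the average-product
  correction (APC) that subtracts the entropic/phylogenetic background
  expected from the row and column means.

* ``mfdca`` — mean-field direct coupling analysis.  A global pairwise
  (Potts) model is fit by inverting the connected-correlation matrix of
  the alignment; each column pair is then scored by direct information
  (DI), the mutual information of the two-site model restricted to the
  direct coupling, which strips transitive correlations that inflate
  local scores.

Pipelines concatenate one protein (MT-ND1 by default) to a partner
protein, score the concatenated alignment, keep the TOP-N pairs per
method, and split them into inter-protein pairs (residues in different
proteins) and intra-protein pairs (both residues in the partner, neither
in the concatenated protein).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

import numpy as np

from .msa import AA20, GAP, ProteinAlignment, dissimilarity

ALPHABET = AA20 + GAP  # index 20 = gap / unknown
Q = len(ALPHABET)  # 21
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

TOP_N_DEFAULT = 500
DEFAULT_CONCAT_PROTEIN = "MT-ND1"


class EmptyIntersectionError(ValueError):
    """No species is shared by all alignments being concatenated."""


class SingularCorrelationError(np.linalg.LinAlgError):
    """Correlation matrix not invertible; raise the pseudocount weight."""


@dataclass(frozen=True)
class Segment:
    """Half-open column span [start, end) occupied by one protein."""

    protein: str
    start: int
    end: int


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Per-species concatenation of several protein alignments."""

    alignment: ProteinAlignment
    segments: tuple[Segment, ...]

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric per-column-pair co-variation scores for one method.

    ``columns`` maps each alignment column to its (protein, 1-based human
    position); the position is None for columns gapped in the human
    reference, which are excluded from ranking.
    """

    method: str
    scores: np.ndarray
    columns: tuple[tuple[str, int | None], ...]
    params: dict | None = None

    def __post_init__(self) -> None:
        s = self.scores
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("score matrix must be square")
        if s.shape[0] != len(self.columns):
            raise ValueError("column labels do not match matrix size")

    @property
    def segments(self) -> tuple[Segment, ...]:
        segs = []
        for i, (protein, _) in enumerate(self.columns):
            if not segs or segs[-1][0] != protein:
                segs.append([protein, i, i + 1])
            else:
                segs[-1][2] = i + 1
        return tuple(Segment(*s) for s in segs)


@dataclass(frozen=True)
class CovaryingPair:
    """A scored residue pair in human protein coordinates (1-based)."""

    protein_a: str
    position_a: int
    protein_b: str
    position_b: int
    method: str
    score: float
    klass: str | None = None

    @property
    def key(self) -> tuple:
        """Unordered identity of the pair, independent of method/score."""
        a = (self.protein_a, self.position_a)
        b = (self.protein_b, self.position_b)
        return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# encoding and weighting


def encode(aln) -> np.ndarray:
    """Integer-encode sequences: 0..19 residues, 20 gap or unknown symbol."""
    base = aln.alignment if isinstance(aln, ConcatenatedAlignment) else aln
    n, length = base.n_records, base.n_columns
    out = np.full((n, length), Q - 1, dtype=np.int8)
    for i, seq in enumerate(base.sequences):
        out[i] = [_AA_INDEX.get(c, Q - 1) for c in seq]
    return out


def sequence_weights(aln, identity_threshold: float = 0.8) -> np.ndarray:
    """Redundancy-correcting sequence weights.

    Each record's weight is 1 / (number of records, itself included, with
    fractional identity >= the threshold).  The sum of weights is the
    effective sequence number M_eff.
    """
    x = encode(aln)
    n = x.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    # chunked pairwise identity; gap treated as an ordinary 21st symbol
    chunk = max(1, int(2e7 // max(1, n * x.shape[1])))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        ident = (x[lo:hi, None, :] == x[None, :, :]).mean(axis=2)
        counts[lo:hi] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def effective_sequences(weights: np.ndarray) -> float:
    return float(np.sum(weights))


# ---------------------------------------------------------------------------
# concatenation


def concatenate(alns: list[ProteinAlignment]) -> ConcatenatedAlignment:
    """Join alignments species-wise, keeping species present in all inputs.

    When a species has several rows in one input (paralogs/duplicates), the
    row closest to that alignment's human sequence is used.  Record order
    follows species order of the first alignment.
    """
    if len(alns) < 2:
        raise ValueError("concatenation requires at least two alignments")
    per_aln_rows: list[dict[str, int]] = []
    for aln in alns:
        best: dict[str, int] = {}
        ref = aln.reference_sequence
        for i, sp in enumerate(aln.species):
            if sp not in best:
                best[sp] = i
            else:
                d_new = dissimilarity(aln.sequences[i], ref)
                d_old = dissimilarity(aln.sequences[best[sp]], ref)
                if d_new < d_old:
                    best[sp] = i
        # the designated reference row always wins for its species
        best[aln.reference_species] = aln.reference_index
        per_aln_rows.append(best)
    shared = [
        sp for sp in per_aln_rows[0] if all(sp in rows for rows in per_aln_rows)
    ]
    if not shared:
        raise EmptyIntersectionError("no species shared by all alignments")
    ref_species = alns[0].reference_species
    if ref_species not in shared:
        raise EmptyIntersectionError(
            f"reference species {ref_species!r} not shared by all alignments"
        )
    seqs = []
    for sp in shared:
        seqs.append(
            "".join(
                aln.sequences[rows[sp]]
                for aln, rows in zip(alns, per_aln_rows)
            )
        )
    segments = []
    offset = 0
    for aln in alns:
        name = aln.name or f"protein{len(segments) + 1}"
        segments.append(Segment(name, offset, offset + aln.n_columns))
        offset += aln.n_columns
    base = ProteinAlignment(
        identifiers=tuple(shared),
        species=tuple(shared),
        sequences=tuple(seqs),
        reference_index=shared.index(ref_species),
        name="+".join(s.protein for s in segments),
    )
    return ConcatenatedAlignment(alignment=base, segments=tuple(segments))


def _column_labels(aln) -> tuple[tuple[str, int | None], ...]:
    """(protein, 1-based human position | None) for every alignment column."""
    if isinstance(aln, ConcatenatedAlignment):
        base, segments = aln.alignment, aln.segments
    else:
        base = aln
        segments = (Segment(aln.name or "protein1", 0, aln.n_columns),)
    ref = base.reference_sequence
    labels: list[tuple[str, int | None]] = []
    for seg in segments:
        pos = 0
        for col in range(seg.start, seg.end):
            if ref[col] == GAP:
                labels.append((seg.protein, None))
            else:
                pos += 1
                labels.append((seg.protein, pos))
    return tuple(labels)


# ---------------------------------------------------------------------------
# mutual information with average-product correction


def _pair_counts(xi, xj, weights) -> np.ndarray:
    """Weighted 21x21 joint count table for two encoded columns."""
    idx = xi.astype(np.int64) * Q + xj
    return np.bincount(idx, weights=weights, minlength=Q * Q).reshape(Q, Q)


def mutual_information(
    aln, pseudocount: float = 0.0, weights: np.ndarray | None = None
) -> np.ndarray:
    """Raw pairwise MI matrix in bits (no background correction)."""
    x = encode(aln)
    if x.shape[1] < 2:
        raise ValueError("MI requires at least two columns")
    if weights is None:
        weights = sequence_weights(aln)
    total = weights.sum()
    length = x.shape[1]
    mi = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 1, length):
            counts = _pair_counts(x[:, i], x[:, j], weights)
            pij = (counts + pseudocount / (Q * Q)) / (total + pseudocount)
            pi = pij.sum(axis=1)
            pj = pij.sum(axis=0)
            mask = pij > 0
            outer = np.outer(pi, pj)
            mi[i, j] = mi[j, i] = float(
                np.sum(pij[mask] * np.log2(pij[mask] / outer[mask]))
            )
    return mi


def apc(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: MIp(i,j) = MI(i,j) - MI(i,.)MI(.,j)/MI(..)."""
    length = mi.shape[0]
    if length < 2:
        return mi.copy()
    off = mi.copy()
    np.fill_diagonal(off, 0.0)
    row_mean = off.sum(axis=1) / (length - 1)
    grand = off.sum() / (length * (length - 1))
    corrected = mi - (
        np.outer(row_mean, row_mean) / grand if grand != 0 else 0.0
    )
    np.fill_diagonal(corrected, 0.0)
    return corrected


def mi_apc(
    aln, pseudocount: float = 0.5, weights: np.ndarray | None = None
) -> ScoreMatrix:
    """Average-product-corrected mutual information score matrix."""
    mi = mutual_information(aln, pseudocount=pseudocount, weights=weights)
    return ScoreMatrix(
        method="MI_APC",
        scores=apc(mi),
        columns=_column_labels(aln),
        params={"pseudocount": pseudocount},
    )


# ---------------------------------------------------------------------------
# mean-field direct coupling analysis


def mfdca(
    aln,
    pseudocount_weight: float = 0.5,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ScoreMatrix:
    """Mean-field DCA scored by direct information.

    Weighted single/pair frequencies are regularized with pseudocount weight
    ``lambda``: f = lambda/q + (1-lambda) f_emp (q = 21 with the gap as an
    ordinary state).  The connected-correlation matrix C over the reduced
    alphabet (gap state removed as reference) is inverted to give couplings
    e = -C^-1; each pair is scored by the direct information of the two-site
    model with fields matched to the single-site marginals.
    """
    x = encode(aln)
    n, length = x.shape
    if length < 2:
        raise ValueError("mfDCA requires at least two columns")
    if weights is None:
        weights = sequence_weights(aln)
    total = weights.sum()
    if total <= 1:
        raise ValueError("effective sequence number must exceed 1")
    lam = pseudocount_weight

    # single-site frequencies (L, q)
    fi = np.zeros((length, Q))
    for i in range(length):
        fi[i] = np.bincount(x[:, i], weights=weights, minlength=Q) / total
    fi = lam / Q + (1 - lam) * fi

    qr = Q - 1  # reduced alphabet: gap state dropped as reference
    corr = np.empty((length * qr, length * qr))
    for i in range(length):
        for j in range(i, length):
            if i == j:
                fij = np.diag(lam / Q + (1 - lam) * np.bincount(
                    x[:, i], weights=weights, minlength=Q) / total)
            else:
                emp = _pair_counts(x[:, i], x[:, j], weights) / total
                fij = lam / (Q * Q) + (1 - lam) * emp
            block = fij[:qr, :qr] - np.outer(fi[i, :qr], fi[j, :qr])
            corr[i * qr:(i + 1) * qr, j * qr:(j + 1) * qr] = block
            if i != j:
                corr[j * qr:(j + 1) * qr, i * qr:(i + 1) * qr] = block.T
    try:
        couplings = -np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError(
            "connected-correlation matrix is singular; raise "
            "pseudocount_weight or provide a deeper alignment"
        ) from exc

    di = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 1, length):
            eij = np.zeros((Q, Q))
            eij[:qr, :qr] = couplings[
                i * qr:(i + 1) * qr, j * qr:(j + 1) * qr
            ]
            di[i, j] = di[j, i] = _direct_information(
                eij, fi[i], fi[j], max_iter=max_iter, tol=tol
            )
    return ScoreMatrix(
        method="mfDCA",
        scores=di,
        columns=_column_labels(aln),
        params={"pseudocount_weight": pseudocount_weight},
    )


def _direct_information(eij, fi, fj, max_iter=500, tol=1e-4) -> float:
    """DI of the two-site model exp(e_ij + h_i + h_j) matching marginals."""
    w = np.exp(eij)
    mu1 = np.full(Q, 1.0 / Q)
    mu2 = np.full(Q, 1.0 / Q)
    for _ in range(max_iter):
        s1 = w @ mu2
        s2 = mu1 @ w
        new1 = fi / s1
        new1 /= new1.sum()
        new2 = fj / s2
        new2 /= new2.sum()
        delta = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
        mu1, mu2 = new1, new2
        if delta < tol:
            break
    pdir = w * np.outer(mu1, mu2)
    pdir /= pdir.sum()
    fifj = np.outer(fi, fj)
    tiny = 1e-100
    return float(np.sum(pdir * np.log((pdir + tiny) / (fifj + tiny))))


# ---------------------------------------------------------------------------
# ranking and filtering


def top_pairs(m: ScoreMatrix, n: int = TOP_N_DEFAULT) -> list[CovaryingPair]:
    """The n highest-scoring distinct column pairs in human coordinates.

    Columns gapped in the human reference are excluded.  Ties are broken by
    (protein_a, position_a, position_b) in segment order; within a pair the
    lower (segment, position) side is reported first.  Returns all pairs when
    fewer than n exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seg_order: dict[str, int] = {}
    for protein, _ in m.columns:
        seg_order.setdefault(protein, len(seg_order))
    valid = [k for k, (_, pos) in enumerate(m.columns) if pos is not None]
    entries = []
    for ai in range(len(valid)):
        for bi in range(ai + 1, len(valid)):
            i, j = valid[ai], valid[bi]
            a = (seg_order[m.columns[i][0]], m.columns[i][1], i)
            b = (seg_order[m.columns[j][0]], m.columns[j][1], j)
            if b < a:
                a, b = b, a
            entries.append((-m.scores[i, j], a[0], a[1], b[0], b[1], a[2], b[2]))
    entries.sort()
    out = []
    for neg, sa, pa, sb, pb, _, _ in entries[:n]:
        proteins = list(seg_order)
        out.append(
            CovaryingPair(
                protein_a=proteins[sa],
                position_a=pa,
                protein_b=proteins[sb],
                position_b=pb,
                method=m.method,
                score=-neg,
            )
        )
    return out


def filter_inter(pairs: list[CovaryingPair]) -> list[CovaryingPair]:
    """Keep pairs whose residues lie in different proteins (klass 'inter')."""
    return [
        replace(p, klass="inter") for p in pairs if p.protein_a != p.protein_b
    ]


def filter_intra(
    pairs: list[CovaryingPair],
    concat_protein: str = DEFAULT_CONCAT_PROTEIN,
) -> list[CovaryingPair]:
    """Keep same-protein pairs with neither residue in the concatenated protein."""
    return [
        replace(p, klass="intra")
        for p in pairs
        if p.protein_a == p.protein_b and p.protein_a != concat_protein
    ]


def combine_methods(
    a: list[CovaryingPair], b: list[CovaryingPair]
) -> tuple[list[CovaryingPair], list[CovaryingPair]]:
    """Union of two methods' pair lists, plus the pairs common to both.

    The union keeps every entry from both lists (a shared pair appears once
    per method, so |union| = |a| + |b|); ``common`` holds one entry per pair
    whose residue coordinates occur in both lists, irrespective of order.
    """
    keys_b = {p.key for p in b}
    common = [p for p in a if p.key in keys_b]
    return list(a) + list(b), common


# ---------------------------------------------------------------------------
# on-disk formats


def write_score_matrix(m: ScoreMatrix, path) -> None:
    """TSV with a '#'-prefixed header block (method, columns, params)."""
    with open(path, "w") as fh:
        fh.write(f"# method\t{m.method}\n")
        cols = ";".join(
            f"{protein}/{'-' if pos is None else pos}"
            for protein, pos in m.columns
        )
        fh.write(f"# columns\t{cols}\n")
        fh.write(f"# params\t{json.dumps(m.params or {})}\n")
        for row in m.scores:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_score_matrix(path) -> ScoreMatrix:
    method, columns, params = None, None, {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, value = line[2:].split("\t", 1)
                if key == "method":
                    method = value
                elif key == "columns":
                    columns = tuple(
                        (p, None if pos == "-" else int(pos))
                        for p, pos in (tok.rsplit("/", 1) for tok in value.split(";"))
                    )
                elif key == "params":
                    params = json.loads(value)
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    if method is None or columns is None:
        raise ValueError(f"{path} is not a score-matrix TSV")
    return ScoreMatrix(
        method=method, scores=np.array(rows), columns=columns, params=params
    )


def read_icoms_matrix(path, method: str) -> ScoreMatrix:
    """Adapter for labeled raw score matrices (I-COMS-style dialect).

    Expected layout: optional '#' comment lines; a header row of column
    labels of the form ``PROTEIN/position``; then one row per column with its
    label followed by the scores.  Positions are 1-based human positions.
    """
    labels = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = re.split(r"[\t ]+", line)
            if labels is None:
                labels = toks
            else:
                rows.append([float(v) for v in toks[1:]])
    if labels is None or not rows:
        raise ValueError(f"{path} contains no matrix data")
    columns = tuple(
        (p, int(pos)) for p, pos in (tok.rsplit("/", 1) for tok in labels)
    )
    return ScoreMatrix(method=method, scores=np.array(rows), columns=columns)


PAIR_COLUMNS = [
    "protein_a", "position_a", "protein_b", "position_b",
    "method", "score", "klass",
]


def pairs_to_frame(pairs: list[CovaryingPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein_a": p.protein_a,
                "position_a": p.position_a,
                "protein_b": p.protein_b,
                "position_b": p.position_b,
                "method": p.method,
                "score": p.score,
                "klass": p.klass or "",
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    )
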