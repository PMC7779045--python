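# Methods

This note documents the models, conventions and numerical choices behind
`mitonet`, and what the synthetic fixtures do and do not demonstrate.

## Ortholog filtering and dissimilarity

Dissimilarity between two aligned sequences is the fraction of differing
columns among the compared ones. Columns gapped in *both* sequences leave
the denominator; a gap aligned against a residue counts as a difference.
This matches common percent-identity conventions; the alternative
(normalizing over the human ungapped length) was a genuinely open choice
and is *not* claimed to be what any particular upstream tool does. Two
consequences are worth noting: dissimilarity is symmetric, and it is
computed on the alignment as delivered — sequences are never re-aligned
after filtering. Discarding uses a strict `>` comparison against the
threshold (default 0.5; 0.3 for MT-ATP8, whose short length makes the
relaxed cutoff too permissive), so a sequence exactly at the threshold is
kept. The human reference row is always retained.

## CPD calling

A variant's protein position (1-based, human ungapped) is mapped to the
alignment column holding the corresponding human residue. The flank window
is the 10 *human* positions surrounding the variant (5 each side), mapped
individually to columns — anchoring the window to human coordinates means
insertions private to an ortholog cannot shift it. Within the window:

* a gap in the ortholog counts as non-identical;
* window slots that run off either protein terminus count as
  non-identical, which keeps the ≥7-of-10 requirement meaningful near the
  ends (a 7/10 threshold over a 6-slot window would otherwise be
  unreachable and a 10-slot one trivially conserved).

A CPD call requires at least one non-human row (decided by species string,
default reference species `Homo sapiens`) carrying the alternative residue
at the variant column with flank identity ≥ 7. Prevalence
(`ortholog_fraction`) is computed over *all* non-human rows, not only
flank-qualified ones; both conventions are distinguishable downstream
because supporting species are listed with their flank counts.

## Co-variation scoring

Both scorers operate on integer-encoded alignments over 21 states (20
residues + gap; unknown symbols map to gap) and share redundancy weights:
a record's weight is 1/(number of records within fractional identity ≥ 0.8
of it, itself included), and M_eff is the weight sum. The 0.8 threshold is
the field-standard default for contact-prediction reweighting and is
configurable.

**MI + APC.** Pairwise joint frequencies use weighted counts plus a
uniform pseudocount (default 0.5 effective counts spread over the 21×21
cells). MI is in bits. The average-product correction subtracts
MI(i,·)MI(·,j)/MI(·,·) (row means over j≠i, grand mean over off-diagonal
cells), which removes most entropic and phylogenetic background. The
pairwise-MI-with-APC score stands in for per-residue cumulative-MI scores
used elsewhere; ranking pairs requires a pairwise score, and APC-MI is the
standard information-theoretic choice.

**Mean-field DCA.** Frequencies are regularized as
f = λ/q + (1−λ)f_emp with pseudocount weight λ = 0.5 (the canonical
mean-field value; raise it if the correlation matrix is reported
singular). The connected-correlation matrix C is built over the reduced
alphabet with the gap state removed as reference (L×20 dimensions);
couplings are e = −C⁻¹. Each pair is scored by direct information: the
two-site distribution P_dir ∝ exp(e_ij) with fields fitted by fixed-point
iteration (tolerance 1e-4, ≤500 iterations) to reproduce the single-site
marginals, then DI = KL(P_dir ‖ f_i⊗f_j) in nats. DI is symmetric and
non-negative. Background DI on uncoupled alignments is finite-sample
noise that decays with depth; the inversion estimates 20L parameters per
column pair, so alignments with M_eff well below 20L give noisy couplings
(the test fixtures use M_eff ≈ 250 for ranking at L = 60, and ≈ 800 for
the chained-coupling comparison at L = 40 for exactly this reason).

**Concatenation and filtering.** Alignments are concatenated per species;
only species present in all inputs are kept, and a species with several
rows in one input contributes the row closest to that alignment's human
sequence. TOP-N ranking (default 500) excludes columns gapped in the
human reference so every reported pair maps to a human position, and
breaks score ties deterministically by (protein order, position_a,
position_b). Inter-protein filtering keeps pairs spanning two proteins;
intra-protein filtering keeps same-protein pairs with neither residue in
the concatenated protein (default MT-ND1). The union of two methods keeps
one entry per method (so its size is the sum of the list sizes), with
common pairs identified by unordered residue coordinates.

## Energetic compensation

Threshold semantics are strict on both sides: disruptive iff
|ΔΔG| > 0.61 kcal/mol, compensatory iff |ΔΔG| < 0.1 kcal/mol, so the
boundary values classify as tolerated / non-compensatory respectively.
When replica values are present, ΔΔG is their arithmetic mean and the
record enforces that invariant. The pair ΔΔG is taken as supplied (a
double-mutant measurement), never as the sum of singles; an `epistasis`
diagnostic (ΔΔG_pair − ΔΔG_a − ΔΔG_b) is emitted for inspection. A
*compensation event* requires ≥1 disruptive single and a compensatory
pair; whether the partner must itself be tolerated is left to downstream
filtering, since both single calls are reported. The interface class
requires *both* positions in the supplied interface set (the set is an
input — deriving it from structure superposition is upstream of this
package); remaining pairs are inter/intra by protein identity. The
partition is exhaustive and disjoint.

## Variant enumeration

Genes come from a GenBank flat file (CDS features; minus-strand features
reverse-complemented) or an equivalent TSV. Features ending mid-codon are
completed with `A` bases — the mitochondrial polyadenylation-completed
stop — and flagged; padded bases are never enumerated. Translation uses
NCBI table 2 (TGA=Trp, ATA=Met, AGA/AGG=stop). For each codon all nine
substitutions are tested; a variant is emitted iff the residue changes.
The default stop policy excludes any substitution whose reference or
alternative codon is a stop (truncations are not amino-acid variations);
`include-stops` emits them with `*`. The policy is recorded in run
manifests because genome-wide totals depend on it. Overlapping genes
(ATP8/ATP6, ND4L/ND4) are enumerated independently, so one genomic
substitution may yield one record per gene.

## Trajectory summaries

Superposition is the least-squares Kabsch fit with the determinant
correction enforcing a proper rotation; configurations with fewer than 3
atoms or collinear atoms are rejected. RMSD series fit every frame to a
chosen reference frame (entry at the reference index is exactly 0). RMSF
superposes all frames to an iteratively refined average structure — two
refinement passes, stated explicitly because MD packages differ here —
then takes per-atom √⟨|xᵢ−⟨xᵢ⟩|²⟩. Essential dynamics eigendecomposes the
3N×3N covariance (denominator F−1) of the superposed coordinates;
eigenvalues are clipped at 0, sorted descending, and sum to the total
coordinate variance (asserted to 1e-8 relative). Mass weighting is off by
default; the atom subset analysed (Cα, backbone, all) is whatever the
input table contains — it is an input, not a guess. Only plain tabular
trajectories are read; binary MD formats are out of scope.

## Synthetic generators

`simulate_alignment` uses a star phylogeny: every non-human row derives
independently from the human (ancestral) row, each column substituting
with probability 1−exp(−d) for divergence d (expected substitutions per
site), uniformly over the 19 other residues; no indels. Coupled pairs
co-substitute through a fixed residue bijection with the given strength;
the default test fixtures use strength 0.9 and divergence 0.3–0.6, deep
enough that M_eff ≈ the species count. Planted CPDs fix the alternative
residue in chosen carriers, hold carrier flanks identical to human at the
stated conservation rate (1.0 for true CPDs, 0.0 for decoys — margins
chosen so calls are unambiguous), and remove chance alt-residue carriers
so the ground truth is exact. What the star model omits: tree-structured
covariance (phylogenetic pseudo-correlation), indels, rate variation and
empirical exchangeabilities. Passing recovery tests therefore shows the
scorers and the CPD caller are correct implementations, not that they are
robust to phylogenetic confounding on real mammalian data — the sequence
reweighting and APC mitigate but cannot eliminate that on real inputs.

`simulate_ddg_table` builds classifications by construction (disruptive
singles at |ΔΔG| ≥ 0.91, compensatory pairs within ±0.04, violations well
outside the cutoffs) with replica noise (default sd 0.01 kcal/mol) small
against those margins, so the planted compensated fraction is recovered
exactly — the test is of the screen's logic, not of threshold robustness.

`simulate_trajectory` superimposes harmonic motion along random
orthonormal collective modes (amplitude a ⇒ positional variance a², with
integer cycle counts so sampled variances are exact) on a static
structure, plus isotropic noise and optional per-frame rigid drift. Modes
are projected out of the rigid-body subspace (translations, infinitesimal
rotations about the base structure) before orthonormalization; otherwise
the analysis superposition would absorb part of the planted amplitude and
bias the recovered eigenvalue spectrum.

## Problem sizes

Test and acceptance fixtures use alignments of 150–1500 sequences × 20–120
columns, 400 ΔΔG pairs, 30-codon genes and 200-frame/20-atom
trajectories. These sizes put M_eff and the mean-field inversion in their
intended regimes while keeping the full suite and the acceptance script in
the seconds range on one CPU.

## Known limitations

* The co-variation scorers correct for redundancy and background but not
  for tree topology; strongly clonal clades can still induce spurious
  pairs on real data.
* Mean-field DCA background DI does not vanish at finite depth; compare
  scores within one run, not across alignments of different M_eff.
* The CPD caller trusts the input alignment; misalignment around the
  variant column translates directly into wrong calls.
* Reproduction of published pair counts and the genome-wide variant total
  requires external reference inputs (released score matrices; the
  NC_012920.1 record) that are not bundled.
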