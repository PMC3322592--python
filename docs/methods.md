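# Methods

## The fragment database

The database is a single flat list of amino-acid records.  Each record stores
a one-letter residue type (alphabet `ACDEFGHIKLMNPQRSTVWY`, indexable 0–19 in
that order — this ordering defines the bit positions of the residue-type
masks and is frozen into the file format) and the orthogonal-Å coordinates of
the N, Cα and C atoms.  These three atoms are sufficient to place the
remaining mainchain atoms: Cβ at the ideal tetrahedral position (1.53 Å from
Cα, 110.5° to both the N and C bonds, L-configuration) and the carbonyl O in
the peptide plane (1.23 Å from C along the outward bisector of the
Cα–C–N(next) angle, which puts both flanking angles near 121–122°).  These
are fixed Engh–Huber-style constants, not fitted values.

Admission rules for building a database from refined chains: a residue needs
all of N/Cα/C, a Cα B-factor of at most `b_max` (default 40 Å²), a standard
type (a small table maps common modified residues, e.g. MSE→MET; anything
else is excluded so the 20-bit mask semantics stay clean), alternate location
'A' or blank only, and N–Cα / Cα–C bond lengths in (1.0, 2.0) Å.

**Continuity.**  Residues *i*, *i*+1 are continuous iff the C(*i*)–N(*i*+1)
distance is ≤ 1.8 Å — generous against distorted peptide bonds (ideal
1.33 Å) while rejecting chain jumps.  Breaks are inserted at chain ends, at
every excluded residue (no re-bridging across exclusions — conservative) and
at stretched peptide bonds.

**Running distance matrix.**  An *n* × *W* matrix (default *W* = 20,
supporting fragments of up to *W*+1 = 21 residues; configurable and recorded
in the file header) holds in row *r*, column *j* the distance
|Cα(*r*) − Cα(*r*+*j*+1)| when both residues lie in the same continuous
fragment, else the flag −1.0 (any negative value is safe since no real
distance is negative; −1.0 serializes exactly).  The database file is a
versioned little-endian binary (magic, version, counts, then the raw arrays);
round trips are bit-exact, and wrong magic/version or truncation raise a
format error.

## The two-stage search

A query (`SearchFragment`) is an ordered list of Cα slots, any of which may
be null, with a per-slot 20-bit type mask (default: all types allowed).  Its
triangular distance matrix stores row *i* → distances to slots *i*+1…*n*−1,
flag wherever a null participates; the columns correspond to the diagonals of
a conventional distance matrix, i.e. exactly the layout of the database's
running matrix, so scoring a database offset is a direct window comparison.

**Pre-screen.**  For each admissible offset, the SSD over the query's defined
entries against the corresponding running-matrix entries.  An offset is
admissible iff its window lies inside one continuous fragment (equivalently:
no required entry is the flag — scoring across chain breaks is rejected
outright rather than skipped) and every slot's mask admits the database
residue type at that position.  Masks are therefore enforced *inside* the
pre-screen as part of admissibility (they are cheap bit tests); the public
`mask_pass` predicate exposes the same rule and the test suite checks that
surviving offsets are exactly those passing it.  The best `n_prescreen`
offsets (default 500) are retained in a bounded max-heap whose root — the
worst retained SSD — is the early-termination threshold: each offset's sum is
abandoned as soon as it exceeds that threshold.  The no-early-exit reference
path accumulates entries in the same order, so the two paths give
bit-identical results (ties order by lower offset).

**Re-scoring.**  The distance matrix of a point set is invariant under
inversion through a centre of symmetry, so the pre-screen cannot reject
mirror images of chiral queries.  Candidates are therefore superposed onto
the query's non-null Cαs by closed-form Kabsch (SVD with determinant
correction; only proper rotations, so a mirror hit acquires a large RMSD),
re-sorted ascending by Cα RMSD (ties: lower SSD, then lower offset), filtered
by the optional `rmsd_max`, and the best `n_return` (default 50) kept.
Superposition fits Cαs only; N and C atoms of matched records are carried
through the transform but not fitted.  The Kabsch solve is batched over
candidates (one `numpy` batched SVD) for speed; point sets whose second
singular value is below 1e−8 (collinear) raise a degeneracy error.

**Coverage experiment.**  Every continuous window of a chosen length is used
as a query in turn; the best match is always the window itself and is
discarded, and the second-best match's Cα RMSD (or worst-atom displacement)
is recorded.  The sorted vector is the tail-curve data answering how well
each fragment can be represented by some *other* database fragment.  At full
scale this requires an external multi-hundred-structure database; the package
runs it at any scale, and the shipped tests/acceptance script exercise a
scaled-down synthetic database (≈ 20 motifs, ~440 residues, length 6) chosen
to finish in seconds while still exhibiting the qualitative behaviour (exact
twins score ≈ 0; unique random-coil windows have no good twin).

## Rebuilding operations

All rebuilt coordinates are copied from database records and moved by a
match's rigid transform — never interpolated — and carry a provenance tag
naming the source record.

* **Cα → mainchain:** for each peptide bond, a six-residue window centred on
  the bond (3+3, shrunk to a minimum of four at the termini) is matched; C(i)
  and N(i+1) come from the middle peptide of the best match; O atoms are then
  placed from the rebuilt peptide planes; Cα positions are the input's own.
* **Loop building:** two stem residues either side of *g* null slots; the
  best match with stem RMSD ≤ `stem_rmsd_max` supplies the null coordinates.
  `stem_rmsd_max` defaults to 0.75 Å — between exactness and the 1 Å
  conformation-similarity threshold used for fragment overlaps.
* **Bridging a numbered break:** prunings of both ends are enumerated —
  always at least enough that no sequence number appears on both sides, plus
  up to `p_max` = 2 extra per end — with the implied insertion count required
  to fill exactly the missing numbers and the whole bridging fragment capped
  at six residues.  The cap is exposed as a parameter but not adapted during
  building.  Proposals are tried in order of least modification (smallest
  total pruning first) and a later proposal replaces an earlier one only if
  its stem RMSD improves by more than 1e−6 Å: when the source motif is
  present verbatim in the database, many prunings tie at RMSD ≈ 0 and the
  tie must resolve to the least destructive repair.
* **Terminus linking** (sequence-blind): all C/N terminus pairs within reach
  (a distance gate of 4.2 Å per bridged residue) are tried with 0–2 inserted
  residues; merges apply greedily in ascending stem-RMSD order, each terminus
  used at most once, self-links allowed only with ≥ 2 insertions; merged
  chains renumber consecutively across the join.
* **Indel correction:** one or three suspect residues, with two stems either
  side, are rebuilt as two; downstream numbering shifts by ±1.

## Tidying

Per sequence: the overlap matrix (entries are the shared-seqnum count iff
> 12 shared numbers *and* similar conformation — superpose all overlapped Cα
pairs once, keep the best ⌈k/2⌉ residuals, re-superpose, require RMSD < 1 Å;
a single trim pass, deterministic and cheap) feeds a depth-first maximum-
clique search with branch-and-bound pruning; among equal-size cliques the
greatest total residue count wins, then the lexicographically smallest index
set.  With no passing overlap the longest fragment is the lone seed.  Seeds
take chain identifiers A, B, C… ordered by descending length; leftover
fragments continue the alphabet (then two-letter codes) as dummy chains.

Growth considers, each round, every unallocated fragment of the sequence
against every chain *of that sequence* over all candidate transforms (space-
group operators conjugated into the orthogonal frame, composed with lattice
translations of ±1 cell per axis by default — compact molecules never need
distant cells).  Score: +1 per fragment Cα within 5 Å of a chain Cα (nearest-
neighbour lookup via a k-d tree; each fragment atom counts at most once), −2
per docked residue whose number is already in the chain (only when fragment
and chain share a sequence).  The single best strictly-positive move is
applied and all scores recomputed.  Undocked fragments are allocated
afterwards across all chains by the geometric term alone; they cannot seed
new chains.  Strict readings throughout: "exceeds 12" → ≥ 13, "within 5 Å"
→ ≤ 5.0, "less than 1 Å" → < 1.0.

Assembly concatenates each chain's fragments by ascending first sequence
number; duplicated numbers get insertion codes A, B, … in encounter order
(single letters only — no plausible chain exceeds 26 collisions at one
number).  Remaining numbered discontinuities are then offered to the
bridging step where a database is supplied.

## Synthetic data

The generators build mainchains by internal-coordinate extension (NeRF) with
ideal bond lengths/angles and trans peptides, driven by per-residue (φ, ψ):
ideal helices (−57°, −47°), strands (−120°, +130°), and "varied" chains
whose torsions are drawn in runs of 3–8 residues from four allowed
Ramachandran regions (α, β, PPII, left-handed α with weights
0.45/0.30/0.18/0.07) — a stand-in for the conformational diversity of a
refined structure set.  A two-helix hairpin (fixed turn torsions chosen to
pack the helices antiparallel at van der Waals distance) provides the compact
fold the tidying score needs.

`scatter_model` emulates a fragmentary autobuilt model: molecules (repeated
sequence ids model NCS copies) are cut at random junctions, junction residues
are deleted with a configurable rate (incompleteness), every fragment is
displaced by a random space-group operator (scattering uses translation
shell 0 so that a tidy search with shell 1 can express any composition
S<sub>a</sub>·S<sub>b</sub>⁻¹ of a scatter op with an inverse), some
fragments optionally lose their sequence docking, and isotropic Gaussian
noise (default σ = 0.1 Å — perturbs superpositions without destroying
motifs) is added.  The ground-truth fragment → molecule mapping is returned
alongside.  The hetero-dimer preset (two sequences, two NCS copies each,
~10 fragments, P2₁ cell sized to about twice the molecular extent) places
molecules ≥ 10 Å apart including their symmetry images, so ground-truth
membership is unambiguous.

**What the synthetic fixtures do not model:** real crystal packing brings
neighbouring molecules into genuine 4 Å contact, which is exactly the regime
where sequence-blind linking goes wrong in practice; electron-density
quality, sequence-docking errors and register shifts are absent; and the
all-alanine hairpin sequences make sequence docking trivial.  Passing the
tidying tests therefore demonstrates the correctness of the scoring and
assembly machinery under unambiguous geometry, not robustness to adversarial
packing — the published experience is that assignment accuracy degrades when
chains are under ~50–60 % complete, and the low-completeness fixtures show
the same qualitative behaviour (unallocated fragments, shorter chains) while
keeping every confident assignment pure.

## Numerical choices and degenerate inputs

* Flag value −1.0 for undefined distances; rejected offsets are those whose
  window would read any flag.
* Superposition requires ≥ 3 points; collinear sets raise rather than
  silently returning an arbitrary rotation about the line.
* Rigid transforms validate orthogonality (1e−6) and det = +1; improper
  operators (which cannot occur in the Sohncke space groups of chiral
  macromolecules, but can arise from an inconsistent cell/space-group pair)
  are rejected with an error.
* Deterministic ordering everywhere: pre-screen ties by offset, re-score
  ties by (SSD, offset), growth ties by (chain id, fragment index),
  allocation-transform ties by candidate order, clique ties by weight then
  index set.  Repeated runs on identical input are bit-identical.
* All generators are pure functions of their arguments including the seed.

## Problem sizes

The shipped tests and the acceptance script use databases of 200–500
synthetic residues, 100-query search/bridging trials, 200 random overlap
graphs (≤ 12 fragments, checked against exhaustive 2ⁿ enumeration) and ten
scattered hetero-dimer models — sizes chosen so the whole suite runs in well
under a minute while every check remains statistically meaningful.  The
full-scale numbers from a multi-hundred-structure curated database (~10⁵
records) are reproducible with `fragweaver build-db` on such a structure set
followed by `fragweaver coverage`, given the data and a few hours of compute.

## Known limitations

* Loops longer than the *W*+1 window cannot be built in one step; no
  stepwise long-loop assembly.
* Sequence docking is taken as input (or reconstructed by exact type/number
  match when reading plain coordinate files, which cannot carry docking
  assignments); no density-likelihood re-docking, so links validated only by
  sequence cannot be re-checked — a limitation inherited from the method.
* The bridge cap is fixed per run; no late-stage relaxation policy.
* No seqnum-proximity reward in the allocation score (a deliberate omission:
  it would aggravate incorrect cross-contact linking early in building).
* Linear scan with early exit only; no approximate nearest-neighbour index.
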