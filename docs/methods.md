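# Methods

`lhlkit` quantifies geometric diversity in de novo designed alpha-beta
proteins whose loop-helix-loop (LHL) elements have been reshaped against a
fixed beta sheet, and implements the dataset-curation and stability-
classification procedures such a design campaign needs: sheet-aligned helix
RMSD metrics, 6D helix-vector binning, structure-aware train/test
splitting, scramble-control generation, design-selection filters, and
protease-resistance classification.  This note records the models,
conventions and tunable parameters, and what the synthetic-data generator
does and does not emulate.

## Geometry

**Superposition.** All alignments use least-squares rigid superposition
(Kabsch, SVD with reflection excluded).  RMSDs default to the four
backbone heavy atoms N, CA, C, O per residue; a CA-only switch exists for
data where only CA correspondence is trustworthy.

**Pairwise helix RMSD.** Two annotated structures are aligned on their
position-matched beta-sheet residues; the RMSD is then taken over the
concatenated backbone atoms of all matched reshaped helices, without
re-superposing on the helices — so the metric measures where the helices
sit relative to the shared sheet, not just their internal shape.  When a
matched helix pair has unequal lengths, the longer helix is trimmed to its
central window of the shorter's length; an odd total trim keeps the extra
residue at the N terminus (floor(d/2) removed N-terminally, ceil(d/2)
C-terminally).  Both helices are concatenated into one RMSD rather than
averaged per-helix.

**LHL RMSD.** A prediction is aligned to its design model on the backbone
atoms of every residue *outside* the reshaped LHL ranges; the RMSD is then
computed over the LHL residues.  For prediction ensembles, either the
minimum over members ("lowest") or the member with highest pLDDT
("rank1", ties broken by member order) is reported.

**Helix vectors and bins.** A helix is summarised by a 6D descriptor: the
centroid of its backbone atoms plus the normalised mean of per-residue
unit C→O vectors.  The raw mean's sign depends on bookkeeping, so it is
flipped to have positive dot product with (CA_last − CA_first), making it
a true N-to-C direction.  Bins combine a cubic voxel of centroid space
(edge 2.0 Å, origin at the frame origin, floor indexing) with the sign
octant of the direction (a component exactly 0 counts as +).  Occupancy
of a subset is the fraction of the bins occupied by a stated comparison
universe that the subset also occupies; the universe is an explicit
parameter because the natural choice (all designs of a fold set) depends
on the analysis.  Octants are taken in the frame in which the structures
were mutually aligned.

**Bias statistics.** For index-aligned (design, prediction) pairs and an
idealized reference, the package reports the fraction of predictions whose
sheet-aligned helix RMSD to the reference is smaller than to their own
design model, and the fraction more than a margin (default 1.0 Å) closer.
A tie counts as *not* closer, which is conservative toward a claim of
idealization bias.

**Sheet face and shells.** The sheet face of a helix is the sign of the
dot product between the sheet's best-fit-plane normal and the vector from
the sheet CA centroid to the helix centroid; the normal's orientation is
fixed by the cross product of the first two non-collinear inter-CA
vectors, so signs are reproducible for a given residue ordering, and a
centroid exactly in-plane maps to +1.  Shell 1 around the reshaped LHLs
contains every LHL residue plus any residue within 10 Å (CA–CA) of an LHL
residue that also "points toward" one; shell 2 grows shell 1 by the same
rule at 8 Å.  "Points toward" is defined here as: the angle between
(CB − CA) of the candidate and (CA_target − CA) is below 90°, with a
virtual CB built from ideal tetrahedral geometry for glycine.

## Helix assignment

When no annotation is supplied, helices are assigned from backbone
dihedrals: maximal runs of at least 4 consecutive residues with
phi ∈ [−100°, −30°] and psi ∈ [−80°, +5°].  Terminal residues lack one
dihedral and never count, so a planted L-residue ideal helix is recovered
as at least its L−2 interior residues.  This window is this package's
definition of "helical"; it does not distinguish 3₁₀ from alpha helix.
Ranges supplied in a `SegmentAnnotation` always take precedence.

## Structure-based train/test split

All-by-all helix-RMSD matrices (overall, helix 1, helix 2) drive the
split.  The overall matrix is converted to a Gaussian affinity
A_ij = exp(−d_ij²/(2σ²)).  The default kernel scale is local: the median
over points of the distance to their ⌈log₂ n⌉-th nearest neighbour.  A
global median scale is also available, but when the distance distribution
is bimodal — tight structural families separated by large gaps, exactly
the regime a leakage-controlled split exists for — the global median sits
in the between-family mode, the affinity contrast washes out, and
spectral clusters straddle families; the local scale keeps within-family
edges strong and between-family edges negligible.

Spectral clustering follows the standard normalized recipe: symmetric
normalized Laplacian, the k eigenvectors of smallest eigenvalue,
row-normalised embedding, seeded k-means (k = 25 by default).  A
disconnected affinity graph is reported as an error rather than silently
mis-clustered.

The search tries `n_cluster_seeds` clusterings (seed_i = master_seed + i)
times `n_bipartitions_per_seed` random bipartitions of the clusters
(default 1,000 × 1,000; every candidate is scored and the count is
recorded in the provenance).  Candidate score, maximized:

    min over cross-split pairs of min(helix1, helix2) RMSD
    − λ · |train_fraction − target_train_fraction|

with λ = 10 Å per unit fraction and target 0.9.  The side whose size
fraction is closer to the target is labelled train.  The winner is then
pruned: iteratively remove the example participating in the most
cross-split pairs with helix-1 *or* helix-2 RMSD below 2.0 Å, breaking
ties by which removal leaves the train fraction closest to target, then
by removing from the larger side, then lexicographically; the same greedy
pass afterwards removes cross-split pairs sharing a linker identifier.
If pruning empties a side the split is reported infeasible.  An
independent checker (`check_split`) re-scans the matrices to assert the
partition, leakage and linker contracts on every output.  The random
validation split draws round-half-up(n · fraction) ids (at least 1)
without replacement, deterministically per seed.

## Scramble controls

Full scrambles are seeded uniform permutations of the whole sequence
(numpy PCG64, reproducible across platforms).  Patterned scrambles
permute identities only within the hydrophobic class and within the polar
class, leaving Gly/Pro positions untouched, so length, composition and
the per-position hydrophobic/polar/fixed labels are preserved exactly.
The hydrophobic class defaults to {A, V, L, I, M, F, W, Y} — cysteine is
absent because the design libraries handled here are Cys-free — and the
partition is configurable and recorded in output metadata; it is this
package's convention, not a canonical one.

## Design selection

Oligo arithmetic: a pool of ≤ 300-nt oligos with 21-nt primers at both
ends leaves 258 variable nucleotides = 86 variable residues; with the
21-nt reverse primer encoding the first 7 of 17 vector-supplied fixed
C-terminal residues, designs of up to 103 total residues are orderable.
The orderability filter is inclusive at 103 and rejects any forbidden
residue (default: cysteine).

Metric thresholds (all comparisons strict, metrics consumed from a table,
never computed here): fragment quality < 1 Å, holes score < 0,
helix complementarity > 0.6, buried unsatisfied H-bonds < 2 (i.e. ≤ 1),
oversaturated H-bonds = 0, hydrophobic SASA ratio < 0.58 for the Rosetta
set; best reshaped pLDDT > 85 and minimum LHL RMSD < 1.5 Å for the
prediction set.  The two pass flags define four quadrants
(RP/RF × AP/AF).

Backbones carrying several designs are reduced to one design each by a
staged priority that populates the scarcer Rosetta-Pass quadrants first:
backbones with designs in both RP-AP and RP-AF are evenly split between
them (seeded shuffle then alternating assignment, counts differing by at
most 1); remaining RP backbones go to their quadrant; then RF-AP; RF-AF
takes the rest.  Per-quadrant sampling (default 2,500) is seeded and
without replacement.

## Stability classification

A read counts for a design when the region between the fixed flanking
hexamers TCAATG…CTCGAG translates to exactly the design's protein
sequence — synonymous nucleotide changes still count; both strands are
scanned and a read matches at most one design.  Designs sharing a protein
are reported once and merged under the lexicographically first id.

Records are retained when the EC50 95% credible-interval width is
strictly below 2.0 on both proteases.  The stability threshold per
protease is the 95th percentile (linear interpolation) of the
patterned-scramble control EC50s — full scrambles are excluded by
default, with a pooling switch — and a design is stable iff its EC50
strictly exceeds the threshold for *both* trypsin and chymotrypsin.

## Synthetic data

The generator provides every pipeline input with known ground truth:

* **Scaffold**: an idealized antiparallel beta sheet (4 strands × 5
  residues by default) built from internal coordinates, standing in for a
  fixed Rossmann-like sheet.
* **LHL variants**: ideal alpha-helices (phi = −57°, psi = −47°, giving
  the textbook ~1.5 Å rise/residue and ~2.3 Å CA radius) placed at
  requested centroid/axis, joined to the scaffold by geometrically
  interpolated loops.  Loops are smooth coordinate paths, not physically
  valid backbones — no in-scope operation evaluates loop physics.  The
  planted centroid/axis are exact by construction; per-LHL linker ids
  hash the loop/helix placement spec.  Variants clashing with the sheet
  (CA–CA < 3 Å) are rejected.  Two regimes emulate the study conditions:
  a *diverse* regime sampling broad centroid/axis ranges and an
  (near-idealized) *regular* regime with small jitter around one
  placement.
* **Prediction ensembles**: members displace only reshaped-LHL atoms by a
  rigid translation sized to a target LHL RMSD (verified within 5%),
  with independently assigned pLDDTs so rank-1 and lowest-RMSD selection
  can disagree.
* **Metric tables**: independent per-metric draws strictly inside or
  outside each threshold with planted pass probabilities.
* **Assay simulator**: proteolysis survival exp(−k·c) with k = ln 2/EC50,
  so survival is ½ at the planted EC50.  Defaults: 2,000 designs, 60%
  planted stable, 190 controls of each scramble type (the 10,000-design /
  950-per-type library scaled by 1/5); stable designs draw EC50 from a
  log-normal with median 12 (one underlying value shared across
  proteases), unstable designs and scrambles from median 0.2 log-normals
  drawn independently per protease; credible-interval widths are
  log-normal around 0.8 so most records pass the < 2.0 filter; reported
  EC50s carry multiplicative log-normal noise with σ tied to the drawn
  interval width.  The protease concentration schedule follows the
  three-round trypsin/chymotrypsin series used by the high-throughput
  assay (0.07–51.99 µM and 0.08–20 µM).  Optional per-round read sets are
  multinomial samples of the surviving population, emitted as
  flank-delimited coding sequences for the read counter.

What the generator does **not** emulate: real packing or loop physics,
sequence-dependent protease site counts, FACS gating noise, correlated
metric errors, or prediction errors with any structure beyond a rigid LHL
displacement.  Passing tests therefore demonstrate algorithmic
correctness and planted-parameter recovery, not performance on
experimental data.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical checks are
meaningful: cohorts of 15–25 backbones for diversity and oracle
comparisons, 200 variant specs for parameter recovery, a 200-example
two-family dataset with a 10 × 10 search (production defaults remain
25 clusters and 1,000 × 1,000 candidates), 10,000 scramble property
cases, and 2,000-design assay simulations.  Quantiles use linear
interpolation between order statistics (numpy default) everywhere;
negative pseudo-log-likelihoods use natural log; all stochastic steps
take explicit seeds and derived seeds are documented (seed_i =
master_seed + i for the cluster search).

## Known limitations

* The dihedral-window helix assigner is a coarse stand-in for a full
  secondary-structure algorithm; it will under-call distorted helices.
* PDB I/O is deliberately minimal: ATOM records, first model, one chain,
  no insertion codes.
* The greedy split pruning has no optimality guarantee; it is
  deterministic and contract-checked, not minimal.
* EC50s are treated on whatever scale the input table uses; no unit
  conversion is attempted, and the Bayesian EC50 inference itself is out
  of scope (the forward simulator generates consistent tables instead).
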