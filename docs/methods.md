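# Methods

## Scope and model

`sercakit` quantifies the conformational states of the SERCA Ca²⁺-ATPase
from crystal structures along three complementary axes: a corpus-wide
backbone-RMSD census that groups structures into catalytic-state clusters,
rigid-body kinematics of the three cytosolic domains measured in a common
anchor frame, and per-helix geometry of the transmembrane (TM) domain. The
underlying assumption throughout is rigid-body behaviour at the domain
scale: the A, N, and P domains and the TM7–TM10 bundle are treated as
internally rigid bodies whose relative placement encodes the catalytic
state, which the crystal corpus supports (TM7–TM10 superposes to small
residuals across states, and domain-internal RMSDs are small compared to
inter-state motion).

## Structure model

Structures are parsed (PDB or mmCIF, first model only) with alternate
locations resolved to highest occupancy. The longest protein chain is
taken as the pump; regulatory peptides (phospholamban, sarcolipin),
waters, ions, lipids, and inhibitors are retained in a ligand table that
geometry operations never read. Non-standard residues with modified
backbone chemistry (phospho-aspartate mimics) are excluded from backbone
geometry. Residue numbers follow the SERCA1a convention (1-based, 994
residues, UniProt P04191-2); other isoforms are renumbered by global
pairwise alignment (BLOSUM62, free terminal gaps), dropping residues with
no reference counterpart (e.g. the SERCA2b TM11 fragment). Alignment
identity below 50% aborts the mapping. The reference sequence is supplied
by the user as FASTA; it is not bundled.

Missing loops are **not** modelled. Every ensemble computation restricts
itself to the intersection of backbone-complete residues across the
structures involved (`common_residues`). This removes a non-deterministic
external modelling dependency at the cost of measuring slightly fewer
atoms per pair; because the residues missing from crystal structures are
flexible loops that contribute noise rather than signal to rigid-domain
comparisons, cluster topology is expected to be robust to the choice, and
the clustering cutoff is a parameter should a user want to re-tune against
loop-modelled inputs.

Working coordinates are double precision. The biotite `AtomArray` inside
each `Structure` keeps the single-precision copy conventional for
structure I/O; geometry operates on the float64 array so that synthetic
ground-truth recovery is limited by algorithmic error, not storage width.

## Superposition and clustering

Superposition uses the Kabsch algorithm (SVD of the cross-covariance with
determinant correction, so reflections are never returned). Degenerate
inputs — fewer than three points or collinear sets, where the rotation is
underdetermined — are rejected. The backbone RMSD between two structures
is measured after fitting on the same region (backbone = N, Cα, C, O).
RMSD is stored internally in Ångström and reported in nm, the convention
of the corpus literature.

The all-vs-all matrix is computed over the ensemble-wide common residue
set so that every entry measures the same atoms. Clustering is
single-linkage at a cutoff of 0.23 nm: flat clusters are exactly the
connected components of the graph with edges where d ≤ cutoff. The
component containing the reference structure (2c9m, E1·2Ca²⁺) is named C1;
remaining clusters are numbered by ascending first appearance in the input
order. With `singletons="unassigned"`, single-membered components other
than the reference's are reported as *unassigned* — the convention for
structures that cannot be unequivocally grouped — rather than inflating
the cluster count. Average and complete linkage are exposed behind a flag
for sensitivity checks (complete linkage splits chained clusters; see the
chaining test).

## Headpiece kinematics

Every structure is first superposed on the reference over the Cα atoms of
the TM7–TM10 anchor (residues 831–855, 895–915, 933–948, 966–994; at
least 10 common residues required). In that frame, the Kabsch fit of the
reference domain's Cα set onto the target's yields the domain rotation
operator; the angle is arccos((tr R − 1)/2) ∈ [0°, 180°], the axis comes
from the skew part (eigenvector fallback at 180°), and the sense is
*clockwise* when the axis points against the membrane normal, viewing from
the cytosolic side down the normal. Flipping the axis flips the sense, as
it must.

"Displacement distance" is defined as the Euclidean shift of the domain's
Cα centre of geometry between reference and anchor-aligned target — not
the translation component of the equivalent screw motion, which is also
computed and reported (`screw_translation_A`). The COG convention matches
the tens-of-Ångström magnitudes that headpiece motion exhibits and is the
quantity a COG-distance analysis composes with; the screw translation of a
domain rotating about a distant axis is much smaller and answers a
different question.

The membrane normal is the +z axis of the pre-oriented reference frame.
Crystal structures deposited in membrane-aligned orientations satisfy this
directly; otherwise the user supplies the normal of their orientation
convention. No membrane-embedding optimisation is performed.

The Met1–Asn510 Cα distance (A-domain N-terminus to N-domain core) is the
structural counterpart of intramolecular FRET between fluorophores at
those positions and tracks headpiece opening.

## Secondary structure and TM geometry

Helicity uses a minimal Kabsch–Sander assignment. Amide hydrogens, absent
from crystal structures, are reconstructed on each nitrogen along the
bisector of the N→C(prev) and N→Cα directions at 1.01 Å. The hydrogen-bond
energy is the classic electrostatic model

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol

with a bond when E < −0.5 kcal/mol. Two consecutive i→i+4 turns label
residues i+1…i+4 as H; isolated β-bridges reduce to E; everything else is
C. Proline never donates; chain breaks (C–N distance > 2.5 Å) and residues
missing backbone atoms interrupt bookkeeping, and incomplete residues are
always labelled C. Ends of a perfect helix fray by up to two residues by
construction — a property of the assignment, not a defect.

A helix axis is the largest-variance principal direction of the Cα set
(≥ 5 points), oriented N→C. The bending angle follows the three-section
construction: centroids of the first, middle, and last `window` (default
4) Cα positions define arm vectors m−b and t−m whose angle is the bend. A
4-residue window spans ~300° of helical phase, so section centroids sit
within ~0.3 Å of the true axis and a straight ideal helix measures < 5°.
Tilt is arccos|a·n| ∈ [0°, 90°]; crossing angles use the directed
convention arccos(a₁·a₂) ∈ [0°, 180°] (antiparallel helices → 180°), since
the N→C orientation of TM helices is meaningful.

TM helix residue ranges: TM1a 48–55, TM1b 61–78, TM4a 290–306, TM4b
311–329, the TM6 cytosolic segment 800–808, and TM7–TM10 as in the anchor
are fixed by the corpus literature. TM2 (89–114), TM3 (248–270), TM5
(747–780), and TM6 overall (789–810) are packaged defaults from standard
SERCA1a topology annotations; the whole table is a constructor parameter
of `TransmembraneGeometry`, and conclusions that depend on the exact
bounds of those helices should be sensitivity-checked against the user's
preferred annotation.

## Synthetic generators

The generators exist so that every measured quantity has an analytic
oracle. Backbone atoms are placed on coaxial cylinders whose radius/phase/
z offsets relative to the Cα cylinder were calibrated once from a
canonical α-helix built by internal-coordinate chain extension
(φ = −57°, ψ = −47°, standard bond lengths and angles). This yields exact
helical symmetry — axis, rise (default 1.5 Å/residue), and twist (default
100°/residue) are analytic — while keeping peptide geometry realistic
enough that interior residues satisfy the i→i+4 hydrogen-bond criterion
(E(i,i+4) ≈ −2.2 kcal/mol at defaults).

Kinked helices join two arms whose axes meet at exactly the requested
angle, with the vertex half a rise beyond each arm and the helical phase
continued across the junction, as at a proline kink. The three-section
bend estimator recovers constructed kinks of 20–90° within 3° for equal
arms of ≥ 20 residues; markedly unequal arms shift the middle section away
from the vertex and degrade recovery — a limitation of the estimator on
off-centre kinks, shared with its use on real helices.

Toy pumps emit a reference/moved pair of multi-block structures (helical
blocks standing in for anchor, A, N, P, with residue ranges inside the
packaged domain definitions). Each block's transform — rotation about its
own Cα centroid, then translation — is recorded as exact ground truth, so
the recovered angle equals the applied one and the COG displacement equals
|translation|. Default transforms (A: 110°, 27.4 Å; N: 65° clockwise,
25 Å; P: 20°, 7.8 Å) mirror the magnitudes the corpus shows across the
E1→E2 transition. Noise, when requested, is applied to the moved copy
only, after the transform, from a seeded generator; all generators are
bit-reproducible for a fixed seed.

What the toy pump does **not** emulate: internal domain flexibility,
correlated loop motion, crystal-contact distortions, isoform sequence
differences, or real side chains. Passing the synthetic suite therefore
demonstrates that the estimators are exact on rigid-body input; it does
not by itself validate conclusions about flexible regions of real
structures.

## Numerical choices

- Rotation operators are validated orthonormal to 1e-10 with det +1.
- The 180° rotation axis falls back to the +1-eigenvector of (R + Rᵀ)/2;
  the identity returns a conventional +z axis with angle 0.
- Collinearity in superposition is detected via the second singular value
  (≤ 1e-8 relative).
- RMSD matrices are validated symmetric with zero diagonal; clustering is
  deterministic under input permutation up to label renaming.
- Pipeline TSVs are written atomically (tmp + rename) with fixed float
  formatting, so re-runs with identical inputs are byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
structures: helices of 15–25 residues (one 200-residue helix for the
noise-statistic check), toy pumps of four 25–40-residue blocks, ensembles
of up to six structures, and random distance matrices of up to 10 entries
for the clustering oracle. These sizes were chosen as the smallest at
which every estimator's behaviour is distinguishable from its failure
modes; the operations scale to the full 994-residue pump and the ~74-entry
corpus without modification (the matrix step is O(n²) Kabsch fits of
~4000-atom selections).

## Known limitations

- Corpus analyses require the user to supply the crystal structures and
  the reference sequence; the package ships only the manifest metadata
  established in the corpus literature (reference, exclusions, regulatory
  complexes, isoform entries), not the full deposited list.
- The bending estimator is biased low for kinks far from the chain
  midpoint (see above).
- The mini-DSSP implements only the α-helix pattern and isolated bridges;
  3₁₀/π helices reduce to C, which slightly lowers helicity fractions at
  helix termini relative to a full DSSP.
- Cluster naming beyond C1 follows input order, not biochemical state;
  pipeline users control semantics via manifest ordering.
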