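# Methods

## Binding-site definition

The site is defined structurally, not by annotation: every residue of the
protein with at least one heavy (non-hydrogen, non-deuterium) atom within a
cutoff distance of any heavy atom of the bound ligand. The default cutoff is
5.0 Å and the comparison is inclusive (≤), so a residue exactly at the cutoff
belongs to the site; the rule is tolerance-free and documented rather than
fuzzy. Hydrogens are ignored on both sides — deposited structures at the
relevant resolutions carry none — and contacts are searched on the ligand's
own chain by default so that a pocket on one subunit of a hetero-oligomer is
not padded with neighbouring-chain residues. Residues are identified by
author (PDB) numbering throughout, matching the numbering convention of the
ligand-bound β-tubulin reference structure; mapping from structure numbering
to alignment columns goes through a named reference row, counting its
non-gap positions from a configurable offset.

For the bundled dataset the site comprises 22 residues, of which 8 are
strictly conserved across the 125 sequences (27, 217, 230, 237, 274, 275,
320, 360) and 14 vary; the bundled strings cover the 14 variable positions.
The residue-number annotation of those 14 columns is
22, 23, 26, 226, 229, 233, 236, 272, 276, 277, 278, 369, 370, 371: positions
23, 26, 229, 233, 272, 277 and 278 are fixed by the mutational record the
dataset annotates (the yeast resistance mutations and the isotype
differences), the remainder are the best structural annotation of the other
variable contact-shell positions. Only columns 23, 26 and 277 carry
assertions in the test suite; the other labels are descriptive.

## One-hot sequence-space PCA

Each variable position becomes a 21-channel indicator block (alphabetical
one-letter amino acids, gap last), so M sequences over P positions give an
M × N binary matrix, N = 21·P. The channel covariance uses the unbiased
denominator M − 1 and is diagonalized with a dense symmetric
eigendecomposition. Eigenpairs are sorted by descending eigenvalue; exact
ties break by the ascending channel index of each vector's largest-magnitude
component, and signs follow a largest-component-positive convention, so the
decomposition is bit-reproducible.

Two algebraic consequences of one-hot encoding are enforced as tests rather
than assumed: each position block of the covariance has zero row-sums
(indicator channels within a block sum to 1 for every sequence), hence every
eigenvector with nonzero eigenvalue has zero component-sum per block, and
the rank is at most min(M − 1, N − P).

Projection supports two modes. The centered mode projects a_i − ā (standard
PCA scores, zero-mean by construction); the raw mode projects the binary
vector itself. The two differ by the sequence-independent constant ā·V_k, so
cluster geometry is identical; centered is the default and the pipeline's
group partition is invariant to the choice (the constant is removed before
partitioning when raw mode is selected).

Composition profiles report, for a displacement t along mode k, the
per-(position, letter) deviation t·v_k from the dataset-average composition;
deviations within a position sum to zero for every nonzero-eigenvalue mode,
which is the block-sum property restated.

## Axis orientation and group partition

Eigenvector signs are statistically arbitrary, so both leading axes are
anchored to observable sequence features before interpretation: PC1 is
flipped, if needed, so carriers of the fungal-type marker (Thr at the
position-23 column or Gly at the position-26 column) have positive mean
score, and PC2 so Ser-277 carriers have positive mean score. The features
are configuration, not hard-coded residue numbers, so the pipeline applies
to other binding sites.

The partition into groups A–D was a genuinely open design point. A literal
quadrant rule about the origin is implemented (`assign_quadrant`, with
on-axis points taking the non-negative side and flagged), but it cannot
reproduce the four observed clusters on the bundled data: the drug-sensitive
majority cluster surrounds the centered origin by construction (centered
scores are zero-mean and that cluster dominates the mean), and the raw-score
origin sits inside the cluster cloud as well. The observed structure is four
well-separated clusters arranged quadrant-fashion around a crosshair that is
not the origin. The default partition is therefore a deterministic
feature-seeded nearest-centroid clustering: initial centroids are the means
of the four cells of the 2×2 presence/absence table of the two marker
features (A = both markers, B = PC1 marker only, C = PC2 marker only,
D = neither), refined by Lloyd iterations to convergence. Seeding encodes
the biological meaning of the quadrants; the refinement lets a sequence
whose remaining substitutions dominate its position join its geometric
cluster rather than its marker cell (e.g. a Ser-277 carrier whose many other
fungal-type changes place it with the yeast-like group). On the bundled data
the iteration converges immediately and reproduces the curated group labels
except for one row of the duplicated *Lentinus sajor-caju* pair, which
appears twice with the same string but conflicting labels, so at most one
copy can ever match; both copies are retained and flagged as a known data
inconsistency.

Out-of-sample sequences (the human isotype panel, excluded from the default
fit) are placed by nearest group in per-group standardized distance: each
group contributes its mean and per-axis standard deviation (floored at 5% of
the global training spread so tiny groups remain usable), and a point joins
the group minimizing the standardized Euclidean distance. Plain Euclidean
nearest-centroid is also provided, but it misplaces the one-substitution
βIII isotype: βIII sits midway between the tight sensitive cluster and the
broad Ala-277 composite group, and the variance-blind metric hands it to the
tight cluster, whereas scale-aware assignment recognizes that a broad group
should claim a moderately displaced point. With the scaled metric the panel
lands as expected: isotypes I, IIa, IIb, IVa, IVb, V with the sensitive
cluster, βIII with the Ala-277 group, βVI with the yeast-like group.

## Sequence logos

Per column, letter frequencies are computed over amino acids only (gaps are
excluded from the distribution but reported as a gap fraction), information
content is log2(20) minus the column's Shannon entropy in bits, and letter
heights apportion the information by frequency. The optional small-sample
correction subtracts 19/(2·ln2·n) with n the column's non-gap count; it is
off by default since the per-family sample sizes (28–38) make it minor.
All-gap columns yield undefined (NaN) information with a warning rather than
a silent zero. Majority-letter transitions between two groups are reported
per column and ranked by the product of the two majority frequencies, so
near-fixed differences rank first.

## Structural geometry

All geometric operators work on heavy atoms only and output distances,
angles and booleans — no energies, docking or dynamics. Criteria and
defaults, all configurable:

* **Hydrogen bond:** donor–acceptor (N/O) distance ≤ 3.5 Å and
  antecedent–donor–acceptor angle ≥ 120°, where the antecedent is the
  donor's nearest heavy atom in its own residue. Hydrogen-free by design.
  Same-residue pairs and sub-2.2 Å (covalent-range) pairs are never
  reported.
* **Salt bridge:** any charged-nitrogen (Lys NZ, Arg NE/NH*, His ND1/NE2)
  to carboxylate-oxygen (Glu OE*, Asp OD*) distance ≤ 4.0 Å.
* **Hydrophobic staple:** three residues whose pairwise minimum side-chain
  carbon–carbon distances are all ≤ 5.0 Å.
* **Helix backbone:** O(i)···N(i+4) ≤ 3.5 Å with carbonyl angle
  C(i)–O(i)–N(i+4) ≥ 120°; residues with missing backbone atoms yield
  missing-flagged entries, not failures.

In-silico mutation replaces a side chain with idealized geometry built on
the untouched backbone (backbone coordinates are bit-identical before and
after). The original CB is kept when present; shortening mutations truncate
and rename. The first side-chain dihedral χ1 is preserved where the target
type supports it, measured to the type's canonical γ atom, with −60°
(the most common rotamer) as the fallback. Distal dihedrals are fixed at
ideal anti/planar values: only χ1 is a free variable, and the χ1 scan
(default −60°/60°/180°) rebuilds the side chain at each requested angle.
Bond lengths and angles come from a small internal template table of
standard values; aromatic rings and proline are not rebuildable (ring
closure needs more than a χ1 scan) and are rejected explicitly. Atom
placement uses the natural-extension reference frame construction, verified
against independent dihedral/angle measurement.

## Synthetic data

The alignment generator emulates the statistical structure of the
binding-site dataset: a consensus string, *modes* — sets of position
substitutions toggled jointly per sequence with a Bernoulli probability —
and independent per-position background substitution noise. The default
study configuration mirrors the two real axes on the 14-position consensus
of the sensitive majority: a two-position co-varying mode (T at the 23
column, G at the 26 column) and a one-position mode (A at the 277 column),
each toggled with probability 0.5, n = 200 sequences, zero noise unless
requested. Ground-truth mode membership accompanies every draw. All
randomness flows through the seed in the specification; there is no global
random state.

What the generator does *not* emulate: phylogenetic correlation between
sequences (draws are exchangeable), position-specific substitution
preferences, and indel processes beyond a fixed consensus gap. The
covariance PCA itself treats sequences as exchangeable, so tests passing on
this generator show the estimator recovers planted covariance structure —
they do not show robustness to tree-structured sampling bias in real data.

Structure fixtures are minimal valid PDB models with planted geometry:
a one-atom ligand with single-atom residues at exact radii (contact shell),
ideal polypeptides at fixed (φ, ψ) — α-helix at (−57°, −47°), extended chain
at (180°, 180°) — a donor–acceptor pair at an exact distance and antecedent
angle, and a three-residue staple triangle with exact pairwise side-chain
distances (triangle inequality enforced). Written PDB text re-parses to the
same coordinates within the format's 10⁻³ Å precision.

## Problem sizes and determinism

The bundled analysis is small by construction (125 sequences × 294
channels); a full reproduction run, including logos and composition
profiles, completes in well under a second, and the synthetic recovery
studies use n = 200 sequences with 5 replicate seeds. Reruns with the same
configuration are byte-identical, and the run manifest (configuration,
package and numpy versions, eigenvalue head, applied axis flips, group
sizes) suffices to re-execute a run exactly.

## Known limitations

* The group partition is defined in the two leading modes only; sequences
  whose variation lives in lower modes (e.g. the position-369/370/371
  channels dominating PC3/PC4) are partitioned by their PC1/PC2 shadow.
* The geometry operators state possibilities, not energetics: a detected
  rotamer-dependent hydrogen bond is a geometric fact about an idealized
  side chain, not a free-energy claim.
* χ2 and beyond are never scanned; conclusions about long side chains
  (Lys, Arg) depend on ideal anti conformations of the distal dihedrals.
* The duplicated *Lentinus sajor-caju* row and its conflicting labels are
  preserved as published; consumers should treat that organism's group as
  ambiguous.
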