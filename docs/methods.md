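# Methods

This note records the models, conventions, and design choices behind
`ohecc`, in the spirit of a package methods appendix.  Nothing here states a
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Representations

**OHECC.**  A molecule of `n ≤ max_atoms` atoms over an ordered element
vocabulary `V` maps to a `max_atoms × (3 + |V|)` matrix: row *i* holds the
atom's Cartesian coordinates (Å) followed by its one-hot element indicator;
rows `n … max_atoms−1` are zero.  Defaults: `max_atoms = 27`,
`V = (H, C, N, O, F)`, giving the flat 216-vector used by every classifier.
Coordinates are used exactly as supplied — no centering, scaling or
re-ordering — because the encoding's value lies precisely in preserving the
absolute arrangement of atoms; atom order is input order throughout.
Changing the vocabulary changes the feature width and is never done
silently.

**Coulomb matrix.**  `M_ii = 0.5 Z_i^2.4`, `M_ij = Z_i Z_j / d_ij` with
distances in Å.  The matrix is used here purely as a representation (no
energy semantics), so no unit conversion, row sorting or eigenspectrum
canonicalization is applied; a sorted-eigenvalue helper exists for
atom-order-robust comparisons.  Atoms closer than `min_distance = 1e−6` Å
are rejected rather than allowed to blow up the entry.  Because every entry
is a function of distances and charges only, the matrix is invariant under
all isometries including reflection — two enantiomers with the same atom
order have *identical* Coulomb matrices, which is the degeneracy the OHECC
representation exists to break.

## Stereocenter labeling

Full CIP perception (isotopes, duplicated atoms for multiple bonds, rules
4/5) is deliberately not implemented; the labeler targets the acyclic
H/C/N/O/F substituents produced by the synthetic generator, for which CIP
rule 1 suffices.

*Ranking.*  For each of the four neighbors of a degree-4 atom, the branch is
explored breadth-first away from the center (depth cap 6); sphere *d* is
the multiset of atomic numbers at graph distance *d*, sorted descending.
Branches are compared sphere by sphere, lexicographically, shorter spheres
padded with phantom zeros.  If two branches agree at every compared sphere,
a tie is flagged and the atom is not a stereocenter.

*Handedness.*  With u₁, u₂, u₃ the vectors from the center to the
priority-1, 2, 3 neighbors, the signed volume s = u₁·(u₂×u₃) is computed;
|s| < 1e−6 Å³ is treated as degenerate (near-coplanar) geometry.  The sign
convention — **s < 0 ⇔ R** — was fixed once by cross-checking against
RDKit's `AssignStereochemistryFrom3D` on reference centers covering all 24
assignments of four prioritized substituents to tetrahedron vertices under
random rotations; the test suite re-runs that cross-check, so the constant
can never silently drift.  Reflection flips every label and proper rigid
motions preserve them; swapping any two priorities flips the label (odd
permutation property).

## Synthetic molecules

The generator emulates the *structure* of quantum-chemistry benchmark inputs
— ≤ 27 atoms over {H,C,N,O,F}, 0–4 tetrahedral stereocenters, enantiomer
pairs, a signed rotation label — with idealized geometry and no energetics.

Each stereocenter is a carbon whose four branches begin with four different
elements: F, an oxygen branch, a nitrogen branch, and a carbon-or-hydrogen
branch.  Priority is therefore settled at the first sphere, ties are
impossible by construction, and the intended R/S label is realized purely by
which tetrahedron vertex each branch occupies (one transposition flips the
handedness).  Multi-center molecules are chains of such carbons joined by
alternating −O− and −NH− bridges, so interior centers keep four distinct
first atoms; terminal centers receive OH/NH₂ instead.  The fourth branch is
drawn from {H, CH₃, CH₂F, CH₂OH} within the 27-atom budget.  Bond lengths
are standard single-bond values, branch placement uses exact tetrahedral
directions plus Gaussian jitter (default sd 0.02 Å; redrawn in the rare case
it degrades a signed volume below 1e−4 Å³ or flips a label, so the
construction labels remain ground truth).  Achiral molecules are built from
center templates with a repeated substituent.

**Orientation.**  After construction each molecule receives a random proper
rotation and a random translation (uniform in ±5 Å), and is then, by
default, re-expressed in a *standard orientation*: charge-weighted centroid
at the origin, principal axes of the nuclear charge second-moment tensor
along x/y/z (largest spread first), axis signs fixed by the third charge
moment (first-atom fallback), and the z axis taken as x × y so the transform
is always a proper rotation and chirality is untouched.  This emulates how
quantum-chemistry programs print optimized geometries: the real datasets
this generator stands in for are canonically oriented by the electronic
structure code, not randomly posed, and that shared frame is what makes raw
Cartesian features comparable across molecules.  It matters empirically: on
the single-center handedness task a random forest reaches ≈ 0.99 test
accuracy in standard orientation, but is at chance under uniformly random
poses, because sign-of-volume functions over a rotation manifold are
pathological for axis-aligned tree splits.  `orientation="random"` retains
the random pose for invariance studies.  Consequently, results on this
generator speak to canonically oriented geometries only.

**Surrogate rotation.**  α̃ = Σₖ sₖ wₖ + ε with sₖ = +1 for R and −1 for S,
default weights (10, 6, 3.5, 2) — chosen so that no ± combination cancels
to zero, hence the sign is always configuration-determined at zero noise —
and ε ~ N(0, noise_sd²), default noise_sd 1.0 (degree-like arbitrary
units).  Achiral molecules get pure noise (exactly 0 at zero noise).  For
archive export the 589.3 nm value is scaled by 2.8 at 355 nm and 0.85 at
633 nm, a crude normal-dispersion shape.  The surrogate captures *sign
determined by configuration* and nothing else: no magnitude physics, no
conformational effects, no near-resonance outliers.  Passing tests on it
demonstrate that the pipeline can recover configuration-determined signal
from OHECC features, not that real optical rotations are this learnable.

## Tasks, balancing, splitting

Six tasks are built from records: existence ({0} vs {≥1}), 0-vs-1 centers,
(R)-vs-(S) within single-center molecules, rotation sign at 589.3 nm
(single-center and all-molecule variants), and 0–4 center counting.  Classes
are declared in a fixed order and the *first-listed* class ({0}, (R), "−")
is the positive class everywhere.  Each class is downsampled without
replacement to `per_class` (shortfalls are an error naming the deficit),
then split 80–20.  The split is stratified by label — the balanced pool
stays balanced in both folds; this is an assumption, chosen because nothing
about the procedure suggests otherwise and it removes a source of variance.
The (R)-vs-(S) task is balanced by downsampling like the others (also an
assumption).  Records with an exactly zero rotation value carry no sign and
are excluded from the sign tasks with a log record.  Molecules with ≤ 17
atoms count as "small" in the size partition; the boundary is exposed as a
parameter.  Sampling and splitting run under `numpy.random.default_rng(seed)`,
so membership is exactly reproducible.

The OR-QM9-style archive reader is schema-driven: a small YAML manifest maps
record fields (index, InChI, OHECC row, center count/locations/labels,
rotations × wavelength) to NPZ array names, since deposited archives differ
in internal naming.  The package's own writer emits the same layout, so the
reader is fully exercised offline; deposited center counts are consumed as
data, never recomputed.

## Models

* **rf** — `RandomForestClassifier` with `min_samples_leaf=2`,
  `max_features="sqrt"`; desk scale 300 trees of depth 50, paper scale
  1200–1800 trees of depth 100–420 per task (`configs/table2_rf.yaml`).
  The ensemble prediction is the majority vote of the trees;
  `majority_vote()` recomputes it from the individual trees and the test
  suite checks it against the library's aggregation.
* **xgb** — `XGBClassifier` with `max_depth=20`; per-task η (0.13 for the
  single-center sign task, 0.1 plus error-rate eval metric for the
  all-molecule sign task) in `configs/table3_xgb.yaml`; histogram tree
  method, single thread.
* **ann** — a feed-forward network 216 → 500 → 200 → softmax with
  cross-entropy loss, implemented with scikit-learn's `MLPClassifier`
  (ReLU, Adam at 1e−3, patience-based stopping on a 10% validation split,
  epoch cap 300 desk / 10,000 paper scale).  Regularization uses L2 weight
  decay in place of per-layer dropout, which the MLP implementation does not
  expose; given the small capacity gap this is the closest available
  realization of the published architecture and is flagged as such.
  Weight initialization and learning-rate schedule follow the library
  defaults and are not claimed to match the original runs.

All three families train single-threaded with a fixed seed and give
identical predictions on identical inputs.  Labels are label-encoded
internally and decoded on the way out.

## Metrics

Confusion matrices are stored and printed with **rows = predicted, columns
= true**.  With positive class index *p*: accuracy = trace/total (any k);
precision = `cm[p,p]` / row-*p* sum; recall = `cm[p,p]` / column-*p* sum;
F1 = harmonic mean — binary matrices only.  This first-listed-positive,
rows-predicted convention is the unique one under which the published
reference tables are mutually consistent, and it is the opposite of the
common "positive = second class" habit, hence stated on every report.
Zero denominators yield an explicit NaN with a warning.  Full precision is
kept internally; table output rounds half-to-even at 3 decimals.  Two cells
of the published metric rows disagree with their own matrices by exactly one
unit in the third decimal (double-rounding slips); the tests assert the
matrix-derived values and record the printed variants.  One published
(R)-vs-(S) matrix is internally inconsistent (its total disagrees with every
other study of the same molecule set) and is excluded from reproduction
rather than reconciled.

## Distribution statistics

`describe()` removes values with |z| > z_cut (default 3) in a single pass —
z-scores come from the unfiltered mean and population sd, so the result is
order-independent and not iterative — then reports mean, sample sd
(ddof=1), skewness, and *excess* (Fisher) kurtosis, the convention inferred
from the near-0/1 values the reference summaries show for near-normal
classes.  At least 4 survivors are required (kurtosis); zero post-filter
variance is an error.  On a |z| ≤ 3 truncated standard normal the closed
form gives sd ≈ 0.9866 and negative excess kurtosis, which the seeded
100,000-sample check reproduces.  `outlier_census()` reports the fraction
of |values| beyond a threshold (default 1000°) and the maximum magnitude.
`label_sign_correlation()` encodes R/S as ±1, reduces rotations to their
sign (exact zeros excluded, logged), and returns the Pearson r with the
standard two-sided non-correlation p-value.  Reproducing the reference
moment tables verbatim requires the deposited rotation data and is wired as
a CLI path, not a unit test.

## Problem sizes and determinism

Default experiment sizes — 100 enantiomer pairs, 1000 stereo round trips,
2000 molecules for the handedness benchmark, 100,000 draws for the moment
checks, a 46,000-record build for the task arithmetic — were chosen so the
whole suite and the acceptance script each complete in well under a minute
on a single CPU while keeping Monte-Carlo noise far below the asserted
margins.  Every stochastic path takes an explicit seed; the CLI refuses to
run stochastic subcommands without one and writes a manifest (arguments,
seed, library versions) next to each output.

## Known limitations

* The stereo labeler is not full CIP: rings, isotopes, multiple bonds, and
  like-element first spheres with deep ties are out of scope; on inputs
  outside the generator's vocabulary it may flag ties where CIP would
  resolve.  Non-tetrahedral (intrinsic/axial) chirality is not detected.
* Synthetic geometry is idealized; bond lengths and angles are plausible
  but not relaxed, and steric clashes between distant branches are not
  prevented (they are irrelevant to the representations tested).
* Learnability results depend on the standard-orientation convention (see
  above); they do not transfer to randomly posed point clouds.
* The surrogate rotation is a linear signed sum, far simpler than any
  physical rotation model; magnitude statistics of real data (heavy tails,
  near-resonance outliers) are emulated only qualitatively.
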