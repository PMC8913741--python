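# Methods

This note records the scientific conventions, numerical choices and
known limitations behind each part of the toolkit.

## Alignment handling

a3m files are normalized at parse time: lowercase letters and `.`
(insertion states relative to the query) are deleted, so every row of a
loaded MSA has exactly the query length. Organism identity is the NCBI
taxon in a UniProt-style `OX=<digits>` header token; rows without one
are excluded from pairing (they cannot be matched across chains).

**Gap filtering.** Hits with *more than* 90% gaps are dropped before
pairing (strict inequality; a row at exactly 90% is kept). The query
row is always retained regardless of its gap content, because it
defines the column coordinate system every downstream operation relies
on.

**Pairing.** "Best hit per organism" means lowest row index in the
source a3m: HHblits writes hits in E-value order, so file order is hit
rank. For each organism present in both chains' alignments exactly one
concatenated row is emitted — the best A-hit joined to the best B-hit —
and the query pair is row 0. One pair per organism is a deliberate
choice; matching k-th hit to k-th hit within an organism is a known
variant and out of scope.

**Block diagonalization** pads every non-query row of chain A with L_B
gaps on the right and every non-query row of chain B with L_A gaps on
the left. The construction conserves residue content exactly, which the
tests check as an invariant.

**Neff** is the cluster count from greedy single-pass clustering at 62%
identity with 90% coverage of the shorter sequence, the conventional
depth estimate for coevolution-bearing alignments. Unlike CD-HIT, which
realigns unaligned FASTA and accelerates candidate search with a word
filter, identity here is computed directly on the already-aligned rows
over columns where both sequences are non-gap, and coverage is shared
non-gap columns divided by the shorter ungapped length. This is
deterministic and dependency-free; the word-size heuristic is an
accelerator, not a different definition, and is not reproduced. Rows
are processed longest-first (stable for ties) and join the
first-founded matching cluster. Note that appending a row can in
principle *bridge* two clusters and is therefore not guaranteed to be
monotone in cluster count; in practice, on the random alignments in the
test suite, monotonicity holds and is checked at fixed seeds.

## Structures and interface metrics

PDB input is read through Bio.PDB: first MODEL only, waters and
heteroatoms skipped, alternate locations resolved to the
highest-occupancy conformer, insertion codes kept as part of residue
identity, numbering gaps (including the large inter-chain offsets some
prediction pipelines insert) tolerated. Per-residue plDDT is read from
the B-factor column.

The interface is defined on Cβ atoms at 8 Å. Residues without a
deposited Cβ (glycine foremost) get a **virtual Cβ** from ideal
backbone geometry (the standard N/CA/C cross-product construction),
falling back to CA when backbone atoms are missing; `strict=True`
excludes such residues instead, for workflows that reject Cβ-less
inputs outright. Contacts are unordered residue pairs counted once, and
`IF_residues` sums interface residues over both chains. When a model
has no inter-chain contact at all, the interface confidence average is
undefined; it is carried as 0.0 with an explicit `empty_interface`
flag.

## pDockQ

The combined statistic is x = IF_plDDT · log(IF_contacts). The log base
defaults to 10 and is configurable (10 or e); base 10 is consistent
with the default midpoint x0 ≈ 153 given IF_plDDT ∈ [0, 100] and
typical contact counts of 10–1000, and the chosen base is recorded in
all serialized parameter files. A zero-contact model scores pDockQ =
0.0 rather than the sigmoid floor b: no predicted interface is treated
as an explicit non-interactor signal, which is what makes pDockQ usable
for interacting-vs-non-interacting discrimination.

**Re-fitting** uses trust-region-reflective nonlinear least squares,
initialised at L = max(DockQ), x0 = median(x), k = 0.05,
b = min(DockQ), bounded to L ∈ (0, 1.5], k ∈ (0, 1], b ∈ [0, 0.5]
(x0 effectively unbounded), with step/function tolerances of 1e-12 —
tight enough that noiseless synthetic data recovers generator
parameters to 1e-6. Constant-DockQ, constant-x or sub-8-point inputs
raise rather than return a meaningless fit, and the result carries the
mean absolute residual so calibration quality is visible.

## DockQ

The three CAPRI components are combined with the standard scale
constants 1.5 Å (iRMS) and 8.5 Å (LRMS); the acceptability threshold is
DockQ ≥ 0.23. Conventions:

- **Contacts (Fnat)**: residue pairs from different chains with any
  supplied-atom distance ≤ 5 Å. Supplied atoms are backbone N, CA, C
  plus Cβ, because end-to-end predictors emit backbone-only models; this
  is a documented approximation to the all-heavy-atom definition of the
  reference implementation, so exact numeric parity with it on
  full-atom structures is not a goal.
- **iRMS**: native interface residues are those in any 10 Å residue
  pair; the model is superposed onto the native over the backbone atoms
  of those residues and the RMSD of that superposition is iRMS.
- **LRMS**: the receptor is the chain with more residues (ties: chain
  A); the model is superposed on the native receptor backbone and LRMS
  is the resulting RMSD over the ligand backbone.
- Model and native must have identical residue sets per chain
  (renumber beforehand if needed); mismatches raise with the offending
  residues listed. A native without inter-chain contacts is unscorable
  and raises.

Superposition is classical Kabsch (via SVD) with a proper-rotation
guarantee, and requires ≥ 3 non-collinear points.

## Evaluation statistics

A score ≥ threshold is a positive call (boundary inclusive, matching
the ≥ 0.23 success-rate convention). ROC curves sweep all observed
score values; AUC is trapezoidal, which on tie-free data equals the
Mann–Whitney concordant-pair probability — the test suite checks that
equivalence against a brute-force pair count. Operating points
(`tpr_at_fpr`) use conservative step interpolation: the reported TPR at
an FPR budget is one an actual threshold achieves, never an
interpolated optimistic value. Rates with zero denominators are NaN
rather than silently 0.

Coupling-signal precision takes an |A| × |B| inter-chain coupling
matrix (e.g. DCA output — the inference itself is out of scope, the
matrix is consumed as data), selects the N highest cells where N is the
number of true interface contacts, breaking ties deterministically in
row-major order, and reports the fraction that are true contacts. The
measure is invariant under any strictly monotone transform of the
couplings.

DSSP 8-state annotation collapses to three classes — helix (H, G, I),
sheet (E, B), loop (everything else, including T, S, C, P and blanks) —
and an interface is labelled by residue majority, with ties resolved
toward the more structured class (helix > sheet > loop). Tertile
binning splits at the 1/3 and 2/3 empirical quantiles (values equal to
a boundary fall into the lower bin); a constant list collapses into one
bin and is flagged degenerate.

## Synthetic fixtures

The generators trade realism for provability:

- **Toy complexes** place chains on a 4 Å lattice with a 7.5 Å
  inter-chain gap so that an all-pairs Cβ scan yields *exactly* the
  planted number of 8 Å contacts (diagonal neighbours sit at 8.5 Å),
  and dip chain B's backbone N atoms so each planted pair also carries
  exactly one sub-5 Å atom contact for DockQ's native-contact set.
  plDDT profiles are per-chain Gaussian draws clipped to [0, 100].
  Identical specs produce byte-identical files.
- **Decoy series** rigidly translate the ligand chain along +z; offset
  0 returns the native bytes, and DockQ is non-increasing along the
  series.
- **Toy MSA pairs** mutate a random query at 15% per position with 5%
  gap injection and stamp `OX=` tokens from the supplied organism
  lists; the expected pairing count is emitted alongside.
- **Sigmoid datasets** draw x uniformly (default [50, 250]) and add
  Gaussian noise to the sigmoid value, truncated to [0, 1] by
  *clipping*: DockQ is a bounded score, and saturation at the bounds is
  how bounded measurements behave. Clipping has a consequence worth
  knowing: near the low end of the x range the curve sits near b ≈
  0.02, negative noise excursions pile up at 0, and the conditional
  mean of the observed score rises by roughly σ·φ(µ/σ) ≈ 0.03 at σ =
  0.1. Plain least squares absorbs that into the baseline, so recovered
  b is biased upward by ~0.03 (with a compensating downward bias in L)
  under the default noise level. This is a property of fitting clipped
  data, not of the optimizer; rejection-sampling truncation would
  roughly double the low-tail bias.

None of the generators attempt realistic protein geometry, sequence
evolution or predictor error modes, so passing tests demonstrate
correctness of the *calculus* (contacts, scores, rates, fits), not
predictive performance on real complexes.

## Problem sizes and defaults

The reference parameter-recovery experiment uses n = 1481 points per
fit and 20 seeds — the benchmark-scale sample size for this kind of
calibration — and completes in seconds. Random-oracle suites use up to
100 instances with n ≤ 200 (ROC) and point clouds of ≤ 15 residues per
chain (interfaces), sizes at which the brute-force oracles are exact
and instantaneous.

The CLI's default interaction-call threshold (pDockQ ≥ 0.5) is an
uncalibrated placeholder: operating points, not a single universal
threshold, are what the score supports. Calibrate on labelled data
(e.g. maximize Youden's J on an ROC curve from `ppikit roc`) before
interpreting the binary calls.
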