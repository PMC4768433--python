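# Methods

This note records the mathematical definitions, conventions and design
choices behind `nlamd`, in the order of the computation pipeline.

## Pairwise metrics (codes M1–M16)

All pairwise metrics act on the Cartesian coordinate triples (h = 3) of
two atoms X, Y:

- **Minkowski (M1–M7)**: `(Σ_j |x_j − y_j|^p)^{1/p}` with p fixed per code
  at 0.25, 0.5, 1 (Manhattan), 1.5, 2 (Euclidean), 2.5, 3; any of the seven
  exponents can also be requested explicitly on any of these codes.
- **Chebyshev (M8)**: `max_j |x_j − y_j|`, the p → ∞ Minkowski limit (a
  test asserts the monotone approach of M3/M5/M7 toward M8).
- **Canberra (M10)**: `Σ_j |x_j − y_j| / (|x_j| + |y_j|)`; range [0, 3].
- **Bray–Curtis (M11)**: `Σ|x_j − y_j| / Σ(|x_j| + |y_j|)`.
- **Clark (M12)**: `sqrt(Σ ((x_j − y_j)/(|x_j| + |y_j|))²)`.
- **Soergel (M13)**: `Σ |x_j − y_j| / max{x_j, y_j}`. A 1/n-prefactor
  variant exists in parts of the literature, but published example matrices
  contain entries above 1, which is inconsistent with that factor; the
  default therefore omits it and a flag restores it.
- **Bhattacharyya (M14)**: `sqrt(Σ (√x_j − √y_j)²)`; requires non-negative
  coordinates. Policy `strict` (default) raises on negative input; policy
  `shift` translates both points by the common minimum first.
- **Wave–Edges (M15)**: `Σ (1 − min{x_j,y_j}/max{x_j,y_j})`.
- **Angular separation (M16)**: `1 − cos(X, Y)`; range [0, 2].

Terms with a zero denominator contribute 0 (continuity convention),
including the all-zero-vector case of M16. Codes M9, M17, M18 are
unassigned. M10–M16 operate on *raw coordinates*, so they are **not**
rigid-motion invariant; the default origin policy uses the file
coordinates unchanged, and the tests assert the documented
frame-dependence rather than hiding it. Per-metric "average" and "range"
normalizations described alongside these metrics in the literature are
documented here but deliberately not applied in descriptor computation.

## Ternary and quaternary measures (M19–M30)

- Perimeter (M19/M20) and sides summation (M25/M26) are defined for both
  triples and quadruples and accept any pairwise metric as the side
  length; triangle area (M21/M22) uses Heron's formula with the radicand
  clipped at 0 for near-collinear triples.
- The bond angle (M27/M28) of the tensor entry `gt_ijl` has its **vertex at
  the leading (row) atom i** and ends j, l; this convention is fixed by the
  published example tensor, whose entries match the law-of-cosines values
  of the vertex-at-i angle. Degenerate triples (coincident vertex/end)
  return 0.
- Volume (M23/M24) is `|det[r_b − r_a, r_c − r_a, r_d − r_a]| / 6`; the
  absolute value makes the measure independent of the arbitrary sign of
  the atom enumeration.
- The dihedral (M29/M30) of tuple (a, b, c, d) is the angle between the
  normals of planes (a, b, c) and (d, b, c); collinear plane atoms give a
  zero normal and a 0 return.

Paired codes are implemented as one measure selectable for either arity
where mathematically defined.

## Tensor pipeline

Order of operations (fixed): build the non-stochastic k = 1 tensor →
optional fragment projection → probabilistic transform → Hadamard power k
→ atom-level split. Entries with any repeated atom index are zero.
Descriptors are computed on hydrogen-suppressed structures by default
(the hydrogen counts of heavy atoms are retained for fragment perception);
a flag re-includes hydrogens.

- **Fragment projection**: weight 1 when all participating atoms are in
  the fragment, 1/2 when at least one but not all, 0 otherwise. This rule
  reproduces the published fragment-projected matrices exactly.
- **Simple-stochastic**: each leading-index slice (the row at order 2, the
  (j,l)/(j,l,h) block at orders 3/4) is divided by its sum; all-zero
  slices stay zero. The generalization to orders 3/4 — normalize over all
  trailing indices per fixed leading index — is an interpretation chosen
  because it reduces to row-normalization at order 2.
- **Double-stochastic** (order 2 only): Sinkhorn–Knopp scaling
  `D_r A D_c`, with the two scaling vectors geometrically averaged each
  sweep when the input is symmetric so the output is symmetric to machine
  precision. Defaults: tolerance 1e−8 on every row/column sum, 10,000
  iterations, non-convergence raises naming the residual slack.
- **Mutual probability**: divide by the grand total; the all-zero tensor
  is returned unchanged.
- **Hadamard power**: k ∈ ±1..±12; negative k is the |k|-th power of the
  entrywise reciprocal with 0 ↦ 0, keeping the sparsity pattern and
  avoiding infinities. The power is applied after the probabilistic
  transform of the k = 1 tensor; the reverse order is conceivable but the
  adopted order follows the staged workflow exactly.
- **Atom-level split**: atom a's tensor retains entries with ≥ 1 index
  equal to a (any-index rule at every order, generalizing the row+column
  rule of matrices).

## Contraction and aggregation

`L_a` is the sum of the atom-a split tensor times the product of property
components over indices. It is computed by inclusion–exclusion over which
index positions equal `a` (einsum diagonal sums), which is algebraically
identical to splitting and contracting per atom but avoids n extra
tensors; a brute-force index-loop oracle pins the equivalence at 1e−10.

Aggregation operators over L (n = number of atoms):

| id | definition |
|----|------------|
| N1 | Σ |L_a| |
| N2 | sqrt(Σ L_a²) |
| N3 | (Σ |L_a|³)^{1/3} |
| ES | Σ L_a |
| AM | mean |
| GM | geometric mean of |L_a|, 0 if any entry is 0 |
| P  | sign-preserving geometric mean: (Π sign L_a) · GM |
| SD / V | sample standard deviation / variance (ddof = 1), 0 when n < 2 |
| S / K | bias-corrected skewness / excess kurtosis, 0 when undefined |
| RA | max − min |
| i50 | median |
| MX / MN | max / min |
| PN | Σ of negative entries |
| AC[k] | lag-k autocorrelation of L in atom order; 0 for zero variance |
| TS[k] | Σ L_a · L_{a+k} |
| GV[k] | Σ_{|a−b|=k} L_a L_b / d_ab² with Euclidean d |

Chains of two operators are allowed when the first is a lag operator: it
produces the lag profile over lags 1..k and the second (scalar) operator
is applied to that profile, e.g. `AC[3]_K`. Lag operators use input-file
atom order, which is documented as part of the descriptor definition;
order-free operators are tested for permutation invariance. These operator
definitions are fixed by this package's documentation; other descriptor
software may use the same ids for different formulas.

Descriptor names follow the bijective grammar
`STATEk-OPCHAIN-FORM[props]-METRIC[-FRAGMENT]` with FORM ∈ {B, Tr, Qu} by
order, quadratic forms written as repeated properties (`B[m,m]`), linear
forms with the unit property (`B[m,u]`), negative powers as `n2` etc.;
parsing round-trips and an injectivity sweep is tested.

## Atomic properties

Element-keyed tables (mass, electronegativity, Bondi vdW radius → volume,
polarizability, covalent radius, coarse Crippen-style hydrophobicity,
softness, refractivity) ship as a versioned JSON data file so every value
is explicit. Refractivity adds a per-suppressed-hydrogen increment; polar
surface area uses simplified Ertl-style N/O/S contributions keyed on
hydrogen count. Partial charges are never defaulted: they must arrive as a
per-atom SDF annotation (`ATOM_PROP_c`) or via the explicit RDKit
Gasteiger adapter. Implicit hydrogens are counted from a documented
default-valence table (C 4, N 3, O 2, S 2, halogens 1, P 3) adjusted by
formal charge. Aromaticity trusts input aromatic bond flags (order 1.5);
full ring perception is out of scope and an adapter can pre-annotate.

## The reference fixture

The reference molecule (chloro(methoxy)methane, heavy atoms C1, C2, O3,
Cl4) is published as a distance matrix, not coordinates. Coordinates are
recovered by classical multidimensional scaling (eigen-decomposition of
the double-centered Gram form, fixed sign convention, deterministic); the
shipped SDF is therefore labelled *embedded* — synthetic coordinates that
reproduce the known distances to ≤ 0.002 Å. Because the printed distances
carry 3-decimal rounding, derived matrix entries are reproducible to about
±0.002 and angles to about ±0.005 rad; those are the tolerances the tests
use for geometry-derived values, while pure normalization arithmetic is
checked at ±0.0005. The absolute coordinate frame of the original
structure is unrecoverable from distances, so the frame-dependent metric
matrices (M11/M13/M16) are not used as reproduction anchors.

## QSAR workflow

Thinning runs entropy → magnitude → correlation, each a pure function:

1. **Entropy filter**: Shannon entropy (bits) of an equal-width histogram
   per descriptor (bins default = number of molecules); keep the top-k
   (default 1000), ties broken by name.
2. **Magnitude filter**: drop descriptors containing any |value| > 1e5 or
   0 < |value| < 1e−5; exact zeros are retained.
3. **Correlation filter**: drop columns with standardized entropy
   H/log2(bins) < 0.3, then greedily prune |Pearson r| ≥ 0.95 pairs
   keeping the higher-entropy member.

**OLS** is fit with an intercept by least squares; coefficient standard
errors come from the usual covariance formula (an independent statsmodels
fit is the test oracle). **Q²loo** = 1 − PRESS/SS_tot with LOO residuals
from the hat-matrix identity e_i/(1 − h_ii), verified against explicit
refits at 1e−9; a leverage of 1 raises.

**GA selection** is a seeded steady-state GA over descriptor subsets of
size 3–9: population 100; per iteration one offspring by subset crossover
(probability = the reproduction/mutation trade-off, 0.5) or add/remove/swap
mutation, with size repair; the offspring replaces the current worst
individual when fitter (implicit elitism); parent selection is uniformly
random until 80 % of the iterations, then a size-3 tournament (selection
pressure ramp-up). Default budget is 500,000 iterations; the tests and the
acceptance script use 5,000 iterations at n = 60, p = 100, which the
recovery experiments show is ample for the planted-signal conditions and
keeps a 20-run experiment under half a minute.

**Q²boot** resamples n rows with replacement per repetition (default
5000), fits, predicts the out-of-bag rows, and pools squared errors and
squared deviations from each repetition's training mean; degenerate
repetitions are skipped and counted. **Y-scrambling** (default 300
repetitions) permutes y, records the scrambled Q²loo and r =
|corr(y_perm, y)|, and reports a(Q²) as the intercept of the least-squares
line of Q² on r — the r → 0 extrapolation; the mean-of-scrambled-Q²
alternative is available behind a flag. The intercept form is adopted
because reported chance-correlation levels for sound models are uniformly
negative, which is characteristic of the extrapolated intercept. The model
choice score is f = (1 − Q²boot) + |a(Q²)| over the top-50 models by
Q²loo; smallest f wins. **External validation** uses the *training* mean
in the Q²ext denominator, so worse-than-mean prediction scores negative;
SDEP = sqrt(mean squared prediction error). A p-value stepwise
(enter 0.05 / remove 0.10) pre-selector is provided as a convenience.

## Synthetic data: what it emulates and what it does not

`synthetic_regression` plants y = X·β on a known sparse support
(default n = 60 molecules, p = 100 descriptors, β = (2, −1, 0.5), noise at
10 % of the signal sd) inside a table of standard-normal columns with a
few correlated pairs, optional exact duplicates and constants to exercise
the filters; the truth record carries support, β and the achievable R².
It emulates the *dimensionality and collinearity structure* of a thinned
descriptor table, not real descriptor distributions (heavy tails,
discreteness, block correlation from shared configurations) — so passing
recovery tests demonstrates the correctness of the search machinery, not
expected performance on real chemistry. `random_molecule` produces chain
molecules with ≥ 1 Å atom separation in a 10 Å box (halogens/oxygen kept
terminal so valences are chemically readable) for geometry tests, not
realistic conformers.

## Numerical choices and limitations

- Tensors are dense; order-4 construction is refused above 120 atoms
  (n⁴ memory guard).
- Heron radicands and arccos arguments are clipped for numerical safety;
  degenerate geometry returns 0 rather than NaN.
- GA reproducibility is exact under a fixed seed; bootstrap and
  scrambling seeds are derived per candidate model.
- The worked-example tolerances (±0.0005 arithmetic, ±0.002 matrix
  entries, ±0.005 rad angles) are propagated-rounding bounds of the
  3-decimal published values, not fitted numbers.
- Known limitations: no conformer generation (descriptors are only as
  good as the input 3D structures, and models built on one generator's
  geometries need not transfer to another's), no V3000/stereo support,
  simplified aromaticity and PSA perception, no sparse tensor backend,
  and aggregation-operator naming may collide with other software's
  different definitions.
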