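# nlamd — 3D N-linear algebraic molecular descriptors and GA-MLR QSAR

`nlamd` computes alignment-free 3D molecular descriptors built from
N-linear (multi-linear) algebraic forms, and provides the QSAR
model-building workflow that typically surrounds them: descriptor thinning,
genetic-algorithm variable selection for multiple linear regression, and
bootstrap / Y-scrambling / external validation. It is aimed at
cheminformatics practitioners who want interpretable, geometry-derived
descriptors for small-molecule activity modeling without superposing
structures onto a reference.

## The model

For a molecule with `n` atoms and 3D coordinates, order-N *spatial
(dis)similarity tensors* are built over atom tuples:

- order 2: `g_ij = d(r_i, r_j)` for a pairwise metric `d` — the Minkowski
  family at p ∈ {0.25, 0.5, 1, 1.5, 2, 2.5, 3} (codes M1–M7), Chebyshev
  (M8), and the coordinate-wise Canberra, Bray–Curtis, Clark, Soergel,
  Bhattacharyya, Wave–Edges and angular-separation measures (M10–M16);
- order 3: `gt_ijl` from ternary measures — perimeter, triangle area
  (Heron), sides summation, or the bond angle at vertex atom `i` with ends
  `j`, `l` (codes M19–M28);
- order 4: `gq_ijlh` from quaternary measures — perimeter, sides
  summation, tetrahedron volume, dihedral angle (M19–M30).

Entries with repeated atom indices are zero. The non-stochastic (`NS`)
tensor may be projected onto a *local fragment* F (H-bond acceptors A,
aliphatic carbons C, donors D, halogens G, terminal methyls M, aromatic
carbons P, heteroatoms X): entries are kept when all participating atoms
are in F, halved when some are, zeroed when none are. Probabilistic
normalizations give the simple-stochastic (`SS`, unit leading-index
slices), double-stochastic (`DS`, Sinkhorn–Knopp row/column balancing,
matrices only) and mutual-probability (`MP`, unit grand total) forms, each
then raised to a Hadamard (entrywise) power k ∈ ±1..±12.

The descriptor contracts the tensor with atomic-property vectors
(mass `m`, van der Waals volume `v`, polarizability `p`, electronegativity
`e`, refractivity `a`, charge `c`, polar surface area `psa`, covalent
radius `r`, hydrophobicity `h`, softness `s`, or the unit vector `u`):

    L_a = Σ_{(i1..iN) ∋ a}  T[i1..iN] · x¹_{i1} ⋯ x^N_{iN}

and an aggregation operator (norms N1/N2/N3, sum ES, statistics AM/SD/V/S/K,
range RA, median i50, extremes MX/MN, negative-sum PN, geometric means
GM/P, and the lag operators AC[k]/TS[k]/GV[k], optionally chained with a
scalar statistic) turns the atom-contribution vector `L` into the scalar
molecular descriptor. Descriptors are named by a canonical grammar,
e.g. `SS2-RA-B[a,c]-M1-total`.

On the modeling side, Q²loo (leave-one-out, hat-matrix PRESS), Q²boot
(bootstrap with pooled out-of-bag errors), the Y-scrambling chance level
a(Q²) (intercept of Q² versus |corr(y_perm, y)|), the model choice score
f = (1 − Q²boot) + |a(Q²)|, and external Q²ext/SDEP are implemented; a
steady-state GA with Q²loo fitness searches 3–9-variable MLR models.

## Worked example

The shipped reference structure is chloro(methoxy)methane (heavy atoms
C1, C2, O3, Cl4; coordinates embedded from its known inter-atomic distance
matrix):

```python
from nlamd import (MetricSpec, build_total_matrix, simple_stochastic,
                   double_stochastic, mutual_probability, worked_example)

we = worked_example()
t = build_total_matrix(we.molecule, 2, MetricSpec("M5"))  # Euclidean
print(round(t.values[0, 1], 3))                        # 2.408  (C1-C2 distance)
print(round(simple_stochastic(t).values[0, 1], 3))     # 0.309  (row-normalized)
print(round(double_stochastic(t).values[0, 1], 3))     # 0.387  (Sinkhorn)
print(round(mutual_probability(t).values[0, 3], 3))    # 0.145  (C1-Cl4 share)
```

The row-normalized 0.309 is the C1→C2 share of C1's total distance mass;
the Sinkhorn value balances both rows and columns to unit sums; the
mutual-probability 0.145 is the C1–Cl4 pair's share of the whole matrix.

A full descriptor through the CLI:

```
nlamd compute --input src/nlamd/data/chloromethoxymethane_embedded.sdf \
      --preset basic --output table.csv
nlamd model --descriptors table.csv --activity act.csv --report model.json
```

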