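"""Reference fixtures and synthetic inputs with known structure.

The worked example is chloro(methoxy)methane (CH3-O-CH2-Cl), whose
heavy-atom scaffold C1, C2, O3, Cl4 has published two-tuple Euclidean,
fragment-projected and probabilistically normalized matrices, and a
three-tuple bond-angle tensor.  Only the inter-atomic distance matrix is
published, not coordinates, so 3D coordinates are recovered by classical
multidimensional scaling; the printed distances carry 3-decimal rounding,
which bounds the reproduction error of derived angles at about 0.005 rad.

The synthetic regression generator plants a sparse linear signal inside a
descriptor table so variable-selection recovery can be measured against a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import Molecule3D

__all__ = [
    "WorkedExample",
    "worked_example",
    "worked_example_sdf_path",
    "embed_from_distances",
    "SyntheticRegressionSpec",
    "synthetic_regression",
    "random_molecule",
]

ATOM_LABELS = ("C1", "C2", "O3", "Cl4")

# two-tuple total Euclidean (dis)similarity matrix of the heavy-atom scaffold
EUCLIDEAN = np.array([
    [0.000, 2.408, 1.439, 3.939],
    [2.408, 0.000, 1.438, 1.757],
    [1.439, 1.438, 0.000, 2.598],
    [3.939, 1.757, 2.598, 0.000],
])

# simple-stochastic (row-normalized) form
SS = np.array([
    [0.000, 0.309, 0.185, 0.506],
    [0.430, 0.000, 0.257, 0.314],
    [0.263, 0.263, 0.000, 0.475],
    [0.475, 0.212, 0.313, 0.000],
])

# double-stochastic (Sinkhorn) form
DS = np.array([
    [0.000, 0.387, 0.246, 0.368],
    [0.387, 0.000, 0.368, 0.246],
    [0.246, 0.368, 0.000, 0.387],
    [0.368, 0.246, 0.387, 0.000],
])

# mutual-probability (grand-total normalized) form
MP = np.array([
    [0.000, 0.089, 0.053, 0.145],
    [0.089, 0.000, 0.053, 0.065],
    [0.053, 0.053, 0.000, 0.096],
    [0.145, 0.065, 0.096, 0.000],
])

# fragment-projected matrices: full weight when both atoms are in the
# fragment, half when exactly one is, zero otherwise
FRAGMENT_HALOGEN = np.array([
    [0.000, 0.000, 0.000, 1.969],
    [0.000, 0.000, 0.000, 0.878],
    [0.000, 0.000, 0.000, 1.299],
    [1.969, 0.878, 1.299, 0.000],
])

FRAGMENT_METHYL = np.array([
    [0.000, 1.204, 0.719, 1.969],
    [1.204, 0.000, 0.000, 0.000],
    [0.719, 0.000, 0.000, 0.000],
    [1.969, 0.000, 0.000, 0.000],
])

FRAGMENT_HETERO = np.array([
    [0.000, 0.000, 0.719, 1.969],
    [0.000, 0.000, 0.719, 0.878],
    [0.719, 0.719, 0.000, 2.598],
    [1.969, 0.878, 2.598, 0.000],
])

FRAGMENT_MEMBERS = {"G": ("Cl4",), "M": ("C1",), "X": ("O3", "Cl4")}

# three-tuple bond-angle tensor gt[i, j, l]: angle (rad) at vertex atom i
# with ends j and l; published slide s is the slice gt[:, :, s]
_ANGLE_SLIDES = [
    [[0.000, 0.000, 0.000, 0.000],
     [0.000, 0.000, 0.578, 2.470],
     [0.000, 1.985, 0.000, 2.682],
     [0.000, 0.390, 0.163, 0.000]],
    [[0.000, 0.000, 0.578, 0.281],
     [0.000, 0.000, 0.000, 0.000],
     [1.985, 0.000, 0.000, 0.697],
     [0.390, 0.000, 0.553, 0.000]],
    [[0.000, 0.578, 0.000, 0.297],
     [0.578, 0.000, 0.000, 1.892],
     [0.000, 0.000, 0.000, 0.000],
     [0.163, 0.553, 0.000, 0.000]],
    [[0.000, 0.281, 0.297, 0.000],
     [2.470, 0.000, 1.892, 0.000],
     [2.682, 0.697, 0.000, 0.000],
     [0.000, 0.000, 0.000, 0.000]],
]
ANGLE_TENSOR = np.stack([np.array(s) for s in _ANGLE_SLIDES], axis=2)


def embed_from_distances(D: np.ndarray, dim: int = 3, warn_tol: float = 1e-6) -> np.ndarray:
    """Classical MDS embedding of a distance matrix into ``dim`` dimensions.

    Deterministic: eigen-decomposition of the double-centered Gram form with
    a fixed sign convention (largest-magnitude component of each axis made
    positive).  Warns when more than ``dim`` significantly positive
    eigenvalues remain, reporting the residual.
    """
    import warnings

    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if n > dim + 1 and w.size > dim and w[dim] > warn_tol * max(w[0], 1.0):
        warnings.warn(
            f"distance matrix is not exactly {dim}-embeddable; "
            f"residual eigenvalue {w[dim]:.3e}", stacklevel=2,
        )
    coords = np.zeros((n, dim))
    for d in range(min(dim, n)):
        if w[d] <= 0:
            break
        axis = V[:, d] * np.sqrt(w[d])
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, d] = axis
    return coords


@dataclass(frozen=True)
class WorkedExample:
    """All published matrices of the reference molecule plus embedded coordinates."""

    labels: tuple[str, ...]
    euclidean: np.ndarray
    ss: np.ndarray
    ds: np.ndarray
    mp: np.ndarray
    fragment_matrices: dict
    fragment_members: dict
    angle_tensor: np.ndarray
    coords: np.ndarray
    molecule: Molecule3D = field(repr=False, default=None)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def worked_example() -> WorkedExample:
    """The chloro(methoxy)methane reference fixture (heavy atoms only)."""
    coords = embed_from_distances(EUCLIDEAN)
    # bonds: C1-O3, O3-C2, C2-Cl4; implicit hydrogens follow from valence
    mol = Molecule3D(
        "chloromethoxymethane",
        elements=["C", "C", "O", "Cl"],
        coords=coords,
        bonds=[(0, 2, 1.0), (2, 1, 1.0), (1, 3, 1.0)],
    )
    return WorkedExample(
        labels=ATOM_LABELS,
        euclidean=EUCLIDEAN.copy(),
        ss=SS.copy(),
        ds=DS.copy(),
        mp=MP.copy(),
        fragment_matrices={
            "G": FRAGMENT_HALOGEN.copy(),
            "M": FRAGMENT_METHYL.copy(),
            "X": FRAGMENT_HETERO.copy(),
        },
        fragment_members=dict(FRAGMENT_MEMBERS),
        angle_tensor=ANGLE_TENSOR.copy(),
        coords=coords,
        molecule=mol,
    )


def worked_example_sdf_path():
    """Path to the shipped SDF of the reference molecule.

    The coordinates in the file are synthetic: they were embedded from the
    published distance matrix (classical MDS), not taken from any original
    structure file.
    """
    from importlib import resources

    return resources.files("nlamd.data").joinpath("chloromethoxymethane_embedded.sdf")


# ---------------------------------------------------------------------------
# synthetic regression data


@dataclass(frozen=True)
class SyntheticRegressionSpec:
    """Planted sparse linear signal inside a descriptor table.

    Defaults mirror the variable-selection recovery conditions used in the
    test suite: 60 molecules, 100 candidate descriptors, a 3-descriptor
    support with coefficients (2, -1, 0.5) and noise at 10 % of the signal's
    standard deviation.
    """

    n: int = 60
    p: int = 100
    support: tuple[int, ...] = (3, 7, 12)
    beta: tuple[float, ...] = (2.0, -1.0, 0.5)
    noise_sd_fraction: float = 0.1
    n_correlated_pairs: int = 5
    n_duplicates: int = 0
    n_constant: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.support) != len(self.beta):
            raise ValueError("support and beta lengths differ")
        if any(not 0 <= s < self.p for s in self.support):
            raise ValueError("support indices out of range")


def synthetic_regression(spec: SyntheticRegressionSpec):
    """Generate (descriptor table, activity vector, truth record).

    Columns are i.i.d. standard normal except for ``n_correlated_pairs``
    pairs (r about 0.8, to exercise correlation pruning), ``n_duplicates``
    exact copies of earlier columns and ``n_constant`` constant columns
    appended at the end.  The activity is X[:, support] @ beta plus Gaussian
    noise scaled to the requested fraction of the signal's sd.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    protected = set(spec.support)
    free = [j for j in range(spec.p) if j not in protected]
    pair_targets = []
    for pi in range(min(spec.n_correlated_pairs, len(free) // 2)):
        j1, j2 = free[2 * pi], free[2 * pi + 1]
        X[:, j2] = 0.8 * X[:, j1] + 0.6 * rng.standard_normal(spec.n)
        pair_targets.append((j1, j2))
    dup_sources = []
    for d in range(spec.n_duplicates):
        src = free[-(d + 1)]
        X[:, src] = X[:, spec.support[0] if d % 2 else free[0]]
        dup_sources.append(src)
    const_cols = []
    for cidx in range(spec.n_constant):
        col = free[-(spec.n_duplicates + cidx + 1)]
        X[:, col] = 1.0
        const_cols.append(col)
    signal = X[:, list(spec.support)] @ np.asarray(spec.beta)
    noise_sd = spec.noise_sd_fraction * np.std(signal)
    y = signal + rng.normal(0.0, noise_sd, spec.n)
    names = [f"X{j:03d}" for j in range(spec.p)]
    table = pd.DataFrame(X, columns=names,
                         index=[f"mol{i:03d}" for i in range(spec.n)])
    var_signal = float(np.var(signal))
    truth = {
        "support": tuple(names[j] for j in spec.support),
        "support_idx": spec.support,
        "beta": spec.beta,
        "noise_sd": float(noise_sd),
        "correlated_pairs": pair_targets,
        "duplicate_columns": tuple(names[j] for j in dup_sources),
        "constant_columns": tuple(names[j] for j in const_cols),
        "achievable_r2": var_signal / (var_signal + noise_sd ** 2) if noise_sd else 1.0,
    }
    return table, pd.Series(y, index=table.index, name="activity"), truth


_ELEMENT_POOL = ("C", "N", "O", "S", "F", "Cl")
_INTERIOR_POOL = ("C", "C", "N", "S")  # monovalent halogens/divalent O stay terminal


def random_molecule(n_atoms: int, seed: int) -> Molecule3D:
    """A random chain molecule in a 10 A box with min pairwise separation 1 A."""
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    coords = np.empty((n_atoms, 3))
    placed = 0
    while placed < n_atoms:
        cand = rng.uniform(0.0, 10.0, 3)
        if placed == 0 or np.min(np.linalg.norm(coords[:placed] - cand, axis=1)) >= 1.0:
            coords[placed] = cand
            placed += 1
    elements = [str(rng.choice(_ELEMENT_POOL)) if i in (0, n_atoms - 1)
                else str(rng.choice(_INTERIOR_POOL)) for i in range(n_atoms)]
    bonds = [(i, i + 1, 1.0) for i in range(n_atoms - 1)]
    return Molecule3D(f"random{seed}", elements, coords, bonds=bonds)
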