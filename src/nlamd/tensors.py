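"""Order-N spatial (dis)similarity tensors and their transforms.

The pipeline mirrors the standard workflow for N-linear algebraic indices:

1. build the non-stochastic (``ns``) total tensor at Hadamard power k = 1,
2. optionally project onto a local chemical fragment,
3. apply a probabilistic transform (simple-stochastic ``ss``, Sinkhorn
   double-stochastic ``ds`` for matrices, or mutual-probability ``mp``),
4. raise to the Hadamard power k,
5. split into atom-level tensors.

Entries with any repeated atom index are zero by construction, so the
"distance of an atom to itself" never contributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .metrics import MetricSpec, MultiMetricSpec, distance_matrix

__all__ = [
    "TupleMatrix",
    "FragmentMask",
    "build_total_matrix",
    "apply_fragment",
    "simple_stochastic",
    "double_stochastic",
    "mutual_probability",
    "hadamard_power",
    "atom_level_split",
]

log = logging.getLogger(__name__)

#: order-4 tensors are dense; refuse absurd molecule sizes
MAX_ATOMS_ORDER4 = 120


@dataclass(frozen=True)
class FragmentMask:
    """Boolean membership of each atom in a local fragment (atom-type group)."""

    fragment_id: str
    members: np.ndarray  # bool, one per atom

    def __post_init__(self):
        object.__setattr__(self, "members", np.asarray(self.members, dtype=bool))


@dataclass(frozen=True)
class TupleMatrix:
    """An order-N dense tensor over atoms with provenance tags."""

    order: int
    values: np.ndarray
    state: str = "ns"  # ns | ss | ds | mp
    power: int = 1
    fragment: str | None = None
    metric_tag: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != self.order:
            raise ValueError(f"tensor rank {v.ndim} != declared order {self.order}")
        if len(set(v.shape)) != 1:
            raise ValueError("tensor must be hypercubic over atoms")
        if not np.all(np.isfinite(v)):
            raise ValueError("tensor entries must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


def _repeated_index_mask(n: int, order: int) -> np.ndarray:
    """Boolean mask, True where any two of the ``order`` indices coincide."""
    grids = np.indices((n,) * order)
    mask = np.zeros((n,) * order, dtype=bool)
    for a in range(order):
        for b in range(a + 1, order):
            mask |= grids[a] == grids[b]
    return mask


def build_total_matrix(mol, order: int, spec) -> TupleMatrix:
    """Build the ns, k=1 total tensor of a molecule for one (multi-)metric.

    ``mol`` may be a Molecule3D or a bare (n, 3) coordinate array.
    """
    coords = np.asarray(getattr(mol, "coords", mol), dtype=float)
    n = coords.shape[0]
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3 or 4")
    if n < order:
        raise ValueError(f"need at least {order} atoms, molecule has {n}")
    if order == 4 and n > MAX_ATOMS_ORDER4:
        raise ValueError(f"order-4 tensor refused for n={n} > {MAX_ATOMS_ORDER4} atoms")
    if order == 2:
        if not isinstance(spec, MetricSpec):
            raise TypeError("order 2 requires a MetricSpec")
        vals = distance_matrix(spec, coords)
        np.fill_diagonal(vals, 0.0)
        return TupleMatrix(2, vals, metric_tag=spec.tag)
    if not isinstance(spec, MultiMetricSpec):
        raise TypeError(f"order {order} requires a MultiMetricSpec")
    vals = _build_higher(coords, order, spec)
    vals[_repeated_index_mask(n, order)] = 0.0
    return TupleMatrix(order, vals, metric_tag=spec.tag)


def _build_higher(coords: np.ndarray, order: int, spec: MultiMetricSpec) -> np.ndarray:
    n = coords.shape[0]
    kind = spec.kind
    if kind in ("perimeter", "area", "sides_sum"):
        D = distance_matrix(spec.base_metric, coords)
        i, j, l = np.ix_(range(n), range(n), range(n))
        if order == 3:
            if kind == "perimeter":
                return D[i, j] + D[j, l] + D[l, i]
            if kind == "sides_sum":
                return D[i, j] + D[j, l]
            # Heron's formula; clip near-collinear radicands at zero
            a, b, c = D[i, j], D[j, l], D[l, i]
            s = 0.5 * (a + b + c)
            rad = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
            return np.sqrt(rad)
        i, j, l, h = np.ix_(range(n), range(n), range(n), range(n))
        if kind == "perimeter":
            return D[i, j] + D[j, l] + D[l, h] + D[h, i]
        if kind == "sides_sum":
            return D[i, j] + D[j, l] + D[l, h]
        raise ValueError(f"{spec.code} undefined at order 4")
    if kind == "angle":
        if order != 3:
            raise ValueError("bond angle is a ternary measure")
        # vertex at the leading (row) index i, ends j and l
        disp = coords[None, :, :] - coords[:, None, :]  # disp[i, j] = r_j - r_i
        norms = np.linalg.norm(disp, axis=2)
        dots = np.einsum("ijk,ilk->ijl", disp, disp)
        den = norms[:, :, None] * norms[:, None, :]
        cosang = np.divide(dots, den, out=np.ones_like(dots), where=den != 0)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        ang[den == 0] = 0.0
        return ang
    if kind in ("volume", "dihedral"):
        if order != 4:
            raise ValueError(f"{spec.code} is a quaternary measure")
        out = np.zeros((n,) * 4)
        if kind == "volume":
            for i in range(n):
                e = coords - coords[i]  # edge vectors from atom i
                # det[e_j, e_l, e_h] / 6 via scalar triple product
                cr = np.cross(e[:, None, :], e[None, :, :])  # (n, n, 3)
                out[i] = np.abs(np.einsum("jlk,hk->jlh", cr, e)) / 6.0
            return out
        for j in range(n):
            u = coords - coords[j]  # vectors from hinge atom b=j
            for l in range(n):
                na = np.cross(u, u[l])  # normals of planes (i, j, l)
                nn = np.linalg.norm(na, axis=1)
                dots = na @ na.T
                den = np.outer(nn, nn)
                cosang = np.divide(dots, den, out=np.ones_like(dots), where=den != 0)
                ang = np.arccos(np.clip(cosang, -1.0, 1.0))
                ang[den == 0] = 0.0
                out[:, j, l, :] = ang
        return out
    raise AssertionError(kind)


def apply_fragment(t: TupleMatrix, mask: FragmentMask) -> TupleMatrix:
    """Project a ns tensor onto a fragment.

    Entries are kept in full when every participating atom belongs to the
    fragment, halved when at least one (but not all) belongs, and zeroed
    when none does.
    """
    if t.state != "ns":
        raise ValueError("fragment projection must precede probabilistic transforms")
    m = mask.members
    if m.shape[0] != t.n_atoms:
        raise ValueError("fragment mask length does not match atom count")
    # count of in-fragment atoms at each entry's index tuple
    cnt = np.zeros(t.values.shape)
    for axis in range(t.order):
        shape = [1] * t.order
        shape[axis] = t.n_atoms
        cnt = cnt + m.astype(float).reshape(shape)
    weight = np.where(cnt == t.order, 1.0, np.where(cnt > 0, 0.5, 0.0))
    return replace(t, values=t.values * weight, fragment=mask.fragment_id)


def simple_stochastic(t: TupleMatrix) -> TupleMatrix:
    """Normalize each leading-index slice to unit sum (rows at order 2)."""
    if t.state != "ns":
        raise ValueError("simple_stochastic expects a ns tensor")
    flat = t.values.reshape(t.n_atoms, -1)
    sums = flat.sum(axis=1, keepdims=True)
    out = np.divide(flat, sums, out=np.zeros_like(flat), where=sums != 0)
    return replace(t, values=out.reshape(t.values.shape), state="ss")


def double_stochastic(t: TupleMatrix, tol: float = 1e-8, max_iter: int = 10_000) -> TupleMatrix:
    """Sinkhorn-Knopp balancing of a non-negative matrix to doubly stochastic.

    Uses the two-sided scaling form D_r A D_c; for symmetric input the two
    scaling vectors are averaged each sweep so the output stays symmetric.
    """
    if t.order != 2:
        raise ValueError("double-stochastic normalization is defined for matrices only")
    if t.state != "ns":
        raise ValueError("double_stochastic expects a ns matrix")
    A = t.values
    if np.any(A < 0):
        raise ValueError("Sinkhorn balancing requires a non-negative matrix")
    n = t.n_atoms
    symmetric = np.allclose(A, A.T, atol=1e-12)
    r = np.ones(n)
    c = np.ones(n)
    for _ in range(max_iter):
        cs = A.T @ r
        c = np.divide(1.0, cs, out=np.zeros(n), where=cs != 0)
        rs = A @ c
        r = np.divide(1.0, rs, out=np.zeros(n), where=rs != 0)
        if symmetric:
            g = np.sqrt(r * c)
            r = c = g
        S = (r[:, None] * A) * c[None, :]
        if (np.abs(S.sum(axis=1) - 1).max() < tol
                and np.abs(S.sum(axis=0) - 1).max() < tol):
            return replace(t, values=S, state="ds")
    slack = max(np.abs(S.sum(axis=1) - 1).max(), np.abs(S.sum(axis=0) - 1).max())
    raise RuntimeError(
        f"Sinkhorn-Knopp did not converge in {max_iter} iterations "
        f"(worst row/col sum deviation {slack:.3e})"
    )


def mutual_probability(t: TupleMatrix) -> TupleMatrix:
    """Divide every entry by the grand total so the tensor sums to 1."""
    if t.state != "ns":
        raise ValueError("mutual_probability expects a ns tensor")
    total = t.values.sum()
    if total == 0:
        return replace(t, state="mp")
    return replace(t, values=t.values / total, state="mp")


def hadamard_power(t: TupleMatrix, k: int) -> TupleMatrix:
    """Entrywise power k; negative k is the |k| power of the 0-preserving reciprocal."""
    if k == 0 or abs(k) > 12:
        raise ValueError("Hadamard power k must satisfy 1 <= |k| <= 12")
    v = t.values
    if k < 0:
        v = np.divide(1.0, v, out=np.zeros_like(v), where=v != 0)
    out = v ** abs(k)
    return replace(t, values=out, power=k)


def atom_level_split(t: TupleMatrix, atom: int) -> TupleMatrix:
    """Keep only entries with at least one index equal to ``atom``."""
    n = t.n_atoms
    if not 0 <= atom < n:
        raise IndexError(f"atom index {atom} out of range for {n} atoms")
    grids = np.indices(t.values.shape)
    keep = np.zeros(t.values.shape, dtype=bool)
    for g in grids:
        keep |= g == atom
    return replace(t, values=np.where(keep, t.values, 0.0))
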