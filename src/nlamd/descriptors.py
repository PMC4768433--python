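"""N-linear algebraic descriptors: tensor-property contraction and aggregation.

A descriptor is the composition

    build ns tensor -> [fragment projection] -> probabilistic transform
    -> Hadamard power k -> atom-level split -> N-linear contraction with
    atomic-property vectors -> aggregation operator over the atom
    contributions.

The contraction of an order-N tensor ``T`` with property vectors
``x1..xN`` restricted to atom ``a`` is

    L_a = sum over index tuples (i1..iN) containing a of
          T[i1..iN] * x1[i1] * ... * xN[iN]

so ``L`` holds one contribution per atom; the aggregation operator turns
``L`` into the scalar molecular descriptor.  A quadratic form repeats one
property vector; a linear form pairs a property with the unit vector ``u``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem_io import Molecule3D, assign_fragments, property_vector
from .metrics import MetricSpec, MultiMetricSpec, MINKOWSKI_P
from .tensors import (
    TupleMatrix,
    apply_fragment,
    build_total_matrix,
    double_stochastic,
    hadamard_power,
    mutual_probability,
    simple_stochastic,
)

__all__ = [
    "DescriptorConfig",
    "contract",
    "aggregate",
    "compute_descriptor",
    "compute_table",
    "descriptor_name",
    "parse_descriptor_name",
    "SCALAR_OPERATORS",
    "LAG_OPERATORS",
]

_FORM_BY_ORDER = {2: "B", 3: "Tr", 4: "Qu"}
_ORDER_BY_FORM = {v: k for k, v in _FORM_BY_ORDER.items()}


@dataclass(frozen=True)
class DescriptorConfig:
    """One descriptor's full recipe.

    ``props`` has one property id per tensor order (repeats allowed; ``u``
    is the all-ones unit property, giving linear forms).  ``operators`` is a
    chain of one or two ids: either a single scalar/lag operator, or a lag
    operator followed by a scalar statistic applied to its lag profile.
    """

    order: int
    spec: MetricSpec | MultiMetricSpec
    props: tuple[str, ...]
    state: str = "NS"  # NS | SS | DS | MP
    k: int = 1
    fragment: str | None = None
    operators: tuple[str, ...] = ("ES",)

    def __post_init__(self):
        if self.order not in (2, 3, 4):
            raise ValueError("order must be 2, 3 or 4")
        if len(self.props) != self.order:
            raise ValueError(f"need {self.order} property ids, got {len(self.props)}")
        if self.state not in ("NS", "SS", "DS", "MP"):
            raise ValueError(f"unknown matrix state {self.state!r}")
        if self.state == "DS" and self.order != 2:
            raise ValueError("double-stochastic normalization requires order 2")
        if not 1 <= len(self.operators) <= 2:
            raise ValueError("operator chain must have length 1 or 2")
        for op in self.operators:
            _parse_operator(op)
        if len(self.operators) == 2:
            name, lag = _parse_operator(self.operators[0])
            if name not in LAG_OPERATORS or lag is None:
                raise ValueError("a 2-operator chain must start with a lag operator, e.g. AC[3]")
            name2, lag2 = _parse_operator(self.operators[1])
            if lag2 is not None:
                raise ValueError("the second chain operator must be a scalar statistic")


# ---------------------------------------------------------------------------
# contraction


def _axes_fixed_sum(P: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Vector over a of sum of P with all ``axes`` pinned to a, others summed."""
    letters = [chr(ord("b") + i) for i in range(P.ndim)]
    for ax in axes:
        letters[ax] = "a"
    return np.einsum("".join(letters) + "->a", P)


def contract(t: TupleMatrix, props: tuple[np.ndarray, ...]) -> np.ndarray:
    """Atom-contribution vector L of the N-linear form over atom-level tensors.

    Equivalent to contracting each atom's split tensor with the property
    vectors; computed by inclusion-exclusion over which indices equal the
    atom, which avoids materializing n split tensors.
    """
    if len(props) != t.order:
        raise ValueError(f"order-{t.order} tensor needs {t.order} property vectors")
    vecs = [np.asarray(p, dtype=float) for p in props]
    for v in vecs:
        if v.shape != (t.n_atoms,):
            raise ValueError("property vector length must equal atom count")
    P = t.values
    for ax, v in enumerate(vecs):
        shape = [1] * t.order
        shape[ax] = t.n_atoms
        P = P * v.reshape(shape)
    L = np.zeros(t.n_atoms)
    for r in range(1, t.order + 1):
        sign = 1.0 if r % 2 else -1.0
        for axes in itertools.combinations(range(t.order), r):
            L += sign * _axes_fixed_sum(P, axes)
    return L


# ---------------------------------------------------------------------------
# aggregation operators

_OP_RE = re.compile(r"^([A-Za-z]+\d*[A-Za-z]*?)(?:\[(\d+)\])?$")

LAG_OPERATORS = ("AC", "TS", "GV")


def _parse_operator(op: str) -> tuple[str, int | None]:
    m = _OP_RE.match(op)
    if not m:
        raise ValueError(f"malformed operator id {op!r}")
    name, lag = m.group(1), m.group(2)
    lag = int(lag) if lag is not None else None
    if name in LAG_OPERATORS:
        if lag is None or lag < 1:
            raise ValueError(f"operator {name} needs a positive lag, e.g. {name}[2]")
    elif lag is not None:
        raise ValueError(f"operator {name} takes no lag")
    elif name not in SCALAR_OPERATORS:
        raise ValueError(f"unknown aggregation operator {name!r}")
    return name, lag


def _sd(L):
    return float(np.std(L, ddof=1)) if L.size >= 2 else 0.0


def _skew(L):
    if L.size < 3 or np.std(L) == 0:
        return 0.0
    return float(stats.skew(L, bias=False))


def _kurt(L):
    if L.size < 4 or np.std(L) == 0:
        return 0.0
    return float(stats.kurtosis(L, fisher=True, bias=False))


def _gm(L):
    absL = np.abs(L)
    if np.any(absL == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(absL))))


def _signed_gm(L):
    g = _gm(L)
    return float(np.prod(np.sign(L)) * g)


SCALAR_OPERATORS = {
    "N1": lambda L: float(np.sum(np.abs(L))),
    "N2": lambda L: float(np.sqrt(np.sum(L ** 2))),
    "N3": lambda L: float(np.sum(np.abs(L) ** 3) ** (1.0 / 3.0)),
    "ES": lambda L: float(np.sum(L)),
    "AM": lambda L: float(np.mean(L)),
    "GM": _gm,
    "P": _signed_gm,
    "SD": _sd,
    "V": lambda L: float(np.var(L, ddof=1)) if L.size >= 2 else 0.0,
    "S": _skew,
    "K": _kurt,
    "RA": lambda L: float(np.max(L) - np.min(L)),
    "i50": lambda L: float(np.median(L)),
    "MX": lambda L: float(np.max(L)),
    "MN": lambda L: float(np.min(L)),
    "PN": lambda L: float(np.sum(L[L < 0])),
}


def _lag_value(name: str, L: np.ndarray, lag: int, coords: np.ndarray | None) -> float:
    n = L.size
    if lag >= n:
        return 0.0
    if name == "AC":
        dev = L - L.mean()
        den = float(np.sum(dev ** 2))
        if den == 0:
            return 0.0
        return float(np.sum(dev[:-lag] * dev[lag:]) / den)
    if name == "TS":
        return float(np.sum(L[:-lag] * L[lag:]))
    if name == "GV":
        if coords is None:
            raise ValueError("GV aggregation needs atomic coordinates")
        d = np.linalg.norm(coords[:-lag] - coords[lag:], axis=1)
        terms = np.divide(L[:-lag] * L[lag:], d ** 2, out=np.zeros(n - lag), where=d != 0)
        return float(np.sum(terms))
    raise AssertionError(name)


def aggregate(L: np.ndarray, operators, coords: np.ndarray | None = None) -> float:
    """Apply an aggregation operator (or a lag-then-statistic chain) to L.

    Atom order is the input-file order; lag operators (AC/TS/GV) depend on
    it and are documented as part of the descriptor definition.
    """
    L = np.asarray(L, dtype=float)
    if isinstance(operators, str):
        operators = (operators,)
    if len(operators) == 1:
        name, lag = _parse_operator(operators[0])
        if lag is not None:
            return _lag_value(name, L, lag, coords)
        return SCALAR_OPERATORS[name](L)
    name, lag = _parse_operator(operators[0])
    profile = np.array([_lag_value(name, L, t, coords) for t in range(1, lag + 1)])
    name2, _ = _parse_operator(operators[1])
    return SCALAR_OPERATORS[name2](profile)


# ---------------------------------------------------------------------------
# end-to-end descriptor


def _transform(t: TupleMatrix, state: str) -> TupleMatrix:
    if state == "NS":
        return t
    if state == "SS":
        return simple_stochastic(t)
    if state == "DS":
        return double_stochastic(t)
    if state == "MP":
        return mutual_probability(t)
    raise ValueError(state)


def compute_descriptor(mol: Molecule3D, cfg: DescriptorConfig,
                       fragments: dict | None = None) -> float:
    """Compute one molecular descriptor value for one molecule."""
    t = build_total_matrix(mol, cfg.order, cfg.spec)
    if cfg.fragment is not None:
        masks = fragments if fragments is not None else assign_fragments(mol)
        if cfg.fragment not in masks:
            raise ValueError(f"fragment {cfg.fragment!r} unavailable for {mol.id}")
        t = apply_fragment(t, masks[cfg.fragment])
    t = _transform(t, cfg.state)
    if cfg.k != 1:
        t = hadamard_power(t, cfg.k)
    props = tuple(property_vector(mol, p) for p in cfg.props)
    L = contract(t, props)
    return aggregate(L, cfg.operators, coords=mol.coords)


def compute_table(mols, cfgs, on_error: str = "nan"):
    """Molecules x descriptors table as a pandas DataFrame.

    Per-molecule failures become NaN rows (``on_error="nan"``) or raise
    (``on_error="raise"``); columns follow the canonical descriptor names in
    the order given.
    """
    import pandas as pd

    names = [descriptor_name(c) for c in cfgs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate descriptor configurations")
    rows = {}
    for mol in mols:
        frg = None
        if any(c.fragment for c in cfgs):
            frg = assign_fragments(mol)
        vals = []
        for cfg in cfgs:
            try:
                vals.append(compute_descriptor(mol, cfg, fragments=frg))
            except Exception:
                if on_error == "raise":
                    raise
                vals.append(np.nan)
        rows[mol.id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# canonical naming grammar
#
#   STATEk-OPCHAIN-FORM[p1,p2,..]-METRIC-FRAGMENT
#
# e.g. "SS2-RA-B[a,c]-M1-total", "NSn2-AC[3]_K-Tr[m,m,m]-M21(M5)-G".
# Negative Hadamard powers spell k as "n<abs>"; FORM is B/Tr/Qu by order.

_NAME_RE = re.compile(
    r"^(NS|SS|DS|MP)(n?\d+)-([^-]+)-(B|Tr|Qu)\[([a-z0-9,]+)\]-(M\d+(?:\(M\d+\))?)-(\w+)$"
)


def descriptor_name(cfg: DescriptorConfig) -> str:
    k = f"n{-cfg.k}" if cfg.k < 0 else str(cfg.k)
    op = "_".join(cfg.operators)
    form = _FORM_BY_ORDER[cfg.order]
    props = ",".join(cfg.props)
    frag = cfg.fragment if cfg.fragment else "total"
    return f"{cfg.state}{k}-{op}-{form}[{props}]-{cfg.spec.tag}-{frag}"


def parse_descriptor_name(name: str) -> DescriptorConfig:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a canonical descriptor name: {name!r}")
    state, kstr, opchain, form, props, metric, frag = m.groups()
    k = -int(kstr[1:]) if kstr.startswith("n") else int(kstr)
    order = _ORDER_BY_FORM[form]
    base_m = re.match(r"^(M\d+)(?:\((M\d+)\))?$", metric)
    code, base = base_m.group(1), base_m.group(2)
    if order == 2:
        spec = MetricSpec(code)
    else:
        spec = MultiMetricSpec(code, MetricSpec(base) if base else None)
    ops = tuple(opchain.split("_"))
    return DescriptorConfig(
        order=order, spec=spec, props=tuple(props.split(",")), state=state,
        k=k, fragment=None if frag == "total" else frag, operators=ops,
    )
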