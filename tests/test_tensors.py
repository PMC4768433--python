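"""Total tensors, fragment projection, normalizations and splitting."""

import itertools

import numpy as np
import pytest

from nlamd.metrics import MetricSpec, MultiMetricSpec
from nlamd.tensors import (
    FragmentMask,
    TupleMatrix,
    apply_fragment,
    atom_level_split,
    build_total_matrix,
    double_stochastic,
    hadamard_power,
    mutual_probability,
    simple_stochastic,
)

EUCLID = MetricSpec("M5")


def rigid_motion(coords, rng):
    q = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(q)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return coords @ Q.T + rng.uniform(-5, 5, 3)


# ---------------------------------------------------------------------------
# building


def test_total_matrix_matches_published_euclidean(we):
    t = build_total_matrix(we.molecule, 2, EUCLID)
    i, j = we.index("C1"), we.index("C2")
    assert t.values[i, j] == pytest.approx(2.408, abs=0.002)
    assert np.abs(t.values - we.euclidean).max() < 0.002
    assert np.allclose(t.values, t.values.T)
    assert np.allclose(np.diag(t.values), 0)


def test_angle_tensor_matches_published_slices(we):
    t = build_total_matrix(we.molecule, 3, MultiMetricSpec("M27"))
    assert t.values[we.index("C2"), we.index("Cl4"), we.index("C1")] == pytest.approx(2.470, abs=0.005)
    nz = we.angle_tensor > 0
    assert np.abs(t.values - we.angle_tensor)[nz].max() < 0.005
    assert np.abs(t.values[~nz]).max() < 0.005


def test_two_atom_molecule():
    t = build_total_matrix(np.array([[0.0, 0, 0], [1, 1, 1]]), 2, EUCLID)
    assert t.values[0, 0] == t.values[1, 1] == 0
    assert t.values[0, 1] == t.values[1, 0] > 0


def test_build_errors():
    coords = np.zeros((2, 3))
    with pytest.raises(ValueError, match="at least 3"):
        build_total_matrix(coords, 3, MultiMetricSpec("M27"))
    with pytest.raises(TypeError):
        build_total_matrix(np.eye(3), 2, MultiMetricSpec("M27"))
    with pytest.raises(TypeError):
        build_total_matrix(np.eye(3), 3, EUCLID)


def test_repeated_indices_are_zero(mol5):
    for order, spec in [(3, MultiMetricSpec("M19")), (4, MultiMetricSpec("M25"))]:
        t = build_total_matrix(mol5, order, spec)
        for idx in itertools.product(range(5), repeat=order):
            if len(set(idx)) < order:
                assert t.values[idx] == 0.0


def test_order4_volume_against_direct_determinant(rng):
    from nlamd.metrics import quaternary_measure

    coords = rng.uniform(0, 5, (5, 3))
    spec = MultiMetricSpec("M23")
    t = build_total_matrix(coords, 4, spec)
    for idx in [(0, 1, 2, 3), (4, 2, 1, 0), (1, 3, 4, 2)]:
        direct = quaternary_measure(spec, *(coords[i] for i in idx))
        assert t.values[idx] == pytest.approx(direct, abs=1e-10)


def test_order4_dihedral_against_direct(rng):
    from nlamd.metrics import quaternary_measure

    coords = rng.uniform(0, 5, (5, 3))
    spec = MultiMetricSpec("M29")
    t = build_total_matrix(coords, 4, spec)
    for idx in [(0, 1, 2, 3), (3, 0, 4, 1), (2, 4, 1, 0)]:
        direct = quaternary_measure(spec, *(coords[i] for i in idx))
        assert t.values[idx] == pytest.approx(direct, abs=1e-10)


def test_euclidean_rigid_motion_invariance(we, rng):
    t0 = build_total_matrix(we.coords, 2, EUCLID)
    t1 = build_total_matrix(rigid_motion(we.coords, rng), 2, EUCLID)
    assert np.abs(t0.values - t1.values).max() < 1e-9


@pytest.mark.parametrize("code", ["M11", "M13", "M16"])
def test_coordinate_metrics_are_frame_dependent(code, we, rng):
    """Raw-coordinate metrics are documented as NOT rigid-motion invariant."""
    t0 = build_total_matrix(we.coords, 2, MetricSpec(code))
    t1 = build_total_matrix(we.coords + np.array([5.0, -3.0, 2.0]), 2, MetricSpec(code))
    assert np.abs(t0.values - t1.values).max() > 1e-3


# ---------------------------------------------------------------------------
# fragment projection


def test_fragment_projection_matches_published(we):
    t = build_total_matrix(we.molecule, 2, EUCLID)
    for frag, printed in we.fragment_matrices.items():
        members = np.array([lbl in we.fragment_members[frag] for lbl in we.labels])
        out = apply_fragment(t, FragmentMask(frag, members))
        assert np.abs(out.values - printed).max() < 0.002


def test_fragment_halving_rule(we):
    t = build_total_matrix(we.molecule, 2, EUCLID)
    mask = FragmentMask("G", np.array([False, False, False, True]))
    out = apply_fragment(t, mask)
    c1, cl4, o3 = we.index("C1"), we.index("Cl4"), we.index("O3")
    assert out.values[c1, cl4] == pytest.approx(t.values[c1, cl4] / 2)
    assert out.values[c1, o3] == 0.0


def test_fragment_all_atoms_is_identity(mol5):
    t = build_total_matrix(mol5, 3, MultiMetricSpec("M19"))
    out = apply_fragment(t, FragmentMask("F", np.ones(5, dtype=bool)))
    assert np.array_equal(out.values, t.values)


def test_fragment_errors(mol5):
    t = build_total_matrix(mol5, 2, EUCLID)
    with pytest.raises(ValueError, match="length"):
        apply_fragment(t, FragmentMask("F", np.ones(4, dtype=bool)))
    ss = simple_stochastic(t)
    with pytest.raises(ValueError, match="precede"):
        apply_fragment(ss, FragmentMask("F", np.ones(5, dtype=bool)))


# ---------------------------------------------------------------------------
# probabilistic transforms


def test_simple_stochastic_matches_published(we):
    ss = simple_stochastic(build_total_matrix(we.molecule, 2, EUCLID))
    c1, c2 = we.index("C1"), we.index("C2")
    assert ss.values[c1, c2] == pytest.approx(0.309, abs=0.0005)
    assert ss.values[c2, c1] == pytest.approx(0.430, abs=0.0005)
    assert np.abs(ss.values - we.ss).max() < 0.0005


def test_simple_stochastic_uniform_rows():
    vals = np.full((5, 5), 2.0)
    np.fill_diagonal(vals, 0.0)
    ss = simple_stochastic(TupleMatrix(2, vals))
    off = ss.values[~np.eye(5, dtype=bool)]
    assert np.allclose(off, 1 / 4)


@pytest.mark.parametrize("order", [2, 3])
def test_simple_stochastic_slice_sums(order, mol5):
    spec = EUCLID if order == 2 else MultiMetricSpec("M21")
    ss = simple_stochastic(build_total_matrix(mol5, order, spec))
    sums = ss.values.reshape(5, -1).sum(axis=1)
    assert np.allclose(sums[sums != 0], 1.0, atol=1e-12)


def test_double_stochastic_matches_published(we):
    ds = double_stochastic(build_total_matrix(we.molecule, 2, EUCLID))
    assert ds.values[we.index("C1"), we.index("C2")] == pytest.approx(0.387, abs=0.002)
    assert np.abs(ds.values - we.ds).max() < 0.002


def test_double_stochastic_properties(rng):
    A = rng.uniform(0.5, 2.0, (6, 6))
    A = A + A.T
    np.fill_diagonal(A, 0.0)
    ds = double_stochastic(TupleMatrix(2, A), tol=1e-10)
    assert np.abs(ds.values.sum(axis=0) - 1).max() < 1e-8
    assert np.abs(ds.values.sum(axis=1) - 1).max() < 1e-8
    assert np.abs(ds.values - ds.values.T).max() < 1e-9


def test_double_stochastic_fixed_point():
    A = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    ds = double_stochastic(TupleMatrix(2, A))
    assert np.abs(ds.values - A).max() < 1e-7


def test_double_stochastic_order3_rejected(mol5):
    t = build_total_matrix(mol5, 3, MultiMetricSpec("M19"))
    with pytest.raises(ValueError, match="matrices only"):
        double_stochastic(t)


def test_mutual_probability_matches_published(we):
    mp = mutual_probability(build_total_matrix(we.molecule, 2, EUCLID))
    assert mp.values[we.index("C1"), we.index("Cl4")] == pytest.approx(0.145, abs=0.0005)
    assert mp.values.sum() == pytest.approx(1.0, abs=1e-12)


def test_mutual_probability_small_cases():
    # two equal off-diagonal entries split the unit mass equally
    mp = mutual_probability(TupleMatrix(2, np.array([[0.0, 4.0], [4.0, 0.0]])))
    assert np.allclose(mp.values, [[0, 0.5], [0.5, 0]])
    assert mp.values.sum() == 1.0
    z = mutual_probability(TupleMatrix(2, np.zeros((3, 3))))
    assert np.all(z.values == 0) and z.state == "mp"


@pytest.mark.parametrize("order", [2, 3])
def test_normalizations_commute_with_relabeling(order, rng, mol5):
    """Permutation equivariance: transform(P T) = P transform(T)."""
    spec = EUCLID if order == 2 else MultiMetricSpec("M19")
    t = build_total_matrix(mol5, order, spec)
    perm = rng.permutation(5)
    permuted = t.values
    for ax in range(order):
        permuted = np.take(permuted, perm, axis=ax)
    tp = TupleMatrix(order, permuted)
    for fn in (simple_stochastic, mutual_probability):
        direct = fn(tp).values
        relabeled = fn(t).values
        for ax in range(order):
            relabeled = np.take(relabeled, perm, axis=ax)
        assert np.abs(direct - relabeled).max() < 1e-12


# ---------------------------------------------------------------------------
# Hadamard powers and atom-level splitting


def test_hadamard_power_conventions():
    t = TupleMatrix(2, np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert np.array_equal(hadamard_power(t, 1).values, t.values)
    assert hadamard_power(t, 3).values[0, 1] == 8.0
    neg = hadamard_power(t, -1)
    assert neg.values[0, 1] == 0.5
    assert neg.values[0, 0] == 0.0  # zero entries stay zero
    with pytest.raises(ValueError):
        hadamard_power(t, 0)
    with pytest.raises(ValueError):
        hadamard_power(t, 13)


def test_atom_split_order2(mol5):
    t = build_total_matrix(mol5, 2, EUCLID)
    s = atom_level_split(t, 2)
    keep = np.zeros((5, 5), dtype=bool)
    keep[2, :] = keep[:, 2] = True
    assert np.array_equal(s.values, np.where(keep, t.values, 0.0))
    total = sum(atom_level_split(t, a).values for a in range(5))
    assert np.abs(total - 2 * t.values).max() < 1e-12  # zero diagonal counted twice


def test_atom_split_order3_brute_force(rng):
    vals = rng.standard_normal((4, 4, 4))
    t = TupleMatrix(3, vals)
    for a in range(4):
        s = atom_level_split(t, a)
        expected = np.zeros_like(vals)
        for idx in itertools.product(range(4), repeat=3):
            if a in idx:
                expected[idx] = vals[idx]
        assert np.array_equal(s.values, expected)


def test_atom_split_out_of_range(mol5):
    t = build_total_matrix(mol5, 2, EUCLID)
    with pytest.raises(IndexError):
        atom_level_split(t, 5)
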