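"""Featurization: radius graph, node features, contact order.

Oracles are naive re-implementations (all-pairs scans, scalar atan2
dihedral) kept independent of the vectorized library code.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldembed.features import (
    N_NODE_FEATURES,
    build_edges,
    contact_order,
    density_feature,
    featurize,
    positional_encoding,
    tau_angles,
    terminus_flags,
)

from conftest import make_structure, random_rigid_transform


# ---- independent oracles ----------------------------------------------


def edges_oracle(coords, cutoff=10.0):
    out = set()
    for i in range(len(coords)):
        for j in range(len(coords)):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                out.add((i, j))
    return out


def dihedral_oracle(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return np.arctan2(m1 @ n2, n1 @ n2)


def contact_order_oracle(atoms, L, cutoff=8.0):
    total, n = 0, 0
    for i in range(L):
        for j in range(i + 1, L):
            if np.linalg.norm(atoms[i] - atoms[j]) <= cutoff:
                total += j - i
                n += 1
    return (total / (L * n) if n else 0.0), n


# ---- build_edges -------------------------------------------------------


class TestBuildEdges:
    def test_below_cutoff_pair(self):
        edges = build_edges(np.array([[0.0, 0, 0], [9.9, 0, 0]]))
        assert sorted(map(tuple, edges)) == [(0, 1), (1, 0)]

    def test_above_cutoff_pair(self):
        assert len(build_edges(np.array([[0.0, 0, 0], [10.1, 0, 0]]))) == 0

    def test_exactly_at_cutoff_included(self):
        assert len(build_edges(np.array([[0.0, 0, 0], [10.0, 0, 0]]))) == 2

    def test_collinear_points_enumeration(self):
        # 5 points, 4 Å apart: neighbours at separations 1 (4 Å) and
        # 2 (8 Å) are in range, separation 3 (12 Å) is not -> 4 + 3 = 7
        # undirected edges.
        coords = np.column_stack([4.0 * np.arange(5), np.zeros(5), np.zeros(5)])
        edges = build_edges(coords)
        assert len(edges) == 14
        assert set(map(tuple, edges)) == edges_oracle(coords)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            coords = rng.uniform(0, 25, size=(rng.integers(2, 40), 3))
            edges = build_edges(coords)
            assert set(map(tuple, edges)) == edges_oracle(coords)
            assert np.all(edges[:, 0] != edges[:, 1])

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        edges = set(map(tuple, build_edges(rng.uniform(0, 20, (30, 3)))))
        assert all((j, i) in edges for i, j in edges)


# ---- density -----------------------------------------------------------


class TestDensity:
    def test_single_residue_is_zero(self):
        np.testing.assert_array_equal(density_feature(np.zeros((1, 3))), [0.0])

    def test_three_collinear_counts(self):
        coords = np.column_stack([6.0 * np.arange(3), np.zeros(3), np.zeros(3)])
        np.testing.assert_allclose(density_feature(coords), [0.5, 1.0, 0.5])

    def test_max_is_one_unless_empty(self):
        rng = np.random.default_rng(5)
        dense = density_feature(rng.uniform(0, 15, (20, 3)))
        assert dense.max() == pytest.approx(1.0)
        sparse = density_feature(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        np.testing.assert_array_equal(sparse, [0.0, 0.0])


# ---- terminus flags ----------------------------------------------------


@pytest.mark.parametrize(
    "L, expected",
    [
        (3, [(1, 0), (0, 0), (0, 1)]),
        (1, [(1, 1)]),
    ],
)
def test_terminus_flags(L, expected):
    np.testing.assert_array_equal(terminus_flags(L), expected)


def test_terminus_flags_sum_two():
    assert terminus_flags(17).sum() == 2


# ---- tau ---------------------------------------------------------------


class TestTau:
    def test_planar_cis_quadruple(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(tau_angles(coords)[1], [0.0, 1.0], atol=1e-12)

    def test_planar_trans_quadruple(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], dtype=float)
        np.testing.assert_allclose(tau_angles(coords)[1], [0.0, -1.0], atol=1e-12)

    def test_short_chain_all_zero(self):
        np.testing.assert_array_equal(tau_angles(np.random.rand(3, 3)), np.zeros((3, 2)))

    def test_terminal_rows_zero(self):
        rng = np.random.default_rng(6)
        out = tau_angles(rng.uniform(0, 10, (8, 3)))
        np.testing.assert_array_equal(out[[0, -2, -1]], np.zeros((3, 2)))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, (15, 3))
        out = tau_angles(coords)
        for i in range(1, 13):
            tau = dihedral_oracle(*coords[i - 1 : i + 3])
            np.testing.assert_allclose(out[i], [np.sin(tau), np.cos(tau)], atol=1e-12)

    def test_degenerate_quadruple_gives_zero(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        np.testing.assert_array_equal(tau_angles(coords), np.zeros((5, 2)))


# ---- positional encoding ----------------------------------------------


class TestPositionalEncoding:
    def test_position_zero_alternates(self):
        row = positional_encoding(1)[0]
        np.testing.assert_array_equal(row[0::2], np.zeros(32))
        np.testing.assert_array_equal(row[1::2], np.ones(32))

    def test_position_one_first_pair(self):
        row = positional_encoding(2)[1]
        assert row[0] == pytest.approx(np.sin(1.0))
        assert row[1] == pytest.approx(np.cos(1.0))

    def test_bounded(self):
        pe = positional_encoding(500)
        assert np.all(np.abs(pe) <= 1.0)
        assert np.all(np.sum(pe**2, axis=1) <= 64.0)


# ---- featurize ---------------------------------------------------------


class TestFeaturize:
    def test_feature_matrix_shape(self, small_dataset):
        s = small_dataset.domains[0].structure
        g = featurize(s)
        assert g.node_features.shape == (s.L, N_NODE_FEATURES)
        assert np.all(np.isfinite(g.node_features))

    def test_density_column_matches_density_feature(self, small_dataset):
        s = small_dataset.domains[1].structure
        np.testing.assert_allclose(
            featurize(s).node_features[:, 0], density_feature(s.ca_coords)
        )

    def test_rigid_transform_leaves_features_invariant(self, small_dataset):
        rng = np.random.default_rng(8)
        s = small_dataset.domains[2].structure
        g = featurize(s)
        for _ in range(5):
            moved = featurize(
                make_structure(random_rigid_transform(s.ca_coords, rng))
            )
            # discrete-origin columns are bit-identical; the τ columns are
            # continuous functions of rotated floats, identical to ~1e-12
            np.testing.assert_array_equal(
                moved.node_features[:, [0, 1, 2]], g.node_features[:, [0, 1, 2]]
            )
            np.testing.assert_array_equal(
                moved.node_features[:, 5:], g.node_features[:, 5:]
            )
            np.testing.assert_allclose(
                moved.node_features[:, 3:5], g.node_features[:, 3:5], atol=1e-12
            )
            np.testing.assert_array_equal(moved.edges, g.edges)

    def test_single_residue_degenerate(self):
        g = featurize(make_structure([[1.0, 2.0, 3.0]]))
        expected = np.concatenate([[0.0, 1.0, 1.0, 0.0, 0.0], positional_encoding(1)[0]])
        np.testing.assert_array_equal(g.node_features[0], expected)
        assert len(g.edges) == 0


# ---- contact order -----------------------------------------------------


class TestContactOrder:
    def test_single_contact_pair(self):
        # only residues 0 and 3 are within 8 Å: S = 3, N = 1, L = 4
        coords = np.array(
            [[0, 0, 0], [0, 50, 0], [0, 100, 0], [5, 0, 0]], dtype=float
        )
        result = contact_order(make_structure(coords))
        assert result.contact_order == pytest.approx(0.75)
        assert result.N == 1 and result.L == 4
        assert result.pair_separations.tolist() == [3]

    def test_straight_chain_enumeration(self):
        # 3.8 Å spacing, L = 5: contacts at separation 1 (4 pairs, 3.8 Å)
        # and 2 (3 pairs, 7.6 Å) -> ΣS = 10, N = 7 -> 10/35
        coords = np.column_stack([3.8 * np.arange(5), np.zeros(5), np.zeros(5)])
        result = contact_order(make_structure(coords))
        assert result.contact_order == pytest.approx(10 / 35)
        assert result.N == 7

    def test_no_contacts_returns_zero(self, caplog):
        coords = np.column_stack([50.0 * np.arange(3), np.zeros(3), np.zeros(3)])
        result = contact_order(make_structure(coords))
        assert result.contact_order == 0.0 and result.N == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            L = int(rng.integers(2, 40))
            s = make_structure(rng.uniform(0, 20, (L, 3)))
            result = contact_order(s)
            expected, n = contact_order_oracle(s.ca_coords, L)
            assert result.N == n
            assert result.contact_order == pytest.approx(expected, abs=1e-12)

    def test_uses_cb_when_present(self):
        ca = np.array([[0, 0, 0], [100, 0, 0]], dtype=float)
        s = make_structure(ca)
        s.cb_coords = np.array([[0, 0, 0], [5, 0, 0]], dtype=float)
        result = contact_order(s)
        assert result.N == 1  # Cβ atoms touch even though Cα do not

    def test_invariant_in_formula(self):
        rng = np.random.default_rng(10)
        s = make_structure(rng.uniform(0, 15, (20, 3)))
        r = contact_order(s)
        assert r.contact_order == pytest.approx(
            r.pair_separations.sum() / (r.L * r.N)
        )


# ---- property: SE(3) invariance of the whole pipeline ------------------


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_edges_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 20, (12, 3))
    moved = random_rigid_transform(coords, rng)
    assert set(map(tuple, build_edges(coords))) == set(map(tuple, build_edges(moved)))
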