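"""Canonical strings, enumeration and orbit numbering."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import orbiteq as oq
from orbiteq._perm import code_length, connected_code, edges_from_code

from conftest import G18_EDGES


def random_permutation(n, rng):
    p = list(range(n))
    rng.shuffle(p)
    return tuple(p)


class TestTriangularString:
    def test_reference_graphlet_identity_encoding(self, graphlet18):
        assert oq.triangular_string(graphlet18, range(5)) == "1101011100"

    def test_complete_graph_any_permutation(self, triangle):
        for perm in [(0, 1, 2), (2, 0, 1), (1, 2, 0)]:
            assert oq.triangular_string(triangle, perm) == "111"

    def test_path_two_labelings(self, path3):
        assert oq.triangular_string(path3, (0, 1, 2)) == "101"
        # relabel so the middle vertex carries the highest label
        assert oq.triangular_string(path3, (0, 2, 1)) == "011"

    def test_rejects_non_bijection(self, path3):
        with pytest.raises(oq.InputError):
            oq.triangular_string(path3, (0, 0, 2))


class TestCanonicalString:
    def test_path_and_triangle(self, path3, triangle):
        assert oq.canonical_string(path3) == "011"
        assert oq.canonical_string(triangle) == "111"

    def test_not_always_the_identity_encoding(self, graphlet18):
        assert oq.canonical_string(graphlet18) < "1101011100"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        code=st.integers(min_value=0, max_value=(1 << 10) - 1),
        perm_seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_isomorphism_invariance(self, code, perm_seed):
        """Relabeling never changes the canonical string (order 5)."""
        if not connected_code(5, code):
            return
        g = oq.Graphlet(5, edges_from_code(5, code))
        perm = random_permutation(5, random.Random(perm_seed))
        assert oq.canonical_string(oq.relabel(g, perm)) == oq.canonical_string(g)

    @pytest.mark.parametrize("order", [4, 5])
    def test_agrees_with_networkx_isomorphism(self, order):
        """Canonical-string equality must coincide with graph isomorphism."""
        rng = random.Random(7)
        length = code_length(order)
        codes = []
        while len(codes) < 16:
            c = rng.randrange(1 << length)
            if connected_code(order, c):
                codes.append(c)

        def to_nx(code):
            g = nx.Graph()
            g.add_nodes_from(range(order))
            g.add_edges_from(edges_from_code(order, code))
            return g

        for i, c1 in enumerate(codes):
            for c2 in codes[i + 1 :]:
                ours = oq.canonical_string(
                    oq.Graphlet(order, edges_from_code(order, c1))
                ) == oq.canonical_string(oq.Graphlet(order, edges_from_code(order, c2)))
                theirs = nx.is_isomorphic(to_nx(c1), to_nx(c2))
                assert ours == theirs


class TestEnumeration:
    @pytest.mark.parametrize("order,count", [(1, 1), (2, 1), (3, 2), (4, 6), (5, 21)])
    def test_catalog_sizes(self, order, count, request):
        if order <= 2:
            catalog = oq.enumerate_graphlets(order)
        else:
            catalog = request.getfixturevalue(f"catalog{order}")
        assert catalog.n_graphlets == count

    def test_catalog_is_sorted_and_connected(self, catalog5):
        canon = [e.canonical for e in catalog5.entries]
        assert canon == sorted(canon)
        assert len(set(canon)) == len(canon)
        for e in catalog5.entries:
            assert oq.is_connected(e.graphlet)
            assert e.canonical == oq.canonical_string(e.graphlet)

    def test_order_above_bound_rejected(self):
        with pytest.raises(oq.CapabilityError):
            oq.enumerate_graphlets(8)

    def test_order_below_one_rejected(self):
        with pytest.raises(oq.InputError):
            oq.enumerate_graphlets(0)


class TestOrbitNumbering:
    def test_order3_orbit_layout(self, catalog3):
        orbits = list(catalog3.orbit_representatives())
        assert [o.global_id for o in orbits] == [0, 1, 2]
        # path-end, path-middle, then triangle
        degrees = [len(o.representative.graphlet.adjacency[0]) for o in orbits]
        assert degrees == [1, 2, 2]
        assert orbits[2].representative.graphlet.size == 3

    @pytest.mark.parametrize("order,total", [(3, 3), (4, 11), (5, 58)])
    def test_orbit_totals(self, order, total, request):
        catalog = request.getfixturevalue(f"catalog{order}")
        assert catalog.n_orbits == total

    @pytest.mark.parametrize("order", [3, 4, 5])
    def test_complete_graphlet_is_last_with_one_orbit(self, order, request):
        catalog = request.getfixturevalue(f"catalog{order}")
        last = catalog.entries[-1]
        assert last.canonical == "1" * code_length(order)
        assert len(last.orbits) == 1
        assert last.orbits[0].global_id == catalog.n_orbits - 1

    def test_orbit_ids_group_by_graphlet(self, catalog5):
        seen = -1
        for entry in catalog5.entries:
            for orb in entry.orbits:
                assert orb.global_id == seen + 1
                seen = orb.global_id
            mins = [o.members[0] for o in entry.orbits]
            assert mins == sorted(mins)


class TestClassification:
    def test_path_then_triangle(self, path3, triangle, catalog3):
        assert oq.classify_graphlet(path3, catalog3) == 0
        assert oq.classify_graphlet(triangle, catalog3) == 1

    def test_complete_graphlet_is_last(self, catalog4):
        k4 = oq.make_graphlet(4, [(u, v) for u in range(4) for v in range(u + 1, 4)])
        assert oq.classify_graphlet(k4, catalog4) == 5

    def test_disconnected_rejected(self, catalog4):
        g = oq.make_graphlet(4, [(0, 1), (2, 3)], strict=False)
        with pytest.raises(oq.InputError):
            oq.classify_graphlet(g, catalog4)

    def test_marked_position_distinguishes_orbits(self, catalog3, path_end_rep, path_mid_rep):
        assert oq.classify_orbit(path_end_rep, catalog3) == 0
        assert oq.classify_orbit(path_mid_rep, catalog3) == 1

    def test_triangle_marked_anywhere(self, catalog3):
        rep = oq.make_representative(3, [(0, 1), (1, 2), (0, 2)])
        assert oq.classify_orbit(rep, catalog3) == 2

    def test_diamond_marks_give_distinct_orbits(self, catalog4, triangle_rep, path_mid_rep):
        deg2 = oq.extend_with_vertex(triangle_rep, {1, 2})
        deg3 = oq.extend_with_vertex(path_mid_rep, {0, 1, 2})
        ids = {catalog4.classify_orbit(deg2), catalog4.classify_orbit(deg3)}
        assert len(ids) == 2
        # same graphlet: consecutive global ids within the diamond entry
        assert max(ids) - min(ids) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        idx=st.integers(min_value=0, max_value=20),
        perm_seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_classification_is_relabeling_invariant(self, idx, perm_seed, catalog5):
        g = catalog5.entries[idx].graphlet
        perm = random_permutation(5, random.Random(perm_seed))
        assert oq.classify_graphlet(oq.relabel(g, perm), catalog5) == idx


class TestEdgeAdditionMonotonicity:
    @pytest.mark.parametrize("order", [3, 4, 5])
    def test_canonical_string_strictly_grows(self, order, request):
        """Adding any edge makes the canonical string lexicographically larger."""
        catalog = request.getfixturevalue(f"catalog{order}")
        for entry in catalog.entries:
            g = entry.graphlet
            for u in range(order):
                for v in range(u + 1, order):
                    if g.has_edge(u, v):
                        continue
                    bigger = oq.add_edges(g, [(u, v)])
                    assert oq.canonical_string(bigger) > entry.canonical
                    assert catalog.classify_graphlet(bigger) > entry.id

    @pytest.mark.parametrize("order", [3, 4])
    def test_orbit_id_strictly_grows(self, order, request):
        catalog = request.getfixturevalue(f"catalog{order}")
        for orb in catalog.orbit_representatives():
            rep = orb.representative
            g = rep.graphlet
            for u in range(order):
                for v in range(u + 1, order):
                    if g.has_edge(u, v):
                        continue
                    bigger = oq.add_edges(rep, [(u, v)])
                    assert catalog.classify_orbit(bigger) > orb.global_id


def test_catalog_export_schema(catalog4):
    obj = catalog4.to_json()
    assert obj["order"] == 4
    assert obj["n_graphlets"] == 6 and obj["n_orbits"] == 11
    first = obj["graphlets"][0]
    assert set(first) == {"id", "canonical_string", "edges", "orbits"}
    assert set(first["orbits"][0]) == {
        "global_id",
        "member_vertices",
        "representative_edges",
    }
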