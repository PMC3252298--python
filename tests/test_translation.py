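"""Binding layer: compartmentalization, Hines ordering, scaling, connectivity."""

import math

import numpy as np
import pytest

from arborsim.binding.connectivity import ConnectivityError, translate_connectivity
from arborsim.binding.discretize import (
    compartmentalize,
    electrotonic_length,
    expand_cell,
    linearize,
    scale_parameters,
)
from arborsim.fixtures import make_fixture
from arborsim.model.container import ModelContainer
from arborsim.model.document import load_model
from arborsim.model.types import (
    CellModel,
    ChannelPlacement,
    PopulationSpec,
    ProjectionSpec,
    SegmentSpec,
)

PASSIVE = dict(ra=1.0, rm=1.0, cm=0.01, em=-0.065)


def _segment(name="seg", parent=None, length=100e-6, diameter=2e-6, **kw):
    return SegmentSpec(name=name, parent=parent, length=length, diameter=diameter,
                       **{**PASSIVE, **kw})


class TestCompartmentalize:
    def test_short_segment_is_not_split(self):
        # lambda = sqrt(1 * 2e-6 / 4) ~ 0.707 mm; 35.4 um -> L_e = 0.05
        cell = CellModel("c", [_segment(length=35.36e-6)])
        assert electrotonic_length(cell.segments[0]) == pytest.approx(0.05, rel=1e-3)
        out = compartmentalize(cell, l_max=0.1)
        assert len(out.segments) == 1
        assert out.segments[0].name == "seg"

    def test_ceiling_rule_gives_four_subsegments(self):
        lam = math.sqrt(1.0 * 2e-6 / 4.0)
        cell = CellModel("c", [_segment(length=0.35 * lam)])
        out = compartmentalize(cell, l_max=0.1)
        assert len(out.segments) == 4
        assert [s.name for s in out.segments] == [f"seg.{k}" for k in range(4)]
        # chained distally
        assert [s.parent for s in out.segments] == [None, "seg.0", "seg.1", "seg.2"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_splitting_conserves_area_length_and_axial_resistance(self, seed):
        mtext, _ = make_fixture("random_tree", n=12, seed=seed)
        cell = load_model(mtext).cells["rtree"]
        out = compartmentalize(cell, l_max=0.02)

        def area(seg):
            return math.pi * seg.diameter * seg.length

        def r_axial(seg):
            return seg.ra * seg.length / (math.pi * (seg.diameter / 2) ** 2)

        for orig in cell.segments:
            subs = [s for s in out.segments
                    if s.name == orig.name or s.name.startswith(orig.name + ".")]
            assert sum(s.length for s in subs) == pytest.approx(orig.length, rel=1e-12)
            assert sum(area(s) for s in subs) == pytest.approx(area(orig), rel=1e-12)
            assert sum(s.spine_area for s in subs) == pytest.approx(orig.spine_area, rel=1e-12)
            # series resistance along the unbranched split is preserved
            assert sum(r_axial(s) for s in subs) == pytest.approx(r_axial(orig), rel=1e-12)
            for s in subs:  # densities are intensive: inherited unchanged
                assert [(p.channel, p.density) for p in s.channels] == [
                    (p.channel, p.density) for p in orig.channels
                ]


class TestLinearize:
    def test_unbranched_cable_is_leaf_to_root(self):
        segs = [_segment("a"), _segment("b", parent="a"), _segment("c", parent="b")]
        order = [s.name for s in linearize(CellModel("c", segs))]
        assert order == ["c", "b", "a"]

    def test_parent_always_after_child(self):
        mtext, _ = make_fixture("y_branch")
        cell = load_model(mtext).cells["ycell"]
        ordered = linearize(cell)
        pos = {s.name: i for i, s in enumerate(ordered)}
        for s in ordered:
            if s.parent is not None:
                assert pos[s.parent] > pos[s.name]

    def test_zero_fill_in_on_branched_tree(self, fill_in_count):
        mtext, _ = make_fixture("y_branch")
        model = ModelContainer.from_text(mtext).expand().solvers[0]
        parents = [c.parent_index for c in model.compartments]
        assert fill_in_count(parents, list(range(len(parents)))) == 0

    def test_random_trees_fill_in_free_and_bad_orders_are_not(self, fill_in_count):
        rng = np.random.default_rng(42)
        any_bad_fill = False
        for seed in range(20):
            mtext, _ = make_fixture("random_tree", n=50, seed=seed)
            model = ModelContainer.from_text(mtext).expand().solvers[0]
            parents = [c.parent_index for c in model.compartments]
            assert fill_in_count(parents, list(range(len(parents)))) == 0
            perm = list(rng.permutation(len(parents)))
            if fill_in_count(parents, perm) > 0:
                any_bad_fill = True
        assert any_bad_fill, "random permutations should produce fill-in on some tree"


class TestScaleParameters:
    def test_capacitance_scaling(self):
        comp = scale_parameters(_segment(), {}, 0, None, "/c/seg")
        assert comp.cm == pytest.approx(6.2832e-12, rel=1e-4)

    def test_spine_rule_capacitance_includes_conductance_excludes(self):
        mtext, _ = make_fixture("hh_soma")
        channels = load_model(mtext).channels
        seg = _segment(spine_area=200e-12)
        seg.channels = [ChannelPlacement(channel="na", density=10.0, erev=0.05)]
        comp = scale_parameters(seg, channels, 0, None, "/c/seg")
        assert comp.cm == pytest.approx(8.2832e-12, rel=1e-4)
        assert comp.channels[0].gmax == pytest.approx(6.2832e-9, rel=1e-4)
        # leak follows the membrane (spine-corrected) area
        assert comp.g_leak == pytest.approx((628.3185e-12 + 200e-12) / 1.0, rel=1e-4)

    def test_axial_resistance(self):
        comp = scale_parameters(_segment(parent="x"), {}, 0, 1, "/c/seg")
        assert comp.ra == pytest.approx(3.1831e7, rel=1e-4)

    def test_missing_parameter_reported_with_path(self):
        seg = _segment()
        seg.rm = None
        with pytest.raises(Exception) as err:
            scale_parameters(seg, {}, 0, None, "/c/seg")
        assert "/c/seg" in str(err.value) and "RM" in str(err.value)


class TestProvenance:
    def test_binding_is_one_to_one_with_the_biology(self):
        """Every compartment traces to exactly one segment and every scaled
        field reproduces from that segment's quantities alone."""
        mtext, _ = make_fixture("y_branch")
        container = ModelContainer.from_text(mtext)
        model = container.expand().solvers[0]
        cell = container.model.cells["ycell"]
        paths = [c.source_path for c in model.compartments]
        assert len(set(paths)) == len(paths)
        for comp in model.compartments:
            seg = cell.segment(comp.source_path.rsplit("/", 1)[1])
            area = math.pi * seg.diameter * seg.length
            assert comp.cm == pytest.approx(seg.cm * (area + seg.spine_area), rel=1e-12)
            assert comp.g_leak == pytest.approx((area + seg.spine_area) / seg.rm, rel=1e-12)
            assert comp.e_leak == seg.em


class TestConnectivity:
    def _net(self, n_a=2, n_b=2, rule=("all_to_all",), **proj_kw):
        pops = [PopulationSpec("a", "cell", n_a), PopulationSpec("b", "cell", n_b)]
        proj = ProjectionSpec(name="p", source="a", target="b", rule=rule,
                              weight=1e-9, delay=1e-3, **proj_kw)
        ids = {"a": list(range(n_a)), "b": list(range(n_a, n_a + n_b))}
        return pops, [proj], ids

    def test_all_to_all_is_the_full_product(self):
        pops, projs, ids = self._net()
        wires = translate_connectivity(pops, projs, ids, lambda s, seg: 0)
        assert len(wires) == 4
        assert {(w.pre_solver, w.post_solver) for w in wires} == {
            (0, 2), (0, 3), (1, 2), (1, 3)
        }

    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 400)])
    def test_probability_boundaries(self, p, expected):
        pops, projs, ids = self._net(20, 20, rule=("probabilistic", p, 7))
        wires = translate_connectivity(pops, projs, ids, lambda s, seg: 0)
        assert len(wires) == expected

    def test_probabilistic_count_and_determinism(self):
        pops, projs, ids = self._net(20, 20, rule=("probabilistic", 0.3, 123))
        wires = translate_connectivity(pops, projs, ids, lambda s, seg: 0)
        mean, sd = 400 * 0.3, math.sqrt(400 * 0.3 * 0.7)
        assert abs(len(wires) - mean) <= 3 * sd
        again = translate_connectivity(pops, projs, ids, lambda s, seg: 0)
        assert wires == again

    def test_self_connections_excluded_only_when_flagged(self):
        pops = [PopulationSpec("a", "cell", 3)]
        ids = {"a": [0, 1, 2]}
        keep = ProjectionSpec("p", "a", "a", ("all_to_all",), 1e-9, 1e-3)
        drop = ProjectionSpec("p", "a", "a", ("all_to_all",), 1e-9, 1e-3,
                              self_connections=False)
        assert len(translate_connectivity(pops, [keep], ids, lambda s, g: 0)) == 9
        assert len(translate_connectivity(pops, [drop], ids, lambda s, g: 0)) == 6

    def test_unresolvable_endpoint_is_an_error(self):
        pops, projs, ids = self._net()

        def resolve(_s, _seg):
            raise KeyError(_seg)

        with pytest.raises(ConnectivityError):
            translate_connectivity(pops, projs, ids, resolve)

    def test_endpoints_resolve_through_the_container(self):
        mtext, _ = make_fixture("random_network", n_cells=6, p=0.5, seed=2)
        container = ModelContainer.from_text(mtext)
        binding = container.expand()
        for w in binding.wiring:
            pre = binding.solvers[w.pre_solver]
            assert 0 <= w.pre_comp < pre.n_compartments
            post = binding.solvers[w.post_solver]
            assert 0 <= w.post_comp < post.n_compartments


class TestExpandCell:
    def test_incomplete_cell_expands_to_incomplete_model(self):
        seg = _segment()
        seg.ra = None
        model = expand_cell(CellModel("c", [seg]), {}, "/c")
        assert not model.complete
        assert model.missing == [("/c/seg", "RA")]
        assert model.compartments == []
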