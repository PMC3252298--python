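"""Biology model container: documents, queries, completeness, resolution."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborsim.fixtures import make_fixture
from arborsim.model.container import ModelContainer, UnknownPathError
from arborsim.model.document import DocumentError, load_model, save_model
from arborsim.model.types import CellModel, ConceptualModel, ModelValidationError, SegmentSpec

MINIMAL_DOC = """
version: 1
name: tiny
cells:
  tiny:
    segments:
      soma:
        parent: null
        length: 10.0e-6
        diameter: 10.0e-6
        RA: 1.0
        RM: 1.0
        CM: 0.01
        Em: -0.065
"""


class TestLoad:
    def test_single_segment_document(self):
        model = load_model(MINIMAL_DOC)
        cell = model.cells["tiny"]
        assert len(cell.segments) == 1
        assert cell.root().name == "soma"
        assert cell.children_of("soma") == []

    def test_dangling_parent_names_the_segment(self):
        doc = MINIMAL_DOC + """
      dend:
        parent: missing
        length: 10.0e-6
        diameter: 1.0e-6
"""
        with pytest.raises(ModelValidationError) as err:
            load_model(doc)
        assert "dend" in str(err.value)
        assert "missing" in str(err.value)

    def test_unknown_key_rejected_with_path(self):
        doc = MINIMAL_DOC.replace("Em: -0.065", "Em: -0.065\n        banana: 1")
        with pytest.raises(DocumentError) as err:
            load_model(doc)
        assert "banana" in str(err.value)
        assert "/cells/tiny/segments/soma" in str(err.value)

    def test_version_key_mandatory(self):
        with pytest.raises(DocumentError):
            load_model("cells: {}\n")

    def test_ball_and_stick_matches_direct_construction(self):
        mtext, _ = make_fixture("ball_and_stick", n=5)
        cell = load_model(mtext).cells["cell"]
        assert cell.root().name == "soma"
        chain = []
        cur = "soma"
        while True:
            kids = cell.children_of(cur)
            if not kids:
                break
            assert len(kids) == 1
            chain.append(kids[0].name)
            cur = kids[0].name
        assert chain == [f"dend{i}" for i in range(5)]

    def test_units_block_converts_on_load(self):
        doc = """
version: 1
units: {length: um, voltage: mV, membrane_resistance: kohm*cm^2}
cells:
  c:
    segments:
      soma: {parent: null, length: 100, diameter: 2, RM: 10, Em: -65}
"""
        seg = load_model(doc).cells["c"].segment("soma")
        assert seg.length == pytest.approx(100e-6)
        assert seg.diameter == pytest.approx(2e-6)
        assert seg.rm == pytest.approx(1.0)  # 10 kohm*cm^2 = 1 ohm*m^2
        assert seg.em == pytest.approx(-0.065)


class TestRoundTrip:
    def test_empty_network_round_trips(self):
        model = ConceptualModel(name="empty")
        assert load_model(save_model(model)) == model

    def test_hh_soma_round_trips_to_full_precision(self):
        mtext, _ = make_fixture("hh_soma")
        model = load_model(mtext)
        assert load_model(save_model(model)) == model

    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_round_trip(self, seed):
        mtext, _ = make_fixture("random_tree", n=20, seed=seed)
        model = load_model(mtext)
        assert load_model(save_model(model)) == model

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 1_000_000), st.floats(1e-6, 1e-3),
                              st.floats(1e-7, 1e-4)), min_size=1, max_size=12))
    def test_arbitrary_trees_round_trip(self, raw):
        segs = []
        for i, (parent_pick, length, diameter) in enumerate(raw):
            segs.append(SegmentSpec(
                name=f"s{i}", parent=None if i == 0 else f"s{parent_pick % i}",
                length=length, diameter=diameter, ra=1.0, rm=1.0, cm=0.01, em=-0.065,
            ))
        model = ConceptualModel(name="h", cells={"h": CellModel("h", segs)})
        assert load_model(save_model(model)) == model

    def test_network_documents_round_trip(self):
        mtext, _ = make_fixture("random_network", n_cells=4, p=0.5, seed=3)
        model = load_model(mtext)
        assert load_model(save_model(model)) == model


class TestCompleteness:
    def test_missing_axial_resistivity_reported(self):
        mtext, _ = make_fixture("passive_soma", drop_params={"soma": ["RA"]})
        container = ModelContainer.from_text(mtext)
        report = container.check_completeness()
        assert not report.complete
        assert report.missing == [("/cell/soma", "RA")]

    def test_fully_parameterized_model_is_complete(self, hh_container):
        report = hh_container.check_completeness()
        assert report.complete and report.missing == []

    def test_missing_parameter_is_local_to_its_segment(self):
        mtext, _ = make_fixture("ball_and_stick", n=3)
        container = ModelContainer.from_text(mtext)
        container.set_parameter("/cell/dend1", "CM", value=None)
        report = container.check_completeness()
        assert report.missing == [("/cell/dend1", "CM")]

    def test_incomplete_model_remains_loadable_and_queryable(self):
        mtext, _ = make_fixture("passive_soma", drop_params={"soma": ["RA"]})
        container = ModelContainer.from_text(mtext)
        area = container.query_surface_area("cell")
        assert area > 0
        # and it round-trips
        assert load_model(container.to_text()) == container.model


class TestQueries:
    def test_cylinder_lateral_area(self):
        mtext, _ = make_fixture("passive_soma", length=100e-6, diameter=2e-6)
        container = ModelContainer.from_text(mtext)
        area = container.query_surface_area("cell")
        assert area * 1e12 == pytest.approx(628.3185, abs=1e-3)

    def test_spine_correction_adds_spine_area(self):
        mtext, _ = make_fixture("passive_soma", length=100e-6, diameter=2e-6,
                                spine_area=200e-12)
        container = ModelContainer.from_text(mtext)
        bare = container.query_surface_area("cell", spine_corrected=False)
        corrected = container.query_surface_area("cell", spine_corrected=True)
        assert bare * 1e12 == pytest.approx(628.3185, abs=1e-3)
        assert corrected * 1e12 == pytest.approx(828.3185, abs=1e-3)

    def test_area_matches_brute_force_sum(self):
        mtext, _ = make_fixture("ball_and_stick", n=5)
        container = ModelContainer.from_text(mtext)
        expected = sum(
            math.pi * s.diameter * s.length
            for s in container.model.cells["cell"].segments
        )
        assert container.query_surface_area("cell") == pytest.approx(expected, rel=1e-12)

    def test_unknown_cell_raises(self, hh_container):
        with pytest.raises(UnknownPathError):
            hh_container.query_surface_area("nope")

    def test_channel_table_one_row_per_placement(self, hh_container):
        rows = hh_container.query_channel_table("cell")
        assert [(r[0], r[1]) for r in rows] == [("/cell/soma", "k"), ("/cell/soma", "na")]
        densities = {name: d for _p, name, d, _e in rows}
        assert densities == {"na": 1200.0, "k": 360.0}

    def test_channel_table_empty_without_channels(self, passive_container):
        assert passive_container.query_channel_table("cell") == []

    def test_channel_table_matches_tree_traversal(self):
        mtext, _ = make_fixture("random_tree", n=15, seed=5)
        container = ModelContainer.from_text(mtext)
        cell = container.model.cells["rtree"]
        expected = sorted(
            (f"/rtree/{s.name}", p.channel, p.density, p.erev)
            for s in cell.segments for p in s.channels
        )
        assert container.query_channel_table("rtree") == expected

    def test_queries_do_not_mutate_the_model(self, hh_container):
        before = hh_container.to_text()
        hh_container.query_surface_area("cell", spine_corrected=True)
        hh_container.query_channel_table("cell")
        hh_container.check_completeness()
        hh_container.expand()
        hh_container.resolve_identifier("/cell/soma", "Vm")
        assert hh_container.to_text() == before


class TestResolveIdentifier:
    def test_single_compartment_voltage_is_solver0_index0(self, passive_container):
        passive_container.expand()
        assert passive_container.resolve_identifier("/cell/soma", "Vm") == (0, 0)

    def test_seven_compartment_tree_indices_are_a_permutation(self, fill_in_count):
        mtext, _ = make_fixture("y_branch")
        container = ModelContainer.from_text(mtext)
        container.expand()
        names = [s.name for s in container.model.cells["ycell"].segments]
        ids = [container.resolve_identifier(f"/ycell/{n}", "Vm") for n in names]
        assert all(sid == 0 for sid, _ in ids)
        assert sorted(vi for _, vi in ids) == list(range(7))

    def test_mapping_is_a_bijection_over_all_state_variables(self, hh_container):
        binding = hh_container.expand()
        index = hh_container.variable_index()
        n_state = sum(len(m.state_layout()) for m in binding.solvers)
        assert len(index) == n_state  # total
        assert len(set(index.values())) == n_state  # injective
        gate_vars = {v for _p, v in index if v != "Vm"}
        assert gate_vars == {"na.m", "na.h", "k.n"}

    def test_misspelled_path_raises_unknown_path(self, hh_container):
        hh_container.expand()
        with pytest.raises(UnknownPathError):
            hh_container.resolve_identifier("/cell/axon", "Vm")

    def test_resolution_requires_expansion(self, hh_container):
        with pytest.raises(RuntimeError):
            hh_container.resolve_identifier("/cell/soma", "Vm")

    def test_mutation_invalidates_cached_expansion(self, passive_container):
        passive_container.expand()
        passive_container.set_parameter("/cell/soma", "RM", scale=2.0)
        with pytest.raises(RuntimeError):
            passive_container.resolve_identifier("/cell/soma", "Vm")
        binding = passive_container.expand()
        # leak halves when RM doubles
        assert binding.solvers[0].compartments[0].g_leak == pytest.approx(
            passive_container.query_surface_area("cell") / 2.0
        )
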