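"""Pathway network construction, activation, reachability and EPA routes."""

import itertools

import pytest

from pufamap.core_io import RuleConfig, ValidationError
from pufamap.pathway_model import (
    DEFAULT_SOURCES,
    EdgeCompartment,
    EdgeFamily,
    EnzymePresence,
    FattySpecies,
    ReactionEdge,
    RouteClass,
    activate_edges,
    build_default_model,
    consistency_report,
    enumerate_epa_routes,
    reachable_species,
    read_presence_table,
    strain_presence,
    write_presence_table,
)

ER = EdgeCompartment.ER
CHL = EdgeCompartment.CHLOROPLAST


def all_families_everywhere():
    return [
        EnzymePresence(f, frozenset({ER, CHL})) for f in EdgeFamily
    ]


@pytest.fixture
def active_model():
    return activate_edges(build_default_model(), strain_presence())


def test_species_id_round_trip():
    for sid in ["C16:0", "C16:3", "C18:1n9", "C18:2n6", "C20:5n3"]:
        assert FattySpecies.parse(sid).id == sid
    with pytest.raises(ValidationError):
        FattySpecies.parse("18:2n6")


def test_default_model_counts():
    model = build_default_model()
    assert len(model.species) == 14
    assert len(model.edges) == 13


def test_stoichiometry_enforced_at_construction():
    for e in build_default_model(include_alternative_route=True).edges:
        dc = e.product.carbons - e.substrate.carbons
        db = e.product.double_bonds - e.substrate.double_bonds
        if e.enzyme_family in (EdgeFamily.D6_ELONGASE, EdgeFamily.D9_ELONGASE):
            assert (dc, db) == (2, 0)
        else:
            assert (dc, db) == (0, 1)
    with pytest.raises(ValidationError):
        ReactionEdge(
            FattySpecies.parse("C18:0"),
            FattySpecies.parse("C20:1n9"),
            EdgeFamily.D6_ELONGASE,
            ER,
        )


def test_alternative_route_disabled_by_default():
    default_ids = {s.id for s in build_default_model().species}
    assert "C20:2n6" not in default_ids
    alt = build_default_model(include_alternative_route=True)
    assert "C20:2n6" in {s.id for s in alt.species}
    assert len(alt.edges) == 15


def test_strain_presence_activation(active_model):
    """The strain's enzyme placements leave the plastid C16:3 step and the
    ER omega-3 branch entry inactive, and the terminal EPA step active."""
    by_pair = {
        (e.substrate.id, e.product.id): e for e in active_model.edges
    }
    assert by_pair[("C20:4n6", "C20:5n3")].active
    assert not by_pair[("C16:2", "C16:3")].active  # uncertain edge
    assert not by_pair[("C18:2n6", "C18:3n3")].active  # omega-3 entry missing


def test_uncertain_edge_can_be_switched_on():
    cfg = RuleConfig(activate_uncertain_edges=True)
    model = activate_edges(
        build_default_model(), all_families_everywhere(), config=cfg
    )
    by_pair = {(e.substrate.id, e.product.id): e for e in model.edges}
    assert by_pair[("C16:2", "C16:3")].active


def test_transport_gate():
    model = activate_edges(
        build_default_model(), strain_presence(), allow_transport=False
    )
    by_pair = {(e.substrate.id, e.product.id): e for e in model.edges}
    assert not by_pair[("C20:4n6", "C20:5n3")].active


def test_empty_presence_deactivates_everything():
    model = activate_edges(build_default_model(), [])
    assert sum(e.active for e in model.edges) == 0
    closure = reachable_species(model, DEFAULT_SOURCES)
    assert {s.id for s in closure} == set(DEFAULT_SOURCES)


def test_reachability_closure_under_strain_presence(active_model):
    closure = {s.id for s in reachable_species(active_model, DEFAULT_SOURCES)}
    # hand closure on the 13-edge graph with the strain's activation
    assert closure == {
        "C16:0", "C16:1", "C16:2",
        "C18:0", "C18:1n9", "C18:2n6", "C18:3n6", "C20:3n6", "C20:4n6",
        "C20:5n3",
    }
    assert "C20:5n3" in closure
    for omega3_intermediate in ("C16:3", "C18:3n3", "C18:4n3", "C20:4n3"):
        assert omega3_intermediate not in closure


def test_reachability_all_edges_active_covers_all_species():
    cfg = RuleConfig(activate_uncertain_edges=True)
    model = activate_edges(
        build_default_model(), all_families_everywhere(), config=cfg
    )
    closure = reachable_species(model, DEFAULT_SOURCES)
    assert len(closure) == 14


def test_reachability_unknown_source_errors(active_model):
    with pytest.raises(ValidationError):
        reachable_species(active_model, ["C22:6n3"])


def test_single_omega6_epa_route(active_model):
    routes = enumerate_epa_routes(active_model)
    assert len(routes) == 1
    assert routes[0].classification is RouteClass.OMEGA6
    assert routes[0].ids == (
        "C18:0", "C18:1n9", "C18:2n6", "C18:3n6", "C20:3n6", "C20:4n6", "C20:5n3"
    )


def test_adding_er_omega3_opens_second_route():
    presence = [
        p
        if p.enzyme_family is not EdgeFamily.OMEGA3
        else EnzymePresence(EdgeFamily.OMEGA3, frozenset({ER, CHL}))
        for p in strain_presence()
    ]
    model = activate_edges(build_default_model(), presence)
    routes = enumerate_epa_routes(model)
    assert len(routes) == 2
    assert {r.classification for r in routes} == {RouteClass.OMEGA6, RouteClass.OMEGA3}


def test_no_routes_without_activation():
    model = activate_edges(build_default_model(), [])
    assert enumerate_epa_routes(model) == []


def test_deactivating_any_family_never_enlarges_closure():
    base_presence = strain_presence()
    base = {
        s.id
        for s in reachable_species(
            activate_edges(build_default_model(), base_presence), DEFAULT_SOURCES
        )
    }
    for drop in EdgeFamily:
        reduced = [p for p in base_presence if p.enzyme_family is not drop]
        closure = {
            s.id
            for s in reachable_species(
                activate_edges(build_default_model(), reduced), DEFAULT_SOURCES
            )
        }
        assert closure <= base


def test_consistency_report_with_observed_profile(active_model):
    observed = [
        "C16:0", "C16:1", "C16:2", "C16:3",
        "C18:0", "C18:1n9", "C18:2n6", "C18:3n6", "C20:3n6", "C20:4n6", "C20:5n3",
    ]
    rep = consistency_report(active_model, observed)
    detected_inactive = {s.id for s in rep.detected_but_inactive}
    undetected = {s.id for s in rep.predicted_active_but_undetected}
    assert detected_inactive == {"C16:3"}
    assert undetected == set()
    omega3 = {"C18:3n3", "C18:4n3", "C20:4n3"}
    assert not (detected_inactive | undetected) & omega3


def test_consistency_report_flags_observed_omega3(active_model):
    rep = consistency_report(active_model, ["C18:3n3", "C20:5n3"])
    assert FattySpecies.parse("C18:3n3") in rep.detected_but_inactive


def test_consistency_report_empty_when_observed_equals_closure(active_model):
    closure = reachable_species(active_model, DEFAULT_SOURCES)
    rep = consistency_report(active_model, closure)
    assert not rep.predicted_active_but_undetected
    assert not rep.detected_but_inactive


def test_presence_table_round_trip(tmp_path):
    path = tmp_path / "presence.tsv"
    presence = strain_presence()
    write_presence_table(presence, path)
    assert read_presence_table(path) == presence
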