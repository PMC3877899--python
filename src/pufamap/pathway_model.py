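"""Compartment-aware fatty-acid desaturation/elongation network for EPA synthesis.

The network encodes the two desaturation tracks of a diatom: a plastid track
acting on C16 acyl chains (Δ9 → Δ12 → (Δ6)) and an ER track acting on C18/C20
chains (Δ9 → Δ12 → Δ6 → Δ6-elongase → Δ5), converging on eicosapentaenoic
acid (EPA, C20:5n3). The ω3-desaturase can act early (C18:2n6 → C18:3n3,
opening the classical ω3 route) or last (C20:4n6 → C20:5n3, finishing the ω6
route). In this model the terminal ω3 step is a chloroplast reaction fed by
an ER-made precursor, so that edge carries ``requires_transport``.

Edges become active only when an enzyme of the required family is present in
the edge's compartment; reachability and route enumeration over active edges
turn a presence table into pathway conclusions (which species are makeable,
and whether EPA is reachable via the ω6 route, the ω3 route, or both).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from .core_io import RuleConfig, ValidationError
from .enzyme_annotation import Family


class EdgeCompartment(str, enum.Enum):
    ER = "ER"
    CHLOROPLAST = "CHLOROPLAST"


class EdgeFamily(str, enum.Enum):
    """Enzyme families that can label a reaction edge."""

    D9 = "D9"
    D12 = "D12"
    OMEGA3 = "OMEGA3"
    D6_DESATURASE = "D6_DESATURASE"
    D5_DESATURASE = "D5_DESATURASE"
    D6_ELONGASE = "D6_ELONGASE"
    D9_ELONGASE = "D9_ELONGASE"
    D8_DESATURASE = "D8_DESATURASE"


class RouteClass(str, enum.Enum):
    OMEGA6 = "OMEGA6"
    OMEGA3 = "OMEGA3"
    MIXED = "MIXED"


_SPECIES_RE = re.compile(r"^C(\d+):(\d+)(?:n(\d+))?$")


@dataclass(frozen=True, order=True)
class FattySpecies:
    """A fatty-acyl species, e.g. C20:5n3 (20 carbons, 5 double bonds, ω3)."""

    carbons: int
    double_bonds: int
    omega_series: Optional[int] = None

    def __post_init__(self) -> None:
        if self.double_bonds < 0:
            raise ValidationError("double_bonds must be >= 0")
        if self.omega_series is not None and self.omega_series not in (3, 6, 9):
            raise ValidationError("omega series must be 3, 6 or 9")

    @property
    def id(self) -> str:
        base = f"C{self.carbons}:{self.double_bonds}"
        return base if self.omega_series is None else f"{base}n{self.omega_series}"

    @classmethod
    def parse(cls, species_id: str) -> "FattySpecies":
        m = _SPECIES_RE.match(species_id)
        if not m:
            raise ValidationError(f"unparseable species id {species_id!r}")
        omega = int(m.group(3)) if m.group(3) else None
        return cls(int(m.group(1)), int(m.group(2)), omega)

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True)
class ReactionEdge:
    """One desaturation or elongation step.

    Elongases add 2 carbons at constant unsaturation; desaturases add one
    double bond at constant chain length (checked at construction).
    ``requires_transport`` marks steps whose substrate is made in the other
    compartment; ``uncertain`` marks steps whose catalyzing enzyme has not
    been placed in the required compartment in any sequenced diatom.
    """

    substrate: FattySpecies
    product: FattySpecies
    enzyme_family: EdgeFamily
    compartment: EdgeCompartment
    requires_transport: bool = False
    active: bool = False
    uncertain: bool = False

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValidationError("substrate and product must differ")
        dc = self.product.carbons - self.substrate.carbons
        db = self.product.double_bonds - self.substrate.double_bonds
        if self.enzyme_family in (EdgeFamily.D6_ELONGASE, EdgeFamily.D9_ELONGASE):
            if (dc, db) != (2, 0):
                raise ValidationError(
                    f"elongase edge {self.substrate}->{self.product} must add "
                    "2 carbons at constant unsaturation"
                )
        else:
            if (dc, db) != (0, 1):
                raise ValidationError(
                    f"desaturase edge {self.substrate}->{self.product} must add "
                    "1 double bond at constant chain length"
                )


@dataclass(frozen=True)
class EnzymePresence:
    """Which compartments hold an enzyme of one family (may be empty)."""

    enzyme_family: EdgeFamily
    compartments: frozenset[EdgeCompartment] = frozenset()


@dataclass
class PathwayModel:
    """Species + reaction edges; thin wrapper around a directed graph."""

    species: list[FattySpecies]
    edges: list[ReactionEdge]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species in model")
        known = set(self.species)
        for e in self.edges:
            if e.substrate not in known or e.product not in known:
                raise ValidationError(
                    f"edge {e.substrate}->{e.product} references unknown species"
                )

    def active_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(s.id for s in self.species)
        for e in self.edges:
            if e.active:
                g.add_edge(e.substrate.id, e.product.id, edge=e)
        return g

    def get_species(self, species_id: str) -> FattySpecies:
        for s in self.species:
            if s.id == species_id:
                return s
        raise ValidationError(f"unknown species {species_id!r}")


def _sp(species_id: str) -> FattySpecies:
    return FattySpecies.parse(species_id)


#: Default seed species for reachability: the saturated chain starters.
DEFAULT_SOURCES = ("C16:0", "C18:0")


def build_default_model(include_alternative_route: bool = False) -> PathwayModel:
    """The strain's desaturation/elongation network: 14 species, 13 core edges.

    Plastid track: C16:0 → C16:1 (Δ9) → C16:2 (Δ12) → C16:3 (Δ6, uncertain —
    no diatom has a predicted chloroplast Δ6-desaturase). ER ω6 track:
    C18:0 → C18:1n9 (Δ9) → C18:2n6 (Δ12) → C18:3n6 (Δ6) → C20:3n6
    (Δ6-elongase) → C20:4n6 (Δ5), finished by the chloroplast ω3-desaturase
    C20:4n6 → C20:5n3 (requires transport of the ER-made precursor). ER ω3
    branch: C18:2n6 → C18:3n3 (ω3) → C18:4n3 (Δ6) → C20:4n3 (Δ6-elongase) →
    C20:5n3 (Δ5).

    ``include_alternative_route`` adds the Δ9-elongation/Δ8-desaturation
    bypass (C18:2n6 → C20:2n6 → C20:3n6) described in other diatoms; it is
    off by default because no Δ9-elongase or Δ8-desaturase gene is reported
    for this strain.
    """
    species = [
        _sp("C16:0"),
        _sp("C16:1"),
        _sp("C16:2"),
        _sp("C16:3"),
        _sp("C18:0"),
        _sp("C18:1n9"),
        _sp("C18:2n6"),
        _sp("C18:3n6"),
        _sp("C20:3n6"),
        _sp("C20:4n6"),
        _sp("C18:3n3"),
        _sp("C18:4n3"),
        _sp("C20:4n3"),
        _sp("C20:5n3"),
    ]
    C = EdgeCompartment.CHLOROPLAST
    E = EdgeCompartment.ER
    edges = [
        # plastid C16 track
        ReactionEdge(_sp("C16:0"), _sp("C16:1"), EdgeFamily.D9, C),
        ReactionEdge(_sp("C16:1"), _sp("C16:2"), EdgeFamily.D12, C),
        ReactionEdge(
            _sp("C16:2"), _sp("C16:3"), EdgeFamily.D6_DESATURASE, C, uncertain=True
        ),
        # ER ω6 track
        ReactionEdge(_sp("C18:0"), _sp("C18:1n9"), EdgeFamily.D9, E),
        ReactionEdge(_sp("C18:1n9"), _sp("C18:2n6"), EdgeFamily.D12, E),
        ReactionEdge(_sp("C18:2n6"), _sp("C18:3n6"), EdgeFamily.D6_DESATURASE, E),
        ReactionEdge(_sp("C18:3n6"), _sp("C20:3n6"), EdgeFamily.D6_ELONGASE, E),
        ReactionEdge(_sp("C20:3n6"), _sp("C20:4n6"), EdgeFamily.D5_DESATURASE, E),
        # terminal ω3 desaturation in the plastid, fed from the ER
        ReactionEdge(
            _sp("C20:4n6"),
            _sp("C20:5n3"),
            EdgeFamily.OMEGA3,
            C,
            requires_transport=True,
        ),
        # ER ω3 branch
        ReactionEdge(_sp("C18:2n6"), _sp("C18:3n3"), EdgeFamily.OMEGA3, E),
        ReactionEdge(_sp("C18:3n3"), _sp("C18:4n3"), EdgeFamily.D6_DESATURASE, E),
        ReactionEdge(_sp("C18:4n3"), _sp("C20:4n3"), EdgeFamily.D6_ELONGASE, E),
        ReactionEdge(_sp("C20:4n3"), _sp("C20:5n3"), EdgeFamily.D5_DESATURASE, E),
    ]
    if include_alternative_route:
        species.append(_sp("C20:2n6"))
        edges.append(
            ReactionEdge(_sp("C18:2n6"), _sp("C20:2n6"), EdgeFamily.D9_ELONGASE, E)
        )
        edges.append(
            ReactionEdge(_sp("C20:2n6"), _sp("C20:3n6"), EdgeFamily.D8_DESATURASE, E)
        )
    return PathwayModel(species=species, edges=edges)


def strain_presence() -> list[EnzymePresence]:
    """The strain's enzyme-family → compartment assignments.

    Δ9 and Δ12 desaturases occur as ER and chloroplast isoforms; the
    ω3-desaturases are chloroplast-only; the front-end desaturases and the
    Δ6-elongase are ER-only.
    """
    C = EdgeCompartment.CHLOROPLAST
    E = EdgeCompartment.ER
    return [
        EnzymePresence(EdgeFamily.D9, frozenset({E, C})),
        EnzymePresence(EdgeFamily.D12, frozenset({E, C})),
        EnzymePresence(EdgeFamily.OMEGA3, frozenset({C})),
        EnzymePresence(EdgeFamily.D6_DESATURASE, frozenset({E})),
        EnzymePresence(EdgeFamily.D5_DESATURASE, frozenset({E})),
        EnzymePresence(EdgeFamily.D6_ELONGASE, frozenset({E})),
    ]


def presence_from_annotations(annotations, calls) -> list[EnzymePresence]:
    """Derive the presence table from enzyme annotations + localization calls.

    Only ER and chloroplast calls contribute (the pathway edges live in those
    two compartments); families never annotated get an empty compartment set.
    """
    from .localization import Compartment

    comp_map = {c.protein_id: c.compartment for c in calls}
    found: dict[EdgeFamily, set[EdgeCompartment]] = {}
    for ann in annotations:
        if ann.family == Family.UNKNOWN:
            continue
        comp = comp_map.get(ann.protein_id)
        if comp == Compartment.ER:
            found.setdefault(EdgeFamily(ann.family.value), set()).add(
                EdgeCompartment.ER
            )
        elif comp == Compartment.CHLOROPLAST:
            found.setdefault(EdgeFamily(ann.family.value), set()).add(
                EdgeCompartment.CHLOROPLAST
            )
    return [
        EnzymePresence(fam, frozenset(comps)) for fam, comps in sorted(
            found.items(), key=lambda kv: kv[0].value
        )
    ]


def activate_edges(
    model: PathwayModel,
    presence: Iterable[EnzymePresence],
    allow_transport: bool = True,
    config: Optional[RuleConfig] = None,
) -> PathwayModel:
    """Return a copy of the model with edge ``active`` flags set.

    An edge is active iff an enzyme of its family is present in its
    compartment, transport is allowed when the edge needs it, and the edge is
    not marked uncertain (uncertain edges can be switched on via
    ``config.activate_uncertain_edges`` for what-if analyses).
    """
    activate_uncertain = bool(config and config.activate_uncertain_edges)
    by_family: dict[EdgeFamily, set[EdgeCompartment]] = {}
    for p in presence:
        by_family.setdefault(p.enzyme_family, set()).update(p.compartments)
    new_edges = []
    for e in model.edges:
        ok = e.compartment in by_family.get(e.enzyme_family, set())
        if e.requires_transport and not allow_transport:
            ok = False
        if e.uncertain and not activate_uncertain:
            ok = False
        new_edges.append(replace(e, active=ok))
    return PathwayModel(species=list(model.species), edges=new_edges)


def reachable_species(
    model: PathwayModel, sources: Iterable[FattySpecies | str]
) -> set[FattySpecies]:
    """Transitive closure of the sources over active edges (sources included)."""
    src = [
        s if isinstance(s, FattySpecies) else FattySpecies.parse(s) for s in sources
    ]
    known = set(model.species)
    for s in src:
        if s not in known:
            raise ValidationError(f"unknown source species {s.id!r}")
    g = model.active_graph()
    out: set[str] = set()
    for s in src:
        out.add(s.id)
        out.update(nx.descendants(g, s.id))
    return {model.get_species(i) for i in out}


@dataclass(frozen=True)
class Route:
    """One simple path of active edges from source to target."""

    species: tuple[FattySpecies, ...]
    classification: RouteClass

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)


def _classify_route(path: Sequence[FattySpecies]) -> RouteClass:
    intermediates = path[1:-1]
    through_omega3_branch = any(
        s == FattySpecies(18, 3, 3) for s in intermediates
    )
    n3_intermediate = any(
        s.omega_series == 3 and s.carbons >= 18 for s in intermediates
    )
    if through_omega3_branch:
        return RouteClass.OMEGA3
    if not n3_intermediate:
        return RouteClass.OMEGA6
    return RouteClass.MIXED


def enumerate_epa_routes(
    model: PathwayModel,
    source: FattySpecies | str = "C18:0",
    target: FattySpecies | str = "C20:5n3",
) -> list[Route]:
    """All simple paths from source to target over active edges, classified.

    A route is ω3 when it passes through C18:3n3 (the ω3-branch entry), ω6
    when it carries no n3 intermediate before the terminal desaturation, and
    mixed otherwise.
    """
    src = source if isinstance(source, FattySpecies) else FattySpecies.parse(source)
    tgt = target if isinstance(target, FattySpecies) else FattySpecies.parse(target)
    known = set(model.species)
    if src not in known or tgt not in known:
        raise ValidationError("source and target must be model species")
    g = model.active_graph()
    routes = []
    for path_ids in nx.all_simple_paths(g, src.id, tgt.id):
        path = tuple(model.get_species(i) for i in path_ids)
        routes.append(Route(species=path, classification=_classify_route(path)))
    routes.sort(key=lambda r: r.ids)
    return routes


@dataclass(frozen=True)
class ConsistencyReport:
    """Reachability closure vs. an observed-species set (sources excluded)."""

    predicted_active_but_undetected: frozenset[FattySpecies]
    detected_but_inactive: frozenset[FattySpecies]


def consistency_report(
    model: PathwayModel,
    observed: Iterable[FattySpecies | str],
    sources: Iterable[FattySpecies | str] = DEFAULT_SOURCES,
) -> ConsistencyReport:
    """Compare the active-edge closure with an observed composition.

    ``predicted_active_but_undetected`` lists species the active network can
    make that were not observed; ``detected_but_inactive`` lists observed
    species the active network cannot make. Source species are excluded from
    both lists.
    """
    obs = {
        s if isinstance(s, FattySpecies) else FattySpecies.parse(s) for s in observed
    }
    src = {
        s if isinstance(s, FattySpecies) else FattySpecies.parse(s) for s in sources
    }
    closure = reachable_species(model, src)
    return ConsistencyReport(
        predicted_active_but_undetected=frozenset(closure - obs - src),
        detected_but_inactive=frozenset(obs - closure - src),
    )


EDGE_COLUMNS = [
    "substrate",
    "product",
    "enzyme_family",
    "compartment",
    "requires_transport",
    "active",
    "uncertain",
]


def write_model(model: PathwayModel, path) -> None:
    """Serialize the model as an edge-list TSV."""
    with open(path, "w") as handle:
        handle.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in model.edges:
            handle.write(
                "\t".join(
                    [
                        e.substrate.id,
                        e.product.id,
                        e.enzyme_family.value,
                        e.compartment.value,
                        str(e.requires_transport),
                        str(e.active),
                        str(e.uncertain),
                    ]
                )
                + "\n"
            )


def read_presence_table(path) -> list[EnzymePresence]:
    """Read a presence TSV: ``family<TAB>comma-joined compartments``."""
    presence = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["family", "compartments"]:
            raise ValidationError(
                f"{path}: expected header 'family\\tcompartments', got {header!r}"
            )
        for raw in handle:
            if not raw.strip():
                continue
            fam, comps = raw.rstrip("\n").split("\t")
            comp_set = frozenset(
                EdgeCompartment(c) for c in comps.split(",") if c
            )
            presence.append(EnzymePresence(EdgeFamily(fam), comp_set))
    return presence


def write_presence_table(presence: Iterable[EnzymePresence], path) -> None:
    with open(path, "w") as handle:
        handle.write("family\tcompartments\n")
        for p in presence:
            comps = ",".join(sorted(c.value for c in p.compartments))
            handle.write(f"{p.enzyme_family.value}\t{comps}\n")
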