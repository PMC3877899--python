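"""Desaturase / elongase family annotation by conserved-motif scanning.

Membrane fatty-acid desaturases carry three histidine-rich "boxes" that
coordinate the catalytic di-iron center; the box sequences are diagnostic of
the enzyme family (Δ12, ω3, Δ6, Δ5), and the Δ6-elongase carries a single
conserved motif. Front-end desaturases (Δ6, Δ5) are recognizable by a third
box that begins with glutamine instead of histidine, and by an N-terminal
fused cytochrome-b5 domain whose heme-binding core is the HPGG tetrapeptide.

Matching is literal-template based: a window matches a template iff its anchor
residues (every histidine, plus a leading glutamine or tryptophan when the
template starts with one) are exact and at most ``mismatch_budget`` of the
remaining positions differ. Boxes must occur in order along the sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import ProteinRecord, RuleConfig, ValidationError


class Family(str, enum.Enum):
    D9 = "D9"
    D12 = "D12"
    OMEGA3 = "OMEGA3"
    D6_DESATURASE = "D6_DESATURASE"
    D5_DESATURASE = "D5_DESATURASE"
    D6_ELONGASE = "D6_ELONGASE"
    UNKNOWN = "UNKNOWN"


#: Tie-break order when several families match with equal total mismatches.
FAMILY_ORDER = [
    Family.D12,
    Family.OMEGA3,
    Family.D6_DESATURASE,
    Family.D5_DESATURASE,
    Family.D6_ELONGASE,
    Family.D9,
]

FRONT_END_FAMILIES = {Family.D6_DESATURASE, Family.D5_DESATURASE}

#: Heme-binding core of the cytochrome-b5 domain.
CYTB5_CORE = "HPGG"
#: The fused b5 domain is N-terminal in front-end desaturases; the core must
#: lie entirely within this many residues of the start.
CYTB5_WINDOW = 120


@dataclass(frozen=True)
class MotifHit:
    """One matched box: template set name, 1-based start, matched residues."""

    pattern_name: str
    start: int
    matched: str
    mismatches: int = 0


@dataclass(frozen=True)
class FamilyTemplates:
    """Ordered box-template sets for one family.

    Desaturase families have three box slots; the elongase has one. Each slot
    lists alternative literal residue strings.
    """

    family: Family
    boxes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if self.family == Family.D6_ELONGASE:
            if len(self.boxes) != 1:
                raise ValidationError("elongase templates have one motif slot")
        elif len(self.boxes) != 3:
            raise ValidationError(
                f"{self.family.value}: desaturase templates have three box slots"
            )


def default_templates() -> list[FamilyTemplates]:
    """The built-in family templates (Δ12, ω3, Δ6, Δ5 desaturases, Δ6-elongase).

    Alternatives within a slot cover the box variants observed across diatom
    orthologs. No Δ9 templates are bundled: Δ9 boxes are strain-specific and
    must be supplied via a template override when Δ9 classification is wanted.
    """
    return [
        FamilyTemplates(
            Family.D12,
            (("HECGH",), ("HAKHH", "HAVHH"), ("HVVHH", "HVAHH")),
        ),
        FamilyTemplates(
            Family.OMEGA3,
            (("HDAGH",), ("HKKHH", "HLKHH", "HRKHH"), ("HVIHH", "HLVHH", "HVVHH")),
        ),
        FamilyTemplates(
            Family.D6_DESATURASE,
            (("HDFLHH",), ("WKNKHNGHH",), ("QVDDHHLFP",)),
        ),
        FamilyTemplates(
            Family.D5_DESATURASE,
            (
                ("HDANH",),
                ("WQEQHWTHH", "WIQKHWTHH", "WLAQHWTHH", "WMAQHWTHH"),
                ("QVEHHLFP",),
            ),
        ),
        FamilyTemplates(Family.D6_ELONGASE, (("QLSFLHVYHH",),)),
    ]


def template_anchors(template: str) -> list[int]:
    """0-based positions that must match exactly: every H, plus a leading Q/W."""
    anchors = [i for i, ch in enumerate(template) if ch == "H"]
    if template[0] in "QW" and 0 not in anchors:
        anchors.insert(0, 0)
    return sorted(anchors)


def match_window(window: str, template: str, mismatch_budget: int) -> Optional[int]:
    """Mismatch count if ``window`` matches ``template``, else None.

    Anchor positions must be identical; at most ``mismatch_budget`` of the
    remaining positions may differ.
    """
    if len(window) != len(template):
        return None
    anchors = set(template_anchors(template))
    mismatches = 0
    for i, (a, b) in enumerate(zip(window, template)):
        if a == b:
            continue
        if i in anchors:
            return None
        mismatches += 1
        if mismatches > mismatch_budget:
            return None
    return mismatches


def _slot_matches(
    sequence: str, slot_name: str, alternatives: Sequence[str], budget: int
) -> list[MotifHit]:
    """All windows matching any alternative of one box slot, leftmost first.

    When several alternatives match the same window, the one with the fewest
    mismatches is kept.
    """
    hits: dict[int, MotifHit] = {}
    for alt in alternatives:
        w = len(alt)
        for start0 in range(len(sequence) - w + 1):
            mm = match_window(sequence[start0 : start0 + w], alt, budget)
            if mm is None:
                continue
            prev = hits.get(start0)
            if prev is None or mm < prev.mismatches:
                hits[start0] = MotifHit(
                    pattern_name=slot_name,
                    start=start0 + 1,
                    matched=sequence[start0 : start0 + w],
                    mismatches=mm,
                )
    return [hits[s] for s in sorted(hits)]


def scan_boxes(
    protein: ProteinRecord,
    templates: FamilyTemplates,
    mismatch_budget: int = 1,
) -> list[MotifHit]:
    """Scan a protein for one family's box complement.

    Returns hits in order of position. Overlapping hits within the same box
    slot are resolved leftmost-first (greedy non-overlapping). An empty list
    is a valid result.
    """
    if mismatch_budget < 0:
        raise ValidationError("mismatch_budget must be >= 0")
    prefix = templates.family.value.lower()
    out: list[MotifHit] = []
    for slot_idx, alternatives in enumerate(templates.boxes, start=1):
        name = f"{prefix}_box{slot_idx}"
        chosen: list[MotifHit] = []
        for hit in _slot_matches(protein.sequence, name, alternatives, mismatch_budget):
            if chosen and hit.start < chosen[-1].start + len(chosen[-1].matched):
                continue  # overlaps the previously kept hit for this slot
            chosen.append(hit)
        out.extend(chosen)
    out.sort(key=lambda h: (h.start, h.pattern_name))
    return out


def _best_ordered_assignment(
    sequence: str, templates: FamilyTemplates, budget: int
) -> Optional[list[MotifHit]]:
    """Lowest-mismatch in-order, non-overlapping assignment of all box slots."""
    prefix = templates.family.value.lower()
    per_slot = [
        _slot_matches(sequence, f"{prefix}_box{i}", alts, budget)
        for i, alts in enumerate(templates.boxes, start=1)
    ]
    if any(not hits for hits in per_slot):
        return None

    best: Optional[list[MotifHit]] = None
    best_cost = None

    def extend(slot: int, min_start: int, acc: list[MotifHit], cost: int) -> None:
        nonlocal best, best_cost
        if slot == len(per_slot):
            key = (cost, tuple(h.start for h in acc))
            if best_cost is None or key < best_cost:
                best_cost = key
                best = list(acc)
            return
        for hit in per_slot[slot]:
            if hit.start < min_start:
                continue
            acc.append(hit)
            extend(slot + 1, hit.start + len(hit.matched), acc, cost + hit.mismatches)
            acc.pop()

    extend(0, 1, [], 0)
    return best


def classify_family(
    protein: ProteinRecord,
    all_templates: Optional[Sequence[FamilyTemplates]] = None,
    config: Optional[RuleConfig] = None,
) -> "EnzymeAnnotation":
    """Assign the unique family whose full box complement occurs in order.

    Ties are broken by fewest total mismatches, then by the fixed family order
    Δ12 < ω3 < Δ6 < Δ5 < elongase. ``front_end`` is set iff the third matched
    box begins with glutamine. UNKNOWN when no family's full complement is
    present.
    """
    if all_templates is None:
        all_templates = default_templates()
    if config is None:
        config = RuleConfig()
    budget = config.motif_mismatch_budget

    candidates: list[tuple[int, int, Family, list[MotifHit]]] = []
    for templates in all_templates:
        assignment = _best_ordered_assignment(protein.sequence, templates, budget)
        if assignment is None:
            continue
        total_mm = sum(h.mismatches for h in assignment)
        order = (
            FAMILY_ORDER.index(templates.family)
            if templates.family in FAMILY_ORDER
            else len(FAMILY_ORDER)
        )
        candidates.append((total_mm, order, templates.family, assignment))

    if not candidates:
        return EnzymeAnnotation(
            protein_id=protein.id,
            family=Family.UNKNOWN,
            boxes=[],
            front_end=False,
            cytb5=detect_cytb5(protein),
        )

    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, family, boxes = candidates[0]
    front_end = len(boxes) == 3 and boxes[-1].matched.startswith("Q")
    return EnzymeAnnotation(
        protein_id=protein.id,
        family=family,
        boxes=boxes,
        front_end=front_end,
        cytb5=detect_cytb5(protein),
    )


def detect_cytb5(protein: ProteinRecord) -> bool:
    """True iff the heme-binding HPGG core lies within the first 120 residues."""
    return CYTB5_CORE in protein.sequence[:CYTB5_WINDOW]


def ser_thr_rich(
    protein: ProteinRecord,
    cleavage_pos: int,
    config: Optional[RuleConfig] = None,
) -> Optional[bool]:
    """Is the region after the signal peptide serine/threonine-rich?

    Evaluates the fraction of S+T in a window of ``st_rich_window`` residues
    starting at ``cleavage_pos + 1`` (inclusive threshold). If fewer than 5
    residues remain past the cleavage site the flag is undefined (None); a
    shorter-than-window tail of at least 5 residues is evaluated as is.
    """
    if config is None:
        config = RuleConfig()
    seq = protein.sequence
    window = seq[cleavage_pos : cleavage_pos + config.st_rich_window]
    if len(window) < 5:
        return None
    frac = sum(1 for ch in window if ch in "ST") / len(window)
    return frac >= config.st_rich_fraction


@dataclass(frozen=True)
class EnzymeAnnotation:
    """Family call for one protein plus the motif evidence behind it."""

    protein_id: str
    family: Family
    boxes: list[MotifHit] = field(default_factory=list)
    front_end: bool = False
    cytb5: bool = False
    st_rich_after_signal: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.family != Family.UNKNOWN and not self.boxes:
            raise ValidationError(
                f"{self.protein_id}: family {self.family.value} requires motif hits"
            )
        if self.front_end and self.family not in FRONT_END_FAMILIES:
            raise ValidationError(
                f"{self.protein_id}: front_end only applies to Δ6/Δ5 desaturases"
            )


def load_template_override(path) -> list[FamilyTemplates]:
    """Read a family → box-lists YAML mapping, e.g. for supplying Δ9 boxes.

    Format: ``{FAMILY_NAME: [[alt, ...], [alt, ...], [alt, ...]]}`` (one inner
    list for the elongase). Families present in the file replace the built-in
    templates; others keep their defaults.
    """
    import yaml

    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    overrides = {}
    for fam_name, box_lists in data.items():
        family = Family(fam_name)
        overrides[family] = FamilyTemplates(
            family, tuple(tuple(str(a) for a in alts) for alts in box_lists)
        )
    merged = {t.family: t for t in default_templates()}
    merged.update(overrides)
    return list(merged.values())
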