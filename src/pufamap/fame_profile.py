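"""FAME composition handling: normalization, PUFA fraction, time-course trends.

GC-MS quantifies fatty acid methyl esters (FAMEs) as peak areas; composition
is expressed as percent of total FAME area. A species is polyunsaturated
(PUFA) when its acyl chain carries at least two double bonds. Trends over an
ordered time course are classified strictly: a step smaller than 0.05
percentage points in magnitude counts as flat.

The module also bundles the measured composition of *Fistulifera* sp.
JPCC DA0580 over its oil-accumulation time course (48/96/144 h): the three
dominant species are quantified (C16:0, C16:1 and EPA, with replicate
uncertainties), and the minor species seen only in trace / very small peaks
(C16:2, C16:3, C18:3n6, C20:3n6, C20:4n6) are carried as presence-only
entries without invented percentages.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_io import PathLike, ValidationError
from .pathway_model import FattySpecies

#: A chain is polyunsaturated from this many double bonds (standard usage).
PUFA_MIN_DOUBLE_BONDS = 2

#: Steps within this many percentage points count as flat.
TREND_FLAT_TOLERANCE = 0.05


class Trend(str, enum.Enum):
    INCREASING = "INCREASING"
    DECREASING = "DECREASING"
    NON_MONOTONE = "NON_MONOTONE"
    FLAT = "FLAT"


@dataclass(frozen=True)
class FamePeak:
    """One identified GC-MS peak: species and (non-negative, finite) area."""

    species: FattySpecies
    area: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.area) or self.area < 0:
            raise ValidationError(f"{self.species}: area must be finite and >= 0")


@dataclass(frozen=True)
class FameComposition:
    """Percent-of-total-FAME composition at one time point.

    ``percentages`` maps species id → percent; ``uncertainty`` optionally maps
    species id → ± percent (replicate spread); ``present_only`` lists species
    detected but not quantified (trace peaks). Partial tables are allowed:
    the percentages must not sum to more than 100 (plus a small tolerance).
    """

    time_label: str
    percentages: Mapping[str, float]
    uncertainty: Optional[Mapping[str, float]] = None
    present_only: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for sid, pct in self.percentages.items():
            FattySpecies.parse(sid)
            if pct < 0:
                raise ValidationError(f"{self.time_label}: negative percent for {sid}")
        total = sum(self.percentages.values())
        if total > 100.0 + 0.5:
            raise ValidationError(
                f"{self.time_label}: percentages sum to {total:.2f} > 100"
            )
        for sid in self.present_only:
            FattySpecies.parse(sid)

    @property
    def species_ids(self) -> frozenset[str]:
        """All species seen at this time point (quantified or trace)."""
        return frozenset(self.percentages) | self.present_only


def normalize_peaks(
    peaks: Sequence[FamePeak], time_label: str = ""
) -> FameComposition:
    """Convert peak areas to percent of total area (sums to 100)."""
    if not peaks:
        raise ValidationError("no peaks to normalize")
    total = sum(p.area for p in peaks)
    if total <= 0:
        raise ValidationError("total peak area is zero")
    seen: set[str] = set()
    pct: dict[str, float] = {}
    for p in peaks:
        if p.species.id in seen:
            raise ValidationError(f"duplicate peak for species {p.species.id}")
        seen.add(p.species.id)
        pct[p.species.id] = 100.0 * p.area / total
    return FameComposition(time_label=time_label, percentages=pct)


def pufa_percent(comp: FameComposition) -> float:
    """Summed percent over species with >= 2 double bonds."""
    return sum(
        pct
        for sid, pct in comp.percentages.items()
        if FattySpecies.parse(sid).double_bonds >= PUFA_MIN_DOUBLE_BONDS
    )


def timecourse_trend(
    series: Sequence[FameComposition],
    species: FattySpecies | str,
    flat_tolerance: float = TREND_FLAT_TOLERANCE,
) -> Trend:
    """Classify the trend of one species over an ordered time course.

    INCREASING/DECREASING require every step to move in that direction by
    more than ``flat_tolerance`` percentage points (or stay within it), with
    at least one step beyond the tolerance; all-small steps are FLAT; any
    opposing pair of beyond-tolerance steps is NON_MONOTONE.
    """
    sid = species.id if isinstance(species, FattySpecies) else species
    FattySpecies.parse(sid)
    if len(series) < 2:
        raise ValidationError("need at least two time points")
    values = []
    for comp in series:
        if sid not in comp.percentages:
            raise ValidationError(
                f"species {sid} not quantified at time point {comp.time_label!r}"
            )
        values.append(comp.percentages[sid])
    diffs = [b - a for a, b in zip(values, values[1:])]
    up = any(d > flat_tolerance for d in diffs)
    down = any(d < -flat_tolerance for d in diffs)
    if not up and not down:
        return Trend.FLAT
    if up and down:
        return Trend.NON_MONOTONE
    return Trend.INCREASING if up else Trend.DECREASING


def reference_timecourse() -> list[FameComposition]:
    """The strain's measured FAME composition at 48, 96 and 144 h.

    C16:0, C16:1 and EPA (C20:5n3) carry measured percentages with replicate
    uncertainties; the EPA-pathway intermediates detected only as trace or
    very small peaks are presence-only entries.
    """
    minor = frozenset({"C16:2", "C16:3", "C18:3n6", "C20:3n6", "C20:4n6"})
    data = {
        "48h": ({"C16:0": 29.8, "C16:1": 36.3, "C20:5n3": 17.0},
                {"C16:0": 0.2, "C16:1": 0.3, "C20:5n3": 0.1}),
        "96h": ({"C16:0": 37.3, "C16:1": 42.4, "C20:5n3": 8.3},
                {"C16:0": 0.2, "C16:1": 0.3, "C20:5n3": 0.1}),
        "144h": ({"C16:0": 36.5, "C16:1": 45.9, "C20:5n3": 6.6},
                 {"C16:0": 0.0, "C16:1": 0.0, "C20:5n3": 0.0}),
    }
    return [
        FameComposition(
            time_label=label,
            percentages=pcts,
            uncertainty=uncert,
            present_only=minor,
        )
        for label, (pcts, uncert) in data.items()
    ]


def observed_species(series: Iterable[FameComposition]) -> set[str]:
    """Union of species (quantified or trace) across a time course."""
    out: set[str] = set()
    for comp in series:
        out |= comp.species_ids
    return out


def read_peak_table(path: PathLike) -> list[FamePeak]:
    """Read a peak TSV: ``species<TAB>area`` with header."""
    peaks = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["species", "area"]:
            raise ValidationError(
                f"{path}: expected header 'species\\tarea', got {header!r}"
            )
        for raw in handle:
            if not raw.strip():
                continue
            sid, area = raw.rstrip("\n").split("\t")
            peaks.append(FamePeak(FattySpecies.parse(sid), float(area)))
    return peaks


def write_composition_table(
    series: Sequence[FameComposition], path: PathLike
) -> None:
    """Write a composition TSV: species × time-point percent matrix.

    Trace (presence-only) species are written as ``trace``.
    """
    labels = [c.time_label for c in series]
    all_species = sorted(
        {sid for c in series for sid in c.species_ids},
        key=lambda s: (FattySpecies.parse(s).carbons, FattySpecies.parse(s).double_bonds),
    )
    with open(path, "w") as handle:
        handle.write("species\t" + "\t".join(f"pct_{l}" for l in labels) + "\n")
        for sid in all_species:
            cells = [sid]
            for comp in series:
                if sid in comp.percentages:
                    cells.append(f"{comp.percentages[sid]:.4g}")
                elif sid in comp.present_only:
                    cells.append("trace")
                else:
                    cells.append("")
            handle.write("\t".join(cells) + "\n")
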