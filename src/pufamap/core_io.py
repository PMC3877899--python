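"""Input/output for the standard formats the pipeline touches, plus run configuration.

The pipeline consumes protein FASTA files, a normalized tab-separated table of
external localization-predictor outputs (TargetP / HECTAR / SignalP / Mitoprot /
TMHMM / HMMTOP conclusions, one row per protein), and a small key/value YAML
configuration. Predictor outputs are consumed as categorical conclusions only —
the upstream tools' native report formats vary by version and none of their
internals are re-implemented here.

Coordinates are 1-based and inclusive throughout: a signal-peptide cleavage
position is the index of the LAST residue of the signal peptide, so the "+1
position" of a cleavage site is ``cleavage_pos + 1``.
"""

from __future__ import annotations

import dataclasses
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids plus X (unknown residue).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed value violates a domain invariant."""


class TargetPCall(str, enum.Enum):
    SECRETORY = "SECRETORY"
    MITOCHONDRION = "MITOCHONDRION"
    OTHER = "OTHER"


class HectarCall(str, enum.Enum):
    SIGNAL_PEPTIDE = "SIGNAL_PEPTIDE"
    CHLOROPLAST = "CHLOROPLAST"
    MITOCHONDRION = "MITOCHONDRION"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: identifier, free-text description, residue string.

    The sequence is uppercase one-letter code restricted to the 20 canonical
    residues plus X; anything else is rejected at construction.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.id}: illegal residue(s) {sorted(bad)} "
                "(alphabet is the 20 canonical amino acids plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictorBundle:
    """Parsed external-predictor conclusions for one protein.

    ``signalp_cleavage_pos`` is the 1-based position of the last residue of
    the predicted signal peptide (absent if SignalP predicted no cleavage).
    ``mitoprot_score`` is the probability-like export score in [0, 1].
    """

    protein_id: str
    targetp_call: TargetPCall = TargetPCall.OTHER
    hectar_call: HectarCall = HectarCall.OTHER
    signalp_cleavage_pos: Optional[int] = None
    mitoprot_score: float = 0.0
    tmhmm_tm_count: int = 0
    hmmtop_tm_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mitoprot_score <= 1.0:
            raise ValidationError(
                f"{self.protein_id}: mitoprot_score {self.mitoprot_score} "
                "outside [0, 1]"
            )
        if self.signalp_cleavage_pos is not None and self.signalp_cleavage_pos < 1:
            raise ValidationError(
                f"{self.protein_id}: cleavage position must be >= 1"
            )
        if self.tmhmm_tm_count < 0:
            raise ValidationError(f"{self.protein_id}: TM count must be >= 0")
        if self.hmmtop_tm_count is not None and self.hmmtop_tm_count < 0:
            raise ValidationError(f"{self.protein_id}: TM count must be >= 0")


@dataclass
class RuleConfig:
    """Tunable thresholds of the rule cascade.

    mitoprot_high / mitoprot_agree are the Mitoprot score cutoffs for the
    unconditional and predictor-supported mitochondrial rules (strict >).
    de_abs_lfc is the |log2 fold change| cutoff for the differential-expression
    flag (inclusive). st_rich_window / st_rich_fraction define the
    serine/threonine-rich test applied downstream of signal-peptide cleavage
    sites. motif_mismatch_budget is the number of non-anchor mismatches
    tolerated when matching conserved enzyme motifs.
    """

    mitoprot_high: float = 0.9
    mitoprot_agree: float = 0.8
    de_abs_lfc: float = 1.0
    st_rich_window: int = 20
    st_rich_fraction: float = 0.30
    motif_mismatch_budget: int = 1
    pseudocount: float = 0.0
    activate_uncertain_edges: bool = False
    allow_transport: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mitoprot_agree <= self.mitoprot_high <= 1.0:
            raise ValidationError(
                "require 0 <= mitoprot_agree <= mitoprot_high <= 1, got "
                f"{self.mitoprot_agree}, {self.mitoprot_high}"
            )
        if self.de_abs_lfc <= 0:
            raise ValidationError("de_abs_lfc must be > 0")
        if self.st_rich_window < 1:
            raise ValidationError("st_rich_window must be >= 1")
        if not 0.0 <= self.st_rich_fraction <= 1.0:
            raise ValidationError("st_rich_fraction must be in [0, 1]")
        if self.motif_mismatch_budget < 0:
            raise ValidationError("motif_mismatch_budget must be >= 0")


PREDICTOR_COLUMNS = [
    "protein_id",
    "targetp",
    "hectar",
    "signalp_cleavage",
    "mitoprot",
    "tmhmm_tm",
    "hmmtop_tm",
]


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased; record order is preserved. An illegal residue or
    malformed header raises :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        lines = handle.readlines()
    # Pre-scan for format errors so we can report line numbers, which
    # Bio.SeqIO does not surface.
    seen_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if len(line) == 1:
                raise ParseError(f"{path}:{lineno}: empty FASTA header")
            seen_header = True
        else:
            if not seen_header:
                raise ParseError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            bad = set(line.upper()) - AMINO_ACIDS
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: illegal residue(s) {sorted(bad)}"
                )
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id} has an empty sequence")
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    """Write protein records as FASTA (60-column wrapping)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def _parse_optional_int(token: str, what: str, row: str) -> Optional[int]:
    if token == "":
        return None
    try:
        return int(token)
    except ValueError as exc:
        raise ParseError(f"{what} {token!r} is not an integer in row {row!r}") from exc


def read_predictor_table(path: PathLike) -> list[PredictorBundle]:
    """Read the normalized predictor TSV into :class:`PredictorBundle` objects.

    Expected header: ``protein_id targetp hectar signalp_cleavage mitoprot
    tmhmm_tm hmmtop_tm`` (tab-separated). Empty cells denote absent optional
    values, never zero.
    """
    path = Path(path)
    bundles: list[PredictorBundle] = []
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: missing header row")
        header = header_line.rstrip("\n").split("\t")
        if header != PREDICTOR_COLUMNS:
            raise ParseError(
                f"{path}: unexpected header {header!r}; "
                f"expected {PREDICTOR_COLUMNS!r}"
            )
        for lineno, raw in enumerate(handle, start=2):
            if not raw.strip():
                continue
            cells = raw.rstrip("\n").split("\t")
            if len(cells) != len(PREDICTOR_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(PREDICTOR_COLUMNS)} "
                    f"columns, got {len(cells)}"
                )
            pid, targetp, hectar, cleav, mito, tm, hmmtop = cells
            try:
                targetp_call = TargetPCall(targetp)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: unknown TargetP call {targetp!r}"
                ) from None
            try:
                hectar_call = HectarCall(hectar)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: unknown HECTAR call {hectar!r}"
                ) from None
            try:
                mito_score = float(mito)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: mitoprot score {mito!r} is not a number"
                ) from None
            bundles.append(
                PredictorBundle(
                    protein_id=pid,
                    targetp_call=targetp_call,
                    hectar_call=hectar_call,
                    signalp_cleavage_pos=_parse_optional_int(
                        cleav, "cleavage position", raw.rstrip("\n")
                    ),
                    mitoprot_score=mito_score,
                    tmhmm_tm_count=int(tm) if tm != "" else 0,
                    hmmtop_tm_count=_parse_optional_int(
                        hmmtop, "HMMTOP TM count", raw.rstrip("\n")
                    ),
                )
            )
    return bundles


def write_predictor_table(bundles: Iterable[PredictorBundle], path: PathLike) -> None:
    """Serialize predictor bundles to the normalized TSV (round-trip safe)."""
    with open(path, "w") as handle:
        handle.write("\t".join(PREDICTOR_COLUMNS) + "\n")
        for b in bundles:
            cells = [
                b.protein_id,
                b.targetp_call.value,
                b.hectar_call.value,
                "" if b.signalp_cleavage_pos is None else str(b.signalp_cleavage_pos),
                repr(b.mitoprot_score),
                str(b.tmhmm_tm_count),
                "" if b.hmmtop_tm_count is None else str(b.hmmtop_tm_count),
            ]
            handle.write("\t".join(cells) + "\n")


def read_config(path: PathLike) -> RuleConfig:
    """Load a :class:`RuleConfig` from a YAML key/value file.

    Unknown keys are rejected; omitted keys keep their defaults.
    """
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RuleConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RuleConfig(**data)


def write_config(config: RuleConfig, path: PathLike) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(dataclasses.asdict(config), handle, sort_keys=True)


REPORT_COLUMNS = [
    "protein_id",
    "compartment",
    "evidence",
    "st_rich_support",
    "family",
    "boxes",
    "front_end",
    "cytb5",
]


def write_report(calls, annotations, path: PathLike) -> None:
    """Write the joined localization + enzyme-annotation report as TSV.

    One row per protein in the order of ``calls``; the evidence trail is
    serialized as semicolon-joined rule names, motif hits as
    ``pattern@start`` pairs. Duplicate protein ids are an error.
    """
    ann_by_id = {}
    for ann in annotations:
        if ann.protein_id in ann_by_id:
            raise ValidationError(f"duplicate protein_id {ann.protein_id!r}")
        ann_by_id[ann.protein_id] = ann
    seen: set[str] = set()
    with open(path, "w") as handle:
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for call in calls:
            if call.protein_id in seen:
                raise ValidationError(f"duplicate protein_id {call.protein_id!r}")
            seen.add(call.protein_id)
            ann = ann_by_id.get(call.protein_id)
            cells = [
                call.protein_id,
                call.compartment.value,
                ";".join(call.evidence),
                "" if call.st_rich_support is None else str(call.st_rich_support),
                ann.family.value if ann else "",
                ";".join(f"{h.pattern_name}@{h.start}" for h in ann.boxes)
                if ann
                else "",
                str(ann.front_end) if ann else "",
                str(ann.cytb5) if ann else "",
            ]
            handle.write("\t".join(cells) + "\n")
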