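"""Transcript-abundance screen: RPKM, log2 fold change, DE flag, display bins.

Abundance is normalized as reads per kilobase of exon model per million mapped
reads (RPKM = 1e9 * count / (exon_length_bp * total_mapped)). Expression change
is the log2 ratio of a time point's RPKM to the pre-accumulation reference
(48 h by default); genes with |log2 fold change| >= 1 are flagged UP or DOWN.
For display, RPKM magnitudes are binned on a log2 scale into bins 3..10
(bin k covers [2^k, 2^(k+1)), bin 10 is open-ended, values below 8 fall
below the displayed range).

Zero RPKM in either numerator or denominator yields an UNDEFINED fold change
rather than a silently regularized value; a pseudocount can be enabled in the
configuration but is off by default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core_io import PathLike, RuleConfig, ValidationError


class Undefined(enum.Enum):
    """Singleton marker for fold changes with a zero numerator/denominator."""

    UNDEFINED = "UNDEFINED"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"


UNDEFINED = Undefined.UNDEFINED


class DEFlag(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"
    UNDEFINED = "UNDEFINED"


class BelowRange(enum.Enum):
    """Display-bin marker for RPKM below the smallest displayed bin."""

    BELOW_RANGE = "BELOW_RANGE"


BELOW_RANGE = BelowRange.BELOW_RANGE

BIN_MIN = 3
BIN_MAX = 10

DEFAULT_TIME_LABELS = ("48h", "96h", "144h")
DEFAULT_REFERENCE = "48h"


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene read counts with exon length and library sizes per time point."""

    gene_id: str
    exon_length_bp: int
    counts: Mapping[str, float]
    totals: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.exon_length_bp <= 0:
            raise ValidationError(f"{self.gene_id}: exon length must be > 0")
        if set(self.counts) != set(self.totals):
            raise ValidationError(
                f"{self.gene_id}: counts and totals must share time-point labels"
            )
        for label, c in self.counts.items():
            t = self.totals[label]
            if t <= 0:
                raise ValidationError(f"{self.gene_id}: total at {label} must be > 0")
            if c < 0:
                raise ValidationError(f"{self.gene_id}: negative count at {label}")
            if c > t:
                raise ValidationError(
                    f"{self.gene_id}: count exceeds total mapped reads at {label}"
                )


@dataclass(frozen=True)
class FoldChangeRecord:
    """Derived per-gene quantities: RPKM, log2 fold changes, DE flags, bins."""

    gene_id: str
    rpkm: Mapping[str, float]
    lfc: Mapping[str, Union[float, Undefined]]
    de_flag: Mapping[str, DEFlag]
    bin: Mapping[str, Union[int, BelowRange]]


def rpkm(count: float, exon_length_bp: int, total_mapped: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValidationError("exon length must be > 0")
    if total_mapped <= 0:
        raise ValidationError("total mapped reads must be > 0")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return 1e9 * count / (exon_length_bp * total_mapped)


def log2_fold_change(
    rpkm_t: float, rpkm_ref: float, pseudocount: float = 0.0
) -> Union[float, Undefined]:
    """log2(rpkm_t / rpkm_ref); UNDEFINED when either side is zero.

    With a positive ``pseudocount`` both sides are shifted before the ratio,
    so the result is always defined.
    """
    if rpkm_t < 0 or rpkm_ref < 0:
        raise ValidationError("RPKM values must be >= 0")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    a = rpkm_t + pseudocount
    b = rpkm_ref + pseudocount
    if a == 0 or b == 0:
        return UNDEFINED
    return math.log2(a / b)


def de_flag(
    lfc: Union[float, Undefined], config: Optional[RuleConfig] = None
) -> DEFlag:
    """UP iff lfc >= threshold (inclusive), DOWN iff lfc <= -threshold."""
    if config is None:
        config = RuleConfig()
    if isinstance(lfc, Undefined):
        return DEFlag.UNDEFINED
    if lfc >= config.de_abs_lfc:
        return DEFlag.UP
    if lfc <= -config.de_abs_lfc:
        return DEFlag.DOWN
    return DEFlag.NONE


def rpkm_bin(value: float) -> Union[int, BelowRange]:
    """Display bin: floor(log2(value)) clamped to [3, 10]; < 8 is below range.

    Bin boundaries are half-open: bin k covers [2^k, 2^(k+1)), and bin 10 is
    open-ended above 1024.
    """
    if value < 0:
        raise ValidationError("RPKM must be >= 0")
    if value < 2.0**BIN_MIN:
        return BELOW_RANGE
    return min(int(math.floor(math.log2(value))), BIN_MAX)


def fold_change_record(
    record: ExpressionRecord,
    config: Optional[RuleConfig] = None,
    reference: str = DEFAULT_REFERENCE,
) -> FoldChangeRecord:
    """Compute RPKM per time point, log2 fold changes vs. the reference,
    DE flags, and display bins for one gene."""
    if config is None:
        config = RuleConfig()
    if reference not in record.counts:
        raise ValidationError(
            f"{record.gene_id}: reference label {reference!r} absent from counts"
        )
    rpkms = {
        label: rpkm(record.counts[label], record.exon_length_bp, record.totals[label])
        for label in record.counts
    }
    lfcs: dict[str, Union[float, Undefined]] = {}
    flags: dict[str, DEFlag] = {}
    for label in record.counts:
        if label == reference:
            continue
        val = log2_fold_change(rpkms[label], rpkms[reference], config.pseudocount)
        lfcs[label] = val
        flags[label] = de_flag(val, config)
    bins = {label: rpkm_bin(v) for label, v in rpkms.items()}
    return FoldChangeRecord(
        gene_id=record.gene_id, rpkm=rpkms, lfc=lfcs, de_flag=flags, bin=bins
    )


def compute_fold_changes(
    records: Sequence[ExpressionRecord],
    config: Optional[RuleConfig] = None,
    reference: str = DEFAULT_REFERENCE,
) -> list[FoldChangeRecord]:
    return [fold_change_record(r, config, reference) for r in records]


def read_count_table(
    path: PathLike, labels: Sequence[str] = DEFAULT_TIME_LABELS
) -> list[ExpressionRecord]:
    """Read the count TSV: gene_id, exon_length_bp, count_<L>..., total_<L>..."""
    df = pd.read_csv(path, sep="\t")
    required = (
        ["gene_id", "exon_length_bp"]
        + [f"count_{l}" for l in labels]
        + [f"total_{l}" for l in labels]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene id(s) {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ExpressionRecord(
                gene_id=str(row.gene_id),
                exon_length_bp=int(row.exon_length_bp),
                counts={l: float(getattr(row, f"count_{l}")) for l in labels},
                totals={l: float(getattr(row, f"total_{l}")) for l in labels},
            )
        )
    return records


def fold_changes_frame(
    results: Sequence[FoldChangeRecord],
    labels: Sequence[str] = DEFAULT_TIME_LABELS,
    reference: str = DEFAULT_REFERENCE,
) -> pd.DataFrame:
    """Tabulate fold-change records (one row per gene) for reporting."""
    rows = []
    for r in results:
        row: dict[str, object] = {"gene_id": r.gene_id}
        for l in labels:
            row[f"rpkm_{l}"] = r.rpkm[l]
            b = r.bin[l]
            row[f"bin_{l}"] = b if isinstance(b, int) else b.value
        for l in labels:
            if l == reference:
                continue
            v = r.lfc[l]
            row[f"lfc_{l}"] = v if not isinstance(v, Undefined) else float("nan")
            row[f"de_{l}"] = r.de_flag[l].value
        rows.append(row)
    return pd.DataFrame(rows)


def write_fold_change_table(
    results: Sequence[FoldChangeRecord],
    path: PathLike,
    labels: Sequence[str] = DEFAULT_TIME_LABELS,
    reference: str = DEFAULT_REFERENCE,
) -> None:
    fold_changes_frame(results, labels, reference).to_csv(path, sep="\t", index=False)
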