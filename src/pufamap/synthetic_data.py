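"""Synthetic inputs with the structure the analysis assumes.

Every stage of the pipeline can be exercised without external downloads:

* proteins with planted targeting signals (bipartite plastid signal,
  ER-retention tetrapeptide, PTS1 tripeptide) and planted family box
  complements, on a background alphabet that provably cannot produce a
  spurious motif (it contains none of the anchor residues H/Q/W, no S/T, and
  no L/M, so no box, HPGG core, retention signal or PTS1 can arise by
  chance);
* predictor bundles consistent with the planted ground truth, with an
  optional independent per-field corruption rate;
* count tables with planted log2 fold changes under a Gamma-Poisson
  (negative-binomial) noise model;
* GC-MS peak tables realizing a stated composition under lognormal area
  noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import (
    HectarCall,
    PredictorBundle,
    ProteinRecord,
    TargetPCall,
    ValidationError,
)
from .enzyme_annotation import Family, FamilyTemplates, default_templates
from .expression import ExpressionRecord
from .fame_profile import FameComposition, FamePeak
from .localization import Compartment
from .pathway_model import FattySpecies

#: Residues that can never participate in any rule motif: excludes the box
#: anchors H/Q/W, the S/T of the serine/threonine-rich test, and the L/M that
#: every admissible ER-retention or PTS1 C-terminus ends with.
BACKGROUND_ALPHABET = "ACDEFGIKNPRVY"

#: Hydrophobic subset used for the signal-peptide core.
_HYDROPHOBIC = "AFIVP"

#: Length of the planted signal peptide (cleavage after this residue).
SIGNAL_LENGTH = 18

_PTS1_TRIPEPTIDES = [
    a + b + c for a in "SAC" for b in "KRH" for c in "LM"
] + ["SSL"]

_ER_RETENTION_TAILS = [a + b + "EL" for a in "KD" for b in "DE"]


class ERMechanism(str, enum.Enum):
    """How a synthetic ER protein earns its call: retention signal or TM helices."""

    RETENTION = "RETENTION"
    TM = "TM"


#: A synthetic Δ9-desaturase box triple for exercising the template-override
#: path. These strings are synthetic test motifs, not motifs reported for any
#: strain; real Δ9 classification requires a user-supplied template file.
SYNTHETIC_D9_TEMPLATES = FamilyTemplates(
    Family.D9, (("HRYNNH",), ("HRAHH",), ("HNVNNH",))
)


def templates_with_synthetic_d9() -> list[FamilyTemplates]:
    """Default templates plus the synthetic Δ9 triple (test support)."""
    return default_templates() + [SYNTHETIC_D9_TEMPLATES]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of one synthetic protein + bundle."""

    truth_compartment: Compartment
    family: Optional[Family] = None
    seed: int = 0
    noise_rate: float = 0.0
    length: int = 350
    er_mechanism: Optional[ERMechanism] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError("noise_rate must be in [0, 1]")
        if self.length < 1:
            raise ValidationError("length must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted: the fields the classifiers are expected to recover."""

    protein_id: str
    compartment: Compartment
    family: Optional[Family]
    cleavage_pos: Optional[int]
    er_mechanism: Optional[ERMechanism]
    box_starts: tuple[int, ...] = ()


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n))


def _family_templates(family: Family) -> FamilyTemplates:
    for t in templates_with_synthetic_d9():
        if t.family == family:
            return t
    raise ValidationError(f"no templates for family {family.value}")


def make_protein(spec: SyntheticSpec) -> tuple[ProteinRecord, TruthRecord]:
    """Generate one protein with the requested compartment and family planted.

    Plastid proteins get a signal peptide, an aromatic/leucine +1 residue and
    a Ser/Thr-rich 20-mer; ER proteins get either a signal peptide with a
    C-terminal retention tetrapeptide or nothing sequence-level (the TM
    variant is carried by the bundle); peroxisomal proteins get a C-terminal
    PTS1. Family box complements are planted in order with >= 20-residue
    spacers; front-end families additionally get the cytochrome-b5 HPGG core
    in the N-terminal region.
    """
    rng = np.random.default_rng([spec.seed, 0xA11CE])
    comp = spec.truth_compartment

    er_mech = spec.er_mechanism
    if comp == Compartment.ER and er_mech is None:
        er_mech = ERMechanism(rng.choice([m.value for m in ERMechanism]))
    if comp != Compartment.ER:
        er_mech = None

    seq = list(_background(rng, spec.length))
    cleavage: Optional[int] = None

    has_signal = comp == Compartment.CHLOROPLAST or er_mech == ERMechanism.RETENTION
    plant_from = 0
    if has_signal:
        signal = "M" + "".join(
            rng.choice(list(_HYDROPHOBIC), size=SIGNAL_LENGTH - 1)
        )
        seq[:SIGNAL_LENGTH] = list(signal)
        cleavage = SIGNAL_LENGTH
        if comp == Compartment.CHLOROPLAST:
            seq[SIGNAL_LENGTH] = str(rng.choice(list("FWYL")))
            # Ser/Thr-rich transit-peptide-like region: alternate S/T with
            # background, fraction 0.5 over the 20-mer window.
            window = []
            for i in range(20):
                if i % 2 == 0:
                    window.append(str(rng.choice(["S", "T"])))
                else:
                    window.append(str(rng.choice(list(BACKGROUND_ALPHABET))))
            seq[SIGNAL_LENGTH + 1 : SIGNAL_LENGTH + 21] = window
            plant_from = SIGNAL_LENGTH + 21
        else:
            # secretory signal without the plastid +1 residue
            seq[SIGNAL_LENGTH] = "A"
            plant_from = SIGNAL_LENGTH + 1

    tail_reserved = 0
    if comp == Compartment.PEROXISOME:
        tri = _PTS1_TRIPEPTIDES[int(rng.integers(len(_PTS1_TRIPEPTIDES)))]
        seq[-3:] = list(tri)
        tail_reserved = 3
    elif er_mech == ERMechanism.RETENTION:
        tail = _ER_RETENTION_TAILS[int(rng.integers(len(_ER_RETENTION_TAILS)))]
        seq[-4:] = list(tail)
        tail_reserved = 4

    box_starts: list[int] = []
    if spec.family is not None:
        templates = _family_templates(spec.family)
        boxes = [alts[int(rng.integers(len(alts)))] for alts in templates.boxes]
        if spec.family in (Family.D6_DESATURASE, Family.D5_DESATURASE):
            # fused cytochrome-b5 domain core, N-terminal
            hpgg_at = plant_from
            seq[hpgg_at : hpgg_at + 4] = list("HPGG")
            plant_from = hpgg_at + 4 + 5
        pos = plant_from + 20
        for box in boxes:
            if pos + len(box) > spec.length - tail_reserved - 1:
                raise ValidationError(
                    f"length {spec.length} too short to host the "
                    f"{spec.family.value} box complement"
                )
            seq[pos : pos + len(box)] = list(box)
            box_starts.append(pos + 1)
            pos += len(box) + 20 + int(rng.integers(0, 10))

    protein = ProteinRecord(
        id=f"syn_{comp.value.lower()}_{spec.family.value.lower() if spec.family else 'none'}_{spec.seed}",
        sequence="".join(seq),
    )
    truth = TruthRecord(
        protein_id=protein.id,
        compartment=comp,
        family=spec.family,
        cleavage_pos=cleavage,
        er_mechanism=er_mech,
        box_starts=tuple(box_starts),
    )
    return protein, truth


def make_bundle(truth: TruthRecord, spec: SyntheticSpec) -> PredictorBundle:
    """Generate a predictor bundle consistent with the truth (noise 0).

    With ``noise_rate`` r each field is independently replaced by a random
    admissible value with probability r (fields are corrupted independently;
    correlated predictor failure modes are not modeled).
    """
    rng = np.random.default_rng([spec.seed, 0xB0D1E])
    comp = truth.compartment

    if truth.cleavage_pos is not None:
        cleavage: Optional[int] = truth.cleavage_pos
        targetp = TargetPCall.SECRETORY
        hectar = (
            HectarCall.CHLOROPLAST
            if comp == Compartment.CHLOROPLAST
            else HectarCall.SIGNAL_PEPTIDE
        )
        mitoprot = float(rng.uniform(0.0, 0.5))
        tm = int(rng.integers(3, 7))
    elif comp == Compartment.MITOCHONDRION:
        cleavage = None
        targetp = TargetPCall.MITOCHONDRION
        hectar = HectarCall.MITOCHONDRION
        # Mitoprot score above the unconditional threshold
        mitoprot = float(np.nextafter(1.0, 0.0) - rng.uniform(0.0, 0.0999))
        tm = 0
    elif comp == Compartment.ER and truth.er_mechanism == ERMechanism.TM:
        cleavage = None
        targetp = TargetPCall.OTHER
        hectar = HectarCall.OTHER
        mitoprot = float(rng.uniform(0.0, 0.5))
        tm = int(rng.integers(1, 8))
    elif comp == Compartment.PEROXISOME:
        cleavage = None
        targetp = TargetPCall.OTHER
        hectar = HectarCall.OTHER
        mitoprot = float(rng.uniform(0.0, 0.5))
        tm = int(rng.integers(0, 4))
    else:  # CYTOPLASM
        cleavage = None
        targetp = TargetPCall.OTHER
        hectar = HectarCall.OTHER
        mitoprot = float(rng.uniform(0.0, 0.5))
        tm = 0

    hmmtop: Optional[int] = tm + int(rng.integers(0, 2))

    r = spec.noise_rate
    if r > 0:
        length = spec.length
        if rng.random() < r:
            targetp = TargetPCall(
                str(rng.choice([c.value for c in TargetPCall]))
            )
        if rng.random() < r:
            hectar = HectarCall(str(rng.choice([c.value for c in HectarCall])))
        if rng.random() < r:
            if cleavage is not None and rng.random() < 0.5:
                cleavage = None
            else:
                cleavage = int(rng.integers(5, max(6, length - 30)))
        if rng.random() < r:
            mitoprot = float(rng.uniform(0.0, 1.0))
        if rng.random() < r:
            tm = int(rng.integers(0, 8))
        if rng.random() < r:
            hmmtop = None if rng.random() < 0.2 else int(rng.integers(0, 8))

    return PredictorBundle(
        protein_id=truth.protein_id,
        targetp_call=targetp,
        hectar_call=hectar,
        signalp_cleavage_pos=cleavage,
        mitoprot_score=mitoprot,
        tmhmm_tm_count=tm,
        hmmtop_tm_count=hmmtop,
    )


def make_dataset(
    n_per_class: int,
    seed: int = 0,
    noise_rate: float = 0.0,
    families: Sequence[Optional[Family]] = (None,),
) -> list[tuple[ProteinRecord, PredictorBundle, TruthRecord]]:
    """A balanced protein + bundle set over all five compartments."""
    out = []
    i = 0
    for comp in Compartment:
        for fam in families:
            for k in range(n_per_class):
                spec = SyntheticSpec(
                    truth_compartment=comp,
                    family=fam,
                    seed=seed * 1_000_003 + i,
                    noise_rate=noise_rate,
                )
                protein, truth = make_protein(spec)
                bundle = make_bundle(truth, spec)
                out.append((protein, bundle, truth))
                i += 1
    return out


DEFAULT_TOTALS = {"48h": 1_000_000, "96h": 1_000_000, "144h": 1_000_000}
#: Extra-Poisson variability of counts (negative-binomial dispersion). The
#: default is at the technical-replicate scale (~2% extra CV): the emulated
#: experiment sequenced one library per time point, so variability beyond
#: counting noise is small.
DEFAULT_DISPERSION = 5e-4


def make_counts(
    planted_lfc: Union[Sequence[float], Mapping[str, Sequence[float]]],
    totals: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
    reference: str = "48h",
    rpkm_ref_range: tuple[float, float] = (10.0, 1000.0),
    exon_length_range: tuple[int, int] = (1000, 2000),
) -> tuple[list[ExpressionRecord], pd.DataFrame]:
    """Count tables with planted log2 fold changes.

    Reference expected RPKM is drawn log-uniformly from ``rpkm_ref_range``;
    expected counts follow from exon length, library size and the planted
    fold change. With ``dispersion`` d > 0, counts are Gamma-Poisson draws
    with variance mu + d*mu^2; with d = 0 the exact (real-valued) expected
    counts are emitted, so planted fold changes are recovered exactly.

    Returns the records and a truth table (gene_id, exon length, reference
    RPKM, planted lfc per non-reference label).
    """
    if totals is None:
        totals = dict(DEFAULT_TOTALS)
    if reference not in totals:
        raise ValidationError(f"reference label {reference!r} absent from totals")
    non_ref = [l for l in totals if l != reference]
    if not isinstance(planted_lfc, Mapping):
        planted_lfc = {l: list(planted_lfc) for l in non_ref}
    if set(planted_lfc) != set(non_ref):
        raise ValidationError(
            f"planted_lfc labels {sorted(planted_lfc)} must match "
            f"non-reference labels {sorted(non_ref)}"
        )
    lengths_of_vectors = {len(v) for v in planted_lfc.values()}
    if len(lengths_of_vectors) != 1:
        raise ValidationError("planted_lfc vectors must have equal length")
    n_genes = lengths_of_vectors.pop()
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if min(totals.values()) < 1e5:
        import warnings

        warnings.warn(
            "library sizes below 1e5 make fold-change recovery unreliable",
            stacklevel=2,
        )

    rng = np.random.default_rng([seed, 0xC0047])
    lo, hi = rpkm_ref_range
    rpkm_ref = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    exon_len = rng.integers(exon_length_range[0], exon_length_range[1] + 1, n_genes)

    records = []
    truth_rows = []
    for i in range(n_genes):
        L = int(exon_len[i])
        mu_ref = rpkm_ref[i] * L * totals[reference] / 1e9
        mus = {reference: mu_ref}
        for label in non_ref:
            mus[label] = (
                mu_ref * 2.0 ** planted_lfc[label][i] * totals[label] / totals[reference]
            )
        counts: dict[str, float] = {}
        for label, mu in mus.items():
            if dispersion == 0:
                counts[label] = float(mu)
            else:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
                counts[label] = float(rng.poisson(lam))
        records.append(
            ExpressionRecord(
                gene_id=f"gene_{i:05d}",
                exon_length_bp=L,
                counts=counts,
                totals=dict(totals),
            )
        )
        row = {
            "gene_id": f"gene_{i:05d}",
            "exon_length_bp": L,
            "rpkm_ref": rpkm_ref[i],
        }
        for label in non_ref:
            row[f"lfc_{label}"] = planted_lfc[label][i]
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def make_peaks(
    target: FameComposition,
    total_area: float = 1e6,
    seed: int = 0,
    cv: float = 0.0,
) -> list[FamePeak]:
    """Peak areas realizing a target composition under lognormal noise.

    Areas are proportional to the target percentages, multiplied by lognormal
    noise with coefficient of variation ``cv``. At cv = 0, normalizing the
    peaks reproduces the target exactly when the target percentages sum to
    100 (partial compositions come back rescaled to 100).
    """
    if total_area <= 0:
        raise ValidationError("total_area must be > 0")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    rng = np.random.default_rng([seed, 0xFA3E])
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    peaks = []
    for sid, pct in target.percentages.items():
        area = total_area * pct / 100.0
        if cv > 0:
            area *= float(rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma))
        peaks.append(FamePeak(FattySpecies.parse(sid), area))
    return peaks
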