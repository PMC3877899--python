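"""Rule-based subcellular localization for proteins of a secondary-plastid alga.

Diatoms acquired their plastid by secondary endosymbiosis, so nuclear-encoded
plastid proteins carry a bipartite targeting signal: an ER-type signal peptide
followed by a transit-peptide-like region. The cascade implemented here
assigns each protein to one of five compartments from its sequence plus the
categorical conclusions of external predictors:

1. If SignalP predicted a cleavage site:
   - ER when the C-terminus carries a (K/D)(D/E)EL retention signal;
   - chloroplast when the +1 residue after the cleavage site is F, W, Y or L
     (the conserved aromatic/leucine of the bipartite signal);
   - otherwise ER via the secretory pathway (distinct evidence token).
2. Otherwise mitochondrion when TargetP and HECTAR agree on it, or the
   Mitoprot score exceeds 0.9, or exceeds 0.8 with one supporting call.
3. Otherwise peroxisome when the C-terminal tripeptide is a PTS1.
4. Otherwise ER when TMHMM predicts at least one transmembrane helix
   (membrane protein without any targeting peptide).
5. Otherwise cytoplasm.

A serine/threonine-rich region downstream of the cleavage site is recorded as
supporting (non-decisive) evidence for chloroplast calls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .core_io import (
    HectarCall,
    PredictorBundle,
    ProteinRecord,
    RuleConfig,
    TargetPCall,
    ValidationError,
)
from .enzyme_annotation import ser_thr_rich


class Compartment(str, enum.Enum):
    CHLOROPLAST = "CHLOROPLAST"
    MITOCHONDRION = "MITOCHONDRION"
    ER = "ER"
    PEROXISOME = "PEROXISOME"
    CYTOPLASM = "CYTOPLASM"


# Evidence tokens, in cascade order.
SIGNALP_CLEAVAGE = "SIGNALP_CLEAVAGE"
ER_RETENTION = "ER_RETENTION"
PLUS1_AROMATIC = "PLUS1_AROMATIC"
SIGNAL_NO_MOTIF = "SIGNAL_NO_MOTIF"
MITO_SCORE_HIGH = "MITO_SCORE_HIGH"
MITO_SCORE_AGREE = "MITO_SCORE_AGREE"
MITO_BOTH_CALLS = "MITO_BOTH_CALLS"
MITO_CONFLICT_WITH_SIGNAL = "MITO_CONFLICT_WITH_SIGNAL"
PTS1 = "PTS1"
TM_FALLBACK = "TM_FALLBACK"
DEFAULT_CYTOPLASM = "DEFAULT_CYTOPLASM"

#: Admissible PTS1 tripeptides: [S/A/C][K/R/H][L/M], plus the literal SSL
#: (a genuine addition — SSL is not generated by the bracket pattern).
_PTS1_FIRST = set("SAC")
_PTS1_SECOND = set("KRH")
_PTS1_THIRD = set("LM")


@dataclass(frozen=True)
class LocalizationCall:
    """Compartment assignment with the ordered trail of fired rules.

    The last evidence token is always the rule that fixed the compartment.
    """

    protein_id: str
    compartment: Compartment
    evidence: tuple[str, ...]
    st_rich_support: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValidationError(f"{self.protein_id}: evidence trail is empty")


def check_er_retention(protein: ProteinRecord) -> bool:
    """True iff the final 4 residues match (K/D)(D/E)EL at the C-terminus."""
    seq = protein.sequence
    if len(seq) < 4:
        return False
    tail = seq[-4:]
    return tail[0] in "KD" and tail[1] in "DE" and tail[2] == "E" and tail[3] == "L"


def check_plus1(protein: ProteinRecord, cleavage_pos: int) -> bool:
    """True iff the residue at the +1 position of the cleavage site is F/W/Y/L.

    ``cleavage_pos`` is the 1-based index of the last signal-peptide residue;
    the +1 position is ``cleavage_pos + 1``. A cleavage position at (or past)
    the final residue has no +1 residue and is an error.
    """
    if cleavage_pos < 1:
        raise ValidationError(f"cleavage position {cleavage_pos} must be >= 1")
    if cleavage_pos >= len(protein.sequence):
        raise ValidationError(
            f"{protein.id}: cleavage position {cleavage_pos} leaves no +1 residue "
            f"(sequence length {len(protein.sequence)})"
        )
    return protein.sequence[cleavage_pos] in "FWYL"


def check_pts1(protein: ProteinRecord) -> bool:
    """True iff the C-terminal tripeptide is [S/A/C][K/R/H][L/M] or SSL."""
    seq = protein.sequence
    if len(seq) < 3:
        return False
    tri = seq[-3:]
    if tri == "SSL":
        return True
    return tri[0] in _PTS1_FIRST and tri[1] in _PTS1_SECOND and tri[2] in _PTS1_THIRD


def mitochondrial_rule(
    bundle: PredictorBundle, config: Optional[RuleConfig] = None
) -> bool:
    """Mitochondrial import decision from the three predictors.

    True iff TargetP and HECTAR both call mitochondrion, or Mitoprot > 0.9,
    or Mitoprot > 0.8 with either TargetP or HECTAR calling mitochondrion.
    Thresholds are strict inequalities.
    """
    if config is None:
        config = RuleConfig()
    tp_mito = bundle.targetp_call == TargetPCall.MITOCHONDRION
    hec_mito = bundle.hectar_call == HectarCall.MITOCHONDRION
    if tp_mito and hec_mito:
        return True
    if bundle.mitoprot_score > config.mitoprot_high:
        return True
    return bundle.mitoprot_score > config.mitoprot_agree and (tp_mito or hec_mito)


def _mito_evidence(bundle: PredictorBundle, config: RuleConfig) -> str:
    tp_mito = bundle.targetp_call == TargetPCall.MITOCHONDRION
    hec_mito = bundle.hectar_call == HectarCall.MITOCHONDRION
    if tp_mito and hec_mito:
        return MITO_BOTH_CALLS
    if bundle.mitoprot_score > config.mitoprot_high:
        return MITO_SCORE_HIGH
    return MITO_SCORE_AGREE


def classify_localization(
    protein: ProteinRecord,
    bundle: PredictorBundle,
    config: Optional[RuleConfig] = None,
) -> LocalizationCall:
    """Run the full cascade; total and deterministic for every valid input.

    Rule order: signal peptide → mitochondrion → peroxisome → transmembrane
    fallback → cytoplasm. A protein with both a predicted signal peptide and
    mitochondrial evidence is assigned by the signal branch; the conflict is
    recorded in the evidence trail.
    """
    if protein.id != bundle.protein_id:
        raise ValidationError(
            f"protein id {protein.id!r} does not match bundle id "
            f"{bundle.protein_id!r}"
        )
    if config is None:
        config = RuleConfig()
    if (
        bundle.signalp_cleavage_pos is not None
        and bundle.signalp_cleavage_pos >= len(protein.sequence)
    ):
        raise ValidationError(
            f"{protein.id}: cleavage position {bundle.signalp_cleavage_pos} "
            f"not below sequence length {len(protein.sequence)}"
        )

    evidence: list[str] = []

    if bundle.signalp_cleavage_pos is not None:
        evidence.append(SIGNALP_CLEAVAGE)
        if mitochondrial_rule(bundle, config):
            evidence.append(MITO_CONFLICT_WITH_SIGNAL)
        if check_er_retention(protein):
            evidence.append(ER_RETENTION)
            return LocalizationCall(protein.id, Compartment.ER, tuple(evidence))
        if check_plus1(protein, bundle.signalp_cleavage_pos):
            evidence.append(PLUS1_AROMATIC)
            support = ser_thr_rich(protein, bundle.signalp_cleavage_pos, config)
            return LocalizationCall(
                protein.id,
                Compartment.CHLOROPLAST,
                tuple(evidence),
                st_rich_support=support,
            )
        evidence.append(SIGNAL_NO_MOTIF)
        return LocalizationCall(protein.id, Compartment.ER, tuple(evidence))

    if mitochondrial_rule(bundle, config):
        evidence.append(_mito_evidence(bundle, config))
        return LocalizationCall(protein.id, Compartment.MITOCHONDRION, tuple(evidence))

    if check_pts1(protein):
        evidence.append(PTS1)
        return LocalizationCall(protein.id, Compartment.PEROXISOME, tuple(evidence))

    if bundle.tmhmm_tm_count >= 1:
        evidence.append(TM_FALLBACK)
        return LocalizationCall(protein.id, Compartment.ER, tuple(evidence))

    evidence.append(DEFAULT_CYTOPLASM)
    return LocalizationCall(protein.id, Compartment.CYTOPLASM, tuple(evidence))
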