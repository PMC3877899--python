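"""Targeting-signal checks and the five-compartment decision cascade."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pufamap.core_io import (
    HectarCall,
    PredictorBundle,
    ProteinRecord,
    RuleConfig,
    TargetPCall,
    ValidationError,
)
from pufamap.localization import (
    Compartment,
    classify_localization,
    check_er_retention,
    check_plus1,
    check_pts1,
    mitochondrial_rule,
)


def bundle(pid="p", targetp=TargetPCall.OTHER, hectar=HectarCall.OTHER,
           cleavage=None, mitoprot=0.0, tm=0, hmmtop=None):
    return PredictorBundle(pid, targetp, hectar, cleavage, mitoprot, tm, hmmtop)


# --- ER retention -----------------------------------------------------------

@pytest.mark.parametrize("tail", [a + b + "EL" for a in "KD" for b in "DE"])
def test_er_retention_accepts_all_bracket_expansions(tail):
    assert check_er_retention(ProteinRecord("p", "MAAAA" + tail))


@pytest.mark.parametrize("seq", ["MAKDELA", "MAADEL", "MKEEL".replace("E", "A", 1)])
def test_er_retention_rejects_non_terminal_or_wrong_pattern(seq):
    assert not check_er_retention(ProteinRecord("p", seq))


def test_er_retention_short_sequence_false():
    assert not check_er_retention(ProteinRecord("p", "DEL"))


# --- +1 position ------------------------------------------------------------

@pytest.mark.parametrize("res, expected", [("F", True), ("W", True), ("Y", True),
                                           ("L", True), ("A", False), ("S", False)])
def test_plus1_residue(res, expected):
    seq = "M" * 18 + res + "A" * 30
    assert check_plus1(ProteinRecord("p", seq), 18) is expected


def test_plus1_at_final_residue_is_error():
    with pytest.raises(ValidationError):
        check_plus1(ProteinRecord("p", "M" * 19), 19)


# --- PTS1 -------------------------------------------------------------------

ADMISSIBLE_PTS1 = [a + b + c for a in "SAC" for b in "KRH" for c in "LM"] + ["SSL"]


@pytest.mark.parametrize("tri", ADMISSIBLE_PTS1)
def test_pts1_accepts_all_admissible_tripeptides(tri):
    assert check_pts1(ProteinRecord("p", "MAAA" + tri))


@pytest.mark.parametrize("tri", ["KLM", "SSM", "TKL", "SKA", "AAL"])
def test_pts1_rejects_other_tripeptides(tri):
    assert not check_pts1(ProteinRecord("p", "MAAA" + tri))


def test_pts1_must_be_terminal():
    assert not check_pts1(ProteinRecord("p", "MASKLM"))  # final tri = KLM


# --- mitochondrial rule -----------------------------------------------------

@pytest.mark.parametrize(
    "score, tp, hec, expected",
    [
        # unconditional threshold (strict >0.9)
        (0.95, TargetPCall.OTHER, HectarCall.OTHER, True),
        (0.90, TargetPCall.OTHER, HectarCall.OTHER, False),
        # supported threshold (strict >0.8 with one mitochondrial call)
        (0.85, TargetPCall.OTHER, HectarCall.MITOCHONDRION, True),
        (0.85, TargetPCall.MITOCHONDRION, HectarCall.OTHER, True),
        (0.85, TargetPCall.OTHER, HectarCall.OTHER, False),
        (0.80, TargetPCall.OTHER, HectarCall.MITOCHONDRION, False),
        # two-predictor agreement suffices regardless of the score
        (0.50, TargetPCall.MITOCHONDRION, HectarCall.MITOCHONDRION, True),
        (0.00, TargetPCall.MITOCHONDRION, HectarCall.MITOCHONDRION, True),
        (0.50, TargetPCall.MITOCHONDRION, HectarCall.OTHER, False),
    ],
)
def test_mitochondrial_rule_truth_table(score, tp, hec, expected, config):
    assert mitochondrial_rule(bundle(mitoprot=score, targetp=tp, hectar=hec),
                              config) is expected


def test_mitochondrial_rule_exhaustive_bands(config):
    """Every (score band, call pair) combination matches the written rule."""
    for score, tp, hec in itertools.product(
        [0.0, 0.5, 0.81, 0.85, 0.9, 0.91, 1.0],
        list(TargetPCall),
        list(HectarCall),
    ):
        tp_m = tp is TargetPCall.MITOCHONDRION
        hec_m = hec is HectarCall.MITOCHONDRION
        expected = (
            (tp_m and hec_m)
            or score > 0.9
            or (score > 0.8 and (tp_m or hec_m))
        )
        got = mitochondrial_rule(bundle(mitoprot=score, targetp=tp, hectar=hec),
                                 config)
        assert got is expected, (score, tp, hec)


def test_threshold_boundary_sweep(config):
    """On a 0.01 grid with non-mitochondrial calls, the assignment flips to
    MITOCHONDRION exactly above 0.90."""
    protein = ProteinRecord("p", "M" + "A" * 99)
    flips = []
    for i in range(101):
        score = round(i / 100, 2)
        call = classify_localization(protein, bundle(mitoprot=score), config)
        flips.append(call.compartment is Compartment.MITOCHONDRION)
    assert flips == [s > 90 for s in range(101)]


@given(
    lo=st.floats(0, 1, allow_nan=False),
    hi=st.floats(0, 1, allow_nan=False),
    tp=st.sampled_from(list(TargetPCall)),
    hec=st.sampled_from(list(HectarCall)),
)
def test_mito_rule_monotone_in_score(lo, hi, tp, hec):
    """Raising the Mitoprot score never switches the rule off."""
    lo, hi = min(lo, hi), max(lo, hi)
    cfg = RuleConfig()
    if mitochondrial_rule(bundle(mitoprot=lo, targetp=tp, hectar=hec), cfg):
        assert mitochondrial_rule(bundle(mitoprot=hi, targetp=tp, hectar=hec), cfg)


# --- cascade ----------------------------------------------------------------

def test_cascade_chloroplast_with_st_rich_support(config):
    seq = "M" * 18 + "Y" + "SSTSSTASSTASSTAAAAAA" + "A" * 100
    call = classify_localization(ProteinRecord("p", seq),
                                 bundle(cleavage=18), config)
    assert call.compartment is Compartment.CHLOROPLAST
    assert call.evidence[-1] == "PLUS1_AROMATIC"
    assert call.st_rich_support is True


def test_cascade_er_retention_beats_plus1(config):
    seq = "M" * 18 + "Y" + "A" * 100 + "KDEL"
    call = classify_localization(ProteinRecord("p", seq),
                                 bundle(cleavage=18), config)
    assert call.compartment is Compartment.ER
    assert call.evidence[-1] == "ER_RETENTION"


def test_cascade_signal_without_motifs_goes_to_er(config):
    seq = "M" * 18 + "A" * 100
    call = classify_localization(ProteinRecord("p", seq),
                                 bundle(cleavage=18), config)
    assert call.compartment is Compartment.ER
    assert call.evidence[-1] == "SIGNAL_NO_MOTIF"


def test_cascade_signal_wins_over_high_mitoprot(config):
    seq = "M" * 18 + "Y" + "A" * 100
    call = classify_localization(ProteinRecord("p", seq),
                                 bundle(cleavage=18, mitoprot=0.99), config)
    assert call.compartment is Compartment.CHLOROPLAST
    assert "MITO_CONFLICT_WITH_SIGNAL" in call.evidence


def test_cascade_tm_fallback_to_er(config):
    call = classify_localization(ProteinRecord("p", "M" + "A" * 200),
                                 bundle(mitoprot=0.2, tm=5), config)
    assert call.compartment is Compartment.ER
    assert call.evidence[-1] == "TM_FALLBACK"


def test_cascade_peroxisome_before_tm_fallback(config):
    call = classify_localization(ProteinRecord("p", "M" + "A" * 100 + "SKL"),
                                 bundle(tm=3), config)
    assert call.compartment is Compartment.PEROXISOME


def test_cascade_default_cytoplasm(config):
    call = classify_localization(ProteinRecord("p", "M" + "A" * 100),
                                 bundle(), config)
    assert call.compartment is Compartment.CYTOPLASM
    assert call.evidence == ("DEFAULT_CYTOPLASM",)


def test_cascade_id_mismatch_errors(config):
    with pytest.raises(ValidationError):
        classify_localization(ProteinRecord("a", "MA"), bundle("b"), config)


@given(
    cleavage=st.one_of(st.none(), st.just(18)),
    tp=st.sampled_from(list(TargetPCall)),
    hec=st.sampled_from(list(HectarCall)),
    mitoprot=st.floats(0, 1, allow_nan=False),
    tm=st.integers(0, 8),
    tail=st.sampled_from(["AAA", "SKL", "KDEL", "AAL"]),
)
def test_cascade_is_total_and_deterministic(cleavage, tp, hec, mitoprot, tm, tail):
    """Every (protein, bundle) pair yields exactly one compartment, stably."""
    protein = ProteinRecord("p", "M" * 18 + "A" * 60 + tail)
    b = bundle(targetp=tp, hectar=hec, cleavage=cleavage, mitoprot=mitoprot, tm=tm)
    first = classify_localization(protein, b)
    second = classify_localization(protein, b)
    assert first == second
    assert first.compartment in Compartment
    assert first.evidence[-1] in {
        "ER_RETENTION", "PLUS1_AROMATIC", "SIGNAL_NO_MOTIF", "MITO_SCORE_HIGH",
        "MITO_SCORE_AGREE", "MITO_BOTH_CALLS", "PTS1", "TM_FALLBACK",
        "DEFAULT_CYTOPLASM",
    }
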