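"""ITS scoring: assay binning, in silico calls, combined classification."""

import pytest

from conftest import all_score_combinations, brute_force_classify
from sensits.errors import ValidationError
from sensits.itscore import (
    DpraResult,
    HclatResult,
    call_insilico,
    combine_and_classify,
    score_dpra,
    score_hclat,
)


@pytest.mark.parametrize(
    "cys,lys,coelution,expected",
    [
        (5.0, 5.0, False, 0),       # mean below the 6.38 % nonreactive cutoff
        (0.0, 0.0, False, 0),       # lower edge
        (6.38, 6.38, False, 1),     # left-closed boundary
        (22.62, 22.62, False, 2),
        (42.47, 42.47, False, 3),
        (100.0, 100.0, False, 3),
        (-3.0, 5.0, False, 0),      # negative depletion floored at 0 -> mean 2.5
        (10.0, 30.0, False, 1),     # mean 20
        (99.0, None, True, 3),      # co-elution: cysteine-only top bin
        (13.89, None, True, 1),     # co-elution boundaries
        (23.09, None, True, 2),
        (5.0, None, True, 0),
        (98.24, None, True, 3),
    ],
)
def test_dpra_binning(cys, lys, coelution, expected):
    res = DpraResult(cys_depletion=cys, lys_depletion=lys, lys_coelution=coelution)
    assert score_dpra(res) == expected


def test_dpra_out_of_range_depletion_rejected():
    with pytest.raises(ValidationError):
        score_dpra(DpraResult(150.0, 10.0))
    with pytest.raises(ValidationError):
        score_dpra(DpraResult(10.0, -150.0))


def test_dpra_without_lysine_and_without_coelution_is_an_error():
    with pytest.raises(ValidationError):
        score_dpra(DpraResult(10.0, None, lys_coelution=False))


@pytest.mark.parametrize(
    "mit,expected",
    [
        (None, 0),      # negative outcome
        (2000.0, 1),    # between 150 and 5000
        (5000.0, 1),
        (150.0, 2),     # upper-end inclusive bins
        (10.5, 2),
        (10.0, 3),
        (0.5, 3),
        (5001.0, 0),    # above 5000 treated as negative
    ],
)
def test_hclat_binning(mit, expected):
    assert score_hclat(HclatResult(mit=mit)) == expected


def test_hclat_nonpositive_mit_rejected():
    with pytest.raises(ValidationError):
        score_hclat(HclatResult(mit=0.0))
    with pytest.raises(ValidationError):
        score_hclat(HclatResult(mit=-5.0))


class TestInSilicoCall:
    def test_pesticide_low_score_in_domain_is_negative(self):
        call = call_insilico(0.30, mode="pesticide", in_domain=True)
        assert call.call == "negative" and call.its_score == 0

    def test_pesticide_boundary_04_is_negative(self):
        assert call_insilico(0.4, mode="pesticide", in_domain=True).call == "negative"

    def test_pesticide_out_of_domain_is_missing(self):
        call = call_insilico(0.30, mode="pesticide", in_domain=False)
        assert call.call == "missing" and call.its_score is None

    def test_pesticide_high_score_in_domain_is_positive(self):
        assert call_insilico(0.7, mode="pesticide", in_domain=True).call == "positive"

    def test_non_pesticide_uses_half_cutoff(self):
        assert call_insilico(0.7, mode="non_pesticide", in_domain=True).call == "positive"
        assert call_insilico(0.49, mode="non_pesticide", in_domain=True).call == "negative"

    def test_absent_score_is_missing(self):
        assert call_insilico(None, mode="pesticide", in_domain=True).call == "missing"

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            call_insilico(1.2, mode="pesticide", in_domain=True)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            call_insilico(0.3, mode="in_vitro", in_domain=True)


@pytest.mark.parametrize(
    "d,h,i,hazard,potency",
    [
        (0, 1, 0, "not_classified", "NC"),      # total 1: the formulation-2/18 pattern
        (3, 3, 1, "sensitizer", "1A"),          # total 7
        (1, 1, 0, "sensitizer", "1B"),          # total 2
        (2, 3, 1, "sensitizer", "1A"),          # total 6
        (2, 2, 1, "sensitizer", "1B"),          # total 5
        (0, 1, None, "inconclusive", "inconclusive"),   # range 1-2 straddles cutoff
        (3, 2, None, "sensitizer", "inconclusive"),     # range 5-6 straddles 1B/1A
        (None, None, None, "inconclusive", "inconclusive"),
    ],
)
def test_combined_classification(d, h, i, hazard, potency):
    res = combine_and_classify(d, h, i)
    assert (res.hazard, res.potency) == (hazard, potency)


def test_total_range_bookkeeping():
    res = combine_and_classify(2, None, None)
    assert (res.total_min, res.total_max) == (2, 6)
    res = combine_and_classify(1, 1, 1)
    assert res.total_min == res.total_max == 3


def test_component_scores_out_of_range_rejected():
    with pytest.raises(ValidationError):
        combine_and_classify(4, 0, 0)
    with pytest.raises(ValidationError):
        combine_and_classify(0, 0, 2)


def test_classification_matches_completion_oracle_exhaustively():
    """Every combination incl. missing agrees with brute-force enumeration."""
    for d, h, i in all_score_combinations():
        res = combine_and_classify(d, h, i)
        assert (res.hazard, res.potency) == brute_force_classify(d, h, i), (d, h, i)


def test_monotonicity_in_each_component():
    """Raising any component never demotes hazard or potency."""
    hazard_rank = {"not_classified": 0, "inconclusive": 1, "sensitizer": 2}
    potency_rank = {"NC": 0, "inconclusive": 1, "1B": 2, "1A": 3}
    for d in range(4):
        for h in range(4):
            for i in range(2):
                base = combine_and_classify(d, h, i)
                for dd, hh, ii in ((d + 1, h, i), (d, h + 1, i), (d, h, i + 1)):
                    if dd > 3 or hh > 3 or ii > 1:
                        continue
                    up = combine_and_classify(dd, hh, ii)
                    assert hazard_rank[up.hazard] >= hazard_rank[base.hazard]
                    assert potency_rank[up.potency] >= potency_rank[base.potency]


def test_conclusive_potency_implies_conclusive_hazard():
    for d, h, i in all_score_combinations():
        res = combine_and_classify(d, h, i)
        if res.conclusive_potency:
            assert res.conclusive_hazard
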