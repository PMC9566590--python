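import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensits import (ChemicalRecord, DPRAResult, HCLATResult, Hazard,
                     InSilicoCall, ITSScore, Potency, ScoringConfig,
                     ValidationError, assess_record, call_hazard, call_potency,
                     compute_its_score, score_dpra, score_hclat,
                     score_insilico)


class TestScoreDPRA:
    def test_mean_binning(self, cfg):
        # mean of 30 and 20 is 25, inside [22.62, 42.47)
        assert score_dpra(DPRAResult(30, 20), cfg) == 2

    def test_zero_reactivity(self, cfg):
        assert score_dpra(DPRAResult(0, 0), cfg) == 0

    def test_coelution_uses_cys_only_table(self, cfg):
        assert score_dpra(DPRAResult(100, lys_coelution=True), cfg) == 3

    def test_missing_propagates(self, cfg):
        assert score_dpra(None, cfg) is None

    def test_missing_lys_falls_back_to_cys_only(self, cfg):
        assert score_dpra(DPRAResult(cys_depletion=20.0), cfg) == 1

    @pytest.mark.parametrize("mean,expected", [
        (-20.0, 0), (6.37, 0), (6.38, 1), (22.61, 1), (22.62, 2),
        (42.46, 2), (42.47, 3), (100.0, 3),
    ])
    def test_lower_edge_inclusive(self, cfg, mean, expected):
        assert score_dpra(DPRAResult(mean, mean), cfg) == expected

    @pytest.mark.parametrize("cys,expected", [
        (13.88, 0), (13.89, 1), (23.09, 2), (98.24, 3),
    ])
    def test_cys_only_edges(self, cfg, cys, expected):
        assert score_dpra(DPRAResult(cys, lys_coelution=True), cfg) == expected

    @pytest.mark.parametrize("cys,lys", [(150, 0), (-30, 0), (0, 101)])
    def test_out_of_range_rejected(self, cfg, cys, lys):
        with pytest.raises(ValidationError) as exc:
            score_dpra(DPRAResult(cys, lys), cfg, record_id="X1")
        assert "X1" in str(exc.value)


class TestScoreHCLAT:
    def test_negative_scores_zero(self, cfg):
        assert score_hclat(HCLATResult("negative"), cfg) == 0

    def test_low_mit_scores_high(self, cfg):
        assert score_hclat(HCLATResult("positive", 5), cfg) == 3

    def test_mid_mit(self, cfg):
        assert score_hclat(HCLATResult("positive", 200), cfg) == 1

    def test_missing(self, cfg):
        assert score_hclat(None, cfg) is None

    @pytest.mark.parametrize("mit,expected", [
        (10.0, 3), (10.01, 2), (150.0, 2), (150.01, 1), (5000.0, 1),
        (5000.01, 0),
    ])
    def test_edges_inclusive_toward_higher_score(self, cfg, mit, expected):
        assert score_hclat(HCLATResult("positive", mit), cfg) == expected

    def test_positive_without_mit_rejected(self, cfg):
        with pytest.raises(ValidationError):
            score_hclat(HCLATResult("positive"), cfg)

    def test_positive_with_nonpositive_mit_rejected(self, cfg):
        with pytest.raises(ValidationError):
            score_hclat(HCLATResult("positive", 0.0), cfg)


class TestScoreInsilico:
    def test_above_cutoff(self, cfg):
        assert score_insilico(InSilicoCall(0.8), cfg) == 1

    def test_cutoff_is_strict(self, cfg):
        assert score_insilico(InSilicoCall(0.5), cfg) == 0

    def test_out_of_domain_discarded(self, cfg):
        assert score_insilico(InSilicoCall(0.9, in_domain=False), cfg) is None

    def test_missing(self, cfg):
        assert score_insilico(None, cfg) is None

    def test_score_range_enforced(self, cfg):
        with pytest.raises(ValidationError):
            score_insilico(InSilicoCall(1.2), cfg)


class TestTotalsAndCalls:
    def test_summation_high(self, cfg):
        assert ITSScore(3, 3, 1).total == 7

    def test_summation_low(self, cfg):
        assert ITSScore(1, 0, 0).total == 1

    def test_missing_component_means_inconclusive(self, cfg):
        s = ITSScore(3, 3, None)
        assert s.total is None
        assert call_hazard(s, cfg) is Hazard.INCONCLUSIVE
        assert call_potency(s, cfg) is Potency.INCONCLUSIVE

    @pytest.mark.parametrize("total,hazard", [
        (0, Hazard.NON_SENSITIZER), (1, Hazard.NON_SENSITIZER),
        (2, Hazard.SENSITIZER), (7, Hazard.SENSITIZER),
    ])
    def test_hazard_boundaries(self, cfg, total, hazard):
        assert call_hazard(ITSScore(total, 0, 0), cfg) is hazard

    @pytest.mark.parametrize("d,h,i,potency", [
        (3, 3, 1, Potency.CAT_1A), (3, 3, 0, Potency.CAT_1A),
        (3, 2, 0, Potency.CAT_1B), (2, 0, 0, Potency.CAT_1B),
        (1, 0, 0, Potency.NC), (0, 0, 0, Potency.NC),
    ])
    def test_potency_boundaries(self, cfg, d, h, i, potency):
        assert call_potency(ITSScore(d, h, i), cfg) is potency


class TestAssessRecord:
    def test_composed_calls(self, cfg):
        # points (2, 1, 1): mean depletion 25 -> 2, MIT 200 -> 1, 0.9 -> 1
        rec = ChemicalRecord(id="a", dpra=DPRAResult(30, 20),
                             hclat=HCLATResult("positive", 200),
                             insilico=InSilicoCall(0.9))
        its, hazard, potency = assess_record(rec, cfg)
        assert (its.dpra_points, its.hclat_points, its.insilico_points) == (2, 1, 1)
        assert its.total == 4
        assert hazard is Hazard.SENSITIZER
        assert potency is Potency.CAT_1B

    def test_missing_assay_is_inconclusive(self, cfg):
        rec = ChemicalRecord(id="b", dpra=DPRAResult(30, 20),
                             insilico=InSilicoCall(0.9))
        its, hazard, potency = assess_record(rec, cfg)
        assert its.total is None
        assert hazard is Hazard.INCONCLUSIVE
        assert potency is Potency.INCONCLUSIVE

    def test_all_zero(self, cfg):
        rec = ChemicalRecord(id="c", dpra=DPRAResult(0, 0),
                             hclat=HCLATResult("negative"),
                             insilico=InSilicoCall(0.1))
        its, hazard, potency = assess_record(rec, cfg)
        assert its.total == 0
        assert hazard is Hazard.NON_SENSITIZER
        assert potency is Potency.NC

    def test_inconsistent_reference_rejected(self, cfg):
        rec = ChemicalRecord(id="d", ref_hazard=Hazard.NON_SENSITIZER,
                             ref_potency=Potency.CAT_1A)
        with pytest.raises(ValidationError):
            rec.validate()


class TestScoreSpaceOracle:
    """Brute-force check over all 32 component-point combinations."""

    def test_exhaustive_mapping(self, cfg):
        for d in range(4):
            for h in range(4):
                for i in range(2):
                    s = ITSScore(d, h, i)
                    total = d + h + i
                    assert s.total == total
                    want_h = Hazard.SENSITIZER if 2 <= total <= 7 \
                        else Hazard.NON_SENSITIZER
                    assert call_hazard(s, cfg) is want_h
                    if 6 <= total <= 7:
                        want_p = Potency.CAT_1A
                    elif 2 <= total <= 5:
                        want_p = Potency.CAT_1B
                    else:
                        want_p = Potency.NC
                    assert call_potency(s, cfg) is want_p

    def test_hazard_potency_consistency(self, cfg):
        for d in range(4):
            for h in range(4):
                for i in range(2):
                    s = ITSScore(d, h, i)
                    sens = call_hazard(s, cfg) is Hazard.SENSITIZER
                    pot = call_potency(s, cfg)
                    assert sens == (pot in (Potency.CAT_1A, Potency.CAT_1B))


depletion = st.floats(min_value=-20, max_value=100, allow_nan=False)
mit_values = st.floats(min_value=0.01, max_value=10000, allow_nan=False)


class TestMonotonicity:
    @given(cys=depletion, lys=depletion, bump=st.floats(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_more_depletion_never_scores_lower(self, cfg, cys, lys, bump):
        base = score_dpra(DPRAResult(cys, lys), cfg)
        bumped = score_dpra(
            DPRAResult(min(cys + bump, 100), min(lys + bump, 100)), cfg)
        assert bumped >= base

    @given(mit=mit_values, shrink=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_smaller_mit_never_scores_lower(self, cfg, mit, shrink):
        base = score_hclat(HCLATResult("positive", mit), cfg)
        assert score_hclat(HCLATResult("positive", mit * shrink), cfg) >= base

    @given(d=st.integers(0, 2), h=st.integers(0, 3), i=st.integers(0, 1))
    @settings(max_examples=64, deadline=None)
    def test_extra_point_never_flips_to_nonsensitizer(self, cfg, d, h, i):
        before = call_hazard(ITSScore(d, h, i), cfg)
        after = call_hazard(ITSScore(d + 1, h, i), cfg)
        if before is Hazard.SENSITIZER:
            assert after is Hazard.SENSITIZER


class TestConfig:
    def test_yaml_round_trip_is_identical(self, cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        reloaded = ScoringConfig.from_yaml(path)
        assert reloaded == cfg
        assert score_dpra(DPRAResult(30, 20), reloaded) == \
            score_dpra(DPRAResult(30, 20), cfg)

    def test_non_ascending_bins_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig(dpra_mean_bins=(10, 5, 42))

    def test_overlapping_potency_ranges_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig(potency_1a_range=(4, 7), potency_1b_range=(2, 5))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig.from_dict({"nope": 1})

    def test_custom_edges_change_binning(self, cfg):
        tweaked = cfg.replace(dpra_mean_bins=(30.0, 60.0, 90.0))
        assert score_dpra(DPRAResult(30, 20), tweaked) == 0
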