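import io
import math

import pytest
from hypothesis import given, settings, strategies as st

from mtcnkit import qpcr
from mtcnkit.qpcr import (
    CtMeasurement,
    GenePairing,
    check_ntc,
    delta_ct,
    load_primer_panel,
    mtdnacn_geomean,
    mtdnacn_paired,
    mtdnacn_paired_result,
    parse_ct_table,
    reference_sample_qc,
    relative_copy_number,
    replicate_variability,
    summarize_replicates,
)

from conftest import four_gene_plate, triplicate


CSV_HEADER = "sample_id,gene,replicate,ct,plate_id,run_date,is_ntc\n"


class TestParseCtTable:
    def test_direct_field_mapping(self):
        rows = parse_ct_table(io.StringIO(CSV_HEADER + "S1,ND1,1,17.20,p1,2024-01-01,false\n"))
        (m,) = rows
        assert (m.sample_id, m.gene, m.replicate_index, m.ct) == ("S1", "ND1", 1, 17.20)
        assert not m.is_ntc

    @pytest.mark.parametrize("raw", ["Undetermined", "undetermined", ""])
    def test_undetermined_sentinel(self, raw):
        rows = parse_ct_table(io.StringIO(CSV_HEADER + f"NTC,ND1,1,{raw},p1,,true\n"))
        assert rows[0].ct is None and rows[0].is_ntc

    @pytest.mark.parametrize("raw,canon", [("MT-ND6", "ND6"), ("mt-nd1", "ND1"),
                                           ("NEB1", "NEB"), ("becn1", "BECN1")])
    def test_gene_normalization(self, raw, canon):
        rows = parse_ct_table(io.StringIO(CSV_HEADER + f"S1,{raw},1,20,p1,,false\n"))
        assert rows[0].gene == canon

    def test_unknown_gene_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rows = parse_ct_table(io.StringIO(CSV_HEADER + "S1,ACTB,1,20,p1,,false\n"))
        assert rows == []
        assert "ACTB" in caplog.text

    def test_missing_column_is_hard_error(self):
        with pytest.raises(ValueError, match="ct"):
            parse_ct_table(io.StringIO("sample_id,gene,replicate,is_ntc\nS1,ND1,1,false\n"))

    def test_ct_outside_cycle_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            parse_ct_table(io.StringIO(CSV_HEADER + "S1,ND1,1,41.0,p1,,false\n"))


class TestSummarizeReplicates:
    def test_clean_triplicate(self):
        (s,) = summarize_replicates(triplicate("S1", "ND1", [20.0, 20.2, 20.4]))
        assert s.n_used == 3
        assert s.mean_ct == pytest.approx(20.2)
        assert s.sd_ct == pytest.approx(0.2)
        assert s.flags == frozenset()

    def test_undetermined_excluded_but_flagged(self):
        (s,) = summarize_replicates(triplicate("S1", "ND1", [20.0, None, 20.4]))
        assert s.n_used == 2
        assert s.mean_ct == pytest.approx(20.2)
        assert s.flags == {"HAS_UNDETERMINED"}

    def test_high_sd_flagged(self):
        # sample sd of {20.0, 21.5, 20.1} is 0.8386 cycles, above the 0.5 gate
        (s,) = summarize_replicates(triplicate("S1", "ND1", [20.0, 21.5, 20.1]))
        assert s.sd_ct == pytest.approx(0.83865, abs=1e-4)
        assert "HIGH_CT_SD" in s.flags

    def test_single_replicate_flagged(self):
        (s,) = summarize_replicates([CtMeasurement("S1", "ND1", 1, 20.0)])
        assert "TOO_FEW_REPLICATES" in s.flags and s.sd_ct == 0.0

    def test_all_undetermined_yields_no_summary(self, caplog):
        with caplog.at_level("WARNING"):
            assert summarize_replicates(triplicate("S1", "ND1", [None, None, None])) == []
        assert "S1" in caplog.text

    def test_ntc_wells_rejected(self):
        with pytest.raises(ValueError, match="NTC"):
            summarize_replicates([CtMeasurement("NTC", "ND1", 1, None, is_ntc=True)])


class TestCheckNtc:
    def test_all_undetermined_passes(self):
        wells = [CtMeasurement("NTC", g, 1, None, is_ntc=True)
                 for g in ("ND1", "ND6", "BECN1", "NEB")]
        assert all(v.status == "PASS" for v in check_ntc(wells).values())

    def test_amplifying_ntc_fails_listing_well(self):
        wells = [CtMeasurement("NTC", "ND1", 1, 28.0, is_ntc=True)]
        v = check_ntc(wells)["ND1"]
        assert v.status == "FAIL"
        assert v.offending_wells[0].ct == 28.0

    def test_boundary_above_threshold_passes(self):
        wells = [CtMeasurement("NTC", "ND1", 1, 36.0, is_ntc=True)]
        assert check_ntc(wells, max_allowed_ct=35.0)["ND1"].status == "PASS"

    def test_missing_ntc_warns_not_passes(self):
        verdicts = check_ntc([])
        assert all(v.status == "WARN" for v in verdicts.values())


class TestEstimators:
    def test_delta_ct_examples(self):
        wells = four_gene_plate("S1", nd1=17.0, nd6=22.0, becn1=25.0, neb=22.0)
        d1, d2 = delta_ct(GenePairing(), summarize_replicates(wells), "S1")
        assert d1 == pytest.approx(8.0)
        assert d2 == pytest.approx(0.0)

    def test_delta_ct_missing_gene_names_sample_and_gene(self):
        wells = triplicate("S9", "ND1", [17.0] * 3)
        with pytest.raises(ValueError, match="S9.*BECN1"):
            delta_ct(GenePairing(), summarize_replicates(wells), "S9")

    @pytest.mark.parametrize("dct,expected", [(8, 256), (0, 1), (-1, 0.5), (-2, 0.25)])
    def test_relative_copy_number_exact(self, dct, expected):
        assert relative_copy_number(dct) == expected

    def test_relative_copy_number_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            relative_copy_number(math.nan)

    def test_paired_mean(self):
        assert mtdnacn_paired(256, 200) == 228
        assert mtdnacn_paired(123.4, 123.4) == 123.4
        assert mtdnacn_paired(2**7.4, 2**7.0) == pytest.approx(148.4482, abs=1e-3)

    def test_paired_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mtdnacn_paired(0.0, 10.0)

    def test_geomean_equal_nuclear(self):
        wells = four_gene_plate("S1", nd1=17.0, nd6=17.0, becn1=25.0, neb=25.0)
        assert mtdnacn_geomean(summarize_replicates(wells), "S1").mtdnacn == 256

    def test_geomean_averages_nuclear_in_ct_space(self):
        wells = four_gene_plate("S1", nd1=17.0, nd6=17.0, becn1=24.0, neb=26.0)
        assert mtdnacn_geomean(summarize_replicates(wells), "S1").mtdnacn == 256

    @given(nd1=st.floats(10, 25), nd6=st.floats(10, 25), nuc=st.floats(20, 35))
    @settings(max_examples=50, deadline=None)
    def test_geomean_equals_paired_when_nuclear_cts_match(self, nd1, nd6, nuc):
        wells = four_gene_plate("S1", nd1=nd1, nd6=nd6, becn1=nuc, neb=nuc)
        summaries = summarize_replicates(wells)
        assert mtdnacn_geomean(summaries, "S1").mtdnacn == \
            mtdnacn_paired_result(summaries, "S1").mtdnacn

    @given(shift=st.floats(0.01, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_mtdnacn_strictly_decreasing_in_mito_ct(self, shift):
        base = four_gene_plate("S1", nd1=17.0, nd6=18.0, becn1=25.0, neb=24.0)
        later = four_gene_plate("S1", nd1=17.0 + shift, nd6=18.0, becn1=25.0, neb=24.0)
        low = mtdnacn_paired_result(summarize_replicates(base), "S1").mtdnacn
        high = mtdnacn_paired_result(summarize_replicates(later), "S1").mtdnacn
        assert high < low


class TestPlateQcReports:
    def test_reference_no_drift(self):
        report = reference_sample_qc({"p1": 100.0, "p2": 100.0, "p3": 100.0})
        assert report["cv_pct"] == 0.0 and report["flagged_plates"] == []

    def test_reference_drift_uses_across_plate_mean(self):
        # plate 3 deviates |130-110|/110 = 18.2% from the mean: below the 20% gate
        report = reference_sample_qc({"p1": 100.0, "p2": 100.0, "p3": 130.0})
        assert report["flagged_plates"] == []

    def test_reference_both_plates_flagged(self):
        # both deviate 30/130 = 23% from the across-plate mean 130
        report = reference_sample_qc({"p1": 100.0, "p2": 160.0})
        assert report["flagged_plates"] == ["p1", "p2"]

    def test_reference_empty_warns(self):
        assert reference_sample_qc({})["status"] == "WARN"

    def test_inter_day_cv_zero_for_identical_days(self):
        rows = [("a1", "day1", "run1", 200.0), ("a1", "day2", "run1", 200.0)]
        assert replicate_variability(rows)["a1"]["inter_day_cv_pct"] == 0.0

    def test_intra_day_cv_hand_value(self):
        rows = [("a1", "day1", "run1", 190.0), ("a1", "day1", "run2", 210.0)]
        table = replicate_variability(rows)
        assert table["a1"]["intra_day_cv_pct"] == pytest.approx(7.0711, abs=1e-3)
        assert table["a1"]["inter_day_cv_pct"] == "NA"

    def test_single_day_not_assessable(self):
        rows = [("a1", "day1", "run1", 200.0)]
        assert replicate_variability(rows)["a1"]["inter_day_cv_pct"] == "NA"


def test_primer_panel_is_complete():
    panel = load_primer_panel()
    assert len(panel) == 8
    by_gene = {}
    for p in panel:
        by_gene.setdefault(p.target_gene, set()).add(p.orientation)
        assert set(p.sequence) <= set("ACGT")
    assert by_gene == {g: {"forward", "reverse"} for g in ("ND1", "ND6", "BECN1", "NEB")}


def test_analyze_plate_end_to_end():
    wells = four_gene_plate("S1", 17.0, 17.0, 25.0, 25.0) + \
        four_gene_plate("S2", 18.0, 18.0, 25.0, 25.0) + \
        [CtMeasurement("NTC", g, 1, None, is_ntc=True)
         for g in ("ND1", "ND6", "BECN1", "NEB")]
    results, qc = qpcr.analyze_plate(wells, method="paired")
    assert [r.sample_id for r in results] == ["S1", "S2"]
    assert results[0].mtdnacn == 256 and results[1].mtdnacn == 128
    assert set(qc["ntc"].values()) == {"PASS"}
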