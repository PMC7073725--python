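"""FD/OAV screening cascade on the packaged reference dataset."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aromix as am
from aromix import ValidationError
from aromix.screening import FDRange


class TestOAV:
    @pytest.mark.parametrize(
        "conc,threshold,display",
        [
            (12795, 6.89, "1857"),   # published integer OAV, high-impact ester
            (488275, 32600, "15"),   # 14.98 rounds up
            (8922, 26.8, "333"),
            (3831, 4740, "<1"),      # sub-threshold prints <1
            (1311, 1120, "1"),       # 1.17 passes the >=1 filter but prints 1
        ],
    )
    def test_published_oav_cells(self, conc, threshold, display):
        assert am.format_oav(am.oav(conc, threshold)) == display

    def test_concentration_equal_threshold_is_one(self):
        assert am.oav(55.3, 55.3) == pytest.approx(1.0)

    def test_scale_invariance(self):
        assert am.oav(123.0, 4.56) == pytest.approx(am.oav(123.0 * 7.7, 4.56 * 7.7))

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValidationError):
            am.oav(100.0, None)


class TestScreening:
    def test_fd_filter_count(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        assert sum(r.passes_fd for r in res) == 17

    def test_fd_counts_all_samples(self, compound_records):
        # 17, 17, 16 compounds at FD >= 16 in the three liquors
        counts = {
            sid: sum(
                r.passes_fd
                for r in am.screen_compounds(compound_records, sid, fd_min=16)
            )
            for sid in ("HHL", "ZPL", "LPLJ")
        }
        assert counts == {"HHL": 17, "ZPL": 17, "LPLJ": 16}

    def test_combined_filter_count(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        assert sum(r.is_candidate_key for r in res) == 14

    def test_oav_filter_count(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        assert sum(r.passes_oav for r in res) == 16

    def test_no_threshold_never_passes_oav(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=1, oav_min=0)
        by_name = {r.name: r for r in res}
        # quantified but absent from the threshold table
        assert by_name["Ethyl palmitate"].oav_value is None
        assert not by_name["Ethyl palmitate"].passes_oav

    def test_trivial_thresholds_pass_all_detected(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=1, oav_min=0)
        for r in res:
            assert r.passes_fd == (r.fd is not None)

    def test_extreme_fd_min_selects_single_ester(self, compound_records):
        res = am.screen_compounds(compound_records, "HHL", fd_min=1024)
        assert [r.name for r in res if r.passes_fd] == ["Ethyl hexanoate"]

    def test_count_oracle_brute_force(self, compound_records):
        # pass counts must equal row-by-row filtering done independently
        res = am.screen_compounds(compound_records, "ZPL", fd_min=16, oav_min=1)
        brute = 0
        for r in compound_records:
            fd = r.fd.get("ZPL")
            fd_low = fd.low if isinstance(fd, FDRange) else fd
            conc = r.concentration.get("ZPL")
            if fd_low is None or fd_low < 16:
                continue
            if conc is None or r.threshold is None or conc / r.threshold < 1:
                continue
            brute += 1
        assert sum(r.is_candidate_key for r in res) == brute

    def test_monotonicity_in_filters(self, compound_records):
        prev = None
        for fd_min in (1, 8, 16, 64, 256, 1024):
            n = sum(
                r.is_candidate_key
                for r in am.screen_compounds(compound_records, "HHL", fd_min=fd_min)
            )
            if prev is not None:
                assert n <= prev
            prev = n

    def test_unknown_sample_rejected(self, compound_records):
        with pytest.raises(ValidationError):
            am.screen_compounds(compound_records, "NOPE")

    def test_fd_range_filtered_by_lower_bound(self):
        rec = am.CompoundRecord("r", fd={"s": FDRange(128, 256)},
                                concentration={"s": 100.0}, threshold=1.0)
        res = am.screen_compounds([rec], "s", fd_min=129)
        assert not res[0].passes_fd
        res = am.screen_compounds([rec], "s", fd_min=128)
        assert res[0].passes_fd


class TestKeyEsters:
    def test_published_omission_pattern_selects_five(self, compound_records, omission_pvalues):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        key = am.select_key_esters(res, omission_pvalues, p_max=0.001)
        assert sorted(key) == [
            "Ethyl 2-methylbutyrate",
            "Ethyl 3-methylbutyrate",
            "Ethyl acetate",
            "Ethyl hexanoate",
            "Ethyl phenylacetate",
        ]

    def test_p_max_one_keeps_all_candidates(self, compound_records, omission_pvalues):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        assert len(am.select_key_esters(res, omission_pvalues, p_max=1.0)) == 14

    def test_no_test_below_threshold_gives_empty(self, compound_records, omission_pvalues):
        res = am.screen_compounds(compound_records, "HHL", fd_min=16, oav_min=1)
        weak = {k: 0.5 for k in omission_pvalues}
        assert am.select_key_esters(res, weak, p_max=0.001) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    conc=st.floats(min_value=1e-3, max_value=1e9),
    threshold=st.floats(min_value=1e-3, max_value=1e9),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_oav_scale_invariance_property(conc, threshold, scale):
    assert am.oav(conc * scale, threshold * scale) == pytest.approx(
        am.oav(conc, threshold), rel=1e-9
    )
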