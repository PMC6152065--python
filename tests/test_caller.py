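import itertools

import pytest

from hmwgs.caller import (
    CultivarProfile,
    assign_peaks,
    call_composition,
    call_overexpression,
    compare_to_prior,
    infer_dy,
    match_peak,
)
from hmwgs.chromatogram import Peak
from hmwgs.config import CallConfig, SimConfig
from hmwgs.errors import UnassignableError, ValidationError
from hmwgs.reference import rt_window
from hmwgs.simulate import simulate_chromatogram, simulate_gel
from hmwgs.subunits import LOCUS_TYPES, SubunitId

S = SubunitId


def peak(apex, height=100.0, area=37.6):
    return Peak(apex_rt=apex, height=height, area=area, left_rt=apex - 0.5, right_rt=apex + 0.5)


class TestMatchPeak:
    def test_bx13_unique(self, table):
        assert match_peak(peak(37.285), table, 3) == {S("Bx", "13")}

    def test_by_ambiguity_group(self, table):
        got = {s.label for s in match_peak(peak(33.942), table, 3)}
        assert got == {"8*", "9", "18", "20y"}

    def test_below_all_windows(self, table):
        assert match_peak(peak(24.0), table, 3) == frozenset()

    def test_window_edges_inclusive(self, table):
        entry = table.entry(S("Bx", "13"))
        lo, hi = rt_window(entry, 3)
        assert S("Bx", "13") in match_peak(peak(lo), table, 3)
        assert S("Bx", "13") in match_peak(peak(hi), table, 3)


class TestInferDy:
    @pytest.mark.parametrize(
        "dx,dy", [("5", "10"), ("2", "12"), ("2.2", "12"), ("4", "12")]
    )
    def test_linkage(self, dx, dy):
        assert infer_dy(S("Dx", dx)) == S("Dy", dy)

    def test_non_dx_rejected(self):
        with pytest.raises(ValidationError):
            infer_dy(S("By", "8"))


class TestCallOverexpression:
    def test_doubled_area_is_oe(self):
        others = [peak(26.7), peak(33.9), peak(34.8)]
        assert call_overexpression(peak(38.8, area=75.2), others) == "7OE"

    def test_equal_area_is_7(self):
        others = [peak(26.7), peak(34.1), peak(34.8), peak(40.4)]
        assert call_overexpression(peak(38.8), others) == "7"

    def test_threshold_inclusive(self):
        others = [peak(26.7, area=10.0)]
        assert call_overexpression(peak(38.8, area=15.0), others, threshold=1.5) == "7OE"

    def test_requires_other_peaks(self):
        with pytest.raises(ValidationError):
            call_overexpression(peak(38.8), [])


def oracle_assign(peaks, table, pairing, k):
    """Independent brute-force: score every injective peak->type map, no pruning."""
    peaks = sorted(peaks, key=lambda p: p.apex_rt)
    best = None
    for types in itertools.permutations(LOCUS_TYPES, len(peaks)):
        cands = []
        for p, t in zip(peaks, types):
            c = {s for s in match_peak(p, table, k) if s.locus_type == t}
            cands.append(c)
        if not all(cands):
            continue
        if "Dx" not in types or "Dy" not in types:
            continue
        bx = {s.label for s in cands[types.index("Bx")]} if "Bx" in types else None
        by = {s.label for s in cands[types.index("By")]} if "By" in types else None
        if by is not None and bx is None:
            continue
        if bx is not None:
            allowed = pairing.allowed
            if by is None:
                if not any((x, None) in allowed for x in bx):
                    continue
            elif not any((x, y) in allowed for x in bx for y in by):
                continue
        cost = 0.0
        for p, c in zip(peaks, cands):
            cost += min(
                ((p.apex_rt - table.entry(s).mean_rt) / table.entry(s).sd_rt) ** 2
                for s in c
            )
        if best is None or cost < best[0]:
            best = (cost, types)
    return best


class TestAssignPeaks:
    def test_chinese_spring_order(self, table, pairing):
        peaks = [peak(26.528), peak(35.195), peak(36.060), peak(38.842)]
        got = assign_peaks(peaks, table, pairing)
        types = [a.locus_type for a in got]
        assert types == ["Dy", "Dx", "By", "Bx"]
        # the By-assigned peak elutes after the Dx-assigned peak
        by = next(a for a in got if a.locus_type == "By")
        dx = next(a for a in got if a.locus_type == "Dx")
        assert by.peak.apex_rt > dx.peak.apex_rt

    def test_opata_order_five_peaks(self, table, pairing):
        peaks = [peak(26.528), peak(35.195), peak(35.604), peak(37.285), peak(40.354)]
        types = [a.locus_type for a in assign_peaks(peaks, table, pairing)]
        assert types == ["Dy", "Dx", "By", "Bx", "Ax"]

    def test_three_peaks_by_absent(self, table, pairing):
        peaks = [peak(26.528), peak(35.195), peak(38.842)]
        got = assign_peaks(peaks, table, pairing)
        assert [a.locus_type for a in got] == ["Dy", "Dx", "Bx"]

    def test_candidate_sets_keep_ambiguity(self, table, pairing):
        peaks = [peak(26.528), peak(35.195), peak(38.842)]
        got = {a.locus_type: a for a in assign_peaks(peaks, table, pairing)}
        assert {s.label for s in got["Dx"].candidates} == {"2", "4"}
        assert {s.label for s in got["Bx"].candidates} == {"7", "7OE"}

    def test_unmatchable_peak_raises(self, table, pairing):
        with pytest.raises(UnassignableError):
            assign_peaks([peak(26.528), peak(30.0), peak(35.195)], table, pairing)

    def test_missing_glu_d1_raises(self, table, pairing):
        with pytest.raises(UnassignableError):
            assign_peaks([peak(38.842)], table, pairing)

    def test_agrees_with_bruteforce_on_all_fixtures(self, table, pairing, mobility, fixtures):
        for profile in fixtures.all_profiles():
            peaks = [peak(table.entry(s).mean_rt) for s in profile.subunits()]
            got = assign_peaks(peaks, table, pairing)
            expect = oracle_assign(peaks, table, pairing, 3.0)
            assert expect is not None, profile.name
            got_types = tuple(a.locus_type for a in got)
            assert got_types == expect[1], profile.name
            cost = sum(a.z**2 for a in got)
            assert cost == pytest.approx(expect[0], abs=1e-9)


class TestCultivarProfile:
    def test_dy10_requires_dx5(self, pairing):
        p = CultivarProfile("x", None, S("Bx", "7"), S("By", "8"),
                            S("Dx", "2"), S("Dy", "10"))
        with pytest.raises(ValidationError):
            p.validate(pairing)

    def test_disallowed_pair(self, pairing):
        p = CultivarProfile("x", None, S("Bx", "13"), S("By", "8"),
                            S("Dx", "2"), S("Dy", "12"))
        with pytest.raises(ValidationError):
            p.validate(pairing)

    def test_bx7_alone_allowed(self, pairing):
        p = CultivarProfile("x", None, S("Bx", "7"), None, S("Dx", "2"), S("Dy", "12"))
        p.validate(pairing)

    def test_all_fixtures_valid(self, pairing, fixtures):
        for p in fixtures.all_profiles():
            p.validate(pairing)


def run_call(name, table, pairing, mobility, fixtures, lane=True, **sim_kwargs):
    profile = fixtures.by_name(name)
    trace = simulate_chromatogram(profile, table, SimConfig(**sim_kwargs))
    gel = simulate_gel(profile, mobility) if lane else None
    return profile, call_composition(trace, table, pairing, mobility, lane=gel)


class TestCallComposition:
    def test_chinese_spring_with_lane(self, table, pairing, mobility, fixtures):
        profile, result = run_call("Chinese Spring", table, pairing, mobility, fixtures)
        assert result.exact_match(profile)
        assert result.flags == []
        assert result.evidence == {
            "Ax": "absent", "Bx": "pairing", "By": "rt", "Dx": "gel", "Dy": "linkage",
        }

    def test_sinmichal1_dx2_not_dx22(self, table, pairing, mobility, fixtures):
        profile, result = run_call("Sinmichal1", table, pairing, mobility, fixtures)
        assert result.profile.dx.label == "2"
        assert result.profile.dy.label == "12"
        dx_peak = next(d for d in result.per_peak if d["locus_type"] == "Dx")
        assert dx_peak["apex_rt"] == pytest.approx(35.195, abs=0.005)

    def test_joongmo2008_by_needs_gel(self, table, pairing, mobility, fixtures):
        _, without = run_call("Joongmo2008", table, pairing, mobility, fixtures, lane=False)
        assert any(f.startswith("ambiguous-By") for f in without.flags)
        profile, with_lane = run_call("Joongmo2008", table, pairing, mobility, fixtures)
        assert with_lane.profile.by.label == "18"
        assert with_lane.evidence["By"] == "gel"
        assert with_lane.flags == []

    def test_glenlea_overexpression(self, table, pairing, mobility, fixtures):
        profile, result = run_call("Glenlea", table, pairing, mobility, fixtures)
        assert result.profile.bx.label == "7OE"
        assert result.evidence["Bx"] == "intensity"

    def test_cheyenne_not_overexpressed(self, table, pairing, mobility, fixtures):
        profile, result = run_call("Cheyenne", table, pairing, mobility, fixtures)
        assert result.profile.bx.label == "7"

    def test_no_two_peaks_same_locus_type(self, table, pairing, mobility, fixtures):
        _, result = run_call("Sukang", table, pairing, mobility, fixtures)
        types = [d["locus_type"] for d in result.per_peak]
        assert len(types) == len(set(types))

    def test_no_match_peak_is_flagged_not_fatal(self, table, pairing, mobility, fixtures):
        import numpy as np

        profile = fixtures.by_name("Chinese Spring")
        trace = simulate_chromatogram(profile, table, SimConfig())
        # inject a rogue peak between reference windows
        trace.absorbance += 100.0 * np.exp(-0.5 * ((trace.time - 30.0) / 0.15) ** 2)
        result = call_composition(
            trace, table, pairing, mobility, lane=simulate_gel(profile, mobility)
        )
        assert any(f.startswith("no-match") for f in result.flags)
        assert result.exact_match(profile)


GEL_GROUP = {
    ("Ax", "1"), ("Ax", "2*"),
    ("Dx", "2"), ("Dx", "4"),
    ("By", "8*"), ("By", "9"), ("By", "18"), ("By", "20y"),
}


class TestNoGelFlagging:
    def test_flagged_loci_are_exactly_gel_groups(self, table, pairing, mobility, fixtures):
        for profile in fixtures.standards:
            trace = simulate_chromatogram(profile, table, SimConfig())
            result = call_composition(trace, table, pairing, mobility, lane=None)
            flagged = {
                f.removeprefix("ambiguous-").split(":")[0]
                for f in result.flags
                if f.startswith("ambiguous-")
            }
            expected = {
                t for t in LOCUS_TYPES
                if profile.label_at(t) is not None and (t, profile.label_at(t)) in GEL_GROUP
            }
            assert flagged == expected, profile.name
            # provisional calls still equal the truth at zero jitter
            assert result.exact_match(profile), profile.name


class TestCompareToPrior:
    def test_jonong_by_discrepancy(self, table, pairing, mobility, fixtures):
        _, result = run_call("Jonong", table, pairing, mobility, fixtures)
        diffs = compare_to_prior(result, fixtures.priors["Jonong"])
        assert diffs == [("By", "8", "9")]

    def test_identical_profiles_empty(self, table, pairing, mobility, fixtures):
        _, result = run_call("Keumkang", table, pairing, mobility, fixtures)
        assert compare_to_prior(result, fixtures.priors["Keumkang"]) == []

    def test_name_mismatch_raises(self, table, pairing, mobility, fixtures):
        _, result = run_call("Jonong", table, pairing, mobility, fixtures)
        with pytest.raises(ValidationError):
            compare_to_prior(result, fixtures.priors["Keumkang"])


class TestStochasticRecoverySmoke:
    def test_20_jittered_standards_recover(self, table, pairing, mobility, fixtures):
        from hmwgs.errors import UnassignableError as UErr

        n_ok = 0
        for rep in range(20):
            profile = fixtures.standards[rep % 16]
            cfg = SimConfig(rt_jitter_scale=1.0, seed=7000 + rep)
            trace = simulate_chromatogram(profile, table, cfg)
            try:
                result = call_composition(
                    trace, table, pairing, mobility, lane=simulate_gel(profile, mobility)
                )
                n_ok += result.exact_match(profile)
            except UErr:
                pass
        assert n_ok >= 18
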