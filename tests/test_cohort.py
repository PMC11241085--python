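"""Record validation, PTA arithmetic, sub-group assignment, and moments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speechnorms as sn
from speechnorms.cohort import BUILTIN_SCHEMES, group_records

from conftest import make_cohort_csv


@pytest.mark.parametrize(
    "htls, expected",
    [((10, 10, 10, 10), 10.0), ((20, 30, 40, 50), 35.0), ((0, 5, 5, 10), 5.0)],
)
def test_compute_pta_is_four_frequency_mean(htls, expected):
    assert sn.compute_pta(*htls) == expected


def test_compute_pta_rejects_missing_threshold():
    with pytest.raises(ValueError):
        sn.compute_pta(10, float("nan"), 10, 10)


@pytest.mark.parametrize(
    "air, bone, expected",
    [
        # one 20-dB gap only: not conductive
        ({0.5: 40, 1: 40, 2: 40}, {0.5: 20, 1: 30, 2: 40}, False),
        # two 20-dB gaps: conductive
        ({0.5: 40, 1: 40, 2: 40}, {0.5: 20, 1: 20, 2: 40}, True),
        # air equals bone everywhere: no gap
        ({0.5: 30, 1: 30, 2: 30}, {0.5: 30, 1: 30, 2: 30}, False),
        # exactly 15 dB counts as a gap
        ({0.5: 35, 1: 35, 2: 20}, {0.5: 20, 1: 20, 2: 20}, True),
    ],
)
def test_air_bone_gap_rule(air, bone, expected):
    assert sn.flag_conductive(air, bone) is expected


def test_missing_bone_passes_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert sn.flag_conductive({0.5: 40, 1: 40, 2: 40}, None) is False
    assert "bone" in caplog.text


class TestReadCohort:
    def test_well_formed_file(self, tmp_path):
        path = make_cohort_csv(tmp_path, ["p1,R,10,96", "p1,L,12.5,92", "p2,R,40,80"])
        records = sn.read_cohort(path)
        assert len(records) == 3
        assert records[1].ear == "L" and records[1].pta == 12.5

    def test_out_of_range_score_rejected(self, tmp_path):
        path = make_cohort_csv(tmp_path, ["p1,R,10,103"])
        with pytest.raises(ValueError, match="line 2"):
            sn.read_cohort(path)

    def test_pta_computed_from_thresholds(self, tmp_path):
        path = make_cohort_csv(
            tmp_path,
            ["p1,R,20,30,40,50,76"],
            header="participant_id,ear,htl_500,htl_1000,htl_2000,htl_4000,pbmax",
        )
        (rec,) = sn.read_cohort(path)
        assert rec.pta == 35.0

    def test_off_grid_score_warns_by_default_but_strict_rejects(self, tmp_path):
        path = make_cohort_csv(tmp_path, ["p1,R,10,93"])
        (rec,) = sn.read_cohort(path)  # warn-and-keep
        assert rec.pbmax == 93.0
        with pytest.raises(ValueError, match="multiple of 4"):
            sn.read_cohort(path, strict_step=True)

    def test_conductive_ears_excluded(self, tmp_path):
        header = ("participant_id,ear,htl_500,htl_1000,htl_2000,htl_4000,"
                  "bone_500,bone_1000,bone_2000,pbmax")
        path = make_cohort_csv(
            tmp_path,
            ["p1,R,40,40,40,40,20,20,40,80",   # two 20-dB gaps -> excluded
             "p2,R,40,40,40,40,40,40,40,80"],  # no gaps -> kept
            header=header,
        )
        records = sn.read_cohort(path)
        assert [r.participant_id for r in records] == ["p2"]


class TestSubgroupAssignment:
    @pytest.mark.parametrize(
        "pta, label",
        [(10.2, "<15"), (60.2, "56-65"), (15.5, "<15"), (15.51, "16-25"), (91.2, "86-120")],
    )
    def test_group1_examples_and_boundary_convention(self, pta, label, group1):
        rec = sn.EarRecord("x", "R", pta, 80.0)
        assert sn.assign_subgroup(rec, group1) == label

    def test_out_of_range_pta_raises(self, group1):
        rec = sn.EarRecord("x", "R", 125.0, 80.0)
        with pytest.raises(ValueError, match="outside"):
            sn.assign_subgroup(rec, group1)

    def test_assignment_total_and_single_valued_on_all_schemes(self):
        # every PTA on the 1.25-dB audiometric grid lands in exactly one bin
        ptas = np.arange(0.0, 120.0 + 1e-9, 1.25)
        for scheme in BUILTIN_SCHEMES.values():
            records = [sn.EarRecord(f"p{i}", "R", float(p), 80.0) for i, p in enumerate(ptas)]
            labels = [sn.assign_subgroup(r, scheme) for r in records]
            assert all(lbl in scheme.labels for lbl in labels)
            groups = group_records(records, scheme)
            assert sum(len(g) for g in groups.values()) == len(records)


class TestSummarize:
    def test_constant_sample_has_undefined_shape_moments(self):
        recs = [sn.EarRecord(f"p{i}", "R", 10.0, 96.0) for i in range(3)]
        s = sn.summarize_subgroup(recs)
        assert s.mean_pbmax == 96.0 and s.sd_pbmax == 0.0
        assert math.isnan(s.skewness) and math.isnan(s.kurtosis)

    def test_two_point_sample_sd_uses_n_minus_1(self):
        recs = [sn.EarRecord("a", "R", 10.0, 0.0), sn.EarRecord("b", "R", 10.0, 100.0)]
        s = sn.summarize_subgroup(recs)
        assert s.mean_pbmax == 50.0
        assert s.sd_pbmax == pytest.approx(70.7107, abs=1e-3)

    def test_moment_conventions_on_large_normal_sample(self):
        # third standardized moment ~ 0; non-excess kurtosis ~ 3 for a normal law
        rng = np.random.default_rng(1)
        vals = np.clip(rng.normal(50, 10, 100_000), 0, 100)
        recs = [sn.EarRecord(f"p{i}", "R", 10.0, float(v)) for i, v in enumerate(vals)]
        s = sn.summarize_subgroup(recs)
        assert abs(s.skewness) < 0.05
        assert s.kurtosis == pytest.approx(3.0, abs=0.1)

    def test_pooled_mean_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a = [sn.EarRecord(f"a{i}", "R", 10.0, float(v)) for i, v in enumerate(rng.integers(0, 26, 40) * 4)]
        b = [sn.EarRecord(f"b{i}", "R", 30.0, float(v)) for i, v in enumerate(rng.integers(0, 26, 25) * 4)]
        sa, sb, sab = sn.summarize_subgroup(a), sn.summarize_subgroup(b), sn.summarize_subgroup(a + b)
        pooled = (sa.n * sa.mean_pbmax + sb.n * sb.mean_pbmax) / (sa.n + sb.n)
        brute = np.mean([r.pbmax for r in a + b])
        assert sab.mean_pbmax == pytest.approx(pooled, abs=1e-12)
        assert sab.mean_pbmax == pytest.approx(brute, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sn.summarize_subgroup([])


class TestRoundToStep:
    @pytest.mark.parametrize("value, expected", [(86.99, 88), (78.36, 80), (76.0, 76), (86.0, 88)])
    def test_nearest_multiple_with_half_away_from_zero(self, value, expected):
        assert sn.round_to_step(value) == expected

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=-200, max_value=200, allow_nan=False))
    def test_idempotent_and_within_half_step(self, x):
        r = sn.round_to_step(x, 4)
        assert sn.round_to_step(r, 4) == r
        assert abs(r - x) <= 2.0
        assert r % 4 == 0
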