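"""Plate statistics: Z', SD-distance scoring, hit rule, gated group tests."""

import numpy as np
import pandas as pd
import pytest

from ldscreen import (
    PARAMETERS,
    call_hits,
    compare_groups,
    score_plate,
    zprime,
)
from ldscreen.screenstats import PlateScores, ssmd_replicate


def feature_frame(values, roles=None):
    """values: dict param -> list over wells (compound wells by default)."""
    n = len(next(iter(values.values())))
    df = pd.DataFrame(values)
    df["well"] = [f"A{i + 1:02d}" for i in range(n)]
    df["role"] = roles if roles is not None else "compound"
    df["compound_id"] = [f"C{i}" for i in range(n)]
    return df


class TestZPrime:
    def test_zero_variance_limit_is_exactly_one(self):
        assert zprime([10, 10, 10], [0, 0, 0]).value == 1.0

    def test_hand_computed_four_vs_four(self):
        # means 10 and 0.5, SDs 0 and 1 -> 1 - 3(0+1)/9.5
        res = zprime([10, 10, 10, 10], [0, 0, 0, 2])
        assert res.value == pytest.approx(1 - 3 / 9.5, abs=1e-12)
        assert res.sd_neg == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self, rng):
        a, b = rng.normal(10, 1, 12), rng.normal(0, 1, 12)
        assert zprime(a, b).value == pytest.approx(zprime(b, a).value, abs=1e-12)

    def test_equal_means_flagged_undefined(self):
        res = zprime([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(res.value) and "equal_group_means" in res.flags

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError):
            zprime([1.0], [0.0, 0.0])


class TestScorePlate:
    def test_compound_at_median_scores_zero(self):
        vals = {p: [1.0, 2.0, 3.0, 4.0, 5.0] for p in PARAMETERS}
        scores = score_plate(feature_frame(vals))
        row = scores.scores.set_index("compound_id").loc["C2"]
        for p in PARAMETERS:
            assert row[f"z_{p}"] == 0.0

    def test_hand_computed_score(self):
        # reference {1..9}: median 5, sample SD sqrt(7.5) ~ 2.7386; a compound
        # at 10.4776 sits almost exactly 2 SDs above the median
        vals = {p: [float(v) for v in range(1, 10)] + [10.4776] for p in PARAMETERS}
        roles = ["negative_control"] * 9 + ["compound"]
        df = feature_frame(vals, roles=roles)
        scores = score_plate(df, reference_source="negative_controls")
        z = scores.scores[f"z_{PARAMETERS[0]}"].iloc[0]
        assert z == pytest.approx(5.4776 / np.sqrt(7.5), rel=1e-12)
        assert z == pytest.approx(2.0003, abs=1e-3)

    def test_location_invariance(self, rng):
        vals = {p: rng.normal(10, 2, 40).tolist() for p in PARAMETERS}
        s0 = score_plate(feature_frame(vals))
        shifted = {p: [v + 7.5 for v in vals[p]] for p in PARAMETERS}
        s1 = score_plate(feature_frame(shifted))
        for p in PARAMETERS:
            np.testing.assert_allclose(s0.scores[f"z_{p}"], s1.scores[f"z_{p}"],
                                       atol=1e-9)

    def test_matches_brute_force_recomputation(self, rng):
        """sort-based median + two-pass SD oracle on random tables."""
        for trial in range(100):
            n = int(rng.integers(5, 60))
            vals = {p: rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n)
                    for p in PARAMETERS}
            df = feature_frame({p: v.tolist() for p, v in vals.items()})
            scores = score_plate(df)
            for p in PARAMETERS:
                x = np.sort(vals[p])
                med = (x[(n - 1) // 2] + x[n // 2]) / 2.0
                mean = sum(vals[p]) / n
                sd = (sum((v - mean) ** 2 for v in vals[p]) / (n - 1)) ** 0.5
                expected = (vals[p] - med) / sd
                np.testing.assert_allclose(scores.scores[f"z_{p}"], expected,
                                           rtol=1e-10)

    def test_robust_sd_uses_scaled_mad(self):
        vals = {p: [1.0, 2.0, 3.0, 4.0, 100.0] for p in PARAMETERS}
        s = score_plate(feature_frame(vals), robust_sd=True)
        assert s.reference[PARAMETERS[0]]["sd"] == pytest.approx(1.4826)

    def test_qc_flagged_wells_excluded(self):
        vals = {p: [1.0, 2.0, 3.0, 4.0, 5.0] for p in PARAMETERS}
        df = feature_frame(vals)
        df["qc_flags"] = ["", "", "", "", "no_cells"]
        s = score_plate(df)
        assert s.reference[PARAMETERS[0]]["n"] == 4
        assert len(s.scores) == 4

    def test_small_reference_rejected(self):
        vals = {p: [1.0, 2.0] for p in PARAMETERS}
        with pytest.raises(ValueError, match="< 3"):
            score_plate(feature_frame(vals))


def scores_from_z(zmap):
    rows = {"compound_id": list(zmap), "well": [f"A{i + 1:02d}" for i in range(len(zmap))]}
    for p in PARAMETERS:
        rows[f"value_{p}"] = [0.0] * len(zmap)
        rows[f"z_{p}"] = [z[p] for z in zmap.values()]
    return PlateScores(pd.DataFrame(rows), reference={})


class TestCallHits:
    def z(self, a, t, c, f):
        return dict(zip(PARAMETERS, (a, t, c, f)))

    def test_all_four_bars_cleared_is_hit(self):
        hits = call_hits(scores_from_z({"X": self.z(-2.5, -2.5, -2.5, -4.5)}))
        assert bool(hits["hit"].iloc[0])
        assert hits["total_area_direction"].iloc[0] == "decrease"

    def test_form_factor_below_its_4sd_bar_blocks_hit(self):
        hits = call_hits(scores_from_z({"X": self.z(-2.5, -2.5, -2.5, -3.9)}))
        assert not hits["hit"].iloc[0]
        assert not hits["pass_ld_form_factor"].iloc[0]

    def test_total_area_increase_is_not_a_hit_by_default(self):
        hits = call_hits(scores_from_z({"X": self.z(2.5, 2.5, 2.5, 4.5)}))
        assert not hits["hit"].iloc[0]
        assert hits["total_area_direction"].iloc[0] == "increase"

    def test_raising_threshold_never_creates_hits(self, rng):
        zmap = {f"C{i}": self.z(*rng.normal(0, 3, 4)) for i in range(200)}
        base = call_hits(scores_from_z(zmap))
        for p in PARAMETERS:
            stricter = call_hits(scores_from_z(zmap), thresholds={p: 5.0})
            assert set(stricter.loc[stricter.hit, "compound_id"]) <= set(
                base.loc[base.hit, "compound_id"])

    def test_missing_score_excludes_never_passes(self):
        z = self.z(-5.0, -5.0, -5.0, float("nan"))
        hits = call_hits(scores_from_z({"X": z}))
        assert bool(hits["excluded"].iloc[0]) and not hits["hit"].iloc[0]


class TestCompareGroups:
    def test_identical_samples_mann_whitney_p_one(self):
        # strongly skewed values fail the normality gate; identical samples
        # then give U at its null centre and p = 1
        a = [1.0] * 8 + [50.0, 60.0]
        res = compare_groups(a, a)
        assert res.test_used == "mann-whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_lognormal_groups_select_mann_whitney(self, rng):
        picked = sum(
            compare_groups(rng.lognormal(0, 1, 150),
                           rng.lognormal(0.1, 1, 150)).test_used == "mann-whitney"
            for _ in range(100)
        )
        assert picked > 95

    def test_normal_groups_select_t(self, rng):
        res = compare_groups(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        assert res.test_used == "t"

    def test_all_tied_falls_back_flagged(self):
        res = compare_groups([2.0] * 5, [2.0, 2.0, 2.0, 2.0, 3.0])
        assert res.test_used == "mann-whitney"
        assert "degenerate_group" in res.flags

    def test_large_shift_detected(self, rng):
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert res.p_value < 1e-4

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_ssmd_replicate_closed_form():
    a, b = [3.0, 5.0, 7.0], [1.0, 1.0, 1.0]
    assert ssmd_replicate(a, b) == pytest.approx((5 - 1) / 2.0)
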