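"""Spot rejection rules, replicate aggregation, and their invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acescan import qc
from acescan.simulate import make_scenario, simulate_slide
from conftest import make_spot_frame


def flags_for(median, pixel_sd=None, background=None, **kw):
    return qc.flag_spots(make_spot_frame(median, pixel_sd, background, **kw))


class TestLowSignal:
    @pytest.mark.parametrize(
        "signal,flagged", [(199.9, True), (200.0, False), (5000.0, True * 0)]
    )
    def test_strict_200_rfu_boundary(self, signal, flagged):
        spots = make_spot_frame([signal, 1000.0, 1000.0])
        f = qc.flag_spots(spots)
        assert bool(f.loc[0, "low_signal"]) == bool(flagged)


class TestMorphology:
    def test_single_cv_outlier_flagged_exactly(self):
        median = np.full(1000, 1000.0)
        sd = np.full(1000, 100.0)  # CV 0.10
        sd[123] = 900.0  # CV 0.90
        cv = sd / median
        cut = cv.mean() + 3 * cv.std(ddof=1)
        assert cv[123] > cut and (np.delete(cv, 123) <= cut).all()
        f = flags_for(median, sd)
        assert f["bad_morphology"].sum() == 1 and f.loc[123, "bad_morphology"]

    def test_identical_cv_none_flagged(self):
        f = flags_for(np.full(50, 800.0), np.full(50, 80.0))
        assert not f["bad_morphology"].any()

    def test_all_zero_signals_error(self):
        with pytest.raises(qc.QcError, match="CV"):
            flags_for(np.zeros(5), np.zeros(5))


class TestBackground:
    def test_uniform_background_none_flagged(self):
        f = flags_for(np.full(40, 900.0), background=np.full(40, 60.0))
        assert not f["high_background"].any()

    def test_outlier_at_mean_plus_4sd_flagged(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(60, 5, 200)
        bg[7] = bg.mean() + 4 * bg.std(ddof=1)
        cut = bg.mean() + 3 * bg.std(ddof=1)  # cutoff includes the outlier
        f = flags_for(np.full(200, 900.0), background=bg)
        expect = bg > cut
        assert (f["high_background"].to_numpy() == expect).all()
        assert f.loc[7, "high_background"]

    def test_coincident_outliers_share_the_cutoff(self):
        base = np.full(20, 50.0)
        base[:3] = [49.0, 51.0, 50.5]  # give the bulk nonzero spread
        for pair in (500.0, 58.0):  # far outliers vs borderline pair
            bg = base.copy()
            bg[[4, 9]] = pair
            cut = bg.mean() + 3 * bg.std(ddof=1)
            f = flags_for(np.full(20, 900.0), background=bg)
            assert (f["high_background"].to_numpy() == (bg > cut)).all()


class TestInvariances:
    @given(st.floats(0.1, 100.0))
    def test_flags_invariant_under_uniform_rescaling(self, scale):
        rng = np.random.default_rng(11)
        median = rng.uniform(500, 5000, 60)
        sd = rng.uniform(0.02, 0.2, 60) * median
        bg = rng.normal(70, 12, 60).clip(0)
        f0 = flags_for(median, sd, bg)
        # CV is scale-free and the background rule compares like with like
        f1 = flags_for(median * scale, sd * scale, bg * scale)
        pd.testing.assert_frame_equal(
            f0[["bad_morphology", "high_background"]],
            f1[["bad_morphology", "high_background"]],
        )

    def test_flags_invariant_under_spot_order(self):
        rng = np.random.default_rng(3)
        median = rng.uniform(500, 5000, 40)
        sd = rng.uniform(0.02, 0.4, 40) * median
        bg = rng.normal(70, 12, 40).clip(0)
        f0 = flags_for(median, sd, bg).sort_values("ace_id").reset_index(drop=True)
        perm = rng.permutation(40)
        spots = make_spot_frame(median[perm], sd[perm], bg[perm],
                                ace_ids=[f"ace{i}" for i in perm])
        f1 = qc.flag_spots(spots).sort_values("ace_id").reset_index(drop=True)
        cols = ["ace_id", "low_signal", "bad_morphology", "high_background"]
        pd.testing.assert_frame_equal(f0[cols], f1[cols])


class TestAggregation:
    def _spots_two_subarrays(self):
        frames = []
        for sub in ("s1", "s2"):
            frames.append(
                make_spot_frame(
                    [1000, 1100, 900, 1000, 1000],
                    subarray_id=sub,
                    ace_ids=["aceA"] * 5,
                    replicates=np.arange(1, 6),
                )
            )
        return pd.concat(frames, ignore_index=True)

    def _flags(self, spots, failed):
        f = qc.flag_spots(spots)
        f[["low_signal", "bad_morphology", "high_background"]] = False
        for sub, rep in failed:
            m = (f["subarray_id"] == sub) & (f["replicate"] == rep)
            f.loc[m, "bad_morphology"] = True
        f["pass"] = ~(f["low_signal"] | f["bad_morphology"] | f["high_background"])
        return f

    def test_two_failures_leave_ace_retained(self):
        spots = self._spots_two_subarrays()
        flags = self._flags(spots, [("s1", 1), ("s1", 2)])
        da = qc.aggregate_replicates(spots, flags)
        row = da[(da["ace_id"] == "aceA") & (da["subarray_id"] == "s1")]
        assert (row["n_pass"] == 3).all() and not row["excluded"].any()

    def test_three_failures_in_one_subarray_exclude_everywhere(self):
        spots = self._spots_two_subarrays()
        flags = self._flags(spots, [("s1", 1), ("s1", 2), ("s1", 3)])
        da = qc.aggregate_replicates(spots, flags)
        assert da[da["ace_id"] == "aceA"]["excluded"].all()
        assert da[da["ace_id"] == "aceA"]["mean_signal"].isna().all()

    def test_mean_over_passing_replicates(self):
        spots = make_spot_frame(
            [100.0, 200.0, 300.0, 9999.0],
            ace_ids=["aceA"] * 4,
            replicates=[1, 2, 3, 4],
        )
        flags = qc.flag_spots(spots)
        flags[["low_signal", "bad_morphology", "high_background"]] = False
        flags.loc[flags["replicate"] == 4, "high_background"] = True
        flags["pass"] = ~flags["high_background"]
        da = qc.aggregate_replicates(spots, flags, min_pass=3)
        assert da["mean_signal"].iloc[0] == pytest.approx(200.0)

    def test_raising_min_pass_never_unexcludes(self):
        spots = self._spots_two_subarrays()
        flags = self._flags(spots, [("s1", 1), ("s1", 2)])
        excluded = {}
        for mp in (1, 2, 3, 4, 5, 6):
            da = qc.aggregate_replicates(spots, flags, min_pass=mp)
            excluded[mp] = set(da.loc[da["excluded"], "ace_id"])
        for lo, hi in zip((1, 2, 3, 4, 5), (2, 3, 4, 5, 6)):
            assert excluded[lo] <= excluded[hi]


class TestPlantedFailureRecovery:
    def test_morphology_flags_equal_planted_set(self):
        sc = make_scenario("flat_null", seed=23, replicates=7)
        ds = simulate_slide(sc)
        flags = qc.flag_spots(ds.spots)
        key = ["subarray_id", "ace_id", "replicate"]
        merged = flags.merge(ds.planted_failures, on=key)
        # base pixel CV is constant by construction, so the CV rule recovers
        # exactly the planted morphology failures
        assert (merged["bad_morphology"] == merged["morphology"]).all()
        assert merged["morphology"].sum() > 0
        # planted background failures are all recovered; the normal
        # background tail may add ~0.1% of extra flags
        planted = merged["background"]
        assert merged.loc[planted, "high_background"].all()
        extra = merged["high_background"].sum() - planted.sum()
        assert extra <= np.ceil(0.0035 * len(merged))

    def test_planted_rate_matches_request(self):
        sc = make_scenario("flat_null", seed=29, replicates=7)
        ds = simulate_slide(sc)
        n = len(ds.planted_failures)
        k = ds.planted_failures["morphology"].sum()
        # binomial(n, 0.002) within 4 sigma
        assert abs(k - 0.002 * n) < 4 * np.sqrt(n * 0.002 * 0.998) + 1
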