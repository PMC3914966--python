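"""Z'-factor, Z-scores, hit calling, FP/FN rates, dose-response tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoscreen import (
    ControlStats,
    DegenerateControlsError,
    InputError,
    InsufficientDataError,
    call_hits,
    control_stats,
    dose_response_table,
    fp_fn_rates,
    percent_of_control,
    qc_report,
    zprime,
    zscore,
)
from cytoscreen.screen_stats import cross_timepoint_hits


def stats(mean, sd, endpoint="n_cells", n=8):
    return ControlStats(endpoint=endpoint, mean=mean, sd=sd, cv_pct=0.0, n=n)


class TestControlStats:
    def test_constant_values(self):
        s = control_stats([10, 10, 10])
        assert (s.mean, s.sd, s.cv_pct) == (10, 0, 0)

    def test_two_values_hand_arithmetic(self):
        s = control_stats([8, 12])
        assert s.mean == pytest.approx(10)
        assert s.sd == pytest.approx(2.8284, abs=1e-4)  # sqrt(8), n-1 denominator
        assert s.cv_pct == pytest.approx(28.284, abs=1e-3)

    @pytest.mark.parametrize("values", [[], [5]])
    def test_insufficient_data(self, values):
        with pytest.raises(InsufficientDataError):
            control_stats(values)

    def test_zero_mean_has_undefined_cv(self):
        assert np.isnan(control_stats([-1, 1]).cv_pct)


class TestZPrime:
    def test_hand_example(self):
        assert zprime(stats(10, 1), stats(100, 5)) == pytest.approx(0.8)

    def test_zero_variance_limit(self):
        assert zprime(stats(10, 0), stats(100, 0)) == pytest.approx(1.0)

    def test_overlapping_controls_go_negative(self):
        assert zprime(stats(50, 10), stats(60, 10)) == pytest.approx(-5.0)

    def test_symmetric_under_control_swap(self):
        pos, neg = stats(30, 4), stats(110, 7)
        assert zprime(pos, neg) == pytest.approx(zprime(neg, pos))

    def test_equal_means_degenerate(self):
        with pytest.raises(DegenerateControlsError):
            zprime(stats(10, 1), stats(10, 2))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.1, 50).flatmap(lambda x: st.sampled_from([x, -x])),
        b=st.floats(-100, 100),
        mu_s=st.floats(-50, 50),
        mu_c=st.floats(60, 200),
        sd_s=st.floats(0, 10),
        sd_c=st.floats(0, 10),
    )
    def test_affine_invariance(self, a, b, mu_s, mu_c, sd_s, sd_c):
        z1 = zprime(stats(mu_s, sd_s), stats(mu_c, sd_c))
        z2 = zprime(stats(a * mu_s + b, abs(a) * sd_s), stats(a * mu_c + b, abs(a) * sd_c))
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)
        assert z1 <= 1.0


class TestZScore:
    def test_centering(self):
        assert zscore(100, stats(100, 10)) == 0.0

    def test_hand_examples(self):
        assert zscore(80, stats(100, 10)) == pytest.approx(-2.0)
        assert zscore(35, stats(100, 10)) == pytest.approx(-6.5)

    def test_zero_sd_degenerate(self):
        with pytest.raises(DegenerateControlsError):
            zscore(5, stats(100, 0))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
        x=st.floats(-50, 250),
        mu=st.floats(-50, 50),
        sd=st.floats(0.5, 10),
    )
    def test_affine_equivariance(self, a, b, x, mu, sd):
        z1 = zscore(x, stats(mu, sd))
        z2 = zscore(a * x + b, stats(a * mu + b, a * sd))
        assert z2 == pytest.approx(z1, rel=1e-6, abs=1e-6)


def _screen_frames(neg_values, compound_values, timepoint_h=24):
    """Build summary + layout frames: negatives on one plate per 8 wells."""
    rows, lay = [], []
    for i, v in enumerate(neg_values):
        plate = f"P{i // 8 + 1:02d}"
        well = f"A{i % 8 + 1:02d}"
        rows.append((plate, well, v, 0.0, 0.0))
        lay.append((plate, well, "negative_control", "", np.nan, timepoint_h, False))
    for i, (cid, v) in enumerate(compound_values):
        plate = f"P{i // 8 + 1:02d}"
        well = f"B{i % 8 + 1:02d}"
        rows.append((plate, well, v, 0.0, 0.0))
        lay.append((plate, well, "compound", cid, 20.0, timepoint_h, False))
    summaries = pd.DataFrame(
        rows, columns=["plate_id", "well_id", "n_cells", "pct_abnormal", "pct_mitotic"]
    )
    layout = pd.DataFrame(
        lay,
        columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"],
    )
    return summaries, layout


class TestCallHits:
    # negatives engineered to mean 100, sd exactly 10
    NEG = [90.0, 110.0] * 6

    def test_compound_at_negative_mean_is_not_hit(self):
        s, l = _screen_frames(self.NEG, [("C1", 100.0)])
        hits = call_hits(s, l, "n_cells")
        assert hits.z_score.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not hits.is_hit.iloc[0]

    def test_cutoff_is_inclusive_at_exactly_two_sigma(self):
        neg_sd = float(np.std(self.NEG, ddof=1))
        s, l = _screen_frames(self.NEG, [("C1", 100.0 - 2 * neg_sd)])
        hits = call_hits(s, l, "n_cells")
        assert hits.z_score.iloc[0] == pytest.approx(-2.0)
        assert bool(hits.is_hit.iloc[0])

    def test_strong_displacement_all_recovered(self):
        rng = np.random.default_rng(0)
        neg = list(rng.normal(100, 10, 72))
        mu, sd = np.mean(neg), np.std(neg, ddof=1)
        compounds = [(f"C{i}", mu - 8 * sd) for i in range(10)]
        s, l = _screen_frames(neg, compounds)
        hits = call_hits(s, l, "n_cells")
        assert hits.is_hit.all() and len(hits) == 10

    def test_replicates_aggregated_before_scoring(self):
        s, l = _screen_frames(self.NEG, [("C1", 60.0), ("C1", 100.0)])
        hits = call_hits(s, l, "n_cells", replicate_agg="mean")
        assert len(hits) == 1
        assert hits.n_replicates.iloc[0] == 2
        assert hits.aggregated_value.iloc[0] == pytest.approx(80.0)

    def test_per_well_any_flags_single_extreme_replicate(self):
        s, l = _screen_frames(self.NEG, [("C1", 40.0), ("C1", 100.0), ("C1", 100.0)])
        mean_agg = call_hits(s, l, "n_cells", replicate_agg="mean")
        any_agg = call_hits(s, l, "n_cells", replicate_agg="per_well_any")
        assert not mean_agg.is_hit.iloc[0]  # mean of 80 is within 2 sd
        assert bool(any_agg.is_hit.iloc[0])

    def test_compound_without_usable_wells_flagged_missing(self):
        s, l = _screen_frames(self.NEG, [("C1", np.nan)])
        hits = call_hits(s, l, "n_cells")
        assert hits.n_replicates.iloc[0] == 0
        assert np.isnan(hits.z_score.iloc[0]) and not hits.is_hit.iloc[0]

    def test_excluded_wells_never_enter_statistics(self):
        s, l = _screen_frames(self.NEG, [("C1", 100.0), ("C2", 1e6)])
        l.loc[l.compound_id == "C2", "excluded"] = True
        hits = call_hits(s, l, "n_cells")
        assert list(hits.compound_id) == ["C1"]

    def test_invariant_to_plate_ordering(self):
        rng = np.random.default_rng(1)
        neg = list(rng.normal(100, 10, 24))
        comps = [(f"C{i}", float(v)) for i, v in enumerate(rng.normal(100, 30, 10))]
        s, l = _screen_frames(neg, comps)
        perm = rng.permutation(len(s))
        h1 = call_hits(s, l, "n_cells").sort_values("compound_id").reset_index(drop=True)
        h2 = (
            call_hits(s.iloc[perm].reset_index(drop=True), l, "n_cells")
            .sort_values("compound_id")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(h1, h2)

    def test_unknown_endpoint_rejected(self):
        s, l = _screen_frames(self.NEG, [("C1", 100.0)])
        with pytest.raises(InputError):
            call_hits(s, l, "pct_dead")


class TestFpFnRates:
    def _frames(self, neg, pos):
        rows, lay = [], []
        for i, v in enumerate(neg):
            rows.append(("P1", f"A{i:03d}", v, 0.0, 0.0))
            lay.append(("P1", f"A{i:03d}", "negative_control", "", np.nan, 24, False))
        for i, v in enumerate(pos):
            rows.append(("P1", f"B{i:03d}", v, 0.0, 0.0))
            lay.append(("P1", f"B{i:03d}", "positive_control", "", np.nan, 24, False))
        s = pd.DataFrame(rows, columns=["plate_id", "well_id", "n_cells", "pct_abnormal", "pct_mitotic"])
        l = pd.DataFrame(
            lay,
            columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"],
        )
        return s, l

    def test_tight_negatives_give_zero_fp(self):
        s, l = self._frames([99.0, 101.0] * 10, [30.0] * 5)
        fp, fn = fp_fn_rates(s, l, "n_cells")
        assert fp == 0.0

    def test_fp_counts_match_construction(self):
        # 62 negatives, 2 pushed beyond |Z| > 2 of the given control stats
        neg = [90.0, 110.0] * 30 + [200.0, 0.0]
        s, l = self._frames(neg, [30.0] * 5)
        fp, _ = fp_fn_rates(s, l, "n_cells", neg=stats(100, 10))
        assert fp == pytest.approx(2 / 62)

    def test_strong_positives_give_zero_fn(self):
        # all positives at Z <= -6.5 of the negative controls
        neg = [90.0, 110.0] * 31
        s, l = self._frames(neg, [30.0] * 20)
        fp, fn = fp_fn_rates(s, l, "n_cells", neg=stats(100, 10))
        assert fn == 0.0

    def test_fp_is_strict_fn_is_strict(self):
        # one negative at exactly |Z| = 2 -> not a false positive;
        # one positive at exactly |Z| = 2 -> not a false negative
        neg = [100.0] * 10 + [80.0]
        pos = [80.0]
        s, l = self._frames(neg, pos)
        fp, fn = fp_fn_rates(s, l, "n_cells", neg=stats(100, 10))
        assert fp == 0.0 and fn == 0.0

    def test_missing_role_rejected(self):
        s, l = self._frames([99.0, 101.0], [])
        with pytest.raises(InsufficientDataError):
            fp_fn_rates(s, l, "n_cells")


class TestPercentOfControl:
    def test_examples(self):
        assert percent_of_control([100.0], 100.0) == [100.0]
        assert percent_of_control([54.6], 100.0) == [pytest.approx(54.6)]
        assert percent_of_control([0.0], 100.0) == [0.0]

    def test_zero_control_mean_rejected(self):
        with pytest.raises(InputError):
            percent_of_control([1.0], 0.0)


class TestDoseResponse:
    def _frames(self, doses_means, n_rep=2):
        rows, lay = [], []
        for i in range(4):
            rows.append(("P1", f"N{i:02d}", 100.0, 0.0, 0.0))
            lay.append(("P1", f"N{i:02d}", "negative_control", "", np.nan, 24, False))
        w = 0
        for dose, mean in doses_means:
            for r in range(n_rep):
                rows.append(("P1", f"C{w:02d}", mean + (r - 0.5), 0.0, 0.0))
                lay.append(("P1", f"C{w:02d}", "compound", "CMP", dose, 24, False))
                w += 1
        s = pd.DataFrame(rows, columns=["plate_id", "well_id", "n_cells", "pct_abnormal", "pct_mitotic"])
        l = pd.DataFrame(
            lay,
            columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"],
        )
        return s, l

    def test_single_dose_has_undefined_trend(self):
        s, l = self._frames([(1.0, 80.0)])
        table = dose_response_table(s, l, "CMP", "n_cells")
        assert len(table) == 1 and table.trend.iloc[0] is None

    def test_decreasing_doses_flagged(self):
        s, l = self._frames([(1.0, 90.0), (2.0, 50.0), (4.0, 10.0)])
        table = dose_response_table(s, l, "CMP", "n_cells")
        assert list(table.dose_uM) == [1.0, 2.0, 4.0]
        assert (table.trend == "decreasing").all()
        assert table.pct_of_control.iloc[0] == pytest.approx(90.0)

    def test_constant_means_have_no_trend(self):
        s, l = self._frames([(1.0, 50.0), (2.0, 50.0), (4.0, 50.0)])
        table = dose_response_table(s, l, "CMP", "n_cells")
        assert (table.trend == "none").all()

    def test_unknown_compound_rejected(self):
        s, l = self._frames([(1.0, 80.0)])
        with pytest.raises(InputError):
            dose_response_table(s, l, "NOPE", "n_cells")


def test_qc_report_round_trips_the_formulas():
    rng = np.random.default_rng(2)
    neg = rng.normal(100, 5, 16)
    pos = rng.normal(40, 8, 16)
    rows, lay = [], []
    for i, v in enumerate(neg):
        rows.append(("P1", f"A{i:02d}", v, 3.0, 3.0))
        lay.append(("P1", f"A{i:02d}", "negative_control", "", np.nan, 24, False))
    for i, v in enumerate(pos):
        rows.append(("P1", f"B{i:02d}", v, 30.0, 8.0))
        lay.append(("P1", f"B{i:02d}", "positive_control", "", np.nan, 24, False))
    s = pd.DataFrame(rows, columns=["plate_id", "well_id", "n_cells", "pct_abnormal", "pct_mitotic"])
    l = pd.DataFrame(
        lay, columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"]
    )
    report = qc_report(s, l, endpoints=("n_cells",))
    row = report.iloc[0]
    expected = zprime(control_stats(pos), control_stats(neg))
    assert row.zprime == pytest.approx(expected)
    assert row.neg_mean == pytest.approx(neg.mean())


def test_cross_timepoint_intersection_column():
    hits = pd.DataFrame(
        {
            "compound_id": ["C1", "C1", "C2", "C2"],
            "endpoint": ["n_cells"] * 4,
            "timepoint_h": [24, 48, 24, 48],
            "n_replicates": [4] * 4,
            "aggregated_value": [50.0] * 4,
            "z_score": [-8, -7, -8, 0],
            "is_hit": [True, True, True, False],
        }
    )
    out = cross_timepoint_hits(hits)
    assert out[out.compound_id == "C1"].hit_all_timepoints.all()
    assert not out[out.compound_id == "C2"].hit_all_timepoints.any()
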