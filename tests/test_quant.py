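"""PSM weights, weighted median, filters, roll-ups and WM normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plexquant import (
    WMConfig,
    aggregate_sum,
    base_peak_ratio_filter,
    compute_pif,
    pif_filter,
    psm_weight,
    reference_intensity,
    weighted_median,
    wm_normalize,
)
from conftest import make_design, make_table


def wm_oracle(values, weights):
    """Any minimizer of sum(w * |v - m|); used to validate the weighted median."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    candidates = np.unique(values)
    costs = np.array([(weights * np.abs(values - m)).sum() for m in candidates])
    return candidates[np.isclose(costs, costs.min(), rtol=1e-12)]


class TestPsmWeight:
    @pytest.mark.parametrize(
        "prec,fill,exp,expected",
        [
            (1e6, 10.0, 1.0, 1e7),
            (123.0, 45.0, 0.0, 1.0),
            (4.0, 9.0, 0.5, 6.0),
            (np.nan, 9.0, 1.0, 9.0),  # missing factor treated as 1
            (4.0, np.nan, 1.0, 4.0),
            (np.nan, np.nan, 1.0, 1.0),
        ],
    )
    def test_examples(self, prec, fill, exp, expected):
        assert psm_weight(prec, fill, exp) == pytest.approx(expected)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            psm_weight(1.0, 1.0, -0.5)


class TestWeightedMedian:
    @pytest.mark.parametrize(
        "values,weights,expected",
        [
            ([7.0], [3.0], 7.0),
            ([1, 2, 3], [1, 1, 1], 2.0),
            ([1, 2, 10], [1, 1, 3], 10.0),  # cum weights 1,2,5 vs half-total 2.5
            ([1, 3], [1, 1], 2.0),  # exact half -> midpoint
            ([3, 1, 2], [1, 1, 1], 2.0),  # order-independent
            ([1, 2, 3, 4], [1, 1, 1, 1], 2.5),  # even-count convention
        ],
    )
    def test_examples(self, values, weights, expected):
        assert weighted_median(values, weights) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_median([], [])
        with pytest.raises(ValueError):
            weighted_median([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            weighted_median([1.0], [-1.0])

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=12),
        st.data(),
    )
    def test_minimizes_weighted_absolute_deviation(self, values, data):
        weights = data.draw(
            st.lists(
                st.floats(min_value=0.01, max_value=10),
                min_size=len(values),
                max_size=len(values),
            )
        )
        m = weighted_median(values, weights)
        minimizers = wm_oracle(values, weights)
        # the tie rule may return the midpoint of two adjacent minimizers
        assert (
            np.any(np.isclose(m, minimizers))
            or (len(minimizers) >= 2 and np.min(minimizers) <= m <= np.max(minimizers))
        )
        assert min(values) <= m <= max(values)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=15))
    def test_equal_weights_reproduce_ordinary_median(self, values):
        assert weighted_median(values, np.ones(len(values))) == pytest.approx(
            float(np.median(values)), abs=1e-12
        )

    def test_dominant_weight_pins_result(self):
        assert weighted_median([1.0, 2.0, 9.0], [1.0, 1.0, 1e9]) == 9.0


class TestPif:
    @pytest.mark.parametrize(
        "prec,window,expected",
        [([90], [90, 10], 0.9), ([50, 30], [50, 30, 20], 0.8), ([10, 5], [10, 5], 1.0)],
    )
    def test_compute_pif(self, prec, window, expected):
        assert compute_pif(prec, window) == pytest.approx(expected)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_pif([], [])

    def test_pif_filter_counts(self, duo):
        t = make_table(duo, [("g", "p", [1, 1])] * 3, pif=[0.5, 0.8, 1.0])
        assert len(pif_filter(t, 0.75)) == 2
        assert len(pif_filter(t, 0.0)) == 3

    def test_missing_pif_kept_only_at_zero_threshold(self, duo):
        t = make_table(duo, [("g", "p", [1, 1])] * 2, pif=[np.nan, 0.9])
        assert len(pif_filter(t, 0.0)) == 2
        assert len(pif_filter(t, 0.5)) == 1

    def test_base_peak_ratio_filter(self, duo):
        t = make_table(duo, [("g", "p", [1, 1])] * 3, base_peak_ratio=[0.1, 0.5, np.nan])
        assert len(base_peak_ratio_filter(t, 0.3)) == 1
        assert len(base_peak_ratio_filter(t, 0.0)) == 3

    def test_filters_compose_as_intersection(self, duo):
        t = make_table(
            duo,
            [("g", "p", [1, 1])] * 4,
            pif=[0.9, 0.9, 0.2, 0.2],
            base_peak_ratio=[0.9, 0.2, 0.9, 0.2],
        )
        both = base_peak_ratio_filter(pif_filter(t, 0.5), 0.5)
        assert len(both) == 1 and both.meta["psm_id"].iloc[0] == "p0"


class TestReferenceIntensity:
    def test_reference_mode_sums_reference_channels(self, quad):
        design = make_design(quad, ["sample", "reference", "reference", "carrier"])
        t = make_table(quad, [("g", "plex1", [10.0, 100.0, 140.0, 9999.0])])
        assert reference_intensity(t, design, "reference")[0] == 240.0

    def test_all_sample_sum_excludes_carrier_and_empty(self, quad):
        design = make_design(quad, ["sample", "sample", "carrier", "empty"])
        t = make_table(quad, [("g", "plex1", [10.0, 20.0, 500.0, 30.0])])
        assert reference_intensity(t, design, "all_sample_sum")[0] == 30.0

    def test_reference_mode_without_reference_channel_is_config_error(self, quad):
        design = make_design(quad, ["sample", "sample", "sample", "sample"])
        cfg = WMConfig(mode="reference")
        with pytest.raises(ValueError):
            cfg.validate_against(design)


class TestAggregateSum:
    def test_sums_psms_within_group(self, duo):
        design = make_design(duo, ["sample", "sample"])
        t = make_table(duo, [("g1", "plex1", [10, 1]), ("g1", "plex1", [30, 2])])
        qm = aggregate_sum(t, design)
        assert qm.values.loc["g1", "s0"] == 40.0
        assert qm.support.loc["g1", "s0"] == 2

    def test_fractions_with_same_experiment_are_combined(self, duo):
        design = make_design(duo, ["sample", "sample"])
        t = make_table(
            duo,
            [("g1", "plex1", [10, 1]), ("g1", "plex1", [5, 1])],
            psm_id=["f1_scan1", "f2_scan1"],
        )
        qm = aggregate_sum(t, design)
        assert list(qm.values.columns) == ["s0", "s1"]
        assert qm.values.loc["g1", "s0"] == 15.0

    def test_absent_group_is_missing_not_zero(self, duo):
        design = make_design(duo, ["sample", "sample"], plex="plex1")
        t = make_table(duo, [("g1", "plex1", [10, 1])])
        qm = aggregate_sum(t, design)
        assert "g2" not in qm.values.index


class TestWMNormalize:
    def test_single_psm_ratio(self, duo):
        design = make_design(duo, ["sample", "reference"])
        t = make_table(duo, [("g1", "plex1", [50.0, 100.0])])
        qm = wm_normalize(t, design, WMConfig(mode="reference"))
        assert qm.values.loc["g1", "s0"] == 0.5

    def test_exponent_zero_equals_unweighted_median(self, duo):
        design = make_design(duo, ["sample", "reference"])
        rows = [("g1", "plex1", [v, 100.0]) for v in (10.0, 20.0, 80.0)]
        t = make_table(duo, rows, precursor_intensity=[1e3, 1e6, 1e1])
        qm0 = wm_normalize(t, design, WMConfig(mode="reference", weight_exponent=0.0))
        assert qm0.values.loc["g1", "s0"] == pytest.approx(0.2)
        # with weights, the heavy PSM dominates instead
        qm1 = wm_normalize(t, design, WMConfig(mode="reference", weight_exponent=1.0))
        assert qm1.values.loc["g1", "s0"] == pytest.approx(0.2)

    def test_zero_sample_or_reference_psms_skipped(self, duo):
        design = make_design(duo, ["sample", "reference"])
        t = make_table(
            duo,
            [("g1", "plex1", [0.0, 100.0]), ("g1", "plex1", [50.0, 0.0]),
             ("g1", "plex1", [30.0, 100.0])],
        )
        qm = wm_normalize(t, design, WMConfig(mode="reference"))
        assert qm.values.loc["g1", "s0"] == 0.3
        assert qm.support.loc["g1", "s0"] == 1

    def test_min_psms_gates_cells(self, duo):
        design = make_design(duo, ["sample", "reference"])
        t = make_table(duo, [("g1", "plex1", [50.0, 100.0])])
        qm = wm_normalize(t, design, WMConfig(mode="reference", min_psms=2))
        assert qm.values.empty or np.isnan(qm.values.loc["g1", "s0"])

    def test_plex_scale_invariance(self, duo):
        """Multiplying all intensities of a plex by c leaves WM output unchanged."""
        design = make_design(duo, ["sample", "reference"])
        rows = [("g1", "plex1", [50.0, 100.0]), ("g1", "plex1", [60.0, 90.0])]
        t = make_table(duo, rows)
        t_scaled = make_table(duo, [(g, p, [v * 7.5 for v in vals]) for g, p, vals in rows])
        for mode in ("reference", "all_sample_sum"):
            a = wm_normalize(t, design, WMConfig(mode=mode)).values
            b = wm_normalize(t_scaled, design, WMConfig(mode=mode)).values
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_psm_row_order_is_irrelevant(self, quad):
        design = make_design(quad, ["sample", "sample", "sample", "reference"])
        rng = np.random.default_rng(4)
        rows = [
            (f"g{rng.integers(3)}", "plex1", list(rng.uniform(1, 100, 4))) for _ in range(30)
        ]
        t = make_table(quad, rows)
        perm = rng.permutation(len(rows))
        t_perm = make_table(quad, [rows[i] for i in perm])
        a = wm_normalize(t, design, WMConfig(mode="all_sample_sum")).values
        b = wm_normalize(t_perm, design, WMConfig(mode="all_sample_sum")).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_filter_then_normalize_equals_normalize_of_survivors(self, duo):
        design = make_design(duo, ["sample", "reference"])
        rows = [("g1", "plex1", [50.0, 100.0]), ("g1", "plex1", [80.0, 100.0])]
        t = make_table(duo, rows, pif=[0.9, 0.3])
        via_cfg = wm_normalize(t, design, WMConfig(mode="reference", pif_threshold=0.5))
        via_filter = wm_normalize(pif_filter(t, 0.5), design, WMConfig(mode="reference"))
        np.testing.assert_allclose(
            via_cfg.values.to_numpy(), via_filter.values.to_numpy(), rtol=1e-12
        )
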