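"""Elongation-ratio statistics: profiles, curves, field aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rbcflow as rf
from rbcflow.errors import (
    ConventionViolationError,
    EmptyInputError,
    InvalidMeasurementError,
    InvariantViolationError,
)

er_lists = st.lists(
    st.floats(min_value=1.0, max_value=8.0, allow_nan=False), min_size=1, max_size=60
)


class TestElongationRatio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(5.0, 5.0, 1.0), (13.0, 5.0, 2.6), (3.0, 2.0, 1.5)],
    )
    def test_ratio(self, a, b, expected):
        assert rf.elongation_ratio(a, b) == pytest.approx(expected)

    def test_equal_axes_exactly_one(self):
        # a round, undeformed cell must give exactly 1.0, no rounding
        assert rf.elongation_ratio(7.3, 7.3) == 1.0

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            rf.elongation_ratio(5.0, 0.0)
        with pytest.raises(InvalidMeasurementError):
            rf.elongation_ratio(-2.0, 1.0)

    def test_unsorted_axes_rejected(self):
        with pytest.raises(ConventionViolationError):
            rf.elongation_ratio(2.0, 5.0)


def naive_profile(values, scheme=None):
    """Loop-and-count oracle, independent of the numpy implementation."""
    scheme = scheme or rf.ThresholdScheme()
    u = l = m = h = 0
    for v in values:
        if v < scheme.udfc_upper:
            u += 1
        elif v < scheme.ldfc_upper:
            l += 1
        elif v < scheme.hdfc_lower:
            m += 1
        else:
            h += 1
    n = len(values)
    srt = sorted(values)
    mer = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
    return {
        "mer": mer,
        "aer": sum(values) / n,
        "pct_udfc": 100 * u / n,
        "pct_ldfc": 100 * l / n,
        "pct_mid": 100 * m / n,
        "pct_hdfc": 100 * h / n,
    }


class TestComputeProfile:
    def test_degenerate_rigid_population(self):
        p = rf.compute_profile(rf.ERSample([1.0, 1.0, 1.0, 1.0]))
        assert (p.mer, p.aer) == (1.0, 1.0)
        assert p.pct_udfc == 100.0
        assert p.pct_ldfc == p.pct_mid == p.pct_hdfc == 0.0

    def test_one_cell_per_band(self):
        p = rf.compute_profile(rf.ERSample([1.05, 1.2, 1.5, 2.6]))
        assert p.pct_udfc == p.pct_ldfc == p.pct_mid == p.pct_hdfc == 25.0
        assert p.mer == pytest.approx(1.35)  # midpoint of 1.2 and 1.5

    def test_matches_naive_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(1, 500))
            values = 1.0 + rng.gamma(1.5, 0.5, n)
            p = rf.compute_profile(rf.ERSample(values))
            o = naive_profile(list(values))
            assert p.mer == o["mer"]
            for k in ("pct_udfc", "pct_ldfc", "pct_mid", "pct_hdfc"):
                assert getattr(p, k) == o[k]
            assert p.aer == pytest.approx(o["aer"], rel=1e-12)

    def test_recovers_generator_median(self, crbc_model):
        sample = rf.simulate_er_population(crbc_model, 10_000, seed=5)
        p = rf.compute_profile(sample)
        assert p.mer == pytest.approx(rf.model_quantile(crbc_model, 0.5), abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            rf.compute_profile(rf.ERSample([]))

    def test_sub_unity_values_rejected(self):
        with pytest.raises(InvariantViolationError):
            rf.compute_profile(rf.ERSample([1.2, 0.9]))

    @given(er_lists)
    @settings(max_examples=60, deadline=None)
    def test_partition_sums_to_100(self, values):
        p = rf.compute_profile(rf.ERSample(values))
        total = p.pct_udfc + p.pct_ldfc + p.pct_mid + p.pct_hdfc
        assert total == pytest.approx(100.0, abs=1e-9)

    @given(er_lists)
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, values):
        p1 = rf.compute_profile(rf.ERSample(values))
        p2 = rf.compute_profile(rf.ERSample(values[::-1]))
        assert (p1.mer, p1.pct_udfc, p1.pct_hdfc) == (
            p2.mer, p2.pct_udfc, p2.pct_hdfc)
        # mean is permutation-invariant up to summation order
        assert p1.aer == pytest.approx(p2.aer, rel=1e-12)

    @given(er_lists, st.floats(min_value=2.5, max_value=8.0))
    @settings(max_examples=40, deadline=None)
    def test_adding_hdfc_cell_never_decreases_pct_hdfc(self, values, extra):
        before = rf.compute_profile(rf.ERSample(values)).pct_hdfc
        after = rf.compute_profile(rf.ERSample(values + [extra])).pct_hdfc
        assert after >= before

    @given(er_lists, st.floats(min_value=1.0, max_value=1.0999))
    @settings(max_examples=40, deadline=None)
    def test_adding_rigid_cell_never_decreases_pct_udfc(self, values, extra):
        before = rf.compute_profile(rf.ERSample(values)).pct_udfc
        after = rf.compute_profile(rf.ERSample(values + [extra])).pct_udfc
        assert after >= before


class TestBoundaryConventions:
    # values sitting exactly on the 1.1 / 1.3 / 2.5 cut-points
    def test_disjoint_bins_half_open(self):
        p = rf.compute_profile(rf.ERSample([1.1, 1.3, 2.5]))
        assert p.pct_udfc == 0.0
        assert p.pct_ldfc == pytest.approx(100 / 3)
        assert p.pct_mid == pytest.approx(100 / 3)
        assert p.pct_hdfc == pytest.approx(100 / 3)

    def test_cumulative_closed_upper_edges(self):
        scheme = rf.ThresholdScheme(boundary_convention="cumulative")
        p = rf.compute_profile(rf.ERSample([1.1, 1.3, 2.5]), scheme)
        assert p.pct_udfc == pytest.approx(100 / 3)  # 1.1 counts as undeformable
        assert p.pct_ldfc == pytest.approx(100 / 3)  # 1.3 counts as low-deformable
        assert p.pct_hdfc == pytest.approx(100 / 3)
        total = p.pct_udfc + p.pct_ldfc + p.pct_mid + p.pct_hdfc
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(InvariantViolationError):
            rf.ThresholdScheme(udfc_upper=1.3, ldfc_upper=1.1)


class TestDistributionCurve:
    def test_single_occupied_bin(self):
        c = rf.distribution_curve(rf.ERSample([1.0] * 10), bin_width=0.05)
        assert np.count_nonzero(c.density) == 1
        assert c.cumulative[-1] == pytest.approx(1.0)

    def test_uniform_sample_flat_density(self):
        rng = np.random.default_rng(1)
        c = rf.distribution_curve(rf.ERSample(rng.uniform(1, 2, 10_000)), 0.1)
        occupied = c.density[c.density > 0][:10]
        assert np.allclose(occupied, 0.1, atol=0.015)

    @given(er_lists)
    @settings(max_examples=40, deadline=None)
    def test_density_normalized_cumulative_monotone(self, values):
        c = rf.distribution_curve(rf.ERSample(values), 0.05)
        assert c.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(c.cumulative) >= -1e-12)
        assert c.cumulative[-1] == pytest.approx(1.0, abs=1e-9)

    def test_curve_median_agrees_with_profile(self, crbc_model):
        sample = rf.simulate_er_population(crbc_model, 5000, seed=9)
        mer = rf.compute_profile(sample).mer
        for bw in (0.05, 0.02):
            curve = rf.distribution_curve(sample, bw)
            assert abs(curve.median_from_curve() - mer) <= bw

    def test_rejects_empty_and_bad_binwidth(self):
        with pytest.raises(EmptyInputError):
            rf.distribution_curve(rf.ERSample([]), 0.05)
        with pytest.raises(InvalidMeasurementError):
            rf.distribution_curve(rf.ERSample([1.2]), 0.0)


def _table(ers, qc=True, field="f0"):
    n = len(ers)
    return pd.DataFrame({
        "sample_id": "s", "field_id": field, "cell_id": range(n),
        "major_um": np.asarray(ers) * 5, "minor_um": 5.0, "er": ers,
        "qc_pass": qc if np.ndim(qc) else [qc] * n,
    })


class TestAggregateFields:
    def test_concatenates_passing_cells(self):
        with pytest.warns(UserWarning):
            s = rf.aggregate_fields([_table([1.2]), _table([1.4], field="f1")])
        assert sorted(s.values) == [1.2, 1.4]
        assert s.n_fields == 2

    def test_qc_failed_cells_excluded(self):
        with pytest.warns(UserWarning):
            s = rf.aggregate_fields([_table([1.2, 3.0], qc=[True, False])])
        assert list(s.values) == [1.2]

    def test_all_failed_raises(self):
        with pytest.raises(EmptyInputError):
            rf.aggregate_fields([_table([1.2, 1.4], qc=False)])

    def test_protocol_counts_no_warning(self, recwarn):
        tables = [_table([1.2] * 400, field=f"f{i}") for i in range(25)]
        s = rf.aggregate_fields(tables)
        assert s.n == 10_000 and s.n_fields == 25
        assert not any(isinstance(w.message, UserWarning) for w in recwarn.list)

    def test_low_count_warns_but_returns(self):
        with pytest.warns(UserWarning, match="cell count"):
            s = rf.aggregate_fields([_table([1.2] * 50, field=f"f{i}")
                                     for i in range(25)])
        assert s.n == 1250


class TestIO:
    def test_cell_table_round_trip(self, tmp_path):
        df = _table([1.1, 1.9])
        path = tmp_path / "cells.csv"
        rf.write_cell_table(df, path)
        back = rf.read_cell_table(path)
        assert list(back["er"]) == [1.1, 1.9]

    def test_profile_json_round_trip(self, tmp_path):
        p = rf.compute_profile(rf.ERSample([1.05, 1.2, 1.5, 2.6], "u1", 3))
        path = tmp_path / "p.json"
        p.to_json(path)
        back = rf.DeformabilityProfile.from_json(path)
        assert back == p
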