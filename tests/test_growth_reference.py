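"""LMS transform, inversion, unit equivalents and reference conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from anthrotrend.growth_reference import (
    GrowthDomainError, LMSRow, ReferenceLookupError, ReferenceTable,
    SummaryStatistic, convert_summary_nchs_to_who, lms_inverse, lms_zscore,
    map_summary, zscore_unit_equivalent,
)


def _row(L, M, S, age=24.0, sex="male", metric="weight"):
    return LMSRow(age=age, sex=sex, metric=metric, L=L, M=M, S=S)


class TestLMSTransform:
    @pytest.mark.parametrize("L", [-0.5, 0.0, 0.3, 1.0])
    def test_median_maps_to_zero(self, L):
        assert lms_zscore(12.9, _row(L, 12.9, 0.11)) == pytest.approx(0.0, abs=1e-12)

    def test_l_equal_one_is_linear(self):
        # L=1 reduces to (x - M) / (M * S)
        assert lms_zscore(105.0, _row(1.0, 100.0, 0.05, metric="height")) == pytest.approx(1.0)

    def test_negative_l_example(self):
        # frozen value from a direct evaluation of ((x/M)^L - 1)/(L*S)
        z = lms_zscore(15.0, _row(-0.3, 12.9, 0.11))
        assert z == pytest.approx(1.3405603997792188, abs=1e-9)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(GrowthDomainError):
            lms_zscore(0.0, _row(1.0, 100.0, 0.05))
        with pytest.raises(GrowthDomainError):
            lms_zscore(-3.0, _row(0.0, 100.0, 0.05))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        L=st.floats(-1.5, 2.0), M=st.floats(1.0, 120.0), S=st.floats(0.02, 0.2),
        x1=st.floats(0.5, 150.0), x2=st.floats(0.5, 150.0),
    )
    def test_strictly_increasing_in_measurement(self, L, M, S, x1, x2):
        if x1 == x2:
            return
        row = _row(L, M, S)
        lo, hi = sorted((x1, x2))
        assert lms_zscore(lo, row) < lms_zscore(hi, row)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            row = _row(rng.uniform(-1.0, 1.5), rng.uniform(3, 110), rng.uniform(0.03, 0.15))
            z = rng.uniform(-3.5, 3.5)
            try:
                x = lms_inverse(z, row)
            except GrowthDomainError:
                continue
            assert lms_zscore(x, row) == pytest.approx(z, abs=1e-10)

    def test_inverse_of_zero_is_median(self):
        assert lms_inverse(0.0, _row(0.7, 17.3, 0.12)) == pytest.approx(17.3)

    def test_inverse_linear_case(self):
        assert lms_inverse(-2.0, _row(1.0, 100.0, 0.05)) == pytest.approx(90.0)

    def test_inverse_outside_domain(self):
        with pytest.raises(GrowthDomainError):
            lms_inverse(-25.0, _row(1.0, 100.0, 0.05))


class TestReferenceTable:
    def test_lookup_interpolates_between_grid_points(self, who_table):
        lo = who_table.lookup(24, "male", "height")
        hi = who_table.lookup(30, "male", "height")
        mid = who_table.lookup(27, "male", "height")
        assert mid.M == pytest.approx((lo.M + hi.M) / 2)
        assert mid.S == pytest.approx((lo.S + hi.S) / 2)

    def test_lookup_off_grid_age_fails(self, who_table):
        with pytest.raises(ReferenceLookupError):
            who_table.lookup(70, "male", "height")

    def test_unit_equivalent_requires_grid_age(self, who_table):
        with pytest.raises(ReferenceLookupError):
            zscore_unit_equivalent(25, "height", who_table)

    def test_unit_equivalent_positive_and_growing_with_age(self, who_table):
        vals = [zscore_unit_equivalent(a, "height", who_table) for a in (24, 36, 48, 60)]
        assert all(v > 0 for v in vals)
        assert vals == sorted(vals)

    def test_unit_equivalent_closed_form_under_unit_l(self, who_table):
        # L = 1 for the height table, so one Z equals M*S averaged over sexes
        rows = [who_table.lookup(24, sex, "height") for sex in ("male", "female")]
        expect = np.mean([r.M * r.S for r in rows])
        assert zscore_unit_equivalent(24, "height", who_table) == pytest.approx(expect)


class TestReferenceConversion:
    def test_identity_tables_change_nothing(self, who_table):
        s = SummaryStatistic(mean_z=-1.2, sd_z=1.1, prev_below=0.25, reference="NCHS1977")
        out, cv = convert_summary_nchs_to_who(s, (12, 48), who_table, who_table, "height")
        assert out.reference == "WHO2006"
        assert out.mean_z == pytest.approx(-1.2, abs=1e-9)
        assert out.sd_z == pytest.approx(1.1, abs=1e-6)
        assert cv == pytest.approx(0.0, abs=1e-16)

    def test_requires_nchs_input(self, who_table, nchs_table):
        s = SummaryStatistic(mean_z=-1.0, sd_z=1.0, reference="WHO2006")
        with pytest.raises(ValueError):
            convert_summary_nchs_to_who(s, (12, 48), who_table, nchs_table)

    @pytest.mark.parametrize("metric,mean,sd", [("height", -1.5, 1.1), ("weight", -0.8, 1.2)])
    def test_matches_monte_carlo_oracle(self, who_table, nchs_table, metric, mean, sd):
        """Quantile mapping agrees with sampling a normal NCHS-space population."""
        age_range = (12, 48)
        got_mean, got_sd, got_prev = map_summary(mean, sd, nchs_table, who_table,
                                                 age_range, metric)
        rng = np.random.default_rng(12345)
        n = 10 ** 6
        grid = who_table.grid("male", metric)
        ages = grid[(grid >= age_range[0]) & (grid <= age_range[1])]
        cells = [(a, s) for a in ages for s in ("male", "female")]
        per = n // len(cells)
        zs = []
        for age, sex in cells:
            src = nchs_table.lookup(age, sex, metric)
            tgt = who_table.lookup(age, sex, metric)
            z_n = rng.normal(mean, sd, per)
            if src.L != 0:
                x = src.M * np.clip(1 + src.L * src.S * z_n, 1e-12, None) ** (1 / src.L)
            else:
                x = src.M * np.exp(src.S * z_n)
            if tgt.L != 0:
                zs.append(((x / tgt.M) ** tgt.L - 1) / (tgt.L * tgt.S))
            else:
                zs.append(np.log(x / tgt.M) / tgt.S)
        zs = np.concatenate(zs)
        assert got_mean == pytest.approx(zs.mean(), abs=0.005)
        assert got_sd == pytest.approx(zs.std(), abs=0.005)
        assert got_prev == pytest.approx(np.mean(zs < -2.0), abs=0.005)

    def test_conversion_variance_nonnegative(self, who_table, nchs_table):
        s = SummaryStatistic(mean_z=-1.4, sd_z=1.15, reference="NCHS1977")
        _, cv = convert_summary_nchs_to_who(s, (0, 60), who_table, nchs_table, "height")
        assert cv >= 0.0

    def test_missing_coverage_rejected(self, who_table, nchs_table):
        s = SummaryStatistic(mean_z=-1.0, sd_z=1.0, reference="NCHS1977")
        with pytest.raises(ReferenceLookupError):
            convert_summary_nchs_to_who(s, (0, 80), who_table, nchs_table, "height")
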