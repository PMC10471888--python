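import numpy as np
import pandas as pd
import pytest

from mtspike.copy_number import (PERFECT_EFFICIENCY_SLOPE, CurveQCBounds,
                                 StandardCurve, apply_ct_exclusions,
                                 ct_from_copies, fit_standard_curve,
                                 normalize_plate, quantify)

DILUTION_COPIES = 10.0 ** np.arange(6, 0, -1)  # six 10-fold dilutions


def perfect_curve_cts(intercept=38.0):
    return intercept + PERFECT_EFFICIENCY_SLOPE * np.log10(DILUTION_COPIES)


class TestStandardCurve:
    def test_perfect_efficiency_line(self):
        curve = fit_standard_curve(DILUTION_COPIES, perfect_curve_cts())
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.slope == pytest.approx(PERFECT_EFFICIENCY_SLOPE,
                                            abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_fails_qc(self):
        curve = fit_standard_curve(DILUTION_COPIES, np.full(6, 25.0))
        assert not curve.qc_pass and "slope" in curve.qc_reason

    def test_noisy_curve_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        x = np.log10(DILUTION_COPIES)
        cts = 37.0 - 3.35 * x + rng.normal(0, 0.05, x.size)
        curve = fit_standard_curve(DILUTION_COPIES, cts)
        # normal equations computed independently
        xm, ym = x.mean(), cts.mean()
        slope = np.sum((x - xm) * (cts - ym)) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_bounds_from_assay_validation(self):
        curve = fit_standard_curve(
            DILUTION_COPIES, 37.0 - 3.35 * np.log10(DILUTION_COPIES))
        assert curve.qc_pass
        tight = CurveQCBounds(slope_min=-3.30, slope_max=-3.26)
        assert not fit_standard_curve(DILUTION_COPIES,
                                      37.0 - 3.35 * np.log10(DILUTION_COPIES),
                                      qc=tight).qc_pass

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_standard_curve([10, 100], [30, 27])


class TestQuantify:
    CURVE = StandardCurve(slope=-3.32, intercept=38.0, r_squared=1.0)

    def test_intercept_is_one_copy(self):
        cpc = quantify(38.0, self.CURVE, n_cells=1, volume_factor=1.0)
        assert cpc == pytest.approx(1.0, rel=1e-12)

    def test_one_log10_step_is_ten_copies(self):
        cpc = quantify(38.0 + self.CURVE.slope, self.CURVE, n_cells=1,
                       volume_factor=1.0)
        assert cpc == pytest.approx(10.0, rel=1e-12)

    def test_round_trip_identity(self):
        for copies in (1.0, 57.3, 1e4):
            ct = ct_from_copies(copies, self.CURVE)
            back = quantify(ct, self.CURVE, n_cells=1, volume_factor=1.0)
            assert back == pytest.approx(copies, rel=1e-9)

    def test_volume_and_cells_divide_out(self):
        # 91 cells, 1/25 of the lysate in the reaction
        ct = ct_from_copies(91 * 300 / 25.0, self.CURVE)
        cpc = quantify(ct, self.CURVE, n_cells=91, volume_factor=1 / 25)
        assert cpc == pytest.approx(300.0, rel=1e-9)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            quantify(30.0, self.CURVE, n_cells=0)


class TestNormalizePlate:
    def test_identity_when_sample_equals_control(self):
        assert normalize_plate(123.4, 123.4, 500.0) == pytest.approx(500.0)

    def test_direct_arithmetic(self):
        assert normalize_plate(200.0, 100.0, 150.0) == pytest.approx(300.0)

    def test_scale_equivariance(self):
        base = normalize_plate(200.0, 100.0, 150.0)
        assert normalize_plate(200.0 * 7, 100.0 * 7, 150.0) == \
            pytest.approx(base)

    def test_planted_plate_effect_removed(self):
        # plates differ by a multiplicative offset; normalising by the
        # on-plate control recovers equal means
        rng = np.random.default_rng(1)
        true_cpc = 250.0
        means = []
        for offset in (0.5, 1.0, 2.0):
            absolute = true_cpc * offset * rng.normal(1, 0.01, 30)
            control = true_cpc * offset
            means.append(np.mean([normalize_plate(a, control, true_cpc)
                                  for a in absolute]))
        assert np.ptp(means) / true_cpc < 0.02

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_plate(100.0, 0.0, 100.0)


class TestCtExclusions:
    def hand_fixture(self):
        # expected flags hand-derived from the declared rules
        return pd.DataFrame([
            # sample,        ct1,  ct2,  ct3,  expect_excluded
            ("tight",        25.0, 25.1, 25.2, False),  # sd ~0.1
            ("late",         31.0, 31.0, 31.0, True),   # mean 31 > 30
            ("outlier_ok",   25.0, 25.1, 27.5, False),  # drop 27.5, sd<0.3
            ("wide",         25.0, 25.6, 26.2, True),   # sd 0.6, no outlier
            ("under_sd",     25.0, 25.25, 25.5, False),  # sd 0.25 <= 0.3
            ("boundary_ct",  30.0, 30.0, 30.0, False),  # mean 30, not > 30
            ("missing_two",  25.0, None, None, True),   # <2 usable
            ("missing_one",  25.0, 25.1, None, False),  # pair, sd ~0.07
            ("outlier_late", 31.0, 31.1, 35.0, True),   # drop 35, mean>30
            ("clean",        22.2, 22.3, 22.25, False),
        ], columns=["sample", "ct1", "ct2", "ct3", "expect"])

    def test_hand_computed_flags(self):
        df = self.hand_fixture()
        out = apply_ct_exclusions(df)
        assert list(out.excluded) == list(df.expect)

    def test_outlier_replicate_dropped_before_stats(self):
        out = apply_ct_exclusions(pd.DataFrame(
            [("s", 25.0, 25.1, 27.5)], columns=["sample", "ct1", "ct2", "ct3"]))
        row = out.iloc[0]
        assert row.dropped_replicate == 2
        assert row.n_replicates_used == 2
        assert row.mean_ct == pytest.approx(25.05)
        assert not row.excluded

    def test_idempotent_and_order_independent(self):
        df = self.hand_fixture()
        once = apply_ct_exclusions(df)
        twice = apply_ct_exclusions(once[df.columns])
        assert list(once.excluded) == list(twice.excluded)
        shuffled = df.sample(frac=1, random_state=0)
        out = apply_ct_exclusions(shuffled)
        assert dict(zip(out["sample"], out.excluded)) == \
            dict(zip(once["sample"], once.excluded))


def test_roundtrip_planted_plate():
    """Noise-free synthetic plate: planted copies per cell recovered
    exactly through curve fit + quantification."""
    rng = np.random.default_rng(2)
    curve_true = StandardCurve(slope=-3.40, intercept=37.5, r_squared=1.0)
    cts_std = curve_true.intercept + curve_true.slope * np.log10(
        DILUTION_COPIES)
    curve = fit_standard_curve(DILUTION_COPIES, cts_std)
    planted = rng.uniform(50, 800, size=10)
    n_cells = rng.integers(50, 500, size=10)
    vf = 1 / 25
    for cpc, nc in zip(planted, n_cells):
        ct = ct_from_copies(cpc * nc * vf, curve)
        assert quantify(ct, curve, int(nc), vf) == pytest.approx(
            cpc, rel=1e-9)
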