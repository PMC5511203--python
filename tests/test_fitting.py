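"""Region segmentation and power-law fitting: the heart of the method."""

import math

import numpy as np
import pytest
from scipy import stats

from rentian import (
    EnsembleCharacteristic,
    RentCharacteristic,
    RentPoint,
    dispersion_profile,
    fit_rent,
    fit_sensitivity,
    segment_regions,
    synthetic_characteristic,
)


def char_from_pairs(pairs, source="box_covering"):
    return RentCharacteristic(
        points=[RentPoint(b=i + 1, B=float(B), P=float(P)) for i, (B, P) in enumerate(pairs)],
        source=source,
    )


class TestDispersion:
    def test_identical_replicates_have_zero_cv(self):
        char = synthetic_characteristic(0.7, 2.0, [2, 4, 8, 16])
        c = dispersion_profile([char, char, char])
        assert set(c) == {1, 2, 3, 4}
        assert all(v == 0 for v in c.values())

    def test_two_replicate_hand_computation(self):
        # P = 10 and 100 at one scale: sd(1, 2) / mean(1, 2) = 0.7071/1.5
        a = char_from_pairs([(2, 10.0)])
        b = char_from_pairs([(2, 100.0)])
        c = dispersion_profile([a, b])
        assert c[1] == pytest.approx(math.sqrt(0.5) / 1.5, abs=1e-4)  # 0.4714

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="two replicates"):
            dispersion_profile([char_from_pairs([(2, 10.0)])])

    def test_nonpositive_mean_log_flagged_and_skipped(self, caplog):
        a = char_from_pairs([(2, 0.5)])
        b = char_from_pairs([(2, 0.9)])
        with caplog.at_level("WARNING"):
            c = dispersion_profile([a, b])
        assert c == {}
        assert any("undefined" in r.message for r in caplog.records)

    def test_plain_cv_flag(self):
        a = char_from_pairs([(2, 10.0)])
        b = char_from_pairs([(2, 100.0)])
        c = dispersion_profile([a, b], log=False)
        expected = np.std([10, 100], ddof=1) / 55.0
        assert c[1] == pytest.approx(expected)


class TestSegmentation:
    def test_no_crossing_means_no_region_II(self):
        emp = synthetic_characteristic(0.8, 1.5, [2, 4, 8, 16, 32])
        c = {b: 0.01 for b in range(1, 6)}
        seg = segment_regions(emp, c, beta=0.1)
        assert seg.region_II == ()
        assert set(seg.region_I) == {1, 2, 3, 4, 5}

    def test_region_II_upward_closed_from_first_crossing(self):
        emp = synthetic_characteristic(0.8, 1.5, [2, 4, 8, 16, 32, 64, 128])
        c = {1: 0.0, 2: 0.01, 3: 0.02, 4: 0.0, 5: 0.15, 6: 0.05, 7: 0.3}  # dip at b=6
        seg = segment_regions(emp, c, beta=0.1)
        assert seg.region_II == (5, 6, 7)  # the dip does not reopen Region I
        assert seg.region_I == (1, 2, 3, 4)

    def test_exact_power_law_leaves_region_III_empty(self):
        emp = synthetic_characteristic(0.75, 2.0, [2, 4, 8, 16, 32, 64])
        seg = segment_regions(emp, {}, trim_region_III=True)
        assert seg.region_III == ()
        assert seg.delta_trace == []

    def test_displaced_low_B_points_trimmed_to_region_III(self):
        # two smallest-B points lifted in log10 P (graded so each removal
        # helps); refitting without each must raise R^2 by more than
        # rho = 1e-3, checked against a direct refit oracle below
        B = [2, 4, 8, 16, 32, 64, 128, 256]
        logP = [math.log10(2.0) + 0.75 * math.log10(b) for b in B]
        logP[0] += 0.2
        logP[1] += 0.1
        emp = char_from_pairs(list(zip(B, [10**y for y in logP])))

        def r2(idx):
            x = [math.log10(B[i]) for i in idx]
            y = [logP[i] for i in idx]
            return stats.linregress(x, y).rvalue ** 2

        assert r2(range(1, 8)) - r2(range(8)) > 1e-3  # oracle: first removal
        assert r2(range(2, 8)) - r2(range(1, 8)) > 1e-3  # oracle: second removal

        seg = segment_regions(emp, {}, trim_region_III=True)
        assert seg.region_III == (1, 2)
        assert len(seg.delta_trace) == 2
        assert all(d > 1e-3 for d in seg.delta_trace)

    def test_regions_partition_usable_scales(self):
        B = [2, 4, 8, 16, 32, 64, 128]
        logP = [math.log10(1.5) + 0.7 * math.log10(b) for b in B]
        logP[0] += 0.12
        emp = char_from_pairs(list(zip(B, [10**y for y in logP])))
        c = {b: (0.2 if b >= 6 else 0.0) for b in range(1, 8)}
        seg = segment_regions(emp, c, trim_region_III=True)
        assigned = set(seg.region_I) | set(seg.region_II) | set(seg.region_III)
        assert assigned == {1, 2, 3, 4, 5, 6, 7}
        assert not (set(seg.region_I) & set(seg.region_II))
        assert not (set(seg.region_I) & set(seg.region_III))

    def test_too_few_points_left_errors_with_advice(self):
        emp = synthetic_characteristic(0.8, 1.5, [2, 4, 8, 16])
        c = {b: 0.5 for b in range(1, 5)}  # everything crosses at once
        with pytest.raises(ValueError, match="beta"):
            segment_regions(emp, c, beta=0.1)


class TestFitRent:
    def test_noiseless_recovery_exact(self):
        emp = synthetic_characteristic(0.75, 2.0, [2, 4, 8, 16, 32, 64, 128, 256])
        fit = fit_rent(emp)
        assert fit.p == pytest.approx(0.75, abs=1e-12)
        assert fit.k == pytest.approx(2.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_three_stderr(self):
        emp = synthetic_characteristic(0.8, 1.7, [2, 4, 8, 16, 32, 64, 128, 256],
                                       noise_sigma=0.05, seed=21)
        fit = fit_rent(emp)
        assert abs(fit.p - 0.8) <= 3 * fit.std_err

    def test_recovery_mae_over_100_characteristics(self):
        """|p_hat - p| averages < 0.03 for p ~ U(0.5, 0.95), sigma = 0.05."""
        rng = np.random.default_rng(100)
        errors = []
        for i in range(100):
            true_p = rng.uniform(0.5, 0.95)
            emp = synthetic_characteristic(true_p, 2.0, [2, 4, 8, 16, 32, 64, 128, 256],
                                           noise_sigma=0.05, seed=int(rng.integers(2**31)))
            errors.append(abs(fit_rent(emp).p - true_p))
        assert np.mean(errors) < 0.03

    def test_slope_invariant_to_log_base(self):
        emp = synthetic_characteristic(0.65, 3.0, [2, 4, 8, 16, 32], noise_sigma=0.03, seed=5)
        fit = fit_rent(emp)
        x = np.log([pt.B for pt in emp.points])  # natural log
        y = np.log([pt.P for pt in emp.points])
        assert stats.linregress(x, y).slope == pytest.approx(fit.p, rel=1e-12)

    def test_fewer_than_three_points_rejected(self):
        emp = synthetic_characteristic(0.8, 2.0, [2, 4])
        with pytest.raises(ValueError, match=">= 3"):
            fit_rent(emp)

    def test_restriction_to_region_I(self):
        B = [2, 4, 8, 16, 32, 64]
        logP = [math.log10(2.0) + 0.6 * math.log10(b) for b in B]
        logP[-1] -= 0.5  # region II distortion
        emp = char_from_pairs(list(zip(B, [10**y for y in logP])))
        c = {b: 0.0 for b in range(1, 6)}
        c[6] = 0.5
        seg = segment_regions(emp, c)
        fit = fit_rent(emp, seg)
        assert fit.n_points == 5
        assert fit.p == pytest.approx(0.6, abs=1e-9)


class TestFitSensitivity:
    def test_identity_when_ensemble_copies_empirical(self):
        emp = synthetic_characteristic(0.75, 2.0, [2, 4, 8, 16, 32])
        ens = EnsembleCharacteristic(model="SA", characteristics=[emp, emp])
        fit = fit_sensitivity(emp, ens)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.big_K == pytest.approx(1.0, rel=1e-9)

    def test_exact_power_transform_recovered(self):
        emp = synthetic_characteristic(0.75, 2.0, [2, 4, 8, 16, 32])
        prime = RentCharacteristic(
            points=[RentPoint(b=pt.b, B=pt.B, P=pt.P**1.2) for pt in emp.points],
            source="box_covering",
        )
        ens = EnsembleCharacteristic(model="SA", characteristics=[prime, prime])
        fit = fit_sensitivity(emp, ens)
        assert fit.alpha == pytest.approx(1.2, abs=1e-12)

    def test_noisy_alpha_within_three_stderr(self):
        rng = np.random.default_rng(7)
        emp = synthetic_characteristic(0.75, 2.0, [2, 4, 8, 16, 32, 64])
        chars = []
        for rep in range(50):
            pts = [
                RentPoint(b=pt.b, B=pt.B, P=10 ** (math.log10(3.0) + 1.1 * math.log10(pt.P)
                                                   + rng.normal(0, 0.05)))
                for pt in emp.points
            ]
            chars.append(RentCharacteristic(points=pts, source="box_covering"))
        ens = EnsembleCharacteristic(model="SA", characteristics=chars)
        fit = fit_sensitivity(emp, ens)
        assert abs(fit.alpha - 1.1) <= 3 * fit.std_err
        assert fit.big_K == pytest.approx(3.0, rel=0.2)

    def test_too_few_matched_scales_rejected(self):
        emp = synthetic_characteristic(0.75, 2.0, [2, 4])
        ens = EnsembleCharacteristic(model="SA", characteristics=[emp, emp])
        with pytest.raises(ValueError, match="matched"):
            fit_sensitivity(emp, ens)
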