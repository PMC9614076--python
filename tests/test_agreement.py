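"""Lin's CCC, Fisher-z confidence intervals, and the agreement table."""

import numpy as np
import pytest

from uwbmotion.agreement import (AlignedPair, agreement_table, align_pair,
                                 ccc, ccc_ci)


def brute_force_ccc(x, y):
    """Independent moment-by-moment evaluation of Lin's definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def pair(x, y, **kw):
    return AlignedPair(x=np.asarray(x, float), y=np.asarray(y, float), **kw)


class TestAlignPair:
    def test_identity_with_no_normalization(self):
        p = align_pair([1, 2, 3, 4], [1, 2, 3, 4], normalization="none")
        assert np.array_equal(p.x, p.y)

    def test_disjoint_missing_seconds_dropped_from_both(self):
        a = np.array([1, 2, np.nan, 4, 5, 6.0])
        b = np.array([1, 2, 3, 4, 5, np.nan])
        p = align_pair(a, b, normalization="none")
        assert p.n == 4
        assert np.array_equal(p.x, [1, 2, 4, 5])
        assert np.array_equal(p.y, [1, 2, 4, 5])

    def test_zscore_standardizes(self, rng):
        p = align_pair(rng.uniform(0, 9, 50), rng.uniform(0, 9, 50),
                       normalization="zscore")
        for v in (p.x, p.y):
            assert abs(v.mean()) < 1e-9
            assert v.std() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_joint_seconds_rejected(self):
        with pytest.raises(ValueError, match="jointly valid"):
            align_pair([1, 2, np.nan], [1, 2, 3])


class TestCCC:
    def test_perfect_agreement(self):
        assert ccc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # x=[1,2,3], y=[2,4,6]: population moments give 2*(4/3) over
        # (2/3 + 8/3 + 4) = 8/22
        assert ccc([1, 2, 3], [2, 4, 6]) == pytest.approx(8 / 22)
        assert brute_force_ccc([1, 2, 3], [2, 4, 6]) == pytest.approx(8 / 22)

    def test_perfect_reversal(self):
        assert ccc([-1, 0, 1], [1, 0, -1]) == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            x = rng.normal(2.0, 1.5, size=20)
            y = 0.5 * x + rng.normal(0, 1, size=20)
            assert ccc(x, y) == pytest.approx(brute_force_ccc(x, y), abs=1e-12)

    def test_bounded_by_pearson(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.4 * x
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc(x, y)) <= abs(r) + 1e-12

    def test_invariant_under_shared_affine_map(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.3, size=40)
        base = ccc(x, y)
        assert ccc(3 * x + 5, 3 * y + 5) == pytest.approx(base)
        # one-sided shift attenuates agreement
        assert ccc(x, y + 2.0) < base

    def test_sample_ccc_converges_to_population_value(self):
        # bivariate normal with known population CCC
        rng = np.random.default_rng(2024)
        mu_x, mu_y, sx, sy, rho = 1.0, 2.0, 1.0, 2.0, 0.8
        pop = 2 * rho * sx * sy / (sx**2 + sy**2 + (mu_x - mu_y) ** 2)
        cov = [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
        x, y = rng.multivariate_normal([mu_x, mu_y], cov, size=10_000).T
        assert ccc(x, y) == pytest.approx(pop, abs=0.02)

    def test_constant_pair_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestCCCCI:
    def test_fisher_simple_closed_form_at_zero(self):
        # rho_c ~ 0 at n=403: CI is tanh(+/- 1.96/20) ~ (-0.0975, 0.0975)
        rng = np.random.default_rng(99)
        n = 403
        x = np.concatenate([[0.0, 1.0], rng.normal(size=n - 2)])
        y = np.concatenate([[0.0, 1.0], rng.normal(size=n - 2)])
        p = pair(x, y)
        res = ccc_ci(p, method="fisher_simple")
        point = ccc(p)
        z = np.arctanh(point)
        hw = 1.959963984540054 / np.sqrt(n - 3)
        assert res.ci_low == pytest.approx(np.tanh(z - hw))
        assert res.ci_high == pytest.approx(np.tanh(z + hw))
        assert res.ci_high - res.ci_low == pytest.approx(2 * 0.0975, abs=0.002)

    def test_degenerate_single_resample_bootstrap(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, size=30)
        p = pair(x, y)
        res = ccc_ci(p, method="bootstrap", n_boot=1, seed=5)
        assert res.ci_low <= res.rho_z <= res.ci_high
        # with one resample both percentile bounds collapse onto it
        rng2 = np.random.default_rng(5)
        idx = rng2.integers(0, 30, size=30)
        rep = ccc(x[idx], y[idx])
        assert min(res.ci_low, res.ci_high) == pytest.approx(min(rep, res.rho_z))

    @pytest.mark.parametrize("method", ["fisher_simple", "lin_variance",
                                        "bootstrap"])
    def test_interval_contains_point(self, rng, method):
        x = rng.normal(size=60)
        y = 0.8 * x + rng.normal(0, 0.6, size=60)
        res = ccc_ci(pair(x, y), method=method, seed=11)
        assert res.ci_low <= res.rho_z <= res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_perfect_agreement_degenerates_with_warning(self):
        p = pair([1, 2, 3, 4, 5, 6, 7, 8], [1, 2, 3, 4, 5, 6, 7, 8])
        with pytest.warns(RuntimeWarning, match="point-mass"):
            res = ccc_ci(p)
        assert res.ci_low == res.rho_z == res.ci_high == pytest.approx(1.0)

    def test_small_n_rejected_for_asymptotics(self, rng):
        p = pair(rng.normal(size=5), rng.normal(size=5))
        with pytest.raises(ValueError, match="n >= 8"):
            ccc_ci(p, method="fisher_simple")


class TestAgreementTable:
    def make_pairs(self, rng):
        pairs = []
        for device in ("Actigraphy", "Video"):
            for side in ("left", "right"):
                x = rng.normal(size=40)
                y = x + rng.normal(0, 0.5, size=40)
                pairs.append(pair(x, y, labels=("IR-UWB", device, side)))
        for side in ("left", "right"):
            x = rng.normal(size=40)
            pairs.append(pair(x, x + rng.normal(0, 1, size=40),
                              labels=("Actigraphy", "Video", side)))
        return pairs

    def test_three_device_pairs_by_two_sides(self, rng):
        df = agreement_table(self.make_pairs(rng))
        assert len(df) == 6
        assert set(df["Device"]) == {"IR-UWB vs Actigraphy", "IR-UWB vs Video",
                                     "Actigraphy vs Video"}
        assert list(df.columns[:2]) == ["Device", "Side"]

    def test_rows_ordered_deterministically(self, rng):
        pairs = self.make_pairs(rng)
        df1 = agreement_table(pairs)
        df2 = agreement_table(list(reversed(pairs)))
        assert list(df1["Device"]) == list(df2["Device"])
        assert list(df1["Side"]) == list(df2["Side"])

    def test_failing_pair_kept_as_flagged_row(self, rng):
        good = pair(rng.normal(size=40), rng.normal(size=40),
                    labels=("IR-UWB", "Actigraphy", "left"))
        bad = pair(rng.normal(size=5), rng.normal(size=5),
                   labels=("IR-UWB", "Video", "left"))
        df = agreement_table([good, bad])
        assert len(df) == 2
        flagged = df[df["Device"] == "IR-UWB vs Video"]
        assert np.isnan(flagged["rho_z"].iloc[0])
        assert "n >= 8" in flagged["error"].iloc[0]
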