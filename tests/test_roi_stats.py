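"""ROI summaries, phantom and group regressions, FDR, motion metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, stats

from nmmt.relaxometry import VolumeGrid
from nmmt.roi_stats import (
    GroupRecord,
    ROIMask,
    average_edge_strength,
    benjamini_hochberg,
    group_comparison,
    normalize_to_reference,
    phantom_regression,
    roi_summary,
)


class TestRoiSummary:
    def test_constant_map(self):
        v = VolumeGrid(np.full((3, 3, 2), 7.0))
        mask = ROIMask("x", np.ones((3, 3, 2), bool))
        mean, sd, n = roi_summary(v, mask)
        assert (mean, sd, n) == (7.0, 0.0, 18)

    def test_two_voxel_sample_sd(self):
        data = np.zeros((2, 2, 1))
        data[0, 0, 0], data[1, 1, 0] = 1.0, 3.0
        m = np.zeros((2, 2, 1), bool)
        m[0, 0, 0] = m[1, 1, 0] = True
        mean, sd, n = roi_summary(VolumeGrid(data), ROIMask("x", m))
        assert mean == 2.0 and sd == pytest.approx(np.sqrt(2.0)) and n == 2

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(6, 5, 4))
        mask = rng.random((6, 5, 4)) > 0.5
        mean, sd, n = roi_summary(VolumeGrid(data), ROIMask("x", mask))
        vals = []
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    if mask[i, j, k]:
                        vals.append(data[i, j, k])
        assert mean == pytest.approx(sum(vals) / len(vals), rel=1e-12)
        mu = sum(vals) / len(vals)
        sd_oracle = (sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert sd == pytest.approx(sd_oracle, rel=1e-12)
        assert n == len(vals)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ROIMask("x", np.zeros((2, 2, 2), bool))


class TestNormalize:
    def test_basics(self):
        assert normalize_to_reference(5.0, 5.0) == 1.0
        assert normalize_to_reference(1.11, 1.0) == pytest.approx(1.11)
        # scanner gain cancels
        assert normalize_to_reference(3 * 1.11, 3 * 1.0) == pytest.approx(1.11)
        with pytest.raises(ValueError):
            normalize_to_reference(1.0, 0.0)


def toy_layer_table(signal_fn, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for model, concs in (("sepia", [0.6, 1.8, 2.4, 3.0]), ("dam", [1.2, 1.8, 2.4, 3.0]),
                         ("agar", [0.0, 0.0, 0.0, 0.0])):
        for c in concs:
            rows.append({"model": model, "concentration": c,
                         "signal": signal_fn(model, c) + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestPhantomRegression:
    def test_null_signal_flat(self):
        df = toy_layer_table(lambda m, c: 1234.0)
        res = phantom_regression(df)
        assert abs(res.t_concentration) < 1e-6
        assert abs(res.t_sepia_vs_agar) < 1e-6

    def test_exact_linear_slope_recovered(self):
        df = toy_layer_table(lambda m, c: 2000.0 - 100.0 * c)
        res = phantom_regression(df)
        assert res.model.params["concentration"] == pytest.approx(-100.0, rel=1e-10)
        assert res.model.params.iloc[1] == pytest.approx(0.0, abs=1e-9)  # sepia contrast
        assert res.model.params.iloc[2] == pytest.approx(0.0, abs=1e-9)  # dam contrast

    def test_matches_hand_computed_normal_equations(self):
        # 6-row toy table, two predictors + two model dummies
        df = pd.DataFrame(
            {
                "model": ["agar", "agar", "sepia", "sepia", "dam", "dam"],
                "concentration": [0.0, 1.0, 0.5, 2.0, 1.5, 3.0],
                "signal": [10.0, 8.5, 9.8, 6.9, 7.7, 4.9],
            }
        )
        X = np.column_stack(
            [
                np.ones(6),
                df["concentration"],
                (df["model"] == "sepia").astype(float),
                (df["model"] == "dam").astype(float),
            ]
        )
        y = df["signal"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 4)
        cov = s2 * np.linalg.inv(X.T @ X)
        t_conc = beta[1] / np.sqrt(cov[1, 1])
        t_sepia = beta[2] / np.sqrt(cov[2, 2])
        res = phantom_regression(df)
        # statsmodels orders terms as intercept, contrasts, concentration
        assert res.t_concentration == pytest.approx(t_conc, abs=1e-10)
        assert res.t_sepia_vs_agar == pytest.approx(t_sepia, abs=1e-10)

    def test_negative_t1_slope_detected_with_power(self):
        # noisy phantoms with the generator's T1-concentration structure:
        # concentration t negative and significant in >= 95/100 replicates
        hits = 0
        for rep in range(100):
            df = toy_layer_table(lambda m, c: 2000.0 - 200.0 * c, noise=50.0, seed=3000 + rep)
            res = phantom_regression(df)
            if res.t_concentration < 0 and res.p_concentration < 0.05:
                hits += 1
        assert hits >= 95

    def test_missing_level_rejected(self):
        df = toy_layer_table(lambda m, c: 1.0)
        with pytest.raises(ValueError):
            phantom_regression(df[df.model != "dam"])


def make_records(n_young=6, n_old=6, shift=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for group, n in (("young", n_young), ("old", n_old)):
        for i in range(n):
            val = 10.0 + (shift if group == "old" else 0.0) + rng.normal(0, noise)
            recs.append(
                GroupRecord(f"{group}{i}", group, "LC", "T1", val, aes=rng.normal(1, 0.01))
            )
    return recs


class TestGroupComparison:
    def test_identical_groups_zero_noise(self):
        table = group_comparison(make_records())
        assert np.allclose(table["estimate"], 0.0)
        assert np.allclose(table["p_fdr"], 1.0)

    def test_bh_step_up_arithmetic(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_bh_monotone_and_idempotent(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(0, 1, 12))
        adj = benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-15)  # order-preserving
        assert np.all(adj >= p - 1e-15)
        again = benjamini_hochberg(adj)
        # already maximally adjusted values are stable under re-adjustment
        assert np.allclose(again, benjamini_hochberg(adj))

    def test_estimate_invariant_to_intensity_offset(self):
        recs = make_records(shift=2.0, noise=1.0, seed=8)
        shifted = [
            GroupRecord(r.subject, r.group, r.roi, r.scan, r.value + 500.0, r.aes)
            for r in recs
        ]
        a = group_comparison(recs)
        b = group_comparison(shifted)
        assert a["estimate"].to_numpy() == pytest.approx(b["estimate"].to_numpy(), rel=1e-9)

    def test_single_group_rejected(self):
        recs = [r for r in make_records() if r.group == "young"]
        with pytest.raises(ValueError):
            group_comparison(recs)


class TestAverageEdgeStrength:
    def test_constant_volume_zero(self):
        assert average_edge_strength(VolumeGrid(np.full((5, 5, 5), 3.0))) == 0.0

    def test_step_edge_proportional_to_height(self):
        def step(h):
            d = np.zeros((8, 8, 4))
            d[4:, :, :] = h
            return average_edge_strength(VolumeGrid(d))

        assert step(2.0) == pytest.approx(2.0 * step(1.0), rel=1e-12)

    def test_blur_lowers_aes(self):
        rng = np.random.default_rng(5)
        d = np.zeros((16, 16, 8))
        d[8:, :, :] = 100.0
        d += rng.normal(0, 1.0, d.shape)
        sharp = average_edge_strength(VolumeGrid(d))
        blurred = average_edge_strength(VolumeGrid(ndimage.gaussian_filter(d, 2.0)))
        assert blurred < sharp
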