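"""Calibration, normalization, 37C-minus-4C quantification, and t-tests."""

import numpy as np
import pandas as pd
import pytest

from ndendo.synth import AssayDesign, simulate_assay
from ndendo.uptake import (
    CalibrationSeries,
    calibration_slope,
    compare_types,
    normalize,
    quantify,
    two_sample_p,
    two_sample_p_from_summary,
    uptake_ratio,
)

CONC = np.array([0.0, 5.0, 10.0, 15.0, 20.0])


def pooled_t_stat(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_p(a, b, n_perm, seed):
    """Oracle: permutation distribution of the pooled t statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(pooled_t_stat(a, b))
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    pa, pb = perm[:, : len(a)], perm[:, len(a):]
    va = pa.var(axis=1, ddof=1)
    vb = pb.var(axis=1, ddof=1)
    sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(pooled) - 2)
    t = (pa.mean(axis=1) - pb.mean(axis=1)) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return np.mean(np.abs(t) >= obs - 1e-12)


class TestCalibration:
    def test_exact_linear_series(self):
        s = CalibrationSeries("prickly", CONC, 2.0 * CONC)
        assert calibration_slope(s) == pytest.approx(2.0)

    def test_constant_intensities_give_zero_slope(self):
        s = CalibrationSeries("round", CONC, np.full(5, 7.0))
        assert calibration_slope(s) == pytest.approx(0.0)

    def test_blank_subtraction_leaves_slope_unchanged(self):
        s = CalibrationSeries("prickly", CONC, 3.0 * CONC + 50.0)
        assert calibration_slope(s, blank_subtract=True) == pytest.approx(3.0)
        assert calibration_slope(s, blank_subtract=False) == pytest.approx(3.0)

    def test_noisy_ols_within_three_standard_errors(self):
        rng = np.random.default_rng(21)
        slope_true, sigma = 4.0, 1.5
        n_rep = 40
        conc = np.tile(CONC, n_rep)
        y = slope_true * conc + rng.normal(0, sigma, len(conc))
        s = CalibrationSeries("x", conc, y)
        se = sigma / np.sqrt(np.sum((conc - conc.mean()) ** 2))
        assert abs(calibration_slope(s, blank_subtract=False) - slope_true) < 3 * se

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSeries("x", np.full(4, 5.0), np.arange(4.0))


class TestNormalize:
    def setup_method(self):
        self.assay, _ = simulate_assay(AssayDesign.reference(), seed=1)

    def test_round_trip(self):
        slopes = {"prickly": 2.0, "round": 0.5}
        norm = normalize(self.assay, slopes)
        back = norm.copy()
        back["intensity"] = back["intensity"] * back["nd_type"].map(slopes)
        assert np.allclose(back["intensity"], self.assay["intensity"])

    def test_slope_ratio_two_to_one_halves_first_type(self):
        norm = normalize(self.assay, {"prickly": 2.0, "round": 1.0})
        prickly = self.assay["nd_type"] == "prickly"
        assert np.allclose(norm.loc[prickly, "intensity"],
                           self.assay.loc[prickly, "intensity"] / 2)
        assert np.allclose(norm.loc[~prickly, "intensity"],
                           self.assay.loc[~prickly, "intensity"])

    def test_missing_or_invalid_slope_rejected(self):
        with pytest.raises(ValueError, match="round"):
            normalize(self.assay, {"prickly": 1.0})
        with pytest.raises(ValueError):
            normalize(self.assay, {"prickly": 1.0, "round": 0.0})


class TestQuantify:
    def _assay(self, mean4, mean37, n=4):
        rows = []
        for cond, mean in (("4C", mean4), ("37C", mean37)):
            for rep in range(n):
                rows.append({"nd_type": "prickly", "condition": cond,
                             "time_hr": 1.0, "replicate": rep,
                             "intensity": mean + 0.0})
        rows = pd.DataFrame(rows)
        # inject tiny spread so sds are defined but means exact
        rows.loc[rows["replicate"] == 0, "intensity"] += 1e-9
        return rows

    def test_subtraction_identity(self):
        res = quantify(self._assay(4.0, 10.0))
        row = res.iloc[0]
        assert row.internalized_mean == pytest.approx(6.0)
        assert row.anchored_mean + row.internalized_mean == pytest.approx(row.total_mean)

    def test_identical_conditions_give_zero_internalized(self):
        res = quantify(self._assay(5.0, 5.0))
        assert res.iloc[0].internalized_mean == pytest.approx(0.0, abs=1e-9)

    def test_negative_internalized_flagged_not_clipped(self):
        res = quantify(self._assay(8.0, 5.0))
        assert res.iloc[0].internalized_mean == pytest.approx(-3.0)
        assert bool(res.iloc[0].negative_internalized)

    def test_missing_condition_rejected(self):
        assay = self._assay(4.0, 10.0)
        with pytest.raises(ValueError, match="4C"):
            quantify(assay[assay["condition"] == "37C"])

    def test_quadrature_error_propagation(self):
        rng = np.random.default_rng(5)
        rows = []
        for cond, mu in (("4C", 50.0), ("37C", 120.0)):
            for rep in range(6):
                rows.append({"nd_type": "x", "condition": cond, "time_hr": 2.0,
                             "replicate": rep,
                             "intensity": mu + rng.normal(0, 5)})
        res = quantify(pd.DataFrame(rows)).iloc[0]
        assert res.internalized_sd == pytest.approx(
            np.sqrt(res.anchored_sd**2 + res.total_sd**2)
        )


class TestScaleEquivariance:
    def test_global_intensity_rescaling_changes_nothing(self):
        assay, _ = simulate_assay(AssayDesign.reference(), seed=3)
        cal = {t: CalibrationSeries(t, CONC, s * CONC)
               for t, s in (("prickly", 3.0), ("round", 1.7))}
        c = 12.5

        def pipeline(raw, cals):
            slopes = {t: calibration_slope(s) for t, s in cals.items()}
            res = quantify(normalize(raw, slopes))
            r, _ = uptake_ratio(res, "internalized", "round", "prickly", 10.0)
            p = compare_types(normalize(raw, slopes), "37C", "prickly", "round")
            return r, p["p_value"].to_numpy()

        scaled = assay.copy()
        scaled["intensity"] *= c
        cal_scaled = {t: CalibrationSeries(t, s.concentrations, c * s.intensities)
                      for t, s in cal.items()}
        r1, p1 = pipeline(assay, cal)
        r2, p2 = pipeline(scaled, cal_scaled)
        assert r1 == pytest.approx(r2)
        assert np.allclose(p1, p2)


class TestTwoSampleP:
    def test_identical_groups_give_p_one(self):
        assert two_sample_p([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0

    def test_zeta_potential_summaries(self):
        """Pooled Student's t on the two particle types' zeta potentials."""
        p = two_sample_p_from_summary(-41.9033, 1.6671, 3, -41.5567, 6.93695, 3,
                                      variant="pooled")
        assert p == pytest.approx(0.937, abs=0.002)

    def test_welch_differs_from_pooled_under_unequal_variance(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 10, 15)
        assert two_sample_p(a, b, "pooled") != two_sample_p(a, b, "welch")

    @pytest.mark.parametrize("na,nb,n_perm,tol", [
        (3, 3, 100_000, 0.1),   # exact permutation set has only 20 atoms
        (10, 10, 20_000, 0.05),
    ])
    def test_pooled_p_matches_permutation_oracle(self, na, nb, n_perm, tol):
        rng = np.random.default_rng(31)
        a = rng.normal(0.0, 1.0, na)
        b = rng.normal(0.4, 1.0, nb)
        p_t = two_sample_p(a, b, "pooled")
        p_perm = permutation_p(a, b, n_perm, seed=7)
        assert abs(p_t - p_perm) < tol

    def test_summary_and_raw_agree(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 2, 8)
        p_raw = two_sample_p(a, b, "welch")
        p_sum = two_sample_p_from_summary(a.mean(), a.std(ddof=1), 6,
                                          b.mean(), b.std(ddof=1), 8, "welch")
        assert p_raw == pytest.approx(p_sum)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_p([1.0], [2.0, 3.0])


class TestRecovery:
    def test_time_course_monotone_on_average(self):
        """Saturating truth implies non-decreasing mean total uptake in time."""
        design = AssayDesign.reference()
        totals = []
        for seed in range(200):
            assay, _ = simulate_assay(design, seed=seed)
            res = quantify(assay)
            totals.append(
                res[res.nd_type == "round"].sort_values("time_hr")["total_mean"].to_numpy()
            )
        mean_course = np.mean(totals, axis=0)
        assert np.all(np.diff(mean_course) > 0)

    def test_ratio_recovery_from_synthetic_truth(self):
        assay, truth = simulate_assay(AssayDesign.reference(), seed=77)
        res = quantify(assay)
        r, sd = uptake_ratio(res, "total", "round", "prickly", 10.0)
        tp = truth["per_point"]
        t_r = tp[(tp.nd_type == "round") & (tp.time_hr == 10.0)].iloc[0].total
        t_p = tp[(tp.nd_type == "prickly") & (tp.time_hr == 10.0)].iloc[0].total
        assert abs(r - t_r / t_p) < 2 * sd
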