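import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mmn_rubberband.correlations import (
    all_pairs_correlations,
    count_table,
    normality_check,
    parameter_pairs,
    roi_analysis,
    significance_stars,
    spearman,
)
from mmn_rubberband.extraction import PARAMETER_NAMES


class TestNormality:
    def test_normal_draws_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            normality_check(rng.normal(size=1000)).p < 0.05 for _ in range(100)
        )
        assert rejections <= 10

    def test_exponential_draws_nearly_always_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            normality_check(rng.exponential(size=1000)).p < 0.05
            for _ in range(100)
        )
        assert rejections >= 99

    def test_degenerate_vector_flagged(self):
        res = normality_check([2.0] * 50)
        assert res.degenerate and np.isnan(res.p)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0, 3.0])


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_perfect_antitone(self):
        res = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_ties_match_average_rank_pearson_oracle(self):
        x, y = [1.0, 1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 3.0, 5.0, 4.0]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=22)
            y = 0.4 * x + rng.normal(size=22)
            res = spearman(x, y)
            ref_rho, ref_p = stats.spearmanr(x, y)
            assert res.rho == pytest.approx(ref_rho, abs=1e-12)
            assert res.p == pytest.approx(ref_p, rel=1e-6)

    def test_pairwise_complete_dropping(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan, 12.0]
        res = spearman(x, y, min_n=3)
        assert res.n_used == 4
        assert res.rho == pytest.approx(1.0)

    def test_small_n_missing(self):
        res = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert not res.ok and np.isnan(res.rho)
        assert "n_used" in res.reason

    def test_zero_rank_variance_flagged(self):
        res = spearman([1.0] * 10, list(range(10)))
        assert not res.ok and res.reason == "zero rank variance"

    def test_permutation_p_agrees_with_t_for_clear_effect(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = x + 0.3 * rng.normal(size=12)
        t_res = spearman(x, y)
        p_res = spearman(x, y, method="permutation", n_resamples=4000, seed=0)
        assert p_res.rho == t_res.rho
        assert p_res.p < 0.05 and t_res.p < 0.05

    def test_exhaustive_permutation_small_n(self):
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], method="permutation")
        # exact enumeration of 5! permutations
        assert 0.0 < res.p <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_invariant_under_strictly_monotone_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        trans = spearman(np.exp(a * x + b), y)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)


def _params_table(n_subjects=10, isis=(1.5, 3.0, 4.5, 6.0), channels=("FZ",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for isi in isis:
            for ch in channels:
                row = {"subject_id": s, "isi_s": isi, "channel": ch, "valid": True}
                for name in PARAMETER_NAMES:
                    row[name] = rng.normal()
                rows.append(row)
    return pd.DataFrame(rows)


class TestAllPairs:
    def test_36_pairs_from_nine_parameters(self):
        assert len(parameter_pairs()) == 36

    def test_144_results_per_electrode_with_four_isis(self):
        results = all_pairs_correlations(_params_table())
        assert len(results) == 36 * 4
        assert (results.groupby("channel").size() == 144).all()

    def test_single_pair_single_cell(self):
        table = _params_table(isis=(1.5,))
        results = all_pairs_correlations(table, parameters=("amplitude", "duration"))
        assert len(results) == 1

    def test_absolute_values_used_for_magnitude_parameters(self):
        table = _params_table(isis=(1.5,))
        table["ampavg"] = -table["amplitude"]  # perfectly anti-monotone raw
        results = all_pairs_correlations(table)
        cell = results.query("param_a=='amplitude' and param_b=='ampavg'")
        assert cell["rho"].iloc[0] == pytest.approx(1.0)  # |x| vs |-x|

    def test_invalid_rows_excluded(self):
        table = _params_table(isis=(1.5,), n_subjects=12)
        table.loc[table["subject_id"] < 6, "valid"] = False
        results = all_pairs_correlations(table)
        assert (results["n_used"] == 6).all()

    def test_insufficient_subjects_yield_missing(self):
        table = _params_table(n_subjects=4, isis=(1.5,))
        results = all_pairs_correlations(table)
        assert (~results["ok"]).all()
        assert results["rho"].isna().all()


class TestCountTable:
    def _results(self, pvalues, rhos=None):
        rows = []
        for i, p in enumerate(pvalues):
            rows.append(
                {
                    "param_a": "amplitude",
                    "param_b": "downslope",
                    "isi_s": 1.5,
                    "channel": f"E{i}",
                    "rho": 0.5 if rhos is None else rhos[i],
                    "p": p,
                    "n_used": 22,
                    "ok": True,
                    "reason": None,
                }
            )
        return pd.DataFrame(rows)

    def test_threshold_arithmetic(self):
        p = [0.01, 0.04, 0.07, 0.2] + [0.5] * 9
        counts = count_table(self._results(p))
        assert counts["count_combined"].iloc[0] == 3
        assert counts["count_strict"].iloc[0] == 2

    def test_all_nonsignificant(self):
        counts = count_table(self._results([1.0] * 13))
        assert counts["count_combined"].iloc[0] == 0
        assert counts["count_strict"].iloc[0] == 0

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=13)
        counts = count_table(self._results(list(p)))
        assert counts["count_combined"].iloc[0] == int((p < 0.1).sum())
        assert counts["count_strict"].iloc[0] == int((p < 0.05).sum())

    def test_nan_pvalues_not_counted(self):
        counts = count_table(self._results([0.01, np.nan, np.nan]))
        assert counts["count_combined"].iloc[0] == 1

    def test_invariant_strict_le_combined_le_n(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            counts = count_table(self._results(list(rng.uniform(size=13))))
            row = counts.iloc[0]
            assert 0 <= row["count_strict"] <= row["count_combined"] <= 13

    def test_bad_alphas_rejected(self):
        with pytest.raises(ValueError):
            count_table(self._results([0.5]), alpha_strict=0.1, alpha_combined=0.05)

    def test_sign_tallies(self):
        counts = count_table(
            self._results([0.01, 0.02, 0.5], rhos=[0.5, -0.5, 0.9])
        )
        row = counts.iloc[0]
        assert row["n_positive"] == 1 and row["n_negative"] == 1


def test_significance_stars():
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
    assert significance_stars(float("nan")) == ""


class TestRoiAnalysis:
    def test_scaled_identical_waves_give_perfect_downslope_coupling(self, t_axis):
        """Subjects differing only by a scale factor: amplitude and
        downslope are rank-identical (the rubberband construction)."""
        from conftest import make_wave
        from mmn_rubberband.extraction import extract_table
        from mmn_rubberband.synth.components import mmn_component

        base = mmn_component(t_axis, 1.0, 120, 180, 300)
        rng = np.random.default_rng(7)
        scales = rng.uniform(1.0, 5.0, size=8)
        waves = [
            make_wave(s * base, t_axis, subject_id=i, channel="frontal")
            for i, s in enumerate(scales)
        ]
        table = extract_table(waves)
        roi = roi_analysis(table)
        down = roi[roi["param_b"] == "downslope"]
        assert down["rho"].iloc[0] == pytest.approx(1.0)

    def test_rubberband_cohort_frontal_downslope_significant(self):
        """Reduced-scale simulation oracle: frontal ROI shows a significant
        positive amplitude-downslope correlation in ≥3 of 4 ISIs for most
        seeded runs."""
        from mmn_rubberband import PipelineConfig, simulate_waves
        from mmn_rubberband.channels import DEFAULT_REGIONS
        from mmn_rubberband.extraction import extract_table
        from mmn_rubberband.waveforms import roi_average

        hits = 0
        n_runs = 5
        for seed in range(n_runs):
            cfg = PipelineConfig(
                seed=seed, n_subjects=22,
                electrodes=DEFAULT_REGIONS["frontal"],
                n_deviant_trials=30, n_standard_trials=120,
                regions={"frontal": DEFAULT_REGIONS["frontal"]},
            )
            _, waves = simulate_waves(cfg)
            roi_params = extract_table(roi_average(waves, cfg.regions))
            roi = roi_analysis(roi_params)
            down = roi[(roi["param_b"] == "downslope")]
            n_sig = int(((down["p"] < 0.05) & (down["rho"] > 0)).sum())
            hits += n_sig >= 3
        assert hits >= 4, f"only {hits}/{n_runs} runs had >=3 significant ISIs"

    def test_null_cohort_upslope_rarely_significant(self):
        """Reduced-scale type-I check: in null mode the frontal ROI
        amplitude-upslope correlation is significant only occasionally."""
        from mmn_rubberband import PipelineConfig, simulate_waves
        from mmn_rubberband.channels import DEFAULT_REGIONS
        from mmn_rubberband.extraction import extract_table
        from mmn_rubberband.waveforms import roi_average

        cells = sig = 0
        for seed in range(8):
            cfg = PipelineConfig(
                seed=100 + seed, mode="null", n_subjects=22,
                electrodes=DEFAULT_REGIONS["frontal"], isis_s=(1.5, 3.0),
                n_deviant_trials=30, n_standard_trials=120,
                regions={"frontal": DEFAULT_REGIONS["frontal"]},
            )
            _, waves = simulate_waves(cfg)
            roi_params = extract_table(roi_average(waves, cfg.regions))
            roi = roi_analysis(roi_params)
            up = roi[roi["param_b"] == "upslope"]
            cells += len(up)
            sig += int((up["p"] < 0.05).sum())
        assert cells == 16
        assert sig / cells <= 0.35  # loose bound at this reduced scale

    def test_stars_column(self):
        table = _params_table(isis=(1.5,), channels=("frontal",))
        table["upslope"] = table["amplitude"]
        roi = roi_analysis(table)
        up = roi[roi["param_b"] == "upslope"]
        assert up["stars"].iloc[0] == "**"


def test_type_one_error_calibration_of_correlation_stage():
    """Under the null generator, p < 0.05 rejections land in [0.03, 0.07]
    (600 independent amplitude/descent-rate cells, n = 22 each)."""
    from mmn_rubberband.synth.truth import draw_ground_truth

    rejections = 0
    n_cells = 600
    for seed in range(n_cells):
        t = draw_ground_truth("null", 22, seed=seed, isis=(1.5,), electrodes=("FZ",))
        res = spearman(t["amplitude_uv"], t["descent_rate_uv_ms"])
        rejections += res.p < 0.05
    rate = rejections / n_cells
    assert 0.03 <= rate <= 0.07, f"type-I rate {rate}"
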