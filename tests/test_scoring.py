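"""GI scores, robust Z, tail-area FDR and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barseqfit import (
    FitnessModel,
    SimulationConfig,
    call_hits,
    classify_expressivity,
    generate_library,
    gi_score,
    normalize_counts,
    robust_z,
    score_screen,
    simulate_counts,
    tail_area_fdr,
)
from barseqfit.scoring import NIQR_FACTOR, DegenerateScreenError


def series(values, prefix="m"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestNormalizeCounts:
    def test_two_entry_column(self):
        counts = pd.DataFrame({"s": [1, 3]}, index=["a", "b"])
        norm = normalize_counts(counts, pseudocount=1.0).frame
        assert norm["s"].tolist() == pytest.approx([1e6 / 3, 2e6 / 3])

    def test_uniform_column(self):
        counts = pd.DataFrame({"s": [7] * 10})
        norm = normalize_counts(counts).frame
        assert np.allclose(norm["s"], 1e5)

    def test_columns_sum_to_scale(self, small_counts):
        norm = normalize_counts(small_counts).frame
        assert np.allclose(norm.sum(axis=0), 1e6, rtol=1e-9)
        assert (norm > 0).all().all()

    def test_all_zero_column_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(pd.DataFrame({"s": [0, 0]}))

    def test_nonpositive_pseudocount_raises(self, small_counts):
        with pytest.raises(ValueError):
            normalize_counts(small_counts, pseudocount=0.0)


class TestGiScore:
    def test_equal_counts_zero(self):
        gi = gi_score(series([100, 200]), series([100, 200]), doublings=5)
        assert np.allclose(gi, 0.0)

    def test_thirtytwo_fold_depletion_is_one(self):
        gi = gi_score(series([3200, 100]), series([100, 100]), doublings=5)
        assert gi.iloc[0] == pytest.approx(np.log2(32) / 5)
        assert gi.iloc[0] == pytest.approx(1.0)

    def test_two_fold_depletion(self):
        gi = gi_score(series([200]), series([100]), doublings=5)
        assert gi.iloc[0] == pytest.approx(0.2)

    def test_missing_mutant_propagates_nan(self):
        c = pd.Series({"a": 100.0, "b": 50.0})
        t = pd.Series({"a": 100.0})
        gi = gi_score(c, t, 5)
        assert np.isnan(gi["b"]) and gi["a"] == 0.0

    def test_bad_doublings(self):
        with pytest.raises(ValueError):
            gi_score(series([1]), series([1]), doublings=0)


class TestRobustZ:
    def test_median_scores_zero(self):
        gi = series(np.arange(11.0))
        z, stats_ = robust_z(gi)
        assert z[gi.index[5]] == pytest.approx(0.0)
        assert stats_.median == 5.0

    def test_niqr_is_consistent_sigma_estimate(self):
        """NIQR = IQR/1.349 recovers sigma of a standard normal within 1%."""
        rng = np.random.default_rng(0)
        gi = pd.Series(rng.normal(0, 1, 100_000))
        z, stats_ = robust_z(gi)
        assert stats_.niqr == pytest.approx(1.0, rel=0.01)
        assert np.corrcoef(z, gi)[0, 1] > 0.999

    def test_degenerate_vector_raises(self):
        with pytest.raises(DegenerateScreenError):
            robust_z(series([0.0] * 12))

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            robust_z(series([0.0, 1.0, 2.0]))

    @given(shift=st.floats(min_value=-5, max_value=5))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance(self, shift):
        """Adding a constant to every GI moves the median, not the Z-scores."""
        rng = np.random.default_rng(7)
        gi = pd.Series(rng.normal(0.1, 0.3, 500))
        z0, _ = robust_z(gi)
        z1, _ = robust_z(gi + shift)
        assert np.allclose(z0, z1, atol=1e-9)

    def test_niqr_constant_matches_normal_quantiles(self):
        from scipy.stats import norm

        assert NIQR_FACTOR == pytest.approx(2 * norm.ppf(0.75), abs=5e-4)


class TestTailAreaFdr:
    def test_null_sample_bounds_and_median(self):
        rng = np.random.default_rng(3)
        z = pd.Series(rng.normal(0, 1, 3000))
        fdr, null = tail_area_fdr(z)
        assert ((fdr >= 0) & (fdr <= 1)).all()
        median_mutant = (z - z.median()).abs().idxmin()
        assert fdr[median_mutant] > 0.95
        assert 0.9 <= null.pi0 <= 1.0
        assert null.sigma0 == pytest.approx(1.0, rel=0.1)

    def test_planted_outlier_gets_tiny_fdr(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = pd.Series(np.append(rng.normal(0, 1, 3000), 10.0))
            fdr, _ = tail_area_fdr(z)
            assert fdr.iloc[-1] < 0.01

    def test_pi0_recovery_in_mixture(self):
        """90% null + 10% shifted alternative: pi0 estimated within 0.05."""
        rng = np.random.default_rng(11)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 4500), rng.normal(4, 1, 500)]))
        _, null = tail_area_fdr(z)
        assert null.pi0 == pytest.approx(0.9, abs=0.05)

    def test_monotone_non_increasing_in_abs_z(self):
        rng = np.random.default_rng(5)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 900), rng.normal(3, 1, 100)]))
        fdr, _ = tail_area_fdr(z)
        order = z.abs().sort_values().index
        diffs = np.diff(fdr[order].to_numpy())
        assert (diffs <= 1e-12).all()

    def test_missing_z_propagates(self):
        rng = np.random.default_rng(6)
        z = pd.Series(rng.normal(0, 1, 200))
        z.iloc[0] = np.nan
        fdr, _ = tail_area_fdr(z)
        assert np.isnan(fdr.iloc[0]) and fdr.iloc[1:].notna().all()

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            tail_area_fdr(pd.Series(np.arange(50.0)))

    def test_overwhelming_tail_raises(self):
        rng = np.random.default_rng(8)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 100), rng.normal(12, 0.5, 400)]))
        with pytest.raises(DegenerateScreenError):
            tail_area_fdr(z)


class TestCallHits:
    def make_screens(self, fdr_rows, gi_value=0.8):
        """fdr_rows: mutant -> list of per-screen FDR (NaN = not assayed)."""
        n_screens = len(next(iter(fdr_rows.values())))
        filler = {f"bg{i}": [0.9] * n_screens for i in range(10)}
        rows = {**fdr_rows, **filler}
        screens = {}
        for s in range(n_screens):
            frame = pd.DataFrame(
                {
                    "gi": [gi_value if np.isfinite(v[s]) else np.nan for v in rows.values()],
                    "fdr": [v[s] for v in rows.values()],
                },
                index=list(rows),
            )
            frame["z"] = frame["gi"] * 10
            screens[f"scr{s}"] = frame
        return screens

    def test_pass_in_all_screens_is_hit(self):
        screens = self.make_screens({"mA": [0.05, 0.03, 0.08]})
        calls = call_hits(screens, fdr_cutoff=0.1)
        assert "mA" in calls.hits.index

    def test_partial_significance_goes_to_rescreen(self):
        screens = self.make_screens({"mA": [0.05, 0.5, 0.03]})
        calls = call_hits(screens, fdr_cutoff=0.1)
        assert "mA" not in calls.hits.index
        assert "mA" in calls.rescreen_candidates.index

    def test_enriched_direction_never_hits(self):
        screens = self.make_screens({"mA": [0.001, 0.001]}, gi_value=-0.8)
        calls = call_hits(screens, fdr_cutoff=0.1)
        assert "mA" not in calls.hits.index
        assert "mA" not in calls.rescreen_candidates.index

    def test_missing_screen_judged_on_present_screens(self):
        screens = self.make_screens({"mA": [0.05, np.nan, 0.03]})
        calls = call_hits(screens, fdr_cutoff=0.1)
        assert "mA" in calls.hits.index
        assert calls.hits.loc["mA", "n_screens_assayed"] == 2

    def test_no_screens_raises(self):
        with pytest.raises(ValueError):
            call_hits({})

    def test_bad_cutoff_raises(self):
        screens = self.make_screens({"mA": [0.05]})
        with pytest.raises(ValueError):
            call_hits(screens, fdr_cutoff=1.5)


class TestClassifyExpressivity:
    @pytest.mark.parametrize(
        "gi,expected", [(1.0, "high"), (0.61, "high"), (0.3, "medium"), (0.25, "medium"), (0.1, "low")]
    )
    def test_default_cutoffs(self, gi, expected):
        assert classify_expressivity(gi) == expected

    def test_unordered_cutoffs_raise(self):
        with pytest.raises(ValueError):
            classify_expressivity(0.5, cutoffs=(0.6, 0.25))


class TestEstimatorConsistency:
    def test_gi_recovers_planted_fitness_and_classes(self):
        """At depth 1e6 over 3000 mutants, mean |GI - (1-f)| < 0.02 and
        planted low/medium/high classes are recovered with >= 90% accuracy."""
        n = 3000
        design = generate_library(n, seed=2)
        fm = FitnessModel.with_planted_classes(n, 100, 100, 100, seed=3)
        config = SimulationConfig(n_mutants=n, reads_per_sample=1_000_000, seed=4)
        rng = np.random.default_rng(4)
        # each arm is sequenced as two tag libraries whose counts are summed
        counts = pd.DataFrame(
            {
                "control": simulate_counts(design, fm, config, "control", rng)
                + simulate_counts(design, fm, config, "control", rng),
                "treatment": simulate_counts(design, fm, config, "treatment", rng)
                + simulate_counts(design, fm, config, "treatment", rng),
            }
        )
        scores = score_screen(counts, "control", "treatment", doublings=5.0)
        truth = fm.truth_table(design.mutants)
        # planted depletion shrinks the treatment pool, offsetting every GI
        # by the renormalization constant; the median (a null mutant) anchors
        # the scale, exactly as the robust-Z centering does
        centered = scores["gi"] - scores["gi"].median()
        err = (centered - truth["expected_gi"]).abs()
        assert err.mean() < 0.02
        planted = truth["class_label"] != "none"
        predicted = centered[planted].map(classify_expressivity)
        accuracy = (predicted == truth.loc[planted, "class_label"]).mean()
        assert accuracy >= 0.90
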