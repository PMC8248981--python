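"""Hill/sigmoid models and fitters, normalisation, and binned responses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdksize.dose_response import (
    binned_response,
    fit_hill,
    fit_sigmoid,
    hill_model,
    normalize_to_reference,
    sigmoid_model,
)
from cdksize.errors import InsufficientDataError, NormalizationError

DOSES = np.array([0.0, 31.25, 62.5, 125.0, 250.0, 500.0, 1000.0])


class TestHillModel:
    def test_midpoint_identity(self):
        for h in (-1.71, -0.5, 1.0, 3.2):
            assert hill_model(200.0, 200.0, h, 1.0, 0.0) == pytest.approx(0.5)

    def test_limits_for_decreasing_curve(self):
        assert hill_model(0.0, 115.4, -1.71, 1.0, 0.0) == pytest.approx(1.0)
        assert hill_model(1e12, 115.4, -1.71, 1.0, 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hill_model(-1.0, 100.0, -1.0, 1.0, 0.0)

    def test_matches_independent_loglogistic(self):
        """Log-logistic evaluation coded independently: the response is a
        logistic function of log-dose with slope -h."""
        ic50, h, top, bottom = 115.4, -1.71, 1.2, 0.1
        doses = np.geomspace(1.0, 2000.0, 20)
        expected = bottom + (top - bottom) / (
            1.0 + np.exp(-h * (np.log(doses) - np.log(ic50)))
        )
        np.testing.assert_allclose(hill_model(doses, ic50, h, top, bottom), expected)

    @given(st.floats(min_value=0.2, max_value=4.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_dose(self, habs):
        doses = np.linspace(0.0, 1000.0, 50)
        dec = hill_model(doses, 150.0, -habs, 1.0, 0.0)
        inc = hill_model(doses, 150.0, habs, 1.0, 0.0)
        assert np.all(np.diff(dec) <= 1e-12)
        assert np.all(np.diff(inc) >= -1e-12)


class TestFitHill:
    def test_noiseless_recovery_of_reported_curve(self):
        """Points generated from the published inhibitor response (IC50
        115.4 nM, Hill coefficient -1.71) refit to within 1%."""
        y = hill_model(DOSES, 115.4, -1.71, 1.0, 0.0)
        fit = fit_hill(DOSES, y)
        assert fit.converged
        assert fit.ic50 == pytest.approx(115.4, rel=0.01)
        assert fit.hill_coef == pytest.approx(-1.71, rel=0.01)

    def test_flat_data_not_converged(self):
        fit = fit_hill(DOSES, np.full_like(DOSES, 0.7))
        assert not fit.converged

    def test_too_few_doses(self):
        with pytest.raises(InsufficientDataError):
            fit_hill([1.0, 2.0, 3.0], [1.0, 0.5, 0.2])

    def test_rss_beats_grid_search(self, rng):
        """Fitted RSS is no worse than a 50x50 grid over (ic50, coefficient)
        with the plateaus pinned at their generating values."""
        y = hill_model(DOSES, 115.4, -1.71, 1.0, 0.0) + rng.normal(0, 0.02, len(DOSES))
        fit = fit_hill(DOSES, y)
        best = np.inf
        for ic in np.geomspace(20, 600, 50):
            for h in np.linspace(-4.0, -0.2, 50):
                rss = float(np.sum((hill_model(DOSES, ic, h, 1.0, 0.0) - y) ** 2))
                best = min(best, rss)
        assert fit.rss <= best + 1e-12


class TestFitSigmoid:
    def test_recovery_of_reported_ploidy_ec50s(self):
        """Haploid/diploid EC50s (372 and 663 AU) refit to within 1% and the
        printed ratio (haploid is 56% of diploid) is reproduced."""
        levels = np.geomspace(10.0, 2000.0, 25)
        fits = {}
        for name, ec in (("haploid", 372.0), ("diploid", 663.0)):
            y = sigmoid_model(levels, ec, 2.0, 10.0, 0.5)
            fits[name] = fit_sigmoid(levels, y)
            assert fits[name].ec50 == pytest.approx(ec, rel=0.01)
        ratio = 100.0 * fits["haploid"].ec50 / fits["diploid"].ec50
        assert round(ratio) == 56

    def test_exact_recovery_slope_one(self):
        levels = np.linspace(10.0, 900.0, 15)
        y = sigmoid_model(levels, 300.0, 1.0, 5.0, 0.0)
        fit = fit_sigmoid(levels, y)
        assert fit.ec50 == pytest.approx(300.0, rel=1e-4)
        assert fit.slope == pytest.approx(1.0, rel=1e-4)

    def test_rss_beats_grid_search(self, rng):
        levels = np.geomspace(20.0, 1500.0, 18)
        y = sigmoid_model(levels, 400.0, 2.0, 8.0, 0.5) + rng.normal(0, 0.1, 18)
        fit = fit_sigmoid(levels, y)
        best = np.inf
        for ec in np.geomspace(50, 1200, 50):
            for s in np.linspace(0.3, 6.0, 50):
                rss = float(np.sum((sigmoid_model(levels, ec, s, 8.0, 0.5) - y) ** 2))
                best = min(best, rss)
        assert fit.rss <= best + 1e-12

    def test_ec50_bias_small_under_noise(self, rng):
        """Recovered EC50 bias stays below 3% with 5%-of-top Gaussian noise
        (200 replicates)."""
        levels = np.geomspace(20.0, 2000.0, 20)
        clean = sigmoid_model(levels, 400.0, 2.0, 10.0, 0.5)
        est = []
        for _ in range(200):
            f = fit_sigmoid(levels, clean + rng.normal(0, 0.5, len(levels)))
            if f.converged:
                est.append(f.ec50)
        bias = abs(np.mean(est) / 400.0 - 1.0)
        assert bias < 0.03

    def test_pinned_plateaus(self):
        levels = np.geomspace(10.0, 2000.0, 25)
        y = sigmoid_model(levels, 372.0, 2.0, 10.0, 0.5)
        fit = fit_sigmoid(levels, y, fix_top=10.0, fix_bottom=0.5)
        assert fit.top == 10.0 and fit.bottom == 0.5
        assert fit.ec50 == pytest.approx(372.0, rel=0.01)

    def test_diploid_ec50_exceeds_haploid_with_dna_inhibition(self):
        """Generator + fitter: with gamma > 0 the diploid population fits to
        a higher EC50 than the haploid at matched sizes."""
        from cdksize import synthetic as syn

        fits = {}
        for ploidy in (1, 2):
            cfg = syn.SimConfig(
                seed=21, n_cells=20000, genotypes=("AF_ppa2d",), ploidies=(ploidy,),
                radius_um={1: 2.0, 2: 2.0},  # matched volume at matched length
                level=syn.LevelParams(mode="induction", sample_window_s=6000.0),
            )
            rec, _ = syn.simulate_population(cfg)
            grp = rec.groupby(pd.cut(rec["cdk_level_au"], np.arange(0, 1500, 50)),
                              observed=True)["activity_nc"].mean().dropna()
            centers = np.array([iv.mid for iv in grp.index])
            fits[ploidy] = fit_sigmoid(centers, grp.to_numpy())
        assert fits[2].ec50 > fits[1].ec50


class TestNormalizeAndBin:
    def test_reference_identity(self, rng):
        v = rng.uniform(1, 5, 20)
        assert np.allclose(np.median(normalize_to_reference(v, v)), 1.0)

    def test_half_reference(self):
        assert normalize_to_reference([1.0], [2.0, 2.0, 2.0])[0] == pytest.approx(0.5)

    def test_matches_manual_division(self, rng):
        vals = rng.uniform(0, 10, 50)
        ref = rng.uniform(1, 3, 30)
        np.testing.assert_allclose(
            normalize_to_reference(vals, ref), vals / np.median(ref)
        )

    def test_nonpositive_reference_raises(self):
        with pytest.raises(NormalizationError):
            normalize_to_reference([1.0], [-1.0, 0.0])
        with pytest.raises(NormalizationError):
            normalize_to_reference([1.0], [])

    def test_single_record_single_bin(self):
        df = pd.DataFrame(
            {"area_px2": [1234.0], "activity_nc": [2.5], "gated": [True]}
        )
        out = binned_response(df, "area_px2", 500.0)
        assert len(out) == 1
        assert out["mean"].iloc[0] == 2.5
        assert bool(out["low_n"].iloc[0])

    def test_bin_means_match_groupby(self, rng):
        df = pd.DataFrame(
            {
                "area_px2": rng.uniform(0, 5000, 800),
                "activity_nc": rng.normal(3, 1, 800),
                "gated": True,
            }
        )
        out = binned_response(df, "area_px2", 500.0, min_n=5)
        # direct group-by on the same 500 px^2 windows
        which = (df["area_px2"] // 500).astype(int)
        direct = df.groupby(which)["activity_nc"].agg(["mean", "size"])
        for _, row in out.iterrows():
            b = int(row["bin_left"] // 500)
            assert row["mean"] == pytest.approx(direct.loc[b, "mean"])
            assert row["n"] == direct.loc[b, "size"]
        assert np.allclose(out["bin_right"] - out["bin_left"], 500.0)
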