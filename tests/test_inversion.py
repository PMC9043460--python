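"""Sampling, regression fitting/validation and the published equations."""

import numpy as np
import pandas as pd
import pytest

from orasim.inversion import (NormalizationConstants, SweepRanges,
                              fit_inversion, invert_published, load_models,
                              predict_biomechanics, published_models,
                              relaxation_limit, run_sweep, sample_parameters,
                              save_models, validate_inversion)
from orasim.pipeline import SimulationConfig

#: healthy-cohort mean inputs (geometry from tomography, features from the
#: device): R, CCT, bIOP, w1, w2, p1, p2
COHORT = dict(R_mm=7.77, CCT_um=526.1, IOP_mmHg=18.7,
              w1=11.10, w2=15.20, p1_mmHg=17.45, p2_mmHg=10.67)


def _random_feature_table(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "R_mm": rng.uniform(6, 8, n),
        "CCT_um": rng.uniform(450, 650, n),
        "IOP_mmHg": rng.uniform(10, 30, n),
        "w1": rng.uniform(5, 15, n),
        "w2": rng.uniform(10, 25, n),
        "p1_mmHg": rng.uniform(8, 20, n),
        "p2_mmHg": rng.uniform(3, 12, n),
    })


class TestSampling:
    def test_shape_bounds_and_reproducibility(self):
        r = SweepRanges(n_samples=2000, seed=11)
        a = sample_parameters(r)
        b = sample_parameters(r)
        assert a.shape == (2000, 6)
        assert a.equals(b)
        for name in ("R_mm", "CCT_um", "IOP_mmHg", "E_MPa", "a1", "tau1_s"):
            lo, hi = getattr(r, name)
            assert a[name].between(lo, hi).all()

    def test_column_means_approach_midpoints(self):
        r = SweepRanges(n_samples=100_000, seed=3)
        table = sample_parameters(r)
        for name in ("R_mm", "CCT_um", "IOP_mmHg", "E_MPa", "a1", "tau1_s"):
            lo, hi = getattr(r, name)
            mid = 0.5 * (lo + hi)
            assert abs(table[name].mean() - mid) / (hi - lo) < 0.01

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SweepRanges(E_MPa=(0.6, 0.2))


class TestPublishedInversion:
    def test_cohort_means_reproduce_reported_modulus(self):
        p = invert_published(**COHORT)
        assert p.E_MPa == pytest.approx(0.6505988235294118, abs=1e-12)
        assert round(p.E_MPa, 2) == 0.65

    def test_unit_normalized_inputs(self):
        # every normalized ratio equals one -> the coefficient sums
        p = invert_published(R_mm=7.0, CCT_um=550.0, IOP_mmHg=15.0,
                             w1=10.0, w2=17.0, p1_mmHg=10.0, p2_mmHg=5.0)
        assert p.E_MPa == pytest.approx(0.393, abs=1e-12)
        assert p.a1 == pytest.approx(0.351, abs=1e-12)

    def test_double_evaluation_is_bitwise_identical(self):
        a = invert_published(**COHORT)
        b = invert_published(**COHORT)
        assert (a.E_MPa, a.a1, a.tau1_s, a.G_inf) == \
            (b.E_MPa, b.a1, b.tau1_s, b.G_inf)

    def test_modulus_equation_linearity(self):
        """Inverting mean inputs equals the mean of per-row inversions."""
        table = _random_feature_table(64, seed=1)
        rows = invert_published(table["R_mm"].values, table["CCT_um"].values,
                                table["IOP_mmHg"].values, table["w1"].values,
                                table["w2"].values, table["p1_mmHg"].values,
                                table["p2_mmHg"].values)
        mean_in = invert_published(*[float(table[c].mean()) for c in table])
        assert mean_in.E_MPa == pytest.approx(rows["E_MPa"].mean(), abs=1e-12)

    def test_out_of_range_inputs_warn_not_raise(self):
        with pytest.warns(UserWarning, match="sweep range"):
            invert_published(R_mm=9.0, CCT_um=550.0, IOP_mmHg=15.0,
                             w1=10.0, w2=17.0, p1_mmHg=10.0, p2_mmHg=5.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            invert_published(R_mm=-7.0, CCT_um=550.0, IOP_mmHg=15.0,
                             w1=10.0, w2=17.0, p1_mmHg=10.0, p2_mmHg=5.0)

    def test_published_models_reproduce_equation_terms(self):
        models = published_models()
        assert models["E"].provenance == "published"
        coeffs = dict(zip(models["E"].terms, models["E"].coefficients))
        assert coeffs == {"1": 0.323, "R": -0.030, "IOP": -0.018,
                          "w1": -0.034, "w2": -0.078, "p2": 0.230}
        a1_terms = dict(zip(models["a1"].terms, models["a1"].coefficients))
        assert a1_terms["w1^2"] == 0.330 and a1_terms["p2^2"] == 0.075


class TestRelaxationLimit:
    @pytest.mark.parametrize("a, expected", [
        ((0.54, 0.1, 0.1), 0.26),
        ((0.0, 0.0, 0.0), 1.0),
        ((0.4, 0.1, 0.1), 0.4),
    ])
    def test_values(self, a, expected):
        assert relaxation_limit(*a) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            relaxation_limit(0.9, 0.1, 0.1)
        with pytest.raises(ValueError):
            relaxation_limit(-0.1)


class TestFitInversion:
    def _table_from_published(self, n=400, noise=0.0, seed=2):
        feats = _random_feature_table(n, seed=seed)
        truth = invert_published(
            feats["R_mm"].values, feats["CCT_um"].values,
            feats["IOP_mmHg"].values, feats["w1"].values, feats["w2"].values,
            feats["p1_mmHg"].values, feats["p2_mmHg"].values)
        rng = np.random.default_rng(seed + 1)
        table = feats.copy()
        table["E_MPa"] = truth["E_MPa"] + noise * rng.normal(size=n)
        table["a1"] = truth["a1"] + noise * rng.normal(size=n)
        table["tau1_s"] = 10.0 ** (np.log10(truth["tau1_s"] / 0.001)
                                   + noise * rng.normal(size=n)) * 0.001
        return table

    def test_noiseless_recovery_of_generating_coefficients(self):
        """Fitting a table generated exactly by the published equations
        recovers those coefficients (absent terms at zero) to 1e-8."""
        table = self._table_from_published()
        fit = fit_inversion(table, split=0.7, seed=0)
        for target in ("E", "a1", "lgtau1"):
            fitted = dict(zip(fit.models[target].terms,
                              fit.models[target].coefficients))
            published = dict(zip(published_models()[target].terms,
                                 published_models()[target].coefficients))
            for term, value in fitted.items():
                assert value == pytest.approx(published.get(term, 0.0),
                                              abs=1e-8), (target, term)

    def test_noisy_recovery_keeps_high_heldout_r2(self):
        table = self._table_from_published(noise=0.01)
        fit = fit_inversion(table, split=0.7, seed=0)
        metrics = validate_inversion(fit, fit.heldout_predictions)
        for target in ("E", "a1", "lgtau1"):
            assert metrics[target]["r2"] > 0.95

    def test_degenerate_split_rejected(self):
        table = self._table_from_published(n=50)
        with pytest.raises(ValueError, match="held-out"):
            fit_inversion(table, split=1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_inversion(self._table_from_published(n=10))

    def test_rank_deficiency_names_collinear_terms(self):
        table = self._table_from_published(n=200)
        table["CCT_um"] = 550.0  # constant column collides with intercept
        with pytest.raises(np.linalg.LinAlgError, match="CCT"):
            fit_inversion(table, split=0.7, seed=0)

    def test_backward_elimination_drops_noise_terms(self):
        # small noise keeps the OLS p-values well defined
        table = self._table_from_published(n=400, noise=0.005)
        fit = fit_inversion(table, split=0.7, seed=0, eliminate=True)
        kept = set(fit.models["E"].terms)
        assert {"1", "w2", "p2"} <= kept
        assert "CCT" not in kept  # the modulus equation never used CCT

    def test_model_json_roundtrip(self, tmp_path):
        table = self._table_from_published()
        fit = fit_inversion(table, split=0.7, seed=0)
        path = tmp_path / "model.json"
        save_models(fit, path)
        loaded = load_models(path)
        feats = _random_feature_table(10, seed=9)
        out_a = predict_biomechanics(fit, feats)
        out_b = predict_biomechanics(loaded, feats)
        pd.testing.assert_frame_equal(out_a, out_b)


class TestValidateInversion:
    def test_perfect_and_constant_models(self):
        table = TestFitInversion()._table_from_published(n=200)
        fit = fit_inversion(table, split=0.7, seed=0)
        metrics = validate_inversion(fit, fit.heldout_predictions)
        assert metrics["E"]["r2"] == pytest.approx(1.0, abs=1e-9)
        assert metrics["E"]["rmse"] == pytest.approx(0.0, abs=1e-9)
        # a constant predictor cannot beat the mean
        const = published_models()
        const["E"].coefficients = np.zeros_like(const["E"].coefficients)
        const["E"].coefficients[0] = 1.0
        m = validate_inversion(const, table)
        assert m["E"]["r2"] <= 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            validate_inversion(published_models(),
                               _random_feature_table(0))


class TestRunSweep:
    def test_smoke_rows_and_determinism(self):
        """Three scaled-down forward rows: finite features, identical rows
        give identical features."""
        samples = pd.DataFrame({
            "R_mm": [7.0, 7.0, 7.5], "CCT_um": [550.0, 550.0, 500.0],
            "IOP_mmHg": [15.0, 15.0, 20.0], "E_MPa": [0.4, 0.4, 0.3],
            "a1": [0.4, 0.4, 0.5], "tau1_s": [0.003, 0.003, 0.01],
        })
        cfg = SimulationConfig().coarse(n_radial=16, n_thickness=3,
                                        output_frames=101, n_rays=600)
        table = run_sweep(samples, cfg)
        assert (table["status"] == "ok").all()
        cols = ["t1_s", "t2_s", "w1", "w2", "p1_mmHg", "p2_mmHg"]
        assert np.isfinite(table[cols].to_numpy()).all()
        pd.testing.assert_series_equal(table.loc[0, cols], table.loc[1, cols],
                                       check_names=False)

    def test_heldout_modulus_recovery(self, sweep_fit):
        """Forward-simulate known parameters, invert with the fitted model:
        the recovered modulus lands near the set value."""
        _, fit, _ = sweep_fit
        held = fit.heldout_predictions
        rel_err = np.abs(held["E_MPa_pred"] - held["E_MPa"]) / held["E_MPa"]
        assert np.median(rel_err) < 0.2
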