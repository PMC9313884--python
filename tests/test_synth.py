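"""Synthetic-garden generator: distributions, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

import xylophen as xp
from xylophen.synth import SynthConfig, _lognormal


def test_config_validation():
    with pytest.raises(ValueError, match="porosity_mix"):
        SynthConfig(porosity_mix=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="lambda_true"):
        SynthConfig(lambda_true=1.5)
    with pytest.raises(ValueError, match="positive"):
        SynthConfig(diffuse_mean_diam=-1.0)


def test_vessels_zero_cv_degenerate():
    cfg = SynthConfig(diam_cv=0.0, diffuse_mean_diam=20.0)
    d = xp.simulate_vessels(cfg, "diffuse", n=150)
    np.testing.assert_allclose(d, 20.0)


def test_ring_all_earlywood_unimodal():
    cfg = SynthConfig(diam_cv=0.0, earlywood_fraction=1.0,
                      ring_earlywood_mean=55.0)
    d = xp.simulate_vessels(cfg, "ring", n=50)
    np.testing.assert_allclose(d, 55.0)


def test_diffuse_mean_law_of_large_numbers(rng):
    cfg = SynthConfig(diffuse_mean_diam=20.0, diam_cv=0.2)
    d = xp.simulate_vessels(cfg, "diffuse", n=10_000, rng=rng)
    assert d.mean() == pytest.approx(20.0, rel=0.01)
    assert (d > 0).all()


def test_unknown_porosity_rejected():
    with pytest.raises(ValueError, match="porosity"):
        xp.simulate_vessels(SynthConfig(), "vortex")


def test_diffuse_minimum_vessel_count():
    with pytest.raises(ValueError, match="at least 100"):
        xp.simulate_vessels(SynthConfig(), "diffuse", n=50)


def test_ring_exceeds_diffuse_over_threshold(rng):
    cfg = SynthConfig()
    ring = xp.pct_over_threshold(xp.simulate_vessels(cfg, "ring", n=2000, rng=rng))
    diff = xp.pct_over_threshold(xp.simulate_vessels(cfg, "diffuse", n=2000, rng=rng))
    assert ring > diff


def test_seed_reproducibility_byte_identical(tmp_path):
    cfg = SynthConfig(n_species=8, n_stems_per_species=2, seed=11)
    for sub in ("a", "b"):
        xp.simulate_garden(cfg).write(tmp_path / sub)
    for name in ("vessels.csv", "traits.csv", "weather.csv", "areas.csv",
                 "tree.nwk", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_outputs_strictly_positive():
    g = xp.simulate_garden(SynthConfig(n_species=10, seed=3))
    assert (g.vessels["diameter_um"] > 0).all()
    assert (g.traits["height_m"] > 0).all()
    assert (g.traits["leafout_gdd"] > 0).all()


def test_traits_noise_free_linear():
    cfg = SynthConfig(n_species=12, resid_sd=0.0, seed=5)
    g = xp.simulate_garden(cfg)
    fit = xp.ols_fit(g.traits["leafout_gdd"], g.traits["mean_vessel_diameter"])
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(fit.params, [cfg.beta0, cfg.beta1], rtol=1e-10)


def test_lambda_zero_residuals_independent():
    # with lambda_true=0 residual covariance is diagonal: the residual vector
    # equals resid_sd * z with iid z, regardless of the tree
    cfg = SynthConfig(n_species=40, lambda_true=0.0, resid_sd=50.0, seed=9)
    tree = xp.simulate_tree(cfg, np.random.default_rng(0))
    traits, truth = xp.simulate_traits(cfg, tree, np.random.default_rng(1))
    resid = (traits["leafout_gdd"]
             - cfg.beta0 - cfg.beta1 * traits["mean_vessel_diameter"])
    # compare with the same generator stream drawn manually
    assert abs(resid.mean()) < 50.0  # sanity: centered noise
    assert resid.std() == pytest.approx(50.0, rel=0.35)


def test_truth_sidecar_separate_from_tables(tmp_path):
    g = xp.simulate_garden(SynthConfig(n_species=6, seed=2))
    g.write(tmp_path)
    traits = pd.read_csv(tmp_path / "traits.csv")
    assert "beta1" not in traits.columns
    import json
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["beta1"] == g.config.beta1
    assert truth["lambda_true"] == g.config.lambda_true


def test_tree_unit_depth_and_tip_count():
    cfg = SynthConfig(n_species=25, seed=7)
    tree = xp.simulate_tree(cfg)
    V, labels = xp.vcv_matrix(tree)
    assert len(labels) == 25
    np.testing.assert_allclose(np.diag(V), 1.0, atol=1e-9)
    assert np.linalg.eigvalsh(V).min() > 0


def test_weather_zero_noise_identical_years():
    cfg = SynthConfig(n_weather_years=3, weather_noise_sd=0.0, seed=4)
    w = xp.simulate_weather(cfg)
    years = [w[w["year"] == y]["tmean_c"].to_numpy() for y in w["year"].unique()]
    np.testing.assert_allclose(years[0], years[1])
    np.testing.assert_allclose(years[0], years[2])
    # deep winter is below freezing in every year
    jan = w[w["doy"] <= 15]
    assert (jan["tmin_c"] < 0).all()


def test_weather_frost_frequency_matches_construction(rng):
    # with Gaussian noise around a known seasonal mean, the per-day frost
    # frequency across many years should track the analytic probability
    cfg = SynthConfig(n_weather_years=200, weather_noise_sd=3.0, seed=6)
    w = xp.simulate_weather(cfg)
    from scipy import stats as ss
    day = 110
    sub = w[w["doy"] == day]
    mu = (cfg.weather_tmid - cfg.weather_amp * np.cos(2 * np.pi * (day - 15) / 365)
          - cfg.tmin_offset)
    sd = np.sqrt(cfg.weather_noise_sd ** 2 + (cfg.weather_noise_sd / 2) ** 2)
    p_frost = ss.norm.cdf(0.0, loc=mu, scale=sd)
    observed = (sub["tmin_c"] <= 0).mean()
    ci = 3 * np.sqrt(p_frost * (1 - p_frost) / len(sub))
    assert abs(observed - p_frost) <= max(ci, 0.01)


def test_lognormal_mean_cv_parameterization(rng):
    d = _lognormal(rng, 30.0, 0.4, 200_000)
    assert d.mean() == pytest.approx(30.0, rel=0.01)
    assert d.std() / d.mean() == pytest.approx(0.4, rel=0.02)
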