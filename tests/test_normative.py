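"""Fitting, site adaptation, scoring and centiles of the normative model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normdev.cohort_sim import shash_noise
from normdev.dataio import ROIDataset
from normdev.normative import (
    BasisSpec,
    NormativeModelParams,
    WarpParams,
    _design,
    adapt_to_site,
    compute_zscores,
    fit_models,
    fit_normative_model,
    load_models,
    predict_centiles,
    predictive_logpdf,
    save_models,
    score_dataset,
)
from conftest import make_linear_dataset


def dataset_from_arrays(y, age, site="A", modality="thickness", **cov_extra):
    n = len(y)
    idx = pd.Index([f"s{i:05d}" for i in range(n)], name="subject_id")
    values = pd.DataFrame({"roi1": np.asarray(y, float)}, index=idx)
    site_col = np.full(n, site) if isinstance(site, str) else np.asarray(site)
    cov = pd.DataFrame(
        {"age": np.asarray(age, float), "sex": "M", "site": site_col, "group": "REF",
         "icv_mm3": np.nan, "pclr_total": np.nan},
        index=idx,
    )
    return ROIDataset(modality, values, cov)


def test_noiseless_linear_data_recovered_exactly():
    rng = np.random.default_rng(0)
    age = rng.uniform(10, 80, 200)
    y = 2.0 + 0.5 * age
    ds = dataset_from_arrays(y, age)
    model = fit_normative_model(ds, "roi1", warp_mode="identity", seed=0)
    Psi = _design(age, ds.covariates["site"], model.knots, model.basis.degree,
                  model.train_sites)
    pred = Psi @ model.w_mean
    assert np.max(np.abs(pred - y)) < 1e-6


def test_identity_warp_fit_equals_bayesian_ridge_oracle():
    rng = np.random.default_rng(1)
    for rep in range(3):
        age = rng.uniform(5, 90, 250)
        site = rng.choice(["A", "B"], 250)
        y = 1.0 + 0.02 * age + 0.3 * (site == "B") + 0.2 * rng.standard_normal(250)
        ds = dataset_from_arrays(y, age, site=site)
        model = fit_normative_model(ds, "roi1", warp_mode="identity", seed=rep)
        Psi = _design(age, ds.covariates["site"], model.knots, model.basis.degree,
                      model.train_sites)
        lam = model.alpha / model.beta
        w_oracle = np.linalg.solve(Psi.T @ Psi + lam * np.eye(Psi.shape[1]), Psi.T @ y)
        np.testing.assert_allclose(model.w_mean, w_oracle, atol=1e-6)


def test_warped_fit_beats_identity_on_skewed_data():
    wins = 0
    reps = 5
    for rep in range(reps):
        rng = np.random.default_rng(100 + rep)
        n = 2000
        age = rng.uniform(10, 80, n)
        eta = rng.standard_normal(n)
        y = 2.5 - 0.01 * age + 0.15 * shash_noise(eta, 0.5, 1.3)
        train = dataset_from_arrays(y[: n // 2], age[: n // 2])
        test = dataset_from_arrays(y[n // 2:], age[n // 2:])
        shash = fit_normative_model(train, "roi1", warp_mode="shash", seed=rep)
        ident = fit_normative_model(train, "roi1", warp_mode="identity", seed=rep)
        if predictive_logpdf(shash, test).sum() > predictive_logpdf(ident, test).sum():
            wins += 1
    assert wins >= 4


def test_adaptation_null_and_offset_recovery():
    rng = np.random.default_rng(3)
    n = 400
    sigma = 0.2
    age = rng.uniform(10, 80, n)
    y = 1.5 + 0.01 * age + sigma * rng.standard_normal(n)
    train = dataset_from_arrays(y, age, site="A")
    model = fit_normative_model(train, "roi1", warp_mode="identity", seed=0)
    # null site: same generative law, new label
    age2 = rng.uniform(10, 80, 200)
    y2 = 1.5 + 0.01 * age2 + sigma * rng.standard_normal(200)
    null_site = dataset_from_arrays(y2, age2, site="NEW")
    anull = adapt_to_site(model, null_site)
    assert abs(anull.mu) < 3.0 / np.sqrt(200)
    assert abs(anull.rho - 1.0) < 0.15
    # site with +0.3 offset in measurement units
    y3 = 1.5 + 0.01 * age2 + 0.3 + sigma * rng.standard_normal(200)
    off_site = dataset_from_arrays(y3, age2, site="OFF")
    aoff = adapt_to_site(model, off_site)
    sd_pred = np.sqrt(1.0 / model.beta)
    assert aoff.mu == pytest.approx(0.3 / sd_pred, abs=4.0 / np.sqrt(200))
    assert aoff.n == 200
    with pytest.raises(ValueError, match="minimum"):
        adapt_to_site(model, dataset_from_arrays(y3[:5], age2[:5], site="TINY"))


def test_zscore_is_definitional_under_known_model():
    # identity warp, flat mean 1.0, unit noise precision, no weight uncertainty
    knots = np.array([0.0] * 4 + [100.0] * 4)
    m = 1 + 3  # intercept + 3 remaining spline columns
    model = NormativeModelParams(
        roi="roi1", modality="thickness",
        w_mean=np.array([1.0, 0.0, 0.0, 0.0]),
        w_cov=np.zeros((m, m)),
        alpha=1.0, beta=1.0,
        warp_params=WarpParams(),
        basis=BasisSpec(degree=3, n_interior_knots=0),
        knots=knots, train_sites=["A"], age_range=(0.0, 100.0),
    )
    sd_pred = 1.0
    ds = dataset_from_arrays([1.0 + 2.0 * sd_pred], [50.0], site="A")
    z = compute_zscores(model, None, ds)
    assert z.iloc[0] == pytest.approx(2.0, abs=1e-10)
    # unknown site without adaptation points the user to adapt_to_site
    ds_new = dataset_from_arrays([1.0], [50.0], site="ELSEWHERE")
    with pytest.raises(KeyError, match="adapt_to_site"):
        compute_zscores(model, None, ds_new)


def test_heldout_tail_probability_matches_gaussian_oracle():
    rng = np.random.default_rng(4)
    n = 3000
    age = rng.uniform(10, 80, n)
    y = 2.0 + 0.005 * age + 0.1 * rng.standard_normal(n)
    train = dataset_from_arrays(y[:1000], age[:1000])
    model = fit_normative_model(train, "roi1", warp_mode="identity", seed=0)
    held = dataset_from_arrays(y[1000:], age[1000:])
    z = compute_zscores(model, None, held)
    frac = float((z < -2).mean())
    p = stats.norm.cdf(-2)
    lo, hi = np.array(stats.binom.interval(0.999, 2000, p)) / 2000
    assert lo <= frac <= hi


def test_serialization_round_trip_bit_identical(tmp_path, reference_cohort):
    data, _ = reference_cohort
    ds = data["thickness"]
    rois = ds.roi_names[:2]
    models = fit_models(ds, rois=rois, seed=0)
    dev_mem = score_dataset(models, None, ds)
    save_models(tmp_path, models)
    loaded, adaptations = load_models(tmp_path, "thickness")
    dev_disk = score_dataset(loaded, None, ds)
    assert (dev_mem.zscores.to_numpy() == dev_disk.zscores.to_numpy()).all()


def test_centiles_median_equals_mean_and_monotone():
    rng = np.random.default_rng(5)
    age = rng.uniform(10, 80, 300)
    y = 2.0 + 0.01 * age + 0.1 * rng.standard_normal(300)
    ds = dataset_from_arrays(y, age)
    model = fit_normative_model(ds, "roi1", warp_mode="identity", seed=0)
    grid = np.linspace(15, 75, 20)
    cent = predict_centiles(model, None, grid, [0.025, 0.5, 0.975])
    Psi = _design(grid, None, model.knots, model.basis.degree, model.train_sites)
    np.testing.assert_allclose(cent[0.5].to_numpy(), Psi @ model.w_mean, atol=1e-10)
    assert (cent[0.975].to_numpy() > cent[0.025].to_numpy()).all()
    with pytest.raises(ValueError):
        predict_centiles(model, None, grid, [])
    with pytest.raises(ValueError):
        predict_centiles(model, None, grid, [0.0, 0.5])


def test_centile_band_coverage_under_generative_truth():
    rng = np.random.default_rng(6)
    n = 6000
    age = rng.uniform(10, 80, n)
    eta = rng.standard_normal(n)
    y = 2.5 - 0.005 * age + 0.12 * shash_noise(eta, 0.3, 1.2)
    train = dataset_from_arrays(y[:1000], age[:1000])
    model = fit_normative_model(train, "roi1", warp_mode="shash", seed=0)
    held_age = age[1000:]
    held_y = y[1000:]
    cent = predict_centiles(model, None, held_age, [0.025, 0.975])
    inside = (held_y > cent[0.025].to_numpy()) & (held_y < cent[0.975].to_numpy())
    assert 0.94 <= inside.mean() <= 0.96


def test_rank_deficient_basis_reported():
    rng = np.random.default_rng(7)
    age = rng.choice([30.0, 60.0], 200)  # two ages cannot support a 5-knot cubic
    y = rng.standard_normal(200)
    ds = dataset_from_arrays(y, age)
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
        fit_normative_model(ds, "roi1", warp_mode="identity", seed=0)


def test_extrapolation_warns_but_scores(caplog):
    ds = make_linear_dataset(n=200, seed=8)
    model = fit_normative_model(ds, "roi1", warp_mode="identity", seed=0)
    out_of_range = dataset_from_arrays([2.0 + 0.5 * 95.0], [95.0], site="A")
    with caplog.at_level("WARNING"):
        z = compute_zscores(model, None, out_of_range)
    assert np.isfinite(z.iloc[0])
    assert any("extrapolat" in r.getMessage() for r in caplog.records)
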