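"""Permutation GLM, matching, effect sizes and multiplicity correction,
checked against brute-force/enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normdev.inference import (
    DesignMatrix,
    burden_permutation_test,
    cohens_d,
    correct_multiplicity,
    group_contrast_design,
    permutation_glm,
    propensity_match,
    trait_association,
    westfall_young,
)
from normdev.normative import DeviationMatrix


def two_group_design(labels, nuisance=None):
    ind = (np.asarray(labels) == 1).astype(float).reshape(-1, 1)
    nuis = np.empty((len(labels), 0)) if nuisance is None else np.asarray(nuisance)
    return DesignMatrix(interest=ind, nuisance=nuis, contrast=np.array([1.0]))


def test_zero_variance_outcome_gives_t0_p1():
    labels = np.array([1, 1, 1, 0, 0, 0])
    y = np.ones(6)
    res = permutation_glm(y, two_group_design(labels), exact=True)
    assert res.t[0] == 0.0
    assert res.p_unc[0] == 1.0


def oracle_exhaustive_glm_p(y, labels, nuisance):
    """Enumeration oracle: Freedman-Lane by hand with statsmodels-free OLS."""
    n = len(y)
    ind = (labels == 1).astype(float)
    X = np.column_stack([ind, nuisance])
    X = X - X.mean(0)
    yc = y - y.mean()

    def tstat(yv):
        XtXi = np.linalg.inv(X.T @ X)
        b = XtXi @ X.T @ yv
        r = yv - X @ b
        s2 = (r @ r) / (n - X.shape[1] - 1)
        return b[0] / np.sqrt(s2 * XtXi[0, 0])

    N = nuisance - nuisance.mean(0)
    resid = yc - N @ np.linalg.lstsq(N, yc, rcond=None)[0]
    t_obs = abs(tstat(yc))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        t_p = abs(tstat(resid[list(perm)]))
        if t_p >= t_obs - 1e-10:
            count += 1
        total += 1
    return count / total


def test_exhaustive_permutation_matches_enumeration_oracle():
    rng = np.random.default_rng(17)
    labels = np.array([1, 1, 1, 0, 0, 0])
    y = rng.standard_normal(6) + 0.8 * labels
    nuis = rng.standard_normal((6, 1))
    res = permutation_glm(y, two_group_design(labels, nuis), exact=True)
    expected = oracle_exhaustive_glm_p(y, labels, nuis)
    assert res.p_unc[0] == pytest.approx(expected, abs=1e-12)


def test_permutation_reproducible_and_seed_sensitive():
    rng = np.random.default_rng(18)
    labels = np.repeat([1, 0], 20)
    y = rng.standard_normal((40, 3))
    d = two_group_design(labels)
    r1 = permutation_glm(y, d, n_perm=200, seed=5)
    r2 = permutation_glm(y, d, n_perm=200, seed=5)
    np.testing.assert_array_equal(r1.p_unc, r2.p_unc)
    r3 = permutation_glm(y, d, n_perm=200, seed=6)
    assert not np.array_equal(r1.p_unc, r3.p_unc)


def test_cohens_d_conventions():
    assert cohens_d(0.0, 10, 12) == 0.0
    assert cohens_d(2.0, 50, 50) == pytest.approx(0.4)
    # matches classic pooled-sd d for a plain two-sample comparison
    rng = np.random.default_rng(19)
    n = 30
    y = np.concatenate([rng.standard_normal(n) + 0.5, rng.standard_normal(n)])
    labels = np.repeat([1, 0], n)
    res = permutation_glm(y, two_group_design(labels), n_perm=100, seed=0)
    d_from_t = cohens_d(res.t[0], n, n)
    m1, m0 = y[:n].mean(), y[n:].mean()
    sp = np.sqrt(((n - 1) * y[:n].var(ddof=1) + (n - 1) * y[n:].var(ddof=1)) / (2 * n - 2))
    assert d_from_t == pytest.approx((m1 - m0) / sp, abs=1e-10)


def test_bh_correction_hand_example():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(correct_multiplicity(p), [0.04, 0.04, 0.04, 0.04])
    assert correct_multiplicity(np.array([0.2]))[0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        correct_multiplicity(np.array([]))


def test_westfall_young_bounds_and_order():
    rng = np.random.default_rng(20)
    labels = np.repeat([1, 0], 15)
    y = rng.standard_normal((30, 10))
    y[:, 0] += labels * 2.0
    res = permutation_glm(y, two_group_design(labels), n_perm=300, seed=1, return_null=True)
    p_fwe = westfall_young(res.t, res.t_null)
    assert np.all(p_fwe >= res.p_unc - 1e-12)
    assert np.all((p_fwe > 0) & (p_fwe <= 1))
    assert p_fwe[0] == p_fwe.min()


def test_burden_test_identical_groups_p_near_one():
    counts = np.tile([3, 1, 4, 1, 5], 2)
    labels = np.repeat(["A", "B"], 5)
    stat, p = burden_permutation_test(counts, labels, "A", "B", n_perm=200, seed=0)
    assert stat == 0.0
    assert p > 0.5


def test_burden_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(21)
    counts = rng.poisson(3.0, 8).astype(float)
    counts[:4] += 2
    labels = np.repeat(["A", "B"], 4)
    stat, p = burden_permutation_test(counts, labels, "A", "B", exact=True)
    # oracle: enumerate all C(8,4) assignments
    obs = counts[:4].mean() - counts[4:].mean()
    hits = total = 0
    for combo in itertools.combinations(range(8), 4):
        a = np.zeros(8, bool)
        a[list(combo)] = True
        if counts[a].mean() - counts[~a].mean() >= obs - 1e-10:
            hits += 1
        total += 1
    assert total == 70
    assert p == pytest.approx(hits / 70, abs=1e-12)
    assert stat == pytest.approx(obs)


def test_burden_degenerate_counts_warns_p1():
    counts = np.ones(10)
    labels = np.repeat(["A", "B"], 5)
    with pytest.warns(UserWarning, match="degenerate"):
        stat, p = burden_permutation_test(counts, labels, "A", "B", n_perm=100, seed=0)
    assert p == 1.0


def _violence_covariates(n, rng):
    idx = pd.Index([f"v{i}" for i in range(n)], name="subject_id")
    return pd.DataFrame(
        {
            "age": rng.normal(37, 11, n),
            "sex": "M",
            "site": "T1",
            "group": rng.choice(["SSD-V", "nonSSD-V"], n, p=[0.65, 0.35]),
            "icv_mm3": rng.normal(1.55e6, 1.3e5, n),
            "pclr_total": np.clip(rng.normal(19.5, 8.0, n), 0, 40),
        },
        index=idx,
    )


def test_trait_association_null_p_values_uniform():
    rng = np.random.default_rng(22)
    n, m = 58, 327
    cov = _violence_covariates(n, rng)
    Z = pd.DataFrame(rng.standard_normal((n, m)), index=cov.index,
                     columns=[f"r{j}" for j in range(m)])
    dev = DeviationMatrix(zscores=Z, modality="thickness")
    res = trait_association(dev, cov, "thickness", n_perm=499, seed=3)
    assert stats.kstest(res.p_unc, "uniform").pvalue > 0.01


def test_trait_association_requires_enough_pclr():
    rng = np.random.default_rng(23)
    cov = _violence_covariates(8, rng)
    Z = pd.DataFrame(rng.standard_normal((8, 3)), index=cov.index, columns=list("abc"))
    dev = DeviationMatrix(zscores=Z, modality="thickness")
    with pytest.raises(ValueError, match="PCL-R"):
        trait_association(dev, cov, "thickness", n_perm=100, seed=0)


def test_icv_enters_design_only_for_area_and_volume():
    rng = np.random.default_rng(24)
    cov = _violence_covariates(40, rng)
    design_a, _ = group_contrast_design(
        cov.assign(group=np.repeat(["SSD-V", "nonSSD-V"], 20)), "SSD-V", "nonSSD-V",
        include_icv=True,
    )
    design_t, _ = group_contrast_design(
        cov.assign(group=np.repeat(["SSD-V", "nonSSD-V"], 20)), "SSD-V", "nonSSD-V",
        include_icv=False,
    )
    assert design_a.nuisance.shape[1] == design_t.nuisance.shape[1] + 1
    assert "icv" in design_a.names


def make_match_frames(rng, n_cases=30, n_controls=120, age_shift=0.0):
    cases = pd.DataFrame(
        {"age": rng.normal(40 + age_shift, 8, n_cases),
         "site": rng.choice(["T1", "T2"], n_cases)},
        index=[f"c{i}" for i in range(n_cases)],
    )
    controls = pd.DataFrame(
        {"age": rng.normal(40, 8, n_controls),
         "site": rng.choice(["T1", "T2"], n_controls)},
        index=[f"k{i}" for i in range(n_controls)],
    )
    return cases, controls


def test_matching_one_to_one_without_reuse():
    rng = np.random.default_rng(25)
    cases, controls = make_match_frames(rng)
    result = propensity_match(cases, controls)
    assert len(result.pairs) == len(cases)
    assert result.pairs["control_id"].is_unique
    assert set(result.pairs["case_id"]) == set(cases.index)


def test_matching_identical_covariates_zero_distance():
    cases = pd.DataFrame({"age": [30.0, 40.0], "site": ["T1", "T1"]}, index=["c0", "c1"])
    controls = pd.DataFrame(
        {"age": [30.0, 40.0, 50.0], "site": ["T1", "T1", "T1"]}, index=["k0", "k1", "k2"]
    )
    result = propensity_match(cases, controls)
    matched = result.pairs.set_index("case_id")["control_id"]
    assert matched["c0"] == "k0" and matched["c1"] == "k1"
    assert (result.pairs["distance"] < 1e-6).all()


def test_matching_greedy_equals_brute_force_oracle():
    # hand-set ages produce distinct propensities; oracle replays greedy
    cases = pd.DataFrame({"age": [50.0, 44.0, 38.0]}, index=["c0", "c1", "c2"])
    controls = pd.DataFrame({"age": [36.0, 39.0, 45.0, 49.0, 60.0]},
                            index=[f"k{i}" for i in range(5)])
    result = propensity_match(cases, controls, covariates=("age",))
    # oracle: logistic distance is monotone in age here, so greedy on raw age
    order = np.argsort(-cases["age"].to_numpy())
    avail = set(controls.index)
    expected = {}
    for i in order:
        cid = cases.index[i]
        best = min(avail, key=lambda k: abs(controls.loc[k, "age"] - cases.loc[cid, "age"]))
        avail.discard(best)
        expected[cid] = best
    got = dict(zip(result.pairs["case_id"], result.pairs["control_id"]))
    assert got == expected


def test_matching_improves_age_balance():
    rng = np.random.default_rng(26)
    cases, controls = make_match_frames(rng, age_shift=6.0)
    result = propensity_match(cases, controls)
    bal = result.balance.set_index("covariate")
    assert abs(bal.loc["age", "smd_pre"]) > 0.5
    assert abs(bal.loc["age", "smd_post"]) < 0.1


def test_rank_deficient_design_names_columns():
    x = np.repeat([1.0, 0.0], 10)
    with pytest.raises(np.linalg.LinAlgError, match="col"):
        DesignMatrix(interest=x.reshape(-1, 1), nuisance=x.reshape(-1, 1),
                     contrast=np.array([1.0]), names=["group", "copy"])
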