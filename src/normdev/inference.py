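"""Group-difference and trait-association inference on deviation scores.

Implements the study's statistical battery: 1:1 propensity matching on
age and site (logistic-regression distance), permutation GLMs with the
Freedman-Lane scheme for nuisance covariates, Cohen's d effect sizes,
nested multiplicity correction over regions / contrasts / modalities
(Benjamini-Hochberg FDR by default, max-statistic Westfall-Young FWE as
an alternative), one-sided permutation tests on per-individual extreme
deviation burden, and PCL-R trait association.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from ._rng import stream

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "PermutationResult",
    "MatchResult",
    "propensity_match",
    "permutation_glm",
    "cohens_d",
    "correct_multiplicity",
    "westfall_young",
    "burden_permutation_test",
    "trait_association",
    "group_contrast_design",
]


# ---------------------------------------------------------------------------
# design matrices


def _demean(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


@dataclass
class DesignMatrix:
    """Permutation-GLM design: interest regressors (tested), nuisance
    regressors (Freedman-Lane), and a contrast over interest columns.

    All columns and the outcome are demeaned before testing, so no
    explicit intercept enters the model (one residual df is charged for
    it).
    """

    interest: np.ndarray
    nuisance: np.ndarray
    contrast: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.interest = np.atleast_2d(np.asarray(self.interest, dtype=float))
        if self.interest.shape[0] == 1 and self.interest.shape[1] > 1:
            self.interest = self.interest.T
        n = self.interest.shape[0]
        self.nuisance = np.asarray(self.nuisance, dtype=float).reshape(n, -1)
        self.contrast = np.asarray(self.contrast, dtype=float).ravel()
        if self.contrast.shape[0] != self.interest.shape[1]:
            raise ValueError("contrast length must equal number of interest columns")
        self.interest = _demean(self.interest)
        if self.nuisance.size:
            self.nuisance = _demean(self.nuisance)
        X = self.full
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0)).tolist()
            names = [self.names[i] if i < len(self.names) else f"col{i}" for i in bad]
            raise np.linalg.LinAlgError(f"design matrix is rank deficient; columns {names}")

    @property
    def full(self) -> np.ndarray:
        return np.hstack([self.interest, self.nuisance]) if self.nuisance.size else self.interest

    @property
    def n(self) -> int:
        return self.interest.shape[0]


def group_contrast_design(
    covariates: pd.DataFrame,
    group_a: str,
    group_b: str,
    include_icv: bool = False,
) -> tuple[DesignMatrix, pd.Index]:
    """Design for the contrast group_a > group_b with age (and optional
    ICV) as Freedman-Lane nuisance covariates.

    Subjects missing ICV are excluded when ICV is a covariate (area and
    volume modalities), with a logged count.  Returns the design and the
    subject index it covers.
    """
    mask = covariates["group"].isin([group_a, group_b])
    sub = covariates.loc[mask]
    if include_icv:
        has = sub["icv_mm3"].notna()
        if (~has).any():
            logger.info("excluding %d subject(s) without ICV", int((~has).sum()))
        sub = sub.loc[has]
    indicator = (sub["group"] == group_a).to_numpy(dtype=float)
    nuis = [sub["age"].to_numpy(dtype=float)]
    names = [f"{group_a}>{group_b}", "age"]
    if include_icv:
        nuis.append(sub["icv_mm3"].to_numpy(dtype=float))
        names.append("icv")
    design = DesignMatrix(
        interest=indicator.reshape(-1, 1),
        nuisance=np.column_stack(nuis),
        contrast=np.array([1.0]),
        names=names,
    )
    return design, sub.index


# ---------------------------------------------------------------------------
# permutation GLM (Freedman-Lane)


@dataclass
class PermutationResult:
    """Per-region t, Cohen's d and permutation p-values for one contrast."""

    roi_names: list[str]
    t: np.ndarray
    p_unc: np.ndarray
    n_perm: int
    seed: int | None
    df: int
    t_null: np.ndarray | None = field(default=None, repr=False)
    cohens_d: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"roi": self.roi_names, "t": self.t, "p_unc": self.p_unc})
        if self.cohens_d is not None:
            out["cohens_d"] = self.cohens_d
        out["n_perm"] = self.n_perm
        return out


def _tstats(X: np.ndarray, Y: np.ndarray, contrast: np.ndarray, df: int) -> np.ndarray:
    """OLS t statistics for one contrast, vectorized over outcome columns."""
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c_var = float(contrast @ XtX_inv @ contrast)
    num = contrast @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(sigma2 * c_var)
    return np.where(np.isfinite(t), t, 0.0)


def _count_ge(t_null_abs: np.ndarray, t_abs: np.ndarray) -> np.ndarray:
    # tie-tolerant >= (identity permutation reproduces t up to rounding)
    tol = 1e-12 + 1e-10 * t_abs
    return (t_null_abs >= t_abs - tol).sum(axis=0)


def permutation_glm(
    Y: pd.DataFrame | np.ndarray,
    design: DesignMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    two_sided: bool = True,
    exact: bool = False,
    return_null: bool = False,
) -> PermutationResult:
    """Permutation GLM for one contrast over many regions.

    The observed t comes from OLS on the demeaned design; the null is
    built with the Freedman-Lane scheme: residualize the outcome on the
    nuisance regressors, permute those residuals, refit the full model.
    ``exact=True`` enumerates every permutation (feasible for n <= 9)
    and returns the exhaustive p; otherwise p_unc uses the add-one
    Monte-Carlo estimator (1 + #{|t*| >= |t|}) / (1 + n_perm).
    """
    if isinstance(Y, pd.DataFrame):
        roi_names = list(Y.columns)
        Ymat = Y.to_numpy(dtype=float)
    else:
        Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
        if Ymat.shape[0] == 1:
            Ymat = Ymat.T
        roi_names = [f"y{j}" for j in range(Ymat.shape[1])]
    n = design.n
    if Ymat.shape[0] != n:
        raise ValueError(f"outcome has {Ymat.shape[0]} rows but design has {n}")
    if not exact and n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or use exact=True)")
    Ymat = _demean(Ymat)
    X = design.full
    k = X.shape[1]
    df = n - k - 1  # one df charged for the implicit intercept (demeaning)
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    contrast_full = np.concatenate(
        [design.contrast, np.zeros(X.shape[1] - design.contrast.shape[0])]
    )
    t_obs = _tstats(X, Ymat, contrast_full, df)

    # Freedman-Lane residual-forming matrix for the nuisance block
    if design.nuisance.size:
        N = design.nuisance
        Rz = Ymat - N @ np.linalg.lstsq(N, Ymat, rcond=None)[0]
    else:
        Rz = Ymat

    if exact:
        if n > 9:
            raise ValueError(f"exact enumeration infeasible for n={n}")
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = stream(seed, "inference/permutation_glm")
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    t_null = np.empty((len(perms), Ymat.shape[1]))
    for i, p in enumerate(perms):
        t_null[i] = _tstats(X, Rz[p], contrast_full, df)

    if two_sided:
        count = _count_ge(np.abs(t_null), np.abs(t_obs))
    else:
        tol = 1e-12 + 1e-10 * np.abs(t_obs)
        count = (t_null >= t_obs - tol).sum(axis=0)
    if exact:
        p_unc = count / len(perms)
    else:
        p_unc = (1.0 + count) / (1.0 + len(perms))
    return PermutationResult(
        roi_names=roi_names,
        t=t_obs,
        p_unc=p_unc,
        n_perm=len(perms),
        seed=None if exact else seed,
        df=df,
        t_null=t_null if return_null else None,
    )


def cohens_d(t: np.ndarray | float, n1: int, n2: int) -> np.ndarray | float:
    """Effect size from the contrast t statistic: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    return np.asarray(t, dtype=float) * math.sqrt(1.0 / n1 + 1.0 / n2)


# ---------------------------------------------------------------------------
# multiplicity correction


def correct_multiplicity(p_unc: np.ndarray, method: str = "bh") -> np.ndarray:
    """Correct a pooled family of p-values.

    'bh' applies Benjamini-Hochberg step-up FDR over the pool.  Nested
    tiers (regions; regions x contrasts; regions x contrasts x
    modalities) are realized by pooling the corresponding family before
    calling.
    """
    p_unc = np.asarray(p_unc, dtype=float)
    if p_unc.size == 0:
        raise ValueError("empty p-value pool")
    if method == "bh":
        return multipletests(p_unc, method="fdr_bh")[1]
    raise ValueError(f"unknown correction method {method!r}")


def westfall_young(t: np.ndarray, t_null: np.ndarray) -> np.ndarray:
    """Max-statistic familywise-corrected p-values.

    ``t_null`` is the (n_perm, n_tests) null matrix from a common
    permutation scheme; each test's FWE p is the add-one proportion of
    permutations whose max |t*| across the family reaches its |t|.
    """
    t = np.abs(np.asarray(t, dtype=float))
    max_null = np.abs(t_null).max(axis=1, keepdims=True)
    count = _count_ge(max_null, t)
    return (1.0 + count) / (1.0 + t_null.shape[0])


# ---------------------------------------------------------------------------
# burden permutation test


def burden_permutation_test(
    counts: np.ndarray,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
    direction: str = "greater",
    n_perm: int = 10000,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """One-sided permutation test on per-individual burden counts.

    Statistic: mean(group_a) - mean(group_b).  direction='greater' tests
    whether group_a carries more extreme deviations than group_b.
    Returns (statistic, p).  ``exact=True`` enumerates all label
    assignments (feasible for small groups).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    labels = np.asarray(labels)
    counts = np.asarray(counts, dtype=float)
    sel = np.isin(labels, [group_a, group_b])
    counts, labels = counts[sel], labels[sel]
    n1 = int((labels == group_a).sum())
    if n1 == 0 or n1 == len(labels):
        raise ValueError("both groups must be non-empty")
    sign = 1.0 if direction == "greater" else -1.0
    raw = counts[labels == group_a].mean() - counts[labels == group_b].mean()
    stat = sign * raw
    if np.ptp(counts) == 0:
        warnings.warn("all burden counts identical; permutation test degenerate, p = 1")
        return float(raw), 1.0
    n = len(counts)
    tol = 1e-12 + 1e-10 * abs(stat)
    if exact:
        total = math.comb(n, n1)
        if total > 2_000_000:
            raise ValueError(f"exact enumeration infeasible: C({n},{n1}) = {total}")
        count_ge = 0
        idx = np.arange(n)
        for combo in itertools.combinations(idx, n1):
            a = np.zeros(n, dtype=bool)
            a[list(combo)] = True
            s = sign * (counts[a].mean() - counts[~a].mean())
            if s >= stat - tol:
                count_ge += 1
        return float(raw), count_ge / total
    rng = stream(seed, "inference/burden_permutation")
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a = np.zeros(n, dtype=bool)
        a[perm[:n1]] = True
        s = sign * (counts[a].mean() - counts[~a].mean())
        if s >= stat - tol:
            count_ge += 1
    return float(raw), (1.0 + count_ge) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# trait association


def trait_association(
    dev,
    covariates: pd.DataFrame,
    modality: str,
    n_perm: int = 10000,
    seed: int = 0,
    min_n: int = 10,
    return_null: bool = False,
) -> PermutationResult:
    """Association between PCL-R psychopathy totals and deviation scores.

    Restricted to subjects with a PCL-R score (the violence groups); the
    PCL-R regressor is tested with age, psychosis status (SSD diagnosis
    indicator) and - for area and volume - ICV as nuisance covariates.
    """
    cov = covariates.loc[dev.zscores.index]
    has = cov["pclr_total"].notna()
    include_icv = modality in ("area", "volume")
    if include_icv:
        has &= cov["icv_mm3"].notna()
    n = int(has.sum())
    if n < min_n:
        raise ValueError(f"only {n} subjects with PCL-R (and required covariates); need >= {min_n}")
    cov = cov.loc[has]
    Z = dev.zscores.loc[has]
    psychosis = cov["group"].isin(["SSD-V", "SSD-NV"]).to_numpy(dtype=float)
    nuis = [cov["age"].to_numpy(dtype=float), psychosis]
    names = ["pclr_total", "age", "psychosis"]
    if include_icv:
        nuis.append(cov["icv_mm3"].to_numpy(dtype=float))
        names.append("icv")
    design = DesignMatrix(
        interest=cov["pclr_total"].to_numpy(dtype=float).reshape(-1, 1),
        nuisance=np.column_stack(nuis),
        contrast=np.array([1.0]),
        names=names,
    )
    result = permutation_glm(
        Z, design, n_perm=n_perm, seed=seed, two_sided=True, return_null=return_null
    )
    result.cohens_d = cohens_d(result.t, n // 2, n - n // 2)
    return result


# ---------------------------------------------------------------------------
# propensity matching


@dataclass
class MatchResult:
    """1:1 matched pairs with propensity scores and balance diagnostics."""

    pairs: pd.DataFrame  # columns: case_id, control_id, distance
    propensity: pd.Series = field(repr=False)
    balance: pd.DataFrame = field(repr=False, default=None)

    @property
    def case_ids(self) -> list:
        return self.pairs["case_id"].tolist()

    @property
    def control_ids(self) -> list:
        return self.pairs["control_id"].tolist()

    @property
    def matched_ids(self) -> list:
        return self.case_ids + self.control_ids


def _smd(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardized mean difference with pooled sd."""
    v = 0.5 * (np.var(x1, ddof=1) + np.var(x2, ddof=1))
    if v == 0:
        return 0.0
    return float((np.mean(x1) - np.mean(x2)) / np.sqrt(v))


def _covariate_matrix(
    cov: pd.DataFrame, covariates: tuple[str, ...], site_levels: list[str]
) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "site":
            for level in site_levels[1:]:
                cols.append((cov["site"] == level).to_numpy(dtype=float))
        else:
            cols.append(cov[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def propensity_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "site"),
) -> MatchResult:
    """1:1 nearest-neighbor matching on logistic-regression distance.

    Fits a logistic model of case membership on the covariates (site as
    one-hot), then greedily pairs each case - processed in descending
    propensity order - with the nearest unused control on the linear
    predictor, without replacement.  Falls back to standardized
    Euclidean covariate distance if the logistic fit separates
    perfectly.
    """
    if len(controls) < len(cases):
        raise ValueError(f"need at least as many controls ({len(controls)}) as cases ({len(cases)})")
    site_levels = sorted(set(cases.get("site", pd.Series(dtype=str))) | set(controls.get("site", pd.Series(dtype=str)))) if "site" in covariates else []
    Xc = _covariate_matrix(cases, covariates, site_levels)
    Xk = _covariate_matrix(controls, covariates, site_levels)
    X = np.vstack([Xc, Xk])
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    lp = None
    if np.ptp(X, axis=0).max() > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegression(penalty=None, max_iter=2000)
            model.fit(X, y)
        prob = model.predict_proba(X)[:, 1]
        separated = np.all((prob > 1 - 1e-8) == (y == 1))
        if not separated:
            lp = model.decision_function(X)
    if lp is None:
        warnings.warn(
            "logistic propensity model degenerate or separated; falling back to "
            "standardized covariate distance"
        )
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = X / sd
        # first principal direction of case-control difference as a 1-d score
        diff = Xs[y == 1].mean(axis=0) - Xs[y == 0].mean(axis=0)
        norm = np.linalg.norm(diff)
        direction = diff / norm if norm > 0 else np.ones(Xs.shape[1]) / np.sqrt(Xs.shape[1])
        lp = Xs @ direction
    lp_cases = lp[: len(cases)]
    lp_controls = lp[len(cases):]
    prop = pd.Series(
        1.0 / (1.0 + np.exp(-lp)), index=list(cases.index) + list(controls.index)
    )
    order = np.argsort(-lp_cases, kind="mergesort")
    available = np.ones(len(controls), dtype=bool)
    pairs = []
    for i in order:
        dist = np.abs(lp_controls - lp_cases[i])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        available[j] = False
        pairs.append((cases.index[i], controls.index[j], float(dist[j])))
    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "distance"])
    # balance diagnostics (age + site indicators)
    rows = []
    matched_controls = controls.loc[pairs_df["control_id"]]
    for c in covariates:
        if c == "site":
            for level in site_levels:
                pre = _smd(
                    (cases["site"] == level).to_numpy(float),
                    (controls["site"] == level).to_numpy(float),
                )
                post = _smd(
                    (cases["site"] == level).to_numpy(float),
                    (matched_controls["site"] == level).to_numpy(float),
                )
                rows.append((f"site[{level}]", pre, post))
        else:
            pre = _smd(cases[c].to_numpy(float), controls[c].to_numpy(float))
            post = _smd(cases[c].to_numpy(float), matched_controls[c].to_numpy(float))
            rows.append((c, pre, post))
    balance = pd.DataFrame(rows, columns=["covariate", "smd_pre", "smd_post"])
    return MatchResult(pairs=pairs_df, propensity=prop, balance=balance)
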