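"""Warped Bayesian linear regression normative models.

Each region's measurement y is mapped to warped space by an affine
sinh-arcsinh transform

    phi(y) = sinh( delta * arcsinh((y - c)/d) - epsilon ),

modelled there as Gaussian around a basis expansion of age and site,

    phi(y) | x  ~  N( w' psi(x), 1/beta ),      w ~ N(0, I/alpha),

and fitted by maximizing the type-II marginal likelihood (including the
warp Jacobian) over (epsilon, log delta, log alpha, log beta), with the
weight posterior available in closed form given those hyperparameters;
the warp's affine part (c, d) is anchored at the training moments.
The age basis is a cubic B-spline with interior knots at training-age
quantiles; scanner sites enter as one-hot fixed effects.

Transfer to a scanner site absent from training re-centers and
re-scales the standardized warped residuals of healthy calibration
controls from that site; deviation Z-scores then use the adapted
moments.  The predictive sd includes the weight-posterior term, so
deviations far outside the training age bulk shrink toward zero.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from ._rng import stream
from .dataio import ROIDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BasisSpec",
    "WarpParams",
    "NormativeModelParams",
    "SiteAdaptation",
    "DeviationMatrix",
    "warp",
    "warp_inverse",
    "warp_log_deriv",
    "fit_normative_model",
    "fit_models",
    "adapt_to_site",
    "adapt_models",
    "compute_zscores",
    "score_dataset",
    "predict_centiles",
    "save_models",
    "load_models",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# sinh-arcsinh warp


@dataclass(frozen=True)
class WarpParams:
    """Affine-then-sinh-arcsinh warp parameters.

    epsilon skews, delta (> 0) controls tailweight; c and d (> 0) are the
    affine location/scale applied before the map.  (0, 1, 0, 1) is the
    identity.
    """

    epsilon: float = 0.0
    delta: float = 1.0
    c: float = 0.0
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.d <= 0:
            raise ValueError(f"d must be > 0, got {self.d}")


def warp(y, params: WarpParams):
    """phi(y): strictly increasing map to the Gaussian modelling space."""
    u = (np.asarray(y, dtype=float) - params.c) / params.d
    return np.sinh(params.delta * np.arcsinh(u) - params.epsilon)


def warp_inverse(z, params: WarpParams):
    """phi^{-1}(z), exact closed form."""
    z = np.asarray(z, dtype=float)
    return params.c + params.d * np.sinh((np.arcsinh(z) + params.epsilon) / params.delta)


def _logcosh(x: np.ndarray) -> np.ndarray:
    # overflow-safe log cosh
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def warp_log_deriv(y, params: WarpParams):
    """log phi'(y), the Jacobian term of the warped likelihood."""
    u = (np.asarray(y, dtype=float) - params.c) / params.d
    arg = params.delta * np.arcsinh(u) - params.epsilon
    return (
        np.log(params.delta / params.d) + _logcosh(arg) - 0.5 * np.log1p(u * u)
    )


# ---------------------------------------------------------------------------
# basis


@dataclass(frozen=True)
class BasisSpec:
    """Age basis: cubic B-spline with interior knots at training-age
    quantiles, plus intercept and one-hot site fixed effects."""

    degree: int = 3
    n_interior_knots: int = 5

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.n_interior_knots < 0:
            raise ValueError("interior knot count must be >= 0")


def _make_knots(age: np.ndarray, spec: BasisSpec) -> np.ndarray:
    k = spec.degree
    lo, hi = float(np.min(age)), float(np.max(age))
    # widen the boundary slightly so training ages are strictly interior
    span = max(hi - lo, 1e-6)
    lo -= 1e-6 * span
    hi += 1e-6 * span
    if spec.n_interior_knots > 0:
        qs = np.linspace(0, 1, spec.n_interior_knots + 2)[1:-1]
        interior = np.quantile(age, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])


def _design(
    age: np.ndarray,
    sites: pd.Series | None,
    knots: np.ndarray,
    degree: int,
    train_sites: list[str],
    adapted_sites: set[str] | None = None,
) -> np.ndarray:
    """[intercept | spline (first column dropped) | site dummies (ref = first
    training site)].  Sites absent from training get all-zero dummies;
    they must carry a calibration adaptation instead."""
    age = np.asarray(age, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    n_out = int(np.sum((age < lo) | (age > hi)))
    if n_out:
        logger.warning("extrapolating beyond training age range for %d subject(s)", n_out)
    S = BSpline.design_matrix(age, knots, degree, extrapolate=True).toarray()
    cols = [np.ones((len(age), 1)), S[:, 1:]]  # drop 1st spline col: partition of unity
    if train_sites:
        dummies = np.zeros((len(age), max(len(train_sites) - 1, 0)))
        if sites is not None:
            site_arr = np.asarray(sites)
            known = set(train_sites)
            for i, s in enumerate(site_arr):
                if s in known:
                    j = train_sites.index(s)
                    if j > 0:
                        dummies[i, j - 1] = 1.0
                elif adapted_sites is not None and s not in adapted_sites:
                    raise KeyError(
                        f"site {s!r} was not in training and has no calibration "
                        "adaptation; run adapt_to_site first"
                    )
        cols.append(dummies)
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class NormativeModelParams:
    """Fitted per-region model: weight posterior, noise/prior precision,
    warp, basis specification, and the training envelope."""

    roi: str
    modality: str
    w_mean: np.ndarray
    w_cov: np.ndarray
    alpha: float
    beta: float
    warp_params: WarpParams
    basis: BasisSpec
    knots: np.ndarray
    train_sites: list[str]
    age_range: tuple[float, float]
    log_evidence: float = float("nan")
    version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        C = np.asarray(self.w_cov)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("weight covariance must be symmetric")

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "roi": self.roi,
            "modality": self.modality,
            "w_mean": self.w_mean.tolist(),
            "w_cov": self.w_cov.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "warp": {
                "epsilon": self.warp_params.epsilon,
                "delta": self.warp_params.delta,
                "c": self.warp_params.c,
                "d": self.warp_params.d,
            },
            "basis": {
                "degree": self.basis.degree,
                "n_interior_knots": self.basis.n_interior_knots,
            },
            "knots": self.knots.tolist(),
            "train_sites": self.train_sites,
            "age_range": list(self.age_range),
            "log_evidence": self.log_evidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModelParams":
        return cls(
            roi=d["roi"],
            modality=d["modality"],
            w_mean=np.asarray(d["w_mean"], dtype=float),
            w_cov=np.asarray(d["w_cov"], dtype=float),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            warp_params=WarpParams(**d["warp"]),
            basis=BasisSpec(**d["basis"]),
            knots=np.asarray(d["knots"], dtype=float),
            train_sites=list(d["train_sites"]),
            age_range=tuple(d["age_range"]),
            log_evidence=float(d.get("log_evidence", float("nan"))),
            version=int(d.get("version", SCHEMA_VERSION)),
        )


@dataclass(frozen=True)
class SiteAdaptation:
    """Calibration moments for one (region, site): mean and sd of the
    standardized warped residuals of that site's healthy controls."""

    site: str
    mu: float
    rho: float
    n: int

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")


@dataclass
class DeviationMatrix:
    """Subjects-by-ROIs deviation Z-scores for one modality."""

    zscores: pd.DataFrame
    modality: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.zscores.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("Z-score matrix contains non-finite entries")

    @property
    def subjects(self) -> list[str]:
        return list(self.zscores.index)

    @property
    def roi_names(self) -> list[str]:
        return list(self.zscores.columns)


# ---------------------------------------------------------------------------
# fitting


def _evidence_terms(z: np.ndarray, Psi: np.ndarray, alpha: float, beta: float):
    """Closed-form BLR posterior and log marginal likelihood for fixed
    warped outcome z (Gaussian evidence, Bishop-style)."""
    n, m = Psi.shape
    G = Psi.T @ Psi
    A = alpha * np.eye(m) + beta * G
    cho = cho_factor(A, lower=True)
    w = beta * cho_solve(cho, Psi.T @ z)
    resid = z - Psi @ w
    e_w = 0.5 * beta * float(resid @ resid) + 0.5 * alpha * float(w @ w)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ll = 0.5 * m * np.log(alpha) + 0.5 * n * np.log(beta) - e_w - 0.5 * logdet \
        - 0.5 * n * np.log(2.0 * np.pi)
    return ll, w, cho


def _check_rank(Psi: np.ndarray) -> None:
    _, R = np.linalg.qr(Psi)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
    if bad.size:
        raise np.linalg.LinAlgError(
            f"design basis is rank deficient; collinear column indices: {bad.tolist()}"
        )


def fit_normative_model(
    train: ROIDataset,
    roi: str,
    basis: BasisSpec | None = None,
    warp_mode: str = "shash",
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-8,
) -> NormativeModelParams:
    """Fit one region's warped-BLR normative model by type-II maximum
    likelihood.

    ``warp_mode='identity'`` freezes the warp at the identity, reducing
    the model to textbook Bayesian ridge regression on the raw outcome.
    The optimizer runs quasi-Newton over (epsilon, log delta, log alpha,
    log beta) from ``n_restarts`` seeded starts around the identity warp.
    """
    basis = basis or BasisSpec()
    if roi not in train.values.columns:
        raise KeyError(f"ROI {roi!r} not in dataset")
    y = train.values[roi].to_numpy(dtype=float)
    age = train.covariates["age"].to_numpy(dtype=float)
    site_series = train.covariates["site"]
    train_sites = sorted(site_series.unique().tolist())
    knots = _make_knots(age, basis)
    Psi = _design(age, site_series, knots, basis.degree, train_sites)
    n, m = Psi.shape
    if n < m + 10:
        raise ValueError(f"need at least basis-dim+10 = {m + 10} training subjects, got {n}")
    _check_rank(Psi)

    if warp_mode == "identity":
        c, d = 0.0, 1.0
        fit_warp = False
    elif warp_mode == "shash":
        # anchor the warp's affine part at the training moments; only the
        # shape (epsilon, delta) is optimized.  Freeing (c, d) makes the
        # likelihood multimodal and prone to sharp-warp overfitting when
        # the age trend moves the location, so the anchored form is both
        # the stabler and the better-generalizing choice.
        c, d = float(np.mean(y)), float(np.std(y)) or 1.0
        fit_warp = True
    else:
        raise ValueError(f"unknown warp_mode {warp_mode!r}")

    def unpack(theta):
        if fit_warp:
            eps, logdelta, logalpha, logbeta = theta
        else:
            eps, logdelta = 0.0, 0.0
            logalpha, logbeta = theta
        wp = WarpParams(epsilon=float(eps), delta=float(np.exp(logdelta)), c=c, d=d)
        return wp, float(np.exp(logalpha)), float(np.exp(logbeta))

    def nll(theta):
        try:
            wp, alpha, beta = unpack(theta)
            z = warp(y, wp)
            ll, _, _ = _evidence_terms(z, Psi, alpha, beta)
            ll += float(np.sum(warp_log_deriv(y, wp)))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = stream(seed, f"normative/fit/{train.modality}/{roi}")
    x0_base = np.zeros(4 if fit_warp else 2)
    if fit_warp:
        # box constraints keep the warp in the mild-skew regime typical of
        # morphometry residuals and rule out degenerate sharp warps
        bounds = [(-2.0, 2.0), (np.log(0.3), np.log(3.0)), (None, None), (None, None)]
    else:
        bounds = [(None, None), (None, None)]
    best = None
    traces = []
    for r in range(max(n_restarts, 1)):
        x0 = x0_base if r == 0 else x0_base + rng.normal(scale=0.3, size=x0_base.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "maxiter": 500},
            )
        traces.append(f"restart {r}: fun={res.fun:.6g} status={res.status} {res.message}")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("normative fit did not converge:\n" + "\n".join(traces))

    wp, alpha, beta = unpack(best.x)
    z = warp(y, wp)
    ll, w_mean, cho = _evidence_terms(z, Psi, alpha, beta)
    w_cov = cho_solve(cho, np.eye(m))
    w_cov = 0.5 * (w_cov + w_cov.T)
    return NormativeModelParams(
        roi=roi,
        modality=train.modality,
        w_mean=w_mean,
        w_cov=w_cov,
        alpha=alpha,
        beta=beta,
        warp_params=wp,
        basis=basis,
        knots=knots,
        train_sites=train_sites,
        age_range=(float(age.min()), float(age.max())),
        log_evidence=float(ll + np.sum(warp_log_deriv(y, wp))),
    )


def fit_models(
    train: ROIDataset,
    rois: list[str] | None = None,
    basis: BasisSpec | None = None,
    warp_mode: str = "shash",
    seed: int = 0,
) -> dict[str, NormativeModelParams]:
    """Fit normative models for every requested region of one modality."""
    rois = rois if rois is not None else train.roi_names
    models = {}
    for roi in rois:
        models[roi] = fit_normative_model(train, roi, basis=basis, warp_mode=warp_mode, seed=seed)
    return models


# ---------------------------------------------------------------------------
# prediction internals


def _predict(model: NormativeModelParams, data: ROIDataset, adapted_sites: set[str]):
    """Warped-space predictive mean and sd (epistemic + aleatoric)."""
    Psi = _design(
        data.covariates["age"].to_numpy(dtype=float),
        data.covariates["site"],
        model.knots,
        model.basis.degree,
        model.train_sites,
        adapted_sites=adapted_sites,
    )
    mean = Psi @ model.w_mean
    var_w = np.einsum("ij,jk,ik->i", Psi, model.w_cov, Psi)
    sd = np.sqrt(1.0 / model.beta + var_w)
    return mean, sd


def predictive_logpdf(model: NormativeModelParams, data: ROIDataset) -> np.ndarray:
    """Per-subject predictive log density of the warped-Gaussian model
    (in the original measurement units, i.e. including the Jacobian)."""
    mean, sd = _predict(model, data, adapted_sites=set())
    y = data.values[model.roi].to_numpy(dtype=float)
    z = warp(y, model.warp_params)
    return norm.logpdf(z, loc=mean, scale=sd) + warp_log_deriv(y, model.warp_params)


# ---------------------------------------------------------------------------
# site adaptation and scoring


def adapt_to_site(
    model: NormativeModelParams,
    calib: ROIDataset,
    site: str | None = None,
    min_n: int = 10,
) -> SiteAdaptation:
    """Estimate calibration moments for one unseen site from healthy
    controls scanned there."""
    if site is not None:
        calib = ROIDataset(
            calib.modality,
            calib.values.loc[calib.covariates["site"] == site],
            calib.covariates.loc[calib.covariates["site"] == site],
        )
    else:
        sites = calib.covariates["site"].unique()
        if len(sites) != 1:
            raise ValueError(
                f"calibration data spans sites {sorted(sites)}; pass site= to select one"
            )
        site = sites[0]
    n = calib.n_subjects
    if n < min_n:
        raise ValueError(
            f"site {site!r}: {n} calibration subjects < required minimum {min_n}"
        )
    mean, sd = _predict(model, calib, adapted_sites={site})
    z = warp(calib.values[model.roi].to_numpy(dtype=float), model.warp_params)
    r = (z - mean) / sd
    return SiteAdaptation(site=site, mu=float(np.mean(r)), rho=float(np.std(r, ddof=1)), n=n)


def adapt_models(
    models: dict[str, NormativeModelParams], calib: ROIDataset, min_n: int = 10
) -> dict[str, dict[str, SiteAdaptation]]:
    """adapt_to_site for every model and every site in the calibration pool."""
    out: dict[str, dict[str, SiteAdaptation]] = {}
    for roi, model in models.items():
        out[roi] = {}
        for site in sorted(calib.covariates["site"].unique()):
            out[roi][site] = adapt_to_site(model, calib, site=site, min_n=min_n)
    return out


def compute_zscores(
    model: NormativeModelParams,
    adaptation: dict[str, SiteAdaptation] | SiteAdaptation | None,
    data: ROIDataset,
) -> pd.Series:
    """Deviation Z-scores for one region.

    Z = (phi(y) - predictive mean - mu_s * sd_pred) / (rho_s * sd_pred),
    with (mu_s, rho_s) = (0, 1) for training sites and the calibration
    moments for adapted sites.
    """
    if isinstance(adaptation, SiteAdaptation):
        adaptation = {adaptation.site: adaptation}
    adaptation = adaptation or {}
    sites = data.covariates["site"]
    mean, sd = _predict(model, data, adapted_sites=set(adaptation))
    mu = np.zeros(len(sites))
    rho = np.ones(len(sites))
    for i, s in enumerate(sites):
        if s in adaptation:
            mu[i] = adaptation[s].mu
            rho[i] = adaptation[s].rho
    z = warp(data.values[model.roi].to_numpy(dtype=float), model.warp_params)
    Z = (z - mean - mu * sd) / (rho * sd)
    return pd.Series(Z, index=data.values.index, name=model.roi)


def score_dataset(
    models: dict[str, NormativeModelParams],
    adaptations: dict[str, dict[str, SiteAdaptation]] | None,
    data: ROIDataset,
) -> DeviationMatrix:
    """Z-score every modelled region of a dataset."""
    cols = {}
    for roi, model in models.items():
        adapt = adaptations.get(roi) if adaptations else None
        cols[roi] = compute_zscores(model, adapt, data)
    frame = pd.DataFrame(cols)
    modality = next(iter(models.values())).modality
    return DeviationMatrix(zscores=frame, modality=modality, provenance={"n_models": len(models)})


def predict_centiles(
    model: NormativeModelParams,
    adaptation: SiteAdaptation | None,
    ages: np.ndarray,
    probs: list[float],
) -> pd.DataFrame:
    """Normative centile curves in measurement units (rows: age, columns:
    centile probability)."""
    probs = list(probs)
    if not probs:
        raise ValueError("probs must be non-empty")
    if not all(0.0 < p < 1.0 for p in probs):
        raise ValueError("probs must lie strictly inside (0, 1)")
    mu_s = adaptation.mu if adaptation else 0.0
    rho_s = adaptation.rho if adaptation else 1.0
    ages = np.asarray(ages, dtype=float)
    dummy_cov = pd.DataFrame(
        {
            "age": ages,
            "sex": "M",
            "site": model.train_sites[0] if adaptation is None else adaptation.site,
            "group": "REF",
            "icv_mm3": np.nan,
            "pclr_total": np.nan,
        },
        index=pd.Index([f"grid{i}" for i in range(len(ages))], name="subject_id"),
    )
    dummy_vals = pd.DataFrame({model.roi: np.zeros(len(ages))}, index=dummy_cov.index)
    grid = ROIDataset(model.modality, dummy_vals, dummy_cov)
    adapted = {adaptation.site} if adaptation else set()
    mean, sd = _predict(model, grid, adapted_sites=adapted)
    out = {}
    for p in probs:
        zq = mean + sd * (mu_s + rho_s * norm.ppf(p))
        out[p] = warp_inverse(zq, model.warp_params)
    return pd.DataFrame(out, index=pd.Index(ages, name="age"))


# ---------------------------------------------------------------------------
# model store


def save_models(
    out_dir: str | Path,
    models: dict[str, NormativeModelParams],
    adaptations: dict[str, dict[str, SiteAdaptation]] | None = None,
) -> Path:
    """One JSON per (modality, region) with model + adaptation entries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for roi, model in models.items():
        payload = model.to_dict()
        payload["adaptations"] = [
            {"site": a.site, "mu": a.mu, "rho": a.rho, "n": a.n}
            for a in (adaptations or {}).get(roi, {}).values()
        ]
        safe = roi.replace("/", "_")
        (out / f"{model.modality}__{safe}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )
    return out


def load_models(
    store: str | Path, modality: str
) -> tuple[dict[str, NormativeModelParams], dict[str, dict[str, SiteAdaptation]]]:
    models: dict[str, NormativeModelParams] = {}
    adaptations: dict[str, dict[str, SiteAdaptation]] = {}
    for path in sorted(Path(store).glob(f"{modality}__*.json")):
        payload = json.loads(path.read_text())
        model = NormativeModelParams.from_dict(payload)
        models[model.roi] = model
        adaptations[model.roi] = {
            a["site"]: SiteAdaptation(site=a["site"], mu=a["mu"], rho=a["rho"], n=a["n"])
            for a in payload.get("adaptations", [])
        }
    return models, adaptations
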