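"""Synthetic multi-site morphometry cohorts with known ground truth.

The generator emulates the statistical structure of a forensic-psychiatry
morphometry study: male cohorts in four diagnostic groups (SSD-V n=38,
SSD-NV n=138, nonSSD-V n=20, HC n=196), a large healthy reference pool
for model training, and a healthy calibration pool (n=998) for site
transfer.  Each region's measurement follows

    y = trajectory(age) + icv_term + site_offset + site_scale * sigma * S(eta)

where ``trajectory`` is a cubic polynomial in age, ``S`` is the inverse
sinh-arcsinh map applied to standard-normal noise (giving skewed,
heavy/light-tailed residuals exactly in the family the normative module
fits), and site offset/scale are scanner effects.  Sparse group-specific
deviation effects are injected into a Bernoulli-drawn subset of each
clinical group, and an optional trait link couples a simulated PCL-R
psychopathy total (0-40) to selected regions.

Group age distributions and PCL-R moments default to truncated normals
with the study's published sample descriptives (e.g. SSD-V age
34.7 +/- 8.9 years over 19.2-54.1, PCL-R 18.9 +/- 8.15).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .dataio import ROIDataset
from .roi import ROIDictionary, MODALITIES, default_roi_dictionary

__all__ = [
    "AgeSpec",
    "SiteSpec",
    "NoiseSpec",
    "CohortSpec",
    "DeviationEffect",
    "DeviationEffectSpec",
    "TruthTable",
    "simulate_reference_cohort",
    "simulate_clinical_groups",
    "write_cohort",
]

CLINICAL_GROUPS = ("SSD-V", "SSD-NV", "nonSSD-V", "HC")
VIOLENCE_GROUPS = ("SSD-V", "nonSSD-V")
SSD_GROUPS = ("SSD-V", "SSD-NV")


@dataclass(frozen=True)
class AgeSpec:
    """Truncated-normal age distribution (years)."""

    mean: float
    sd: float
    min: float
    max: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not self.min < self.max:
            raise ValueError(f"age_range min {self.min} must be < max {self.max}")
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class SiteSpec:
    """Scanner site effect: additive offset (in residual-sigma units) and
    multiplicative residual scale."""

    name: str
    offset: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"site {self.name!r}: scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class NoiseSpec:
    """Sinh-arcsinh residual law per modality.

    sigma_rel scales each region's sigma as a fraction of its baseline
    level (area/volume); sigma_abs is an absolute sigma (thickness, mm).
    epsilon skews the residuals, delta controls tailweight (1 = Gaussian
    when epsilon = 0).
    """

    epsilon: float = 0.0
    delta: float = 1.0
    sigma_abs: float | None = None
    sigma_rel: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"noise delta must be > 0, got {self.delta}")
        if (self.sigma_abs is None) == (self.sigma_rel is None):
            raise ValueError("exactly one of sigma_abs / sigma_rel must be set")
        sig = self.sigma_abs if self.sigma_abs is not None else self.sigma_rel
        if sig < 0:
            raise ValueError(f"noise sigma must be >= 0, got {sig}")


def shash_noise(eta: np.ndarray, epsilon: float, delta: float) -> np.ndarray:
    """Inverse sinh-arcsinh map: standard normal -> skewed residual."""
    return np.sinh((np.arcsinh(eta) + epsilon) / delta)


_DEFAULT_AGES = {
    "SSD-V": AgeSpec(34.7, 8.9, 19.2, 54.1),
    "SSD-NV": AgeSpec(29.0, 8.7, 15.1, 57.8),
    "nonSSD-V": AgeSpec(42.4, 14.4, 9.2, 71.0),
    "HC": AgeSpec(31.9, 10.0, 15.7, 70.9),
    "REF": AgeSpec(35.0, 18.0, 8.0, 85.0),
    "CALIB": AgeSpec(35.0, 15.0, 8.0, 80.0),
}

_DEFAULT_PCLR = {"SSD-V": (18.9, 8.15), "nonSSD-V": (20.8, 7.84)}

_DEFAULT_NOISE = {
    "thickness": NoiseSpec(epsilon=0.2, delta=1.1, sigma_abs=0.12),
    "area": NoiseSpec(epsilon=0.15, delta=1.05, sigma_rel=0.06),
    "volume": NoiseSpec(epsilon=0.1, delta=1.1, sigma_rel=0.08),
}

_DEFAULT_ICV_LOADING = {"thickness": 0.0, "area": 0.45, "volume": 0.35}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort's generative law."""

    dictionary: ROIDictionary = field(default_factory=default_roi_dictionary)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "SSD-V": 38,
            "SSD-NV": 138,
            "nonSSD-V": 20,
            "HC": 196,
            "REF": 1000,
            "CALIB": 998,
        }
    )
    age_specs: dict[str, AgeSpec] = field(default_factory=lambda: dict(_DEFAULT_AGES))
    sites: tuple[SiteSpec, ...] = (
        SiteSpec("S1", 0.0, 1.0),
        SiteSpec("S2", 0.2, 0.9),
        SiteSpec("S3", -0.25, 1.15),
        SiteSpec("S4", 0.1, 1.05),
    )
    target_sites: tuple[SiteSpec, ...] = (
        SiteSpec("T1", 0.5, 1.2),
        SiteSpec("T2", -0.4, 0.85),
    )
    noise: dict[str, NoiseSpec] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    icv_mean: float = 1.55e6
    icv_sd: float = 1.3e5
    icv_loading: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ICV_LOADING)
    )
    pclr_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PCLR)
    )
    sex: str = "M"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group_sizes[{g!r}] must be >= 0, got {n}")
            if n > 0 and g not in self.age_specs:
                raise ValueError(f"no age_specs entry for group {g!r}")
        if not self.sites:
            raise ValueError("sites list must be non-empty")
        for m, ns in self.noise.items():
            if m not in MODALITIES:
                raise ValueError(f"noise: unknown modality {m!r}")
            _ = ns  # validated in NoiseSpec.__post_init__

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if m in set(self.dictionary.table["modality"])]


@dataclass(frozen=True)
class DeviationEffect:
    """One sparse group-level deviation: a signed shift (in units of the
    site-scaled residual sigma) carried by a Bernoulli(prevalence)
    subset of the group, optionally linked to the PCL-R trait."""

    group: str
    roi: str
    modality: str
    shift: float = 0.0
    prevalence: float = 0.0
    trait_link: float = 0.0  # Z-units per PCL-R point

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0,1], got {self.prevalence}")


@dataclass
class DeviationEffectSpec:
    effects: list[DeviationEffect] = field(default_factory=list)

    def validate(self, spec: CohortSpec) -> None:
        for e in self.effects:
            if e.group not in spec.group_sizes:
                raise ValueError(f"effect references unknown group {e.group!r}")
            if e.roi not in spec.dictionary.names(e.modality):
                raise ValueError(
                    f"effect references unknown ROI {e.roi!r} for modality {e.modality!r}"
                )

    def for_group(self, group: str, modality: str) -> list[DeviationEffect]:
        return [e for e in self.effects if e.group == group and e.modality == modality]


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort: per-subject group/site/carrier
    flags and the generative parameters per region."""

    subjects: pd.DataFrame  # index subject_id: group, site, age, icv, pclr
    carriers: dict[str, dict[str, list[str]]]  # modality -> roi -> subject ids
    trajectories: dict[str, dict[str, list[float]]]  # modality -> roi -> coeffs
    site_params: dict[str, dict[str, float]]  # site -> offset(sigma units), scale

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        records = self.subjects.reset_index().to_dict(orient="records")
        for rec in records:  # NaN (absent PCL-R) is not valid JSON
            for k, v in rec.items():
                if isinstance(v, float) and not np.isfinite(v):
                    rec[k] = None
        payload = {
            "subjects": records,
            "carriers": self.carriers,
            "trajectories": self.trajectories,
            "site_params": self.site_params,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, allow_nan=False))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        subjects = pd.DataFrame(payload["subjects"]).set_index("subject_id")
        return cls(
            subjects=subjects,
            carriers=payload["carriers"],
            trajectories=payload["trajectories"],
            site_params=payload["site_params"],
        )


def _roi_rng(modality: str, roi: str) -> np.random.Generator:
    # per-ROI deterministic stream, independent of the cohort seed: the
    # trajectory is a fixed property of the synthetic "population"
    return np.random.default_rng(
        np.random.SeedSequence([zlib.crc32(modality.encode()), zlib.crc32(roi.encode())])
    )


_BASELINE_RANGE = {"thickness": (2.1, 3.1), "area": (300.0, 2600.0), "volume": (700.0, 18000.0)}


def roi_trajectory_coeffs(modality: str, roi: str) -> np.ndarray:
    """Deterministic cubic age-trajectory coefficients for one region.

    The polynomial is in u = (age - 35)/30; coefficients give a baseline
    level typical of the modality with a gentle age-related decline and
    mild curvature, varying region to region.
    """
    rng = _roi_rng(modality, roi)
    lo, hi = _BASELINE_RANGE[modality]
    b0 = rng.uniform(lo, hi)
    rel = rng.uniform(0.02, 0.08)  # fractional change per 30 years
    b1 = -rel * b0
    b2 = rng.uniform(-0.02, 0.005) * b0
    b3 = rng.uniform(-0.008, 0.008) * b0
    return np.array([b0, b1, b2, b3])


def roi_sigma(modality: str, roi: str, noise: NoiseSpec) -> float:
    if noise.sigma_abs is not None:
        return float(noise.sigma_abs)
    b0 = roi_trajectory_coeffs(modality, roi)[0]
    return float(noise.sigma_rel * b0)


def _eval_trajectory(coeffs: np.ndarray, age: np.ndarray) -> np.ndarray:
    u = (age - 35.0) / 30.0
    return coeffs[0] + coeffs[1] * u + coeffs[2] * u**2 + coeffs[3] * u**3


def _simulate(
    spec: CohortSpec,
    groups: list[str],
    sites: tuple[SiteSpec, ...],
    effects: DeviationEffectSpec | None,
    id_prefix: str,
) -> tuple[dict[str, ROIDataset], TruthTable]:
    seed = spec.seed
    rows = []
    rng_age = stream(seed, f"ages/{id_prefix}")
    rng_site = stream(seed, f"sites/{id_prefix}")
    rng_icv = stream(seed, f"icv/{id_prefix}")
    rng_pclr = stream(seed, f"pclr/{id_prefix}")
    site_names = [s.name for s in sites]
    for group in groups:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        ages = spec.age_specs[group].sample(n, rng_age)
        subj_sites = rng_site.choice(site_names, size=n)
        icv = rng_icv.normal(spec.icv_mean, spec.icv_sd, size=n)
        if group in spec.pclr_moments:
            mu, sd = spec.pclr_moments[group]
            pclr = np.clip(rng_pclr.normal(mu, sd, size=n), 0.0, 40.0)
        else:
            pclr = np.full(n, np.nan)
        for i in range(n):
            rows.append((group, float(ages[i]), subj_sites[i], float(icv[i]), float(pclr[i])))
    subjects = pd.DataFrame(rows, columns=["group", "age", "site", "icv_mm3", "pclr_total"])
    subjects.index = pd.Index(
        [f"{id_prefix}{i:05d}" for i in range(len(subjects))], name="subject_id"
    )
    subjects["sex"] = spec.sex

    site_lookup = {s.name: s for s in sites}
    offsets = subjects["site"].map(lambda s: site_lookup[s].offset).to_numpy()
    scales = subjects["site"].map(lambda s: site_lookup[s].scale).to_numpy()
    icv_z = (subjects["icv_mm3"].to_numpy() - spec.icv_mean) / spec.icv_sd
    ages = subjects["age"].to_numpy()

    if effects is not None:
        effects.validate(spec)

    datasets: dict[str, ROIDataset] = {}
    carriers: dict[str, dict[str, list[str]]] = {}
    trajectories: dict[str, dict[str, list[float]]] = {}
    for modality in spec.modalities:
        roi_names = spec.dictionary.names(modality)
        noise = spec.noise[modality]
        loading = spec.icv_loading.get(modality, 0.0)
        rng_noise = stream(seed, f"noise/{id_prefix}/{modality}")
        rng_carrier = stream(seed, f"carriers/{id_prefix}/{modality}")
        values = np.empty((len(subjects), len(roi_names)))
        carriers[modality] = {}
        trajectories[modality] = {}
        for j, roi in enumerate(roi_names):
            coeffs = roi_trajectory_coeffs(modality, roi)
            sigma = roi_sigma(modality, roi, noise)
            trajectories[modality][roi] = [float(v) for v in coeffs] + [float(sigma)]
            eta = rng_noise.standard_normal(len(subjects))
            resid = sigma * shash_noise(eta, noise.epsilon, noise.delta)
            # icv coefficient chosen so corr(ICV, value) = loading when age
            # and site variance are absent
            icv_coef = (
                sigma * loading / np.sqrt(1.0 - loading**2) if abs(loading) < 1 else 0.0
            )
            y = (
                _eval_trajectory(coeffs, ages)
                + icv_coef * icv_z
                + offsets * sigma
                + scales * resid
            )
            if effects is not None:
                for eff in [e for e in effects.effects if e.modality == modality and e.roi == roi]:
                    in_group = (subjects["group"] == eff.group).to_numpy()
                    draw = rng_carrier.random(len(subjects)) < eff.prevalence
                    carry = in_group & draw
                    y = y + np.where(carry, eff.shift * sigma * scales, 0.0)
                    if eff.trait_link != 0.0:
                        pclr = subjects["pclr_total"].to_numpy()
                        centered = np.where(
                            in_group & np.isfinite(pclr),
                            pclr - np.nanmean(pclr[in_group]),
                            0.0,
                        )
                        y = y + eff.trait_link * centered * sigma * scales
                    if eff.shift != 0.0 and eff.prevalence > 0.0:
                        carriers[modality].setdefault(roi, [])
                        carriers[modality][roi].extend(subjects.index[carry].tolist())
            values[:, j] = y
        frame = pd.DataFrame(values, index=subjects.index, columns=roi_names)
        cov = subjects[["age", "sex", "site", "group", "icv_mm3", "pclr_total"]]
        datasets[modality] = ROIDataset(modality, frame, cov)

    site_params = {
        s.name: {"offset_sigma": s.offset, "scale": s.scale} for s in sites
    }
    truth = TruthTable(
        subjects=subjects[["group", "site", "age", "icv_mm3", "pclr_total"]],
        carriers=carriers,
        trajectories=trajectories,
        site_params=site_params,
    )
    return datasets, truth


def simulate_reference_cohort(spec: CohortSpec) -> tuple[dict[str, ROIDataset], TruthTable]:
    """Simulate the healthy reference pool (group REF) at the training sites."""
    return _simulate(spec, ["REF"], spec.sites, None, id_prefix="ref-")


def simulate_clinical_groups(
    spec: CohortSpec, effects: DeviationEffectSpec | None = None
) -> tuple[dict[str, ROIDataset], TruthTable]:
    """Simulate the clinical groups, HC and the calibration pool at the
    target (transfer) sites, injecting any specified deviation effects."""
    groups = [g for g in ("SSD-V", "SSD-NV", "nonSSD-V", "HC", "CALIB") if spec.group_sizes.get(g, 0) > 0]
    unknown = set(spec.group_sizes) - {"REF"} - set(groups) - {g for g in spec.group_sizes if spec.group_sizes[g] == 0}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    return _simulate(spec, groups, spec.target_sites, effects, id_prefix="sub-")


def write_cohort(
    datasets: dict[str, ROIDataset], truth: TruthTable, out_dir: str | Path
) -> dict[str, Path]:
    """Write participants.tsv, one wide roi_<modality>.tsv per modality,
    and truth.json; round-trips losslessly through the dataio readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    first = next(iter(datasets.values()))
    participants = first.covariates.copy()
    participants.index.name = "subject_id"
    cols = ["age", "sex", "site", "group", "icv_mm3", "pclr_total"]
    ppath = out / "participants.tsv"
    participants[cols].to_csv(ppath, sep="\t", float_format="%.12g")
    paths["participants"] = ppath
    for modality, ds in datasets.items():
        mpath = out / f"roi_{modality}.tsv"
        frame = ds.values.copy()
        frame.index.name = "subject_id"
        frame.to_csv(mpath, sep="\t", float_format="%.12g")
        paths[modality] = mpath
    paths["truth"] = truth.to_json(out / "truth.json")
    return paths
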