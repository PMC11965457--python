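"""End-to-end orchestration: simulate -> fit -> adapt -> score -> map ->
test -> associate, with a validated run configuration and a manifest
that makes any run bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .cohort_sim import (
    CohortSpec,
    DeviationEffect,
    DeviationEffectSpec,
    simulate_clinical_groups,
    simulate_reference_cohort,
    write_cohort,
)
from .dataio import write_deviations, write_results
from .deviation import (
    group_mean_extreme_rate,
    roi_extreme_frequency,
    subject_extreme_burden,
    threshold_extremes,
    top_regions,
)
from .inference import (
    burden_permutation_test,
    cohens_d,
    correct_multiplicity,
    group_contrast_design,
    permutation_glm,
    propensity_match,
    trait_association,
    westfall_young,
)
from .normative import adapt_models, fit_models, save_models, score_dataset
from .roi import default_roi_dictionary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "EffectConfig", "validate_config", "run_all", "DEFAULT_CONTRASTS"]

# four group pairings, both directions: the default 8-contrast family
DEFAULT_CONTRASTS = [
    ("SSD-V", "HC"),
    ("HC", "SSD-V"),
    ("SSD-NV", "HC"),
    ("HC", "SSD-NV"),
    ("nonSSD-V", "HC"),
    ("HC", "nonSSD-V"),
    ("SSD-V", "SSD-NV"),
    ("SSD-NV", "SSD-V"),
]


class EffectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    group: str
    roi: str
    modality: str
    shift: float = 0.0
    prevalence: float = Field(0.0, ge=0.0, le=1.0)
    trait_link: float = 0.0


def _default_effects() -> list[EffectConfig]:
    # demo ground truth: sparse -3 sigma deviations in three SSD-V
    # thickness regions, a milder SSD-NV effect, and one PCL-R link
    return [
        EffectConfig(group="SSD-V", roi="lh_G_and_S_frontomargin", modality="thickness", shift=-3.0, prevalence=0.3),
        EffectConfig(group="SSD-V", roi="lh_G_and_S_occipital_inf", modality="thickness", shift=-3.0, prevalence=0.3),
        EffectConfig(group="SSD-V", roi="lh_G_and_S_paracentral", modality="thickness", shift=-3.0, prevalence=0.3),
        EffectConfig(group="SSD-NV", roi="lh_G_and_S_subcentral", modality="thickness", shift=-2.0, prevalence=0.2),
        EffectConfig(group="SSD-V", roi="lh_G_and_S_transv_frontopol", modality="thickness", trait_link=0.05, prevalence=1.0),
        EffectConfig(group="nonSSD-V", roi="lh_G_and_S_transv_frontopol", modality="thickness", trait_link=0.05, prevalence=1.0),
    ]


class RunConfig(BaseModel):
    """Validated configuration of a full synthetic-study run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(ge=0)
    out_dir: Path
    n_cortical: Optional[int] = 12  # regions kept per cortical modality
    n_subcortical: Optional[int] = 7
    ref_size: int = Field(500, ge=100)
    calib_size: int = Field(200, ge=20)
    modalities: list[str] = ["thickness", "area", "volume"]
    threshold: float = 2.0
    n_perm: int = Field(1000, ge=100)
    matching: Literal["1to1", "full"] = "1to1"
    correction: Literal["bh", "wy"] = "bh"
    outcome_channel: Literal["signed", "positive", "negative"] = "signed"
    warp_mode: Literal["shash", "identity"] = "shash"
    effects: list[EffectConfig] = Field(default_factory=_default_effects)

    @field_validator("threshold")
    @classmethod
    def _threshold_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"threshold must satisfy threshold > 0, got {v}")
        return v

    @field_validator("modalities")
    @classmethod
    def _known_modalities(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"thickness", "area", "volume"}
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        if not v:
            raise ValueError("modalities must be non-empty")
        return v


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; every violation is
    reported at once and unknown keys are rejected."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("config must be a YAML mapping")
    try:
        return RunConfig(**payload)
    except ValidationError as err:
        msgs = [f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()]
        raise ValueError("invalid config:\n  " + "\n  ".join(msgs)) from err


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_spec(config: RunConfig) -> CohortSpec:
    dictionary = default_roi_dictionary(
        n_cortical=config.n_cortical, n_subcortical=config.n_subcortical
    )
    keep = dictionary.table["modality"].isin(config.modalities)
    dictionary = type(dictionary)(dictionary.table[keep].reset_index(drop=True))
    sizes = {
        "SSD-V": 38, "SSD-NV": 138, "nonSSD-V": 20, "HC": 196,
        "REF": config.ref_size, "CALIB": config.calib_size,
    }
    return CohortSpec(dictionary=dictionary, group_sizes=sizes, seed=config.seed)


def _apply_channel(frame: pd.DataFrame, channel: str) -> pd.DataFrame:
    if channel == "signed":
        return frame
    if channel == "positive":
        return frame.clip(lower=0.0)
    return frame.clip(upper=0.0)


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write results + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "warnings": [],
    }
    cfg_digest = hashlib.sha256(config.model_dump_json().encode()).hexdigest()
    manifest["config_sha256"] = cfg_digest
    written: list[Path] = []

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(p.relative_to(out)): _sha256(p) for p in paths
        }
        written.extend(paths)
        logger.info("stage %s: wrote %d file(s)", stage, len(paths))

    try:
        spec = _cohort_spec(config)
        effects = DeviationEffectSpec(
            effects=[DeviationEffect(**e.model_dump()) for e in config.effects]
        )
        # drop effects whose region fell outside the truncated dictionary
        effects.effects = [
            e for e in effects.effects
            if e.modality in config.modalities and e.roi in spec.dictionary.names(e.modality)
        ]

        # --- simulate ------------------------------------------------------
        ref_data, ref_truth = simulate_reference_cohort(spec)
        clin_data, clin_truth = simulate_clinical_groups(spec, effects)
        paths = write_cohort(ref_data, ref_truth, out / "reference")
        paths.update(
            {f"clin_{k}": v for k, v in write_cohort(clin_data, clin_truth, out / "clinical").items()}
        )
        record("simulate", list(paths.values()))

        # --- fit / adapt / score ------------------------------------------
        study = {}  # modality -> (clinical DeviationMatrix)
        for modality in config.modalities:
            ref = ref_data[modality]
            models = fit_models(ref, warp_mode=config.warp_mode, seed=config.seed)
            clin = clin_data[modality]
            calib = clin.select_group("CALIB")
            adaptations = adapt_models(models, calib)
            store = save_models(out / "models", models, adaptations)
            groups_ds = clin.select_group("SSD-V", "SSD-NV", "nonSSD-V", "HC")
            dev = score_dataset(models, adaptations, groups_ds)
            study[modality] = (dev, groups_ds)
        record("fit", sorted((out / "models").glob("*.json")))
        dev_paths = [
            write_deviations(dev, out / f"deviations_{m}.tsv") for m, (dev, _) in study.items()
        ]
        record("score", dev_paths)

        # --- map extreme deviations ---------------------------------------
        masks, freq_frames, rate_frames = {}, [], []
        for modality, (dev, ds) in study.items():
            mask = threshold_extremes(dev, threshold=config.threshold)
            masks[modality] = mask
            groups = ds.covariates["group"]
            freq_frames.append(roi_extreme_frequency(mask, groups))
            rate_frames.append(group_mean_extreme_rate(mask, groups))
        freq = pd.concat(
            [f.assign(modality=m) for f, m in zip(freq_frames, study)], ignore_index=True
        )
        rates = pd.concat(rate_frames, ignore_index=True)
        burden = subject_extreme_burden(list(masks.values()))
        any_ds = next(iter(study.values()))[1]
        burden["group"] = any_ds.covariates["group"]
        map_paths = [
            write_results(freq, out / "extreme_summary_roi.tsv"),
            write_results(rates, out / "extreme_summary_group.tsv"),
        ]
        bpath = out / "subject_burden.tsv"
        burden.to_csv(bpath, sep="\t")
        map_paths.append(bpath)
        record("map", map_paths)

        # --- group GLM -----------------------------------------------------
        results = _group_tests(config, study)
        glm_path = write_results(results, out / "results_group.tsv")
        record("test", [glm_path])

        # --- burden permutation tests -------------------------------------
        brows = []
        labels = burden["group"].to_numpy()
        for ga, gb in [("SSD-V", "HC"), ("SSD-NV", "HC"), ("nonSSD-V", "HC"),
                       ("SSD-V", "SSD-NV"), ("SSD-V", "nonSSD-V"), ("SSD-NV", "nonSSD-V")]:
            for sign, direction in (("negative", "greater"), ("positive", "less")):
                col = "n_neg" if sign == "negative" else "n_pos"
                stat, p = burden_permutation_test(
                    burden[col].to_numpy(), labels, ga, gb,
                    direction=direction, n_perm=config.n_perm, seed=config.seed,
                )
                brows.append((ga, gb, sign, direction, stat, p, config.n_perm, config.seed))
        bres = pd.DataFrame(
            brows,
            columns=["group_a", "group_b", "sign", "direction", "mean_diff", "p", "n_perm", "seed"],
        )
        bres_path = write_results(bres, out / "results_burden.tsv")
        record("burden", [bres_path])

        # --- PCL-R association --------------------------------------------
        arows = []
        for modality, (dev, ds) in study.items():
            viol = ds.covariates["group"].isin(["SSD-V", "nonSSD-V"])
            sub = type(dev)(
                zscores=dev.zscores.loc[viol], modality=modality, provenance=dev.provenance
            )
            res = trait_association(
                sub, ds.covariates, modality, n_perm=config.n_perm, seed=config.seed
            )
            frame = res.as_frame().assign(modality=modality, contrast="pclr_total", seed=config.seed)
            arows.append(frame)
        assoc = pd.concat(arows, ignore_index=True)
        assoc["p_fwe_roi"] = np.nan
        for m in assoc["modality"].unique():
            sel = assoc["modality"] == m
            assoc.loc[sel, "p_fwe_roi"] = correct_multiplicity(assoc.loc[sel, "p_unc"].to_numpy())
        assoc["p_fwe_roi_contrast"] = assoc["p_fwe_roi"]  # single trait contrast
        assoc["p_fwe_roi_contrast_modality"] = np.maximum(
            correct_multiplicity(assoc["p_unc"].to_numpy()), assoc["p_fwe_roi_contrast"]
        )
        assoc_path = write_results(assoc, out / "results_pclr.tsv")
        record("associate", [assoc_path])

        # --- summary report ------------------------------------------------
        report = _summary_report(config, freq, rates, burden, bres, results, assoc)
        rpath = out / "summary.txt"
        rpath.write_text(report)
        record("report", [rpath])
    except Exception as err:  # preserve partial outputs, name the stage
        done = list(manifest["stages"])
        stage = "unknown"
        for s in ["simulate", "fit", "score", "map", "test", "burden", "associate", "report"]:
            if s not in done:
                stage = s
                break
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _group_tests(config: RunConfig, study: dict) -> pd.DataFrame:
    """Permutation GLM for the default 8-contrast family, per modality."""
    frames = []
    for modality, (dev, ds) in study.items():
        include_icv = modality in ("area", "volume")
        cov = ds.covariates
        for ga, gb in DEFAULT_CONTRASTS:
            sub_cov = cov
            if config.matching == "1to1" and "HC" in (ga, gb):
                clin = ga if gb == "HC" else gb
                cases = cov[cov["group"] == clin]
                controls = cov[cov["group"] == "HC"]
                match = propensity_match(cases, controls)
                sub_cov = cov.loc[match.matched_ids]
            design, idx = group_contrast_design(sub_cov, ga, gb, include_icv=include_icv)
            Z = _apply_channel(dev.zscores.loc[idx], config.outcome_channel)
            res = permutation_glm(
                Z, design, n_perm=config.n_perm, seed=config.seed,
                return_null=(config.correction == "wy"),
            )
            n1 = int((sub_cov.loc[idx, "group"] == ga).sum())
            n2 = int((sub_cov.loc[idx, "group"] == gb).sum())
            frame = res.as_frame()
            frame["cohens_d"] = cohens_d(res.t, n1, n2)
            frame["modality"] = modality
            frame["contrast"] = f"{ga}>{gb}"
            frame["seed"] = config.seed
            if config.correction == "wy":
                frame["p_fwe_roi"] = westfall_young(res.t, res.t_null)
            frames.append(frame)
    results = pd.concat(frames, ignore_index=True)
    if config.correction == "bh":
        results["p_fwe_roi"] = np.nan
        for (m, c), sel in results.groupby(["modality", "contrast"]).groups.items():
            results.loc[sel, "p_fwe_roi"] = correct_multiplicity(
                results.loc[sel, "p_unc"].to_numpy()
            )
        results["p_fwe_roi_contrast"] = np.nan
        for m, sel in results.groupby("modality").groups.items():
            results.loc[sel, "p_fwe_roi_contrast"] = correct_multiplicity(
                results.loc[sel, "p_unc"].to_numpy()
            )
        results["p_fwe_roi_contrast_modality"] = correct_multiplicity(
            results["p_unc"].to_numpy()
        )
        # report tiers as non-decreasing: BH over a wider pool can dip
        # below the narrower tier, so take the running maximum
        results["p_fwe_roi_contrast"] = results[["p_fwe_roi", "p_fwe_roi_contrast"]].max(axis=1)
        results["p_fwe_roi_contrast_modality"] = results[
            ["p_fwe_roi_contrast", "p_fwe_roi_contrast_modality"]
        ].max(axis=1)
    else:
        # max-statistic FWE is exact over regions (common permutations);
        # wider tiers apply Bonferroni across contrasts and modalities
        n_contrast = results["contrast"].nunique()
        n_mod = results["modality"].nunique()
        results["p_fwe_roi_contrast"] = np.minimum(1.0, results["p_fwe_roi"] * n_contrast)
        results["p_fwe_roi_contrast_modality"] = np.minimum(
            1.0, results["p_fwe_roi"] * n_contrast * n_mod
        )
    return results


def _summary_report(config, freq, rates, burden, bres, results, assoc) -> str:
    lines = ["normdev synthetic study report", "=" * 32, ""]
    lines.append(f"seed: {config.seed}; permutations: {config.n_perm}; "
                 f"matching: {config.matching}; correction: {config.correction}")
    lines.append("")
    for group in ("SSD-V", "SSD-NV", "nonSSD-V"):
        in_group = burden["group"] == group
        if not in_group.any():
            continue
        pct_any = 100.0 * burden.loc[in_group, "has_any"].mean()
        lines.append(f"{group}: {pct_any:.1f}% of subjects have >=1 extreme deviation")
        top = top_regions(freq, group, sign="negative", k=5)
        for _, row in top.iterrows():
            lines.append(
                f"  top negative {row['modality']}/{row['roi']}: "
                f"{row['pct']:.1f}% ({row['count']}/{row['group_n']})"
            )
    lines.append("")
    lines.append("group mean extreme rates (% of regions):")
    for _, row in rates.iterrows():
        lines.append(
            f"  {row['group']:>9} {row['modality']:>9} {row['sign']:>8}: {row['mean_pct']:.2f}%"
        )
    lines.append("")
    lines.append("burden permutation tests (mean count difference, one-sided p):")
    for _, row in bres.iterrows():
        lines.append(
            f"  {row['group_a']} vs {row['group_b']} [{row['sign']}]: "
            f"diff={row['mean_diff']:.2f}, p={row['p']:.4f}"
        )
    sig = results[results["p_fwe_roi_contrast_modality"] < 0.05]
    lines.append("")
    lines.append(
        f"group GLM: {len(results)} tests; {len(sig)} significant at the "
        "regions x contrasts x modalities tier"
    )
    best = assoc.nsmallest(3, "p_unc")
    lines.append("PCL-R association, smallest uncorrected p:")
    for _, row in best.iterrows():
        lines.append(
            f"  {row['modality']}/{row['roi']}: t={row['t']:.2f}, p_unc={row['p_unc']:.4f}"
        )
    return "\n".join(lines) + "\n"
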