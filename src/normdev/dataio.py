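"""Readers/writers for the tabular formats the pipeline touches.

All files are tab-separated UTF-8 text with a mandatory header row and
'.' decimals.  Participants tables follow BIDS-participants conventions
(subject_id, age, sex, site, group, icv_mm3, pclr_total); ROI tables are
wide, one row per subject, one column per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import MODALITIES, ROIDictionary

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("SSD-V", "SSD-NV", "nonSSD-V", "HC", "REF", "CALIB")

PARTICIPANT_COLUMNS = ["subject_id", "age", "sex", "site", "group", "icv_mm3", "pclr_total"]
_MANDATORY = ["subject_id", "age", "sex", "site", "group"]

RESULT_COLUMNS = [
    "modality",
    "roi",
    "contrast",
    "t",
    "cohens_d",
    "p_unc",
    "p_fwe_roi",
    "p_fwe_roi_contrast",
    "p_fwe_roi_contrast_modality",
    "n_perm",
    "seed",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass
class ROIDataset:
    """One modality's subjects-by-ROIs matrix joined to covariates.

    ``values`` is indexed by subject_id with one column per region;
    ``covariates`` shares the index and carries age (years), sex, site,
    group, icv_mm3 and optional pclr_total.
    """

    modality: str
    values: pd.DataFrame = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate subject_id values: {dup[:5]}")
        if not self.values.index.equals(self.covariates.index):
            raise SchemaError("values and covariates subject indices differ")
        if len(set(self.values.columns)) != len(self.values.columns):
            raise SchemaError("duplicate ROI columns")
        for col in ("age", "site"):
            if self.covariates[col].isna().any():
                bad = self.covariates.index[self.covariates[col].isna()].tolist()
                raise SchemaError(f"subjects missing {col}: {bad[:5]}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def select_subjects(self, ids) -> "ROIDataset":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown subjects: {sorted(missing)[:5]}")
        return ROIDataset(self.modality, self.values.loc[ids], self.covariates.loc[ids])

    def select_group(self, *groups: str) -> "ROIDataset":
        mask = self.covariates["group"].isin(groups)
        return ROIDataset(self.modality, self.values.loc[mask], self.covariates.loc[mask])


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])


def _numeric(series: pd.Series, name: str) -> pd.Series:
    """Strict numeric parse: a malformed cell raises instead of becoming 0/NaN."""
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"non-numeric value {series.iloc[row]!r} in column {name!r} at data row {row}"
        )
    return out.astype(float)


def read_participants(
    path: str | Path, groups: tuple[str, ...] = DEFAULT_GROUPS
) -> pd.DataFrame:
    """Read and validate a participants table.

    Returns a DataFrame indexed by subject_id with typed columns; group
    labels must belong to ``groups``; pclr_total and icv_mm3 may be
    missing (NaN).
    """
    table = _read_tsv(path)
    missing = [c for c in _MANDATORY if c not in table.columns]
    if missing:
        raise SchemaError(f"participants file missing mandatory column(s): {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"duplicate subject_id: {dup[:5]}")
    out = pd.DataFrame(index=pd.Index(table["subject_id"], name="subject_id"))
    out["age"] = _numeric(table["age"], "age").to_numpy()
    out["sex"] = table["sex"].to_numpy()
    out["site"] = table["site"].to_numpy()
    out["group"] = table["group"].to_numpy()
    unknown = sorted(set(out["group"]) - set(groups))
    if unknown:
        raise SchemaError(f"group label(s) outside vocabulary {groups}: {unknown}")
    for optional in ("icv_mm3", "pclr_total"):
        if optional in table.columns:
            out[optional] = _numeric(table[optional], optional).to_numpy()
        else:
            out[optional] = np.nan
    if out["age"].isna().any():
        bad = out.index[out["age"].isna()].tolist()
        raise SchemaError(f"subjects missing age: {bad[:5]}")
    return out


def read_roi_table(
    path: str | Path,
    modality: str,
    participants: pd.DataFrame,
    dictionary: ROIDictionary | None = None,
    unknown_roi: str = "drop",
) -> ROIDataset:
    """Read a wide ROI table and join it to already-loaded covariates.

    Unknown ROI columns (not in ``dictionary``) are dropped with a
    warning by default (``unknown_roi='error'`` raises instead).
    Subjects present in the ROI table but absent from participants are
    an error; participants without morphometry are reported and skipped.
    """
    table = _read_tsv(path)
    if "subject_id" not in table.columns:
        raise SchemaError("ROI table must have a subject_id first column")
    table = table.set_index("subject_id")
    if dictionary is not None:
        known = set(dictionary.names(modality))
        unknown = [c for c in table.columns if c not in known]
        if unknown:
            if unknown_roi == "error":
                raise SchemaError(f"unknown ROI column(s): {unknown[:5]}")
            logger.warning(
                "dropping %d ROI column(s) not in dictionary: %s", len(unknown), unknown[:5]
            )
            table = table.drop(columns=unknown)
    values = pd.DataFrame(
        {c: _numeric(table[c], c).to_numpy() for c in table.columns}, index=table.index
    )
    extra = set(values.index) - set(participants.index)
    if extra:
        raise SchemaError(f"subjects in ROI table absent from participants: {sorted(extra)[:5]}")
    lacking = [s for s in participants.index if s not in set(values.index)]
    if lacking:
        logger.info("%d participants have no %s morphometry", len(lacking), modality)
    order = [s for s in participants.index if s in set(values.index)]
    return ROIDataset(modality, values.loc[order], participants.loc[order])


def write_deviations(dev, path: str | Path) -> Path:
    """Write a DeviationMatrix to TSV (subject_id + one column per ROI)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = dev.zscores.copy()
    frame.index.name = "subject_id"
    frame.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_deviations(path: str | Path, modality: str):
    from .normative import DeviationMatrix

    table = _read_tsv(path).set_index("subject_id")
    values = pd.DataFrame(
        {c: _numeric(table[c], c).to_numpy() for c in table.columns}, index=table.index
    )
    return DeviationMatrix(zscores=values, modality=modality)


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write an inference result table with a stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path
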