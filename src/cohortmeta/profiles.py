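"""Merged taxonomic profile tables and curated sample metadata.

The profile dialect is the one produced by marker-based taxonomic
profilers when several per-sample outputs are merged: a TSV whose first
column (``clade_name``) holds a full taxonomy path with levels separated
by ``|`` and a terminal species-level genome bin (SGB) token prefixed
``t__``; the remaining columns are samples, values are relative
abundances on the percent scale.

Whether an SGB is a *known* species (kSGB, anchored by at least one
isolate reference genome) or an *unknown* one (uSGB, supported only by
metagenome-assembled genomes) is encoded in the clade naming: unknown
species carry a placeholder species epithet built from bin identifiers
(``GGB...``/``SGB...``) instead of a Linnaean name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileFormatError",
    "ValidationError",
    "ProfileMatrix",
    "PrevalenceTable",
    "read_merged_profiles",
    "read_sample_metadata",
    "arcsin_sqrt_transform",
    "compute_prevalence",
    "filter_features",
    "cohort_summaries",
]


class ProfileFormatError(ValueError):
    """The file does not follow the merged-profile TSV dialect."""


class ValidationError(ValueError):
    """The parsed content violates a profile/metadata invariant."""


#: species-epithet tokens that mark a placeholder (metagenomic) name
_PLACEHOLDER = re.compile(r"(?:^|_)(?:GGB|SGB|FGB)\d+", flags=re.IGNORECASE)

METADATA_COLUMNS = (
    "sample_id",
    "dataset_id",
    "diet_class",
    "fat_pct",
    "duration_days",
    "age_days",
    "sex",
    "strain",
    "body_site",
    "antibiotics",
    "mouse_id",
    "timepoint",
)

DIET_CLASSES = ("high_fat", "low_fat")
BODY_SITES = ("feces", "cecum", "ileum")


def _species_token(clade_name: str) -> str:
    tokens = clade_name.split("|")
    for tok in reversed(tokens):
        if tok.startswith("s__"):
            return tok[3:]
    # fall back to the level above the terminal token
    return tokens[-2].split("__", 1)[-1] if len(tokens) > 1 else tokens[-1]


def _genus_token(clade_name: str) -> str | None:
    for tok in clade_name.split("|"):
        if tok.startswith("g__"):
            return tok[3:]
    return None


def feature_info_from_clade(clade_name: str) -> dict:
    """Infer SGB identity and known/unknown status from a clade path."""
    terminal = clade_name.split("|")[-1]
    feature_id = terminal.split("__", 1)[-1]
    species = _species_token(clade_name)
    genus = _genus_token(clade_name)
    return {
        "feature_id": feature_id,
        "clade_name": clade_name,
        "known": not bool(_PLACEHOLDER.search(species)),
        "genus_level_assigned": genus is not None
        and not bool(_PLACEHOLDER.search(genus)),
    }


@dataclass
class ProfileMatrix:
    """SGB x sample relative abundances (percent) with feature annotations.

    ``abundances`` is indexed by feature_id with one column per sample;
    ``features`` is indexed identically and carries ``clade_name``,
    ``known`` and ``genus_level_assigned``.
    """

    features: pd.DataFrame
    abundances: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.abundances.index):
            raise ValidationError("feature annotation and abundance rows differ")
        if self.features.index.has_duplicates:
            raise ValidationError("duplicate feature_id")
        if self.abundances.columns.has_duplicates:
            raise ValidationError("duplicate sample column")
        vals = self.abundances.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError("negative abundance")
        col_sums = vals.sum(axis=0)
        if np.any(col_sums > 100 + 1e-6):
            bad = self.abundances.columns[col_sums > 100 + 1e-6]
            raise ValidationError(f"sample column sums exceed 100%: {list(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.index)

    def subset_features(self, feature_ids: Sequence[str]) -> "ProfileMatrix":
        idx = pd.Index(feature_ids)
        return ProfileMatrix(self.features.loc[idx], self.abundances.loc[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProfileMatrix":
        cols = list(sample_ids)
        return ProfileMatrix(self.features, self.abundances[cols])

    def write_tsv(self, path: str | Path, include_unclassified: bool = False) -> None:
        """Write the merged-profile TSV dialect.

        With ``include_unclassified`` an UNCLASSIFIED row carrying the
        residual mass up to a 100% column sum is emitted, as profilers
        do; readers drop it again without renormalising.
        """
        out = self.abundances.copy()
        out.insert(0, "clade_name", self.features["clade_name"].to_numpy())
        if include_unclassified:
            residual = (100.0 - self.abundances.sum(axis=0)).clip(lower=0.0)
            row = pd.DataFrame(
                [["UNCLASSIFIED", *residual.to_numpy()]], columns=out.columns
            )
            out = pd.concat([row, out], ignore_index=True)
        out.to_csv(path, sep="\t", index=False)


def read_merged_profiles(
    path: str | Path,
    level: str = "t__",
    known_override: str | Path | None = None,
) -> ProfileMatrix:
    """Read a merged profile TSV, keeping rows terminating at *level*.

    Parameters
    ----------
    path:
        TSV with a ``clade_name`` first column and one column per sample.
    level:
        Prefix of the terminal taxonomy token to retain (default ``t__``,
        the SGB level).
    known_override:
        Optional two-column TSV (feature_id, known) that overrides the
        known/unknown flag inferred from clade naming.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0].lstrip("#") != "clade_name":
        raise ProfileFormatError(
            f"{path}: first header column must be 'clade_name', got {header[:1]}"
        )
    sample_cols = header[1:]
    if len(set(sample_cols)) != len(sample_cols):
        dup = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
        raise ValidationError(f"duplicate sample column(s): {dup}")

    raw = pd.read_csv(path, sep="\t", header=0, names=header, comment=None)
    raw = raw[~raw["clade_name"].str.upper().isin({"UNCLASSIFIED", "UNKNOWN"})]
    terminal = raw["clade_name"].str.split("|").str[-1]
    raw = raw[terminal.str.startswith(level)]

    feats = pd.DataFrame(
        [feature_info_from_clade(c) for c in raw["clade_name"]]
    ).set_index("feature_id")
    abund = raw.set_index(feats.index)[sample_cols].astype(float)
    if abund.isna().any().any():
        raise ProfileFormatError(f"{path}: non-numeric or missing abundance values")

    if known_override is not None:
        override = pd.read_csv(known_override, sep="\t", index_col=0)
        shared = feats.index.intersection(override.index)
        feats.loc[shared, "known"] = override.loc[shared].iloc[:, 0].astype(bool)

    return ProfileMatrix(feats, abund)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the curated per-sample metadata TSV.

    Returns a DataFrame indexed by sample_id. Missing values are encoded
    as ``NA`` in the file and become NaN.
    """
    meta = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ProfileFormatError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_diet = set(meta["diet_class"].dropna()) - set(DIET_CLASSES)
    if bad_diet:
        raise ValidationError(f"unknown diet_class values: {sorted(bad_diet)}")
    fat = meta["fat_pct"].astype(float)
    if ((fat < 0) | (fat > 100)).any():
        raise ValidationError("fat_pct outside [0, 100]")
    if isinstance(meta["antibiotics"].dtype, object.__class__):
        meta["antibiotics"] = (
            meta["antibiotics"]
            .map({True: True, False: False, "True": True, "False": False,
                  "true": True, "false": False, 1: True, 0: False})
        )
    return meta.set_index("sample_id", drop=False)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    """Write metadata in the curated TSV dialect (missing values as NA)."""
    meta.reset_index(drop=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def arcsin_sqrt_transform(matrix: ProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilising arcsine-square-root transform of percent abundances.

    Each percent value x is mapped to ``asin(sqrt(x / 100))``; the result
    lives in [0, pi/2] and preserves shape and ordering.
    """
    ab = matrix.abundances if isinstance(matrix, ProfileMatrix) else matrix
    vals = ab.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100 + 1e-9):
        raise ValidationError("abundances outside [0, 100] percent")
    return pd.DataFrame(
        np.arcsin(np.sqrt(np.clip(vals / 100.0, 0.0, 1.0))),
        index=ab.index,
        columns=ab.columns,
    )


@dataclass
class PrevalenceTable:
    """Per-dataset and averaged detection prevalence for every feature.

    ``overall`` is the unweighted mean of per-dataset prevalences over
    *all* analysis datasets: a dataset where the feature is never seen
    contributes 0 (fixed denominator), while ``n_datasets_detected``
    counts only datasets with at least one detection.
    """

    per_dataset: pd.DataFrame  # features x datasets, values in [0, 1]
    overall: pd.Series = field(init=False)
    n_datasets_detected: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        vals = self.per_dataset.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("prevalence outside [0, 1]")
        self.overall = self.per_dataset.mean(axis=1)
        self.n_datasets_detected = (self.per_dataset > 0).sum(axis=1)


def compute_prevalence(
    matrix: ProfileMatrix,
    meta: pd.DataFrame,
    detection_threshold: float = 0.0,
) -> PrevalenceTable:
    """Fraction of samples with detection, per dataset and averaged.

    Detection is abundance strictly greater than *detection_threshold*
    (default 0).
    """
    missing = set(matrix.samples) - set(meta.index)
    if missing:
        raise KeyError(f"samples without metadata: {sorted(missing)[:5]}")
    datasets = meta.loc[matrix.samples, "dataset_id"]
    detected = matrix.abundances.gt(detection_threshold)
    per_dataset = detected.T.groupby(datasets.to_numpy()).mean().T
    return PrevalenceTable(per_dataset)


def filter_features(
    prev: PrevalenceTable,
    min_overall_prevalence: float = 0.20,
    min_datasets: int = 5,
) -> list[str]:
    """Features with overall prevalence strictly above the threshold and
    detected in at least *min_datasets* datasets, in input order."""
    keep = (prev.overall > min_overall_prevalence) & (
        prev.n_datasets_detected >= min_datasets
    )
    return list(prev.overall.index[keep])


def cohort_summaries(
    matrix: ProfileMatrix,
    meta: pd.DataFrame | None = None,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-sample kSGB/uSGB richness and summed percent abundances."""
    known = matrix.features["known"].to_numpy(dtype=bool)
    ab = matrix.abundances
    detected = ab.gt(detection_threshold)
    out = pd.DataFrame(
        {
            "ksgb_count": detected.loc[known].sum(axis=0),
            "usgb_count": detected.loc[~known].sum(axis=0),
            "ksgb_pct": ab.loc[known].sum(axis=0),
            "usgb_pct": ab.loc[~known].sum(axis=0),
        }
    )
    if meta is not None:
        out["dataset_id"] = meta.loc[out.index, "dataset_id"]
    return out
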