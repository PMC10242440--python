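"""Synthetic multi-cohort SGB tables with known ground truth.

The generator emulates the statistical structure of pooled mouse
high-fat-diet metagenomic cohorts: study-dominated between-dataset
variance, a small panel of diet-responsive biomarker SGBs, covariate
effects (sex, age), heterogeneous dietary-fat formulations per study
arm, zero inflation from limited detection, and compositional closure.

Effects are injected additively on the arcsine-square-root scale, the
same scale on which the pipeline fits its models, so a biomarker's true
standardised mean difference is exactly the injected effect divided by
the residual standard deviation. Latent values are mapped back through
sin^2 and zero-inflated; the remainder up to 100% is carried by an
unclassified residual pool, exactly as marker-based profilers report the
non-assignable read mass. Closing the SGB rows themselves to 100% would
couple every feature to the diet-driven mass shift of the biomarker
panel and bias the injected effect sizes, so the composition is closed
over SGBs + residual instead (the residual row appears when tables are
written to disk and is dropped again on reading, without
renormalisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_longitudinal"]

PHASE_FAT = {"N": 12.0, "LFD": 10.0, "HFD": 40.0, "LLFD": 6.2}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic multi-cohort experiment.

    Defaults describe the reference conditions used throughout the test
    suite: 6 cohorts with 40 samples per diet arm, 200 SGBs of which 8
    are high-fat biomarkers with a true SMD of 1.0 on the transformed
    scale, 57% of features flagged as unknown (uSGB), per-study fat
    formulations of ~40-60% (high-fat arms) vs ~5-17% (low-fat arms) of
    calories from fat, and a between-study shift 1.5x the residual sd so
    that study identity dominates the compositional variance.
    """

    n_datasets: int = 6
    samples_per_arm: int = 40
    n_features: int = 200
    fraction_unknown: float = 0.57
    n_biomarkers: int = 8
    biomarker_smd: float = 1.0
    biomarkers: tuple[tuple[int, float], ...] | None = None  # (index, signed SMD)
    biomarkers_unknown: bool = True
    study_effect_sd: float = 1.5  # in units of the per-feature residual sd
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.4, "age_days": 0.3}
    )
    prevalence_range: tuple[float, float] = (0.3, 0.95)
    biomarker_prevalence: float = 1.0
    fat_high: tuple[float, float] = (40.0, 60.0)
    fat_low: tuple[float, float] = (5.0, 17.0)
    fat_jitter: float = 3.0
    duration_range: tuple[float, float] = (21.0, 112.0)
    fat_correlations: tuple[tuple[int, float], ...] = ()  # (index, partial rho)
    noise_cv: float = 0.35  # residual sd relative to the base arcsine value
    antibiotic_fraction: float = 0.0
    seed: int = 0

    def to_json(self, path) -> None:
        """Serialise the study conditions to a JSON config file."""
        import json
        from dataclasses import asdict

        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        import json

        raw = json.loads(Path(path).read_text())
        for key in ("biomarkers", "fat_correlations"):
            if raw.get(key) is not None:
                raw[key] = tuple(tuple(item) for item in raw[key])
        for key in ("prevalence_range", "fat_high", "fat_low", "duration_range"):
            raw[key] = tuple(raw[key])
        return cls(**raw)

    def biomarker_list(self) -> list[tuple[int, float]]:
        if self.biomarkers is not None:
            return list(self.biomarkers)
        return [(i, self.biomarker_smd) for i in range(self.n_biomarkers)]

    def validate(self) -> None:
        if not 0 <= self.fraction_unknown <= 1:
            raise ValueError("fraction_unknown must lie in [0, 1]")
        for idx, smd in self.biomarker_list():
            if not 0 <= idx < self.n_features:
                raise ValueError(f"biomarker index {idx} out of range")
            if abs(smd) * self.noise_cv > 2.0:
                raise ValueError(
                    f"biomarker effect {smd} too large for the arcsine scale"
                )
        for idx, rho in self.fat_correlations:
            if not 0 <= idx < self.n_features:
                raise ValueError(f"fat-correlation index {idx} out of range")
            if not -0.95 <= rho <= 0.95:
                raise ValueError("fat correlation must lie in [-0.95, 0.95]")


@dataclass
class GroundTruth:
    """What the generator actually injected, aligned with the features."""

    feature_ids: list[str]
    true_smd: np.ndarray  # signed, 0 for non-biomarkers
    fat_rho: np.ndarray  # target partial correlation with fat percentage
    biomarker: np.ndarray  # boolean mask
    study_effects: np.ndarray  # features x datasets, arcsine scale


def _feature_frame(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_features
    unknown = rng.random(n) < spec.fraction_unknown
    if spec.biomarkers_unknown:
        for idx, _ in spec.biomarker_list():
            unknown[idx] = True
    rows = []
    for i in range(n):
        sgb = f"SGB{9000 + i}"
        if unknown[i]:
            clade = (
                "k__Bacteria|p__Firmicutes|c__Clostridia|o__Lachnospirales"
                f"|f__Lachnospiraceae|g__GGB{4000 + i}|s__GGB{4000 + i}_{sgb}|t__{sgb}"
            )
        else:
            clade = (
                "k__Bacteria|p__Firmicutes|c__Clostridia|o__Lachnospirales"
                f"|f__Lachnospiraceae|g__Genus{i % 40}|s__Genus{i % 40}_species_{i}|t__{sgb}"
            )
        rows.append(
            {
                "feature_id": sgb,
                "clade_name": clade,
                "known": not unknown[i],
                "genus_level_assigned": not unknown[i],
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def _metadata(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for d in range(spec.n_datasets):
        ds = f"D{d + 1}"
        fat_means = {
            "high_fat": rng.uniform(*spec.fat_high),
            "low_fat": rng.uniform(*spec.fat_low),
        }
        strain = f"strain_{d % 3}"
        body_site = ["feces", "feces", "feces", "cecum", "ileum"][d % 5]
        for diet in ("high_fat", "low_fat"):
            for i in range(spec.samples_per_arm):
                sid = f"{ds}_{diet[:2]}_{i:03d}"
                rows.append(
                    {
                        "sample_id": sid,
                        "dataset_id": ds,
                        "diet_class": diet,
                        "fat_pct": float(
                            np.clip(
                                fat_means[diet]
                                + rng.uniform(-spec.fat_jitter, spec.fat_jitter),
                                0.5,
                                99.5,
                            )
                        ),
                        "duration_days": float(rng.uniform(*spec.duration_range)),
                        "age_days": float(rng.uniform(56, 140)),
                        "sex": rng.choice(["female", "male"]),
                        "strain": strain,
                        "body_site": body_site,
                        "antibiotics": bool(rng.random() < spec.antibiotic_fraction),
                        "mouse_id": f"{ds}_m{diet[:2]}{i:03d}",
                        "timepoint": np.nan,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _base_scales(spec: SyntheticSpec, rng: np.random.Generator):
    raw = rng.lognormal(mean=0.0, sigma=1.2, size=spec.n_features)
    props = raw / raw.sum() * 0.9  # mean composition sums to ~90% pre-closure
    base = np.arcsin(np.sqrt(props))
    sigma = spec.noise_cv * base + 0.005
    return base, sigma


def _latent_to_percent(
    latent: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Clip to the arcsine domain, invert and zero-inflate.

    Values are percent; the gap up to a 100% column sum is the
    unclassified residual. The rare column whose SGB mass alone exceeds
    100% is scaled back onto the simplex.
    """
    vals = np.sin(np.clip(latent, 0.0, np.pi / 2 - 1e-9)) ** 2 * keep * 100.0
    col_sums = vals.sum(axis=0)
    over = col_sums > 100.0
    if np.any(over):
        vals[:, over] *= 100.0 / col_sums[over]
    return vals


def generate(spec: SyntheticSpec) -> tuple[ProfileMatrix, pd.DataFrame, GroundTruth]:
    """One multi-cohort profile table, metadata, and its ground truth.

    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    feats = _feature_frame(spec, rng)
    meta = _metadata(spec, rng)
    base, sigma = _base_scales(spec, rng)
    n_f, n_s = spec.n_features, len(meta)

    true_smd = np.zeros(n_f)
    for idx, smd in spec.biomarker_list():
        true_smd[idx] = smd
    fat_rho = np.zeros(n_f)
    for idx, rho in spec.fat_correlations:
        fat_rho[idx] = rho
    biomarker = true_smd != 0

    study = rng.normal(0.0, 1.0, size=(n_f, spec.n_datasets)) * (
        spec.study_effect_sd * sigma[:, None]
    )
    ds_codes = pd.factorize(meta["dataset_id"])[0]

    latent = base[:, None] + study[:, ds_codes]
    latent += rng.normal(0.0, 1.0, size=(n_f, n_s)) * sigma[:, None]

    # covariate effects: per-feature random coefficients on standardised values
    cov_values = {}
    if "sex" in spec.covariate_effects:
        cov_values["sex"] = (meta["sex"] == "male").to_numpy(dtype=float)
    if "age_days" in spec.covariate_effects:
        age = meta["age_days"].to_numpy(dtype=float)
        cov_values["age_days"] = (age - age.mean()) / age.std()
    for cov, scale in spec.covariate_effects.items():
        if cov not in cov_values:
            continue
        beta = rng.normal(0.0, scale, size=n_f) * sigma
        latent += beta[:, None] * cov_values[cov][None, :]

    # diet effect on biomarkers: SMD x residual sd for high-fat samples
    high = (meta["diet_class"] == "high_fat").to_numpy(dtype=float)
    latent += (true_smd * sigma)[:, None] * high[None, :]

    # fat-percentage-correlated features. The target is a *Spearman*
    # partial correlation, so the effect rides on within-dataset normal
    # scores of fat (rank-based, hence well-defined for the bimodal
    # two-formulation fat distributions) with the Greiner relation
    # rho_pearson = 2 sin(pi rho_s / 6) linking the injected linear
    # correlation to the rank-scale estimand.
    if spec.fat_correlations:
        from scipy import stats as _stats

        fat = meta["fat_pct"].to_numpy(dtype=float)
        z_fat = np.empty(n_s)
        for d in range(spec.n_datasets):
            m = ds_codes == d
            ranks = _stats.rankdata(fat[m])
            z_fat[m] = _stats.norm.ppf((ranks - 0.5) / m.sum())
        rho_lin = 2.0 * np.sin(np.pi * fat_rho / 6.0)
        slope = sigma * rho_lin / np.sqrt(1.0 - rho_lin**2)
        latent += slope[:, None] * z_fat[None, :]

    prev = rng.uniform(*spec.prevalence_range, size=n_f)
    prev[biomarker] = spec.biomarker_prevalence
    for idx, _ in spec.fat_correlations:
        prev[idx] = max(prev[idx], spec.biomarker_prevalence)
    keep = (rng.random((n_f, n_s)) < prev[:, None]).astype(float)

    vals = _latent_to_percent(latent, keep)
    abund = pd.DataFrame(vals, index=feats.index, columns=meta.index)
    truth = GroundTruth(
        feature_ids=list(feats.index),
        true_smd=true_smd,
        fat_rho=fat_rho,
        biomarker=biomarker,
        study_effects=study,
    )
    return ProfileMatrix(feats, abund), meta, truth


def generate_longitudinal(
    spec: SyntheticSpec,
    phases: Sequence[str],
    n_mice: int = 6,
    timepoints_per_phase: int = 3,
    lag: float = 0.4,
    dataset_id: str = "LONG1",
) -> tuple[ProfileMatrix, pd.DataFrame, GroundTruth]:
    """Per-mouse trajectories across an ordered dietary phase schedule.

    Phases come from {N, LFD, HFD, LLFD}; a phase counts as high-fat when
    its fat percentage is at least 30%. Biomarker latents relax toward
    the phase-appropriate mean geometrically with factor *lag* per
    timepoint, emulating the within-days response of diet-sensitive SGBs.
    """
    if not phases:
        raise ValueError("phase schedule is empty")
    unknown_phases = set(phases) - set(PHASE_FAT)
    if unknown_phases:
        raise ValueError(f"unknown phases: {sorted(unknown_phases)}")
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    feats = _feature_frame(spec, rng)
    base, sigma = _base_scales(spec, rng)
    n_f = spec.n_features
    true_smd = np.zeros(n_f)
    for idx, smd in spec.biomarker_list():
        true_smd[idx] = smd
    biomarker = true_smd != 0

    rows = []
    columns = {}
    for mouse in range(n_mice):
        state = base.copy()
        t = 0
        mouse_shift = rng.normal(0.0, 0.3, size=n_f) * sigma
        for phase in phases:
            fat = PHASE_FAT[phase]
            target = base + mouse_shift + np.where(fat >= 30, true_smd * sigma, 0.0)
            for _ in range(timepoints_per_phase):
                state = target + (state - target) * lag
                latent = state + rng.normal(0.0, 0.5, size=n_f) * sigma
                sid = f"{dataset_id}_m{mouse}_t{t:02d}"
                keep = np.ones(n_f)
                columns[sid] = _latent_to_percent(latent[:, None], keep[:, None])[:, 0]
                rows.append(
                    {
                        "sample_id": sid,
                        "dataset_id": dataset_id,
                        "diet_class": "high_fat" if fat >= 30 else "low_fat",
                        "fat_pct": fat,
                        "duration_days": float(t * 7),
                        "age_days": float(56 + t * 7),
                        "sex": "female",
                        "strain": "strain_0",
                        "body_site": "feces",
                        "antibiotics": False,
                        "mouse_id": f"{dataset_id}_m{mouse}",
                        "timepoint": t,
                        "phase": phase,
                    }
                )
                t += 1
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    abund = pd.DataFrame(columns, index=feats.index)
    truth = GroundTruth(
        feature_ids=list(feats.index),
        true_smd=true_smd,
        fat_rho=np.zeros(n_f),
        biomarker=biomarker,
        study_effects=np.zeros((n_f, 1)),
    )
    return ProfileMatrix(feats, abund), meta, truth


def null_spec(spec: SyntheticSpec | None = None, seed: int = 0) -> SyntheticSpec:
    """The same study conditions with every diet effect removed."""
    base = spec or SyntheticSpec()
    return replace(base, biomarkers=(), fat_correlations=(), seed=seed)
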