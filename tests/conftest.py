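import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cohortmeta import SyntheticSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


PROFILE_TSV = """clade_name\tS1\tS2\tS3
UNCLASSIFIED\t40.0\t10.0\t100.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Lachnospirales|f__Lachnospiraceae|g__Lachnospira|s__Lachnospiraceae_bacterium_28_4|t__SGB7272\t35.0\t60.0\t0.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Oscillospirales|f__Ruminococcaceae|g__GGB4421|s__GGB4421_SGB43546|t__SGB43546\t25.0\t30.0\t0.0
"""


@pytest.fixture
def profile_path(tmp_path):
    p = tmp_path / "merged_profiles.tsv"
    p.write_text(PROFILE_TSV)
    return p


@pytest.fixture
def tiny_meta():
    """Metadata for a 3-dataset hand fixture."""
    rows = []
    for ds, samples in {"A": ["S1", "S2"], "B": ["S3", "S4"], "C": ["S5", "S6"]}.items():
        for i, s in enumerate(samples):
            rows.append(
                {
                    "sample_id": s,
                    "dataset_id": ds,
                    "diet_class": "high_fat" if i == 0 else "low_fat",
                    "fat_pct": 45.0 if i == 0 else 10.0,
                    "duration_days": 28.0,
                    "age_days": 70.0,
                    "sex": "female",
                    "strain": "B6",
                    "body_site": "feces",
                    "antibiotics": False,
                    "mouse_id": f"{ds}m{i}",
                    "timepoint": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured multi-cohort study with ground truth."""
    spec = SyntheticSpec(
        n_datasets=4, samples_per_arm=15, n_features=60, n_biomarkers=4, seed=42
    )
    return generate(spec)
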