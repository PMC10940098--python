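"""Shared study configuration for the analysis scripts.

One synthetic cohort (n = 80, 2 mm isotropic phantoms) serves the whole
narrative; every script regenerates what it needs deterministically from
this config, so the scripts can be run independently and in order.
Images and other bulky intermediates go under scratch/, tables under
results/.
"""

from pathlib import Path

from immunorad import FeatureConfig, SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_CONFIG = SyntheticConfig(
    n_patients=80,
    seed=20240501,
    rho=0.2,
    texture_effect=4.0,
    count_effect=0.7,
    semi_axis_range_mm=(8.0, 12.0),
    spacing_mm=(1.0, 1.0, 1.0),
    immunotherapy_fraction=0.6,
)

FEATURE_CONFIG = FeatureConfig()          # reference inventory: 584 features

COVARIATE_COLUMNS = ["age", "tumor_size_mm", "tnm_stage", "cea_positive",
                     "ca199_positive", "chemotherapy"]


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
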