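"""Synthetic phantom cohorts with a latent lymphoid/myeloid immune context.

Every downstream stage of the pipeline is testable against this generator
under a known truth:

* each patient carries a latent ``(lymphoid, myeloid)`` pair drawn from a
  standard bivariate normal with correlation ``rho``;
* the CT stand-in is an ellipsoidal phantom whose interior holds stationary
  correlated noise — the noise SD grows linearly with the lymphoid latent
  (slope ``texture_effect``) and the correlation length grows with the
  myeloid latent, so texture features are informative about the context;
* IHC counts (CD3/CD8 for lymphoid, CD66b for myeloid, intratumoral and
  peritumoral) are negative-binomial with log-mean shifted by
  ``count_effect`` x latent;
* survival follows a Weibull proportional-hazards model with hazard ratios
  attached to the LIS/MIS statuses and independent uniform censoring;
* immunotherapy response is Bernoulli with a per-subtype probability
  (defaults follow the reported subtype response rates
  27.3 / 53.3 / 10.2 / 30.0%).

Cohorts are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import ihc as ihc_mod
from .grids import ImageVolume, VoxelMask
from .signature import assign_subtype

__all__ = ["LatentContext", "PhantomGeometry", "SyntheticConfig",
           "SyntheticPatient", "generate_phantom", "simulate_ihc_counts",
           "simulate_outcomes", "generate_cohort", "cohort_table",
           "save_cohort"]

_MARKER_BASE_MEAN = {"cd3": 50.0, "cd8": 30.0, "cd66b": 20.0}
_PERI_FACTOR = 0.8   # peritumoral counts run a little lower than intratumoral
_LYMPHOID_MARKERS = ("cd3", "cd8")


@dataclass(frozen=True)
class LatentContext:
    """Unobserved immune context on a standard-normal scale."""

    lymphoid: float
    myeloid: float

    def __post_init__(self):
        if not (np.isfinite(self.lymphoid) and np.isfinite(self.myeloid)):
            raise ValueError("latent values must be finite")


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid phantom geometry (mm)."""

    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 10.0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 5.0
    baseline: float = 60.0


@dataclass
class SyntheticConfig:
    n_patients: int = 100
    seed: int = 0
    rho: float = 0.2                     # latent lymphoid/myeloid correlation
    # imaging texture
    texture_effect: float = 4.0          # noise-SD units per lymphoid SD
    base_noise_sd: float = 10.0
    base_corr_mm: float = 1.5            # noise correlation length
    corr_effect_mm: float = 0.5          # per myeloid SD
    semi_axis_range_mm: tuple[float, float] = (8.0, 25.0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    include_images: bool = True
    # IHC counts
    count_effect: float = 0.7            # log-mean units per latent SD
    count_dispersion: float = 2.0        # NB size; np.inf -> Poisson
    # outcomes
    hr_lis_high: float = 0.25            # within the reported 0.183-0.362
    hr_mis_high: float = 3.0             # within the reported 1.971-6.014
    weibull_shape: float = 1.2
    weibull_scale_months: float = 49.0   # baseline median survival ~36 months
    censor_horizon: float = 60.0         # months
    # immunotherapy response
    immunotherapy_fraction: float = 0.3
    subtype_response_probs: tuple[float, float, float, float] = (
        0.273, 0.533, 0.102, 0.300)
    cr_fraction: float = 0.15            # CR share among responders
    cps_effect: float = 0.5              # log-CPS shift for responders
    confound_covariates: bool = False

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be >= 0")
        for p in self.subtype_response_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must lie in [0, 1]")
        if not 0.0 <= self.cr_fraction <= 1.0:
            raise ValueError("cr_fraction must lie in [0, 1]")
        if not 0.0 <= self.immunotherapy_fraction <= 1.0:
            raise ValueError("immunotherapy_fraction must lie in [0, 1]")
        if self.hr_lis_high <= 0 or self.hr_mis_high <= 0:
            raise ValueError("hazard ratios must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")


@dataclass
class SyntheticPatient:
    patient_id: str
    latent: LatentContext
    volume: ImageVolume | None
    tumor_mask: VoxelMask | None
    ihc_counts: dict[str, int]
    covariates: dict[str, object]
    lis: int
    mis: int
    lis_status: str
    mis_status: str
    subtype: int
    survival_time: float
    event: int
    immunotherapy: bool
    response: str | None              # CR/PR/SD/PD, immunotherapy only
    cps: float | None


# ------------------------------------------------------------------ phantom

def generate_phantom(latent: LatentContext, geometry: PhantomGeometry,
                     seed: int, texture_effect: float = 4.0,
                     base_noise_sd: float = 10.0, base_corr_mm: float = 1.5,
                     corr_effect_mm: float = 0.5) -> tuple[ImageVolume, VoxelMask]:
    """Ellipsoidal phantom: constant background, interior = baseline plus
    correlated noise whose SD tracks the lymphoid latent and whose
    correlation length tracks the myeloid latent."""
    axes = np.asarray(geometry.semi_axes_mm, dtype=float)
    spacing = np.asarray(geometry.spacing_mm, dtype=float)
    if np.any(axes / spacing < 3):
        raise ValueError("semi-axes must span >= 3 voxels at this spacing")

    half = np.ceil((axes + geometry.margin_mm) / spacing).astype(int)
    shape = 2 * half + 1
    center = half.astype(float)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                             indexing="ij")
    norm = (((zz - center[0]) * spacing[0] / axes[0]) ** 2
            + ((yy - center[1]) * spacing[1] / axes[1]) ** 2
            + ((xx - center[2]) * spacing[2] / axes[2]) ** 2)
    mask = norm <= 1.0

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(tuple(shape))
    corr_mm = max(0.2, base_corr_mm + corr_effect_mm * latent.myeloid)
    field = gaussian_filter(noise, sigma=tuple(corr_mm / spacing))
    fstd = field[mask].std()
    if fstd > 0:
        field = field / fstd          # unit in-mask variance before scaling

    sd = max(0.0, base_noise_sd + texture_effect * latent.lymphoid)
    # background holds the constant baseline; texture lives inside the tumor
    values = np.full(tuple(shape), geometry.baseline)
    values[mask] += sd * field[mask]
    sp = tuple(float(s) for s in spacing)
    return ImageVolume(values, sp), VoxelMask(mask, sp)


# ------------------------------------------------------------------- counts

def simulate_ihc_counts(latent: LatentContext, config: SyntheticConfig,
                        seed: int | np.random.Generator) -> dict[str, int]:
    """Overdispersed marker counts for the six marker-region cells.

    Negative binomial with log-mean ``log(base) + count_effect x latent``
    (lymphoid latent for CD3/CD8, myeloid for CD66b); Poisson when the
    dispersion is infinite.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out: dict[str, int] = {}
    for marker, base in _MARKER_BASE_MEAN.items():
        lat = latent.lymphoid if marker in _LYMPHOID_MARKERS else latent.myeloid
        for region, factor in (("intra", 1.0), ("peri", _PERI_FACTOR)):
            mean = factor * np.exp(np.log(base) + config.count_effect * lat)
            if np.isinf(config.count_dispersion):
                count = rng.poisson(mean)
            else:
                theta = config.count_dispersion
                lam = rng.gamma(theta, mean / theta)
                count = rng.poisson(lam)
            out[f"{marker}_{region}"] = int(count)
    return out


# ----------------------------------------------------------------- outcomes

def simulate_outcomes(lis_status, mis_status, subtype, config: SyntheticConfig,
                      seed: int | np.random.Generator):
    """Vectorized survival and response simulation.

    Event times follow a Weibull proportional-hazards model with log-hazard
    ``log(hr_lis_high) 1[LIS high] + log(hr_mis_high) 1[MIS high]`` and
    independent uniform censoring on (0, censor_horizon].  Response is
    Bernoulli with the per-subtype probability, split CR/PR among
    responders and SD/PD among the rest.

    Returns (time, event, response_category) arrays; responses are drawn
    for every patient and the caller masks non-immunotherapy records.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lis_high = (np.asarray(lis_status) == "high").astype(float)
    mis_high = (np.asarray(mis_status) == "high").astype(float)
    subtype = np.asarray(subtype, dtype=int)
    if np.any((subtype < 1) | (subtype > 4)):
        raise ValueError("unknown subtype (must be 1-4)")
    n = len(subtype)

    loghr = (np.log(config.hr_lis_high) * lis_high
             + np.log(config.hr_mis_high) * mis_high)
    u = rng.uniform(size=n)
    k, lam = config.weibull_shape, config.weibull_scale_months
    t_event = lam * (-np.log(u) / np.exp(loghr)) ** (1.0 / k)
    censor = rng.uniform(0.0, config.censor_horizon, size=n)
    censor = np.maximum(censor, 1e-6)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    probs = np.asarray(config.subtype_response_probs)[subtype - 1]
    responder = rng.uniform(size=n) < probs
    cr = rng.uniform(size=n) < config.cr_fraction
    pd_ = rng.uniform(size=n) < 0.5
    response = np.where(responder, np.where(cr, "CR", "PR"),
                        np.where(pd_, "PD", "SD"))
    return time, event, response


# ------------------------------------------------------------------- cohort

def _draw_covariates(rng: np.random.Generator, latent: LatentContext,
                     size_mm: float, config: SyntheticConfig) -> dict[str, object]:
    stage_probs = np.array([0.30, 0.45, 0.25])
    if config.confound_covariates:
        shift = 0.15 * latent.myeloid
        stage_probs = stage_probs + np.array([-shift, 0.0, shift]) / 2
        stage_probs = np.clip(stage_probs, 0.01, None)
        stage_probs /= stage_probs.sum()
    return {
        "age": float(np.clip(rng.normal(60, 10), 25, 90)),
        "sex": "male" if rng.uniform() < 0.6 else "female",
        "location": rng.choice(["cardia", "body", "antrum"],
                               p=[0.3, 0.3, 0.4]),
        "differentiation": rng.choice(["well", "moderate", "poor"],
                                      p=[0.15, 0.45, 0.40]),
        "lauren": rng.choice(["intestinal", "diffuse", "mixed"],
                             p=[0.5, 0.3, 0.2]),
        "tumor_size_mm": float(size_mm),
        "cea_positive": int(rng.uniform() < 0.30),
        "ca199_positive": int(rng.uniform() < 0.25),
        "chemotherapy": int(rng.uniform() < 0.50),
        "tnm_stage": int(rng.choice([2, 3, 4], p=stage_probs)),
    }


def generate_cohort(config: SyntheticConfig) -> list[SyntheticPatient]:
    """Generate a fully synthetic cohort; identical config + seed gives
    bitwise-identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    # bivariate normal via explicit Cholesky factor (exact at |rho| = 1)
    z = rng.standard_normal((n, 2))
    latents = np.empty((n, 2))
    latents[:, 0] = z[:, 0]
    latents[:, 1] = (config.rho * z[:, 0]
                     + np.sqrt(max(0.0, 1.0 - config.rho ** 2)) * z[:, 1])

    lo, hi = config.semi_axis_range_mm
    semi_axes = rng.uniform(lo, hi, size=(n, 3))
    phantom_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    count_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    io_flags = rng.uniform(size=n) < config.immunotherapy_fraction
    cps_noise = rng.standard_normal(n)

    patients: list[dict] = []
    counts_rows = []
    for i in range(n):
        latent = LatentContext(float(latents[i, 0]), float(latents[i, 1]))
        geom = PhantomGeometry(tuple(semi_axes[i]), config.spacing_mm)
        if config.include_images:
            vol, mask = generate_phantom(
                latent, geom, int(phantom_seeds[i]),
                texture_effect=config.texture_effect,
                base_noise_sd=config.base_noise_sd,
                base_corr_mm=config.base_corr_mm,
                corr_effect_mm=config.corr_effect_mm)
        else:
            vol, mask = None, None
        counts = simulate_ihc_counts(latent, config, int(count_seeds[i]))
        counts_rows.append(counts)
        covs = _draw_covariates(rng, latent, 2 * semi_axes[i].max(), config)
        patients.append({"latent": latent, "volume": vol, "mask": mask,
                         "counts": counts, "covariates": covs})

    counts_df = pd.DataFrame(counts_rows)
    thresholds = ihc_mod.fit_medians(counts_df)
    scores = ihc_mod.score_table(counts_df, thresholds)
    subtypes = np.array([assign_subtype(l, m) for l, m in
                         zip(scores["lis_status"], scores["mis_status"])])

    outcome_seed = int(rng.integers(0, 2 ** 31 - 1))
    time, event, response = simulate_outcomes(
        scores["lis_status"].to_numpy(), scores["mis_status"].to_numpy(),
        subtypes, config, outcome_seed)

    out: list[SyntheticPatient] = []
    for i, rec in enumerate(patients):
        responder = response[i] in ("CR", "PR")
        cps = float(np.round(np.exp(1.0 + 0.8 * cps_noise[i]
                                    + config.cps_effect * responder), 1))
        out.append(SyntheticPatient(
            patient_id=f"P{i + 1:04d}",
            latent=rec["latent"],
            volume=rec["volume"],
            tumor_mask=rec["mask"],
            ihc_counts=rec["counts"],
            covariates=rec["covariates"],
            lis=int(scores["lis"].iloc[i]),
            mis=int(scores["mis"].iloc[i]),
            lis_status=str(scores["lis_status"].iloc[i]),
            mis_status=str(scores["mis_status"].iloc[i]),
            subtype=int(subtypes[i]),
            survival_time=float(time[i]),
            event=int(event[i]),
            immunotherapy=bool(io_flags[i]),
            response=str(response[i]) if io_flags[i] else None,
            cps=cps if io_flags[i] else None,
        ))
    return out


def cohort_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Flatten a cohort into the per-patient analysis table."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id,
               "lymphoid_latent": p.latent.lymphoid,
               "myeloid_latent": p.latent.myeloid,
               **p.ihc_counts, **p.covariates,
               "lis": p.lis, "mis": p.mis,
               "lis_status": p.lis_status, "mis_status": p.mis_status,
               "subtype": p.subtype,
               "survival_time": p.survival_time, "event": p.event,
               "immunotherapy": int(p.immunotherapy),
               "response": p.response, "cps": p.cps}
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(patients: list[SyntheticPatient], out_dir: str | Path,
                config: SyntheticConfig | None = None) -> None:
    """Write volumes/masks as NIfTI, the cohort table as CSV and the config
    as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_table(patients).to_csv(out / "cohort.csv", index=False)
    if config is not None:
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2))
    img_dir = out / "images"
    for p in patients:
        if p.volume is not None:
            img_dir.mkdir(exist_ok=True)
            p.volume.save(img_dir / f"{p.patient_id}_ct.nii.gz")
            p.tumor_mask.save(img_dir / f"{p.patient_id}_mask.nii.gz")
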