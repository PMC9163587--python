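"""Synthetic two-cohort voxel datasets with tract-specific fibre geometry.

The generator emulates the statistical structure that the downstream
analysis assumes, so every stage can be exercised and validated without
patient data:

* three tract ROIs (optic radiation OR, splenium SCC, superior longitudinal
  fascicle SLF) with characteristic fibre-to-field angle distributions —
  narrow and near-perpendicular in SCC, moderately narrow in OR, broad in
  SLF — produced by a Watson-type axial dispersion model around a mean
  fibre direction, with the angle taken to a fixed field axis (B0 = z);
* a healthy-control (HC) and a multiple-sclerosis (MS) cohort with
  realistic covariates: age, age at disease onset, disease duration
  (median ~9 years, range 1-32), and per-ROI lesion-load fractions
  (zero-inflated Beta, support [0, 1], identically 0 for HC);
* subject-level isotropic AMS and apparent MSA drawn from cohort-specific
  normal distributions, shifted by linear covariate effects (ageing per
  decade from the 30-year reference, disease duration per decade, lesion
  load per unit fraction);
* voxels on the cos^2 law ``chi_app = dchi_eff * cos^2(theta) + iso_eff``
  with i.i.d. Gaussian noise.

Default parameter values reproduce the study conditions the analysis is
designed for (64 HC / 89 MS, apparent-MSA scenario values 27 / 21 / -30 ppb
in OR / SCC / SLF); everything is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AngleProfile",
    "ROIConfig",
    "GeneratorConfig",
    "default_config",
    "sample_fibre_angles",
    "sample_covariates",
    "generate_subject_voxels",
    "generate_cohort_dataset",
    "inject_orientation_artifact",
    "population_truth",
    "save_config",
    "load_config",
]

COHORTS = ("HC", "MS")

#: reference age (years) and scale (years) for the ageing covariate
AGE_REFERENCE = 30.0
AGE_SCALE = 10.0


@dataclass(frozen=True)
class AngleProfile:
    """Watson-type axial orientation dispersion for one tract.

    ``mean_deg`` is the angle between the mean fibre direction and B0, in
    [0, 90].  ``dispersion`` is the Watson concentration parameter kappa:
    0 yields uniformly distributed axes (theta density proportional to
    sin(theta) on [0, 90]); infinity collapses theta onto ``mean_deg``.
    """

    mean_deg: float
    dispersion: float

    def __post_init__(self):
        if not (0.0 <= self.mean_deg <= 90.0):
            raise ValueError("mean fibre-to-field angle must lie in [0, 90] degrees")
        if self.dispersion < 0.0:
            raise ValueError("Watson concentration (dispersion) must be >= 0")


@dataclass(frozen=True)
class ROIConfig:
    """Generating truth for one tract ROI.

    Means/SDs are ppb; ``beta``/``tau`` are ppb per decade; ``lambda_``
    terms are ppb per unit lesion-load fraction.  ``mu_*``/``sigma_*`` map
    cohort name to value.  Lesion load for MS subjects is drawn from a
    zero-inflated Beta(``lesion_a``, ``lesion_b``) with P(0) =
    ``lesion_zero_prob``.
    """

    profile: AngleProfile
    mu_iso: dict
    mu_dchi: dict
    sigma_iso: dict
    sigma_dchi: dict
    beta_iso: float
    beta_dchi: float
    tau_iso_ms: float
    tau_dchi_ms: float
    lambda_iso_ms: float
    lambda_dchi_ms: float
    lesion_zero_prob: float = 0.25
    lesion_a: float = 1.3
    lesion_b: float = 15.0

    def __post_init__(self):
        for d in (self.sigma_iso, self.sigma_dchi):
            if any(v < 0 for v in d.values()):
                raise ValueError("cohort SDs must be >= 0")
        if not (0.0 <= self.lesion_zero_prob <= 1.0):
            raise ValueError("lesion_zero_prob must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic two-cohort dataset."""

    rois: dict  # name -> ROIConfig
    n_hc: int = 64
    n_ms: int = 89
    voxels_per_roi: int = 500
    voxel_noise_sd: float = 10.0
    # covariate samplers
    hc_age_mean: float = 35.0
    hc_age_sd: float = 10.0
    hc_age_range: tuple = (24.0, 66.0)
    ms_onset_mean: float = 29.0
    ms_onset_sd: float = 10.0
    ms_onset_range: tuple = (18.0, 55.0)
    dd_log_median: float = math.log(9.0)
    dd_log_sd: float = 0.6
    dd_range: tuple = (1.0, 32.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_hc <= 0 or self.n_ms <= 0 or self.voxels_per_roi <= 0:
            raise ValueError("cohort sizes and voxels_per_roi must be positive")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be >= 0")
        if not self.rois:
            raise ValueError("at least one ROI must be configured")


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-condition defaults: 64 HC / 89 MS, three tract ROIs.

    Apparent-MSA cohort means use the scenario values 27 (OR), 21 (SCC)
    and -30 ppb (SLF); the OR cohort difference of -6 ppb at a pooled SD
    of 10 ppb encodes a true effect size of -0.6.
    """
    rois = {
        "OR": ROIConfig(
            profile=AngleProfile(90.0, 12.0),
            mu_iso={"HC": -40.0, "MS": -39.0},
            mu_dchi={"HC": 27.0, "MS": 21.0},
            sigma_iso={"HC": 5.0, "MS": 5.0},
            sigma_dchi={"HC": 10.0, "MS": 10.0},
            beta_iso=3.0,
            beta_dchi=-2.0,
            tau_iso_ms=1.0,
            tau_dchi_ms=0.0,
            lambda_iso_ms=20.0,
            lambda_dchi_ms=-30.0,
            lesion_zero_prob=0.15,
            lesion_a=1.5,
            lesion_b=12.0,
        ),
        "SCC": ROIConfig(
            profile=AngleProfile(90.0, 40.0),
            mu_iso={"HC": -35.0, "MS": -34.0},
            mu_dchi={"HC": 21.0, "MS": 15.0},
            sigma_iso={"HC": 5.0, "MS": 5.0},
            sigma_dchi={"HC": 15.0, "MS": 15.0},
            beta_iso=5.0,
            beta_dchi=-5.0,
            tau_iso_ms=2.0,
            tau_dchi_ms=-10.0,
            lambda_iso_ms=-10.0,
            lambda_dchi_ms=10.0,
            lesion_zero_prob=0.40,
            lesion_a=1.2,
            lesion_b=20.0,
        ),
        "SLF": ROIConfig(
            profile=AngleProfile(45.0, 1.0),
            mu_iso={"HC": -15.0, "MS": -15.0},
            mu_dchi={"HC": -30.0, "MS": -28.0},
            sigma_iso={"HC": 5.0, "MS": 5.0},
            sigma_dchi={"HC": 8.0, "MS": 8.0},
            beta_iso=1.0,
            beta_dchi=1.0,
            tau_iso_ms=-1.0,
            tau_dchi_ms=3.0,
            lambda_iso_ms=-20.0,
            lambda_dchi_ms=20.0,
            lesion_zero_prob=0.25,
            lesion_a=1.2,
            lesion_b=15.0,
        ),
    }
    return GeneratorConfig(rois=rois, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# fibre-to-field angles


def _watson_cosines(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Cosines of the angle to the mean axis under Watson(kappa).

    Density proportional to exp(kappa * c^2) on [-1, 1].  Exact rejection
    sampler: |c| proposed from a truncated exponential on [0, 1] (density
    prop. to exp(kappa * c)), accepted with probability
    exp(kappa * (c^2 - c)) <= 1; acceptance >= ~1/2 for every kappa.
    """
    if kappa == 0.0:
        return rng.uniform(-1.0, 1.0, n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        u = rng.uniform(size=m)
        c = 1.0 + np.log(u + (1.0 - u) * math.exp(-kappa)) / kappa
        keep = np.log(rng.uniform(size=m)) < kappa * (c * c - c)
        c = c[keep][: n - filled]
        out[filled : filled + c.size] = c
        filled += c.size
    sign = rng.uniform(size=n) < 0.5
    return np.where(sign, out, -out)


def sample_fibre_angles(profile: AngleProfile, n: int, seed=None) -> np.ndarray:
    """Sample ``n`` fibre-to-field angles (degrees in [0, 90]) for a tract.

    Axes are drawn from a Watson distribution about a mean direction that
    makes ``profile.mean_deg`` with B0; the returned angle is between the
    sampled axis and B0, folded under antipodal symmetry.  ``seed`` may be
    an int or a ``numpy.random.Generator``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if math.isinf(profile.dispersion):
        return np.full(n, profile.mean_deg, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = math.radians(profile.mean_deg)
    mu = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
    # orthonormal frame about the mean axis
    e1 = np.array([math.cos(alpha), 0.0, -math.sin(alpha)])
    e2 = np.array([0.0, 1.0, 0.0])
    c = _watson_cosines(profile.dispersion, n, rng)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
    axes = (
        c[:, None] * mu
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
    cos_field = np.abs(axes[:, 2])
    return np.degrees(np.arccos(np.clip(cos_field, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# covariates and subject-level truth


def _truncated_normal(mean, sd, lo, hi, n, rng):
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_covariates(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Subject table: cohort membership and covariates.

    Columns: ``subject_id``, ``cohort``, ``age``, ``age_at_onset``,
    ``disease_duration`` (years) and one ``lesion_load_<ROI>`` fraction per
    ROI.  HC subjects have disease duration and lesion loads identically 0
    and ``age_at_onset`` equal to their age at examination (the ageing
    covariate of the analysis).  MS ages satisfy
    ``age = age_at_onset + disease_duration``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    rows = []
    hc_age = _truncated_normal(
        config.hc_age_mean, config.hc_age_sd, *config.hc_age_range, config.n_hc, rng
    )
    for i in range(config.n_hc):
        row = {
            "subject_id": f"HC{i + 1:03d}",
            "cohort": "HC",
            "age": float(hc_age[i]),
            "age_at_onset": float(hc_age[i]),
            "disease_duration": 0.0,
        }
        for roi in config.rois:
            row[f"lesion_load_{roi}"] = 0.0
        rows.append(row)
    onset = _truncated_normal(
        config.ms_onset_mean, config.ms_onset_sd, *config.ms_onset_range, config.n_ms, rng
    )
    dd = np.exp(rng.normal(config.dd_log_median, config.dd_log_sd, config.n_ms))
    dd = np.clip(dd, *config.dd_range)
    for i in range(config.n_ms):
        row = {
            "subject_id": f"MS{i + 1:03d}",
            "cohort": "MS",
            "age": float(onset[i] + dd[i]),
            "age_at_onset": float(onset[i]),
            "disease_duration": float(dd[i]),
        }
        for roi, rc in config.rois.items():
            if rng.uniform() < rc.lesion_zero_prob:
                row[f"lesion_load_{roi}"] = 0.0
            else:
                row[f"lesion_load_{roi}"] = float(rng.beta(rc.lesion_a, rc.lesion_b))
        rows.append(row)
    return pd.DataFrame(rows)


def _subject_truth(subjects: pd.DataFrame, config: GeneratorConfig, rng) -> pd.DataFrame:
    """Draw latent subject effects and tabulate effective components."""
    rows = []
    for _, s in subjects.iterrows():
        ao = (s["age_at_onset"] - AGE_REFERENCE) / AGE_SCALE
        dd = s["disease_duration"] / 10.0
        for roi, rc in config.rois.items():
            coh = s["cohort"]
            ll = s[f"lesion_load_{roi}"]
            chi_iso_subj = rng.normal(rc.mu_iso[coh], rc.sigma_iso[coh])
            dchi_subj = rng.normal(rc.mu_dchi[coh], rc.sigma_dchi[coh])
            is_ms = 1.0 if coh == "MS" else 0.0
            eff_iso = (
                chi_iso_subj
                + rc.beta_iso * ao
                + is_ms * (rc.tau_iso_ms * dd + rc.lambda_iso_ms * ll)
            )
            eff_dchi = (
                dchi_subj
                + rc.beta_dchi * ao
                + is_ms * (rc.tau_dchi_ms * dd + rc.lambda_dchi_ms * ll)
            )
            rows.append(
                {
                    "subject_id": s["subject_id"],
                    "cohort": coh,
                    "roi": roi,
                    "chi_iso_subj": chi_iso_subj,
                    "dchi_subj": dchi_subj,
                    "eff_chi_iso": eff_iso,
                    "eff_dchi": eff_dchi,
                }
            )
    return pd.DataFrame(rows)


def generate_subject_voxels(
    subject,
    config: GeneratorConfig,
    seed=None,
    rois=None,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Voxel table for one subject (a row of the subject table).

    Each voxel satisfies ``chi_app = eff_dchi * cos^2(theta) + eff_chi_iso
    + eps`` with ``eps ~ N(0, voxel_noise_sd)``; the effective components
    apply the ageing / disease-duration / lesion-load shifts to the
    subject's latent (chi_iso, dchi).  Pre-drawn latents can be supplied
    via ``truth`` (as returned by :func:`generate_cohort_dataset`);
    otherwise they are drawn here.  FA and peak-quotient columns are filled
    with values inside the crossing-fibre acceptance region.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rois is None:
        rois = list(config.rois)
    unknown = [r for r in rois if r not in config.rois]
    if unknown:
        raise KeyError(f"ROI(s) {unknown} not present in the generator configuration")
    if truth is None:
        truth = _subject_truth(pd.DataFrame([dict(subject)]), config, rng)
    frames = []
    for roi in rois:
        rc = config.rois[roi]
        t = truth[(truth["subject_id"] == subject["subject_id"]) & (truth["roi"] == roi)]
        eff_iso = float(t["eff_chi_iso"].iloc[0])
        eff_dchi = float(t["eff_dchi"].iloc[0])
        n = config.voxels_per_roi
        theta = sample_fibre_angles(rc.profile, n, rng)
        noise = rng.normal(0.0, config.voxel_noise_sd, n) if config.voxel_noise_sd > 0 else 0.0
        chi = eff_dchi * np.cos(np.deg2rad(theta)) ** 2 + eff_iso + noise
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject["subject_id"],
                    "cohort": subject["cohort"],
                    "roi": roi,
                    "theta_deg": theta,
                    "chi_app_ppb": chi,
                    "fa": 0.6 + 0.35 * rng.beta(2.0, 2.0, n),
                    "pq": 0.3 * rng.beta(1.5, 4.0, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic dataset: (voxel table, subject table, truth table).

    Deterministic given ``config.seed``.  The truth table records every
    subject-level generating value (latent and effective components); the
    population-level generating values live in ``config`` itself (see
    :func:`population_truth`).
    """
    rng = np.random.default_rng(config.seed)
    subjects = sample_covariates(config, rng)
    truth = _subject_truth(subjects, config, rng)
    frames = [
        generate_subject_voxels(s, config, rng, truth=truth)
        for _, s in subjects.iterrows()
    ]
    voxels = pd.concat(frames, ignore_index=True)
    return voxels, subjects, truth


def population_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Generating population parameters, named as in the multilevel model."""
    rows = []
    for roi, rc in config.rois.items():
        for coh in COHORTS:
            rows.append((roi, f"mu_iso_{coh}", rc.mu_iso[coh]))
            rows.append((roi, f"mu_dchi_{coh}", rc.mu_dchi[coh]))
            rows.append((roi, f"sigma_iso_{coh}", rc.sigma_iso[coh]))
            rows.append((roi, f"sigma_dchi_{coh}", rc.sigma_dchi[coh]))
        rows.append((roi, "beta_iso", rc.beta_iso))
        rows.append((roi, "beta_dchi", rc.beta_dchi))
        rows.append((roi, "tau_iso_MS", rc.tau_iso_ms))
        rows.append((roi, "tau_dchi_MS", rc.tau_dchi_ms))
        rows.append((roi, "lambda_iso_MS", rc.lambda_iso_ms))
        rows.append((roi, "lambda_dchi_MS", rc.lambda_dchi_ms))
        rows.append((roi, "noise_sd", config.voxel_noise_sd))
    return pd.DataFrame(rows, columns=["roi", "parameter", "value"])


def inject_orientation_artifact(
    voxels: pd.DataFrame, amplitude: float, seed=None, form: str = "cos2"
) -> pd.DataFrame:
    """Add a theta-correlated reconstruction bias of given RMS amplitude.

    ``form='cos2'`` adds ``amplitude * cos^2(theta)`` — fully collinear
    with the anisotropy regressor, shifting fitted dchi by exactly the
    amplitude in the noiseless case.  ``form='orthogonal'`` adds a
    cos^4-shaped bias residualized against [1, cos^2(theta)] within each
    (subject, ROI) group and scaled to the given RMS, which leaves OLS
    (dchi, chi_iso) unchanged.  ``amplitude=0`` is the identity.  The bias
    forms are deterministic; ``seed`` is accepted for interface uniformity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = voxels.copy()
    if amplitude == 0:
        return out
    c2 = np.cos(np.deg2rad(out["theta_deg"].to_numpy())) ** 2
    if form == "cos2":
        out["chi_app_ppb"] = out["chi_app_ppb"].to_numpy() + amplitude * c2
        return out
    if form != "orthogonal":
        raise ValueError("form must be 'cos2' or 'orthogonal'")
    chi = out["chi_app_ppb"].to_numpy(dtype=float).copy()
    for _, idx in out.groupby(["subject_id", "roi"]).indices.items():
        c = c2[idx]
        v = c**2
        X = np.column_stack([np.ones_like(c), c])
        resid = v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
        rms = np.sqrt(np.mean(resid**2))
        if rms > 0:
            chi[idx] = chi[idx] + amplitude * resid / rms
    out["chi_app_ppb"] = chi
    return out


# ---------------------------------------------------------------------------
# config I/O


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["rois"] = {}
    for roi, rc in config.rois.items():
        rd = asdict(rc)
        rd["profile"] = {"mean_deg": rc.profile.mean_deg, "dispersion": rc.profile.dispersion}
        d["rois"][roi] = rd
    d["hc_age_range"] = list(config.hc_age_range)
    d["ms_onset_range"] = list(config.ms_onset_range)
    d["dd_range"] = list(config.dd_range)
    return d


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    rois = {}
    for roi, rd in d.pop("rois").items():
        prof = AngleProfile(**rd.pop("profile"))
        rois[roi] = ROIConfig(profile=prof, **rd)
    for key in ("hc_age_range", "ms_onset_range", "dd_range"):
        d[key] = tuple(d[key])
    return GeneratorConfig(rois=rois, **d)
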