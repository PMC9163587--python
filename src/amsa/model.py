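"""Bayesian multilevel model of tract AMS across two cohorts.

For one tract ROI, every voxel of every subject is modelled as

    chi_app = [chi_iso_subj + beta_iso*AO + tau_iso*DD + lambda_iso*LL]
            + [dchi_subj   + beta_dchi*AO + tau_dchi*DD + lambda_dchi*LL] * cos^2(theta)
            + eps,      eps ~ Normal(0, noise_sd)

where AO is age (at onset) referenced to 30 years and scaled by 10 years,
DD is disease duration in decades (0 for controls), LL the lesion-load
fraction (0 for controls), and the subject-specific components are drawn
from cohort-specific normal distributions,

    chi_iso_subj ~ Normal(mu_iso_coh,  sigma_iso_coh)
    dchi_subj    ~ Normal(mu_dchi_coh, sigma_dchi_coh).

The ageing effect beta is shared by both cohorts; disease-duration and
lesion-load effects exist only for the MS cohort (the HC covariates are
structurally zero, so tau/lambda for HC are not parameters at all).
Priors are weakly informative on the standardized chi_app scale:
Normal(0, 1) for all location parameters — deliberately symmetric about
zero for the anisotropy terms, so a negative apparent MSA is admissible —
and Half-Normal(1) for all scales.

Inference
---------
The model is linear-Gaussian given its five scale parameters (four cohort
SDs and the voxel noise SD): both the subject effects and every
population-level location parameter (cohort means and covariate effects)
can be integrated out in closed form, using a 2x2 Woodbury identity per
subject and one rank-L update for the L location parameters.  Sampling
therefore proceeds as a fully collapsed scheme:

1. MCMC on the collapsed posterior of the scale parameters only —
   typically 5-dimensional, smooth and close to Gaussian on the log
   scale.  The default sampler is independence Metropolis-Hastings with a
   Laplace-approximation proposal (multivariate t fitted at the numerically
   located mode), which is exact MCMC and, because proposals do not depend
   on the current state, can be evaluated in a single vectorized pass;
   chains are independent restarts.  An affine-invariant ensemble sampler
   (emcee) is available as an alternative backend;
2. exact multivariate-normal draws of the location parameters from their
   Gaussian conditional, one per retained scale draw;
3. exact bivariate-normal draws of every subject's (chi_iso, dchi) pair
   from its full conditional.

The returned posterior covers all model parameters, and the conditional
draws in steps 2-3 carry no additional Monte-Carlo bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .orientation import StandardizationParams, standardize_ams

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "TractAnisotropyModel",
    "TractAnisotropyResults",
    "build_design_matrix",
    "sample_posterior",
    "convergence_diagnostics",
    "split_rhat",
    "fit_cohort_model",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Priors, covariate coding and MCMC settings.

    Prior scales refer to the standardized chi_app scale.  ``np.inf`` for
    ``mu_prior_scale`` gives a flat prior on the cohort means.  ``fixed_*``
    values (data units, i.e. ppb when the input is in ppb) remove the
    corresponding scale parameter from sampling — used for degenerate
    analytic checks.  ``sampler`` selects the scale-parameter MCMC:
    ``"imh"`` (default) runs ``chains`` independence Metropolis-Hastings
    chains of ``n_steps`` draws (after ``n_warmup`` discarded) against a
    multivariate-t Laplace proposal with ``proposal_df`` degrees of
    freedom and covariance inflated by ``proposal_inflation``;
    ``"ensemble"`` runs ``chains`` independent emcee ensembles of
    ``n_walkers`` walkers.  Retained draws are thinned to at most
    ``thin_target`` per chain.
    """

    mu_prior_scale: float = 1.0
    effect_prior_scale: float = 1.0
    sigma_prior_scale: float = 1.0
    noise_prior_scale: float = 1.0
    age_reference: float = 30.0
    age_scale: float = 10.0
    include_covariates: bool = True
    fixed_noise_sd: float | None = None
    fixed_sigma_iso: float | None = None
    fixed_sigma_dchi: float | None = None
    sampler: str = "imh"
    chains: int = 4
    n_walkers: int = 48
    n_warmup: int = 200
    n_steps: int = 3000
    thin_target: int = 1000
    proposal_df: float = 6.0
    proposal_inflation: float = 1.15
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least two chains are required for diagnostics")
        for name in (
            "effect_prior_scale",
            "sigma_prior_scale",
            "noise_prior_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_prior_scale <= 0:
            raise ValueError("mu_prior_scale must be positive (np.inf for flat)")
        if self.sampler not in ("imh", "ensemble"):
            raise ValueError("sampler must be 'imh' or 'ensemble'")


def build_design_matrix(
    subjects: pd.DataFrame, roi: str, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Per-subject covariate rows for one ROI.

    The ageing covariate ``ao_scaled`` uses age at examination for HC and
    age at onset for MS, referenced and scaled per ``spec`` (default
    (x - 30)/10).  ``dd_decades`` is disease duration / 10 and
    ``ll_fraction`` the ROI lesion-load fraction; both are 0 for HC.
    """
    spec = spec or ModelSpec()
    for col in ("subject_id", "cohort", "age"):
        if col not in subjects.columns:
            raise ValueError(f"subject table lacks required column {col!r}")
    rows = []
    for _, s in subjects.iterrows():
        coh = s["cohort"]
        if coh not in ("HC", "MS"):
            raise ValueError(f"unknown cohort {coh!r}")
        if coh == "HC":
            ao_years, dd, ll = s["age"], 0.0, 0.0
        else:
            ao_years = s.get("age_at_onset", np.nan)
            dd = s.get("disease_duration", np.nan)
            ll = s.get(f"lesion_load_{roi}", s.get("lesion_load", np.nan))
            if any(pd.isna(v) for v in (ao_years, dd, ll)):
                raise ValueError(
                    f"MS subject {s['subject_id']!r} lacks age_at_onset, "
                    f"disease_duration or lesion load for ROI {roi!r}"
                )
        if pd.isna(ao_years):
            raise ValueError(f"subject {s['subject_id']!r} lacks age information")
        if not (0.0 <= ll <= 1.0):
            raise ValueError("lesion load must be a fraction in [0, 1]")
        rows.append(
            {
                "subject_id": s["subject_id"],
                "cohort": coh,
                "ao_scaled": (float(ao_years) - spec.age_reference) / spec.age_scale,
                "dd_decades": float(dd) / 10.0,
                "ll_fraction": float(ll),
                "roi": roi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PosteriorSamples:
    """MCMC draws for all model parameters, shaped (chain, draw[, subject]).

    Population-level draws are keyed by parameter name (``mu_iso_HC``,
    ``mu_dchi_MS``, ``beta_iso``, ``tau_dchi_MS``, ``lambda_iso_MS``,
    ``sigma_dchi_HC``, ``noise_sd``, ...); subject-level draws are under
    ``chi_iso_subj`` and ``dchi_subj`` with a trailing subject axis aligned
    with ``subject_ids``.
    """

    population: dict
    subject: dict
    subject_ids: list
    subject_cohorts: list

    @property
    def n_chains(self) -> int:
        return next(iter(self.population.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.population.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one population parameter, chains concatenated."""
        return self.population[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: chain, draw, parameter, value."""
        recs = []
        for name, arr in self.population.items():
            c, d = arr.shape
            recs.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def to_inference_data(self):
        """arviz.InferenceData view of the population-level draws."""
        import arviz as az

        return az.from_dict(posterior=dict(self.population))


class _ParamLayout:
    """Names, priors and transforms for the model parameters.

    Scale parameters (cohort SDs, noise SD) are sampled by MCMC on the log
    scale; location parameters (means and covariate effects) are
    marginalized during sampling and drawn from their exact Gaussian
    conditional afterwards.
    """

    def __init__(self, cohorts, spec: ModelSpec, fixed: dict, covariate_sds: dict | None = None):
        self.spec = spec
        self.fixed = dict(fixed)  # natural name -> value on model scale
        self.scale_entries = []  # (name, prior half-normal scale)
        for coh in cohorts:
            if spec.fixed_sigma_iso is None:
                self.scale_entries.append((f"sigma_iso_{coh}", spec.sigma_prior_scale))
            if spec.fixed_sigma_dchi is None:
                self.scale_entries.append((f"sigma_dchi_{coh}", spec.sigma_prior_scale))
        if spec.fixed_noise_sd is None:
            self.scale_entries.append(("noise_sd", spec.noise_prior_scale))
        self.loc_entries = []  # (name, prior normal scale)
        for coh in cohorts:
            self.loc_entries.append((f"mu_iso_{coh}", spec.mu_prior_scale))
            self.loc_entries.append((f"mu_dchi_{coh}", spec.mu_prior_scale))
        if spec.include_covariates:
            # effect priors are autoscaled by the covariate's spread so that
            # "weakly informative" holds per covariate SD, not per raw unit
            sds = covariate_sds or {}

            def esc(cov_name):
                return spec.effect_prior_scale / max(sds.get(cov_name, 1.0), 1e-6)

            self.loc_entries.append(("beta_iso", esc("ao")))
            self.loc_entries.append(("beta_dchi", esc("ao")))
            if "MS" in cohorts:
                for nm, cv in (
                    ("tau_iso_MS", "dd"),
                    ("tau_dchi_MS", "dd"),
                    ("lambda_iso_MS", "ll"),
                    ("lambda_dchi_MS", "ll"),
                ):
                    self.loc_entries.append((nm, esc(cv)))
        self.scale_names = [e[0] for e in self.scale_entries]
        self.loc_names = [e[0] for e in self.loc_entries]
        self.ndim = len(self.scale_entries)

    def unpack_scales(self, vec: np.ndarray) -> dict:
        """(K, P) log-scale vectors -> dict of (K,) positive SDs + fixed."""
        vec = np.atleast_2d(vec)
        out = {name: np.exp(vec[:, j]) for j, (name, _) in enumerate(self.scale_entries)}
        for name, val in self.fixed.items():
            out[name] = np.full(vec.shape[0], val)
        return out

    def pack_scales(self, values: dict) -> np.ndarray:
        return np.array([math.log(float(values[name])) for name, _ in self.scale_entries])

    def log_prior_scales(self, vec: np.ndarray) -> np.ndarray:
        """Half-Normal priors on the SDs, with the log-transform Jacobian."""
        vec = np.atleast_2d(vec)
        lp = np.zeros(vec.shape[0])
        for j, (_, scale) in enumerate(self.scale_entries):
            x = vec[:, j]
            sigma = np.exp(x)
            lp += (
                0.5 * math.log(2.0 / math.pi)
                - math.log(scale)
                - 0.5 * (sigma / scale) ** 2
                + x
            )
        return lp

    def log_prior_locations(self, loc: dict) -> float:
        lp = 0.0
        for name, scale in self.loc_entries:
            if np.isfinite(scale):
                x = float(loc[name])
                lp += -0.5 * (x / scale) ** 2 - math.log(scale) - 0.5 * _LOG2PI
        return lp


class TractAnisotropyModel:
    """Multilevel cohort model for one tract ROI.

    Build with :meth:`from_tables`; call :meth:`fit` to sample the
    posterior.  ``chi_app`` is standardized internally (pooled across
    subjects within the ROI) and every reported draw is rescaled back to
    the input units.
    """

    def __init__(
        self,
        voxels: pd.DataFrame,
        design: pd.DataFrame,
        roi: str,
        spec: ModelSpec | None = None,
        standardization: StandardizationParams | None = None,
    ):
        self.spec = spec or ModelSpec()
        self.roi = roi
        self.design = design.reset_index(drop=True)
        self.standardization = standardization
        self.cohorts = tuple(c for c in ("HC", "MS") if (self.design["cohort"] == c).any())
        if not self.cohorts:
            raise ValueError("no subjects in design")
        self._prepare(voxels)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        voxels: pd.DataFrame,
        subjects: pd.DataFrame,
        roi: str,
        spec: ModelSpec | None = None,
        standardize: bool = True,
    ) -> "TractAnisotropyModel":
        """Build the model for ``roi`` from voxel and subject tables."""
        spec = spec or ModelSpec()
        vox = voxels[voxels["roi"] == roi]
        if vox.empty:
            raise ValueError(f"no voxels for ROI {roi!r}")
        subs = subjects[subjects["subject_id"].isin(vox["subject_id"].unique())]
        design = build_design_matrix(subs, roi, spec)
        standardization = None
        if standardize:
            vox, params = standardize_ams(vox)
            standardization = params[roi]
        return cls(vox, design, roi, spec=spec, standardization=standardization)

    def _prepare(self, voxels: pd.DataFrame) -> None:
        """Sufficient statistics and design maps used by every density."""
        spec = self.spec
        ids = list(self.design["subject_id"])
        stats = {"n": [], "Sc": [], "Scc": [], "Sy": [], "Syc": [], "Syy": []}
        grouped = dict(iter(voxels.groupby("subject_id")))
        for sid in ids:
            if sid not in grouped:
                raise ValueError(f"subject {sid!r} has no voxels in ROI {self.roi!r}")
            g = grouped[sid]
            c = np.cos(np.deg2rad(g["theta_deg"].to_numpy(dtype=float))) ** 2
            y = g["chi_app_ppb"].to_numpy(dtype=float)
            stats["n"].append(c.size)
            stats["Sc"].append(c.sum())
            stats["Scc"].append((c * c).sum())
            stats["Sy"].append(y.sum())
            stats["Syc"].append((y * c).sum())
            stats["Syy"].append((y * y).sum())
        self._st = {k: np.asarray(v, dtype=float) for k, v in stats.items()}
        self.n_subjects = len(ids)
        self.n_voxels = int(self._st["n"].sum())
        self._is_ms = (self.design["cohort"] == "MS").to_numpy()
        self._coh_idx = self._is_ms.astype(int)  # 0 = HC, 1 = MS
        self._ao = self.design["ao_scaled"].to_numpy(dtype=float)
        self._dd = self.design["dd_decades"].to_numpy(dtype=float)
        self._ll = self.design["ll_fraction"].to_numpy(dtype=float)
        # fixed scale parameters, converted to the (standardized) model scale
        s = self.standardization.sd if self.standardization is not None else 1.0
        fixed = {}
        if spec.fixed_noise_sd is not None:
            fixed["noise_sd"] = spec.fixed_noise_sd / s
        for coh in self.cohorts:
            if spec.fixed_sigma_iso is not None:
                fixed[f"sigma_iso_{coh}"] = spec.fixed_sigma_iso / s
            if spec.fixed_sigma_dchi is not None:
                fixed[f"sigma_dchi_{coh}"] = spec.fixed_sigma_dchi / s
        cov_sds = {
            "ao": float(np.std(self._ao)),
            "dd": float(np.std(self._dd)),
            "ll": float(np.std(self._ll)),
        }
        self._layout = _ParamLayout(self.cohorts, spec, fixed, covariate_sds=cov_sds)
        # location design: prior mean of subject (intercept, slope) is
        # (Ga @ loc, Gb @ loc) for the location parameter vector loc
        L = len(self._layout.loc_entries)
        S = self.n_subjects
        Ga = np.zeros((S, L))
        Gb = np.zeros((S, L))
        col = {name: j for j, (name, _) in enumerate(self._layout.loc_entries)}
        for coh in self.cohorts:
            m = (self.design["cohort"] == coh).to_numpy()
            Ga[m, col[f"mu_iso_{coh}"]] = 1.0
            Gb[m, col[f"mu_dchi_{coh}"]] = 1.0
        if spec.include_covariates:
            Ga[:, col["beta_iso"]] = self._ao
            Gb[:, col["beta_dchi"]] = self._ao
            if "MS" in self.cohorts:
                Ga[:, col["tau_iso_MS"]] = self._dd
                Gb[:, col["tau_dchi_MS"]] = self._dd
                Ga[:, col["lambda_iso_MS"]] = self._ll
                Gb[:, col["lambda_dchi_MS"]] = self._ll
        self._Ga, self._Gb = Ga, Gb
        # per-subject outer products, flattened for fast batched contraction
        self._out_aa = np.einsum("si,sj->sij", Ga, Ga).reshape(S, L * L)
        self._out_ab = (
            np.einsum("si,sj->sij", Ga, Gb) + np.einsum("si,sj->sij", Gb, Ga)
        ).reshape(S, L * L)
        self._out_bb = np.einsum("si,sj->sij", Gb, Gb).reshape(S, L * L)
        self._vp_inv = np.array(
            [0.0 if not np.isfinite(sc) else 1.0 / sc**2 for _, sc in self._layout.loc_entries]
        )
        self._log_vp = float(
            sum(2.0 * math.log(sc) for _, sc in self._layout.loc_entries if np.isfinite(sc))
        )

    # -- densities ---------------------------------------------------------

    def _subject_scales(self, p: dict) -> tuple[np.ndarray, np.ndarray]:
        def stack(name):
            fallback = next(v for k, v in p.items() if k.startswith(name))
            return np.stack(
                [p.get(f"{name}_{coh}", fallback) for coh in ("HC", "MS")], axis=1
            )

        sa, sb = stack("sigma_iso"), stack("sigma_dchi")
        return sa[:, self._coh_idx], sb[:, self._coh_idx]

    def _per_subject_gaussians(self, p: dict):
        """2x2 Woodbury pieces of each subject's marginal Gaussian.

        Given scale draws ``p`` (dict of (K,) arrays), returns per-subject
        quantities of shape (K, S): the information matrix J = X' Sigma^-1 X,
        the projected data h = X' Sigma^-1 y, the scalar y' Sigma^-1 y and
        log|Sigma|, where Sigma = noise^2 I + X diag(sig_a^2, sig_b^2) X'.
        """
        st = self._st
        sig_a, sig_b = self._subject_scales(p)
        sn2 = (p["noise_sd"] ** 2)[:, None]
        n, Sc, Scc = st["n"], st["Sc"], st["Scc"]
        A11 = 1.0 / sig_a**2 + n / sn2
        A22 = 1.0 / sig_b**2 + Scc / sn2
        A12 = Sc / sn2
        detA = A11 * A22 - A12**2
        # B = (X'X) A^-1 (X'X): exploit symmetry of X'X = [[n, Sc], [Sc, Scc]]
        # A^-1 = [[A22, -A12], [-A12, A11]] / detA
        i11, i12, i22 = A22 / detA, -A12 / detA, A11 / detA
        B11 = n * n * i11 + 2 * n * Sc * i12 + Sc * Sc * i22
        B12 = n * Sc * i11 + (n * Scc + Sc * Sc) * i12 + Sc * Scc * i22
        B22 = Sc * Sc * i11 + 2 * Sc * Scc * i12 + Scc * Scc * i22
        J11 = n / sn2 - B11 / sn2**2
        J12 = Sc / sn2 - B12 / sn2**2
        J22 = Scc / sn2 - B22 / sn2**2
        hy1, hy2 = st["Sy"], st["Syc"]
        w1 = i11 * hy1 + i12 * hy2
        w2 = i12 * hy1 + i22 * hy2
        h1 = hy1 / sn2 - (n * w1 + Sc * w2) / sn2**2
        h2 = hy2 / sn2 - (Sc * w1 + Scc * w2) / sn2**2
        r0 = st["Syy"] / sn2 - (hy1 * w1 + hy2 * w2) / sn2**2
        logdet = n * np.log(sn2) + 2 * np.log(sig_a) + 2 * np.log(sig_b) + np.log(detA)
        return J11, J12, J22, h1, h2, r0, logdet

    def _collapsed_moments(self, p: dict):
        """Precision P = Vp^-1 + F' Sigma^-1 F and b = F' Sigma^-1 y, batched."""
        J11, J12, J22, h1, h2, r0, logdet = self._per_subject_gaussians(p)
        Ga, Gb = self._Ga, self._Gb
        L = Ga.shape[1]
        M = (J11 @ self._out_aa + J12 @ self._out_ab + J22 @ self._out_bb).reshape(
            -1, L, L
        )
        b = h1 @ Ga + h2 @ Gb
        P = M + np.diag(self._vp_inv)
        return P, b, r0.sum(axis=1), logdet.sum(axis=1)

    def collapsed_loglike(self, vec: np.ndarray) -> np.ndarray:
        """Log-likelihood of the scale parameters with subject effects AND
        location parameters integrated out (up to an additive constant)."""
        vec = np.atleast_2d(vec)
        p = self._layout.unpack_scales(vec)
        P, b, r0, logdet = self._collapsed_moments(p)
        sign, logdetP = np.linalg.slogdet(P)
        sol = np.linalg.solve(P, b[..., None])[..., 0]
        quad = np.einsum("ki,ki->k", b, sol)
        N = self.n_voxels
        return -0.5 * (
            N * _LOG2PI + logdet + self._log_vp + logdetP + r0 - quad
        )

    def log_prob(self, vec: np.ndarray) -> np.ndarray:
        """Collapsed posterior log-density of the scale parameters."""
        vec = np.atleast_2d(vec)
        lp = self._layout.log_prior_scales(vec)
        ok = np.isfinite(lp)
        out = np.full(vec.shape[0], -np.inf)
        if np.any(ok):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                ll = self.collapsed_loglike(vec[ok])
            ll[~np.isfinite(ll)] = -np.inf
            out[ok] = lp[ok] + ll
        return out

    def loglike_marginal(self, scales: dict, locations: dict) -> float:
        """Marginal log-likelihood with only the subject effects integrated
        out, given scalar scale and location parameters (model scale)."""
        p = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in scales.items()}
        for name, val in self._layout.fixed.items():
            p.setdefault(name, np.atleast_1d(float(val)))
        loc = np.array([float(locations[name]) for name in self._layout.loc_names])
        J11, J12, J22, h1, h2, r0, logdet = self._per_subject_gaussians(p)
        mu_a = self._Ga @ loc
        mu_b = self._Gb @ loc
        quad = (
            J11[0] * mu_a**2
            + 2 * J12[0] * mu_a * mu_b
            + J22[0] * mu_b**2
            - 2 * (h1[0] * mu_a + h2[0] * mu_b)
            + r0[0] * 1.0
        )
        # r0 already sums y'Sigma^-1 y per subject; assemble the quadratic form
        n_total = self.n_voxels
        return float(
            -0.5 * (n_total * _LOG2PI + logdet[0].sum() + quad.sum() + 0.0)
        )

    def log_joint_density(self, params: dict) -> float:
        """Full joint log-density including subject-level effects.

        ``params`` maps every population parameter name to a scalar plus
        ``chi_iso_subj`` / ``dchi_subj`` arrays aligned with the design
        rows, all on the model's (standardized) data scale.  Returns -inf
        for out-of-support scale parameters, never NaN.
        """
        for name in self._layout.scale_names + list(self._layout.fixed):
            if params[name] <= 0:
                return -np.inf
        scales = {
            name: np.atleast_1d(float(params[name]))
            for name in self._layout.scale_names + list(self._layout.fixed)
        }
        loc = {name: float(params[name]) for name in self._layout.loc_names}
        sig_a, sig_b = self._subject_scales(scales)
        a = np.asarray(params["chi_iso_subj"], dtype=float)
        b = np.asarray(params["dchi_subj"], dtype=float)
        loc_vec = np.array([loc[name] for name in self._layout.loc_names])
        mu_a = self._Ga @ loc_vec
        mu_b = self._Gb @ loc_vec
        # covariate contributions shift the subject effects inside the mean
        mu_only_a = np.zeros_like(mu_a)
        mu_only_b = np.zeros_like(mu_b)
        for coh in self.cohorts:
            m = self.design["cohort"].to_numpy() == coh
            mu_only_a[m] = loc[f"mu_iso_{coh}"]
            mu_only_b[m] = loc[f"mu_dchi_{coh}"]
        cov_a = mu_a - mu_only_a
        cov_b = mu_b - mu_only_b
        lp = float(
            np.sum(_norm_logpdf(a, mu_only_a, sig_a[0]))
            + np.sum(_norm_logpdf(b, mu_only_b, sig_b[0]))
        )
        a_eff = a + cov_a
        b_eff = b + cov_b
        st = self._st
        sn = float(scales["noise_sd"][0])
        rtr = (
            st["Syy"]
            - 2.0 * (a_eff * st["Sy"] + b_eff * st["Syc"])
            + a_eff**2 * st["n"]
            + 2.0 * a_eff * b_eff * st["Sc"]
            + b_eff**2 * st["Scc"]
        )
        lp += float(np.sum(-0.5 * (st["n"] * (_LOG2PI + 2.0 * math.log(sn)) + rtr / sn**2)))
        free_scales = self._layout.pack_scales({k: params[k] for k in self._layout.scale_names}) if self._layout.scale_names else np.empty(0)
        if self._layout.scale_names:
            lp += float(self._layout.log_prior_scales(free_scales[None, :])[0])
        lp += self._layout.log_prior_locations(loc)
        return lp

    # -- sampling ----------------------------------------------------------

    def _initial_scales(self) -> dict:
        """Moment-based starting SDs from per-subject OLS fits."""
        st = self._st
        n, Sc, Scc = st["n"], st["Sc"], st["Scc"]
        det = n * Scc - Sc**2
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (n * st["Syc"] - Sc * st["Sy"]) / det
            a = (st["Sy"] - b * Sc) / n
        resid_var = np.maximum(
            (
                st["Syy"]
                - 2 * a * st["Sy"]
                - 2 * b * st["Syc"]
                + a**2 * n
                + 2 * a * b * Sc
                + b**2 * Scc
            )
            / np.maximum(n - 2, 1),
            1e-12,
        )
        vals = {}
        for coh in self.cohorts:
            m = (self.design["cohort"] == coh).to_numpy()
            vals[f"sigma_iso_{coh}"] = float(max(np.std(a[m]), 0.05))
            vals[f"sigma_dchi_{coh}"] = float(max(np.std(b[m]), 0.05))
        vals["noise_sd"] = float(max(np.sqrt(np.mean(resid_var)), 1e-3))
        return vals

    def fit(self, seed: int | None = None, **overrides) -> "TractAnisotropyResults":
        """Sample the posterior and return a results object.

        ``overrides`` may adjust any :class:`ModelSpec` MCMC field
        (``chains``, ``n_walkers``, ``n_warmup``, ``n_steps``, ...)
        without rebuilding the model.
        """
        spec = replace(self.spec, **overrides) if overrides else self.spec
        layout = self._layout
        ndim = layout.ndim
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        chain_seeds = ss.spawn(spec.chains + 2)
        if ndim > 0:
            if spec.sampler == "imh":
                chains_out = self._run_imh(
                    spec, chain_seeds[: spec.chains], chain_seeds[spec.chains]
                )
            else:
                chains_out = self._run_ensembles(spec, chain_seeds[: spec.chains])
        else:
            # every scale fixed: the posterior over the remaining parameters
            # is exactly Gaussian; draws below are i.i.d. conditionals
            chains_out = [
                np.empty((spec.thin_target, 0)) for _ in range(spec.chains)
            ]
        draws = np.stack(chains_out)  # (chains, kept, ndim)
        n_chains, n_kept, _ = draws.shape
        scales_flat = layout.unpack_scales(draws.reshape(n_chains * n_kept, ndim))
        rng = np.random.default_rng(chain_seeds[-1])
        loc_flat = self._draw_locations(scales_flat, rng)
        subject_std = self._sample_subject_effects(scales_flat, loc_flat, rng)
        population_std = {
            name: loc_flat[name].reshape(n_chains, n_kept) for name in layout.loc_names
        }
        for name, arr in scales_flat.items():
            population_std[name] = arr.reshape(n_chains, n_kept)
        subject_std = {
            k: v.reshape(n_chains, n_kept, self.n_subjects) for k, v in subject_std.items()
        }
        population, subject = self._rescale(population_std, subject_std)
        posterior = PosteriorSamples(
            population=population,
            subject=subject,
            subject_ids=list(self.design["subject_id"]),
            subject_cohorts=list(self.design["cohort"]),
        )
        diagnostics = convergence_diagnostics(posterior)
        max_rhat = float(diagnostics["rhat"].max())
        converged = max_rhat < spec.rhat_threshold
        if not converged:
            warnings.warn(
                f"ROI {self.roi}: split-R-hat {max_rhat:.3f} exceeds "
                f"{spec.rhat_threshold}; treat posterior summaries with caution",
                RuntimeWarning,
                stacklevel=2,
            )
        return TractAnisotropyResults(
            model=self,
            posterior=posterior,
            diagnostics=diagnostics,
            converged=converged,
            seed=seed,
        )

    def _sigma_log_prob(self, S: np.ndarray) -> np.ndarray:
        """Collapsed posterior density of the scale SDs on the natural scale.

        The IMH proposal lives on the sigma scale, where the target's
        density is bounded near zero (so independence proposals cover it);
        points outside the positive orthant get -inf.
        """
        S = np.atleast_2d(S)
        out = np.full(S.shape[0], -np.inf)
        ok = np.all(S > 0, axis=1)
        if np.any(ok):
            vec = np.log(S[ok])
            out[ok] = self.log_prob(vec) - vec.sum(axis=1)
        return out

    def _laplace_proposal(self, spec: ModelSpec):
        """Mode and covariance of the collapsed scale posterior (sigma scale)."""
        from scipy import optimize

        x0 = self._layout.pack_scales(self._initial_scales())

        def neg(v):
            return -float(self.log_prob(v[None, :])[0])

        res = optimize.minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        mode = np.exp(res.x)
        ndim = mode.size
        # central-difference Hessian of the negative log-density in sigma,
        # with steps kept inside the positive orthant
        h = np.maximum(1e-5, 0.01 * mode)
        h = np.minimum(h, 0.4 * mode)
        H = np.zeros((ndim, ndim))
        for i in range(ndim):
            for j in range(i, ndim):
                d = h[i] * _e(i, ndim) + h[j] * _e(j, ndim)
                dm = h[i] * _e(i, ndim) - h[j] * _e(j, ndim)
                pts = np.array([mode + d, mode + dm, mode - dm, mode - d])
                f = -self._sigma_log_prob(pts)
                H[i, j] = H[j, i] = (f[0] - f[1] - f[2] + f[3]) / (4 * h[i] * h[j])
        H = np.nan_to_num(H, nan=0.0, posinf=0.0, neginf=0.0)
        try:
            w, V = np.linalg.eigh(H)
        except np.linalg.LinAlgError:
            w, V = np.ones(ndim), np.eye(ndim)
        floor = max(1e-8, 1e-3 * float(np.max(np.abs(w))) if np.any(w > 0) else 1.0)
        w = np.maximum(w, floor)
        cov = (V / w) @ V.T * spec.proposal_inflation**2
        # cap proposal spread: the posterior SD cannot plausibly exceed the
        # mode by orders of magnitude on any axis
        cap = np.outer(mode + 1.0, mode + 1.0)
        cov = np.clip(cov, -cap, cap)
        if np.any(np.diag(cov) <= 0):
            cov = cov + np.diag(0.01 * (mode + 0.1) ** 2)
        return mode, cov

    def _adapt_proposal(self, spec: ModelSpec, mode, cov, rng, n_pilot: int = 3000):
        """Refine the proposal by importance-weighted moment matching.

        The Laplace covariance can be far too narrow when a cohort SD is
        weakly identified (a nearly flat likelihood profile, as happens for
        the anisotropy SD in tracts with a narrow angle range).  Two rounds
        of truncated importance sampling against a defensive mixture
        re-estimate the posterior mean and covariance of the scales and
        typically fix such directions.
        """
        from scipy.special import logsumexp
        from scipy.stats import multivariate_t

        center = mode.copy()
        for _ in range(2):
            comps = [
                (0.85, multivariate_t(loc=center, shape=cov, df=spec.proposal_df)),
                (0.15, multivariate_t(loc=center, shape=cov * 9.0, df=3)),
            ]
            which = rng.random(n_pilot) < comps[0][0]
            ndim = center.size
            P1 = np.atleast_2d(comps[0][1].rvs(size=n_pilot, random_state=rng)).reshape(n_pilot, ndim)
            P2 = np.atleast_2d(comps[1][1].rvs(size=n_pilot, random_state=rng)).reshape(n_pilot, ndim)
            props = np.where(which[:, None], P1, P2)
            lq = logsumexp(
                np.stack([np.log(a) + d.logpdf(props) for a, d in comps]), axis=0
            )
            lw = self._sigma_log_prob(props) - lq
            ok = np.isfinite(lw)
            if ok.sum() < 50:
                break
            w = np.exp(lw[ok] - lw[ok].max())
            # truncated importance weights stabilise the moment estimates
            w = np.minimum(w, np.sqrt(ok.sum()) * w.mean())
            w /= w.sum()
            pts = props[ok]
            center = w @ pts
            d = pts - center
            cov_new = (d * w[:, None]).T @ d
            cov = cov_new + np.diag(np.full(center.size, 1e-8))
        return center, cov

    def _run_imh(self, spec: ModelSpec, chain_seeds, adapt_seed) -> list:
        """Independence MH against an adaptively fitted mixture proposal.

        The proposal mixes a multivariate t (Laplace fit refined by
        importance-weighted moment matching) with a wider, heavier-tailed
        component — a standard defensive mixture keeping importance ratios
        bounded.  Proposals do not depend on the current state, so each
        chain needs exactly one batched density evaluation; the
        accept/reject recursion is a cheap scalar loop.  Chains are
        returned on the log-sigma scale.
        """
        from scipy.special import logsumexp
        from scipy.stats import multivariate_t

        mode, cov = self._laplace_proposal(spec)
        mode, cov = self._adapt_proposal(
            spec, mode, cov, np.random.default_rng(adapt_seed)
        )
        cov = cov * spec.proposal_inflation**2
        ndim = mode.size
        comps = [
            (0.85, multivariate_t(loc=mode, shape=cov, df=spec.proposal_df)),
            (0.15, multivariate_t(loc=mode, shape=cov * 9.0, df=3)),
        ]
        n_tot = spec.n_warmup + spec.n_steps

        def mix_logpdf(pts):
            return logsumexp(
                np.stack([np.log(a) + d.logpdf(pts) for a, d in comps]), axis=0
            )

        w_mode = float(self._sigma_log_prob(mode[None, :])[0] - mix_logpdf(mode[None, :].reshape(1, -1)))
        chains_out = []
        for c in range(spec.chains):
            rng = np.random.default_rng(chain_seeds[c])
            which = rng.random(n_tot) < comps[0][0]
            props = np.where(
                which[:, None],
                np.atleast_2d(comps[0][1].rvs(size=n_tot, random_state=rng)).reshape(n_tot, ndim),
                np.atleast_2d(comps[1][1].rvs(size=n_tot, random_state=rng)).reshape(n_tot, ndim),
            )
            lp = self._sigma_log_prob(props)
            lq = np.atleast_1d(mix_logpdf(props))
            logu = np.log(rng.uniform(size=n_tot))
            cur, cur_w = mode, w_mode
            out = np.empty((n_tot, ndim))
            for t in range(n_tot):
                w = lp[t] - lq[t]
                if np.isfinite(w) and logu[t] < w - cur_w:
                    cur, cur_w = props[t], w
                out[t] = cur
            flat = np.log(out[spec.n_warmup :])
            if flat.shape[0] > spec.thin_target:
                idx = np.round(np.linspace(0, flat.shape[0] - 1, spec.thin_target)).astype(int)
                flat = flat[idx]
            chains_out.append(flat)
        return chains_out

    def _run_ensembles(self, spec: ModelSpec, chain_seeds) -> list:
        import emcee

        layout = self._layout
        ndim = layout.ndim
        n_walkers = max(spec.n_walkers, 2 * ndim + 2)
        center = layout.pack_scales(self._initial_scales())
        chains_out = []
        for c in range(spec.chains):
            rng = np.random.default_rng(chain_seeds[c])
            p0 = center[None, :] + 0.2 * rng.standard_normal((n_walkers, ndim))
            sampler = emcee.EnsembleSampler(n_walkers, ndim, self.log_prob, vectorize=True)
            sampler.random_state = np.random.RandomState(
                int(rng.integers(2**31 - 1))
            ).get_state()
            sampler.run_mcmc(p0, spec.n_warmup + spec.n_steps, progress=False)
            chain = sampler.get_chain()[spec.n_warmup :]  # (steps, walkers, dim)
            flat = chain.reshape(-1, ndim)  # step-major order
            if flat.shape[0] > spec.thin_target:
                idx = np.round(np.linspace(0, flat.shape[0] - 1, spec.thin_target)).astype(int)
                flat = flat[idx]
            chains_out.append(flat)
        return chains_out

    def _draw_locations(self, scales_flat: dict, rng) -> dict:
        """Exact MVN draws of the location parameters per scale draw."""
        P, b, _, _ = self._collapsed_moments(scales_flat)
        mean = np.linalg.solve(P, b[..., None])[..., 0]  # (D, L)
        cov = np.linalg.inv(P)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal(mean.shape)
        loc = mean + np.einsum("kij,kj->ki", chol, z)
        return {name: loc[:, j] for j, name in enumerate(self._layout.loc_names)}

    def _sample_subject_effects(self, scales_flat: dict, loc_flat: dict, rng) -> dict:
        """Exact bivariate-normal conditional draws of the subject effects."""
        st = self._st
        loc = np.stack([loc_flat[name] for name in self._layout.loc_names], axis=1)
        mu_a = loc @ self._Ga.T  # (D, S) prior means including covariates
        mu_b = loc @ self._Gb.T
        sig_a, sig_b = self._subject_scales(scales_flat)
        sn2 = (scales_flat["noise_sd"] ** 2)[:, None]
        n, Sc, Scc = st["n"], st["Sc"], st["Scc"]
        A11 = 1.0 / sig_a**2 + n / sn2
        A22 = 1.0 / sig_b**2 + Scc / sn2
        A12 = Sc / sn2
        detA = A11 * A22 - A12**2
        rhs_a = mu_a / sig_a**2 + st["Sy"] / sn2
        rhs_b = mu_b / sig_b**2 + st["Syc"] / sn2
        mean_a = (A22 * rhs_a - A12 * rhs_b) / detA
        mean_b = (A11 * rhs_b - A12 * rhs_a) / detA
        C11 = A22 / detA
        C12 = -A12 / detA
        C22 = A11 / detA
        L11 = np.sqrt(C11)
        L21 = C12 / L11
        L22 = np.sqrt(np.maximum(C22 - L21**2, 1e-300))
        z1 = rng.standard_normal(mean_a.shape)
        z2 = rng.standard_normal(mean_a.shape)
        a_eff = mean_a + L11 * z1
        b_eff = mean_b + L21 * z1 + L22 * z2
        # subtract covariate contributions to recover the latent effects
        mu_only_a = np.zeros_like(mu_a)
        mu_only_b = np.zeros_like(mu_b)
        for coh in self.cohorts:
            m = self.design["cohort"].to_numpy() == coh
            mu_only_a[:, m] = loc_flat[f"mu_iso_{coh}"][:, None]
            mu_only_b[:, m] = loc_flat[f"mu_dchi_{coh}"][:, None]
        return {
            "chi_iso_subj": a_eff - (mu_a - mu_only_a),
            "dchi_subj": b_eff - (mu_b - mu_only_b),
        }

    def _rescale(self, population_std: dict, subject_std: dict) -> tuple[dict, dict]:
        """Map standardized-scale draws back to input (ppb) units."""
        if self.standardization is None:
            return population_std, subject_std
        m, s = self.standardization.mean, self.standardization.sd
        population = {}
        for name, arr in population_std.items():
            if name.startswith("mu_iso"):
                population[name] = m + s * arr
            else:
                population[name] = s * arr
        subject = {
            "chi_iso_subj": m + s * subject_std["chi_iso_subj"],
            "dchi_subj": s * subject_std["dchi_subj"],
        }
        return population, subject

    # -- posterior predictive ---------------------------------------------

    def posterior_predictive(
        self,
        posterior: PosteriorSamples,
        theta_by_subject: dict | None = None,
        n_draws: int = 200,
        seed: int | None = None,
        voxels: pd.DataFrame | None = None,
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Simulate voxel tables from retained posterior draws.

        For each of ``n_draws`` (evenly thinned) draws, simulates
        ``chi_app = a_s + b_s cos^2(theta) + noise`` on the input units for
        every subject's theta set (``theta_by_subject`` maps subject_id to
        angle arrays; defaults to each subject's observed angles when
        ``voxels`` is given).  Returns (simulations, index): simulations of
        shape (n_draws, n_voxels) and a table mapping columns to
        subject/theta.
        """
        rng = np.random.default_rng(seed)
        if theta_by_subject is None:
            if voxels is None:
                raise ValueError("provide theta_by_subject or a voxel table")
            theta_by_subject = {
                sid: g["theta_deg"].to_numpy(dtype=float)
                for sid, g in voxels[voxels["roi"] == self.roi].groupby("subject_id")
            }
        total = posterior.n_chains * posterior.n_draws
        take = np.round(np.linspace(0, total - 1, min(n_draws, total))).astype(int)
        pop = {k: v.reshape(-1)[take] for k, v in posterior.population.items()}
        a = posterior.subject["chi_iso_subj"].reshape(total, -1)[take]
        b = posterior.subject["dchi_subj"].reshape(total, -1)[take]
        zero = np.zeros(take.size)
        cov_a = (
            pop.get("beta_iso", zero)[:, None] * self._ao
            + pop.get("tau_iso_MS", zero)[:, None] * self._dd
            + pop.get("lambda_iso_MS", zero)[:, None] * self._ll
        )
        cov_b = (
            pop.get("beta_dchi", zero)[:, None] * self._ao
            + pop.get("tau_dchi_MS", zero)[:, None] * self._dd
            + pop.get("lambda_dchi_MS", zero)[:, None] * self._ll
        )
        a_eff = a + cov_a
        b_eff = b + cov_b
        cols = []
        sims = []
        sid_index = {sid: i for i, sid in enumerate(self.design["subject_id"])}
        for sid, theta in theta_by_subject.items():
            i = sid_index[sid]
            c2 = np.cos(np.deg2rad(np.asarray(theta, dtype=float))) ** 2
            mean = a_eff[:, i : i + 1] + b_eff[:, i : i + 1] * c2[None, :]
            noise = rng.standard_normal(mean.shape) * pop["noise_sd"][:, None]
            sims.append(mean + noise)
            cols.append(
                pd.DataFrame({"subject_id": sid, "theta_deg": np.asarray(theta, dtype=float)})
            )
        return np.concatenate(sims, axis=1), pd.concat(cols, ignore_index=True)


def _norm_logpdf(x, mu, sd):
    return -0.5 * (_LOG2PI + 2.0 * np.log(sd) + ((x - mu) / sd) ** 2)


def _e(i, n):
    v = np.zeros(n)
    v[i] = 1.0
    return v


# ---------------------------------------------------------------------------
# diagnostics and results


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of one parameter from (chains, draws) samples.

    Each chain is split in half and the pooled-vs-within variance ratio is
    formed; values below 1 (an artefact of the finite-sample correction)
    are clipped to exactly 1.0, so identical chains report 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    c, n = draws.shape
    if c < 2:
        raise ValueError("split-R-hat needs at least two chains")
    half = n // 2
    parts = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    _, nn = parts.shape
    W = parts.var(axis=1, ddof=1).mean()
    B = nn * parts.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (nn - 1) / nn * W + B / nn
    return float(max(math.sqrt(var_plus / W), 1.0))


def convergence_diagnostics(posterior: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and effective sample size per population parameter."""
    if posterior.n_chains < 2:
        raise ValueError("diagnostics require at least two chains")
    import arviz as az

    rows = []
    for name, arr in posterior.population.items():
        if np.ptp(arr) == 0.0:
            ess = float(arr.size)  # fixed parameter: degenerate draws
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess = float(az.ess(np.asarray(arr)))
        rows.append({"parameter": name, "rhat": split_rhat(arr), "ess": min(ess, arr.size)})
    return pd.DataFrame(rows)


class TractAnisotropyResults:
    """Posterior draws, diagnostics and summaries for one ROI fit."""

    def __init__(self, model, posterior, diagnostics, converged, seed=None):
        self.model = model
        self.roi = model.roi
        self.posterior = posterior
        self.diagnostics = diagnostics
        self.converged = converged
        self.seed = seed
        self.standardization = model.standardization

    def summary(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        """MAP, HDI and P(>0) per population parameter, in input units."""
        from .summary import summarize_posterior

        return summarize_posterior(self.posterior, roi=self.roi, hdi_mass=hdi_mass)

    def effect_sizes(self) -> dict:
        """Per-draw standardized cohort differences for iso and dchi."""
        from .summary import effect_size_posterior

        return effect_size_posterior(self.posterior)

    def posterior_predictive(self, **kwargs):
        return self.model.posterior_predictive(self.posterior, **kwargs)

    def __repr__(self):
        return (
            f"<TractAnisotropyResults roi={self.roi!r} "
            f"chains={self.posterior.n_chains} draws={self.posterior.n_draws} "
            f"converged={self.converged}>"
        )


def sample_posterior(
    voxels: pd.DataFrame,
    subjects: pd.DataFrame,
    roi: str,
    spec: ModelSpec | None = None,
    seed: int | None = None,
) -> TractAnisotropyResults:
    """One-call interface: build the ROI model and sample its posterior."""
    model = TractAnisotropyModel.from_tables(voxels, subjects, roi, spec=spec)
    return model.fit(seed=seed)


def fit_cohort_model(
    voxels: pd.DataFrame,
    subjects: pd.DataFrame,
    rois=None,
    spec: ModelSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Fit every ROI independently; returns {roi: TractAnisotropyResults}."""
    if rois is None:
        rois = sorted(voxels["roi"].unique())
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child = ss.generate_state(len(rois)) % (2**31 - 1)
    return {
        roi: sample_posterior(voxels, subjects, roi, spec=spec, seed=int(child[i]))
        for i, roi in enumerate(rois)
    }
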