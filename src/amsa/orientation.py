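"""Tract-level orientation dependence of apparent magnetic susceptibility.

A single-orientation QSM reconstruction assigns each white-matter voxel a
scalar apparent magnetic susceptibility (AMS, ``chi_app``).  For a fibre
bundle whose susceptibility tensor is radially symmetric about the fibre
axis, the AMS varies with the fibre-to-field angle theta as

    chi_app(theta) = (chi_par - chi_perp) * cos^2(theta) + chi_0

Within one tract ROI the same relation is treated as a regression problem,

    chi_app(theta) = dchi * cos^2(theta) + chi_iso,

so that the slope ``dchi`` (apparent magnetic susceptibility anisotropy) and
the intercept ``chi_iso`` (isotropic AMS) can be estimated from the natural
spread of fibre-to-field angles inside the tract, without re-orienting the
subject in the scanner.

This module implements the tensor-to-apparent relation, the per-subject
ordinary-least-squares fit, decile binning of AMS(theta) curves for
visualisation, and the ROI-wise standardization used before hierarchical
modelling.  All susceptibilities are in ppb; angles are degrees in [0, 90]
at the API surface (antipodal fibre symmetry folds theta and 180-theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TensorParams",
    "SubjectFit",
    "BinnedCurve",
    "StandardizationParams",
    "apparent_from_tensor",
    "fit_subject_regression",
    "fit_all_subjects",
    "bin_by_angle_deciles",
    "standardize_ams",
    "rescale_coefficients",
]


@dataclass(frozen=True)
class TensorParams:
    """Radially symmetric fibre susceptibility tensor (ppb).

    ``chi_par`` and ``chi_perp`` are the tensor components parallel and
    perpendicular to the fibre axis; ``chi0`` subsumes every
    orientation-independent contribution to the AMS.
    """

    chi_par: float
    chi_perp: float
    chi0: float


@dataclass(frozen=True)
class SubjectFit:
    """OLS estimates of (dchi, chi_iso) for one subject in one ROI."""

    subject_id: str
    roi: str
    delta_chi: float
    chi_iso: float
    n_voxels: int
    residual_sd: float


@dataclass(frozen=True)
class BinnedCurve:
    """Equally populated theta-decile summary of one subject's AMS(theta)."""

    bin_edges: np.ndarray
    bin_mean_theta: np.ndarray
    bin_mean_chi: np.ndarray
    bin_counts: np.ndarray


@dataclass(frozen=True)
class StandardizationParams:
    """Pooled mean/SD used to standardize chi_app within one ROI."""

    roi: str
    mean: float
    sd: float


def _check_theta(theta_deg: np.ndarray) -> np.ndarray:
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg < 0.0) or np.any(theta_deg > 90.0):
        raise ValueError("fibre-to-field angles must lie in [0, 90] degrees")
    return theta_deg


def apparent_from_tensor(params: TensorParams, theta_deg) -> np.ndarray | float:
    """Apparent susceptibility of a fibre at angle ``theta_deg`` to the field.

    Returns ``(chi_par - chi_perp) * cos^2(theta) + chi0`` (ppb).  At 90
    degrees only the orientation-independent term ``chi0`` remains.
    """
    theta = _check_theta(theta_deg)
    out = (params.chi_par - params.chi_perp) * np.cos(np.deg2rad(theta)) ** 2 + params.chi0
    if np.isscalar(theta_deg):
        return float(out)
    return out


def fit_subject_regression(voxels: pd.DataFrame) -> SubjectFit:
    """OLS of chi_app on cos^2(theta) with intercept for one subject/ROI.

    ``voxels`` must carry columns ``theta_deg`` and ``chi_app_ppb`` (and,
    for labelling, ``subject_id`` and ``roi``).  The slope estimates the
    apparent MSA ``dchi`` and the intercept the isotropic AMS ``chi_iso``.

    Raises ``ValueError`` when fewer than two voxels or fewer than two
    distinct angles are present (the slope is then unestimable).
    """
    theta = _check_theta(voxels["theta_deg"].to_numpy())
    y = voxels["chi_app_ppb"].to_numpy(dtype=float)
    if theta.size < 2:
        raise ValueError("need at least two voxels to fit (dchi, chi_iso)")
    c2 = np.cos(np.deg2rad(theta)) ** 2
    if np.ptp(c2) == 0.0:
        raise ValueError(
            "all voxels share one fibre-to-field angle: dchi is unestimable "
            "(rank-deficient design)"
        )
    X = np.column_stack([c2, np.ones_like(c2)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(theta.size - 2, 1)
    sid = str(voxels["subject_id"].iloc[0]) if "subject_id" in voxels else ""
    roi = str(voxels["roi"].iloc[0]) if "roi" in voxels else ""
    return SubjectFit(
        subject_id=sid,
        roi=roi,
        delta_chi=float(coef[0]),
        chi_iso=float(coef[1]),
        n_voxels=int(theta.size),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def fit_all_subjects(voxels: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-ROI OLS fits as a tidy table (Fig.-style diagnostic)."""
    rows = []
    for (sid, roi), grp in voxels.groupby(["subject_id", "roi"], sort=True):
        fit = fit_subject_regression(grp)
        rows.append(
            {
                "subject_id": sid,
                "roi": roi,
                "delta_chi_ppb": fit.delta_chi,
                "chi_iso_ppb": fit.chi_iso,
                "n_voxels": fit.n_voxels,
                "residual_sd_ppb": fit.residual_sd,
            }
        )
    return pd.DataFrame(rows)


def bin_by_angle_deciles(voxels: pd.DataFrame, n_bins: int = 10) -> BinnedCurve:
    """Bin one subject's voxels into equally populated theta bins.

    Voxels are ordered by theta (stable sort, so ties keep input order) and
    partitioned into ``n_bins`` contiguous groups whose sizes differ by at
    most one; remainder voxels go to the lowest bins.  Per-bin mean theta
    and mean chi_app trace the subject's AMS(theta) curve.
    """
    theta = _check_theta(voxels["theta_deg"].to_numpy())
    chi = voxels["chi_app_ppb"].to_numpy(dtype=float)
    n = theta.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} voxels for {n_bins} bins, got {n}")
    order = np.argsort(theta, kind="stable")
    theta, chi = theta[order], chi[order]
    base, rem = divmod(n, n_bins)
    counts = np.full(n_bins, base, dtype=int)
    counts[:rem] += 1
    stops = np.cumsum(counts)
    starts = stops - counts
    mean_theta = np.array([theta[a:b].mean() for a, b in zip(starts, stops)])
    mean_chi = np.array([chi[a:b].mean() for a, b in zip(starts, stops)])
    edges = np.concatenate([[theta[0]], theta[stops[:-1] - 1], [theta[-1]]])
    return BinnedCurve(
        bin_edges=edges,
        bin_mean_theta=mean_theta,
        bin_mean_chi=mean_chi,
        bin_counts=counts,
    )


def standardize_ams(
    voxels: pd.DataFrame, column: str = "chi_app_ppb"
) -> tuple[pd.DataFrame, dict[str, StandardizationParams]]:
    """Demean and unit-scale chi_app pooled across subjects, per ROI.

    Returns a copy of the table with ``column`` standardized within each ROI
    (population SD, ddof=0) plus the per-ROI parameters needed to map model
    coefficients back to ppb.  Raises on an ROI with zero variance.
    """
    out = voxels.copy()
    params: dict[str, StandardizationParams] = {}
    for roi, grp in voxels.groupby("roi", sort=True):
        vals = grp[column].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise ValueError(f"ROI {roi!r}: chi_app has zero variance, cannot standardize")
        m, s = float(vals.mean()), float(vals.std(ddof=0))
        out.loc[grp.index, column] = (vals - m) / s
        params[roi] = StandardizationParams(roi=str(roi), mean=m, sd=s)
    return out, params


def rescale_coefficients(
    values, params: StandardizationParams, kind: str = "slope"
) -> np.ndarray | float:
    """Map coefficients estimated on the standardized scale back to ppb.

    ``kind='slope'`` (dchi-like means, beta/tau/lambda effects, SDs, noise)
    multiplies by the ROI SD; ``kind='intercept'`` (chi_iso-like means)
    additionally shifts by the ROI mean.
    """
    if kind not in ("slope", "intercept"):
        raise ValueError("kind must be 'slope' or 'intercept'")
    arr = np.asarray(values, dtype=float) * params.sd
    if kind == "intercept":
        arr = arr + params.mean
    if np.isscalar(values):
        return float(arr)
    return arr
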