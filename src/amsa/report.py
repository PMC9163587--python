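"""Report rendering: decile curves, posterior densities, summary tables.

Produces, per ROI, the standard presentation of this analysis: the
AMS(theta) decile curves of individual subjects, marginal posterior
density plots annotated with the MAP (dashed vertical line) and the 95%
HDI (solid horizontal bar), and a machine-readable summary (TSV + JSON)
of MAP / HDI / P(>0) / effect sizes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .orientation import bin_by_angle_deciles
from .summary import hdi, map_estimate

logger = logging.getLogger(__name__)

__all__ = ["render_report", "plot_decile_curves", "plot_posterior_density"]


def plot_decile_curves(voxels: pd.DataFrame, roi: str, ax=None, n_bins: int = 10):
    """Thin per-subject AMS(theta) decile curves plus the cohort averages."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    colors = {"HC": "tab:blue", "MS": "tab:red"}
    sub = voxels[voxels["roi"] == roi]
    for coh, cgrp in sub.groupby("cohort"):
        curves = []
        for _, g in cgrp.groupby("subject_id"):
            if len(g) < n_bins:
                continue
            curve = bin_by_angle_deciles(g, n_bins=n_bins)
            ax.plot(
                curve.bin_mean_theta,
                curve.bin_mean_chi,
                color=colors.get(coh, "grey"),
                alpha=0.15,
                lw=0.7,
            )
            curves.append((curve.bin_mean_theta, curve.bin_mean_chi))
        if curves:
            t = np.mean([c[0] for c in curves], axis=0)
            m = np.mean([c[1] for c in curves], axis=0)
            ax.plot(t, m, color=colors.get(coh, "grey"), lw=2.0, label=coh)
    ax.set_xlabel(r"fibre-to-field angle $\theta$ (deg)")
    ax.set_ylabel(r"$\chi_{app}$ (ppb)")
    ax.set_title(roi)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_posterior_density(draws, name: str, ax=None, hdi_mass: float = 0.95):
    """KDE-style density with MAP (dashed) and HDI (horizontal bar)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 2.4))
    x = np.asarray(draws, dtype=float).reshape(-1)
    lo, hi = hdi(x, hdi_mass)
    mp = map_estimate(x)
    counts, edges = np.histogram(x, bins=80, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.plot(centers, counts, color="k", lw=1.0)
    ax.axvline(mp, ls="--", color="k", lw=1.0)
    ax.hlines(0.0, lo, hi, color="k", lw=2.5)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_title(name, fontsize=9)
    ax.set_yticks([])
    return ax, (mp, lo, hi)


def render_report(
    voxels: pd.DataFrame,
    results_by_roi: dict,
    out_dir,
    subject_fits: pd.DataFrame | None = None,
    hdi_mass: float = 0.95,
) -> dict:
    """Write the full report bundle for a set of fitted ROIs.

    Emits ``summary.tsv`` (one row per population parameter per ROI, plus
    effect sizes when both cohorts are present), ``summary.json`` with the
    same numbers, ``decile_curves_<roi>.png`` and ``posteriors_<roi>.png``.
    ROIs present in the voxel table but without a fit are skipped with a
    logged warning.  Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_rows = []
    bundle: dict = {"rois": {}}
    for roi in sorted(voxels["roi"].unique()):
        if roi not in results_by_roi:
            logger.warning("ROI %s has voxels but no fitted model; skipping", roi)
            continue
        res = results_by_roi[roi]
        summ = res.summary(hdi_mass=hdi_mass)
        cohorts = set(res.posterior.subject_cohorts)
        roi_entry = {"parameters": summ.to_dict(orient="records")}
        if {"HC", "MS"} <= cohorts:
            es = res.effect_sizes()
            for comp in ("eta_iso", "eta_dchi"):
                s = es[comp]
                summ = pd.concat(
                    [
                        summ,
                        pd.DataFrame(
                            [
                                {
                                    "roi": roi,
                                    "parameter": comp,
                                    "map": s.map_estimate,
                                    "hdi_low": s.hdi_low,
                                    "hdi_high": s.hdi_high,
                                    "prob_above_zero": s.prob_above_zero,
                                }
                            ]
                        ),
                    ],
                    ignore_index=True,
                )
            roi_entry["effect_sizes"] = {
                comp: {
                    "map": es[comp].map_estimate,
                    "hdi_low": es[comp].hdi_low,
                    "hdi_high": es[comp].hdi_high,
                    "prob_above_zero": es[comp].prob_above_zero,
                }
                for comp in ("eta_iso", "eta_dchi")
            }
        all_rows.append(summ)
        bundle["rois"][roi] = roi_entry

        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        plot_decile_curves(voxels, roi, ax=ax)
        fig.tight_layout()
        fig.savefig(out / f"decile_curves_{roi}.png", dpi=120)
        plt.close(fig)

        names = [n for n in res.posterior.population if n.startswith(("mu_", "beta", "tau", "lambda"))]
        ncol = 4
        nrow = int(np.ceil(len(names) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.0 * ncol, 2.2 * nrow), squeeze=False)
        for k, name in enumerate(names):
            ax = axes[k // ncol][k % ncol]
            plot_posterior_density(res.posterior.flat(name), name, ax=ax, hdi_mass=hdi_mass)
        for k in range(len(names), nrow * ncol):
            axes[k // ncol][k % ncol].axis("off")
        fig.suptitle(roi)
        fig.tight_layout()
        fig.savefig(out / f"posteriors_{roi}.png", dpi=120)
        plt.close(fig)

    if all_rows:
        table = pd.concat(all_rows, ignore_index=True)
        table.to_csv(out / "summary.tsv", sep="\t", index=False)
    if subject_fits is not None:
        subject_fits.to_csv(out / "subject_fits.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle
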