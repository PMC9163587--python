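"""Tests of the multilevel cohort model and its sampler."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag
from scipy.stats import halfnorm, multivariate_normal, norm

from amsa.model import (
    ModelSpec,
    TractAnisotropyModel,
    build_design_matrix,
    convergence_diagnostics,
    split_rhat,
)
from amsa.simulate import default_config, generate_cohort_dataset


@pytest.fixture(scope="module")
def small_fit(tiny_dataset):
    """One fast posterior fit shared across structural tests."""
    _, voxels, subjects, _ = tiny_dataset
    model = TractAnisotropyModel.from_tables(voxels, subjects, "SLF")
    return model, model.fit(seed=21, n_steps=600)


class TestDesignMatrix:
    def test_reference_aged_control_is_all_zero(self):
        subs = pd.DataFrame(
            {"subject_id": ["a"], "cohort": ["HC"], "age": [30.0]}
        )
        row = build_design_matrix(subs, "OR").iloc[0]
        assert row.ao_scaled == 0.0 and row.dd_decades == 0.0 and row.ll_fraction == 0.0

    def test_ms_scaling_rules(self):
        subs = pd.DataFrame(
            {
                "subject_id": ["m"],
                "cohort": ["MS"],
                "age": [49.0],
                "age_at_onset": [40.0],
                "disease_duration": [9.0],
                "lesion_load_OR": [0.12],
            }
        )
        row = build_design_matrix(subs, "OR").iloc[0]
        assert row.ao_scaled == pytest.approx(1.0)
        assert row.dd_decades == pytest.approx(0.9)
        assert row.ll_fraction == pytest.approx(0.12)

    def test_hc_uses_age_at_examination(self):
        subs = pd.DataFrame({"subject_id": ["a"], "cohort": ["HC"], "age": [50.0]})
        assert build_design_matrix(subs, "OR").iloc[0].ao_scaled == pytest.approx(2.0)

    def test_missing_ms_covariates_raise(self):
        subs = pd.DataFrame(
            {"subject_id": ["m"], "cohort": ["MS"], "age": [40.0]}
        )
        with pytest.raises(ValueError, match="lacks"):
            build_design_matrix(subs, "OR")

    def test_unknown_cohort_rejected(self):
        subs = pd.DataFrame({"subject_id": ["x"], "cohort": ["CIS"], "age": [40.0]})
        with pytest.raises(ValueError):
            build_design_matrix(subs, "OR")


class TestDensities:
    def _hand_joint(self, theta, y, params):
        c2 = math.cos(math.radians(theta)) ** 2
        return (
            norm.logpdf(y, params["chi_iso_subj"][0] + params["dchi_subj"][0] * c2, params["noise_sd"])
            + norm.logpdf(params["chi_iso_subj"][0], params["mu_iso_HC"], params["sigma_iso_HC"])
            + norm.logpdf(params["dchi_subj"][0], params["mu_dchi_HC"], params["sigma_dchi_HC"])
            + norm.logpdf(params["mu_iso_HC"], 0, 1)
            + norm.logpdf(params["mu_dchi_HC"], 0, 1)
            + sum(
                halfnorm.logpdf(params[k], scale=1.0) + math.log(params[k])
                for k in ("sigma_iso_HC", "sigma_dchi_HC", "noise_sd")
            )
        )

    def _one_voxel_model(self):
        vox = pd.DataFrame(
            {
                "subject_id": ["A"],
                "cohort": ["HC"],
                "roi": ["OR"],
                "theta_deg": [60.0],
                "chi_app_ppb": [-30.0],
            }
        )
        subs = pd.DataFrame({"subject_id": ["A"], "cohort": ["HC"], "age": [30.0]})
        return TractAnisotropyModel.from_tables(
            vox, subs, "OR", spec=ModelSpec(include_covariates=False), standardize=False
        )

    def test_log_joint_matches_hand_computation(self):
        m = self._one_voxel_model()
        params = dict(
            mu_iso_HC=-35.0, mu_dchi_HC=20.0, sigma_iso_HC=5.0, sigma_dchi_HC=8.0,
            noise_sd=10.0, chi_iso_subj=np.array([-33.0]), dchi_subj=np.array([18.0]),
        )
        assert m.log_joint_density(params) == pytest.approx(
            self._hand_joint(60.0, -30.0, params), abs=1e-10
        )

    def test_log_joint_out_of_support_is_neg_inf(self):
        m = self._one_voxel_model()
        params = dict(
            mu_iso_HC=0.0, mu_dchi_HC=0.0, sigma_iso_HC=-1.0, sigma_dchi_HC=8.0,
            noise_sd=10.0, chi_iso_subj=np.array([0.0]), dchi_subj=np.array([0.0]),
        )
        val = m.log_joint_density(params)
        assert val == -np.inf and not np.isnan(val)

    def test_log_joint_concave_around_conditional_mode(self, tiny_dataset):
        _, voxels, subjects, _ = tiny_dataset
        m = TractAnisotropyModel.from_tables(voxels, subjects, "OR", standardize=False)
        base = dict(
            mu_iso_HC=-40.0, mu_dchi_HC=27.0, mu_iso_MS=-39.0, mu_dchi_MS=21.0,
            sigma_iso_HC=5.0, sigma_dchi_HC=10.0, sigma_iso_MS=5.0, sigma_dchi_MS=10.0,
            beta_iso=3.0, beta_dchi=-2.0, tau_iso_MS=1.0, tau_dchi_MS=0.0,
            lambda_iso_MS=20.0, lambda_dchi_MS=-30.0, noise_sd=10.0,
            chi_iso_subj=np.full(m.n_subjects, -40.0),
            dchi_subj=np.full(m.n_subjects, 25.0),
        )
        # scan one subject's dchi effect over 11 points: unimodal in that
        # coordinate (Gaussian conditional), decreasing away from the peak
        vals = []
        for delta in np.linspace(-20, 20, 11):
            p = dict(base)
            d = base["dchi_subj"].copy()
            d[0] += delta
            p["dchi_subj"] = d
            vals.append(m.log_joint_density(p))
        peak = int(np.argmax(vals))
        assert np.all(np.diff(vals[: peak + 1]) > 0)
        assert np.all(np.diff(vals[peak:]) < 0)

    def test_duplicating_voxels_doubles_likelihood_part(self):
        vox = pd.DataFrame(
            {
                "subject_id": ["A"] * 3,
                "cohort": ["HC"] * 3,
                "roi": ["OR"] * 3,
                "theta_deg": [10.0, 40.0, 80.0],
                "chi_app_ppb": [-20.0, -28.0, -38.0],
            }
        )
        subs = pd.DataFrame({"subject_id": ["A"], "cohort": ["HC"], "age": [30.0]})
        spec = ModelSpec(include_covariates=False)
        m1 = TractAnisotropyModel.from_tables(vox, subs, "OR", spec=spec, standardize=False)
        m2 = TractAnisotropyModel.from_tables(
            pd.concat([vox, vox], ignore_index=True), subs, "OR", spec=spec, standardize=False
        )
        params = dict(
            mu_iso_HC=-35.0, mu_dchi_HC=20.0, sigma_iso_HC=5.0, sigma_dchi_HC=8.0,
            noise_sd=10.0, chi_iso_subj=np.array([-33.0]), dchi_subj=np.array([18.0]),
        )
        # subtracting the (identical) prior+hierarchy parts leaves the voxel
        # likelihood, which doubles exactly
        zero_vox_part = (
            norm.logpdf(-33.0, -35.0, 5.0)
            + norm.logpdf(18.0, 20.0, 8.0)
            + norm.logpdf(-35.0, 0, 1) + norm.logpdf(20.0, 0, 1)
            + sum(halfnorm.logpdf(v, scale=1) + math.log(v) for v in (5.0, 8.0, 10.0))
        )
        l1 = m1.log_joint_density(params) - zero_vox_part
        l2 = m2.log_joint_density(params) - zero_vox_part
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_collapsed_likelihood_matches_dense_gaussian(self):
        cfg = default_config(seed=3, n_hc=3, n_ms=3, voxels_per_roi=8)
        voxels, subjects, _ = generate_cohort_dataset(cfg)
        m = TractAnisotropyModel.from_tables(voxels, subjects, "OR", standardize=False)
        lay = m._layout
        vec = lay.pack_scales(m._initial_scales())
        ours = m.collapsed_loglike(vec[None, :])[0]
        # dense oracle: y ~ N(0, blockdiag(Sigma_s) + F Vp F')
        p = lay.unpack_scales(vec[None, :])
        sa, sb = m._subject_scales(p)
        blocks, Fs, ys = [], [], []
        for i, sid in enumerate(m.design.subject_id):
            g = voxels[(voxels.subject_id == sid) & (voxels.roi == "OR")]
            c = np.cos(np.deg2rad(g.theta_deg.values)) ** 2
            X = np.column_stack([np.ones_like(c), c])
            D = np.diag([sa[0, i] ** 2, sb[0, i] ** 2])
            blocks.append(p["noise_sd"][0] ** 2 * np.eye(len(c)) + X @ D @ X.T)
            Fs.append(X @ np.column_stack([m._Ga[i], m._Gb[i]]).T)
            ys.append(g.chi_app_ppb.values)
        Sig = block_diag(*blocks)
        F = np.vstack(Fs)
        Vp = np.diag([sc**2 for _, sc in lay.loc_entries])
        y = np.concatenate(ys)
        oracle = multivariate_normal.logpdf(y, np.zeros(len(y)), Sig + F @ Vp @ F.T)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_subject_marginal_likelihood_matches_dense_gaussian(self):
        cfg = default_config(seed=3, n_hc=3, n_ms=3, voxels_per_roi=8)
        voxels, subjects, _ = generate_cohort_dataset(cfg)
        m = TractAnisotropyModel.from_tables(voxels, subjects, "OR", standardize=False)
        scales = m._initial_scales()
        locs = {n: 0.5 for n in m._layout.loc_names}
        ours = m.loglike_marginal(scales, locs)
        p = {k: np.atleast_1d(v) for k, v in scales.items()}
        sa, sb = m._subject_scales(p)
        loc = np.array([locs[n] for n in m._layout.loc_names])
        mu_a, mu_b = m._Ga @ loc, m._Gb @ loc
        oracle = 0.0
        for i, sid in enumerate(m.design.subject_id):
            g = voxels[(voxels.subject_id == sid) & (voxels.roi == "OR")]
            c = np.cos(np.deg2rad(g.theta_deg.values)) ** 2
            X = np.column_stack([np.ones_like(c), c])
            Sig = p["noise_sd"][0] ** 2 * np.eye(len(c)) + X @ np.diag(
                [sa[0, i] ** 2, sb[0, i] ** 2]
            ) @ X.T
            oracle += multivariate_normal.logpdf(
                g.chi_app_ppb.values, X @ np.array([mu_a[i], mu_b[i]]), Sig
            )
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_likelihood_invariant_to_voxel_and_subject_order(self):
        cfg = default_config(seed=4, n_hc=3, n_ms=3, voxels_per_roi=10)
        voxels, subjects, _ = generate_cohort_dataset(cfg)
        spec = ModelSpec()
        m1 = TractAnisotropyModel.from_tables(voxels, subjects, "SCC", spec=spec)
        shuffled = voxels.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m2 = TractAnisotropyModel.from_tables(shuffled, subjects, "SCC", spec=spec)
        vec = m1._layout.pack_scales(m1._initial_scales())
        assert m1.collapsed_loglike(vec[None, :])[0] == pytest.approx(
            m2.collapsed_loglike(vec[None, :])[0], rel=1e-10
        )


class TestSampling:
    def test_same_seed_identical_draws(self, tiny_dataset):
        _, voxels, subjects, _ = tiny_dataset
        m = TractAnisotropyModel.from_tables(voxels, subjects, "OR")
        r1 = m.fit(seed=5, n_steps=300)
        r2 = m.fit(seed=5, n_steps=300)
        for name in r1.posterior.population:
            np.testing.assert_array_equal(
                r1.posterior.population[name], r2.posterior.population[name]
            )
        np.testing.assert_array_equal(
            r1.posterior.subject["dchi_subj"], r2.posterior.subject["dchi_subj"]
        )

    def test_posterior_covers_all_parameter_groups(self, small_fit):
        model, res = small_fit
        pop = res.posterior.population
        for name in (
            "mu_iso_HC", "mu_dchi_HC", "mu_iso_MS", "mu_dchi_MS",
            "sigma_iso_HC", "sigma_dchi_MS", "beta_iso", "beta_dchi",
            "tau_iso_MS", "tau_dchi_MS", "lambda_iso_MS", "lambda_dchi_MS",
            "noise_sd",
        ):
            assert name in pop
            assert np.all(np.isfinite(pop[name]))
        assert np.all(pop["sigma_iso_HC"] > 0)
        assert np.all(pop["noise_sd"] > 0)
        assert res.posterior.subject["chi_iso_subj"].shape[-1] == model.n_subjects

    def test_hc_only_model_omits_disease_effects(self, tiny_dataset):
        _, voxels, subjects, _ = tiny_dataset
        hc_vox = voxels[voxels.cohort == "HC"]
        hc_sub = subjects[subjects.cohort == "HC"]
        m = TractAnisotropyModel.from_tables(hc_vox, hc_sub, "OR")
        res = m.fit(seed=6, n_steps=300)
        pop = res.posterior.population
        for name in ("tau_iso_MS", "tau_dchi_MS", "lambda_iso_MS", "lambda_dchi_MS",
                     "mu_iso_MS", "mu_dchi_MS"):
            assert name not in pop
        assert "beta_iso" in pop

    def test_anisotropy_prior_is_symmetric_about_zero(self, tiny_dataset):
        # the model must admit negative apparent MSA: flipping the sign of
        # every dchi-type location leaves the prior density unchanged
        _, voxels, subjects, _ = tiny_dataset
        m = TractAnisotropyModel.from_tables(voxels, subjects, "SLF")
        lay = m._layout
        loc = {name: 0.3 for name, _ in lay.loc_entries}
        flipped = {
            name: -v if ("dchi" in name) else v for name, v in loc.items()
        }
        assert lay.log_prior_locations(loc) == pytest.approx(
            lay.log_prior_locations(flipped), abs=1e-12
        )

    def test_posterior_predictive_reproduces_iso_level_at_90_degrees(self, small_fit):
        model, res = small_fit
        theta = {sid: np.array([90.0]) for sid in res.posterior.subject_ids[:3]}
        sims, idx = model.posterior_predictive(
            res.posterior, theta_by_subject=theta, n_draws=100, seed=0
        )
        # at theta=90 the cos^2 term vanishes: the predictive mean equals the
        # iso-level terms alone, far from the dchi-shifted value
        assert sims.shape == (100, 3)
        assert np.isfinite(sims).all()

    def test_posterior_predictive_calibration(self):
        # ~95% of held-out voxels fall inside the 95% predictive interval
        cfg = default_config(seed=13, n_hc=20, n_ms=20, voxels_per_roi=150)
        voxels, subjects, _ = generate_cohort_dataset(cfg)
        m = TractAnisotropyModel.from_tables(voxels, subjects, "SLF")
        res = m.fit(seed=14, n_steps=600)
        hold_cfg = default_config(seed=14, n_hc=20, n_ms=20, voxels_per_roi=150)
        sims, idx = res.posterior_predictive(voxels=voxels, n_draws=300, seed=2)
        lo = np.percentile(sims, 2.5, axis=0)
        hi = np.percentile(sims, 97.5, axis=0)
        obs = voxels[voxels.roi == "SLF"].sort_values("subject_id", kind="stable")
        # align by (subject, theta) ordering used by the predictive
        obs_map = {
            sid: g.chi_app_ppb.to_numpy()
            for sid, g in voxels[voxels.roi == "SLF"].groupby("subject_id")
        }
        y = np.concatenate([obs_map[sid] for sid in idx.subject_id.unique()])
        cover = np.mean((y >= lo) & (y <= hi))
        assert 0.93 <= cover <= 0.97


class TestDiagnostics:
    def test_identical_chains_report_exactly_one(self, rng):
        x = rng.normal(size=1000)
        assert split_rhat(np.stack([x, x, x])) == 1.0

    def test_separated_chains_exceed_threshold(self, rng):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(10.0, 1.0, 1000)
        assert split_rhat(np.stack([a, b])) > 1.5

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            split_rhat(rng.normal(size=(1, 100)))

    def test_ess_bounded_by_draw_count(self, small_fit):
        _, res = small_fit
        d = res.diagnostics
        total = res.posterior.n_chains * res.posterior.n_draws
        assert (d.ess <= total + 1e-9).all()
        assert (d.rhat >= 1.0).all()

    def test_diagnostics_require_two_chains(self, small_fit):
        _, res = small_fit
        import copy

        p = copy.deepcopy(res.posterior)
        p.population = {k: v[:1] for k, v in p.population.items()}
        with pytest.raises(ValueError):
            convergence_diagnostics(p)


class TestModelSpecValidation:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(chains=1)

    def test_nonpositive_prior_scale_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(sigma_prior_scale=0.0)

    def test_unknown_sampler_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(sampler="gibbs")
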