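"""Likelihood identities, sampler determinism, and recovery behavior."""

import numpy as np
import pandas as pd
import pytest

from orthosignal.core_model import CrosstalkParameters
from orthosignal.defaults import promoter_params, OPTIMAL_DEVICE_LEVELS
from orthosignal.inference import (AraTransfer, DEFAULT_BOUNDS, FitParameter,
                                   ParameterModel, _CompiledPosterior,
                                   _log_posterior, fit_mcmc,
                                   infer_ara_transfer, infer_device_levels,
                                   log_likelihood, single_receiver_plan)
from orthosignal.ratiometric import DoseResponseDataset


def make_dataset(params, doses6, doses12=None, sd=0.05, n_reps=3,
                 rho=None, device="dev", promoter="pLux"):
    from orthosignal.core_model import simplified_rate
    c6 = np.asarray(doses6, dtype=float)
    c12 = (np.zeros_like(c6) if doses12 is None
           else np.asarray(doses12, dtype=float))
    mean = rho if rho is not None else simplified_rate(params, c6, c12)
    pts = pd.DataFrame({"c6_nM": c6, "c12_nM": c12,
                        "arabinose_mM": 0.0, "rho_mean": mean,
                        "rho_sd": sd, "n_reps": n_reps})
    return DoseResponseDataset(device=device, promoter=promoter, points=pts)


class TestLogLikelihood:
    def test_perfect_fit_equals_normalization_sum(self, plux_params):
        ds = make_dataset(plux_params, np.geomspace(10, 2e4, 8),
                          sd=1.0, n_reps=1)
        ll = log_likelihood(plux_params, ds)
        # sigma = max(1/sqrt(1), 0.1*pred, 1e-3) = 1 for all points here
        expected = -0.5 * len(ds) * np.log(2 * np.pi)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_one_sigma_shift_costs_half_k_squared(self, plux_params):
        doses = np.geomspace(10, 2e4, 8)
        base = make_dataset(plux_params, doses, sd=1.0, n_reps=1)
        for k in (1.0, 2.5):
            pts = base.points.copy()
            pts.loc[3, "rho_mean"] += k * 1.0
            shifted = DoseResponseDataset("dev", "pLux", pts)
            delta = log_likelihood(plux_params, base) \
                - log_likelihood(plux_params, shifted)
            assert delta == pytest.approx(k ** 2 / 2, rel=1e-9)

    def test_single_replicate_sd_nan_uses_floor(self, plux_params):
        ds = make_dataset(plux_params, [100.0], sd=np.nan, n_reps=1)
        assert np.isfinite(log_likelihood(plux_params, ds))

    def test_mle_on_one_parameter_slice_matches_grid_scan(self, plux_params):
        # brute-force oracle: profile the likelihood over log10 KR6
        rng = np.random.default_rng(2)
        doses = np.geomspace(10, 2e4, 10)
        truth = plux_params
        noisy = make_dataset(
            truth, doses,
            rho=np.asarray([__import__("orthosignal").simplified_rate(
                truth, d, 0.0) for d in doses]) * (1 + 0.02 * rng.standard_normal(10)))
        grid = np.linspace(-4, -1, 1201)
        lls = []
        for g in grid:
            p = CrosstalkParameters(**{**truth.to_dict(), "KR6": 10.0 ** g})
            lls.append(log_likelihood(p, noisy))
        brute = grid[int(np.argmax(lls))]
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda g: -log_likelihood(CrosstalkParameters(
                **{**truth.to_dict(), "KR6": 10.0 ** g}), noisy),
            bounds=(-4, -1), method="bounded")
        assert res.x == pytest.approx(brute, abs=(grid[1] - grid[0]))

    def test_compiled_posterior_matches_reference_path(self, plux_params):
        ds1 = make_dataset(plux_params, np.geomspace(10, 2e4, 8))
        ds2 = make_dataset(plux_params.with_levels(0.0, 1.0),
                           np.zeros(6), np.geomspace(10, 2e4, 6))
        model = single_receiver_plan([ds1, ds2], [(1.0, 1.0), (0.0, 1.0)])
        lo, hi = model.bounds()
        compiled = _CompiledPosterior(model, [ds1, ds2], sd_floor_frac=0.1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = lo + (hi - lo) * rng.uniform(0.05, 0.95, lo.size)
            ref = _log_posterior(theta, model, [ds1, ds2], lo, hi, 0.1)
            assert compiled(theta) == pytest.approx(ref, rel=1e-12)


class TestParameterModel:
    def test_sharing_by_name_and_fixing(self):
        params = [FitParameter("KR6", -6, 2),
                  FitParameter("a0", -3, 4, fixed=0.05)]
        binding = dict(KR6="KR6", KR12=1e-5, KS6=0.0, KS12=0.0, KGR=1.0,
                       KGS=0.0, a0="a0", a1R=10.0, a1S=1.0, n=2.0,
                       r=1.0, s=0.0)
        model = ParameterModel(parameters=params, bindings=[binding] * 2)
        assert model.free_names == ["KR6"]
        built = model.build(np.array([-2.0]))
        assert built[0].KR6 == pytest.approx(1e-2)
        assert built[0].a0 == 0.05
        assert built[0] == built[1]

    def test_unknown_binding_target_rejected(self):
        with pytest.raises(KeyError):
            ParameterModel(parameters=[FitParameter("x", 0, 1)],
                           bindings=[{"KR6": "nope"}])


class TestFitMcmc:
    def _quick_fit(self, seed, n_draws=400):
        p = promoter_params("pLux")
        ds = make_dataset(p, np.geomspace(10, 2e4, 10))
        model = ParameterModel(
            parameters=[FitParameter("KR6", -6, 2),
                        FitParameter("KGR", -6, 2)],
            bindings=[{**p.to_dict(), "KR6": "KR6", "KGR": "KGR"}])
        return fit_mcmc([ds], model, n_draws=n_draws, seed=seed,
                        min_burn_steps=200)

    def test_seeded_chains_are_bit_identical(self):
        a = self._quick_fit(seed=11)
        b = self._quick_fit(seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_prob, b.log_prob)

    def test_different_seeds_differ(self):
        a = self._quick_fit(seed=11)
        b = self._quick_fit(seed=12)
        assert not np.array_equal(a.draws, b.draws)

    def test_requested_draw_count_returned(self):
        assert self._quick_fit(seed=3, n_draws=500).draws.shape[0] == 500

    def test_uninfluential_parameter_returns_its_prior(self):
        # KS12 cannot affect a LuxR-only device (s = 0): its posterior
        # must reproduce the uniform prior
        from scipy.stats import kstest
        p = promoter_params("pLux").with_levels(1.0, 0.0)
        ds = make_dataset(p, np.geomspace(10, 2e4, 10))
        model = ParameterModel(
            parameters=[FitParameter("KR6", -6, 2),
                        FitParameter("KS12", -6, 2)],
            bindings=[{**p.to_dict(), "KR6": "KR6", "KS12": "KS12"}])
        post = fit_mcmc([ds], model, n_draws=4000, seed=4,
                        min_burn_steps=600, optimize_init=False)
        ks = kstest(post.column("KS12"), "uniform", args=(-6.0, 8.0))
        assert ks.statistic < 0.1

    def test_fixing_confounded_level_identifies_kgr(self):
        # (KGR, r) are exactly confounded; pinning r = 1 (the pCat unit
        # convention) collapses the ridge and shrinks the KGR posterior
        p = promoter_params("pLux")
        ds = make_dataset(p, np.geomspace(10, 2e4, 12))

        def fit(r_free):
            params = [FitParameter("KGR", -4, 2),
                      FitParameter("a1R", -3, 4)]
            binding = {**p.to_dict(), "KGR": "KGR", "a1R": "a1R"}
            if r_free:
                params.append(FitParameter("r", -2, 2))
                binding["r"] = "r"
            model = ParameterModel(parameters=params, bindings=[binding])
            return fit_mcmc([ds], model, n_draws=1500, seed=8,
                            min_burn_steps=500)

        sd_free = np.std(fit(True).column("KGR"))
        sd_fixed = np.std(fit(False).column("KGR"))
        assert sd_fixed < 0.5 * sd_free


class TestDeviceLevels:
    def _channel_data(self, r, s, noise=0.0, seed=0):
        from orthosignal.core_model import simplified_rate
        rng = np.random.default_rng(seed)
        doses = np.geomspace(1.0, 2e4, 9)
        out = []
        for promoter in ("pLux76", "pLas81"):
            p = promoter_params(promoter, r=r, s=s)
            rows = []
            for sp, (c6, c12) in (("6", (doses, np.zeros_like(doses))),
                                  ("12", (np.zeros_like(doses), doses))):
                mean = simplified_rate(p, c6, c12)
                mean = mean * (1 + noise * rng.standard_normal(mean.size))
                rows.append(pd.DataFrame({
                    "c6_nM": c6, "c12_nM": c12, "arabinose_mM": 0.0,
                    "rho_mean": mean, "rho_sd": np.maximum(0.05 * mean, 1e-3),
                    "n_reps": 3}))
            out.append(DoseResponseDataset("pR33S175", promoter,
                                           pd.concat(rows,
                                                     ignore_index=True)))
        return out

    def test_recovers_true_levels(self):
        r_true, s_true = OPTIMAL_DEVICE_LEVELS
        cfp, yfp = self._channel_data(r_true, s_true, noise=0.03, seed=1)
        post = infer_device_levels(cfp, yfp, promoter_params("pLux76"),
                                   promoter_params("pLas81"),
                                   n_draws=2000, seed=1)
        for name, truth in (("r", r_true), ("s", s_true)):
            lo, hi = post.credible_interval(name)
            assert lo <= np.log10(truth) <= hi

    def test_absent_receiver_concentrates_at_lower_bound(self):
        cfp, yfp = self._channel_data(0.0, 3.0, noise=0.02, seed=2)
        post = infer_device_levels(cfp, yfp, promoter_params("pLux76"),
                                   promoter_params("pLas81"),
                                   n_draws=2000, seed=2)
        lo_bound = DEFAULT_BOUNDS["level"][0]
        assert np.median(post.column("r")) < lo_bound + 0.5
        s_lo, s_hi = post.credible_interval("s")
        assert s_lo <= np.log10(3.0) <= s_hi

    def test_noisier_channels_widen_intervals(self):
        r_true, s_true = OPTIMAL_DEVICE_LEVELS

        def width(noise, seed):
            cfp, yfp = self._channel_data(r_true, s_true, noise=noise,
                                          seed=seed)
            post = infer_device_levels(cfp, yfp,
                                       promoter_params("pLux76"),
                                       promoter_params("pLas81"),
                                       n_draws=1500, seed=seed)
            lo, hi = post.credible_interval("r")
            return hi - lo

        narrow = np.mean([width(0.02, s) for s in (1, 2, 3)])
        wide = np.mean([width(0.3, s) for s in (1, 2, 3)])
        assert wide > narrow


class TestAraTransfer:
    def test_monotone_and_basal_at_zero(self):
        tr = AraTransfer(basal_level=0.2, vmax_level=25.0, ec50_ara=1.0,
                         hill_ara=1.5)
        assert tr(0.0) == pytest.approx(0.2)
        ara = np.linspace(0, 8, 50)
        assert np.all(np.diff(tr(ara)) >= 0)

    def test_recovery_from_synthetic_titration(self):
        from orthosignal.core_model import simplified_rate
        truth = AraTransfer(basal_level=0.2, vmax_level=25.0, ec50_ara=1.0,
                            hill_ara=1.5)
        base = promoter_params("pLux").with_levels(1.0, 0.0)
        rng = np.random.default_rng(6)
        doses = np.geomspace(10, 2e4, 8)
        frames = []
        for ara in (0.0, 0.1, 0.3, 1.0, 3.0, 8.0):
            p = base.with_levels(float(truth(ara)), 0.0)
            mean = simplified_rate(p, doses, np.zeros_like(doses))
            mean = mean * (1 + 0.03 * rng.standard_normal(mean.size))
            frames.append(pd.DataFrame({
                "c6_nM": doses, "c12_nM": 0.0, "arabinose_mM": ara,
                "rho_mean": mean, "rho_sd": np.maximum(0.05 * mean, 1e-3),
                "n_reps": 3}))
        ds = DoseResponseDataset("pCatS123+pBADLuxR", "pLux",
                                 pd.concat(frames, ignore_index=True))
        fit, levels, band = infer_ara_transfer(ds, base, which="r",
                                               n_draws=500, seed=3,
                                               n_band=50)
        assert fit.ec50_ara == pytest.approx(truth.ec50_ara, rel=1.0)
        ara = np.linspace(0, 8, 30)
        assert np.all(np.diff(fit(ara)) >= 0)
        assert band.shape[1] == len(levels)
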