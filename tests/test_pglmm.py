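"""Posterior summaries, chain policy, and sampler correctness.

The sampler's dual-route check compares the Polya-Gamma Gibbs
implementation against an independent ensemble MCMC (emcee) on the same
small posterior with a star phylogeny (A = identity), where the model is an
ordinary logistic mixed model.
"""

import numpy as np
import pandas as pd
import pytest

import avimast as am
from avimast import pglmm, synth
from avimast.pglmm import polya_gamma_draws


class TestPmcmc:
    def test_printed_definition_arithmetic(self):
        s = np.concatenate([-np.ones(30), np.ones(970)])
        assert pglmm.pmcmc(s) == pytest.approx(0.06)

    def test_all_positive_floor_convention(self):
        s = np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1
        assert pglmm.pmcmc(s) == 0.0
        assert pglmm.format_pmcmc(s) == "< 0.001"

    def test_symmetric_samples_give_one(self):
        s = np.concatenate([-np.arange(1, 501), np.arange(1, 501)])
        assert pglmm.pmcmc(s) == pytest.approx(1.0)

    def test_invariant_under_sign_flip(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0.3, 1.0, size=777)
        assert pglmm.pmcmc(s) == pytest.approx(pglmm.pmcmc(-s))


class TestHpd:
    def test_consecutive_integers_window(self):
        lo, hi = pglmm.hpd(np.arange(1, 1001), 0.95)
        assert hi - lo == 949
        assert lo == 1  # ties resolve to the smallest lower bound

    def test_matches_window_scan_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.gamma(2.0, 1.0, size=500)
        lo, hi = pglmm.hpd(s, 0.9)
        srt = np.sort(s)
        m = int(np.ceil(0.9 * 500))
        best = min((srt[i + m - 1] - srt[i], srt[i], srt[i + m - 1])
                   for i in range(500 - m + 1))
        assert (lo, hi) == (pytest.approx(best[1]), pytest.approx(best[2]))

    def test_constant_samples_zero_width(self):
        lo, hi = pglmm.hpd(np.full(100, 3.3))
        assert lo == hi == 3.3

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=400)
        lo, hi = pglmm.hpd(s)
        lo2, hi2 = pglmm.hpd(5.0 * s - 2.0)
        assert lo2 == pytest.approx(5 * lo - 2)
        assert hi2 == pytest.approx(5 * hi - 2)

    def test_normal_quantile_endpoints(self):
        s = np.random.default_rng(4).standard_normal(100_000)
        lo, hi = pglmm.hpd(s, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


class TestSignal:
    def test_ratio_of_means(self):
        assert pglmm.phylo_signal([99.8], [0.2]) == pytest.approx(0.998)
        assert pglmm.phylo_signal([0.0, 0.0], [1.0, 3.0]) == 0.0
        assert pglmm.phylo_signal([2.0], [2.0]) == 0.5

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vp = rng.gamma(3, 2, 100)
        vr = rng.gamma(2, 1, 100)
        assert pglmm.phylo_signal(vp, vr) == pytest.approx(
            pglmm.phylo_signal(vp * 7.3, vr * 7.3))

    def test_undefined_when_both_zero(self):
        with pytest.raises(pglmm.PGLMMError):
            pglmm.phylo_signal([0.0], [0.0])


class TestChainSettings:
    def test_defaults_are_study_profile(self):
        s = pglmm.ChainSettings()
        assert (s.iterations, s.burn_in, s.thin) == (11_000_000, 1_000_000,
                                                     10_000)
        assert (s.iterations - s.burn_in) // s.thin == 1000

    def test_inconsistent_settings_rejected(self):
        with pytest.raises(pglmm.PGLMMError):
            pglmm.ChainSettings(iterations=100, burn_in=10, thin=7)

    def test_escalation_multiplies_by_ten(self):
        s = pglmm.ChainSettings()
        e = s.escalated()
        assert (e.iterations, e.burn_in, e.thin) == (110_000_000, 10_000_000,
                                                     100_000)
        assert e.target_posterior == 1000

    def test_escalate_if_needed_policy(self):
        s = pglmm.ChainSettings()
        table_ok = pd.DataFrame({"ess": [512.0, 999.0]},
                                index=["(Intercept)", "V_phylo"])
        table_low = pd.DataFrame({"ess": [512.0, 150.0]},
                                 index=["(Intercept)", "V_phylo"])
        assert pglmm.escalate_if_needed(
            pglmm.PosteriorSummary(table_ok), s) is s
        e = pglmm.escalate_if_needed(pglmm.PosteriorSummary(table_low), s)
        assert e.iterations == 110_000_000


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.8, 2.5, 12.0])
    def test_moments_match_analytic(self, z):
        d = polya_gamma_draws(z, 40_000, 11)
        mean = 0.25 if z == 0 else np.tanh(z / 2) / (2 * z)
        assert d.mean() == pytest.approx(mean, rel=0.02)
        if z == 0.0:  # var(PG(1,0)) = 1/24
            assert d.var() == pytest.approx(1 / 24, rel=0.06)


class TestDesign:
    def _frame(self):
        return pd.DataFrame({
            "species": ["a", "a", "b", "b", "c", "c"],
            "masturbation": ["yes", "no", "yes", "yes", "no", "no"],
            "sex": ["male", "female", "male", "unknown", "female", "male"],
            "condition": ["good"] * 6,
        })

    def test_unknown_levels_dropped_and_reference_most_frequent(self):
        d = pglmm.build_design(self._frame(), pglmm.ModelSpec("sex"))
        assert d.n_dropped_unknown == 1
        assert d.reference_level == "male"
        assert d.param_names == ["(Intercept)", "sex:female"]

    def test_single_level_factor_cannot_run(self):
        with pytest.raises(pglmm.PGLMMError, match="single observed level"):
            pglmm.build_design(self._frame(), pglmm.ModelSpec("condition"))

    def test_null_model_is_intercept_only(self):
        d = pglmm.build_design(self._frame(), pglmm.ModelSpec(None))
        assert d.X.shape == (6, 1)
        assert d.param_names == ["(Intercept)"]


class TestChain:
    def test_reproducible_given_seed(self, small_study):
        df = small_study["frame"]
        tree = small_study["tree"]
        kw = dict(settings=pglmm.ChainSettings.quick(seed=9),
                  fix_residual=1.0)
        c1 = pglmm.run_chain(df, tree, pglmm.ModelSpec(None), **kw)
        c2 = pglmm.run_chain(df, tree, pglmm.ModelSpec(None), **kw)
        pd.testing.assert_frame_equal(c1.samples, c2.samples)

    def test_agrees_with_independent_sampler_on_star_tree(self):
        # star phylogeny -> A = I: ordinary logistic mixed model; compare
        # the posterior for beta against emcee on the exact same density
        import emcee

        rng = np.random.default_rng(12)
        S, per = 20, 3
        species = [f"s{i}" for i in range(S)]
        newick = "(" + ",".join(f"{s}:1" for s in species) + ");"
        tree = am.parse_newick(newick)
        u_true = rng.normal(0, 1.0, S)
        sex = rng.choice(["male", "female"], size=S * per)
        sp = np.repeat(np.arange(S), per)
        beta_true = 1.5
        eta = 0.3 + beta_true * (sex == "male") + u_true[sp]
        y = (rng.uniform(size=S * per) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"species": np.array(species)[sp],
                           "masturbation": np.where(y > 0, "yes", "no"),
                           "sex": sex})
        Vp, b_var = 1.0, 25.0
        priors = pglmm.PriorSpec(beta_variance=b_var)
        chain = pglmm.run_chain(
            df, tree, pglmm.ModelSpec("sex"), priors,
            pglmm.ChainSettings.quick(seed=13),
            fix_residual=1e-6, fix_phylo=Vp)
        beta_col = [c for c in chain.samples.columns if c.startswith("sex")][0]
        pg_mean = chain.samples[beta_col].mean()
        pg_sd = chain.samples[beta_col].std()

        ref = chain.reference_level
        x = (sex == ("male" if ref != "male" else "female")).astype(float)

        def logpost(th):
            mu, beta = th[0], th[1]
            u = th[2:]
            lin = mu + beta * x + u[sp]
            ll = np.sum(y * lin - np.log1p(np.exp(lin)))
            lp = -(mu * mu + beta * beta) / (2 * b_var) - np.sum(u * u) / (2 * Vp)
            return ll + lp

        ndim = 2 + S
        nwalk = 64
        p0 = 0.1 * np.random.default_rng(14).standard_normal((nwalk, ndim))
        sampler = emcee.EnsembleSampler(nwalk, ndim, logpost)
        sampler.run_mcmc(p0, 2500, progress=False)
        ref_beta = sampler.get_chain(discard=800, thin=5, flat=True)[:, 1]
        # agreement within Monte-Carlo error of both routes
        assert pg_mean == pytest.approx(ref_beta.mean(), abs=0.25)
        assert pg_sd == pytest.approx(ref_beta.std(), rel=0.30)

    def test_power_recovers_sign_of_known_effect(self):
        # beta = +2 for males and no other effects: the sex model should
        # find a significant male effect in most replicates
        wins = 0
        reps = 8
        for r in range(reps):
            cfg = synth.SynthConfig(
                n_species=100, seed=700 + r, v_phylo=1.0, v_resid=1.0,
                records_per_species_mean=3.0,
                beta={"sex:male": 2.0},
                sex_freqs={"male": 0.5, "female": 0.5})
            tree = synth.simulate_tree(cfg)
            recs, _ = synth.simulate_records(tree, cfg, seed=800 + r)
            df = am.dataset.records_to_frame(recs)
            chain = pglmm.run_chain(df, tree, pglmm.ModelSpec("sex"),
                                    settings=pglmm.ChainSettings.quick(
                                        seed=900 + r),
                                    fix_residual=1.0)
            col = [c for c in chain.samples.columns if c.startswith("sex")][0]
            s = chain.samples[col].to_numpy()
            mean_male = s.mean() if col == "sex:male" else -s.mean()
            if mean_male > 0 and pglmm.pmcmc(s) < 0.05:
                wins += 1
        assert wins >= 6

    def test_separation_warning_emitted(self):
        df = pd.DataFrame({
            "species": ["a", "a", "b", "b"],
            "masturbation": ["yes", "yes", "no", "no"],
            "sex": ["male", "male", "female", "female"],
        })
        tree = am.parse_newick("(a:1,b:1);")
        with pytest.warns(UserWarning, match="separation"):
            pglmm.run_chain(df, tree, pglmm.ModelSpec("sex"),
                            settings=pglmm.ChainSettings.quick(seed=1),
                            fix_residual=1.0)
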