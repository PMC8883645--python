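"""ZINB normalization: sample construction, fitting, residuals."""

import numpy as np
import pandas as pd
import pytest

from hicmag.contact_map import ContactMap, ContigCatalog
from hicmag.hiczin import NormModel, build_intra_samples, fit_hiczin, normalize
from hicmag.synthetic import simulate_intra_samples

TRUE_BETA = (1.5, 0.8, 0.6, 0.4)


@pytest.fixture
def toy_setup():
    ids = ["A", "B", "C", "D"]
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 6  # A-B observed
    a[2, 3] = a[3, 2] = 2  # C-D observed
    cmap = ContactMap(ids, a)
    catalog = ContigCatalog(
        pd.DataFrame(
            {
                "length": [2000, 3000, 2500, 4000],
                "coverage": [5.0, 8.0, 6.0, 7.0],
                "sites": [2, 3, 0, 4],
                "signal": [6, 6, 2, 2],
            },
            index=pd.Index(ids, name="contig_id"),
        )
    )
    return cmap, catalog


class TestBuildIntraSamples:
    def test_pair_enumeration_counts(self, toy_setup):
        cmap, catalog = toy_setup
        labels = {"A": "X", "B": "X", "C": "X"}
        df = build_intra_samples(cmap, catalog, labels)
        assert len(df) == 3  # C(3,2)

    def test_cross_species_pairs_excluded(self, toy_setup):
        cmap, catalog = toy_setup
        df = build_intra_samples(cmap, catalog, {"A": "X", "B": "X", "C": "Y"})
        assert len(df) == 1
        assert {df.iloc[0]["contig_a"], df.iloc[0]["contig_b"]} == {"A", "B"}

    def test_unobserved_pair_has_zero_count(self, toy_setup):
        cmap, catalog = toy_setup
        df = build_intra_samples(cmap, catalog, {"A": "X", "C": "X"})
        assert len(df) == 1
        assert df.iloc[0]["count"] == 0

    def test_insufficient_labels(self, toy_setup):
        cmap, catalog = toy_setup
        with pytest.raises(ValueError, match="insufficient labels"):
            build_intra_samples(cmap, catalog, {"A": "X", "B": "Y"})

    def test_zero_sites_floored_before_log(self, toy_setup):
        cmap, catalog = toy_setup
        df = build_intra_samples(cmap, catalog, {"C": "X", "D": "X"})
        # C has 0 sites -> effective 1; ln(1 * 4) = ln 4
        assert df.iloc[0]["ln_sites"] == pytest.approx(np.log(4.0))


class TestFitHiczin:
    def test_parameter_recovery(self):
        df = simulate_intra_samples(beta=TRUE_BETA, theta=2.0, pi=0.3, n=5000, seed=1)
        model = fit_hiczin(df)
        assert model.beta == pytest.approx(np.array(TRUE_BETA), abs=0.1)
        assert model.pi == pytest.approx(0.3, abs=0.05)
        assert model.theta == pytest.approx(2.0, rel=0.3)

    def test_null_slopes_recovered(self):
        df = simulate_intra_samples(beta=(1.5, 0.0, 0.0, 0.0), n=5000, seed=2)
        model = fit_hiczin(df)
        assert model.beta[1:] == pytest.approx(np.zeros(3), abs=0.05)

    def test_lc_mode_has_three_coefficients(self):
        df = simulate_intra_samples(beta=(1.5, 0.6, 0.4), n=2000, seed=3, mode="lc")
        model = fit_hiczin(df, mode="lc")
        assert model.mode == "lc"
        assert len(model.beta) == 3  # intercept + length + coverage
        assert model.covariates == ("ln_length", "ln_coverage")

    def test_sample_floor_enforced(self):
        df = simulate_intra_samples(n=20, seed=0)
        with pytest.raises(ValueError, match=">= 50"):
            fit_hiczin(df)

    def test_matches_statsmodels_zinb(self):
        """Cross-check the own MLE against statsmodels' independent ZINB fit."""
        import statsmodels.api as sm
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        df = simulate_intra_samples(beta=TRUE_BETA, n=3000, seed=4)
        model = fit_hiczin(df)
        u = df[["ln_sites", "ln_length", "ln_coverage"]].to_numpy()
        z = (u - u.mean(axis=0)) / u.std(axis=0)  # same scale the fitter uses
        X = sm.add_constant(z)
        sm_fit = ZeroInflatedNegativeBinomialP(
            df["count"].to_numpy(), X, exog_infl=np.ones((len(df), 1)), p=2
        ).fit(disp=0, maxiter=500)
        sm_beta = np.asarray(sm_fit.params[1:5])
        assert model.beta == pytest.approx(sm_beta, abs=0.02)

    def test_median_recovery_over_seeds(self):
        errs, pis = [], []
        for seed in range(8):
            df = simulate_intra_samples(beta=TRUE_BETA, n=5000, seed=100 + seed)
            model = fit_hiczin(df)
            errs.append(np.abs(model.beta - np.array(TRUE_BETA)))
            pis.append(abs(model.pi - 0.3))
        assert (np.median(errs, axis=0) <= 0.05).all()
        assert np.median(pis) <= 0.05


class TestNormalize:
    def _flat_model(self, beta0, mode="full"):
        k = 3 if mode == "full" else 2
        return NormModel(
            mode=mode,
            covariates=("ln_sites", "ln_length", "ln_coverage")[:k] if mode == "full"
            else ("ln_length", "ln_coverage"),
            beta=np.array([beta0] + [0.0] * k),
            theta=2.0,
            pi=0.1,
            mean=np.zeros(k),
            sd=np.ones(k),
        )

    def test_closed_form_ratio(self, toy_setup):
        cmap, catalog = toy_setup
        model = self._flat_model(np.log(2.0))
        nmap = normalize(cmap, catalog, model)
        assert nmap.value("A", "B") == pytest.approx(3.0)  # 6 / 2
        assert nmap.value("C", "D") == pytest.approx(1.0)  # 2 / 2

    def test_count_equal_to_mu_gives_one(self, toy_setup):
        cmap, catalog = toy_setup
        model = self._flat_model(np.log(6.0))
        nmap = normalize(cmap, catalog, model)
        assert nmap.value("A", "B") == pytest.approx(1.0)

    def test_zero_entries_stay_absent_and_symmetric(self, toy_setup):
        cmap, catalog = toy_setup
        nmap = normalize(cmap, catalog, self._flat_model(0.0))
        assert nmap.matrix.nnz == cmap.matrix.nnz
        assert abs(nmap.matrix - nmap.matrix.T).sum() == pytest.approx(0.0)
        assert (nmap.matrix.data > 0).all()

    def test_mean_ratio_matches_monte_carlo_oracle(self):
        """E[n | C>0] on simulated data vs a 10^5-draw ZINB oracle."""
        rng = np.random.default_rng(5)
        theta, pi, mu = 2.0, 0.3, 8.0
        draws = rng.negative_binomial(theta, theta / (theta + mu), size=100_000)
        draws = np.where(rng.random(100_000) < pi, 0, draws)
        oracle = draws[draws > 0].mean() / mu

        ids = [f"c{i}" for i in range(60)]
        n = len(ids)
        a = np.zeros((n, n))
        vals = rng.negative_binomial(theta, theta / (theta + mu), size=n * (n - 1) // 2)
        vals = np.where(rng.random(vals.shape) < pi, 0, vals)
        iu, ju = np.triu_indices(n, k=1)
        a[iu, ju] = vals
        a += a.T
        cmap = ContactMap(ids, a)
        catalog = ContigCatalog(
            pd.DataFrame(
                {"length": 2000, "coverage": 5.0, "sites": 3, "signal": 1},
                index=pd.Index(ids, name="contig_id"),
            )
        )
        nmap = normalize(cmap, catalog, self._flat_model(np.log(mu)))
        mean_ratio = nmap.matrix.data.mean()
        assert mean_ratio == pytest.approx(oracle, rel=0.05)

    def test_length_rescaling_invariance(self):
        """Multiplying all lengths by a constant shifts the covariate mean,
        which the stored standardization absorbs, leaving residuals unchanged."""
        from hicmag.synthetic import CommunitySpec, simulate_community

        sim = simulate_community(CommunitySpec(n_species=4, contigs_per_species=15, seed=11))
        samples = build_intra_samples(sim.cmap, sim.catalog, sim.labels)
        model = fit_hiczin(samples)
        nmap = normalize(sim.cmap, sim.catalog, model)

        cat2 = ContigCatalog(sim.catalog.df.assign(length=sim.catalog.df["length"] * 10))
        samples2 = build_intra_samples(sim.cmap, cat2, sim.labels)
        model2 = fit_hiczin(samples2)
        nmap2 = normalize(sim.cmap, cat2, model2)
        # identical counts, shifted covariates: residuals agree up to refit noise
        r = nmap.matrix.data
        r2 = nmap2.matrix.data
        assert np.median(np.abs(r - r2) / r) < 0.05

    def test_missing_covariate_fails_by_name(self, toy_setup):
        cmap, catalog = toy_setup
        catalog.df.loc["B", "sites"] = np.nan
        with pytest.raises(ValueError, match="'B'"):
            normalize(cmap, catalog, self._flat_model(0.0))


class TestNormModelIO:
    def test_json_round_trip(self, tmp_path):
        df = simulate_intra_samples(n=500, seed=6)
        model = fit_hiczin(df, min_samples=50)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = NormModel.from_json(path)
        assert back.beta == pytest.approx(model.beta)
        assert back.theta == pytest.approx(model.theta)
        assert back.pi == pytest.approx(model.pi)
        assert back.mean == pytest.approx(model.mean)
        assert back.mode == model.mode
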