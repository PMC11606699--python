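"""Core occupancy model: state space, link, likelihood, fitting, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from camoccu.msom import (ModelStructure, _Prepared, conditional_occupancy,
                          enumerate_states, fit_msom, marginal_occupancy,
                          natural_param_keys, predict_occupancy,
                          site_neg_loglik, state_probs)
from camoccu.simulate import SimulationScenario, gen_dataset


# ---------------------------------------------------------------------------
# independent oracle: term-by-term enumeration of the marginal likelihood

def oracle_site_nll(y, psi, p):
    """Brute-force likelihood: loop every state, species and occasion."""
    S, T = y.shape
    total = 0.0
    for zi, z in enumerate(itertools.product([0, 1], repeat=S)):
        # binary counting: species s is bit s -> reorder
        z = tuple((zi >> s) & 1 for s in range(S))
        contrib = psi[zi]
        for s in range(S):
            for t in range(T):
                if np.isnan(y[s, t]):
                    continue
                if z[s] == 1:
                    contrib *= p[s, t] if y[s, t] == 1 else 1 - p[s, t]
                elif y[s, t] == 1:
                    contrib *= 0.0
        total += contrib
    return -np.log(total)


class TestStateSpace:
    def test_two_species_order(self):
        sp = enumerate_states(2)
        assert sp.states.tolist() == [[0, 0], [1, 0], [0, 1], [1, 1]]

    def test_sizes(self):
        assert len(enumerate_states(3)) == 8
        assert enumerate_states(1).states.tolist() == [[0], [1]]

    def test_invalid(self):
        with pytest.raises(ValueError):
            enumerate_states(0)


class TestStateProbs:
    def test_symmetry_all_zero(self):
        psi = state_probs({}, enumerate_states(3))
        np.testing.assert_allclose(psi, np.full(8, 1 / 8), atol=1e-12)

    def test_single_species_logit(self):
        sp = enumerate_states(3)
        psi = state_probs({"f1": np.log(3)}, sp)
        assert marginal_occupancy(psi, 0, sp) == pytest.approx(0.75, abs=1e-12)

    def test_pairwise_weighting(self):
        sp = enumerate_states(2)
        psi = state_probs({"f12": np.log(4)}, sp)
        np.testing.assert_allclose(psi, [1 / 7, 1 / 7, 1 / 7, 4 / 7], atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            state_probs({"f1": np.inf}, enumerate_states(2))


class TestMarginalConditional:
    sp2 = enumerate_states(2)
    psi = np.array([1 / 7, 1 / 7, 1 / 7, 4 / 7])

    def test_uniform_marginals(self):
        sp = enumerate_states(3)
        psi = np.full(8, 1 / 8)
        for s in range(3):
            assert marginal_occupancy(psi, s, sp) == pytest.approx(0.5)

    def test_marginal_and_conditionals(self):
        assert marginal_occupancy(self.psi, 0, self.sp2) == pytest.approx(5 / 7)
        assert conditional_occupancy(self.psi, 0, (1, True), self.sp2) == pytest.approx(4 / 5)
        assert conditional_occupancy(self.psi, 0, (1, False), self.sp2) == pytest.approx(1 / 2)

    def test_degenerate_mass(self):
        sp = enumerate_states(3)
        psi = np.zeros(8)
        psi[-1] = 1.0
        assert marginal_occupancy(psi, 2, sp) == 1.0
        with pytest.raises(ValueError, match="probability zero"):
            conditional_occupancy(psi, 0, (1, False), sp)

    def test_independence_factorizes(self, rng):
        """With all pairwise terms zero, conditional = marginal for every pair."""
        sp = enumerate_states(3)
        for _ in range(20):
            f = {f"f{i}": rng.normal() for i in (1, 2, 3)}
            psi = state_probs(f, sp)
            for s, g in itertools.permutations(range(3), 2):
                m = marginal_occupancy(psi, s, sp)
                assert conditional_occupancy(psi, s, (g, True), sp) == pytest.approx(m, abs=1e-10)
                assert conditional_occupancy(psi, s, (g, False), sp) == pytest.approx(m, abs=1e-10)


class TestSiteLikelihood:
    def test_single_species_closed_form(self):
        """S=1, T=2, psi=0.5, p=0.5, empty history: 0.5 + 0.5*0.25 = 0.625."""
        y = np.zeros((1, 2))
        nll = site_neg_loglik(y, np.array([0.5, 0.5]), np.full((1, 2), 0.5))
        assert nll == pytest.approx(-np.log(0.625), abs=1e-12)

    def test_detection_excludes_absent_states(self):
        y = np.array([[1.0, 0.0]])
        psi = np.array([0.3, 0.7])
        p = np.full((1, 2), 0.4)
        expected = 0.7 * 0.4 * 0.6
        assert site_neg_loglik(y, psi, p) == pytest.approx(-np.log(expected), abs=1e-12)

    def test_detection_on_missing_occasion_errors(self):
        y = np.array([[0.0, 1.0]])
        mask = np.array([[True, False]])   # detection recorded without effort
        with pytest.raises(ValueError, match="no-effort"):
            site_neg_loglik(y, np.array([0.5, 0.5]), np.full((1, 2), 0.5), mask=mask)

    def test_matches_enumeration_oracle(self, rng):
        """Random S=3, T=4 instances agree with the brute-force enumeration."""
        sp = enumerate_states(3)
        for _ in range(25):
            psi = rng.dirichlet(np.ones(8))
            p = rng.uniform(0.05, 0.95, size=(3, 4))
            z = sp.states[rng.integers(8)]
            y = (rng.random((3, 4)) < p) * z[:, None] * 1.0
            y[:, rng.integers(4)] = np.nan
            assert site_neg_loglik(y, psi, p) == pytest.approx(
                oracle_site_nll(y, psi, p), abs=1e-10)


# ---------------------------------------------------------------------------
# full-likelihood machinery


def _tiny_structure(species=("marten", "human", "cat"), pair=[]):
    occ = {"f1": ["ele"], "f2": ["dist_road"], "f3": ["dist_settl"],
           "f12": pair, "f13": pair, "f23": None}
    return ModelStructure(species, occ, {sp: ["jdate"] for sp in species}, label="tiny")


class TestLikelihoodMachinery:
    def test_vectorized_equals_per_site_oracle(self, small_dataset, rng):
        ds = small_dataset
        st = _tiny_structure()
        prep = _Prepared(ds.history, ds.covariates, st)
        beta = rng.normal(scale=0.4, size=prep.K)
        nll = prep.nll(beta)
        psi = np.exp(prep.log_psi(beta))
        p = 1 / (1 + np.exp(-prep.det_linear(beta)))
        manual = sum(
            oracle_site_nll(ds.history.y[:, i, :], psi[i], p[:, i, :])
            for i in range(len(ds.history.site_order)))
        assert nll == pytest.approx(manual, rel=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, small_dataset, rng):
        ds = small_dataset
        prep = _Prepared(ds.history, ds.covariates, _tiny_structure())
        beta = rng.normal(scale=0.3, size=prep.K)
        _, g = prep.nll_grad(beta)
        for k in range(prep.K):
            e = np.zeros(prep.K)
            e[k] = 1e-6
            fd = (prep.nll(beta + e) - prep.nll(beta - e)) / 2e-6
            assert g[k] == pytest.approx(fd, abs=5e-4, rel=1e-4)

    def test_species_permutation_invariance(self, rng):
        """Relabelling species together with data and structure keeps the likelihood."""
        sc = SimulationScenario(n_sites=25)
        ds = gen_dataset(sc, seed=4, with_events=False)
        st = _tiny_structure()
        prep = _Prepared(ds.history, ds.covariates, st)
        beta = rng.normal(scale=0.3, size=prep.K)
        nll_ref = prep.nll(beta)

        # swap human (f2) and cat (f3): permute history, structure and beta blocks
        import copy
        h2 = copy.deepcopy(ds.history)
        h2.y = h2.y[[0, 2, 1]]
        h2.species_order = ("marten", "cat", "human")
        occ = {"f1": ["ele"], "f2": ["dist_settl"], "f3": ["dist_road"],
               "f12": [], "f13": [], "f23": None}
        st2 = ModelStructure(("marten", "cat", "human"), occ,
                             {sp: ["jdate"] for sp in ("marten", "cat", "human")})
        prep2 = _Prepared(h2, ds.covariates, st2)
        beta2 = np.empty_like(beta)
        for src, dst in [("f1", "f1"), ("f2", "f3"), ("f3", "f2"),
                         ("f12", "f13"), ("f13", "f12"),
                         ("det:human", "det:human"), ("det:cat", "det:cat"),
                         ("det:marten", "det:marten")]:
            beta2[prep2.slices[dst]] = beta[prep.slices[src]]
        assert prep2.nll(beta2) == pytest.approx(nll_ref, rel=1e-12)


class TestFormulaStructures:
    def test_from_formulas_matches_explicit(self):
        st = ModelStructure.from_formulas(
            ("marten", "human", "cat"),
            ["f1 ~ veg + ele + I(ele^2)", "f2 ~ dist_road", "f3 ~ dist_settl",
             "f12 ~ 1", "f13 ~ ele + dist_road + ele:dist_road",
             "det.marten ~ jdate + I(jdate^2)", "det.human ~ jdate",
             "det.cat ~ 1"], label="mix")
        assert st.occ["f1"] == ["veg", "ele", "I(ele^2)"]
        assert st.occ["f12"] == []                      # intercept-only
        assert st.occ.get("f23") is None                # omitted -> fixed at 0
        assert st.occ["f13"] == ["ele", "dist_road", "ele:dist_road"]
        assert st.det["cat"] == []
        assert st.free_keys == ["f1", "f2", "f3", "f12", "f13"]

    def test_serialization_roundtrip(self, small_dataset, tmp_path):
        st = _tiny_structure()
        fit = fit_msom(small_dataset.history, small_dataset.covariates, st)
        path = tmp_path / "fit.json"
        fit.save(path)
        import json
        blob = json.load(open(path))
        assert blob["K"] == fit.K
        np.testing.assert_allclose(blob["beta"], fit.beta)
        assert blob["occ"]["f1"] == ["ele"]
        assert "moments" in blob and "ele" in blob["moments"]


class TestFitting:
    def test_aic_bookkeeping(self, small_dataset):
        st = ModelStructure(("marten", "human", "cat"),
                            {"f1": [], "f2": [], "f3": []},
                            {sp: [] for sp in ("marten", "human", "cat")},
                            label="intercepts")
        fit = fit_msom(small_dataset.history, small_dataset.covariates, st)
        assert fit.K == 6
        assert fit.aic == pytest.approx(2 * 6 - 2 * fit.loglik, abs=1e-12)

    def test_adding_parameter_never_hurts_loglik(self, small_dataset):
        base = _tiny_structure(pair=[])
        bigger = _tiny_structure(pair=["dist_road"])
        f0 = fit_msom(small_dataset.history, small_dataset.covariates, base)
        start = np.concatenate([f0.beta[:6], [f0.beta[6], 0.0, f0.beta[7], 0.0],
                                f0.beta[8:]])
        f1 = fit_msom(small_dataset.history, small_dataset.covariates, bigger,
                      start=start)
        assert f1.loglik >= f0.loglik - 1e-3
        assert f1.K == f0.K + 2


class TestPrediction:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(small_dataset):
        sc = SimulationScenario(n_sites=30, structure_label="Mod2")
        return small_dataset, fit_msom(small_dataset.history,
                                       small_dataset.covariates, sc.structure())

    def test_simplex_and_total_probability(self, fitted):
        ds, fit = fitted
        conds = [(0, 1, True), (0, 1, False)]
        pred = predict_occupancy(fit, ds.covariates.site, standardized=True,
                                 conditionals=conds)
        psi_cols = [c for c in pred.columns if c.startswith("psi_")]
        np.testing.assert_allclose(pred[psi_cols].sum(axis=1), 1.0, atol=1e-10)
        assert ((pred[psi_cols] >= 0) & (pred[psi_cols] <= 1)).all().all()
        # law of total probability: marginal of marten recomposed from conditionals
        m_h = pred["marginal_human"]
        recomposed = (pred["cond_marten_given_human_present"] * m_h
                      + pred["cond_marten_given_human_absent"] * (1 - m_h))
        np.testing.assert_allclose(recomposed, pred["marginal_marten"], atol=1e-10)

    def test_fit_time_sites_reproduce_fitted_psi(self, fitted):
        ds, fit = fitted
        prep = _Prepared(ds.history, ds.covariates, fit.structure)
        psi_fit = np.exp(prep.log_psi(fit.beta))
        pred = predict_occupancy(fit, ds.covariates.site, standardized=True)
        psi_cols = [c for c in pred.columns if c.startswith("psi_")]
        np.testing.assert_allclose(pred[psi_cols].to_numpy(), psi_fit, atol=1e-12)

    def test_zero_vcov_gives_zero_se(self, fitted):
        ds, fit = fitted
        import copy
        f2 = copy.deepcopy(fit)
        f2.vcov = np.zeros((fit.K, fit.K))
        pred = predict_occupancy(f2, ds.covariates.site, standardized=True)
        se_cols = [c for c in pred.columns if c.startswith("se_")]
        assert float(pred[se_cols].abs().max().max()) < 1e-8

    def test_delta_method_agrees_with_parametric_bootstrap(self):
        """Delta-method SE of a marginal occupancy matches a parametric
        bootstrap on a two-parameter single-species toy fit."""
        from camoccu.camdata import build_detection_history, make_covariate_table, \
            standardize_covariates
        from conftest import make_deployments
        rng = np.random.default_rng(8)
        n = 200
        deps = make_deployments(n)
        empty = pd.DataFrame(columns=["station_id", "species", "datetime"])
        h = build_detection_history(empty, deps, species_order=("marten",))
        z = rng.random(n) < 0.6
        h.y[0][z] = (rng.random((z.sum(), 30)) < 0.3).astype(float)
        site = pd.DataFrame({
            "station_id": [f"st{i + 1:03d}" for i in range(n)],
            "veg_type": ["QuercusIlex"] * n,
            "elevation_m": rng.uniform(0, 1000, n),
            "dist_settl_m": rng.lognormal(6, 1, n),
            "dist_road_m": rng.lognormal(5, 1, n)})
        cov = standardize_covariates(make_covariate_table(site, h))
        st = ModelStructure(("marten",), {"f1": []}, {"marten": []}, label="toy")
        fit = fit_msom(h, cov, st)
        assert fit.K == 2
        grid = cov.site.iloc[:1]
        d = predict_occupancy(fit, grid, standardized=True, se_method="delta")
        b = predict_occupancy(fit, grid, standardized=True, se_method="bootstrap",
                              n_boot=10_000, seed=1)
        np.testing.assert_allclose(d["se_marginal_marten"], b["se_marginal_marten"],
                                   rtol=0.10)
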