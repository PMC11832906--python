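"""The multivariate-Bernoulli occupancy core: state distribution, likelihood,
maximum-likelihood fitting, Wald inference and AIC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.special import expit

import ctmsom as cm
from ctmsom.msom import _Packed
from conftest import (
    brute_force_loglik,
    brute_force_site_likelihood,
    intercept_only_data,
    single_species_array,
)


class TestStateProbabilities:
    def test_uniform_when_all_zero(self):
        _, probs = cm.state_probabilities([0.0, 0.0], {(0, 1): 0.0})
        np.testing.assert_allclose(probs, 0.25)

    def test_independence_factorizes(self):
        f1, f2 = 0.8, -1.3
        states, probs = cm.state_probabilities([f1, f2], {(0, 1): 0.0})
        idx = {tuple(map(int, s)): k for k, s in enumerate(states)}
        assert probs[idx[(1, 1)]] == pytest.approx(expit(f1) * expit(f2))
        assert probs[idx[(1, 0)]] == pytest.approx(expit(f1) * (1 - expit(f2)))

    def test_two_species_enumeration_example(self):
        states, probs = cm.state_probabilities([0.5, -0.5], {(0, 1): 1.0})
        idx = {tuple(map(int, s)): k for k, s in enumerate(states)}
        denom = 1 + math.exp(0.5) + math.exp(-0.5) + math.exp(1.0)
        assert probs[idx[(1, 1)]] == pytest.approx(math.exp(1.0) / denom)
        assert probs[idx[(1, 1)]] == pytest.approx(0.4551, abs=5e-5)
        psi1 = probs[idx[(1, 0)]] + probs[idx[(1, 1)]]
        assert psi1 == pytest.approx(0.7311, abs=5e-5)

    @given(st.lists(st.floats(-4, 4), min_size=2, max_size=3),
           st.floats(-3, 3))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sums_to_one_and_matches_enumeration(self, f, f12):
        S = len(f)
        pairs = {(i, j): f12 for i, j in itertools.combinations(range(S), 2)}
        states, probs = cm.state_probabilities(f, pairs)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        # independent direct enumeration
        raw = []
        for z in itertools.product((0, 1), repeat=S):
            e = sum(f[i] * z[i] for i in range(S))
            e += sum(v * z[i] * z[j] for (i, j), v in pairs.items())
            raw.append(math.exp(e))
        np.testing.assert_allclose(probs, np.array(raw) / sum(raw), atol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            cm.state_probabilities([np.inf, 0.0])


class TestDetectionProbability:
    def test_zero_coefficients(self):
        assert cm.detection_probability([0.0, 0.0], [1.0, 0.3]) == pytest.approx(0.5)

    def test_intercept_only_logistic(self):
        # logistic of a plausible intercept around -1.57 gives p near 0.17
        assert cm.detection_probability([-1.568], [1.0]) == pytest.approx(0.173, abs=5e-4)

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(5)
        alpha = rng.normal(size=4)
        v = rng.normal(size=4)
        assert cm.detection_probability(alpha, v) == pytest.approx(
            1.0 / (1.0 + math.exp(-float(np.dot(alpha, v)))))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cm.detection_probability([0.0, 1.0], [1.0, 2.0, 3.0])


class TestSiteLogLikelihood:
    def test_single_species_closed_forms(self):
        # psi = p = 0.5, K = 2: history (0,0) -> 0.5*0.25 + 0.5 = 0.625
        y = np.array([[0.0], [0.0]])
        p = np.full((2, 1), 0.5)
        ll = cm.site_log_likelihood(y, [0.0], np.zeros((1, 1)), p)
        assert math.exp(ll) == pytest.approx(0.625, abs=1e-12)
        # history (1,0): absent state contributes nothing -> 0.5*0.25 = 0.125
        y = np.array([[1.0], [0.0]])
        ll = cm.site_log_likelihood(y, [0.0], np.zeros((1, 1)), p)
        assert math.exp(ll) == pytest.approx(0.125, abs=1e-12)

    def test_missing_occasions_contribute_factor_one(self):
        y_full = np.array([[0.0], [1.0]])
        y_missing = np.array([[np.nan], [0.0], [1.0], [np.nan]])
        p = 0.3 * np.ones((4, 1))
        ll_full = cm.site_log_likelihood(y_full, [0.4], np.zeros((1, 1)), p[:2])
        ll_missing = cm.site_log_likelihood(y_missing, [0.4], np.zeros((1, 1)), p)
        assert ll_missing == pytest.approx(ll_full, abs=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            cm.site_log_likelihood(np.full((3, 1), np.nan), [0.0],
                                   np.zeros((1, 1)), np.full((3, 1), 0.5))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            K, S = 5, 3
            y = rng.integers(0, 2, size=(K, S)).astype(float)
            y[rng.random((K, S)) < 0.2] = np.nan
            if np.isnan(y).all():
                continue
            f = rng.normal(0, 1.5, S)
            pairs = {(i, j): rng.normal(0, 1.0)
                     for i, j in itertools.combinations(range(S), 2)}
            G = np.zeros((S, S))
            for (i, j), v in pairs.items():
                G[i, j] = v
            p = rng.uniform(0.05, 0.95, size=(K, S))
            ll = cm.site_log_likelihood(y, f, G, p)
            oracle = math.log(brute_force_site_likelihood(y, f, pairs, p))
            assert ll == pytest.approx(oracle, abs=1e-10)


def _random_dataset(rng, J=20, K=5, S=3):
    """Random histories + covariates + a random 3-species spec."""
    y = rng.integers(0, 2, size=(J, K, S)).astype(float)
    y[rng.random((J, K, S)) < 0.1] = np.nan
    species = [f"sp{i}" for i in range(S)]
    arr = cm.DetectionArray(y, [f"S{j}" for j in range(J)],
                            pd.date_range("2022-01-01", periods=K), species)
    site_df = pd.DataFrame(rng.normal(size=(J, 2)), columns=["cov1", "cov2"],
                           index=arr.site_ids)
    occ_cov = {"day": np.broadcast_to(rng.normal(size=K), (J, K))}
    spec = cm.ModelSpec(
        species=species,
        occupancy={sp: "~ cov1 + cov2" for sp in species},
        detection={sp: "~ cov1 + day" for sp in species},
        interactions={(species[i], species[j]): "~ cov2"
                      for i, j in itertools.combinations(range(S), 2)},
    )
    data = cm.ModelData(array=arr, site_covariates=site_df,
                        occasion_covariates=occ_cov)
    return spec, data, site_df, occ_cov


def _natural_params_from_theta(packed, theta):
    """Unpack the model's linear predictors for the oracle."""
    J, K, S = packed.J, packed.K, packed.S
    F1 = np.zeros((J, S))
    for i, X, sl in packed.single_designs:
        F1[:, i] = X @ theta[sl]
    Fp = {}
    for col, X, sl in packed.pair_designs:
        pair = [ij for ij, c in packed.pair_index.items() if c == col][0]
        Fp[pair] = X @ theta[sl]
    P = np.zeros((J, K, S))
    for i, V, sl in packed.det_designs:
        P[:, :, i] = expit(V @ theta[sl])
    return F1, Fp, P


class TestMarginalizedLikelihood:
    def test_matches_enumeration_oracle(self):
        """Vectorized log-sum-exp likelihood vs probability-domain enumeration."""
        rng = np.random.default_rng(7)
        spec, data, _, _ = _random_dataset(rng)
        packed = _Packed(spec, data)
        for _ in range(10):
            theta = rng.normal(0, 1.0, packed.n_params)
            nll, _ = packed.nll_grad(theta)
            F1, Fp, P = _natural_params_from_theta(packed, theta)
            oracle = brute_force_loglik(packed.Y, F1, Fp, P)
            assert -nll == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_species_relabeling(self):
        rng = np.random.default_rng(8)
        spec, data, site_df, occ_cov = _random_dataset(rng)
        packed = _Packed(spec, data)
        theta = rng.normal(0, 0.8, packed.n_params)
        nll, _ = packed.nll_grad(theta)

        # permute the species order in the spec; map coefficients by name
        perm = ["sp2", "sp0", "sp1"]
        spec_p = cm.ModelSpec(
            species=perm,
            occupancy={sp: "~ cov1 + cov2" for sp in perm},
            detection={sp: "~ cov1 + day" for sp in perm},
            interactions={pair: "~ cov2" for pair in
                          [("sp0", "sp1"), ("sp0", "sp2"), ("sp1", "sp2")]},
        )
        packed_p = _Packed(spec_p, data)
        names, names_p = packed.coef_names, packed_p.coef_names

        def find(name):
            # pair labels follow each spec's species order: accept either
            if name in names:
                return names.index(name)
            head, _, term = name.partition("] ")
            kind, label = head.split("[")
            a, _, b = label.partition(":")
            return names.index(f"{kind}[{b}:{a}] {term}")

        theta_p = np.array([theta[find(n)] for n in names_p])
        nll_p, _ = packed_p.nll_grad(theta_p)
        assert nll_p == pytest.approx(nll, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        spec, data, _, _ = _random_dataset(rng, J=12, K=4)
        packed = _Packed(spec, data)
        theta = rng.normal(0, 0.7, packed.n_params)
        _, grad = packed.nll_grad(theta)
        for l in rng.choice(packed.n_params, size=8, replace=False):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[l] += h
            tm[l] -= h
            fd = (packed.nll(tp) - packed.nll(tm)) / (2 * h)
            assert grad[l] == pytest.approx(fd, abs=1e-5, rel=1e-5)


class TestFit:
    def test_two_site_toy_matches_grid_search(self):
        """Single-species intercept-only MLE vs an exhaustive 2-D grid."""
        arr = single_species_array([[1.0, 0.0], [0.0, 0.0]])
        data = intercept_only_data(arr)
        spec = cm.ModelSpec(species=["sp"], occupancy={"sp": "~ 1"},
                            detection={"sp": "~ 1"})
        res = cm.fit(spec, data, n_starts=3, seed=0)
        assert res.converged

        def neg_ll(psi, p):
            # site 1: (1,0); site 2: (0,0)
            l1 = psi * p * (1 - p)
            l2 = psi * (1 - p) ** 2 + (1 - psi)
            return -(math.log(l1) + math.log(l2))

        grid = np.linspace(0.001, 0.999, 999)
        vals = np.array([[neg_ll(a, b) for b in grid] for a in grid])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        psi_hat = expit(res.coef("psi[sp] (Intercept)"))
        p_hat = expit(res.coef("p[sp] (Intercept)"))
        assert psi_hat == pytest.approx(grid[i], abs=2e-3)
        assert p_hat == pytest.approx(grid[j], abs=2e-3)
        # the fitted optimum must beat the best grid point, and only by
        # as much as the grid resolution allows
        assert res.loglik >= -vals[i, j] - 1e-9
        assert res.loglik == pytest.approx(-vals[i, j], abs=1e-3)

    def test_no_interactions_separates_into_single_species_fits(self):
        rng = np.random.default_rng(10)
        sim = cm.simulate(cm.SimConfig(
            n_sites=80, study_start="2022-01-01", study_end="2022-01-20",
            deployment="full", simulate_images=False, seed=14,
            interaction_coefs={}))
        data = sim.model_data()
        joint = cm.fit(sim.spec, data, n_starts=1, seed=1, compute_se=False)
        total = 0.0
        for sp in sim.spec.species:
            sub_arr = cm.DetectionArray(
                data.array.values[:, :, [data.array.species_index(sp)]],
                data.array.site_ids, data.array.occasion_dates, [sp])
            sub_data = cm.ModelData(array=sub_arr,
                                    site_covariates=data.site_covariates,
                                    occasion_covariates=data.occasion_covariates)
            sub_spec = cm.ModelSpec(
                species=[sp], occupancy={sp: sim.spec.occupancy[sp]},
                detection={sp: sim.spec.detection[sp]})
            total += cm.fit(sub_spec, sub_data, n_starts=1, seed=1,
                            compute_se=False).loglik
        assert joint.loglik == pytest.approx(total, abs=1e-4)

    def test_binomial_detection_frequency_equivalence(self):
        """With constant p, the daily-Bernoulli MLE equals the MLE of the
        Binomial detection-frequency form (they differ only by a constant)."""
        rng = np.random.default_rng(11)
        J, K = 60, 8
        psi_true, p_true = 0.6, 0.35
        z = rng.random(J) < psi_true
        y = (rng.random((J, K)) < p_true) & z[:, None]
        arr = single_species_array(y.astype(float))
        spec = cm.ModelSpec(species=["sp"], occupancy={"sp": "~ 1"},
                            detection={"sp": "~ 1"})
        res = cm.fit(spec, intercept_only_data(arr), n_starts=2, seed=0)

        counts = y.sum(axis=1)

        def neg_ll_binom(x):
            psi, p = expit(x)
            like = psi * p ** counts * (1 - p) ** (K - counts)
            like = like + (counts == 0) * (1 - psi)
            return -np.log(like).sum()

        opt = optimize.minimize(neg_ll_binom, [0.0, -1.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        psi_hat, p_hat = expit(opt.x)
        assert expit(res.coef("psi[sp] (Intercept)")) == pytest.approx(psi_hat, abs=1e-5)
        assert expit(res.coef("p[sp] (Intercept)")) == pytest.approx(p_hat, abs=1e-5)

    def test_nesting_monotonicity(self, small_fit):
        """Adding a covariate never decreases the maximized log-likelihood."""
        sim, res = small_fit
        richer = cm.ModelSpec(
            species=sim.spec.species,
            occupancy={**{sp: str(sim.spec.occupancy[sp]) for sp in sim.spec.species},
                       "roe": "~ forest + tri + roads + open"},
            detection={sp: str(sim.spec.detection[sp]) for sp in sim.spec.species},
            interactions={p: str(f) for p, f in sim.spec.interactions.items()
                          if not f.absent})
        res2 = cm.fit(richer, sim.model_data(), n_starts=1, seed=3,
                      compute_se=False)
        assert res2.loglik >= res.loglik - 1e-6

    def test_bias_shrinks_with_sample_size(self):
        """Estimator consistency: coefficient bias decreases from J=150 to J=600."""
        biases = {}
        for J, n_rep in [(150, 8), (600, 8)]:
            fits = []
            truth = None
            for r in range(n_rep):
                sim = cm.simulate(cm.SimConfig(
                    n_sites=J, study_start="2022-01-01", study_end="2022-02-09",
                    deployment="full", simulate_images=False, seed=3000 + r))
                truth = sim.theta_true
                fits.append(cm.fit(sim.spec, sim.model_data(), n_starts=1,
                                   seed=r, compute_se=False))
            est = np.stack([f.theta for f in fits])
            biases[J] = np.abs(est.mean(axis=0) - truth).mean()
        assert biases[600] < biases[150]

    def test_missing_species_detections_rejected(self):
        arr = single_species_array(np.zeros((5, 4)))
        spec = cm.ModelSpec(species=["sp"], occupancy={"sp": "~ 1"},
                            detection={"sp": "~ 1"})
        with pytest.raises(ValueError, match="no detections"):
            cm.fit(spec, intercept_only_data(arr))


class TestAIC:
    def test_definition(self, small_fit):
        _, res = small_fit
        assert cm.aic(res) == pytest.approx(-2 * res.loglik + 2 * res.n_params)

    def test_nested_difference_identity(self, small_fit):
        sim, res = small_fit
        smaller = cm.ModelSpec(
            species=sim.spec.species,
            occupancy={sp: str(sim.spec.occupancy[sp]) for sp in sim.spec.species},
            detection={sp: str(sim.spec.detection[sp]) for sp in sim.spec.species},
            interactions={})
        res0 = cm.fit(smaller, sim.model_data(), n_starts=1, seed=4,
                      compute_se=False)
        d_k = res.n_params - res0.n_params
        d_ll = res.loglik - res0.loglik
        assert res.aic - res0.aic == pytest.approx(2 * d_k - 2 * d_ll, abs=1e-9)


class TestModelSpec:
    def test_from_dict_roundtrip(self):
        spec = cm.ModelSpec.from_dict({
            "f[roe]": "~ forest + tri",
            "f[red]": "~ tri",
            "f[roe:red]": "~ 1",
            "p[roe]": "~ visual",
            "p[red]": "~ visual + trail",
        }, name="demo")
        assert spec.species == ("roe", "red")
        assert spec.n_params == 3 + 2 + 1 + 2 + 3
        assert spec.interactions[("roe", "red")].n_params == 1

    def test_unknown_covariate_rejected_at_design_time(self):
        arr = single_species_array(np.ones((3, 2)))
        spec = cm.ModelSpec(species=["sp"], occupancy={"sp": "~ elevation"},
                            detection={"sp": "~ 1"})
        with pytest.raises(KeyError, match="elevation"):
            cm.fit(spec, intercept_only_data(arr))
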