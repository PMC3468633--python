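"""Multi-state robust-design likelihood: designs, forward algorithm, fitting."""

import math

import numpy as np
import pytest

from iporangaia.cmr_likelihood import (
    CmrData,
    CmrParameters,
    CatalogueError,
    ParameterStructure,
    PHI_P_STRUCTURES,
    PSI_STRUCTURES,
    build_design,
    derived_abundance,
    fit_ml,
    forward_loglik,
    primary_detection_prob,
    total_loglik,
    _total_loglik_grad,
)
from iporangaia.encounter_io import EncounterHistory
from _oracles import enumerate_loglik, enumerate_outcome_probs, random_history, tiny_layout


def _random_params(rng, t):
    return CmrParameters(
        rng.uniform(0.1, 0.9, (3, t - 1)),
        rng.uniform(0.1, 0.9, (3, t)),
        rng.uniform(0.1, 0.9, (2, t - 1)),
    )


class TestDesigns:
    def test_constant_has_one_column(self, layout):
        d = build_design(ParameterStructure(phi="constant"), layout)
        assert d.x_phi.shape[1] == 1

    def test_additive_time_category_columns(self, layout):
        d = build_design(ParameterStructure(phi="time+category"), layout)
        assert d.x_phi.shape[1] == 11 + 2  # 11 intervals + 2 category offsets

    def test_state_only_transition_has_two_columns(self, layout):
        d = build_design(ParameterStructure(psi="state"), layout)
        assert d.x_psi.shape[1] == 2

    def test_global_model_k_matches_published_count(self, layout):
        """phi(time+category) p(time+category) psi(time+state) has K = 39."""
        d = build_design(
            ParameterStructure("time+category", "time+category", "time+state"),
            layout,
        )
        assert d.k == 39

    @pytest.mark.parametrize("label,expected", [
        ("constant", 1), ("time", 12), ("category", 3), ("time+category", 14),
        ("time(F)&const(C)&const(N)", 14), ("sex", 2), ("time+sex", 13),
        ("time(F)&const(M)", 13), ("state", 2), ("time+state", 13),
        ("time(NC)&const(C)", 13), ("time(C)&const(NC)", 13),
    ])
    def test_recapture_column_counts(self, layout, label, expected):
        d = build_design(ParameterStructure(p=label), layout)
        assert d.x_p.shape[1] == expected

    def test_unknown_label_raises_catalogue_error(self):
        with pytest.raises(CatalogueError):
            ParameterStructure(phi="seasonality")

    def test_surrogate_replaces_time_factor_with_two_columns(self, layout):
        for surrogate in ("season", "temperature", "rainfall"):
            d = build_design(ParameterStructure(phi="time", time=surrogate), layout)
            assert d.x_phi.shape[1] == 2


class TestPrimaryDetection:
    def test_closed_form_values(self):
        assert primary_detection_prob(0.5, 2) == pytest.approx(0.75)
        assert primary_detection_prob(0.0, 7) == 0.0
        assert primary_detection_prob(0.2, 4) == pytest.approx(0.5904)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            primary_detection_prob(1.5, 2)


class TestForward:
    def test_release_at_last_primary_contributes_zero(self):
        layout = tiny_layout(3, 2)
        rng = np.random.default_rng(0)
        params = _random_params(rng, 3)
        h = EncounterHistory("a", ("0", "0", "0", "0", "0", "N"))
        assert forward_loglik(h, params, layout) == pytest.approx(0.0)

    def test_fully_observed_path_probability(self):
        """p=1, k=1: three caring sightings are two survivals, 0.8^2."""
        layout = tiny_layout(3, 1)
        params = CmrParameters(
            phi=np.array([[0.5] * 2, [0.5] * 2, [0.8] * 2]),
            p=np.ones((3, 3)),
            psi=np.array([[0.3] * 2, [0.0] * 2]),  # C -> N never happens
        )
        h = EncounterHistory("a", ("C", "C", "C"))
        assert forward_loglik(h, params, layout) == pytest.approx(math.log(0.64))

    def test_hidden_state_sum_matches_enumeration(self):
        layout = tiny_layout(3, 2)
        params = CmrParameters(
            phi=np.array([[0.9] * 2, [0.9] * 2, [0.8] * 2]),
            p=np.full((3, 3), 0.4),
            psi=np.array([[0.3] * 2, [0.2] * 2]),
        )
        h = EncounterHistory("a", ("N", "0", "0", "0", "C", "0"))
        assert forward_loglik(h, params, layout) == pytest.approx(
            enumerate_loglik(h, params, layout), abs=1e-12
        )

    def test_forward_equals_enumeration_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            layout = tiny_layout(int(rng.integers(2, 5)), int(rng.integers(1, 3)))
            params = _random_params(rng, layout.n_primary)
            h = random_history(rng, layout)
            assert forward_loglik(h, params, layout) == pytest.approx(
                enumerate_loglik(h, params, layout), abs=1e-10
            )

    def test_post_release_outcomes_sum_to_one(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            layout = tiny_layout(int(rng.integers(2, 5)), 2)
            params = _random_params(rng, layout.n_primary)
            for state in ("F", "N", "C"):
                total = sum(
                    mult * math.exp(forward_loglik(h, params, layout))
                    for h, mult in enumerate_outcome_probs(state, 0, params, layout)
                )
                assert total == pytest.approx(1.0, abs=1e-10)


class TestTotalLoglik:
    def test_frequency_weighting(self):
        layout = tiny_layout(3, 2)
        rng = np.random.default_rng(2)
        h1 = random_history(rng, layout)
        h3 = EncounterHistory("a", h1.codes, frequency=3)
        structure = ParameterStructure()
        design_k = build_design(structure, layout).k
        beta = rng.normal(0, 0.3, design_k)
        single = total_loglik([h1], beta, structure, layout)
        assert total_loglik([h3], beta, structure, layout) == pytest.approx(3 * single)

    def test_duplication_equals_frequency_encoding(self):
        layout = tiny_layout(3, 2)
        rng = np.random.default_rng(3)
        h = random_history(rng, layout)
        structure = ParameterStructure("category", "time", "state")
        beta = rng.normal(0, 0.3, build_design(structure, layout).k)
        dup = total_loglik([h, h], beta, structure, layout)
        freq2 = total_loglik(
            [EncounterHistory("a", h.codes, 2)], beta, structure, layout
        )
        assert dup == pytest.approx(freq2)

    def test_matches_enumeration_totals(self):
        layout = tiny_layout(4, 2)
        rng = np.random.default_rng(4)
        histories = [random_history(rng, layout) for _ in range(20)]
        structure = ParameterStructure("time+category", "state", "time+state")
        beta = rng.normal(0, 0.4, build_design(structure, layout).k)
        params = CmrParameters.from_beta(structure, layout, beta)
        oracle = sum(enumerate_loglik(h, params, layout) for h in histories)
        assert total_loglik(histories, beta, structure, layout) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_analytic_gradient_matches_finite_differences(self):
        layout = tiny_layout(4, 2)
        rng = np.random.default_rng(6)
        histories = [random_history(rng, layout) for _ in range(25)]
        data = CmrData.from_histories(histories, layout)
        for structure in (
            ParameterStructure("time+category", "time+category", "time+state"),
            ParameterStructure("state", "time(M)&const(F)",
                               "time(NtoC)&const(CtoN)", "season"),
        ):
            design = build_design(structure, layout)
            beta = rng.normal(0, 0.5, design.k)
            _, grad = _total_loglik_grad(data, design, beta)
            for j in rng.choice(design.k, size=min(6, design.k), replace=False):
                e = np.zeros(design.k)
                e[j] = 1e-6
                fd = (
                    _total_loglik_grad(data, design, beta + e, False)[0]
                    - _total_loglik_grad(data, design, beta - e, False)[0]
                ) / 2e-6
                assert grad[j] == pytest.approx(fd, abs=1e-5, rel=1e-5)


class TestFitting:
    def test_full_detection_gives_closed_form_survival(self):
        """With p = 1 every survivor is seen, so the interval-specific MLE of
        female survival is the observed fraction re-encountered alive."""
        from iporangaia.synthetic_data import SimulationConfig, simulate_population
        layout = tiny_layout(4, 2)
        t = layout.n_primary
        cfg = SimulationConfig(
            seed=10, layout=layout,
            phi=np.vstack([np.array([0.8, 0.6, 0.7])] * 3),
            p=np.ones((3, t)),
            psi=np.zeros((2, t - 1)),
            recruitment_males=(0,) * t,
            recruitment_females=(400, 0, 0, 0),
        )
        pop = simulate_population(cfg)
        latent = pop["truth"]["latent"]
        alive = (latent[[f"t{i}" for i in range(t)]].to_numpy() >= 0)
        observed_frac = [
            alive[alive[:, i], i + 1].mean() for i in range(t - 1)
        ]
        fit = fit_ml(
            pop["histories"], ParameterStructure(phi="time", p="constant"),
            layout, n_starts=2,
        )
        est = fit.estimates().phi[0]
        assert np.allclose(est, observed_frac, atol=2e-3)

    def test_parameter_recovery_at_scale(self, layout, constant_population,
                                         constant_truth):
        fit = fit_ml(
            constant_population["histories"],
            ParameterStructure("state", "constant", "state"),
            layout, n_starts=2,
        )
        est = fit.estimates()
        assert est.phi[0, 0] == pytest.approx(constant_truth["phi_NC"], abs=0.05)
        assert est.phi[2, 0] == pytest.approx(constant_truth["phi_C"], abs=0.05)
        assert est.p[0, 0] == pytest.approx(constant_truth["p_all"], abs=0.05)
        assert est.psi[0, 0] == pytest.approx(constant_truth["psi_NC"], abs=0.05)
        assert est.psi[1, 0] == pytest.approx(constant_truth["psi_CN"], abs=0.05)

    def test_restarts_reach_same_optimum(self, layout, constant_population):
        fit = fit_ml(
            constant_population["histories"],
            ParameterStructure("state", "constant", "state"),
            layout, n_starts=5, seed=3,
        )
        assert fit.n_starts == 5
        assert max(fit.start_logliks) - min(fit.start_logliks) < 1e-4

    def test_nested_structure_never_beats_nesting_one(self, layout,
                                                      constant_population):
        """Maximised log-likelihood is monotone in design-column nesting."""
        data = CmrData.from_histories(constant_population["histories"], layout)
        pairs = [
            (ParameterStructure(phi="constant"), ParameterStructure(phi="category")),
            (ParameterStructure(phi="sex"), ParameterStructure(phi="category")),
            (ParameterStructure(p="constant"), ParameterStructure(p="time")),
        ]
        for small, big in pairs:
            ll_small = fit_ml(data, small, layout, n_starts=2).log_likelihood
            ll_big = fit_ml(data, big, layout, n_starts=2).log_likelihood
            assert ll_big >= ll_small - 1e-6


class TestAbundance:
    def test_horvitz_thompson_closed_form(self):
        assert 30 / primary_detection_prob(0.5, 2) == pytest.approx(40.0)

    def test_recovers_simulated_population_size(self, layout):
        from iporangaia.synthetic_data import SimulationConfig, simulate_population
        t = layout.n_primary
        cfg = SimulationConfig(
            seed=14,
            phi=np.ones((3, t - 1)), p=np.full((3, t), 0.5),
            psi=np.zeros((2, t - 1)),
            recruitment_males=(0,) * t,
            recruitment_females=(200,) + (0,) * (t - 1),
        )
        pop = simulate_population(cfg)
        fit = fit_ml(
            pop["histories"], ParameterStructure(), layout, n_starts=2,
        )
        table = derived_abundance(fit, pop["histories"], layout)
        females = table[table["category"] == "F"]
        # everyone survives, so every primary should estimate ~200
        assert females["N_hat"].mean() == pytest.approx(200, rel=0.07)

    def test_p_one_returns_count(self, layout, constant_population):
        fit = fit_ml(
            constant_population["histories"],
            ParameterStructure("state", "constant", "state"), layout, n_starts=1,
        )
        fit.beta[fit.design().x_phi.shape[1]] = 15.0  # force p to the boundary
        table = derived_abundance(fit, constant_population["histories"], layout)
        assert np.allclose(table["N_hat"], table["n_captured"], rtol=1e-4)
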