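"""Structure, steady states and stochastic simulation of the kinetic models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from exondef import (ISOFORMS, KineticParameters, SteadyStateError,
                     build_model, isoform_frequencies, simulate_ssa,
                     steady_state, steady_state_distribution)
from exondef.kinetics import degradation_flux

from conftest import random_parameters


class TestBuildModel:
    def test_one_step_structure(self, one_step_params):
        model = build_model("one_step", one_step_params)
        assert len(model.species) == 17
        # RHS of P0_0_0: +s and -(k1+k2+k3+kret)*P0_0_0
        i = model.species.index("P0_0_0")
        p = one_step_params
        assert model.b[i] == pytest.approx(p.s)
        assert model.A[i, i] == pytest.approx(-(p.k1 + p.k2 + p.k3 + p.kret))

    def test_two_step_adds_intermediate_states(self, truth_params):
        model = build_model("two_step", truth_params)
        assert len(model.species) == 21
        for name in ("P0_a_0", "P1_a_0", "P0_a_1", "P1_a_1"):
            assert name in model.species

    def test_zero_definition_rates_leave_only_export_and_decay(self):
        params = KineticParameters(k1=0, k3=0, k2=0, k4=0, k5=0, k6=0,
                                   kspli=0.1, kret=0.01)
        model = build_model("one_step", params)
        x = steady_state(model)
        flowing = {name for name, rate, src, dst in model.reactions
                   if rate * (1.0 if src is None else x[src]) > 0}
        assert flowing == {"s", "kret", "kdr1", "kdr2"}

    def test_unknown_variant_and_negative_rate(self, one_step_params):
        with pytest.raises(ValueError):
            build_model("three_step", one_step_params)
        with pytest.raises(ValueError):
            KineticParameters(k2=0.1, k1=-1.0)

    def test_variant_exclusivity(self):
        with pytest.raises(ValueError):
            KineticParameters(k2=0.1, k2a=0.1, k2b=0.1)


class TestSteadyState:
    def test_no_definition_gives_pure_fullIR(self):
        params = KineticParameters(k1=0, k3=0, k2=0, kspli=0.1, kret=0.01)
        dist = steady_state_distribution(build_model("one_step", params))
        assert dist.fullIR == pytest.approx(1.0)
        assert dist.efficiency == pytest.approx(0.0)

    def test_no_export_gives_full_efficiency(self):
        params = KineticParameters(k1=5, k3=5, k2=1, kret=0.0, kspli=0.5)
        dist = steady_state_distribution(build_model("one_step", params))
        assert dist.efficiency == pytest.approx(1.0)
        assert dist.fullIR == dist.first_ir == dist.second_ir == 0.0

    def test_singular_system_reported(self):
        # inclusion isoform receives influx but never degrades
        params = KineticParameters(k1=1, k3=1, k2=1, kspli=0.5, kret=0.01,
                                   kincl=0.0)
        with pytest.raises(SteadyStateError):
            steady_state(build_model("one_step", params))

    @pytest.mark.parametrize("variant", ["one_step", "two_step"])
    def test_linear_solve_matches_long_time_integration(self, variant):
        rng = np.random.default_rng(42)
        for _ in range(5):
            params = random_parameters(rng, variant)
            model = build_model(variant, params)
            x = steady_state(model)
            sol = solve_ivp(lambda t, y: model.rhs(y), (0.0, 1e7),
                            np.zeros(len(x)), method="LSODA",
                            jac=lambda t, y: model.A, rtol=1e-10, atol=1e-16)
            rel = np.abs(sol.y[:, -1] - x) / np.maximum(np.abs(x), 1e-30)
            assert rel.max() < 1e-6

    @pytest.mark.parametrize("variant", ["one_step", "two_step"])
    def test_mass_balance(self, variant):
        rng = np.random.default_rng(3)
        for _ in range(5):
            params = random_parameters(rng, variant)
            model = build_model(variant, params)
            x = steady_state(model)
            assert degradation_flux(model, x) == pytest.approx(params.s, rel=1e-8)

    def test_exon_exchange_symmetry(self):
        params = KineticParameters(k1=0.03, k3=0.03, k2=0.02, kdr1=0.002,
                                   kdr2=0.002, kspli=0.2, kret=0.004)
        dist = steady_state_distribution(build_model("one_step", params))
        assert dist.first_ir == pytest.approx(dist.second_ir, rel=1e-10)

    def test_psi_monotone_in_k2(self, one_step_params):
        psis = []
        for k2 in np.geomspace(1e-4, 10, 25):
            dist = steady_state_distribution(
                build_model("one_step", one_step_params.replace(k2=k2)))
            psis.append(dist.psi)
        assert np.all(np.diff(psis) >= -1e-9)

    def test_two_step_fast_second_step_limit(self, one_step_params):
        """k2b -> inf funnels the transient intermediate forward, so the
        limit is the one-step model with AE dissociation k5a*k5b/k2b -> 0."""
        k2b = 1e7
        two = one_step_params.replace(k2=None, k2a=one_step_params.k2, k2b=k2b)
        one = one_step_params.replace(k5=two.k5a * two.k5b / k2b)
        d_two = steady_state_distribution(build_model("two_step", two))
        d_one = steady_state_distribution(build_model("one_step", one))
        assert np.abs(d_two.frequencies - d_one.frequencies).max() < 1e-4

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           variant=st.sampled_from(["one_step", "two_step"]))
    def test_nonnegative_steady_state(self, seed, variant):
        params = random_parameters(np.random.default_rng(seed), variant)
        x = steady_state(build_model(variant, params))
        assert np.all(x >= -1e-12)


class TestIsoformFrequencies:
    def test_direct_substitution(self):
        state = np.zeros(17)
        species = build_model("one_step", KineticParameters(k2=1.0)).species
        for iso, val in zip(ISOFORMS, (4.0, 1.0, 3.0, 1.0, 1.0)):
            state[species.index(iso)] = val
        dist = isoform_frequencies(species, state)
        assert dist.frequencies == pytest.approx([0.4, 0.1, 0.3, 0.1, 0.1])
        assert dist.psi == pytest.approx(80.0)
        assert dist.efficiency == pytest.approx(0.5)

    def test_equal_inclusion_skipping_gives_psi_50(self):
        species = build_model("one_step", KineticParameters(k2=1.0)).species
        state = np.zeros(17)
        state[species.index("inclusion")] = 0.2
        state[species.index("skipping")] = 0.2
        state[species.index("fullIR")] = 0.6
        assert isoform_frequencies(species, state).psi == pytest.approx(50.0)

    def test_all_zero_terminal_isoforms_error(self):
        model = build_model("one_step", KineticParameters(k2=1.0))
        with pytest.raises(SteadyStateError):
            isoform_frequencies(model, np.zeros(17))


class TestSSA:
    def test_seeded_reproducibility(self, truth_params):
        model = build_model("two_step", truth_params)
        a = simulate_ssa(model, n_cells=20, t_end=2000, seed=5, scale=50)
        b = simulate_ssa(model, n_cells=20, t_end=2000, seed=5, scale=50)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_inputs(self, truth_params):
        model = build_model("two_step", truth_params)
        with pytest.raises(ValueError):
            simulate_ssa(model, n_cells=5, t_end=0.0, seed=0)
        zero_s = build_model("two_step", truth_params.replace(s=0.0))
        with pytest.raises(ValueError):
            simulate_ssa(zero_s, n_cells=5, t_end=10.0, seed=0)

    def test_ensemble_mean_approaches_ode_and_psi_unimodal(self, truth_params):
        model = build_model("two_step", truth_params)
        t_end = 7.0 * model.relaxation_time()
        result = simulate_ssa(model, n_cells=150, t_end=t_end, seed=1,
                              scale=None)
        ode = steady_state_distribution(model).frequencies
        diff = np.abs(result.mean_frequencies() - ode)
        se = result.frequency_standard_errors()
        assert np.all(diff < 3.0 * np.maximum(se, 1e-4))
        # intermediate AE strength: per-cell PSI distribution is unimodal
        assert result.psi_mode_count() == 1
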