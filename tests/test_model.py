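"""Deterministic model core: drift, Jacobian, equilibria, sweeps, search."""

import numpy as np
import pytest

from ewsbench.errors import (
    DimensionError,
    PreconditionError,
    SweepError,
)
from ewsbench.model import (
    ModelParameters,
    calibrate_sweep_endpoints,
    coexistence_equilibrium,
    default_4d_parameters,
    default_4d_sweep,
    drift,
    find_equilibrium,
    jacobian,
    random_parameter_search,
    stability_metrics,
    sweep_bifurcation_parameter,
)
from conftest import single_species_params


def random_params(rng, sa=2, sp=2):
    gam_A = rng.uniform(0.1, 1.0, (sa, sp))
    gam_P = rng.uniform(0.1, 1.0, (sp, sa))
    c_A = rng.uniform(0.0, 0.1, (sa, sa))
    c_P = rng.uniform(0.0, 0.1, (sp, sp))
    np.fill_diagonal(c_A, 0.3)
    np.fill_diagonal(c_P, 0.3)
    return ModelParameters(
        n_pollinators=sa,
        n_plants=sp,
        r_A=rng.uniform(-0.5, 0.3, sa),
        r_P=rng.uniform(-0.5, 0.3, sp),
        gamma_A=gam_A,
        gamma_P=gam_P,
        c_A=c_A,
        c_P=c_P,
        h_A=rng.uniform(0.2, 1.0, sa),
        h_P=rng.uniform(0.2, 1.0, sp),
        sigma_A=np.full(sa, 0.02),
        sigma_P=np.full(sp, 0.02),
    )


class TestDrift:
    def test_origin_is_absorbing(self, params_4d):
        assert np.array_equal(drift(np.zeros(4), params_4d), np.zeros(4))

    def test_balanced_growth_and_competition_cancel(self):
        # r = 0.3, self-competition 0.3, no mutualism, abundance 1:
        # growth exactly offsets competition in both guilds
        p = single_species_params(r=0.3, c=0.3)
        assert drift(np.ones(2), p) == pytest.approx([0.0, 0.0], abs=1e-15)

    def test_saturating_mutualism_hand_value(self):
        # pollinator: r=-0.1, gamma*P=1, h=0.5 -> mutualism 1/1.5;
        # competition 0.3 -> drift = -0.1 + 2/3 - 0.3 = 0.2667 at A=1
        p = ModelParameters(
            n_pollinators=1,
            n_plants=1,
            r_A=[-0.1],
            r_P=[0.5],
            gamma_A=[[1.0]],
            gamma_P=[[0.0]],
            c_A=[[0.3]],
            c_P=[[0.3]],
            h_A=[0.5],
            h_P=[0.5],
            sigma_A=[0.0],
            sigma_P=[0.0],
        )
        d = drift(np.ones(2), p)
        assert d[0] == pytest.approx(-0.1 + 1.0 / 1.5 - 0.3, abs=1e-12)

    def test_dimension_and_negativity_errors(self, params_4d):
        with pytest.raises(DimensionError):
            drift(np.ones(3), params_4d)
        with pytest.raises(PreconditionError):
            drift(np.array([1.0, -0.1, 1.0, 1.0]), params_4d)


class TestJacobian:
    def test_origin_linearisation_is_growth_rates(self):
        p = single_species_params(r=0.4, c=0.3)
        J = jacobian(np.zeros(2), p)
        assert J == pytest.approx(np.diag([0.4, 0.4]), abs=1e-14)

    def test_logistic_equilibrium_eigenvalue(self):
        # dA/dt = rA - cA^2 has equilibrium r/c with derivative -r
        p = single_species_params(r=0.3, c=0.3)
        eq = np.array([1.0, 1.0])
        J = jacobian(eq, p)
        assert np.diag(J) == pytest.approx([-0.3, -0.3], abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_central_differences(self, trial):
        rng = np.random.default_rng(900 + trial)
        p = random_params(rng)
        x = rng.uniform(0.2, 2.0, 4)
        J = jacobian(x, p)
        eps = 1e-6
        J_num = np.empty_like(J)
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            J_num[:, j] = (drift(x + e, p) - drift(x - e, p)) / (2 * eps)
        assert J == pytest.approx(J_num, rel=1e-5, abs=1e-8)


class TestEquilibrium:
    def test_logistic_closed_form(self):
        p = single_species_params(r=0.3, c=0.3)
        eq = find_equilibrium(p, np.full(2, 0.5))
        assert eq == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_extinction_is_only_equilibrium_without_mutualism(self):
        p = single_species_params(r=-0.2, c=0.3)
        eq = find_equilibrium(p, np.full(2, 0.05))
        assert eq == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_reference_community_resilience(self, params_4d):
        # the calibrated sweep start has dominant eigenvalue -0.45
        params, r0, _ = default_4d_sweep(reactive=False)
        eq = coexistence_equilibrium(params)
        m = stability_metrics(params, eq)
        assert m.dominant_eigenvalue == pytest.approx(-0.45, abs=1e-6)
        assert np.all(eq > 0.1)

    def test_residual_below_tolerance(self, params_4d):
        eq = coexistence_equilibrium(params_4d)
        assert np.max(np.abs(drift(eq, params_4d))) < 1e-10


class TestStabilityMetrics:
    def test_symmetric_jacobian_reactivity_equals_dominant(self):
        # decoupled logistic guilds give a diagonal (hence normal) Jacobian
        p = single_species_params(r=0.3, c=0.3)
        m = stability_metrics(p, np.ones(2))
        assert m.reactivity == pytest.approx(m.dominant_eigenvalue, abs=1e-12)

    def test_shear_makes_stable_system_reactive(self):
        # closed form for J = [[-1, 10], [0, -1]]: eigenvalues -1, -1 but
        # Hermitian part [[-1, 5], [5, -1]] has eigenvalue 4
        J = np.array([[-1.0, 10.0], [0.0, -1.0]])
        dom = max(np.linalg.eigvals(J).real)
        react = max(np.linalg.eigvalsh((J + J.T) / 2))
        assert dom == pytest.approx(-1.0)
        assert react == pytest.approx(4.0)

    def test_reactivity_bounds_dominant_eigenvalue(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_params(rng)
            x = rng.uniform(0.1, 2.0, 4)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = stability_metrics(p, x)
            assert m.reactivity >= m.dominant_eigenvalue - 1e-12

    def test_warns_off_equilibrium(self, params_4d):
        with pytest.warns(UserWarning, match="off-equilibrium"):
            stability_metrics(params_4d, np.full(4, 5.0))


class TestSweep:
    def test_eigenvalue_increases_toward_transition(self, sweep_4d):
        eigs = [s.stability.dominant_eigenvalue for s in sweep_4d]
        assert np.all(np.diff(eigs) > 0)
        assert eigs[0] == pytest.approx(-0.45, abs=1e-4)
        assert eigs[-1] == pytest.approx(-0.15, abs=1e-4)

    def test_reactive_tuning_published_interval_spans_same_range(
        self, sweep_4d_reactive
    ):
        eigs = [s.stability.dominant_eigenvalue for s in sweep_4d_reactive]
        assert eigs[0] == pytest.approx(-0.45, abs=0.01)
        assert eigs[-1] == pytest.approx(-0.15, abs=0.01)

    def test_single_step_sweep_is_start_equilibrium(self, params_4d):
        params, r0, r1 = default_4d_sweep(reactive=False)
        steps = sweep_bifurcation_parameter(params, r0, r1, 1)
        assert len(steps) == 1
        eq = coexistence_equilibrium(params.with_r_A(r0))
        assert steps[0].equilibrium == pytest.approx(eq, abs=1e-8)

    def test_collapsing_path_raises_sweep_error(self):
        params, r0, _ = default_4d_sweep(reactive=False)
        # drive far beyond the fold: the branch must be lost mid-sweep
        with pytest.raises(SweepError):
            sweep_bifurcation_parameter(params, r0, r0 - 1.5, 30)

    def test_calibration_hits_requested_eigenvalues(self, params_4d):
        start, end = calibrate_sweep_endpoints(
            params_4d,
            r_A_ref=np.array([-0.3, -0.2]),
            direction=np.array([-1.0, -1.0]),
            eig_start=-0.4,
            eig_end=-0.2,
            s_bracket=(-0.3, 0.5),
        )
        for target, r in ((-0.4, start), (-0.2, end)):
            p = params_4d.with_r_A(r)
            m = stability_metrics(p, coexistence_equilibrium(p))
            assert m.dominant_eigenvalue == pytest.approx(target, abs=1e-6)


class TestParameterValidation:
    def test_rejects_weak_self_competition(self):
        with pytest.raises(PreconditionError, match="self-competition"):
            ModelParameters(
                n_pollinators=2,
                n_plants=2,
                r_A=[0.1, 0.1],
                r_P=[0.1, 0.1],
                gamma_A=np.eye(2),
                gamma_P=np.eye(2),
                c_A=[[0.1, 0.3], [0.1, 0.3]],
                c_P=[[0.3, 0.1], [0.1, 0.3]],
                h_A=[0.5, 0.5],
                h_P=[0.5, 0.5],
                sigma_A=[0.02, 0.02],
                sigma_P=[0.02, 0.02],
            )

    def test_rejects_negative_rates(self):
        with pytest.raises(PreconditionError):
            single_species_params(sigma=-0.1)


class TestRandomSearch:
    def test_partial_collapse_kills_exactly_driven_half(self):
        res = random_parameter_search(
            dims=(10, 10), collapse_type="partial", seed=1, budget=200
        )
        assert res.extinct_after_collapse.sum() == 5
        assert np.array_equal(np.flatnonzero(res.extinct_after_collapse), res.driven)
        # sweep endpoints span the calibrated resilience range
        steps = sweep_bifurcation_parameter(res.params, res.r_A_start, res.r_A_end, 5)
        assert steps[0].stability.dominant_eigenvalue == pytest.approx(-0.45, abs=1e-4)
        assert steps[-1].stability.dominant_eigenvalue == pytest.approx(-0.15, abs=1e-4)

    def test_full_collapse_extinguishes_everyone(self):
        res = random_parameter_search(
            dims=(10, 10), collapse_type="full", seed=1, budget=200
        )
        assert res.extinct_after_collapse.all()
        assert res.extinct_after_collapse.size == 20

    def test_deterministic_under_seed(self):
        a = random_parameter_search(dims=(10, 10), collapse_type="full", seed=3, budget=200)
        b = random_parameter_search(dims=(10, 10), collapse_type="full", seed=3, budget=200)
        assert np.array_equal(a.params.gamma_A, b.params.gamma_A)
        assert np.array_equal(a.r_A_end, b.r_A_end)
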