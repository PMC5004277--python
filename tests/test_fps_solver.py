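"""Forward film-pore-surface diffusion solver."""

from dataclasses import replace

import numpy as np
import pytest

import cellsorb as cs
from cellsorb.errors import InvalidInputError

from conftest import SAMPLING_TIMES, simulate_expanded_form


class TestEffectiveDiffusivity:
    def test_no_surface_diffusion(self):
        tp = cs.TransportParams(K_L=1.0, D_p=1e-6, D_s=0.0)
        p = cs.LangmuirParams(5.61, 11.5)
        assert cs.effective_diffusivity(0.05, tp, 1.59, p) == 1e-6

    def test_saturation_limit(self):
        tp = cs.TransportParams(K_L=1.0, D_p=1e-6, D_s=1e-5)
        p = cs.LangmuirParams(5.61, 11.5)
        assert cs.effective_diffusivity(1e6, tp, 1.59, p) == pytest.approx(1e-6, rel=1e-6)

    def test_reference_value(self, ugcs):
        der = ugcs.system.derived()
        De = cs.effective_diffusivity(0.079436, ugcs.transport, der.rho_a, ugcs.langmuir)
        assert De == pytest.approx(6.325e-6, rel=1e-3)

    def test_decreasing_in_concentration(self, ugcs):
        der = ugcs.system.derived()
        C = np.linspace(0, 0.2, 50)
        De = cs.effective_diffusivity(C, ugcs.transport, der.rho_a, ugcs.langmuir)
        assert np.all(np.diff(De) < 0)
        assert np.all(De >= ugcs.transport.D_p)


class TestAverageAdsorbed:
    def grid(self, N=101):
        return cs.RadialGrid(R=1.0, times=np.array([1.0]), N=N)

    def test_constant_profile(self):
        g = self.grid()
        assert cs.average_adsorbed(np.full(g.N, 3.7), g) == pytest.approx(3.7, rel=1e-12)

    def test_linear_profile(self):
        g = self.grid(N=201)
        # exact volume average of q = r/R over a sphere is 3/4
        assert cs.average_adsorbed(g.r / g.R, g) == pytest.approx(0.75, rel=1e-3)

    def test_zero_profile(self):
        g = self.grid()
        assert cs.average_adsorbed(np.zeros(g.N), g) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.average_adsorbed(np.zeros(7), self.grid())


class TestSimulate:
    def test_empty_bath_stays_empty(self, sgcs):
        sys0 = replace(sgcs.system, C_0=0.0)
        grid = cs.RadialGrid(R=sys0.R, times=SAMPLING_TIMES, N=30)
        res = cs.simulate(sys0, sgcs.langmuir, sgcs.transport, grid)
        assert np.all(res.C_L == 0.0) and np.all(res.q_a == 0.0)
        assert np.all(res.mass_residual == 0.0)

    def test_monotone_exchange_and_conservation(self, ugcs):
        grid = cs.RadialGrid.default(ugcs.system.R, t_end=120.0, N=60, n_times=40)
        res = cs.simulate(ugcs.system, ugcs.langmuir, ugcs.transport, grid)
        assert res.C_L[0] == pytest.approx(ugcs.system.C_0)
        assert res.q_a[0] == 0.0
        assert np.all(np.diff(res.C_L) <= 1e-9)
        assert np.all(np.diff(res.q_a) >= -1e-8)
        assert np.all(res.C_P >= 0) and np.all(res.q_r >= 0)
        assert res.mass_residual.max() <= 1e-6

    def test_grid_convergence(self, sgcs):
        q = {}
        for N in (60, 120):
            grid = cs.RadialGrid(R=sgcs.system.R, times=SAMPLING_TIMES, N=N)
            q[N] = cs.simulate(sgcs.system, sgcs.langmuir, sgcs.transport, grid).q_a
        assert np.max(np.abs(q[120] - q[60]) / q[120]) < 2e-3

    def test_refining_grid_keeps_conservation(self, sgcs):
        res = {}
        for N in (30, 60):
            grid = cs.RadialGrid(R=sgcs.system.R, times=SAMPLING_TIMES, N=N)
            res[N] = cs.simulate(sgcs.system, sgcs.langmuir, sgcs.transport,
                                 grid).mass_residual.max()
        assert res[60] <= max(res[30], 1e-6)

    def test_conservative_and_expanded_forms_agree(self, sgcs):
        """The flux form and the chain-rule-expanded form solve the same PDE."""
        grid = cs.RadialGrid(R=sgcs.system.R, times=SAMPLING_TIMES, N=161)
        res = cs.simulate(sgcs.system, sgcs.langmuir, sgcs.transport, grid)
        _, _, q_a_exp = simulate_expanded_form(sgcs.system, sgcs.langmuir,
                                               sgcs.transport, grid)
        assert np.max(np.abs(res.q_a - q_a_exp) / res.q_a) < 1e-3

    def test_mass_balance_residual_zero_at_start(self, sgcs):
        grid = cs.RadialGrid(R=sgcs.system.R, times=np.array([0.0, 10.0]), N=30)
        res = cs.simulate(sgcs.system, sgcs.langmuir, sgcs.transport, grid)
        assert res.mass_residual[0] < 1e-12


class TestGridAndParams:
    def test_too_few_nodes_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.RadialGrid(R=1.0, times=np.array([1.0]), N=5)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.RadialGrid(R=1.0, times=np.array([1.0, 1.0]), N=30)

    def test_all_zero_transport_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.TransportParams(K_L=0.0, D_p=0.0, D_s=0.0)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.TransportParams(K_L=-1.0, D_p=1e-6, D_s=0.0)
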