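"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.sparse import diags

import cellsorb as cs
from cellsorb.isotherm import langmuir_slope

hyp_settings.register_profile("suite", derandomize=True)
hyp_settings.load_profile("suite")

#: the kinetic sampling design (min)
SAMPLING_TIMES = np.array([2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0])


@pytest.fixture(scope="session")
def sgcs() -> cs.RunConfig:
    """Sieve-ground corn stover reference system."""
    return cs.builtin_config("sgcs")


@pytest.fixture(scope="session")
def ugcs() -> cs.RunConfig:
    """Ultrafine-ground corn stover reference system."""
    return cs.builtin_config("ugcs")


def finite_bath_sphere_fraction(t: np.ndarray, D: float, R: float, alpha: float,
                                n_terms: int = 60) -> np.ndarray:
    """Classical series solution for uptake from a well-stirred finite bath.

    Fractional uptake M_t/M_inf for linear-partition diffusion into a sphere
    of radius ``R`` with effective diffusivity ``D``, where ``alpha`` is the
    ratio of bath capacity to total sphere capacity (the sphere finally
    holds a fraction 1/(1+alpha) of the solute):

        M_t/M_inf = 1 - sum_n 6 a (1+a) exp(-D q_n^2 t / R^2)
                               / (9 + 9 a + q_n^2 a^2),

    with q_n the non-zero roots of tan(q) = 3q / (3 + a q^2).
    """
    roots = []
    for n in range(1, n_terms + 1):
        f = lambda q: np.tan(q) - 3.0 * q / (3.0 + alpha * q * q)
        roots.append(brentq(f, n * np.pi + 1e-12, (n + 0.5) * np.pi - 1e-12))
    q = np.asarray(roots)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    terms = (6.0 * alpha * (alpha + 1.0)
             * np.exp(-D * q[None, :] ** 2 * t[:, None] / R ** 2)
             / (9.0 + 9.0 * alpha + q[None, :] ** 2 * alpha ** 2))
    return 1.0 - terms.sum(axis=1)


def simulate_expanded_form(sys: cs.ParticleSystem, p: cs.LangmuirParams,
                           tp: cs.TransportParams, grid: cs.RadialGrid,
                           rtol: float = 1e-8, atol: float = 1e-10):
    """Independent forward solver using the chain-rule-expanded PDE.

    Discretises the non-conservative expanded form

        beta(C) dC/dt = D_e(C) C'' + D_e'(C) (C')^2 + (2/r) D_e(C) C'

    with central differences and ghost nodes (symmetry at the centre, the
    film Robin condition at the surface), rather than the conservative
    finite-volume flux form used by the package solver.  Returns (t, C_L,
    q_a) on the grid's output times.
    """
    der = sys.derived()
    N = grid.N
    r = grid.r
    dr = r[1] - r[0]
    phi_eps = der.phi * der.eps

    def rhs(_t, y):
        C = y[:-1]
        C_L = y[-1]
        Cc = np.maximum(C, 0.0)
        fp = langmuir_slope(Cc, p)
        De = tp.D_p + fp * der.rho_a * tp.D_s
        # dDe/dC = f''(C) rho_a D_s
        fpp = -2.0 * p.q_m * p.K_a ** 2 / (1.0 + p.K_a * Cc) ** 3
        dDe = fpp * der.rho_a * tp.D_s
        beta = phi_eps + der.rho_a * fp

        ghost_in = C[1]  # symmetry: C(-dr) = C(dr)
        ghost_out = C[-2] + 2.0 * dr * tp.K_L * (C_L - C[-1]) / De[-1]
        Ce = np.concatenate(([ghost_in], C, [ghost_out]))
        d2 = (Ce[2:] - 2.0 * Ce[1:-1] + Ce[:-2]) / dr ** 2
        d1 = (Ce[2:] - Ce[:-2]) / (2.0 * dr)

        dC = De * d2 + dDe * d1 ** 2
        dC[1:] += 2.0 / r[1:] * De[1:] * d1[1:]
        dC[0] += 2.0 * De[0] * d2[0]  # limit (2/r) C' -> 2 C'' at r = 0
        dC /= beta
        dC_L = -tp.K_L * der.A * (C_L - C[-1]) / sys.V_L
        return np.append(dC, dC_L)

    y0 = np.zeros(N + 1)
    y0[-1] = sys.C_0
    sparsity = diags([np.ones(N), np.ones(N + 1), np.ones(N)], offsets=(-1, 0, 1))
    # the centre/surface ghost rows reach two nodes in; widen the pattern
    sparsity = sparsity.tolil()
    sparsity[0, 2] = 1
    sparsity[N - 1, N - 3] = 1
    sparsity[N - 1, N] = 1
    sparsity[N, N - 1] = 1
    sol = solve_ivp(rhs, (0.0, float(grid.times[-1])), y0, method="BDF",
                    t_eval=grid.times, rtol=rtol, atol=atol,
                    jac_sparsity=sparsity.tocsr())
    assert sol.success, sol.message
    C_P = np.maximum(sol.y.T[:, :-1], 0.0)
    q_r = cs.langmuir_bound(C_P, p)
    q_a = np.array([cs.average_adsorbed(q_r[j], grid) for j in range(len(grid.times))])
    return sol.t, sol.y[-1], q_a
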