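"""Synthetic equilibrium, kinetic and dye-adsorption datasets.

The generators reproduce the experimental design the analysis modules
assume: equilibrium baths dosed at enzyme loadings of 1.5-10.5 mg protein
per g substrate, kinetic sampling at 2, 5, 10, 20, 30, 60, 90 and 120 min
at a 6 mg/g loading, duplicate runs throughout, and dye ladders of
4, 2, 1, 0.25, 0.05, 0 g/L (Congo Red) and 2, 1, 0.5, 0.25, 0.1, 0 g/L
(Azure B) with 100 mg substrate in 10 mL.

Noise is additive Gaussian on the measured bound amount with standard
deviation max(sd_abs, sd_rel * value), truncated below at zero; the free
concentration is then recomputed from the noisy bound amount through the
bath mass balance, mirroring how bound enzyme is obtained experimentally
(initial minus free concentration).  Each replicate draws from its own
child of the seed, so replicates are independent but the whole dataset is
bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fps_solver import RadialGrid, TransportParams, simulate
from .isotherm import Dye, LangmuirParams, batch_equilibrium
from .properties import ParticleSystem

__all__ = [
    "NoiseModel",
    "DEFAULT_LOADINGS",
    "DEFAULT_KINETIC_TIMES",
    "CONGO_RED_LADDER",
    "AZURE_B_LADDER",
    "gen_equilibrium",
    "gen_kinetics",
    "gen_dye",
]

#: enzyme loadings (mg protein / g substrate) of the equilibrium design
DEFAULT_LOADINGS = (1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5)
#: sampling times (min) of the kinetic design
DEFAULT_KINETIC_TIMES = (2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0)
#: initial dye concentrations (g/L)
CONGO_RED_LADDER = (4.0, 2.0, 1.0, 0.25, 0.05, 0.0)
AZURE_B_LADDER = (2.0, 1.0, 0.5, 0.25, 0.1, 0.0)
#: dye bath: 100 mg substrate in 10 mL buffer
DYE_BATH_MASS_G = 0.1
DYE_BATH_VOLUME_ML = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive truncated-Gaussian measurement noise on bound amounts."""

    sd_rel: float = 0.03
    sd_abs: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_rel < 0 or self.sd_abs < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")

    def replicate_rngs(self, n: int) -> list[np.random.Generator]:
        """Independent generators, one per replicate, derived from the seed."""
        return [np.random.default_rng(s) for s in
                np.random.SeedSequence(self.seed).spawn(n)]

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        sd = np.maximum(self.sd_abs, self.sd_rel * v)
        return np.maximum(v + rng.normal(0.0, 1.0, size=v.shape) * sd, 0.0)


def gen_equilibrium(sys: ParticleSystem, p: LangmuirParams,
                    loadings: Sequence[float] = DEFAULT_LOADINGS,
                    reps: int = 2,
                    noise: NoiseModel = NoiseModel()) -> pd.DataFrame:
    """Equilibrium design: one bath per loading, observed (C_f, q_b) pairs.

    Each loading L (mg/g) sets the initial bulk concentration
    C_0 = L * m / V_L; the true equilibrium follows from the closed-bath
    Langmuir fixed point, noise lands on the bound amount, and the reported
    free concentration is recomputed from the mass balance.  Columns:
    ``loading_mg_per_g, C_f_mg_per_mL, q_b_mg_per_g, replicate``.
    """
    loadings = np.asarray(loadings, dtype=float)
    if np.any(loadings <= 0):
        raise InvalidInputError("loadings must be > 0")
    beta = sys.m / sys.V_L
    rows = []
    rngs = noise.replicate_rngs(reps)
    for rep, rng in enumerate(rngs):
        for L in loadings:
            C_0 = L * beta
            bath = replace(sys, C_0=C_0)
            _, q_true = batch_equilibrium(bath, p)
            q_obs = float(noise.perturb(np.array([q_true]), rng)[0])
            q_obs = min(q_obs, C_0 / beta)  # cannot bind more than was dosed
            C_f_obs = C_0 - q_obs * beta
            rows.append((L, C_f_obs, q_obs, rep))
    return pd.DataFrame(rows, columns=["loading_mg_per_g", "C_f_mg_per_mL",
                                       "q_b_mg_per_g", "replicate"])


def gen_kinetics(sys: ParticleSystem, p: LangmuirParams, tp: TransportParams,
                 times: Sequence[float] = DEFAULT_KINETIC_TIMES,
                 reps: int = 2,
                 noise: NoiseModel = NoiseModel(),
                 N: int = 60, **solver_kwargs) -> pd.DataFrame:
    """Kinetic design: noisy samples of the simulated uptake curve q_a(t).

    Extra keyword arguments (``rtol``, ``atol``) go to the forward solver.
    Columns: ``t_min, q_obs_mg_per_g, replicate``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise InvalidInputError("sampling times must be > 0")
    grid = RadialGrid(R=sys.R, times=np.unique(times), N=N)
    res = simulate(sys, p, tp, grid, **solver_kwargs)
    q_true = np.interp(times, res.t, res.q_a)
    rows = []
    for rep, rng in enumerate(noise.replicate_rngs(reps)):
        q_obs = noise.perturb(q_true, rng)
        rows.extend(zip(times, q_obs, [rep] * times.size))
    return pd.DataFrame(rows, columns=["t_min", "q_obs_mg_per_g", "replicate"])


def gen_dye(p: LangmuirParams, dye: Dye,
            concentrations: Sequence[float] | None = None,
            reps: int = 2,
            noise: NoiseModel = NoiseModel(),
            m: float = DYE_BATH_MASS_G,
            V: float = DYE_BATH_VOLUME_ML) -> pd.DataFrame:
    """Dye-adsorption design for the surface-area probes.

    ``p`` is the dye's Langmuir parameter set in dye units: for Congo Red
    q_m in g dye / g substrate with K_a in L/g, for Azure B q_m in
    mg dye / g substrate with K_a in L/g; initial concentrations are g/L.
    The bath equilibrium uses the same closed-bath fixed point as the
    enzyme case (the algebra is unit-agnostic).  Columns:
    ``C0_g_per_L, C_residual_g_per_L, q_dye, replicate``.
    """
    if concentrations is None:
        concentrations = CONGO_RED_LADDER if dye == "congo_red" else AZURE_B_LADDER
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("dye concentrations must be >= 0")
    # mass balance factor: q = (C0 - C_f) * V / m, with V in L for g/L units;
    # Azure B bound amounts are reported in mg/g, so scale by 1000
    unit = 1.0 if dye == "congo_red" else 1000.0
    beta = m / (V / 1000.0) / unit  # (dye conc units) per (q unit)
    rows = []
    for rep, rng in enumerate(noise.replicate_rngs(reps)):
        for C0 in conc:
            if C0 == 0.0:
                rows.append((0.0, 0.0, 0.0, rep))
                continue
            bath = _DyeBath(C_0=C0, beta=beta)
            q_true = _dye_equilibrium(bath, p)
            q_obs = float(noise.perturb(np.array([q_true]), rng)[0])
            q_obs = min(q_obs, C0 / beta)
            rows.append((C0, C0 - q_obs * beta, q_obs, rep))
    return pd.DataFrame(rows, columns=["C0_g_per_L", "C_residual_g_per_L",
                                       "q_dye", "replicate"])


@dataclass(frozen=True)
class _DyeBath:
    C_0: float
    beta: float  # substrate dose expressed in (conc units) per (q unit)


def _dye_equilibrium(bath: _DyeBath, p: LangmuirParams) -> float:
    """Closed-bath Langmuir fixed point in the dye's unit system."""
    a = p.K_a
    b = 1.0 + p.K_a * (bath.beta * p.q_m - bath.C_0)
    c = -bath.C_0
    C_f = (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    return p.q_m * p.K_a * C_f / (1.0 + p.K_a * C_f)
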