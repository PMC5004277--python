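"""Langmuir equilibrium toolkit.

The single-site Langmuir isotherm

    q_b = q_m * K_a * C_f / (1 + K_a * C_f)

relates the bound enzyme amount q_b (mg protein / g substrate) to the free
solution concentration C_f (mg/mL) through the saturation capacity q_m and
the affinity constant K_a (mL/mg).  The product S = q_m * K_a (mL/g) is the
initial slope of the isotherm and serves as a bonding-strength index.

This module provides the law and its slope, nonlinear least-squares fitting
with multi-start initial guesses, the closed-bath equilibrium fixed point,
and the dye-adsorption surface-area conversions (Congo Red for cellulose,
Azure B for lignin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InvalidInputError
from .properties import ParticleSystem

__all__ = [
    "LangmuirParams",
    "FitReport",
    "langmuir_bound",
    "langmuir_slope",
    "bonding_strength",
    "fit_langmuir",
    "batch_equilibrium",
    "dye_surface_area",
    "CONGO_RED_M2_PER_G_DYE",
    "AZURE_B_M2_PER_MG_DYE",
]

#: surface covered by 1 g of adsorbed Congo Red (cellulose probe), m^2
CONGO_RED_M2_PER_G_DYE = 1055.0
#: surface covered by 1 mg of adsorbed Azure B (lignin probe), m^2
AZURE_B_M2_PER_MG_DYE = 1.297

# log10 bounds for both fitted parameters, and the multi-start log grid
_FIT_LOG_BOUNDS = (-3.0, 3.0)
_STARTS = [(qm0, ka0) for qm0 in (0.1, 10.0) for ka0 in (0.01, 1.0, 10.0, 100.0)]
#: Jacobian condition number above which the q_m/K_a split is flagged
ILL_CONDITIONED_THRESHOLD = 1e4


@dataclass(frozen=True)
class LangmuirParams:
    """Langmuir parameters: capacity ``q_m`` (mg/g), affinity ``K_a`` (mL/mg)."""

    q_m: float
    K_a: float

    def __post_init__(self) -> None:
        if self.q_m <= 0 or self.K_a <= 0:
            raise InvalidInputError("q_m and K_a must both be > 0")

    @property
    def S(self) -> float:
        """Bonding strength q_m * K_a (mL/g substrate)."""
        return self.q_m * self.K_a


@dataclass
class FitReport:
    """Outcome of an isotherm fit."""

    params: LangmuirParams
    R2: float
    RMSE: float
    n_obs: int
    condition_number: float
    warnings: list[str] = field(default_factory=list)


def langmuir_bound(C_f, p: LangmuirParams):
    """Bound amount q_b(C_f) = q_m K_a C_f / (1 + K_a C_f); accepts arrays."""
    C = np.asarray(C_f, dtype=float)
    if np.any(C < 0):
        raise InvalidInputError("free concentration must be >= 0")
    out = p.q_m * p.K_a * C / (1.0 + p.K_a * C)
    return float(out) if np.isscalar(C_f) else out


def langmuir_slope(C, p: LangmuirParams):
    """Isotherm slope f'(C) = q_m K_a / (1 + K_a C)^2; accepts arrays.

    f'(0) equals the bonding strength S; the slope decreases monotonically
    to zero as the surface saturates.
    """
    Ca = np.asarray(C, dtype=float)
    if np.any(Ca < 0):
        raise InvalidInputError("concentration must be >= 0")
    out = p.q_m * p.K_a / (1.0 + p.K_a * Ca) ** 2
    return float(out) if np.isscalar(C) else out


def bonding_strength(p: LangmuirParams) -> float:
    """S = q_m * K_a (mL/g substrate)."""
    return p.S


def _coerce_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        xcol = next((cols[k] for k in ("c_f", "c_f_mg_per_ml", "c_residual_g_per_l", "c") if k in cols), None)
        ycol = next((cols[k] for k in ("q_b", "q_b_mg_per_g", "q_dye", "q") if k in cols), None)
        if xcol is None or ycol is None:
            raise InvalidInputError(
                f"dataframe must carry concentration and bound-amount columns, got {list(data.columns)}"
            )
        x = data[xcol].to_numpy(dtype=float)
        y = data[ycol].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in data)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("concentration and response must be 1-D and equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("concentrations and bound amounts must be >= 0")
    return x, y


def goodness_of_fit(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """R^2 against the observed mean and RMSE with an ``n`` denominator."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvalidInputError("R^2 undefined: observations have zero variance")
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / obs.size))


def fit_langmuir(data) -> FitReport:
    """Fit q_m, K_a to (C_f, q_b) pairs by unweighted nonlinear least squares.

    Parameters are optimised on a log10 scale within [1e-3, 1e3] for both
    q_m (mg/g) and K_a (mL/mg), restarting from an 8-point log grid of
    initial guesses; the best-objective solution is kept.  Replicate rows
    enter as independent points.  Data confined to the linear regime
    (K_a C << 1 everywhere) leave only the product q_m*K_a identifiable;
    that situation is detected through the condition number of the
    Jacobian at the solution and flagged in ``warnings``.

    Parameters
    ----------
    data : pandas.DataFrame or (C_f, q_b) array pair
        Free concentrations and bound amounts; zero-concentration rows are
        used as-is (they pin the origin).
    """
    x, y = _coerce_xy(data)
    if np.unique(x).size < 3:
        raise FitError("need at least 3 distinct concentrations to fit q_m and K_a")

    def residuals(theta: np.ndarray) -> np.ndarray:
        q_m, K_a = 10.0 ** theta
        return q_m * K_a * x / (1.0 + K_a * x) - y

    best = None
    for qm0, ka0 in _STARTS:
        try:
            sol = least_squares(
                residuals,
                x0=np.log10([qm0, ka0]),
                bounds=(_FIT_LOG_BOUNDS[0], _FIT_LOG_BOUNDS[1]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy failures on one start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("Langmuir fit did not converge from any multi-start guess")

    q_m, K_a = (float(v) for v in 10.0 ** best.x)
    params = LangmuirParams(q_m=q_m, K_a=K_a)
    pred = langmuir_bound(x, params)
    R2, RMSE = goodness_of_fit(y, pred)

    sv = np.linalg.svd(best.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    warns: list[str] = []
    if cond > ILL_CONDITIONED_THRESHOLD:
        warns.append(
            "ill-conditioned fit: q_m and K_a are not separately identifiable "
            "(data likely confined to the linear low-concentration regime)"
        )
    return FitReport(params=params, R2=R2, RMSE=RMSE, n_obs=x.size,
                     condition_number=cond, warnings=warns)


def batch_equilibrium(sys: ParticleSystem, p: LangmuirParams) -> tuple[float, float]:
    """Equilibrium (C_f, q_b) of a closed bath.

    Combines the isotherm with the mass balance
    ``C_f = C_0 - q_b * m / V_L`` and solves the resulting quadratic in
    C_f, returning the unique non-negative root.
    """
    if sys.C_0 == 0.0:
        return 0.0, 0.0
    beta = sys.m / sys.V_L  # g substrate per mL liquid
    # K_a C^2 + (1 + K_a (beta q_m - C_0)) C - C_0 = 0
    a = p.K_a
    b = 1.0 + p.K_a * (beta * p.q_m - sys.C_0)
    c = -sys.C_0
    disc = b * b - 4.0 * a * c
    if disc < 0:  # pragma: no cover - impossible for valid inputs (c < 0)
        raise FitError("batch equilibrium has no real root")
    # c < 0 guarantees one positive and one negative root; take the positive
    C_f = (-b + np.sqrt(disc)) / (2.0 * a)
    if C_f < 0:  # pragma: no cover
        raise FitError("batch equilibrium has no non-negative root")
    q_b = langmuir_bound(C_f, p)
    return float(C_f), float(q_b)


Dye = Literal["congo_red", "azure_b"]


def dye_surface_area(q_max_dye: float, dye: Dye) -> float:
    """Convert a dye adsorption maximum into a component surface area.

    Congo Red probes cellulose; its maximum is given in g dye / g substrate
    and 1 g of adsorbed dye covers 1055 m^2.  Azure B probes lignin; its
    maximum is given in mg dye / g substrate and 1 mg covers 1.297 m^2.
    Returns m^2 per g substrate.
    """
    if q_max_dye < 0:
        raise InvalidInputError("dye adsorption maximum must be >= 0")
    if dye == "congo_red":
        return q_max_dye * CONGO_RED_M2_PER_G_DYE
    if dye == "azure_b":
        return q_max_dye * AZURE_B_M2_PER_MG_DYE
    raise InvalidInputError(f"unknown dye {dye!r}; expected 'congo_red' or 'azure_b'")
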