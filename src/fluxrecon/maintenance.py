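"""Fitting of growth- and non-growth-associated maintenance (GAM/NGAM).

GAM is the ATP dissipated when 1 gDCW of biomass is synthesized
(mmol ATP/gDCW); it is fitted so that the model's FBA-predicted maximal
yield Y_x/s^max matches the chemostat-measured value.  NGAM is the ATP
dissipated per gDCW per hour for upkeep; it is computed from the measured
maintenance coefficient m_s through the network's maximal ATP yield on
glucose Y_ATP (which depends on the assumed P:O ratio):

    NGAM = m_s * (1000 / M_glc) * Y_ATP    [mmol ATP/gDCW/h]

The predicted Y_x/s^max is extracted as the inverse slope of the glucose
demand q_glc(mu) between two growth rates, which cancels the NGAM offset
and keeps the GAM fit separable from NGAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .model import MetabolicModel, fba, set_maintenance
from .refdata import M_GLC

__all__ = [
    "MaintenanceParams",
    "predicted_yxs_max",
    "fit_gam",
    "compute_ngam",
    "compute_y_atp",
]


@dataclass
class MaintenanceParams:
    gam: float       # mmol ATP/gDCW
    ngam: float      # mmol ATP/gDCW/h
    y_atp: float     # mol ATP/mol glucose
    p_to_o: float    # dimensionless

    def __post_init__(self):
        for name in ("gam", "ngam", "y_atp", "p_to_o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _glucose_exchange(model: MetabolicModel) -> str:
    for rid in ("EX_glc", "EX_glc_e", "EX_glc__D_e"):
        try:
            model.reaction(rid)
            return rid
        except KeyError:
            continue
    raise KeyError("no glucose exchange reaction found (expected EX_glc)")


def _min_glucose_uptake(model: MetabolicModel, mu: float,
                        exchange: Optional[str] = None) -> float:
    """Minimal glucose uptake (mmol/gDCW/h, positive) at fixed growth rate."""
    exchange = exchange or _glucose_exchange(model)
    sol = fba(model, exchange, "max", fixed_fluxes={model.objective_reaction: mu})
    if sol.status != "optimal":
        raise RuntimeError(f"model infeasible at mu={mu}: {sol.status}")
    return -sol.objective_value  # exchange convention: uptake is negative


def predicted_yxs_max(
    model: MetabolicModel,
    mu_points: Tuple[float, float] = (0.1, 0.5),
    m_glc: float = M_GLC,
) -> float:
    """FBA-predicted maximal yield, gDCW/g_glc, from the q_glc(mu) slope."""
    mu1, mu2 = mu_points
    if not (0 < mu1 < mu2):
        raise ValueError("mu points must be positive and increasing")
    q1 = _min_glucose_uptake(model, mu1)
    q2 = _min_glucose_uptake(model, mu2)
    slope = (q2 - q1) / (mu2 - mu1)  # mmol glucose per g biomass
    if slope <= 0:
        raise RuntimeError("glucose demand does not increase with growth rate")
    return 1000.0 / (slope * m_glc)


def fit_gam(
    model: MetabolicModel,
    target_yxs_max: float,
    tol: float = 1e-4,
    bracket: Tuple[float, float] = (0.0, 1000.0),
    max_iter: int = 60,
    ngam: float = 0.0,
    m_glc: float = M_GLC,
) -> float:
    """Bisect GAM until the predicted Y_x/s^max matches the target.

    Yield is strictly decreasing and continuous in GAM, so bisection on the
    bracket converges; NGAM does not influence the slope-based yield but can
    be held at its fitted value for realism.
    """
    if target_yxs_max <= 0:
        raise ValueError("target yield must be positive")
    lo, hi = bracket

    def yield_at(gam: float) -> float:
        try:
            return predicted_yxs_max(set_maintenance(model, gam, ngam), m_glc=m_glc)
        except RuntimeError:
            # probe growth rate unreachable at this GAM (uptake cap): the
            # attainable yield is effectively below any positive target
            return 0.0

    y_lo = yield_at(lo)
    if target_yxs_max > y_lo * (1 + tol):
        raise ValueError(
            f"target yield {target_yxs_max} exceeds the stoichiometric maximum "
            f"{y_lo:.4f} at GAM={lo}"
        )
    if abs(y_lo - target_yxs_max) / target_yxs_max <= tol:
        return lo
    y_hi = yield_at(hi)
    if y_hi > target_yxs_max:
        raise ValueError(f"bracket upper end GAM={hi} still yields {y_hi:.4f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        y_mid = yield_at(mid)
        if abs(y_mid - target_yxs_max) / target_yxs_max <= tol:
            return mid
        if y_mid > target_yxs_max:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_ngam(ms: float, y_atp: float, m_glc: float = M_GLC) -> float:
    """NGAM (mmol ATP/gDCW/h) from the maintenance coefficient m_s."""
    if ms < 0 or y_atp < 0 or m_glc <= 0:
        raise ValueError("ms and y_atp must be non-negative, m_glc positive")
    return ms * (1000.0 / m_glc) * y_atp


def compute_y_atp(model: MetabolicModel, glucose_uptake: float = 1.0) -> float:
    """Maximal ATP yield on glucose (mol ATP/mol glucose).

    Maximizes the ATP-maintenance drain with the biomass flux fixed to zero
    and glucose uptake fixed to ``glucose_uptake``; the result reflects the
    network stoichiometry and the P:O ratio built into its respiratory
    reactions.
    """
    if model.atp_maintenance_reaction is None:
        raise ValueError("model has no ATP maintenance drain")
    exchange = _glucose_exchange(model)
    sol = fba(
        model,
        model.atp_maintenance_reaction,
        "max",
        fixed_fluxes={model.objective_reaction: 0.0, exchange: -glucose_uptake},
    )
    if sol.status == "unbounded":
        raise RuntimeError("ATP yield unbounded: network lacks a closed gas balance")
    if sol.status != "optimal":
        raise RuntimeError(f"ATP yield LP {sol.status}")
    return sol.objective_value / glucose_uptake
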