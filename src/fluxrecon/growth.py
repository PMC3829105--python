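"""Steady-state chemostat analytics.

A chemostat run at dilution rate D fixes the specific growth rate mu = D.
From each steady state this module derives volumetric rates (biomass,
glucose, CO2), the specific substrate uptake q_s and the yield Y_x/s, and
fits the Pirt partition of substrate use into growth and maintenance:

    q_s = D / Y_x/s^max + m_s

where Y_x/s^max (gDCW/g_glc) is the maximal yield and m_s
(g_glc/gDCW/h) the maintenance coefficient.  The maximum specific growth
rate mu_max is estimated from a washout experiment (D > mu_max), where the
cell density decays as Cx(t) = Cx(0) * exp((mu_max - D) t).

Optical density is converted to dry weight through a linear calibration
through the origin; directly filtered dry weights are corrected for the
filter residue blank and a culture-specific factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .refdata import M_C, M_CO2, M_GLC, R_GAS

__all__ = [
    "ChemostatRecord",
    "RatesResult",
    "GrowthParameters",
    "CalibrationModel",
    "calibrate_od_to_dcw",
    "corrected_dcw",
    "steady_state_rates",
    "fit_pirt",
    "fit_washout",
    "element_balance",
    "records_from_tsv",
]


@dataclass
class ChemostatRecord:
    """One steady state's measurements.

    Concentrations: glucose in mmol/L, ammonium-nitrogen in gN/L, biomass
    in gDCW/L.  Off-gas CO2 as a mole fraction of the (dried) gas stream;
    gas flow in L/min at the stated temperature (K) and pressure (Pa).
    """

    D: float
    OD600: Optional[float] = None
    Cx_raw: Optional[float] = None
    Cglc_feed: float = 10.0
    Cglc_residual: float = 0.0
    NH4_feed: Optional[float] = None
    NH4_residual: Optional[float] = None
    co2_offgas_fraction: float = 0.0
    co2_ingas_fraction: float = 0.0
    gas_flow: float = 0.75
    temperature: float = 303.15
    pressure: float = 101325.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("dilution rate D must be positive")
        if self.Cglc_residual > self.Cglc_feed:
            raise ValueError("residual glucose exceeds feed glucose")
        for frac in (self.co2_offgas_fraction, self.co2_ingas_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("off-gas CO2 fractions must be in [0, 1]")


@dataclass
class RatesResult:
    Rx: float      # gDCW/L/h
    Rglc: float    # g_glc/L/h
    Rco2: float    # g_CO2/L/h
    qs: float      # g_glc/gDCW/h
    Yxs: float     # gDCW/g_glc
    Cx: float      # gDCW/L


@dataclass
class GrowthParameters:
    Yxs_max: float
    ms: float
    r_squared: float
    mu_max: Optional[float] = None


@dataclass
class CalibrationModel:
    """OD600 -> dry weight calibration plus direct-DCW corrections."""

    slope: float = 0.35                    # gDCW/L per OD600 unit
    residue: float = 0.356                 # filter blank, g/L
    direct_dcw_factor: float = 0.35 / 0.399
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def calibrate_od_to_dcw(pairs: Sequence[Tuple[float, float]],
                        residue: float = 0.356,
                        direct_dcw_factor: float = 0.35 / 0.399) -> CalibrationModel:
    """Least-squares slope of Cx on OD600, forced through the origin.

    The blank residue and the direct-DCW correction factor are calibration
    configuration, not estimated from these pairs.
    """
    od = np.asarray([p[0] for p in pairs], dtype=float)
    cx = np.asarray([p[1] for p in pairs], dtype=float)
    if len(od) < 2 or np.allclose(od, od[0]):
        raise ValueError("need at least two distinct OD values to calibrate")
    slope = float(np.dot(od, cx) / np.dot(od, od))
    pred = slope * od
    ss_res = float(np.sum((cx - pred) ** 2))
    ss_tot = float(np.sum((cx - cx.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(slope, residue, direct_dcw_factor, r2)


def corrected_dcw(record: ChemostatRecord, cal: CalibrationModel) -> float:
    """Dry weight (gDCW/L) from OD and/or direct filtration.

    OD route: slope * OD600.  Direct route: (Cx_raw - residue) * factor.
    When both measurements exist the unweighted mean of the two estimates
    is returned.
    """
    estimates: List[float] = []
    if record.OD600 is not None:
        estimates.append(cal.slope * record.OD600)
    if record.Cx_raw is not None:
        direct = (record.Cx_raw - cal.residue) * cal.direct_dcw_factor
        if direct < 0:
            raise ValueError(
                f"direct dry weight {record.Cx_raw} g/L below blank residue "
                f"{cal.residue} g/L; check blank specification"
            )
        estimates.append(direct)
    if not estimates:
        raise ValueError("record has neither OD600 nor direct dry weight")
    return float(np.mean(estimates))


def steady_state_rates(record: ChemostatRecord, cal: CalibrationModel,
                       m_glc: float = M_GLC,
                       culture_volume: float = 0.75) -> RatesResult:
    """Volumetric and specific rates for one steady state.

    CO2 production is derived from the in/out mole-fraction difference of
    the gas stream using the ideal gas law p V = n R T at the record's
    temperature and pressure, normalized per liter of culture.
    """
    cx = corrected_dcw(record, cal)
    if cx <= 0:
        raise ValueError("zero biomass concentration")
    rx = record.D * cx
    consumed_mmol = record.Cglc_feed - record.Cglc_residual
    if consumed_mmol <= 0:
        raise ValueError("no glucose consumption at steady state")
    rglc = record.D * consumed_mmol * m_glc / 1000.0
    dfrac = record.co2_offgas_fraction - record.co2_ingas_fraction
    gas_mol_per_h = record.pressure * (record.gas_flow * 60.0 / 1000.0) / (
        R_GAS * record.temperature
    )
    rco2 = max(dfrac, 0.0) * gas_mol_per_h * M_CO2 / culture_volume
    qs = rglc / cx
    return RatesResult(Rx=rx, Rglc=rglc, Rco2=rco2, qs=qs, Yxs=rx / rglc, Cx=cx)


def fit_pirt(points: Sequence[Tuple[float, float]]) -> GrowthParameters:
    """Ordinary least squares of q_s on D; slope = 1/Y_x/s^max, intercept = m_s."""
    if len(points) < 3:
        raise ValueError("Pirt fit needs at least three (D, qs) points")
    d = np.asarray([p[0] for p in points], dtype=float)
    qs = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("Pirt fit needs at least three distinct dilution rates")
    res = stats.linregress(d, qs)
    if res.slope <= 0:
        raise ValueError(
            "non-positive Pirt slope: substrate uptake does not increase with "
            "growth rate (culture not substrate-limited?)"
        )
    return GrowthParameters(
        Yxs_max=1.0 / res.slope,
        ms=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_washout(series: Sequence[Tuple[float, float]], D: float) -> GrowthParameters:
    """mu_max from the log-linear decay of cell density during washout.

    ln Cx is regressed on time; the slope equals mu_max - D.
    """
    if len(series) < 3:
        raise ValueError("washout fit needs at least three time points")
    t = np.asarray([p[0] for p in series], dtype=float)
    cx = np.asarray([p[1] for p in series], dtype=float)
    if np.any(cx <= 0):
        raise ValueError("cell densities must be positive for the log fit")
    res = stats.linregress(t, np.log(cx))
    mu_max = float(res.slope + D)
    return GrowthParameters(
        Yxs_max=float("nan"), ms=float("nan"),
        r_squared=float(res.rvalue**2) if len(series) > 2 else 1.0,
        mu_max=mu_max,
    )


def element_balance(
    pairs: Sequence[Tuple[ChemostatRecord, RatesResult]],
) -> Tuple[Optional[float], Optional[float]]:
    """Average carbon and nitrogen mass fractions of the biomass.

    Carbon: (glucose carbon inflow - CO2 carbon outflow) per Rx, averaged
    over records.  Nitrogen: consumed ammonium nitrogen per Cx, averaged.
    Either fraction is None when the needed measurements are absent.
    """
    carbon: List[float] = []
    nitrogen: List[float] = []
    for record, rates in pairs:
        if rates.Rx <= 0:
            raise ValueError("record with zero biomass production rate")
        if rates.Rco2 > 0 or record.co2_offgas_fraction > 0:
            c_in = rates.Rglc / M_GLC * 6.0 * M_C          # gC/L/h from glucose
            c_out = rates.Rco2 / M_CO2 * M_C               # gC/L/h as CO2
            carbon.append((c_in - c_out) / rates.Rx)
        if record.NH4_feed is not None and record.NH4_residual is not None:
            nitrogen.append((record.NH4_feed - record.NH4_residual) / rates.Cx)
    return (
        float(np.mean(carbon)) if carbon else None,
        float(np.mean(nitrogen)) if nitrogen else None,
    )


_RECORD_FIELDS = [f for f in ChemostatRecord.__dataclass_fields__]


def records_from_tsv(path) -> List[ChemostatRecord]:
    """Read chemostat steady states from a TSV, one row per steady state."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _RECORD_FIELDS:
            if name in df.columns and not pd.isna(row[name]):
                kwargs[name] = float(row[name])
        records.append(ChemostatRecord(**kwargs))
    return records
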