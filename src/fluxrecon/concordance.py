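"""FVA-distance comparison between predicted flux intervals and measured fluxes.

For each measured reaction with flux f and FVA interval [lo, hi], the
minimal contribution is 0 when f lies inside the interval and otherwise the
squared distance to the nearer endpoint; the maximal contribution is the
squared distance to the farther endpoint.  Summing over reactions yields
the (d_min, d_max) pair — the "FVA-distance".  d_min = 0 iff every
measurement is attainable; a large d_max flags wide, poorly constrained
intervals (futile cycles).  Unbounded intervals contribute infinity to
d_max and are reported explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .model import FVAResult, MetabolicModel, fva

__all__ = [
    "MeasuredFluxSet",
    "FVADistance",
    "fva_distance",
    "constrain_and_compare",
    "measured_fluxes_from_tsv",
]


@dataclass
class MeasuredFluxSet:
    """Measured (e.g. 13C-derived) fluxes keyed by model reaction id."""

    fluxes: Dict[str, float]
    sd: Dict[str, float] = field(default_factory=dict)

    def mapped(self, mapping: Mapping[str, Tuple[str, float]]) -> "MeasuredFluxSet":
        """Re-key by a measurement->model mapping with sign re-orientation.

        ``mapping[measured_id] = (model_reaction_id, sign)``; measurements
        without a mapping entry are dropped but returned for reporting via
        the ``unmapped`` attribute of the result.
        """
        out = MeasuredFluxSet({}, {})
        unmapped: List[str] = []
        for mid, flux in self.fluxes.items():
            if mid in mapping:
                rid, sign = mapping[mid]
                out.fluxes[rid] = sign * flux
                if mid in self.sd:
                    out.sd[rid] = self.sd[mid]
            else:
                unmapped.append(mid)
        out.unmapped = unmapped  # type: ignore[attr-defined]
        return out


@dataclass
class FVADistance:
    d_min: float
    d_max: float
    per_reaction: Dict[str, Tuple[float, float]]
    unbounded: List[str] = field(default_factory=list)


def fva_distance(
    fva_result: FVAResult,
    measured: MeasuredFluxSet,
    sd_weight: bool = False,
) -> FVADistance:
    """The (d_min, d_max) squared-distance pair of measured fluxes vs intervals.

    With ``sd_weight`` each squared distance is divided by the measurement
    variance where available (unit variance otherwise); the default is the
    unnormalized sum.
    """
    missing = [rid for rid in measured.fluxes if rid not in fva_result.intervals]
    if missing:
        raise KeyError(f"no FVA interval for measured reactions {missing}")
    per: Dict[str, Tuple[float, float]] = {}
    unbounded: List[str] = []
    d_min = 0.0
    d_max = 0.0
    for rid, f in measured.fluxes.items():
        lo, hi = fva_result.intervals[rid]
        w = 1.0
        if sd_weight and measured.sd.get(rid):
            w = 1.0 / measured.sd[rid] ** 2
        if math.isinf(lo) or math.isinf(hi):
            contrib_max = math.inf
            unbounded.append(rid)
        else:
            contrib_max = w * max((f - lo) ** 2, (f - hi) ** 2)
        if lo <= f <= hi:
            contrib_min = 0.0
        elif math.isinf(lo) and f < hi:
            contrib_min = 0.0
        elif math.isinf(hi) and f > lo:
            contrib_min = 0.0
        else:
            edge = min(abs(f - lo), abs(f - hi))
            contrib_min = w * edge**2
        per[rid] = (contrib_min, contrib_max)
        d_min += contrib_min
        d_max += contrib_max
    return FVADistance(d_min, d_max, per, unbounded)


def constrain_and_compare(
    model: MetabolicModel,
    reaction: str,
    value: float,
    measured: MeasuredFluxSet,
    objective: Optional[str] = None,
    objective_value: Optional[float] = None,
    sd_weight: bool = False,
) -> Tuple[FVADistance, FVADistance]:
    """FVA-distances before and after pinning one reaction to a measured value.

    The reaction's bounds are fixed to [value, value] (it must lie within the
    original bounds); infeasibility after fixing signals a conflict between
    the measurement and the model and is raised.
    """
    rxn = model.reaction(reaction)
    if not (rxn.lower_bound <= value <= rxn.upper_bound):
        raise ValueError(
            f"value {value} outside bounds of {reaction!r} "
            f"[{rxn.lower_bound}, {rxn.upper_bound}]"
        )
    targets = sorted(set(measured.fluxes) | {reaction})
    before = fva(model, objective, objective_value, reactions=targets)
    constrained = model.with_bounds({reaction: (value, value)})
    after = fva(constrained, objective, before.objective_value, reactions=targets)
    return (
        fva_distance(before, measured, sd_weight),
        fva_distance(after, measured, sd_weight),
    )


def measured_fluxes_from_tsv(path, mapping_path=None) -> MeasuredFluxSet:
    """Read a measured-flux TSV (reaction, flux[, sd]); optionally re-map ids.

    The mapping TSV has columns (measured_id, model_id, sign).
    """
    df = pd.read_csv(path, sep="\t")
    fluxes = dict(zip(df["reaction"], df["flux"].astype(float)))
    sd = {}
    if "sd" in df.columns:
        sd = {
            r: float(s)
            for r, s in zip(df["reaction"], df["sd"])
            if not pd.isna(s)
        }
    ms = MeasuredFluxSet(fluxes, sd)
    if mapping_path is not None:
        mdf = pd.read_csv(mapping_path, sep="\t")
        mapping = {
            row["measured_id"]: (row["model_id"], float(row.get("sign", 1.0)))
            for _, row in mdf.iterrows()
        }
        ms = ms.mapped(mapping)
    return ms
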