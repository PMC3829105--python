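"""Synthetic data generators for every pipeline stage.

All generators are pure functions of (spec, seed): the same inputs give the
same outputs, and sigma = 0 yields noise-free data on which every
downstream estimator is exact.  Defaults encode the study conditions of
the glucose-limited P. putida chemostat campaign (Y_x/s^max = 0.397
gDCW/g, m_s = 0.037 g/gDCW/h, mu_max = 0.59 1/h, 10 mM glucose feed,
0.75 L culture sparged at 0.75 L/min, GAM 85, NGAM 3.96, P:O 1.33,
4 expression arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .biomass import build_study_equation, elemental_composition
from .growth import ChemostatRecord
from .model import MetabolicModel, Metabolite, Reaction, fba
from .omics import ExpressionDataset
from .concordance import MeasuredFluxSet
from .refdata import M_C, M_CO2, M_GLC, R_GAS

__all__ = [
    "ChemostatSimSpec",
    "ToyModelSpec",
    "simulate_chemostat",
    "simulate_washout",
    "toy_model",
    "toy_biomass_precursor_demand",
    "simulate_measured_fluxes",
    "simulate_expression",
]


@dataclass
class ChemostatSimSpec:
    """Generating truth for steady-state chemostat records (Pirt-exact)."""

    yxs_max: float = 0.397        # gDCW/g_glc
    ms: float = 0.037             # g_glc/gDCW/h
    mu_max: float = 0.59          # 1/h
    dilution_rates: Sequence[float] = (0.05, 0.1, 0.15, 0.2, 0.26, 0.32, 0.38, 0.44, 0.5)
    feed_glc_mmol: float = 10.0
    biomass_carbon_fraction: float = 0.488
    od_slope: float = 0.35
    residue: float = 0.356
    direct_dcw_factor: float = 0.35 / 0.399
    gas_flow: float = 0.75        # L/min
    temperature: float = 303.15   # K
    pressure: float = 101325.0    # Pa
    culture_volume: float = 0.75  # L
    sigma: float = 0.0            # multiplicative noise on measured channels
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        bad = [d for d in self.dilution_rates if d >= self.mu_max]
        if bad:
            raise ValueError(
                f"dilution rates {bad} reach mu_max={self.mu_max}: no steady state"
            )


def simulate_chemostat(spec: ChemostatSimSpec) -> List[ChemostatRecord]:
    """Steady-state records obeying q_s = D/Y_x/s^max + m_s exactly at sigma=0.

    Glucose is fully consumed (carbon-limited operation); the off-gas CO2
    fraction closes the carbon balance at the specified biomass carbon
    fraction.  Noise is multiplicative log-normal on the concentration
    channels (OD, direct dry weight, off-gas fraction), keeping them
    positive.
    """
    rng = np.random.default_rng(spec.seed)
    consumed_g = spec.feed_glc_mmol * M_GLC / 1000.0
    gas_mol_per_h = spec.pressure * (spec.gas_flow * 60.0 / 1000.0) / (
        R_GAS * spec.temperature
    )
    records = []
    for D in spec.dilution_rates:
        qs = D / spec.yxs_max + spec.ms
        yxs = D / qs
        cx = yxs * consumed_g
        carbon_in = D * consumed_g * (6.0 * M_C / M_GLC)        # gC/L/h
        carbon_x = spec.biomass_carbon_fraction * D * cx
        rco2 = max(carbon_in - carbon_x, 0.0) / M_C * M_CO2     # g/L/h
        co2_frac = rco2 / M_CO2 * spec.culture_volume / gas_mol_per_h

        def jitter(x: float) -> float:
            if spec.sigma == 0:
                return x
            return x * float(np.exp(spec.sigma * rng.standard_normal()))

        records.append(
            ChemostatRecord(
                D=D,
                OD600=jitter(cx / spec.od_slope),
                Cx_raw=jitter(cx) / spec.direct_dcw_factor + spec.residue,
                Cglc_feed=spec.feed_glc_mmol,
                Cglc_residual=0.0,
                co2_offgas_fraction=jitter(co2_frac),
                gas_flow=spec.gas_flow,
                temperature=spec.temperature,
                pressure=spec.pressure,
            )
        )
    return records


def simulate_washout(
    mu_max: float = 0.59,
    D: float = 1.2,
    cx0: float = 0.7,
    times: Optional[Sequence[float]] = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> List[Tuple[float, float]]:
    """Washout decay series Cx(t) = Cx0 exp((mu_max - D) t), D > mu_max."""
    if D <= mu_max:
        raise ValueError("washout requires D > mu_max")
    if cx0 <= 0:
        raise ValueError("initial density must be positive")
    if times is None:
        times = np.linspace(0.0, 3.0, 10)
    rng = np.random.default_rng(seed)
    series = []
    for t in times:
        cx = cx0 * np.exp((mu_max - D) * t)
        if sigma > 0:
            cx *= float(np.exp(sigma * rng.standard_normal()))
        series.append((float(t), float(cx)))
    return series


# ---------------------------------------------------------------------------
# Toy central-carbon network
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Desk-scale central-carbon network emulating glucose-grown P. putida.

    Glucose enters by an ABC-style transporter, is phosphorylated and split
    by a lumped EMP glycolysis (isozyme pair), oxidized through pyruvate
    dehydrogenase (a two-subunit complex) and a lumped TCA cycle, with a
    respiratory chain translating NADH/FADH2 into ATP at ``p_to_o`` ATP per
    oxygen atom.  An optional periplasmic oxidative branch
    (glucose -> gluconate -> 6-phosphogluconate -> Entner-Doudoroff) mirrors
    the organism's glucose-side oxidation loop.  Biomass consumes g6p at the
    carbon density of the assembled biomass equation plus the GAM ATP
    quartet; NGAM is the lower bound of the ATP drain.
    """

    p_to_o: float = 1.33
    gam: float = 85.0            # mmol ATP/gDCW
    ngam: float = 3.96           # mmol ATP/gDCW/h
    include_gluconate_loop: bool = False
    glucose_uptake_max: float = 10.0

    def __post_init__(self):
        if self.p_to_o < 0:
            raise ValueError("p_to_o must be non-negative")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("gam and ngam must be non-negative")


def toy_biomass_precursor_demand() -> float:
    """mmol g6p per gDCW matching the biomass equation's carbon density.

    The full biomass equation's carbon content (mmol C per g) divided by 6
    carbons per hexose; this lumps all monomer demand into one precursor
    while preserving the carbon balance.
    """
    eq, table = build_study_equation(gam=0.0)
    elems = elemental_composition(eq, table)
    carbon_mmol_per_g = elems["C"] / 100.0 / M_C * 1000.0
    return carbon_mmol_per_g / 6.0


def toy_model(spec: Optional[ToyModelSpec] = None) -> MetabolicModel:
    spec = spec or ToyModelSpec()
    P = spec.p_to_o
    n_g6p = toy_biomass_precursor_demand()

    mets = [
        "glc_e", "glc", "g6p", "pyr", "accoa",
        "co2", "co2_e", "o2", "o2_e", "h2o",
        "atp", "adp", "nadh", "nad", "fadh2", "fad",
    ]
    if spec.include_gluconate_loop:
        mets += ["glcn", "pgc"]

    # energy is carried on the ATP/ADP couple; free phosphate is not
    # tracked at toy scale (it cannot be balanced in lumped glycolysis
    # without re-introducing every phosphorylated intermediate)
    biomass_stoich = {"g6p": -n_g6p}
    if spec.gam > 0:
        biomass_stoich.update(
            {"atp": -spec.gam, "h2o": -spec.gam, "adp": spec.gam}
        )

    reactions = [
        Reaction("EX_glc", {"glc_e": -1.0}, -spec.glucose_uptake_max, 0.0),
        Reaction("EX_o2", {"o2_e": -1.0}, -1000.0, 0.0),
        Reaction("EX_co2", {"co2_e": -1.0}, 0.0, 1000.0),
        Reaction("EX_h2o", {"h2o": -1.0}, -1000.0, 1000.0),
        Reaction("GLCt", {"glc_e": -1.0, "glc": 1.0}, 0.0, 1000.0,
                 gpr="gGTS1 and gGTS2"),
        Reaction("O2t", {"o2_e": -1.0, "o2": 1.0}, 0.0, 1000.0),
        Reaction("CO2t", {"co2": -1.0, "co2_e": 1.0}, 0.0, 1000.0),
        Reaction("HEX", {"glc": -1.0, "atp": -1.0, "g6p": 1.0, "adp": 1.0},
                 0.0, 1000.0, gpr="gHEX"),
        Reaction(
            "EMP",
            {"g6p": -1.0, "adp": -3.0, "nad": -2.0,
             "pyr": 2.0, "atp": 3.0, "nadh": 2.0},
            0.0, 1000.0, gpr="gEMP1 or gEMP2",
        ),
        Reaction(
            "PDH",
            {"pyr": -1.0, "nad": -1.0, "accoa": 1.0, "co2": 1.0, "nadh": 1.0},
            0.0, 1000.0, gpr="gPDH1 and gPDH2",
        ),
        Reaction(
            "TCA",
            {"accoa": -1.0, "nad": -3.0, "fad": -1.0, "adp": -1.0,
             "co2": 2.0, "nadh": 3.0, "fadh2": 1.0, "atp": 1.0},
            0.0, 1000.0, gpr="gTCA",
        ),
        Reaction(
            "NADH_DH",
            {"nadh": -1.0, "o2": -0.5, "adp": -P,
             "nad": 1.0, "atp": P, "h2o": 1.0},
            0.0, 1000.0, gpr="gNUO",
        ),
        Reaction(
            "FADH2_DH",
            {"fadh2": -1.0, "o2": -0.5, "adp": -P,
             "fad": 1.0, "atp": P, "h2o": 1.0},
            0.0, 1000.0, gpr="gSDH",
        ),
        Reaction("ATPM", {"atp": -1.0, "h2o": -1.0, "adp": 1.0},
                 spec.ngam, 1000.0),
        Reaction("BIOMASS", biomass_stoich, 0.0, 1000.0),
    ]
    if spec.include_gluconate_loop:
        reactions += [
            Reaction("GCD", {"glc": -1.0, "fad": -1.0, "glcn": 1.0, "fadh2": 1.0},
                     0.0, 1000.0, gpr="gGCD"),
            Reaction("GNK", {"glcn": -1.0, "atp": -1.0, "pgc": 1.0, "adp": 1.0},
                     0.0, 1000.0, gpr="gGNK"),
            Reaction(
                "ED",
                {"pgc": -1.0, "adp": -2.0, "nad": -1.0,
                 "pyr": 2.0, "atp": 2.0, "nadh": 1.0},
                0.0, 1000.0, gpr="gED",
            ),
        ]

    model = MetabolicModel(
        reactions=reactions,
        metabolites=[Metabolite(m) for m in mets],
        objective_reaction="BIOMASS",
        atp_maintenance_reaction="ATPM",
        id="toy_putida",
    )
    return model


def toy_max_yield(gam: float, p_to_o: float, m_glc: float = M_GLC) -> float:
    """Closed-form maximal yield of the toy network (gDCW/g_glc).

    Per gram of biomass, n mmol of glucose become g6p (costing n ATP at the
    hexokinase) and the remaining ATP demand gam + n is met by fully
    oxidizing y glucose at 4 + 12 p_to_o ATP each:

        Y = 1000 / (M_glc * (n + (n + gam) / (4 + 12 p_to_o)))
    """
    n = toy_biomass_precursor_demand()
    a = 4.0 + 12.0 * p_to_o
    return 1000.0 / (m_glc * (n + (n + gam) / a))


# ---------------------------------------------------------------------------
# Measured fluxes and expression arrays
# ---------------------------------------------------------------------------

#: Reactions regarded as the measurable central-metabolism set of the toy.
TOY_CENTRAL_REACTIONS = ("HEX", "EMP", "PDH", "TCA", "NADH_DH", "FADH2_DH")


def simulate_measured_fluxes(
    model: MetabolicModel,
    mu: float = 0.2,
    sigma: float = 0.0,
    seed: int = 0,
    reactions: Optional[Sequence[str]] = None,
) -> MeasuredFluxSet:
    """Emulate a 13C-derived flux set at fixed growth rate.

    Picks the minimal-glucose-uptake FBA solution at biomass flux ``mu``,
    keeps the central-metabolism subset, and perturbs each flux with
    additive Gaussian noise of SD ``sigma``.
    """
    rng = np.random.default_rng(seed)
    sol = fba(model, "EX_glc", "max",
              fixed_fluxes={model.objective_reaction: mu})
    if sol.status != "optimal":
        raise RuntimeError(f"condition mu={mu} infeasible: {sol.status}")
    known = set(r.id for r in model.reactions)
    chosen = [r for r in (reactions or TOY_CENTRAL_REACTIONS) if r in known]
    fluxes = {
        rid: sol.fluxes[rid] + (sigma * float(rng.standard_normal()) if sigma else 0.0)
        for rid in chosen
    }
    sd = {rid: sigma for rid in chosen} if sigma else {}
    return MeasuredFluxSet(fluxes, sd)


def simulate_expression(
    model: MetabolicModel,
    planted_absent: Iterable[str] = (),
    planted_high: Iterable[str] = (),
    seed: int = 0,
    n_arrays: int = 4,
) -> ExpressionDataset:
    """Four-array expression data with planted signal genes.

    Background genes: log2 ~ Normal(9, 0.5), all calls P.  Planted
    "not expressed" genes: log2 ~ Normal(6.5, 0.3), all calls A.  Planted
    high-expression genes: log2 ~ Normal(11, 0.3), calls P (their flux
    behaviour, not their expression, makes them discordant).
    """
    rng = np.random.default_rng(seed)
    absent = set(planted_absent)
    high = set(planted_high)
    genes = model.genes
    unknown = (absent | high) - genes
    if unknown:
        raise ValueError(f"planted genes not in model: {sorted(unknown)}")
    if absent & high:
        raise ValueError("planted sets must be disjoint")
    log2: Dict[str, List[float]] = {}
    calls: Dict[str, List[str]] = {}
    for gene in sorted(genes):
        if gene in absent:
            mean, sd, call = 6.5, 0.3, "A"
        elif gene in high:
            mean, sd, call = 11.0, 0.3, "P"
        else:
            mean, sd, call = 9.0, 0.5, "P"
        log2[gene] = [float(mean + sd * rng.standard_normal()) for _ in range(n_arrays)]
        calls[gene] = [call] * n_arrays
    return ExpressionDataset(log2, calls, n_arrays)
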