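"""Model representation, FBA/FVA correctness, deletions, maintenance."""

import json

import numpy as np
import pytest

from fluxrecon.model import (
    BALANCE_TOL,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    delete_genes,
    essential_genes,
    fba,
    fva,
    load_model,
    save_model,
    set_maintenance,
)
from fluxrecon.synth import ToyModelSpec, toy_model


# -- structure ---------------------------------------------------------

def test_bound_inversion_rejected():
    with pytest.raises(ModelValidationError):
        Reaction("r", {"a": -1.0}, lower_bound=1.0, upper_bound=-1.0)


def test_unknown_metabolite_rejected():
    with pytest.raises(ModelValidationError):
        MetabolicModel(
            reactions=[Reaction("r", {"ghost": -1.0}, 0, 1)],
            metabolites=[Metabolite("a")],
            objective_reaction="r",
        )


def test_duplicate_ids_rejected():
    with pytest.raises(ModelValidationError):
        MetabolicModel(
            reactions=[
                Reaction("r", {"a": -1.0}, 0, 1),
                Reaction("r", {"a": 1.0}, 0, 1),
            ],
            metabolites=[Metabolite("a")],
            objective_reaction="r",
        )


def test_json_roundtrip(tmp_path, toy):
    path = tmp_path / "toy.json"
    save_model(toy, path)
    again = load_model(path)
    assert [r.id for r in again.reactions] == [r.id for r in toy.reactions]
    assert np.allclose(again.stoichiometric_matrix(), toy.stoichiometric_matrix())
    assert again.objective_reaction == toy.objective_reaction
    assert again.atp_maintenance_reaction == toy.atp_maintenance_reaction


def test_json_bound_inversion_raises(tmp_path):
    bad = {
        "metabolites": [{"id": "a"}],
        "reactions": [
            {"id": "r", "stoichiometry": {"a": -1}, "lower_bound": 5, "upper_bound": 1}
        ],
        "objective": "r",
    }
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(bad))
    with pytest.raises(ModelValidationError):
        load_model(path)


def test_sbml_roundtrip(tmp_path, toy):
    from fluxrecon.gpr import parse_gpr

    path = tmp_path / "toy.xml"
    save_model(toy, path, "sbml")
    again = load_model(path, "sbml")
    assert [r.id for r in again.reactions] == [r.id for r in toy.reactions]
    assert np.allclose(again.stoichiometric_matrix(), toy.stoichiometric_matrix())
    for a, b in zip(toy.reactions, again.reactions):
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert parse_gpr(a.gpr) == parse_gpr(b.gpr)
    assert again.atp_maintenance_reaction == "ATPM"
    assert again.objective_reaction == "BIOMASS"


# -- FBA ---------------------------------------------------------------

def test_fba_chain_closed_form(chain_model):
    sol = fba(chain_model, "BIOMASS", "max")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(1.0, abs=1e-9)


def test_fba_chain_min_uptake_at_fixed_biomass(chain_model):
    sol = fba(chain_model, "EX_A", "max", fixed_fluxes={"BIOMASS": 0.2})
    assert sol.status == "optimal"
    assert -sol.objective_value == pytest.approx(2.0, abs=1e-9)
    assert sol.fluxes["BIOMASS"] == pytest.approx(0.2, abs=1e-9)


def test_fba_infeasible_above_maximum(chain_model):
    sol = fba(chain_model, "EX_A", "min", fixed_fluxes={"BIOMASS": 2.0})
    assert sol.status == "infeasible"


def test_fba_mass_balance_and_bounds(toy):
    sol = fba(toy, "BIOMASS", "max")
    assert sol.status == "optimal"
    S = toy.stoichiometric_matrix()
    v = np.array([sol.fluxes[r.id] for r in toy.reactions])
    assert np.max(np.abs(S @ v)) <= BALANCE_TOL
    for rxn in toy.reactions:
        assert rxn.lower_bound - BALANCE_TOL <= sol.fluxes[rxn.id]
        assert sol.fluxes[rxn.id] <= rxn.upper_bound + BALANCE_TOL


def test_fba_reciprocal_yield_relation(toy):
    """Minimizing uptake at fixed growth and maximizing growth at the
    resulting uptake give consistent yields."""
    mu = 0.2
    sol = fba(toy, "EX_glc", "max", fixed_fluxes={"BIOMASS": mu})
    uptake = sol.objective_value
    back = fba(toy, "BIOMASS", "max", fixed_fluxes={"EX_glc": uptake})
    assert back.objective_value == pytest.approx(mu, abs=1e-6)


# -- FVA ---------------------------------------------------------------

def test_fva_parallel_routes(parallel_model):
    result = fva(parallel_model, "DM_A", 10.0)
    assert result["T1"] == pytest.approx((0.0, 10.0), abs=1e-6)
    assert result["T2"] == pytest.approx((0.0, 10.0), abs=1e-6)


def test_fva_blocked_reaction_interval_is_zero(parallel_model):
    result = fva(parallel_model, "DM_A", 10.0)
    assert result["DEAD"] == pytest.approx((0.0, 0.0), abs=1e-9)


def test_fva_contains_optimal_fluxes(toy):
    sol = fba(toy, "BIOMASS", "max")
    result = fva(toy, "BIOMASS", sol.objective_value)
    for rid, flux in sol.fluxes.items():
        lo, hi = result[rid]
        assert lo - 1e-6 <= flux <= hi + 1e-6


def test_fva_contains_sampled_vertices(toy_loop):
    """Random-objective LP vertices at the fixed growth rate all fall inside
    the FVA intervals (brute-force containment oracle)."""
    from scipy.optimize import linprog

    mu = 0.2
    constrained = toy_loop.with_bounds({"BIOMASS": (mu, mu)})
    result = fva(constrained, "BIOMASS", mu)
    S = constrained.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in constrained.reactions]
    rng = np.random.default_rng(7)
    for _ in range(30):
        c = rng.normal(size=len(constrained.reactions))
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        assert res.status == 0
        for j, rxn in enumerate(constrained.reactions):
            lo, hi = result[rxn.id]
            assert lo - 1e-6 <= res.x[j] <= hi + 1e-6


def test_fva_nesting_under_tightened_bound(toy_loop):
    mu = 0.2
    base = toy_loop.with_bounds({"BIOMASS": (mu, mu)})
    outer = fva(base, "BIOMASS", mu)
    lo, hi = outer["GCD"]
    tightened = base.with_bounds({"GCD": (lo, lo + 0.25 * (hi - lo))})
    inner = fva(tightened, "BIOMASS", mu)
    for rid in outer.intervals:
        assert inner[rid][0] >= outer[rid][0] - 1e-6
        assert inner[rid][1] <= outer[rid][1] + 1e-6


def test_fva_infeasible_objective_value(chain_model):
    with pytest.raises(RuntimeError):
        fva(chain_model, "BIOMASS", 5.0)


# -- deletions ---------------------------------------------------------

def test_single_gene_knockout_blocks_reaction(toy):
    ko = delete_genes(toy, {"gHEX"})
    assert ko.reaction("HEX").upper_bound == 0.0
    # without glycolysis the NGAM demand cannot be met: either no growth or
    # outright infeasibility, never silent success
    sol = fba(ko, "BIOMASS", "max")
    assert sol.status == "infeasible" or sol.objective_value < 1e-9


def test_isozyme_pair_survives_single_deletion(toy):
    for gene in ("gEMP1", "gEMP2"):
        ko = delete_genes(toy, {gene})
        assert ko.reaction("EMP").upper_bound > 0
        assert fba(ko, "BIOMASS", "max").objective_value > 0.01


def test_spontaneous_reactions_unaffected(toy):
    ko = delete_genes(toy, set(toy.genes))
    assert ko.reaction("EX_glc").lower_bound == toy.reaction("EX_glc").lower_bound
    assert ko.reaction("ATPM").upper_bound > 0


def _brute_force_essentials(model, threshold=0.01):
    """Independent oracle: re-solve per gene with reactions disabled by a
    hand-rolled boolean evaluation of the rule string."""
    wt = fba(model, model.objective_reaction, "max").objective_value

    def rule_active(rule, gone):
        if not rule.strip():
            return True
        py = rule
        for gene in sorted(model.genes, key=len, reverse=True):
            py = py.replace(gene, str(gene not in gone))
        return bool(eval(py.replace("AND", "and").replace("OR", "or")))

    out = set()
    for gene in model.genes:
        bounds = {
            r.id: (0.0, 0.0)
            for r in model.reactions
            if not rule_active(r.gpr, {gene})
        }
        ko = model.with_bounds(bounds)
        sol = fba(ko, model.objective_reaction, "max")
        growth = sol.objective_value if sol.status == "optimal" else 0.0
        if growth < threshold * wt:
            out.add(gene)
    return out


@pytest.mark.parametrize("loop", [False, True])
def test_essential_genes_match_brute_force(loop):
    model = toy_model(ToyModelSpec(include_gluconate_loop=loop))
    assert essential_genes(model) == _brute_force_essentials(model)


def test_essentials_expected_set(toy):
    assert essential_genes(toy) == {
        "gGTS1", "gGTS2", "gHEX", "gNUO", "gPDH1", "gPDH2", "gSDH", "gTCA"
    }


def test_essential_requires_growing_wild_type(toy):
    dead = toy.with_bounds({"EX_glc": (0.0, 0.0)})
    with pytest.raises(RuntimeError):
        essential_genes(dead)


# -- maintenance injection ---------------------------------------------

def test_ngam_forces_maintenance_flux(toy_bare):
    model = set_maintenance(toy_bare, gam=0.0, ngam=3.96)
    sol = fba(model, "BIOMASS", "max")
    assert sol.status == "optimal"
    assert sol.fluxes["ATPM"] >= 3.96 - 1e-9


def test_zero_maintenance_increases_yield(toy_bare):
    lean = fba(toy_bare, "BIOMASS", "max").objective_value
    burdened = fba(set_maintenance(toy_bare, 85.0, 3.96), "BIOMASS", "max").objective_value
    assert lean > burdened


def test_doubling_gam_increases_glucose_demand(toy_bare):
    mu = 0.2

    def min_uptake(gam):
        model = set_maintenance(toy_bare, gam, 0.0)
        sol = fba(model, "EX_glc", "max", fixed_fluxes={"BIOMASS": mu})
        return -sol.objective_value

    assert min_uptake(100.0) > min_uptake(50.0)


def test_negative_maintenance_rejected(toy):
    with pytest.raises(ValueError):
        set_maintenance(toy, -1.0, 0.0)


# -- independent oracle: cobra ------------------------------------------

def test_fba_agrees_with_cobra(toy):
    """Cross-check the LP layer against cobrapy on the same network."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("toy")
    cm.add_metabolites([cobra.Metabolite(m.id) for m in toy.metabolites])
    rxns = []
    for r in toy.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in toy.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
    cm.objective = "BIOMASS"
    ours = fba(toy, "BIOMASS", "max").objective_value
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-6)
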