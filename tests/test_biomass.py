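"""Biomass-equation construction: composition closure, coefficients,
mass and elemental accounting."""

import pytest

from fluxrecon.biomass import (
    AminoAcidProfile,
    PEPTIDOGLYCAN_SHARE,
    assemble_composition,
    build_study_equation,
    carbohydrate_coefficients,
    cofactor_coefficients,
    dna_composition_from_gc,
    elemental_composition,
    fill_in_profile,
    finalize_equation,
    lipid_coefficients,
    nucleic_acid_coefficients,
    peptidoglycan_coefficients,
    protein_coefficients,
)
from fluxrecon.refdata import (
    PEPTIDOGLYCAN_RESIDUE,
    default_monomer_table,
    formula_mass,
)


# -- composition assembly ----------------------------------------------

def test_remainder_policy_assigns_cofactor_pool():
    comp = assemble_composition(
        {"soluble_protein": 0.40, "lipid": 0.08, "carbohydrate": 0.02,
         "rna": 0.20, "dna": 0.02},
        add_insoluble_protein=True, policy="remainder",
    )
    assert comp.protein == pytest.approx(0.522)
    assert comp.peptidoglycan == pytest.approx(0.086)
    assert comp.cofactor_pool == pytest.approx(1.0 - 0.522 - 0.08 - 0.02 - 0.20
                                               - 0.02 - 0.086)
    assert sum(comp.as_dict().values()) == pytest.approx(1.0, abs=1e-12)


def test_remainder_policy_rejects_overfull():
    with pytest.raises(ValueError):
        assemble_composition(
            {"soluble_protein": 0.70, "lipid": 0.2, "carbohydrate": 0.1,
             "rna": 0.05, "dna": 0.0},
            policy="remainder",
        )


def test_single_fraction_passthrough():
    comp = assemble_composition(
        {"carbohydrate": 1.0},
        add_insoluble_protein=False, peptidoglycan=0.0, cofactor_share=0.0,
        policy="remainder",
    )
    assert comp.carbohydrate == pytest.approx(1.0)
    assert comp.cofactor_pool == pytest.approx(0.0)


def test_pinned_policy_keeps_peptidoglycan_share():
    comp = assemble_composition()  # study defaults: measured fractions > 1
    assert comp.peptidoglycan == pytest.approx(PEPTIDOGLYCAN_SHARE, abs=1e-12)
    assert sum(comp.as_dict().values()) == pytest.approx(1.0, abs=1e-12)
    # measured fractions keep their ratios
    assert comp.rna / comp.dna == pytest.approx(0.226 / 0.022, rel=1e-9)


def test_negative_fraction_rejected():
    with pytest.raises(ValueError):
        assemble_composition({"soluble_protein": -0.1})


# -- proteins ----------------------------------------------------------

def test_protein_single_glycine_closed_form():
    profile = AminoAcidProfile({"gly": 100.0})
    coefs = protein_coefficients(profile, 0.5705)
    # residue mass of glycine is 57.052 g/mol
    assert coefs["gly"] == pytest.approx(0.5705 * 1000.0 / 57.052, rel=1e-9)
    assert coefs["gly"] == pytest.approx(10.0, rel=1e-3)


def test_protein_mass_recovers_fraction():
    profile = fill_in_profile()
    coefs = protein_coefficients(profile, 0.55)
    table = default_monomer_table()
    mass = sum(c * formula_mass(table[aa]) / 1000.0 for aa, c in coefs.items())
    assert mass == pytest.approx(0.55, abs=1e-12)


def test_protein_zero_fraction():
    coefs = protein_coefficients(AminoAcidProfile({"ala": 100.0}), 0.0)
    assert all(c == 0.0 for c in coefs.values())


def test_fill_in_idempotent():
    once = fill_in_profile()
    twice = fill_in_profile(once)
    for aa in once.molpct:
        assert once.molpct[aa] == pytest.approx(twice.molpct[aa], abs=1e-12)
    assert sum(once.molpct.values()) == pytest.approx(100.0, abs=1e-9)
    assert {"cys", "met", "trp"} <= once.filled_in


# -- nucleic acids -----------------------------------------------------

def test_dna_gc_half_is_equimolar():
    comp = dna_composition_from_gc(0.5)
    assert all(v == pytest.approx(0.25) for v in comp.values())


def test_dna_mass_sum_matches_fraction():
    coefs = nucleic_acid_coefficients("dna", 0.022)
    table = default_monomer_table()
    mass = sum(c * formula_mass(table[m]) / 1000.0 for m, c in coefs.items())
    assert mass == pytest.approx(0.022, abs=1e-12)


def test_rna_zero_fraction_empty_contribution():
    coefs = nucleic_acid_coefficients("rna", 0.0)
    assert all(c == 0.0 for c in coefs.values())


def test_bad_base_composition_rejected():
    with pytest.raises(ValueError):
        nucleic_acid_coefficients("dna", 0.02, {"damp": 0.6, "dtmp": 0.6})


# -- lipids ------------------------------------------------------------

def test_lipid_single_species_closed_form():
    coefs, formulas = lipid_coefficients(
        0.05,
        head_groups={"pe": 1.0},
        fatty_acids={"c16:0": 1.0},
        lps_share=0.0,
    )
    # dipalmitoyl-PE: core C5H14NO6P + 2 x C16H30O acyl residues
    species_mass = formula_mass(formulas["pe"])
    assert species_mass == pytest.approx(215.144 + 2 * 238.409, abs=0.05)
    assert coefs["pe"] == pytest.approx(0.05 * 1000.0 / species_mass, rel=1e-9)


def test_lipid_headgroup_ordering():
    coefs, _ = lipid_coefficients(0.084)
    assert coefs["cl"] < coefs["pe"]  # cardiolipin minor vs PE dominant


def test_lipid_all_lps():
    coefs, _ = lipid_coefficients(0.03, lps_share=0.03)
    assert coefs["pe"] == coefs["cl"] == coefs["pg"] == 0.0
    assert coefs["lps"] > 0


def test_lipid_bad_fraction_sums():
    with pytest.raises(ValueError):
        lipid_coefficients(0.05, head_groups={"pe": 0.5, "pg": 0.2})


# -- finalize ----------------------------------------------------------

def test_full_equation_mass_closure():
    eq, table = build_study_equation(gam=0.0)
    assert eq.net_consumed_mass(table) == pytest.approx(1.0, abs=1e-6)


def test_gam_term_written():
    eq, _ = build_study_equation(gam=85.0)
    assert eq.consumed["atp"] == pytest.approx(85.0)
    assert eq.consumed["h2o"] == pytest.approx(85.0)
    assert eq.produced["adp"] == pytest.approx(85.0)
    assert eq.produced["pi"] == pytest.approx(85.0)
    assert eq.gam_atp == 85.0


def test_gam_is_mass_neutral():
    eq0, t0 = build_study_equation(gam=0.0)
    eq85, t85 = build_study_equation(gam=85.0)
    assert eq0.net_consumed_mass(t0) == pytest.approx(
        eq85.net_consumed_mass(t85), abs=1e-9
    )


def test_tampered_coefficients_fail_mass_check():
    eq, table = build_study_equation(gam=0.0)
    doubled = {m: 2 * c for m, c in eq.consumed.items()}
    with pytest.raises(ValueError):
        finalize_equation([doubled], gam=0.0, monomers=table)


def test_peptidoglycan_share_of_assembled_mass():
    eq, table = build_study_equation(gam=0.0)
    mass = eq.consumed["peptidoglycan"] * formula_mass(PEPTIDOGLYCAN_RESIDUE) / 1000.0
    assert mass == pytest.approx(0.086, abs=1e-9)


def test_macromolecule_linearity():
    """Scaling one class fraction scales its coefficients exactly."""
    base = carbohydrate_coefficients(0.02)
    scaled = carbohydrate_coefficients(0.05)
    assert scaled["glycogen"] == pytest.approx(base["glycogen"] * 2.5, rel=1e-12)


# -- elemental composition ---------------------------------------------

def test_glycogen_only_biomass_elements():
    eq = finalize_equation([carbohydrate_coefficients(1.0)], gam=0.0)
    elems = elemental_composition(eq)
    assert elems["C"] == pytest.approx(100 * 6 * 12.011 / 162.141, abs=0.05)
    assert elems["H"] == pytest.approx(100 * 10 * 1.008 / 162.141, abs=0.05)
    assert elems["O"] == pytest.approx(100 * 5 * 15.999 / 162.141, abs=0.05)
    assert elems.total() == pytest.approx(100.0, abs=1e-6)


def test_pure_glycine_protein_nitrogen():
    eq = finalize_equation(
        [protein_coefficients(AminoAcidProfile({"gly": 100.0}), 1.0)], gam=0.0
    )
    elems = elemental_composition(eq)
    assert elems["N"] == pytest.approx(100 * 14.007 / 57.052, abs=0.05)


def test_study_equation_elemental_bracket():
    eq, table = build_study_equation(gam=0.0)
    elems = elemental_composition(eq, table)
    assert elems.total() <= 100.0 + 1e-6
    assert 45.0 <= elems["C"] <= 52.0


def test_elements_invariant_to_species_split():
    """Splitting glycogen into two stoichiometrically equivalent halves
    leaves the elemental composition unchanged."""
    whole = finalize_equation([carbohydrate_coefficients(1.0)], gam=0.0)
    half = carbohydrate_coefficients(0.5)["glycogen"]
    from fluxrecon.refdata import GLYCOGEN_RESIDUE

    split_eq = finalize_equation(
        [{"glycogen": half, "glycogen2": half}],
        gam=0.0,
        monomers={"glycogen2": GLYCOGEN_RESIDUE},
    )
    a = elemental_composition(whole)
    b = elemental_composition(split_eq, {"glycogen2": GLYCOGEN_RESIDUE})
    for el in a.fractions:
        assert a[el] == pytest.approx(b[el], abs=1e-9)
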