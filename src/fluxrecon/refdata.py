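"""Reference data for biomass-equation construction.

Everything in this module is *reference-derived* background data (standard
residue formulas, literature compositions used to fill gaps in the measured
tables), not measurements of this study.  Each block notes its provenance
class so users can swap their own values.

Residue masses are never stored: they are always computed from the elemental
formula, which guarantees formula/mass consistency by construction.
"""

from __future__ import annotations

from typing import Dict, Mapping

#: Standard atomic weights (IUPAC 2021, rounded), g/mol.
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: Glucose molar mass, g/mol (configurable at call sites).
M_GLC = 180.16
#: CO2 molar mass, g/mol.
M_CO2 = 44.009
#: Carbon molar mass, g/mol.
M_C = ATOMIC_MASS["C"]
#: Ideal gas constant, J/(mol K).
R_GAS = 8.314462

Formula = Mapping[str, float]


def formula_mass(formula: Formula) -> float:
    """Molar mass (g/mol) of an elemental formula.

    Fractional atom counts are allowed: averaged species (e.g. the mean
    phospholipid assembled from fatty-acid mol fractions) carry non-integer
    formulas.
    """
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guard
        raise ValueError(f"unknown element in formula: {exc}") from None


def atomic_mass_of(element: str) -> float:
    try:
        return ATOMIC_MASS[element]
    except KeyError:
        raise ValueError(f"unknown element {element!r}") from None


def combine_formulas(*parts: tuple[float, Formula]) -> Dict[str, float]:
    """Weighted sum of formulas: combine_formulas((2, {"C":16}), ...)."""
    out: Dict[str, float] = {}
    for weight, formula in parts:
        for el, n in formula.items():
            out[el] = out.get(el, 0.0) + weight * n
    return {el: n for el, n in out.items() if abs(n) > 1e-12}


# ---------------------------------------------------------------------------
# Amino-acid residues (peptide-bonded, i.e. free amino acid minus H2O).
# Standard biochemistry reference data.
# ---------------------------------------------------------------------------
AMINO_ACID_RESIDUES: Dict[str, Dict[str, float]] = {
    "ala": {"C": 3, "H": 5, "N": 1, "O": 1},
    "arg": {"C": 6, "H": 12, "N": 4, "O": 1},
    "asn": {"C": 4, "H": 6, "N": 2, "O": 2},
    "asp": {"C": 4, "H": 5, "N": 1, "O": 3},
    "cys": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "gln": {"C": 5, "H": 8, "N": 2, "O": 2},
    "glu": {"C": 5, "H": 7, "N": 1, "O": 3},
    "gly": {"C": 2, "H": 3, "N": 1, "O": 1},
    "his": {"C": 6, "H": 7, "N": 3, "O": 1},
    "ile": {"C": 6, "H": 11, "N": 1, "O": 1},
    "leu": {"C": 6, "H": 11, "N": 1, "O": 1},
    "lys": {"C": 6, "H": 12, "N": 2, "O": 1},
    "met": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "phe": {"C": 9, "H": 9, "N": 1, "O": 1},
    "pro": {"C": 5, "H": 7, "N": 1, "O": 1},
    "ser": {"C": 3, "H": 5, "N": 1, "O": 2},
    "thr": {"C": 4, "H": 7, "N": 1, "O": 2},
    "trp": {"C": 11, "H": 10, "N": 2, "O": 1},
    "tyr": {"C": 9, "H": 9, "N": 1, "O": 2},
    "val": {"C": 5, "H": 9, "N": 1, "O": 1},
}

#: E. coli biomass amino-acid mol% used to fill in residues the ninhydrin
#: assay cannot quantify (Cys, Met, Trp).  Reference-derived (E. coli
#: genome-scale biomass composition), not measured here.
ECOLI_FILLIN_MOLPCT: Dict[str, float] = {"cys": 1.7, "met": 2.9, "trp": 1.1}

#: Measured amino-acid mol% of P. putida KT2440 protein at D = 0.2 1/h
#: (ninhydrin assay; Asx/Glx are the acid+amide pools).  Sums to 99 as
#: printed; renormalized downstream after the Cys/Met/Trp fill-in.
MEASURED_AA_MOLPCT: Dict[str, float] = {
    "ala": 12.0,
    "arg": 5.0,
    "asx": 10.0,
    "glx": 12.0,
    "gly": 10.0,
    "his": 2.0,
    "ile": 4.0,
    "leu": 10.0,
    "lys": 5.0,
    "phe": 4.0,
    "pro": 5.0,
    "ser": 5.0,
    "thr": 5.0,
    "tyr": 3.0,
    "val": 7.0,
}

# ---------------------------------------------------------------------------
# Nucleotide monophosphate residues (polymer-bonded, NMP minus H2O).
# ---------------------------------------------------------------------------
DNA_RESIDUES: Dict[str, Dict[str, float]] = {
    "damp": {"C": 10, "H": 12, "N": 5, "O": 5, "P": 1},
    "dtmp": {"C": 10, "H": 13, "N": 2, "O": 7, "P": 1},
    "dgmp": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},
    "dcmp": {"C": 9, "H": 12, "N": 3, "O": 6, "P": 1},
}

RNA_RESIDUES: Dict[str, Dict[str, float]] = {
    "amp": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},
    "ump": {"C": 9, "H": 11, "N": 2, "O": 8, "P": 1},
    "gmp": {"C": 10, "H": 12, "N": 5, "O": 7, "P": 1},
    "cmp": {"C": 9, "H": 12, "N": 3, "O": 7, "P": 1},
}

#: E. coli RNA base composition at D = 0.6 1/h (mol fractions; rRNA
#: dominated).  Reference-derived stand-in mirroring the source the study
#: borrowed from; editable.
ECOLI_RNA_COMPOSITION: Dict[str, float] = {
    "amp": 0.26,
    "ump": 0.21,
    "gmp": 0.32,
    "cmp": 0.21,
}

#: Default GC content for the paired-base DNA model.  Genome-derived
#: reference value for the P. putida KT2440 chromosome; a genome FASTA can
#: be supplied instead (see biomass.dna_composition_from_fasta).
DEFAULT_GC_CONTENT = 0.615

# ---------------------------------------------------------------------------
# Lipids.  Phospholipid "cores" are the fully de-acylated backbones
# (glycerophospho-head); species mass = core + n_acyl * mean acyl residue.
# Acyl residue = fatty acid minus H2O (ester bond).
# ---------------------------------------------------------------------------
PHOSPHOLIPID_CORES: Dict[str, Dict[str, object]] = {
    # phosphatidylethanolamine: glycerophosphoethanolamine core, 2 chains
    "pe": {"formula": {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}, "n_acyl": 2},
    # cardiolipin: bis(glycerophospho)glycerol core, 4 chains
    "cl": {"formula": {"C": 9, "H": 22, "O": 13, "P": 2}, "n_acyl": 4},
    # phosphatidylglycerol: glycerophosphoglycerol core, 2 chains
    "pg": {"formula": {"C": 6, "H": 15, "O": 8, "P": 1}, "n_acyl": 2},
}

#: Head-group mol fractions measured for the close relative P. putida S12.
DEFAULT_HEAD_GROUPS: Dict[str, float] = {"pe": 0.737, "cl": 0.213, "pg": 0.049}

ACYL_RESIDUES: Dict[str, Dict[str, float]] = {
    "c12:0": {"C": 12, "H": 22, "O": 1},
    "c16:0": {"C": 16, "H": 30, "O": 1},
    "c16:1": {"C": 16, "H": 28, "O": 1},
    "c18:1": {"C": 18, "H": 32, "O": 1},
}

#: Fatty-acid mol fractions.  Reference-derived approximation of reported
#: P. putida membrane fatty-acid profiles; editable.
DEFAULT_FATTY_ACIDS: Dict[str, float] = {
    "c12:0": 0.10,
    "c16:0": 0.30,
    "c16:1": 0.35,
    "c18:1": 0.25,
}

#: Aggregate lipid A + core-oligosaccharide species (CDP-ethanolamine moiety
#: removed).  Reference-derived approximate formula of the E. coli-type
#: rough LPS used as a stand-in; labelled synthetic.
LPS_AGGREGATE: Dict[str, float] = {"C": 176, "H": 303, "N": 2, "O": 100, "P": 4}

#: LPS share of dry weight (g/gDCW), E. coli-like default.
DEFAULT_LPS_SHARE = 0.034

# ---------------------------------------------------------------------------
# Other polymers and small species.
# ---------------------------------------------------------------------------
#: Glycogen anhydroglucose repeat unit.
GLYCOGEN_RESIDUE: Dict[str, float] = {"C": 6, "H": 10, "O": 5}

#: Peptidoglycan repeat unit: GlcNAc-MurNAc-L-Ala-D-Glu-mDAP-D-Ala,
#: polymer-bonded.  Reference-derived.
PEPTIDOGLYCAN_RESIDUE: Dict[str, float] = {"C": 40, "H": 62, "N": 8, "O": 21}

#: Cofactor pool members.  The mass share of this pool is negligible; what
#: matters downstream is presence (it couples essentiality to cofactor
#: biosynthesis), so a small representative set suffices.
COFACTOR_SPECIES: Dict[str, Dict[str, float]] = {
    "nad": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "coa": {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1},
    "fad": {"C": 27, "H": 33, "N": 9, "O": 15, "P": 2},
    "thf": {"C": 19, "H": 23, "N": 7, "O": 6},
    "pydx5p": {"C": 8, "H": 10, "N": 1, "O": 6, "P": 1},
}

#: Default mass share of the cofactor pool (g/gDCW) under the pinned
#: closure policy.
DEFAULT_COFACTOR_SHARE = 0.005

#: GAM hydrolysis quartet formulas (mass- and element-neutral couple).
ENERGY_SPECIES: Dict[str, Dict[str, float]] = {
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "pi": {"H": 3, "O": 4, "P": 1},
    "h2o": {"H": 2, "O": 1},
}


def default_monomer_table() -> Dict[str, Dict[str, float]]:
    """Formula lookup for every species the biomass builder can emit."""
    table: Dict[str, Dict[str, float]] = {}
    table.update(AMINO_ACID_RESIDUES)
    table.update(DNA_RESIDUES)
    table.update(RNA_RESIDUES)
    table["glycogen"] = dict(GLYCOGEN_RESIDUE)
    table["peptidoglycan"] = dict(PEPTIDOGLYCAN_RESIDUE)
    table["lps"] = dict(LPS_AGGREGATE)
    table.update(COFACTOR_SPECIES)
    table.update(ENERGY_SPECIES)
    return table
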