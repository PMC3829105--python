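"""Biomass-equation construction from macromolecular composition tables.

The biomass pseudo-reaction consumes monomer precursors (amino-acid,
nucleotide, lipid, sugar residues, peptidoglycan, a small cofactor pool)
in proportions that assemble exactly 1 g of dry biomass per unit flux, with
fluxes in mmol/gDCW/h, plus a growth-associated maintenance (GAM) ATP
hydrolysis term.  For each macromolecule class with mass fraction f
(g/gDCW) and monomer mol fractions x_i with residue masses M_i (g/mol),
the coefficient of monomer i is

    c_i = f * 1000 * x_i / sum_j(x_j * M_j)    [mmol/gDCW]

which makes the class's mass contribution sum to f exactly.  Polymerization
energy is not itemized per bond: it is lumped into the single fitted GAM
term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

from . import refdata
from .refdata import (
    ACYL_RESIDUES,
    AMINO_ACID_RESIDUES,
    COFACTOR_SPECIES,
    DEFAULT_COFACTOR_SHARE,
    DEFAULT_FATTY_ACIDS,
    DEFAULT_GC_CONTENT,
    DEFAULT_HEAD_GROUPS,
    DEFAULT_LPS_SHARE,
    DNA_RESIDUES,
    ECOLI_FILLIN_MOLPCT,
    ECOLI_RNA_COMPOSITION,
    ENERGY_SPECIES,
    MEASURED_AA_MOLPCT,
    PHOSPHOLIPID_CORES,
    RNA_RESIDUES,
    atomic_mass_of,
    combine_formulas,
    default_monomer_table,
    formula_mass,
)

__all__ = [
    "MacromolecularComposition",
    "AminoAcidProfile",
    "BiomassEquation",
    "ElementalComposition",
    "assemble_composition",
    "fill_in_profile",
    "protein_coefficients",
    "nucleic_acid_coefficients",
    "dna_composition_from_gc",
    "dna_composition_from_fasta",
    "lipid_coefficients",
    "carbohydrate_coefficients",
    "peptidoglycan_coefficients",
    "cofactor_coefficients",
    "finalize_equation",
    "elemental_composition",
    "build_study_equation",
]

MASS_TOL = 1e-6

#: Default macromolecular mass fractions measured for P. putida KT2440
#: (g/gDCW): water-soluble protein, lipid, carbohydrate, RNA, DNA.
MEASURED_FRACTIONS: Dict[str, float] = {
    "soluble_protein": 0.528,
    "lipid": 0.084,
    "carbohydrate": 0.021,
    "rna": 0.226,
    "dna": 0.022,
}

#: Water-insoluble (membrane) protein increment, percentage points of DCW.
INSOLUBLE_PROTEIN_PP = 0.122
#: Assumed peptidoglycan share of DCW.
PEPTIDOGLYCAN_SHARE = 0.086


@dataclass
class MacromolecularComposition:
    """Mass fractions (g/gDCW) after closure; they sum to 1."""

    protein: float
    lipid: float
    carbohydrate: float
    rna: float
    dna: float
    peptidoglycan: float
    cofactor_pool: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "protein": self.protein,
            "lipid": self.lipid,
            "carbohydrate": self.carbohydrate,
            "rna": self.rna,
            "dna": self.dna,
            "peptidoglycan": self.peptidoglycan,
            "cofactor_pool": self.cofactor_pool,
        }

    def __post_init__(self):
        for name, val in self.as_dict().items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"fraction {name}={val} outside [0, 1]")
        total = sum(self.as_dict().values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")


@dataclass
class AminoAcidProfile:
    """mol% per amino-acid key; 'asx'/'glx' denote unresolved acid+amide pools."""

    molpct: Dict[str, float]
    filled_in: frozenset = frozenset()

    def normalized(self) -> "AminoAcidProfile":
        total = sum(self.molpct.values())
        if total <= 0:
            raise ValueError("empty amino-acid profile")
        return AminoAcidProfile(
            {k: 100.0 * v / total for k, v in self.molpct.items()}, self.filled_in
        )


@dataclass
class BiomassEquation:
    """consumed/produced in mmol per gDCW (unit biomass flux)."""

    consumed: Dict[str, float]
    produced: Dict[str, float]
    gam_atp: float

    def net_consumed_mass(self, monomers: Mapping[str, Mapping[str, float]]) -> float:
        """Net mass drawn from the network per unit flux, in g."""
        mass = 0.0
        for met, coef in self.consumed.items():
            mass += coef * formula_mass(monomers[met]) / 1000.0
        for met, coef in self.produced.items():
            if met == "biomass":
                continue
            mass -= coef * formula_mass(monomers[met]) / 1000.0
        return mass


@dataclass
class ElementalComposition:
    """Mass fractions of tracked elements, % (w/w)."""

    fractions: Dict[str, float]

    def __getitem__(self, el: str) -> float:
        return self.fractions[el]

    def total(self) -> float:
        return sum(self.fractions.values())


# ---------------------------------------------------------------------------
# Composition assembly
# ---------------------------------------------------------------------------

def assemble_composition(
    measured: Optional[Mapping[str, float]] = None,
    *,
    add_insoluble_protein: bool = True,
    insoluble_protein_pp: float = INSOLUBLE_PROTEIN_PP,
    peptidoglycan: float = PEPTIDOGLYCAN_SHARE,
    cofactor_share: float = DEFAULT_COFACTOR_SHARE,
    policy: str = "pinned",
) -> MacromolecularComposition:
    """Close measured mass fractions into a composition summing to 1.

    ``measured`` carries the assayed fractions (soluble_protein, lipid,
    carbohydrate, rna, dna).  The soluble-protein assay misses membrane
    proteins, so ``insoluble_protein_pp`` percentage points are added to the
    protein pool by default; peptidoglycan is not assayed and enters at its
    assumed share.

    Closure policies:

    - ``"remainder"``: keep all fractions as given and assign the remaining
      mass to the cofactor pool; errors if the fractions already exceed 1.
    - ``"proportional"``: rescale every fraction (additions included) to
      sum to 1.
    - ``"pinned"`` (default): peptidoglycan and the cofactor pool keep their
      stated shares; the measured fractions (plus the insoluble-protein
      increment) are rescaled proportionally into the remaining mass.  The
      measured fractions plus additions exceed unity, so a proportional
      step is unavoidable; pinning keeps the assumed peptidoglycan share
      exact.
    """
    measured = dict(MEASURED_FRACTIONS if measured is None else measured)
    for name, val in measured.items():
        if val < 0:
            raise ValueError(f"negative fraction {name}={val}")
    protein = measured.get("soluble_protein", 0.0)
    if add_insoluble_protein:
        protein += insoluble_protein_pp
    core = {
        "protein": protein,
        "lipid": measured.get("lipid", 0.0),
        "carbohydrate": measured.get("carbohydrate", 0.0),
        "rna": measured.get("rna", 0.0),
        "dna": measured.get("dna", 0.0),
    }
    if policy == "remainder":
        total = sum(core.values()) + peptidoglycan
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"fractions sum to {total:.4f} > 1; remainder policy impossible "
                "(use 'proportional' or 'pinned')"
            )
        return MacromolecularComposition(
            **core, peptidoglycan=peptidoglycan, cofactor_pool=1.0 - total
        )
    if policy == "proportional":
        total = sum(core.values()) + peptidoglycan + cofactor_share
        scale = 1.0 / total
        return MacromolecularComposition(
            **{k: v * scale for k, v in core.items()},
            peptidoglycan=peptidoglycan * scale,
            cofactor_pool=cofactor_share * scale,
        )
    if policy == "pinned":
        room = 1.0 - peptidoglycan - cofactor_share
        if room <= 0:
            raise ValueError("pinned shares leave no room for measured fractions")
        total = sum(core.values())
        if total <= 0:
            raise ValueError("no measured mass to scale")
        scale = room / total
        return MacromolecularComposition(
            **{k: v * scale for k, v in core.items()},
            peptidoglycan=peptidoglycan,
            cofactor_pool=cofactor_share,
        )
    raise ValueError(f"unknown closure policy {policy!r}")


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------

def fill_in_profile(
    profile: Optional[AminoAcidProfile] = None,
    fillin: Mapping[str, float] = ECOLI_FILLIN_MOLPCT,
) -> AminoAcidProfile:
    """Insert reference mol% for residues absent from the assay, renormalize.

    Idempotent: residues already present are never overwritten.
    """
    if profile is None:
        profile = AminoAcidProfile(dict(MEASURED_AA_MOLPCT))
    molpct = dict(profile.molpct)
    added = set(profile.filled_in)
    for aa, pct in fillin.items():
        if aa not in molpct:
            molpct[aa] = pct
            added.add(aa)
    return AminoAcidProfile(molpct, frozenset(added)).normalized()


def _split_ambiguous(molpct: Mapping[str, float]) -> Dict[str, float]:
    """Resolve asx/glx pools 50:50 into acid and amide residues."""
    out: Dict[str, float] = {}
    for aa, pct in molpct.items():
        if aa == "asx":
            out["asp"] = out.get("asp", 0.0) + pct / 2.0
            out["asn"] = out.get("asn", 0.0) + pct / 2.0
        elif aa == "glx":
            out["glu"] = out.get("glu", 0.0) + pct / 2.0
            out["gln"] = out.get("gln", 0.0) + pct / 2.0
        else:
            out[aa] = out.get(aa, 0.0) + pct
    return out


def _class_coefficients(fraction: float, molfrac: Mapping[str, float],
                        monomers: Mapping[str, Mapping[str, float]]) -> Dict[str, float]:
    if fraction == 0.0:
        return {k: 0.0 for k in molfrac}
    missing = [k for k in molfrac if k not in monomers]
    if missing:
        raise KeyError(f"monomer table lacks entries for {missing}")
    denom = sum(x * formula_mass(monomers[k]) for k, x in molfrac.items())
    if denom <= 0:
        raise ValueError("degenerate monomer composition")
    return {k: fraction * 1000.0 * x / denom for k, x in molfrac.items()}


def protein_coefficients(
    profile: AminoAcidProfile,
    protein_fraction: float,
    monomers: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Dict[str, float]:
    """mmol/gDCW of each amino-acid residue for the given protein fraction."""
    monomers = monomers or AMINO_ACID_RESIDUES
    molfrac = _split_ambiguous(profile.normalized().molpct)
    return _class_coefficients(protein_fraction, molfrac, monomers)


# ---------------------------------------------------------------------------
# Nucleic acids
# ---------------------------------------------------------------------------

def dna_composition_from_gc(gc: float = DEFAULT_GC_CONTENT) -> Dict[str, float]:
    """Paired-base dNMP mol fractions from a GC content (A=T, G=C)."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("GC content must be in [0, 1]")
    at = 1.0 - gc
    return {"damp": at / 2, "dtmp": at / 2, "dgmp": gc / 2, "dcmp": gc / 2}


def dna_composition_from_fasta(path) -> Dict[str, float]:
    """dNMP mol fractions counted from a genome FASTA (both strands)."""
    from Bio import SeqIO

    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for base in counts:
            counts[base] += seq.count(base)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no A/C/G/T bases found in {path}")
    # double-stranded DNA: count both strands, which pairs A with T and G with C
    a = (counts["A"] + counts["T"]) / (2 * total)
    g = (counts["G"] + counts["C"]) / (2 * total)
    return {"damp": a, "dtmp": a, "dgmp": g, "dcmp": g}


def nucleic_acid_coefficients(
    kind: str,
    fraction: float,
    base_composition: Optional[Mapping[str, float]] = None,
    monomers: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Dict[str, float]:
    """NMP/dNMP residue coefficients for the DNA or RNA fraction."""
    if kind == "dna":
        comp = dict(base_composition or dna_composition_from_gc())
        table = monomers or DNA_RESIDUES
    elif kind == "rna":
        comp = dict(base_composition or ECOLI_RNA_COMPOSITION)
        table = monomers or RNA_RESIDUES
    else:
        raise ValueError("kind must be 'dna' or 'rna'")
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{kind} base fractions sum to {total}, not 1")
    return _class_coefficients(fraction, comp, table)


# ---------------------------------------------------------------------------
# Lipids
# ---------------------------------------------------------------------------

def lipid_coefficients(
    fraction: float,
    head_groups: Optional[Mapping[str, float]] = None,
    fatty_acids: Optional[Mapping[str, float]] = None,
    lps_share: float = DEFAULT_LPS_SHARE,
) -> Tuple[Dict[str, float], Dict[str, Dict[str, float]]]:
    """Phospholipid-species and LPS coefficients for the lipid fraction.

    Each phospholipid species is the de-acylated head/backbone core plus the
    fatty-acid-profile-averaged acyl residue, twice for PE/PG and four times
    for cardiolipin; the averaged species carries a fractional elemental
    formula.  LPS enters as one aggregate species at ``lps_share`` g/gDCW
    taken out of the lipid fraction.

    Returns (coefficients, species formulas) so downstream mass/element
    accounting uses exactly the averaged species assembled here.
    """
    heads = dict(DEFAULT_HEAD_GROUPS if head_groups is None else head_groups)
    fas = dict(DEFAULT_FATTY_ACIDS if fatty_acids is None else fatty_acids)
    for name, mapping in (("head-group", heads), ("fatty-acid", fas)):
        total = sum(mapping.values())
        # printed percentage tables may sum to 99.9%; renormalize small gaps
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"{name} fractions sum to {total}, not 1")
        for key in mapping:
            mapping[key] /= total
    if not (0.0 <= lps_share <= fraction + 1e-12):
        raise ValueError("LPS share must lie within the lipid fraction")
    mean_acyl = combine_formulas(*((x, ACYL_RESIDUES[fa]) for fa, x in fas.items()))
    formulas: Dict[str, Dict[str, float]] = {}
    for head, spec in PHOSPHOLIPID_CORES.items():
        formulas[head] = combine_formulas(
            (1.0, spec["formula"]), (float(spec["n_acyl"]), mean_acyl)
        )
    phospho_fraction = fraction - lps_share
    coefs = _class_coefficients(phospho_fraction, heads, formulas)
    formulas["lps"] = dict(refdata.LPS_AGGREGATE)
    if lps_share > 0:
        coefs["lps"] = lps_share * 1000.0 / formula_mass(refdata.LPS_AGGREGATE)
    else:
        coefs["lps"] = 0.0
    return coefs, formulas


# ---------------------------------------------------------------------------
# Remaining pools
# ---------------------------------------------------------------------------

def carbohydrate_coefficients(fraction: float) -> Dict[str, float]:
    """Carbohydrate pool as glycogen (anhydroglucose residues)."""
    return _class_coefficients(fraction, {"glycogen": 1.0},
                               {"glycogen": refdata.GLYCOGEN_RESIDUE})


def peptidoglycan_coefficients(fraction: float) -> Dict[str, float]:
    return _class_coefficients(fraction, {"peptidoglycan": 1.0},
                               {"peptidoglycan": refdata.PEPTIDOGLYCAN_RESIDUE})


def cofactor_coefficients(fraction: float) -> Dict[str, float]:
    """Cofactor pool split equally by mass over the representative species.

    The share is negligible by design; inclusion matters for essentiality
    predictions, not for yields.
    """
    n = len(COFACTOR_SPECIES)
    return {
        sp: (fraction / n) * 1000.0 / formula_mass(f)
        for sp, f in COFACTOR_SPECIES.items()
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def finalize_equation(
    parts: Iterable[Mapping[str, float]],
    gam: float = 0.0,
    monomers: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> BiomassEquation:
    """Merge coefficient sets, add the GAM ATP term, verify 1 g closure."""
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    consumed: Dict[str, float] = {}
    for part in parts:
        for met, coef in part.items():
            if coef < 0:
                raise ValueError(f"negative biomass coefficient for {met!r}")
            if coef > 0:
                consumed[met] = consumed.get(met, 0.0) + coef
    produced: Dict[str, float] = {"biomass": 1.0}
    if gam > 0:
        consumed["atp"] = consumed.get("atp", 0.0) + gam
        consumed["h2o"] = consumed.get("h2o", 0.0) + gam
        produced["adp"] = produced.get("adp", 0.0) + gam
        produced["pi"] = produced.get("pi", 0.0) + gam
    eq = BiomassEquation(consumed, produced, gam)
    table = dict(default_monomer_table())
    if monomers:
        table.update(monomers)
    mass = eq.net_consumed_mass(table)
    if abs(mass - 1.0) > MASS_TOL:
        raise ValueError(
            f"biomass equation consumes {mass:.8f} g per unit flux, not 1 g"
        )
    return eq


def elemental_composition(
    eq: BiomassEquation,
    monomers: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> ElementalComposition:
    """Element mass fractions (% w/w) of the 1 g assembled per unit flux.

    Computed as the net elemental flow (consumed minus produced, biomass
    excluded); the GAM quartet is element-neutral and cancels exactly.
    """
    table = dict(default_monomer_table())
    if monomers:
        table.update(monomers)
    net: Dict[str, float] = {}
    for sign, side in ((1.0, eq.consumed), (-1.0, eq.produced)):
        for met, coef in side.items():
            if met == "biomass":
                continue
            if met not in table:
                raise KeyError(f"no elemental formula for species {met!r}")
            for el, count in table[met].items():
                net[el] = net.get(el, 0.0) + sign * coef * count
    fractions = {
        el: 100.0 * n * atomic_mass_of(el) / 1000.0 for el, n in net.items()
    }
    return ElementalComposition({el: v for el, v in fractions.items() if abs(v) > 1e-12})


def build_study_equation(
    gam: float = 0.0,
    *,
    composition: Optional[MacromolecularComposition] = None,
    profile: Optional[AminoAcidProfile] = None,
    gc_content: float = DEFAULT_GC_CONTENT,
) -> Tuple[BiomassEquation, Dict[str, Dict[str, float]]]:
    """Assemble the full study biomass equation with default inputs.

    Returns the equation together with the species formula table (monomer
    table extended with the averaged lipid species).
    """
    comp = composition or assemble_composition()
    prof = fill_in_profile(profile)
    parts = [
        protein_coefficients(prof, comp.protein),
        nucleic_acid_coefficients("dna", comp.dna, dna_composition_from_gc(gc_content)),
        nucleic_acid_coefficients("rna", comp.rna),
        carbohydrate_coefficients(comp.carbohydrate),
        peptidoglycan_coefficients(comp.peptidoglycan),
        cofactor_coefficients(comp.cofactor_pool),
    ]
    min_lps = min(DEFAULT_LPS_SHARE, comp.lipid)
    lipid_coefs, lipid_formulas = lipid_coefficients(comp.lipid, lps_share=min_lps)
    parts.append(lipid_coefs)
    table = dict(default_monomer_table())
    table.update(lipid_formulas)
    eq = finalize_equation(parts, gam=gam, monomers=table)
    return eq, table
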