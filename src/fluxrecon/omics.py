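"""Transcriptome-model consistency assessments.

Three checks connect per-gene microarray expression (log2 values plus
present/absent/marginal detection calls over replicate arrays) with model
predictions:

1. essential-but-not-expressed: genes the model deems essential whose
   expression evidence says "not expressed" (too many absent calls, too few
   present calls, or a low mean log2 value);
2. low-expression-but-required: reactions that must carry flux (non-zero
   minimal |flux| in FVA) whose GPR-aggregated expression is below the
   not-expressed threshold;
3. high-expression-but-idle: genes with high expression whose every
   associated reaction is confined to near-zero flux.

GPR aggregation maps isozymes (OR) to the max and complexes (AND) to the
min of gene-level mean expressions, so an isozyme reaction is flagged only
when all isozymes are low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .gpr import GprError, aggregate_gpr, gpr_genes
from .model import FVAResult, MetabolicModel

__all__ = [
    "ExpressionDataset",
    "ConsistencyReport",
    "flag_not_expressed",
    "essential_not_expressed",
    "reaction_expression",
    "low_expr_required_reactions",
    "high_expr_zero_flux",
]

#: Numeric epsilon below which a minimal FVA |flux| counts as zero.
FLUX_EPS = 1e-9


@dataclass
class ExpressionDataset:
    """Per-gene log2 values and P/A/M calls over n_arrays arrays."""

    log2: Dict[str, List[float]]
    calls: Dict[str, List[str]]
    n_arrays: int = 4

    def __post_init__(self):
        for gene, values in self.log2.items():
            calls = self.calls.get(gene, [])
            if len(values) != self.n_arrays or len(calls) != self.n_arrays:
                raise ValueError(
                    f"gene {gene!r} does not have {self.n_arrays} arrays"
                )
            bad = set(calls) - {"P", "A", "M"}
            if bad:
                raise ValueError(f"gene {gene!r} has invalid calls {bad}")

    @property
    def genes(self) -> Set[str]:
        return set(self.log2)

    def mean_log2(self, gene: str) -> float:
        values = self.log2[gene]
        return sum(values) / len(values)

    def grand_mean(self) -> float:
        """Mean log2 expression over all genes and arrays."""
        total = sum(sum(v) for v in self.log2.values())
        count = sum(len(v) for v in self.log2.values())
        return total / count

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.log2):
            for i in range(self.n_arrays):
                rows.append(
                    {
                        "gene": gene,
                        "array_id": f"array{i + 1}",
                        "log2": self.log2[gene][i],
                        "call": self.calls[gene][i],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDataset":
        log2: Dict[str, List[float]] = {}
        calls: Dict[str, List[str]] = {}
        counts = df.groupby("gene").size()
        n_arrays = int(counts.iloc[0])
        for gene, sub in df.groupby("gene"):
            sub = sub.sort_values("array_id")
            log2[gene] = [float(v) for v in sub["log2"]]
            calls[gene] = [str(c) for c in sub["call"]]
        return cls(log2, calls, n_arrays)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ConsistencyReport:
    essential_not_expressed: Dict[str, Set[str]]
    multi_criteria_count: int
    low_expr_required_reactions: List[str]
    high_expr_zero_flux_genes: List[str]
    unevaluable_reactions: List[str] = field(default_factory=list)


def flag_not_expressed(
    ds: ExpressionDataset,
    absent_gt: int = 2,
    present_lt: int = 3,
    mean_lt: float = 7.5,
) -> Dict[str, Set[str]]:
    """Per-gene set of fired not-expressed criteria (empty set = not flagged).

    Criteria: more than ``absent_gt`` absent calls, fewer than ``present_lt``
    present calls, or mean log2 below ``mean_lt``.  Marginal (M) calls count
    as neither present nor absent.
    """
    if absent_gt >= ds.n_arrays or present_lt > ds.n_arrays:
        raise ValueError("call thresholds inconsistent with the array count")
    flags: Dict[str, Set[str]] = {}
    for gene in ds.genes:
        fired: Set[str] = set()
        calls = ds.calls[gene]
        if calls.count("A") > absent_gt:
            fired.add("absent_calls")
        if calls.count("P") < present_lt:
            fired.add("present_calls")
        if ds.mean_log2(gene) < mean_lt:
            fired.add("low_mean")
        flags[gene] = fired
    return flags


def essential_not_expressed(
    essentials: Iterable[str],
    flags: Mapping[str, Set[str]],
) -> Tuple[Dict[str, Set[str]], int]:
    """Essential genes whose expression evidence fired >= 1 criterion.

    Returns the per-gene fired criteria and the count of genes firing at
    least two criteria (the more trustworthy calls).
    """
    essentials = set(essentials)
    if not essentials:
        import warnings

        warnings.warn("empty essential gene set", stacklevel=2)
    selected = {
        g: set(flags[g]) for g in essentials if g in flags and flags[g]
    }
    multi = sum(1 for crit in selected.values() if len(crit) >= 2)
    return selected, multi


def reaction_expression(
    model: MetabolicModel,
    ds: ExpressionDataset,
) -> Tuple[Dict[str, float], List[str]]:
    """GPR-aggregated expression value per reaction.

    Gene-level values are array means; OR takes the max, AND the min.
    Reactions whose GPR references genes missing from the dataset are
    unevaluable and listed separately; empty-GPR reactions have no value.
    """
    means = {g: ds.mean_log2(g) for g in ds.genes}
    values: Dict[str, float] = {}
    unevaluable: List[str] = []
    for rxn in model.reactions:
        if not rxn.gpr.strip():
            continue
        try:
            values[rxn.id] = aggregate_gpr(rxn.gpr, means)
        except KeyError:
            unevaluable.append(rxn.id)
    return values, unevaluable


def _min_abs_flux(interval: Tuple[float, float]) -> float:
    lo, hi = interval
    if lo <= 0.0 <= hi:
        return 0.0
    return min(abs(lo), abs(hi))


def _max_abs_flux(interval: Tuple[float, float]) -> float:
    lo, hi = interval
    return max(abs(lo), abs(hi))


def low_expr_required_reactions(
    fva_result: FVAResult,
    rxn_expr: Mapping[str, float],
    expr_lt: float = 7.5,
    eps: float = FLUX_EPS,
) -> List[str]:
    """Reactions forced to carry flux whose expression is below threshold.

    "Forced" means the minimal attainable |flux| exceeds ``eps`` at the
    fixed objective; absolute values make reversible reactions symmetric.
    """
    out = []
    for rid, value in rxn_expr.items():
        if rid not in fva_result.intervals:
            continue
        if _min_abs_flux(fva_result.intervals[rid]) > eps and value < expr_lt:
            out.append(rid)
    return sorted(out)


def high_expr_zero_flux(
    ds: ExpressionDataset,
    model: MetabolicModel,
    fva_result: FVAResult,
    flux_lt: float = 0.1,
    expr_high: Optional[float] = None,
) -> List[str]:
    """Highly expressed genes whose reactions are all confined to low flux.

    ``flux_lt`` is the |flux| ceiling (mmol/gDCW/h; the conventional check
    runs at mu = 0.2 1/h).  ``expr_high`` has no unique published value, so
    it must be stated; it defaults to the dataset grand mean and is recorded
    by callers in reports.  Genes with no associated reactions are skipped.
    """
    if expr_high is None:
        expr_high = ds.grand_mean()
    gene_rxns: Dict[str, List[str]] = {}
    for rxn in model.reactions:
        for gene in gpr_genes(rxn.gpr):
            gene_rxns.setdefault(gene, []).append(rxn.id)
    out = []
    for gene in sorted(ds.genes):
        rxns = gene_rxns.get(gene)
        if not rxns:
            continue
        if ds.mean_log2(gene) < expr_high:
            continue
        if all(
            _max_abs_flux(fva_result.intervals[r]) < flux_lt
            for r in rxns
            if r in fva_result.intervals
        ):
            out.append(gene)
    return out
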