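"""End-to-end reconciliation pipeline.

Runs the stages in the order the analysis dictates: chemostat growth
parameters (Pirt fit, washout), biomass-equation construction, GAM/NGAM
fitting, FVA against measured fluxes, and transcriptome consistency — and
emits a versioned JSON report with every fitted parameter, all thresholds
actually used, and input provenance (SHA256 hashes, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .biomass import build_study_equation, elemental_composition
from .concordance import fva_distance, measured_fluxes_from_tsv
from .growth import (
    CalibrationModel,
    element_balance,
    fit_pirt,
    fit_washout,
    records_from_tsv,
    steady_state_rates,
)
from .maintenance import compute_ngam, fit_gam, predicted_yxs_max
from .model import MetabolicModel, essential_genes, fva, load_model, set_maintenance
from .omics import (
    ExpressionDataset,
    essential_not_expressed,
    flag_not_expressed,
    high_expr_zero_flux,
    low_expr_required_reactions,
    reaction_expression,
)
from .refdata import M_GLC

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, constants and thresholds of one reconciliation run."""

    chemostat_tsv: str
    model_json: str
    washout_tsv: Optional[str] = None
    washout_dilution: float = 1.2
    measured_fluxes_tsv: Optional[str] = None
    flux_mapping_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    mu_reference: float = 0.2          # growth rate for FVA / omics checks
    y_atp: float = 19.25               # mol ATP/mol glucose
    p_to_o: float = 1.33
    m_glc: float = M_GLC
    expr_not_expressed: float = 7.5    # log2 threshold
    expr_high: Optional[float] = None  # None -> dataset grand mean
    flux_lt: float = 0.1               # mmol/gDCW/h
    gam_tol: float = 1e-4
    growth_threshold: float = 0.01
    seed: int = 0
    output_dir: str = "fluxrecon_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("chemostat_tsv", "model_json", "washout_tsv",
                     "measured_fluxes_tsv", "flux_mapping_tsv", "expression_tsv"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError("config", f"input file {value!r} does not exist")
        for name in ("mu_reference", "y_atp", "flux_lt", "gam_tol"):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"{name} must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "provenance": {
            name: _sha256(getattr(config, name))
            for name in ("chemostat_tsv", "model_json", "washout_tsv",
                         "measured_fluxes_tsv", "flux_mapping_tsv",
                         "expression_tsv")
            if getattr(config, name) is not None
        },
        "stages": {},
    }

    # -- stage 1: growth parameters ------------------------------------
    try:
        cal = CalibrationModel()
        records = records_from_tsv(config.chemostat_tsv)
        rates = [steady_state_rates(r, cal, m_glc=config.m_glc) for r in records]
        params = fit_pirt([(r.D, rr.qs) for r, rr in zip(records, rates)])
        carbon_frac, nitrogen_frac = element_balance(list(zip(records, rates)))
        mu_max = None
        if config.washout_tsv:
            wdf = pd.read_csv(config.washout_tsv, sep="\t")
            series = list(zip(wdf["t"].astype(float), wdf["Cx"].astype(float)))
            mu_max = fit_washout(series, config.washout_dilution).mu_max
        report["stages"]["growth"] = {
            "yxs_max": params.Yxs_max,
            "ms": params.ms,
            "r_squared": params.r_squared,
            "mu_max": mu_max,
            "carbon_fraction": carbon_frac,
            "nitrogen_fraction": nitrogen_frac,
            "n_steady_states": len(records),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("growth", str(exc)) from exc

    # -- stage 2: biomass equation -------------------------------------
    try:
        eq, table = build_study_equation(gam=0.0)
        elems = elemental_composition(eq, table)
        report["stages"]["biomass"] = {
            "net_consumed_mass_g": eq.net_consumed_mass(table),
            "n_consumed_species": len(eq.consumed),
            "elemental_composition_pct": dict(sorted(elems.fractions.items())),
        }
    except Exception as exc:
        raise PipelineError("biomass", str(exc)) from exc

    # -- stage 3: maintenance ------------------------------------------
    try:
        model = load_model(config.model_json)
        ngam = compute_ngam(params.ms, config.y_atp, config.m_glc)
        gam = fit_gam(model, params.Yxs_max, tol=config.gam_tol, ngam=ngam,
                      m_glc=config.m_glc)
        model = set_maintenance(model, gam, ngam)
        report["stages"]["maintenance"] = {
            "gam": gam,
            "ngam": ngam,
            "y_atp": config.y_atp,
            "p_to_o": config.p_to_o,
            "predicted_yxs_max": predicted_yxs_max(model, m_glc=config.m_glc),
        }
    except Exception as exc:
        raise PipelineError("maintenance", str(exc)) from exc

    # -- stage 4: FVA and flux concordance -----------------------------
    try:
        fva_result = _fva_at_mu(model, config.mu_reference)
        fva_rows = [
            {"reaction": rid, "min_flux": lo, "max_flux": hi}
            for rid, (lo, hi) in sorted(fva_result.intervals.items())
        ]
        pd.DataFrame(fva_rows).to_csv(outdir / "fva.tsv", sep="\t", index=False)
        stage: Dict = {"mu": config.mu_reference,
                       "n_reactions": len(fva_result.intervals)}
        if config.measured_fluxes_tsv:
            measured = measured_fluxes_from_tsv(
                config.measured_fluxes_tsv, config.flux_mapping_tsv
            )
            dist = fva_distance(fva_result, measured)
            stage["fva_distance"] = {
                "d_min": dist.d_min,
                "d_max": dist.d_max,
                "unbounded_reactions": dist.unbounded,
            }
        report["stages"]["concordance"] = stage
    except Exception as exc:
        raise PipelineError("concordance", str(exc)) from exc

    # -- stage 5: omics consistency ------------------------------------
    if config.expression_tsv:
        try:
            ds = ExpressionDataset.from_tsv(config.expression_tsv)
            expr_high = config.expr_high
            if expr_high is None:
                expr_high = ds.grand_mean()
            flags = flag_not_expressed(ds, mean_lt=config.expr_not_expressed)
            essentials = essential_genes(model, config.growth_threshold)
            selected, multi = essential_not_expressed(essentials, flags)
            rxn_expr, unevaluable = reaction_expression(model, ds)
            low_req = low_expr_required_reactions(
                fva_result, rxn_expr, expr_lt=config.expr_not_expressed
            )
            high_idle = high_expr_zero_flux(
                ds, model, fva_result, flux_lt=config.flux_lt, expr_high=expr_high
            )
            report["stages"]["omics"] = {
                "expr_high_threshold": expr_high,
                "expr_not_expressed_threshold": config.expr_not_expressed,
                "flux_lt": config.flux_lt,
                "n_essential": len(essentials),
                "essential_not_expressed": {
                    g: sorted(c) for g, c in sorted(selected.items())
                },
                "n_multi_criteria": multi,
                "low_expr_required_reactions": low_req,
                "high_expr_zero_flux_genes": high_idle,
                "unevaluable_reactions": unevaluable,
            }
            _write_omics_tsv(outdir / "omics_report.tsv", report["stages"]["omics"])
        except Exception as exc:
            raise PipelineError("omics", str(exc)) from exc

    params_out = {
        "yxs_max": report["stages"]["growth"]["yxs_max"],
        "ms": report["stages"]["growth"]["ms"],
        "mu_max": report["stages"]["growth"]["mu_max"],
        "gam": report["stages"]["maintenance"]["gam"],
        "ngam": report["stages"]["maintenance"]["ngam"],
    }
    with open(outdir / "params.json", "w") as fh:
        json.dump(params_out, fh, indent=1, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _fva_at_mu(model: MetabolicModel, mu: float):
    """FVA with glucose uptake minimized at fixed growth rate mu."""
    from .model import fba

    sol = fba(model, "EX_glc", "max", fixed_fluxes={model.objective_reaction: mu})
    if sol.status != "optimal":
        raise RuntimeError(f"model infeasible at mu={mu}")
    constrained = model.with_bounds({model.objective_reaction: (mu, mu)})
    return fva(constrained, "EX_glc", sol.objective_value)


def _write_omics_tsv(path, omics: Dict) -> None:
    rows: List[Dict] = []
    for gene, crit in omics["essential_not_expressed"].items():
        rows.append({"section": "essential_not_expressed", "item": gene,
                     "detail": ",".join(crit)})
    for rid in omics["low_expr_required_reactions"]:
        rows.append({"section": "low_expr_required", "item": rid, "detail": ""})
    for gene in omics["high_expr_zero_flux_genes"]:
        rows.append({"section": "high_expr_zero_flux", "item": gene, "detail": ""})
    pd.DataFrame(rows, columns=["section", "item", "detail"]).to_csv(
        path, sep="\t", index=False
    )
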