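"""End-to-end workflow orchestration and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import flux as flux_mod
from . import stats as stats_mod
from .gem import (
    CurrencySet,
    MetabolicModel,
    default_currency,
    default_essential_amino_acids,
    load_id_list,
    read_sbml,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("mgpflux")


@dataclass
class RunConfig:
    model: str
    expression: str
    variants: str
    output_dir: str
    cohort_id: str = "cohort"
    metabolome: Optional[str] = None
    currency_list: Optional[str] = None
    essential_aa_list: Optional[str] = None
    gene_groups: Optional[str] = None
    alpha: float = 0.05
    z_threshold: float = 3.5
    scale_cap: float = 1000.0
    knn_k: int = 10
    max_missing_frac: float = 0.20
    auc_threshold: float = 0.7
    empirical_resamples: int = 100_000
    mean_scope: str = "mutant"
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("model", "expression", "variants"):
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config is missing required path {name!r}")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("max_missing_frac", 0.0, 1.0),
            ("auc_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v < hi or v in (lo, hi)):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.z_threshold <= 0 or self.scale_cap <= 0 or self.knn_k < 1:
            raise ValueError("z_threshold, scale_cap must be > 0 and knn_k >= 1")
        if self.metabolome is not None and self.seed is None:
            raise ValueError(
                "seed is mandatory when the stochastic metabolome stage is enabled"
            )

    def sha256(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _load_currency(config: RunConfig) -> CurrencySet:
    if config.currency_list:
        return CurrencySet.from_file(config.currency_list)
    return default_currency()


def _load_essential_aa(config: RunConfig) -> FrozenSet[str]:
    if config.essential_aa_list:
        return load_id_list(config.essential_aa_list)
    return default_essential_amino_acids()


def fit_cohort_fluxes(
    model: MetabolicModel,
    expression: pd.DataFrame,
    scale_cap: float = 1000.0,
) -> Dict[str, flux_mod.FluxState]:
    """LAD-fit one flux state per expression sample (rows)."""
    states: Dict[str, flux_mod.FluxState] = {}
    for sample, row in expression.iterrows():
        profile = {g: float(v) for g, v in row.items() if v > 0}
        rxn_expr = flux_mod.map_expression_to_reactions(profile, model)
        states[str(sample)] = flux_mod.fit_fluxes_lad(
            model, rxn_expr, scale_cap=scale_cap
        )
    return states


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run steps 1-4 (and the optional metabolome arm); write TSV outputs and
    a JSON manifest; return a summary dict."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 0: loading inputs")
    model = read_sbml(config.model)
    expression = flux_mod.read_expression_table(config.expression, model)
    variants = cohort_mod.read_variant_table(config.variants)
    currency = _load_currency(config)
    essential_aa = _load_essential_aa(config)

    cohort_samples = [str(s) for s in expression.index]
    logger.info("stage 1: LAD flux fitting for %d samples", len(cohort_samples))
    try:
        states = fit_cohort_fluxes(model, expression, scale_cap=config.scale_cap)
    except flux_mod.FluxFitError as exc:
        raise RuntimeError(f"stage 1 (flux fitting) failed: {exc}") from exc

    fsm = flux_mod.compute_flux_sum_matrix(model, states, exclude_currency=currency)
    fsm.total.to_csv(out_dir / "flux_sums.tsv", sep="\t")
    flux_dir = out_dir / "flux_states"
    flux_dir.mkdir(exist_ok=True)
    for sample, state in states.items():
        state.to_tsv(flux_dir / f"{sample}.tsv")

    logger.info("stage 2-4: normalization, pairing, MGP selection")
    norm = stats_mod.quantile_normalize(fsm)
    mutations = cohort_mod.filter_mutations(variants, cohort_samples)
    if config.gene_groups:
        groups = cohort_mod.read_gene_groups(config.gene_groups)
        mutations = cohort_mod.apply_gene_groups(mutations, groups)
    result = stats_mod.predict_mgps(
        model, norm, mutations,
        alpha=config.alpha, z_threshold=config.z_threshold,
        essential_aa=essential_aa, mean_scope=config.mean_scope,
    )
    pairs_df = pd.DataFrame([vars(p) for p in result.pairs])
    pairs_df.to_csv(out_dir / "mg_pairs.tsv", sep="\t", index=False)
    stats_mod.mgps_to_frame(result.mgps).to_csv(
        out_dir / "mgps.tsv", sep="\t", index=False
    )

    summary: Dict[str, object] = {
        "cohort_id": config.cohort_id,
        "tallies": dict(result.tallies),
        "mutation_tally": dict(mutations.tally),
    }

    if config.metabolome:
        logger.info("metabolome arm: filtering, imputation, AUC")
        metabolome = cohort_mod.read_metabolome(config.metabolome)
        filtered = cohort_mod.filter_peaks(metabolome, config.max_missing_frac)
        imputed = cohort_mod.knn_impute(filtered, k=config.knn_k)
        normalized = cohort_mod.normalize_metabolome(imputed)
        auc_rows: List[dict] = []
        for gene in mutations.status.columns:
            status = mutations.status[gene].reindex(
                normalized.data.columns
            ).fillna(False)
            for peak in normalized.data.index:
                res = cohort_mod.compute_auc(
                    normalized.data.loc[peak].values, status.values,
                    metabolite=str(peak), gene=str(gene),
                )
                auc_rows.append(vars(res))
        auc_df = pd.DataFrame(auc_rows)
        auc_df.to_csv(out_dir / "auc.tsv", sep="\t", index=False)
        summary["metabolome"] = {
            "peaks_in": metabolome.n_peaks,
            "peaks_surviving": filtered.n_peaks,
            "auc_rows": len(auc_df),
        }

    manifest = {
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "summary": summary,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
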