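"""Synthetic toy models and cohorts with planted ground truth.

``generate_toy_gem`` builds a small flux-consistent model of parallel
pathway chains converging on a shared target metabolite, so that the target
has a genuinely multi-pathway production profile.  ``simulate_cohort``
plants a multiplicative expression effect on one pathway's genes in mutant
samples, emits the exact file formats the pipeline consumes, and returns
the ground truth for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import MetabolomeMatrix, VariantTable
from .gem import Metabolite, MetabolicModel, Reaction, UNASSIGNED

__all__ = [
    "ToyGEMSpec",
    "PlantedEffect",
    "CohortSimSpec",
    "GroundTruth",
    "generate_toy_gem",
    "simulate_cohort",
    "assert_flux_consistent",
]


@dataclass(frozen=True)
class ToyGEMSpec:
    n_pathways: int = 3
    reactions_per_pathway: int = 4
    n_shared_metabolites: int = 2  # 2 = shared source + target, 1 = target only
    n_exchanges: int = 0  # extra demand sinks on pathway intermediates
    bound: float = 1000.0
    isozyme_fraction: float = 0.2  # chance a reaction gets an OR-ed second gene
    seed: int = 0


@dataclass(frozen=True)
class PlantedEffect:
    pathway: str
    n_mutant: int
    expression_multiplier: float = 5.0
    metabolome_log2_fc: float = 1.0
    noise_sd: float = 0.3


@dataclass(frozen=True)
class CohortSimSpec:
    n_samples: int = 40
    planted: Mapping[str, PlantedEffect] = field(default_factory=dict)
    missingness: float = 0.0
    n_decoy_peaks: int = 5
    add_decoy_variants: bool = False
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Planted (metabolite base id, gene, pathway) triples with effect sizes."""

    triples: Tuple[Tuple[str, str, str], ...]
    effects: Mapping[str, PlantedEffect]


def pathway_name(p: int) -> str:
    return f"pathway_{p + 1}"


def generate_toy_gem(spec: ToyGEMSpec) -> MetabolicModel:
    """Build a deterministic toy model of parallel chains src -> ... -> tgt.

    Every pathway is a linear chain of ``reactions_per_pathway`` reactions
    converting the (shared or per-pathway) source into the shared target
    metabolite; source import and target export exchanges make every
    reaction able to carry flux.
    """
    if spec.n_pathways < 1:
        raise ValueError("need at least one pathway")
    if spec.reactions_per_pathway < 1:
        raise ValueError("need at least one reaction per pathway")
    if spec.n_shared_metabolites < 1:
        raise ValueError("need at least one shared metabolite")
    rng = np.random.default_rng(spec.seed)
    b = float(spec.bound)

    metabolites: Dict[str, Metabolite] = {}
    reactions: Dict[str, Reaction] = {}
    genes: List[str] = []

    def add_met(met_id: str, comp: str) -> None:
        if met_id not in metabolites:
            metabolites[met_id] = Metabolite(id=met_id, name=met_id, compartment=comp)

    shared_source = spec.n_shared_metabolites >= 2
    add_met("tgt_c", "c")
    add_met("tgt_e", "e")
    if shared_source:
        add_met("src_c", "c")
        add_met("src_e", "e")

    for p in range(spec.n_pathways):
        pw = pathway_name(p)
        if shared_source:
            source = "src_c"
        else:
            source = f"src{p + 1}_c"
            add_met(source, "c")
            add_met(f"src{p + 1}_e", "e")
        chain = [source]
        for k in range(spec.reactions_per_pathway - 1):
            mid = f"m{p + 1}_{k + 1}_c"
            add_met(mid, "c")
            chain.append(mid)
        chain.append("tgt_c")
        for k in range(spec.reactions_per_pathway):
            rid = f"R{p + 1}_{k + 1}"
            gene = f"G{p + 1}_{k + 1}"
            genes.append(gene)
            gpr = gene
            if rng.random() < spec.isozyme_fraction:
                iso = f"G{p + 1}_{k + 1}b"
                genes.append(iso)
                gpr = f"{gene} or {iso}"
            # the converging step yields tgt at ~1/n_pathways so the target's
            # flux-sum interleaves with intermediate flux-sums instead of
            # pinning the top within-sample rank (which quantile
            # normalization would flatten into a constant); dyadic so the
            # coefficient survives SBML round-trips bit-exactly
            if chain[k + 1] == "tgt_c" and spec.n_pathways > 1:
                product_coef = 1.0 / float(
                    2 ** int(np.ceil(np.log2(spec.n_pathways)))
                )
            else:
                product_coef = 1.0
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry={chain[k]: -1.0, chain[k + 1]: product_coef},
                lower_bound=0.0,
                upper_bound=b,
                gpr=gpr,
                pathway=pw,
            )

    # boundary machinery: uptake transport + exchange per source, export for tgt
    sources = ["src"] if shared_source else [f"src{p + 1}" for p in range(spec.n_pathways)]
    for s in sources:
        reactions[f"T_{s}"] = Reaction(
            id=f"T_{s}",
            stoichiometry={f"{s}_e": -1.0, f"{s}_c": 1.0},
            lower_bound=-b, upper_bound=b, pathway="Transport, extracellular",
        )
        reactions[f"EX_{s}_e"] = Reaction(
            id=f"EX_{s}_e",
            stoichiometry={f"{s}_e": -1.0},
            lower_bound=-b, upper_bound=b, pathway="Exchange/demand reaction",
        )
    reactions["T_tgt"] = Reaction(
        id="T_tgt",
        stoichiometry={"tgt_c": -1.0, "tgt_e": 1.0},
        lower_bound=0.0, upper_bound=b, pathway="Transport, extracellular",
    )
    reactions["EX_tgt_e"] = Reaction(
        id="EX_tgt_e",
        stoichiometry={"tgt_e": -1.0},
        lower_bound=0.0, upper_bound=b, pathway="Exchange/demand reaction",
    )
    for i in range(spec.n_exchanges):
        p = i % spec.n_pathways
        if spec.reactions_per_pathway < 2:
            break
        mid = f"m{p + 1}_1_c"
        reactions[f"DM_{mid}"] = Reaction(
            id=f"DM_{mid}", stoichiometry={mid: -1.0},
            lower_bound=0.0, upper_bound=b, pathway=UNASSIGNED,
        )

    return MetabolicModel(
        id=f"toy_gem_seed{spec.seed}",
        metabolites=metabolites,
        reactions=reactions,
        genes=tuple(sorted(set(genes))),
    )


def assert_flux_consistent(model: MetabolicModel) -> None:
    """Check every reaction can carry nonzero flux in some steady state."""
    from scipy.optimize import linprog

    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for m, c in model.reactions[rid].stoichiometry.items():
            S[met_index[m], j] = c
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    for j, rid in enumerate(rxn_ids):
        best = 0.0
        for sign in (-1.0, 1.0):
            c = np.zeros(len(rxn_ids))
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=np.zeros(len(met_ids)), bounds=bounds,
                          method="highs")
            if res.success:
                best = max(best, abs(res.x[j]))
        if best < 1e-6:
            raise AssertionError(f"reaction {rid!r} cannot carry flux")


def _pathway_genes(model: MetabolicModel, pathway: str) -> List[str]:
    from .gem import parse_gpr

    out: set = set()
    for rxn in model.reactions.values():
        if rxn.pathway == pathway and rxn.gpr:
            out |= parse_gpr(rxn.gpr).genes()
    return sorted(out)


def simulate_cohort(
    model: MetabolicModel, spec: CohortSimSpec
) -> Tuple[pd.DataFrame, VariantTable, MetabolomeMatrix, GroundTruth]:
    """Simulate (expression samples x genes, variants, metabolome, truth).

    Baseline expression is log-normal per gene; mutant samples get the
    planted pathway's reaction genes multiplied by the effect size.  Mutant
    blocks are disjoint and deterministic so the filter cascade passes by
    construction.  The metabolome plants a log2 fold change on the target
    metabolite of each planted pathway, with Gaussian noise and MCAR
    missingness.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(model.genes)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    total_mutant = sum(e.n_mutant for e in spec.planted.values())
    if total_mutant > spec.n_samples:
        raise ValueError("more mutant samples than cohort samples")
    mutant_of: Dict[str, List[str]] = {}
    cursor = 0
    for gene, effect in spec.planted.items():
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} absent from the model's GPRs")
        if effect.n_mutant < 3 or spec.n_samples - effect.n_mutant < 3:
            raise ValueError("planted groups must leave >=3 mutant and wild-type")
        mutant_of[gene] = samples[cursor : cursor + effect.n_mutant]
        cursor += effect.n_mutant

    # expression: log-normal baseline, multiplicative planted effect
    base = rng.lognormal(mean=np.log(50.0), sigma=0.5, size=len(genes))
    noise_sd = max((e.noise_sd for e in spec.planted.values()), default=0.3)
    expr = np.empty((spec.n_samples, len(genes)))
    for i in range(spec.n_samples):
        expr[i] = base * rng.lognormal(mean=0.0, sigma=noise_sd, size=len(genes))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for gene, effect in spec.planted.items():
        affected = _pathway_genes(model, effect.pathway)
        cols = [gene_pos[g] for g in affected if g in gene_pos]
        rows = [samples.index(s) for s in mutant_of[gene]]
        for i in rows:
            expr[i, cols] *= effect.expression_multiplier
    expression = pd.DataFrame(expr, index=samples, columns=genes)
    expression.index.name = "sample"

    # variant table
    rows = []
    for gene, effect in spec.planted.items():
        for s in mutant_of[gene]:
            rows.append(
                (s, gene, int(rng.integers(7, 60)), "nonsynonymous")
            )
    if spec.add_decoy_variants:
        for s in samples[:2]:
            rows.append((s, "DECOY_LOW", 3, "nonsynonymous"))
            rows.append((s, "DECOY_SYN", 20, "synonymous"))
    variants = VariantTable(
        pd.DataFrame(rows, columns=["sample", "gene", "alt_reads", "consequence"])
    )

    # metabolome: planted target metabolites + decoy peaks
    planted_mets: Dict[str, str] = {}  # peak -> gene
    for gene, effect in spec.planted.items():
        planted_mets[f"tgt__{gene}"] = gene
    peak_ids = list(planted_mets) + [
        f"decoy_{i + 1}" for i in range(spec.n_decoy_peaks)
    ]
    levels = np.empty((len(peak_ids), spec.n_samples))
    for r, peak in enumerate(peak_ids):
        baseline = rng.lognormal(mean=np.log(100.0), sigma=0.2, size=spec.n_samples)
        levels[r] = baseline
        gene = planted_mets.get(peak)
        if gene is not None:
            effect = spec.planted[gene]
            idx = [samples.index(s) for s in mutant_of[gene]]
            levels[r, idx] *= 2.0 ** effect.metabolome_log2_fc
        levels[r] *= rng.lognormal(mean=0.0, sigma=0.1, size=spec.n_samples)
    if spec.missingness > 0:
        mask = rng.random(levels.shape) < spec.missingness
        levels = np.where(mask, np.nan, levels)
    data = pd.DataFrame(levels, index=peak_ids, columns=samples)
    data.index.name = "peak"
    annotations = pd.DataFrame(
        {
            "name": [p.split("__")[0] if p in planted_mets else "" for p in peak_ids],
            "annotated": [p in planted_mets for p in peak_ids],
        },
        index=data.index,
    )
    metabolome = MetabolomeMatrix(data=data, annotations=annotations)

    truth = GroundTruth(
        triples=tuple(
            ("tgt", gene, effect.pathway) for gene, effect in spec.planted.items()
        ),
        effects=dict(spec.planted),
    )
    return expression, variants, metabolome, truth
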