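"""Seeded end-to-end benchmarks on synthetic cohorts.

Used by the test suite to measure planted-effect recovery and the false
pairing rate under a null effect; exposed here so scripts can reuse the
exact same procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .cohort import filter_mutations
from .flux import compute_flux_sum_matrix
from .gem import default_currency, default_essential_amino_acids, split_compartment
from .pipeline import fit_cohort_fluxes
from .simulate import CohortSimSpec, PlantedEffect, ToyGEMSpec, generate_toy_gem, simulate_cohort
from .stats import predict_mgps

__all__ = ["run_planted_cohort", "recovery_benchmark"]

PLANTED_GENE = "G1_1"
PLANTED_PATHWAY = "pathway_1"


def run_planted_cohort(
    seed: int,
    multiplier: float = 5.0,
    n_samples: int = 40,
    n_mutant: int = 10,
    n_pathways: int = 4,
    reactions_per_pathway: int = 5,
    alpha: float = 0.05,
):
    """Simulate one cohort with a single planted pathway effect and run the
    full pipeline; returns (MGPResult, GroundTruth)."""
    model = generate_toy_gem(
        ToyGEMSpec(n_pathways=n_pathways,
                   reactions_per_pathway=reactions_per_pathway, seed=seed)
    )
    spec = CohortSimSpec(
        n_samples=n_samples,
        planted={PLANTED_GENE: PlantedEffect(
            pathway=PLANTED_PATHWAY, n_mutant=n_mutant,
            expression_multiplier=multiplier,
        )},
        seed=seed + 10_000,
    )
    expression, variants, _, truth = simulate_cohort(model, spec)
    states = fit_cohort_fluxes(model, expression)
    fsm = compute_flux_sum_matrix(model, states, exclude_currency=default_currency())
    from .stats import quantile_normalize

    norm = quantile_normalize(fsm)
    mutations = filter_mutations(variants, [str(s) for s in expression.index])
    result = predict_mgps(
        model, norm, mutations, alpha=alpha,
        essential_aa=default_essential_amino_acids(),
    )
    return result, truth


def recovery_benchmark(
    n_seeds: int = 50,
    multiplier: float = 5.0,
    seed0: int = 0,
    **kwargs,
) -> Dict[str, float]:
    """Fraction of seeds recovering the planted triple, plus the per-test
    metabolite-gene pairing rate (the false-positive rate when the
    multiplier is 1)."""
    recovered = 0
    pairs = 0
    tests = 0
    for seed in range(seed0, seed0 + n_seeds):
        result, truth = run_planted_cohort(seed, multiplier=multiplier, **kwargs)
        hits = {
            (split_compartment(r.metabolite)[0], r.gene, r.pathway)
            for r in result.mgps
        }
        if set(truth.triples) & hits:
            recovered += 1
        pairs += result.tallies["mg_pairs"]
        tests += (
            result.tallies["metabolites_tested"] * result.tallies["genes_tested"]
        )
    return {
        "recovery_rate": recovered / n_seeds,
        "pairing_rate": pairs / tests,
        "n_seeds": n_seeds,
        "n_pair_tests": tests,
    }
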