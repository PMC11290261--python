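"""Flux-sum normalization and MGP selection statistics.

Implements the downstream half of the workflow: quantile normalization with
zero restoration, metabolite-gene pairing by two-sided Wilcoxon rank-sum
tests, pathway-level testing of adjusted target flux-sums, modified Z-score
outlier selection with the |Z| > 3.5 threshold, and compartment-level
deduplication of metabolite-gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .flux import FluxSumMatrix
from .gem import MetabolicModel, classify_reaction, split_compartment

__all__ = [
    "NormalizedFluxSumMatrix",
    "MGPairCandidate",
    "MGPCandidate",
    "MGPRecord",
    "quantile_normalize",
    "wilcoxon_ranksum_p",
    "pair_metabolite_gene",
    "eligible_pathways",
    "pathway_significance",
    "modified_zscore",
    "select_mgps",
    "dedup_compartment_pairs",
    "predict_mgps",
    "mgps_to_frame",
]

#: 1 / Phi^-1(3/4); multiplies MAD into a consistent sigma estimate.
PHI_INV_34 = float(sps.norm.ppf(0.75))

EXACT_WILCOXON_MAX = 8


# ---------------------------------------------------------------------------
# Quantile normalization (columns = samples) with zero restoration
# ---------------------------------------------------------------------------

def _quantile_normalize_columns(A: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization; ties get the mean reference value
    over their rank positions."""
    n, m = A.shape
    order = np.argsort(A, axis=0, kind="mergesort")
    ref = np.take_along_axis(A, order, axis=0).mean(axis=1)
    out = np.empty_like(A, dtype=float)
    for j in range(m):
        col_order = order[:, j]
        sorted_vals = A[col_order, j]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            out[col_order[i : k + 1], j] = ref[i : k + 1].mean()
            i = k + 1
    return out


@dataclass
class NormalizedFluxSumMatrix:
    """Quantile-normalized flux-sums (``total``) and the proportionally
    adjusted pathway decomposition (``target``)."""

    total: pd.DataFrame
    target: pd.DataFrame


def quantile_normalize(matrix: FluxSumMatrix) -> NormalizedFluxSumMatrix:
    """Normalize flux-sums across a cohort, then restore exact zeros and
    rescale the pathway decomposition to preserve within-metabolite ratios.
    """
    if matrix.total.shape[0] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")

    original = matrix.total
    # columns of the normalized matrix are samples -> transpose in, out
    normalized = _quantile_normalize_columns(original.values.T.astype(float)).T
    normalized = pd.DataFrame(
        normalized, index=original.index, columns=original.columns
    )
    normalized[original == 0] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = normalized.values / original.values
    ratio[~np.isfinite(ratio)] = 0.0  # F_i = 0 -> all adjusted shares are 0
    ratio = pd.DataFrame(ratio, index=original.index, columns=original.columns)

    target = matrix.target.copy()
    for met, pathway in target.columns:
        target[(met, pathway)] = target[(met, pathway)] * ratio[met]
    return NormalizedFluxSumMatrix(total=normalized, target=target)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when both groups are small and tie-free,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and min(len(x), len(y)) <= EXACT_WILCOXON_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class MGPairCandidate:
    metabolite: str
    gene: str
    p_value: float
    n_mutant: int
    n_wildtype: int


def _split_groups(
    values: pd.Series, mutant_status: pd.Series
) -> Tuple[np.ndarray, np.ndarray]:
    common = values.index.intersection(mutant_status.index)
    values = values.loc[common]
    status = mutant_status.loc[common].astype(bool)
    return values[status].values, values[~status].values


def pair_metabolite_gene(
    norm: NormalizedFluxSumMatrix,
    mutations,
    gene: str,
    metabolite: str,
    alpha: float = 0.05,
) -> Optional[MGPairCandidate]:
    """Pair a metabolite with a gene when the normalized flux-sum differs
    between mutant and wild-type groups (two-sided Wilcoxon p < alpha)."""
    status = mutations.status
    if gene not in status.columns:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    if metabolite not in norm.total.columns:
        raise KeyError(f"metabolite {metabolite!r} not in flux-sum matrix")
    mut, wt = _split_groups(norm.total[metabolite], status[gene])
    if len(mut) < 3 or len(wt) < 3:
        raise ValueError(
            f"gene {gene!r}: need >=3 mutant and wild-type samples "
            f"(got {len(mut)}/{len(wt)})"
        )
    p = wilcoxon_ranksum_p(mut, wt)
    if p < alpha:
        return MGPairCandidate(
            metabolite=metabolite, gene=gene, p_value=p,
            n_mutant=len(mut), n_wildtype=len(wt),
        )
    return None


# ---------------------------------------------------------------------------
# Pathway-level testing
# ---------------------------------------------------------------------------

def eligible_pathways(
    model: MetabolicModel,
    met_id: str,
    essential_aa: FrozenSet[str] = frozenset(),
) -> FrozenSet[str]:
    """Pathways allowed to carry an MGP for this metabolite.

    A pathway qualifies through a reaction that touches the metabolite and is
    classified metabolic, or is a transport reaction when the metabolite is
    an essential amino acid.  Exchange/demand/unassigned reactions never
    qualify a pathway.
    """
    base = split_compartment(met_id)[0].lower()
    eligible = set()
    for rxn in model.reactions_involving(met_id):
        cls = classify_reaction(rxn, model)
        if cls == "metabolic" or (cls == "transport" and base in essential_aa):
            eligible.add(rxn.pathway)
    return frozenset(eligible)


def pathway_significance(
    norm: NormalizedFluxSumMatrix,
    mutations,
    candidate: MGPairCandidate,
    model: MetabolicModel,
    alpha: float = 0.05,
    essential_aa: FrozenSet[str] = frozenset(),
) -> List[Tuple[str, float]]:
    """Test each eligible producing pathway's adjusted target flux-sum between
    mutant and wild-type groups; return (pathway, p) with p < alpha.

    An empty result means the metabolite-gene pair is dropped.
    """
    allowed = eligible_pathways(model, candidate.metabolite, essential_aa)
    status = mutations.status[candidate.gene]
    out: List[Tuple[str, float]] = []
    met_cols = [
        c for c in norm.target.columns
        if c[0] == candidate.metabolite and c[1] in allowed
    ]
    for met, pathway in met_cols:
        mut, wt = _split_groups(norm.target[(met, pathway)], status)
        p = wilcoxon_ranksum_p(mut, wt)
        if p < alpha:
            out.append((pathway, p))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# Modified Z-score and final selection
# ---------------------------------------------------------------------------

def modified_zscore(values: Sequence[float]) -> np.ndarray:
    """Robust outlier score around the median.

    Uses MAD scaled by 1/Phi^-1(3/4); falls back to the mean absolute
    deviation scaled by sqrt(pi/2) when MAD is zero; all-constant input
    yields all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("modified_zscore requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("modified_zscore requires finite values")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad != 0:
        return dev / (mad / PHI_INV_34)
    mean_ad = np.mean(np.abs(dev))
    if mean_ad == 0:
        return np.zeros_like(x)
    return dev / (np.sqrt(np.pi / 2.0) * mean_ad)


@dataclass(frozen=True)
class MGPCandidate:
    """A (metabolite, gene, pathway) triple that survived steps 2-3."""

    metabolite: str
    gene: str
    pathway: str
    p_mg: float
    p_pathway: float
    mean_target_flux_sum: float


@dataclass(frozen=True)
class MGPRecord:
    metabolite: str
    gene: str
    pathway: str
    p_mg: float
    p_pathway: float
    mean_target_flux_sum: float
    modified_z: float
    selection_reason: str  # "z_threshold" | "small_group"


def select_mgps(
    candidates: Iterable[MGPCandidate],
    z_threshold: float = 3.5,
) -> List[MGPRecord]:
    """Within each (metabolite, pathway) group, flag genes whose mean target
    flux-sum is a modified-Z outlier; groups of fewer than three candidates
    are selected wholesale."""
    groups: Dict[Tuple[str, str], List[MGPCandidate]] = {}
    for cand in candidates:
        groups.setdefault((cand.metabolite, cand.pathway), []).append(cand)

    records: List[MGPRecord] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda c: c.gene)
        if len(members) < 3:
            for cand in members:
                records.append(
                    MGPRecord(
                        **vars(cand), modified_z=float("nan"),
                        selection_reason="small_group",
                    )
                )
            continue
        z = modified_zscore([c.mean_target_flux_sum for c in members])
        for cand, zk in zip(members, z):
            if abs(zk) > z_threshold:
                records.append(
                    MGPRecord(
                        **vars(cand), modified_z=float(zk),
                        selection_reason="z_threshold",
                    )
                )
    return records


def dedup_compartment_pairs(
    pairs: Iterable[MGPairCandidate],
) -> Tuple[int, Dict[Tuple[str, str], List[MGPairCandidate]]]:
    """Count unique (metabolite base id, gene) pairs; compartmented members
    are retained in the mapping."""
    mapping: Dict[Tuple[str, str], List[MGPairCandidate]] = {}
    for pair in pairs:
        key = (split_compartment(pair.metabolite)[0], pair.gene)
        mapping.setdefault(key, []).append(pair)
    return len(mapping), mapping


# ---------------------------------------------------------------------------
# Steps 2-4 wired together
# ---------------------------------------------------------------------------

@dataclass
class MGPResult:
    pairs: List[MGPairCandidate]
    candidates: List[MGPCandidate]
    mgps: List[MGPRecord]
    tallies: Dict[str, int]


def _mean_target_flux_sum(
    norm: NormalizedFluxSumMatrix,
    status: pd.Series,
    metabolite: str,
    pathway: str,
    scope: str,
) -> float:
    values = norm.target[(metabolite, pathway)]
    if scope == "mutant":
        common = values.index.intersection(status.index)
        values = values.loc[common][status.loc[common].astype(bool)]
    elif scope != "all":
        raise ValueError(f"unknown mean scope {scope!r}")
    return float(values.mean())


def predict_mgps(
    model: MetabolicModel,
    norm: NormalizedFluxSumMatrix,
    mutations,
    alpha: float = 0.05,
    z_threshold: float = 3.5,
    essential_aa: FrozenSet[str] = frozenset(),
    mean_scope: str = "mutant",
) -> MGPResult:
    """Run steps 2-4 over every (metabolite, gene) combination."""
    pairs: List[MGPairCandidate] = []
    candidates: List[MGPCandidate] = []
    genes = sorted(mutations.status.columns)
    metabolites = list(norm.total.columns)
    for gene in genes:
        for met in metabolites:
            pair = pair_metabolite_gene(norm, mutations, gene, met, alpha=alpha)
            if pair is None:
                continue
            pairs.append(pair)
            sig = pathway_significance(
                norm, mutations, pair, model, alpha=alpha, essential_aa=essential_aa
            )
            for pathway, p_path in sig:
                mean_f = _mean_target_flux_sum(
                    norm, mutations.status[gene], met, pathway, mean_scope
                )
                candidates.append(
                    MGPCandidate(
                        metabolite=met, gene=gene, pathway=pathway,
                        p_mg=pair.p_value, p_pathway=p_path,
                        mean_target_flux_sum=mean_f,
                    )
                )
    mgps = select_mgps(candidates, z_threshold=z_threshold)
    unique_pairs, _ = dedup_compartment_pairs(pairs)
    tallies = {
        "metabolites_tested": len(metabolites),
        "genes_tested": len(genes),
        "mg_pairs": len(pairs),
        "mg_pairs_unique": unique_pairs,
        "mgp_candidates": len(candidates),
        "mgps": len(mgps),
    }
    return MGPResult(pairs=pairs, candidates=candidates, mgps=mgps, tallies=tallies)


def mgps_to_frame(records: Sequence[MGPRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "metabolite_id": r.metabolite,
                "metabolite_base_id": split_compartment(r.metabolite)[0],
                "gene": r.gene,
                "pathway": r.pathway,
                "p_mg": r.p_mg,
                "p_pathway": r.p_pathway,
                "mean_target_flux_sum": r.mean_target_flux_sum,
                "modified_z": r.modified_z,
                "selection_reason": r.selection_reason,
            }
        )
    columns = [
        "metabolite_id", "metabolite_base_id", "gene", "pathway", "p_mg",
        "p_pathway", "mean_target_flux_sum", "modified_z", "selection_reason",
    ]
    return pd.DataFrame(rows, columns=columns)
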