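"""Expression-constrained flux prediction and flux-sum computation.

Per-sample fluxes are fitted by least-absolute-deviation (LAD): reversible
reactions are split into nonnegative forward/backward components, and the
summed magnitude of each GPR-bearing reaction is pulled toward its rescaled
expression score under the steady-state constraint ``S v = 0``.  Alternate
optima are resolved by a second LP stage minimizing total flux.

Flux-sums count production only: a reaction contributes ``S_ij * v_j`` to
metabolite ``i`` whenever that product is positive (realized direction, not
nominal direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem import CurrencySet, MetabolicModel, parse_gpr

__all__ = [
    "FluxFitError",
    "FluxState",
    "FluxSumMatrix",
    "map_expression_to_reactions",
    "fit_fluxes_lad",
    "compute_flux_sum",
    "compute_target_flux_sum",
    "compute_flux_sum_matrix",
    "read_expression_table",
]

STEADY_STATE_TOL = 1e-6
FLUX_ZERO_TOL = 1e-9


class FluxFitError(RuntimeError):
    """LAD flux fitting failed (infeasible or unbounded LP)."""


@dataclass
class FluxState:
    """Fluxes for one sample plus the attained LAD objective value."""

    fluxes: Dict[str, float]
    objective: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )
        df.to_csv(path, sep="\t", index=False)


def map_expression_to_reactions(
    profile: Mapping[str, float], model: MetabolicModel
) -> Dict[str, float]:
    """Score GPR-bearing reactions from a gene expression profile.

    AND nodes take the minimum of their operands (a complex is limited by its
    scarcest subunit); OR nodes sum (isozymes contribute additively).  Genes
    missing from the profile score 0.  Reactions without a GPR are absent
    from the result.
    """
    if not profile:
        raise ValueError("expression profile is empty")
    scores: Dict[str, float] = {}
    for rxn in model.reactions.values():
        expr = parse_gpr(rxn.gpr)
        if expr.empty:
            continue
        value = expr.evaluate(profile, and_op=min, or_op=sum, missing=0.0)
        scores[rxn.id] = float(value)
    return scores


def _split_bounds(lb: float, ub: float) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    # v = v+ - v-,  v+ in [max(lb,0), max(ub,0)],  v- in [max(-ub,0), max(-lb,0)]
    return (max(lb, 0.0), max(ub, 0.0)), (max(-ub, 0.0), max(-lb, 0.0))


def fit_fluxes_lad(
    model: MetabolicModel,
    rxn_expr: Mapping[str, float],
    scale_cap: float = 1000.0,
) -> FluxState:
    """Fit fluxes minimizing sum |u_j - e_j| over expression-scored reactions.

    ``u_j`` is the total magnitude (forward + backward component) of reaction
    j and ``e_j`` the expression score rescaled so its maximum equals
    ``scale_cap``.  Ties among alternate optima are broken by a second stage
    minimizing total flux sum.
    """
    if scale_cap <= 0:
        raise ValueError("scale_cap must be positive")
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    n = len(rxn_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}

    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for m, coef in model.reactions[rid].stoichiometry.items():
            S[met_index[m], j] = coef

    targets = sorted(set(rxn_expr) & set(rxn_ids))
    raw = np.array([max(float(rxn_expr[r]), 0.0) for r in targets])
    max_raw = raw.max() if len(raw) else 0.0
    e_hat = raw * (scale_cap / max_raw) if max_raw > 0 else np.zeros_like(raw)

    m_t = len(targets)
    # variables: [v+ (n), v- (n), d (m_t)]
    bounds: List[Tuple[float, float]] = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        bp, bm = _split_bounds(rxn.lower_bound, rxn.upper_bound)
        bounds.append(bp)
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        _, bm = _split_bounds(rxn.lower_bound, rxn.upper_bound)
        bounds.append(bm)
    bounds.extend([(0.0, None)] * m_t)

    A_eq = np.hstack([S, -S, np.zeros((S.shape[0], m_t))])
    b_eq = np.zeros(S.shape[0])

    target_pos = {r: k for k, r in enumerate(targets)}
    # |u_j - e_j| <= d_j  as two inequality rows per target
    A_ub = np.zeros((2 * m_t, 2 * n + m_t))
    b_ub = np.zeros(2 * m_t)
    for rid, k in target_pos.items():
        j = rxn_ids.index(rid)
        # u_j - d_j <= e_j
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + j] = 1.0
        A_ub[2 * k, 2 * n + k] = -1.0
        b_ub[2 * k] = e_hat[k]
        # -u_j - d_j <= -e_j
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + j] = -1.0
        A_ub[2 * k + 1, 2 * n + k] = -1.0
        b_ub[2 * k + 1] = -e_hat[k]

    c1 = np.zeros(2 * n + m_t)
    c1[2 * n:] = 1.0

    res1 = linprog(c1, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                   method="highs")
    if res1.status == 2:
        raise FluxFitError(f"LAD flux fit infeasible for model {model.id!r}")
    if res1.status == 3:
        raise FluxFitError(f"LAD flux fit unbounded for model {model.id!r}")
    if not res1.success:
        raise FluxFitError(
            f"LAD flux fit failed for model {model.id!r}: {res1.message}"
        )
    objective = float(res1.fun)

    # stage 2: among LAD optima, minimize total flux magnitude
    c2 = np.zeros(2 * n + m_t)
    c2[: 2 * n] = 1.0
    A_ub2 = np.vstack([A_ub, c1])
    b_ub2 = np.append(b_ub, objective + 1e-9 * (1.0 + abs(objective)))
    res2 = linprog(c2, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                   method="highs")
    if not res2.success:  # pragma: no cover - stage 1 succeeded, 2 should too
        raise FluxFitError(
            f"LAD tie-breaking stage failed for model {model.id!r}: {res2.message}"
        )

    x = res2.x
    v = x[:n] - x[n : 2 * n]
    v[np.abs(v) < FLUX_ZERO_TOL] = 0.0
    # clip LP round-off back into bounds, then assert the contracts
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        v[j] = min(max(v[j], rxn.lower_bound), rxn.upper_bound)
    residual = np.abs(S @ v).max() if n else 0.0
    if residual > STEADY_STATE_TOL:
        raise FluxFitError(
            f"steady-state violation {residual:.3e} for model {model.id!r}"
        )
    return FluxState(fluxes=dict(zip(rxn_ids, v.tolist())), objective=objective)


# ---------------------------------------------------------------------------
# Flux-sums
# ---------------------------------------------------------------------------

def _producing_contributions(
    model: MetabolicModel, flux: FluxState, met_id: str
) -> Iterable[Tuple[str, float]]:
    if met_id not in model.metabolites:
        raise KeyError(f"unknown metabolite {met_id!r}")
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(met_id)
        if coef is None:
            continue
        contribution = coef * flux.fluxes.get(rxn.id, 0.0)
        if contribution > 0:
            yield rxn.id, contribution


def compute_flux_sum(model: MetabolicModel, flux: FluxState, met_id: str) -> float:
    """Total production of the metabolite: sum of positive ``S_ij v_j``."""
    return float(sum(c for _, c in _producing_contributions(model, flux, met_id)))


def compute_target_flux_sum(
    model: MetabolicModel, flux: FluxState, met_id: str
) -> Dict[str, float]:
    """Production of the metabolite grouped by producing reaction's pathway."""
    out: Dict[str, float] = {}
    for rid, contribution in _producing_contributions(model, flux, met_id):
        pathway = model.reactions[rid].pathway
        out[pathway] = out.get(pathway, 0.0) + contribution
    return out


@dataclass
class FluxSumMatrix:
    """Flux-sums for a cohort.

    ``total``: samples x metabolite ids.  ``target``: samples x MultiIndex
    (metabolite, pathway) columns, holding pathway-decomposed production.
    """

    total: pd.DataFrame
    target: pd.DataFrame

    @property
    def samples(self) -> List[str]:
        return list(self.total.index)

    @property
    def metabolites(self) -> List[str]:
        return list(self.total.columns)


def compute_flux_sum_matrix(
    model: MetabolicModel,
    flux_states: Mapping[str, FluxState],
    metabolites: Optional[Sequence[str]] = None,
    exclude_currency: Optional[CurrencySet] = None,
) -> FluxSumMatrix:
    """Flux-sums and pathway decomposition for every sample in a cohort."""
    if metabolites is None:
        metabolites = sorted(model.metabolites)
    if exclude_currency is not None:
        metabolites = [m for m in metabolites if m not in exclude_currency]
    samples = list(flux_states)

    total = pd.DataFrame(0.0, index=samples, columns=list(metabolites))
    per_sample: Dict[str, Dict[Tuple[str, str], float]] = {}
    keys: set = set()
    for sample, state in flux_states.items():
        row: Dict[Tuple[str, str], float] = {}
        for met in metabolites:
            parts = compute_target_flux_sum(model, state, met)
            total.loc[sample, met] = sum(parts.values())
            for pathway, value in parts.items():
                row[(met, pathway)] = value
                keys.add((met, pathway))
        per_sample[sample] = row

    columns = pd.MultiIndex.from_tuples(
        sorted(keys), names=["metabolite", "pathway"]
    ) if keys else pd.MultiIndex.from_tuples([], names=["metabolite", "pathway"])
    target = pd.DataFrame(0.0, index=samples, columns=columns)
    for sample, row in per_sample.items():
        for key, value in row.items():
            target.loc[sample, key] = value
    return FluxSumMatrix(total=total, target=target)


def read_expression_table(path, model: MetabolicModel) -> pd.DataFrame:
    """Read a TSV expression table, auto-detecting orientation.

    Returns samples x genes.  Orientation is decided by matching row/column
    labels against the model's gene ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = set(model.genes)
    col_hits = len(genes & set(df.columns))
    row_hits = len(genes & set(df.index))
    if row_hits > col_hits:
        df = df.T
    elif col_hits == 0 and row_hits == 0:
        raise ValueError(
            f"expression table {path!s} shares no gene ids with the model"
        )
    if (df.values < 0).any():
        raise ValueError(f"expression table {path!s} contains negative values")
    return df
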