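"""Cohort preprocessing: somatic-mutation filter cascade and the
metabolome validation arm (peak filtering, KNN imputation, normalization,
ROC-AUC, empirical significance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "MutationMatrix",
    "MetabolomeMatrix",
    "AUCResult",
    "read_variant_table",
    "filter_mutations",
    "apply_gene_groups",
    "read_metabolome",
    "filter_peaks",
    "knn_impute",
    "normalize_metabolome",
    "compute_auc",
    "empirical_pvalue",
]

CONSEQUENCE_CLASSES = ("synonymous", "nonsynonymous", "other")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Per-sample somatic variants: (sample, gene, alt_reads, consequence)."""

    frame: pd.DataFrame  # columns: sample, gene, alt_reads, consequence

    def __post_init__(self) -> None:
        required = {"sample", "gene", "alt_reads", "consequence"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if (self.frame["alt_reads"] < 0).any():
            raise ValueError("alt_reads must be nonnegative")


@dataclass
class MutationMatrix:
    """Binary sample x gene mutation status after the filter cascade."""

    status: pd.DataFrame  # bool, samples x genes
    tally: Dict[str, int] = field(default_factory=dict)

    @property
    def n_mutant(self) -> pd.Series:
        return self.status.sum(axis=0).astype(int)

    @property
    def n_wildtype(self) -> pd.Series:
        return (~self.status).sum(axis=0).astype(int)


def read_variant_table(path) -> VariantTable:
    """Read a MAF-like TSV with columns sample, gene, t_alt_count/alt_reads,
    consequence."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"t_alt_count": "alt_reads"})
    return VariantTable(df[["sample", "gene", "alt_reads", "consequence"]].copy())


def filter_mutations(
    table: VariantTable,
    cohort: Sequence[str],
    min_alt_reads: int = 7,
    min_group: int = 3,
    drop_subset_genes: bool = True,
) -> MutationMatrix:
    """Apply the mutation filter cascade and binarize.

    Row-level: variants outside the cohort are ignored with a warning;
    variants with fewer than ``min_alt_reads`` alternative reads and
    synonymous variants are dropped.  Gene-level: genes mutant in fewer than
    ``min_group`` samples, wild-type in fewer than ``min_group`` samples, or
    whose mutant-sample set is a strict subset of a larger retained gene's
    are dropped.  The tally reports rows removed per rule.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cohort = list(dict.fromkeys(cohort))
    df = table.frame.copy()
    tally: Dict[str, int] = {"rows_in": len(df)}

    outside = ~df["sample"].isin(cohort)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} variant rows reference samples outside the "
            "cohort and were ignored",
            stacklevel=2,
        )
    tally["dropped_not_in_cohort"] = int(outside.sum())
    df = df[~outside]

    low_reads = df["alt_reads"] < min_alt_reads
    tally["dropped_low_alt_reads"] = int(low_reads.sum())
    df = df[~low_reads]

    synonymous = df["consequence"] == "synonymous"
    tally["dropped_synonymous"] = int(synonymous.sum())
    df = df[~synonymous]

    mutant_sets: Dict[str, frozenset] = {
        gene: frozenset(sub["sample"]) for gene, sub in df.groupby("gene")
    }
    n = len(cohort)
    few_mutant = {g for g, s in mutant_sets.items() if len(s) < min_group}
    few_wildtype = {g for g, s in mutant_sets.items() if n - len(s) < min_group}
    tally["dropped_gene_few_mutant"] = int(
        df["gene"].isin(few_mutant - few_wildtype).sum()
    )
    tally["dropped_gene_few_wildtype"] = int(df["gene"].isin(few_wildtype).sum())
    df = df[~df["gene"].isin(few_mutant | few_wildtype)]
    for g in few_mutant | few_wildtype:
        del mutant_sets[g]

    dropped_subset: set = set()
    if drop_subset_genes:
        # larger mutant set wins; ties broken lexicographically
        order = sorted(mutant_sets, key=lambda g: (-len(mutant_sets[g]), g))
        kept: List[str] = []
        for gene in order:
            s = mutant_sets[gene]
            if any(s < mutant_sets[other] for other in kept):
                dropped_subset.add(gene)
            else:
                kept.append(gene)
    tally["dropped_gene_subset"] = int(df["gene"].isin(dropped_subset).sum())
    df = df[~df["gene"].isin(dropped_subset)]
    tally["rows_kept"] = len(df)

    genes = sorted(set(df["gene"]))
    status = pd.DataFrame(False, index=cohort, columns=genes)
    for gene, sub in df.groupby("gene"):
        status.loc[sorted(set(sub["sample"])), gene] = True
    return MutationMatrix(status=status, tally=tally)


def apply_gene_groups(
    matrix: MutationMatrix, groups: Mapping[str, Sequence[str]]
) -> MutationMatrix:
    """Add merged mutation-status columns: a sample is group-mutant if mutant
    for any member gene (e.g. IDH = IDH1 | IDH2)."""
    status = matrix.status.copy()
    for group, members in groups.items():
        present = [g for g in members if g in status.columns]
        if not present:
            continue
        status[group] = status[present].any(axis=1)
    return MutationMatrix(status=status, tally=dict(matrix.tally))


def read_gene_groups(path) -> Dict[str, List[str]]:
    """Two-column TSV (group, gene) -> {group: [genes]}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["group", "gene"],
                     comment="#")
    return {g: sorted(sub["gene"]) for g, sub in df.groupby("group")}


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------

@dataclass
class MetabolomeMatrix:
    """Peaks x samples relative quantities (NaN = missing) plus per-peak
    annotations (name, mode, flags)."""

    data: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.annotations.index):
            raise ValueError("data and annotations must share the peak index")

    @property
    def n_peaks(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=1)


def read_metabolome(path, sample_columns: Optional[Sequence[str]] = None,
                    sep: Optional[str] = None) -> MetabolomeMatrix:
    """Read a peaks x samples table with leading annotation columns.

    If ``sample_columns`` is not given, a column counts as a sample when its
    values are all numeric or blank.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if sample_columns is None:
        sample_columns = []
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.notna().sum() == df[col].notna().sum():
                sample_columns.append(col)
    data = df[list(sample_columns)].apply(pd.to_numeric, errors="coerce")
    annotations = df.drop(columns=list(sample_columns))
    return MetabolomeMatrix(data=data, annotations=annotations)


def filter_peaks(
    matrix: MetabolomeMatrix, max_missing_frac: float = 0.20
) -> MetabolomeMatrix:
    """Drop peaks missing in strictly more than ``max_missing_frac`` of
    samples."""
    keep = matrix.missing_fraction() <= max_missing_frac
    return MetabolomeMatrix(
        data=matrix.data.loc[keep].copy(),
        annotations=matrix.annotations.loc[keep].copy(),
    )


def knn_impute(matrix: MetabolomeMatrix, k: int = 10) -> MetabolomeMatrix:
    """Feature-wise KNN imputation.

    Each missing entry is replaced by the unweighted mean of the values, in
    the same sample, of the ``k`` nearest peaks — nearness measured by
    root-mean-square difference over co-observed samples.  Observed entries
    are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.data.values.astype(float)
    n_peaks, n_samples = X.shape
    observed = ~np.isnan(X)
    if not observed.any(axis=1).all():
        bad = matrix.data.index[~observed.any(axis=1)].tolist()
        raise ValueError(
            f"peaks with no observed values (run filter_peaks first): {bad}"
        )
    out = X.copy()
    for i in range(n_peaks):
        missing_cols = np.flatnonzero(~observed[i])
        if len(missing_cols) == 0:
            continue
        # RMS distance to every other peak over co-observed samples
        dists = np.full(n_peaks, np.inf)
        for q in range(n_peaks):
            if q == i:
                continue
            shared = observed[i] & observed[q]
            if not shared.any():
                continue
            diff = X[i, shared] - X[q, shared]
            dists[q] = float(np.sqrt(np.mean(diff ** 2)))
        for s in missing_cols:
            donors = np.flatnonzero(np.isfinite(dists) & observed[:, s])
            if len(donors) == 0:
                raise ValueError(
                    f"no donor peaks available to impute peak "
                    f"{matrix.data.index[i]!r} in sample {matrix.data.columns[s]!r}"
                )
            if len(donors) < k:
                warnings.warn(
                    f"only {len(donors)} donor peaks for peak "
                    f"{matrix.data.index[i]!r} (k={k}); using all",
                    stacklevel=2,
                )
            chosen = donors[np.argsort(dists[donors], kind="mergesort")[:k]]
            out[i, s] = float(np.mean(X[chosen, s]))
    return MetabolomeMatrix(
        data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        annotations=matrix.annotations.copy(),
    )


def _glog(x: np.ndarray, lam: float) -> np.ndarray:
    return np.log2((x + np.sqrt(x ** 2 + lam ** 2)) / 2.0)


def normalize_metabolome(
    matrix: MetabolomeMatrix, glog_lambda: float = 1.0
) -> MetabolomeMatrix:
    """Sample-sum normalization, generalized-log transform, autoscaling.

    Each sample column is divided by its total; values are rescaled by the
    global minimum positive value before the glog transform so the default
    lambda of 1 sits on the data scale; each peak is then mean-centered and
    divided by its standard deviation (ddof=1).
    """
    X = matrix.data.values.astype(float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run knn_impute first")
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        bad = [c for c, t in zip(matrix.data.columns, totals) if t <= 0]
        raise ValueError(f"nonpositive sample totals for: {bad}")
    X = X / totals

    positive = X[X > 0]
    if positive.size:
        X = X / positive.min()
    X = _glog(X, glog_lambda)

    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = matrix.data.index[np.flatnonzero(sd[:, 0] == 0)].tolist()
        raise ValueError(f"constant peaks cannot be autoscaled: {bad}")
    X = (X - mean) / sd
    return MetabolomeMatrix(
        data=pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns),
        annotations=matrix.annotations.copy(),
    )


# ---------------------------------------------------------------------------
# ROC-AUC and empirical significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCResult:
    metabolite: str
    gene: str
    auc: float
    n_mutant: int
    n_wildtype: int


def compute_auc(
    values: Sequence[float],
    status: Sequence[bool],
    metabolite: str = "",
    gene: str = "",
) -> AUCResult:
    """Direction-agnostic ROC AUC by pairwise comparison (ties count 1/2)."""
    values = np.asarray(values, dtype=float)
    status = np.asarray(status, dtype=bool)
    if values.shape != status.shape:
        raise ValueError("values and status must align")
    mut = values[status]
    wt = values[~status]
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("both mutant and wild-type groups must be non-empty")
    wins = (mut[:, None] > wt[None, :]).sum()
    ties = (mut[:, None] == wt[None, :]).sum()
    a = (wins + 0.5 * ties) / (len(mut) * len(wt))
    return AUCResult(
        metabolite=metabolite, gene=gene, auc=float(max(a, 1.0 - a)),
        n_mutant=len(mut), n_wildtype=len(wt),
    )


def empirical_pvalue(
    observed_hits: int,
    n_pairs: int,
    pool: Sequence[float],
    threshold: float = 0.7,
    n_resamples: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """P(resampled hit count >= observed) when drawing ``n_pairs`` AUC values
    without replacement from the pool, with +1/(N+1) smoothing."""
    pool = np.asarray(
        [p.auc if isinstance(p, AUCResult) else float(p) for p in pool], dtype=float
    )
    if len(pool) < n_pairs:
        raise ValueError(
            f"pool of {len(pool)} AUCs is smaller than n_pairs={n_pairs}"
        )
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000")
    rng = np.random.default_rng(seed)
    above = pool > threshold
    # draw-without-replacement via random keys; argpartition picks n_pairs
    keys = rng.random((n_resamples, len(pool)))
    picked = np.argpartition(keys, n_pairs - 1, axis=1)[:, :n_pairs]
    hits = above[picked].sum(axis=1)
    count = int((hits >= observed_hits).sum())
    return (count + 1.0) / (n_resamples + 1.0)
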