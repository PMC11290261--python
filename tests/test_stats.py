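import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mgpflux.cohort import MutationMatrix
from mgpflux.flux import FluxSumMatrix
from mgpflux.gem import MetabolicModel, Metabolite, Reaction
from mgpflux.stats import (
    MGPCandidate,
    MGPairCandidate,
    dedup_compartment_pairs,
    modified_zscore,
    pair_metabolite_gene,
    pathway_significance,
    quantile_normalize,
    select_mgps,
    wilcoxon_ranksum_p,
)


def enumeration_ranksum_p(x, y):
    """Independent oracle: full enumeration of the rank-sum null."""
    pooled = np.concatenate([x, y])
    n, k = len(pooled), len(x)
    ranks = rankdata(pooled)
    obs = ranks[:k].sum()
    stats = np.array([
        ranks[list(idx)].sum() for idx in itertools.combinations(range(n), k)
    ])
    p = 2 * min((stats <= obs).mean(), (stats >= obs).mean())
    return min(p, 1.0)


def make_fsm(total, target=None):
    total = pd.DataFrame(total)
    if target is None:
        target = pd.DataFrame(
            index=total.index,
            columns=pd.MultiIndex.from_tuples([], names=["metabolite", "pathway"]),
        )
    return FluxSumMatrix(total=total, target=target)


class TestQuantileNormalize:
    def test_rank_mean_hand_example(self):
        # two samples [1,2,3] and [4,5,6] -> both [2.5, 3.5, 4.5]
        fsm = make_fsm(pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["s1", "s2"], columns=["a_c", "b_c", "c_c"],
        ))
        norm = quantile_normalize(fsm)
        assert np.allclose(norm.total.loc["s1"], [2.5, 3.5, 4.5])
        assert np.allclose(norm.total.loc["s2"], [2.5, 3.5, 4.5])

    def test_identical_samples_fixed_point(self):
        row = [3.0, 1.0, 2.0]
        fsm = make_fsm(pd.DataFrame([row, row], index=["s1", "s2"],
                                    columns=["a", "b", "c"]))
        norm = quantile_normalize(fsm)
        assert np.allclose(norm.total.values, [row, row])

    def test_zero_restoration(self):
        fsm = make_fsm(pd.DataFrame(
            [[0.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["s1", "s2"], columns=["a", "b", "c"],
        ))
        norm = quantile_normalize(fsm)
        assert norm.total.loc["s1", "a"] == 0.0

    def test_columns_identical_after_normalization(self):
        rng = np.random.default_rng(0)
        fsm = make_fsm(pd.DataFrame(
            rng.uniform(0.1, 10, size=(5, 8)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"m{i}" for i in range(8)],
        ))
        norm = quantile_normalize(fsm)
        sorted_rows = np.sort(norm.total.values, axis=1)
        for i in range(1, 5):
            assert np.allclose(sorted_rows[i], sorted_rows[0])

    def test_adjusted_target_preserves_ratio_and_conserves(self):
        total = pd.DataFrame([[4.0, 1.0], [2.0, 8.0]], index=["s1", "s2"],
                             columns=["m", "n"])
        target = pd.DataFrame(
            {("m", "P1"): [3.0, 0.5], ("m", "P2"): [1.0, 1.5]},
            index=["s1", "s2"],
        )
        target.columns = pd.MultiIndex.from_tuples(target.columns,
                                                   names=["metabolite", "pathway"])
        norm = quantile_normalize(FluxSumMatrix(total=total, target=target))
        for s in ["s1", "s2"]:
            f_star = norm.total.loc[s, "m"]
            parts = [norm.target.loc[s, ("m", p)] for p in ("P1", "P2")]
            assert sum(parts) == pytest.approx(f_star, rel=1e-9)
            # ratio preserved
            orig = [target.loc[s, ("m", p)] for p in ("P1", "P2")]
            assert parts[0] * orig[1] == pytest.approx(parts[1] * orig[0], rel=1e-9)

    def test_zero_total_zeroes_adjusted_target(self):
        total = pd.DataFrame([[0.0, 1.0], [2.0, 3.0]], index=["s1", "s2"],
                             columns=["m", "n"])
        target = pd.DataFrame({("m", "P1"): [0.0, 2.0]}, index=["s1", "s2"])
        target.columns = pd.MultiIndex.from_tuples(target.columns,
                                                   names=["metabolite", "pathway"])
        norm = quantile_normalize(FluxSumMatrix(total=total, target=target))
        assert norm.target.loc["s1", ("m", "P1")] == 0.0

    def test_single_sample_rejected(self):
        fsm = make_fsm(pd.DataFrame([[1.0, 2.0]], index=["s1"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            quantile_normalize(fsm)


class TestWilcoxon:
    def test_exact_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(1)
        for n1 in range(2, 5):
            for n2 in range(2, 5):
                for _ in range(20):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    assert wilcoxon_ranksum_p(x, y) == pytest.approx(
                        enumeration_ranksum_p(x, y), abs=1e-12
                    )

    def test_worked_example_3v3(self):
        assert wilcoxon_ranksum_p([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)

    def test_worked_example_4v4(self):
        assert wilcoxon_ranksum_p([10, 11, 12, 13], [1, 2, 3, 4]) == pytest.approx(
            2 / 70
        )

    def test_identical_groups_p_one(self):
        assert wilcoxon_ranksum_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(
            1.0
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum_p([], [1.0])


def make_norm_and_mutations(wt_values, mut_values, metabolite="m_c"):
    from mgpflux.stats import NormalizedFluxSumMatrix

    samples = [f"w{i}" for i in range(len(wt_values))] + [
        f"m{i}" for i in range(len(mut_values))
    ]
    total = pd.DataFrame({metabolite: list(wt_values) + list(mut_values)},
                         index=samples)
    target = pd.DataFrame(
        index=total.index,
        columns=pd.MultiIndex.from_tuples([], names=["metabolite", "pathway"]),
    )
    norm = NormalizedFluxSumMatrix(total=total, target=target)
    status = pd.DataFrame(
        {"GENE": [False] * len(wt_values) + [True] * len(mut_values)}, index=samples
    )
    return norm, MutationMatrix(status=status)


class TestPairing:
    def test_3v3_separated_not_significant(self):
        norm, muts = make_norm_and_mutations([1, 2, 3], [10, 11, 12])
        assert pair_metabolite_gene(norm, muts, "GENE", "m_c") is None

    def test_4v4_separated_significant(self):
        norm, muts = make_norm_and_mutations([1, 2, 3, 4], [10, 11, 12, 13])
        pair = pair_metabolite_gene(norm, muts, "GENE", "m_c")
        assert pair is not None
        assert pair.p_value == pytest.approx(2 / 70)
        assert (pair.n_mutant, pair.n_wildtype) == (4, 4)

    def test_identical_groups_no_candidate(self):
        norm, muts = make_norm_and_mutations([1, 2, 3], [1, 2, 3])
        assert pair_metabolite_gene(norm, muts, "GENE", "m_c") is None

    def test_unknown_gene_raises(self):
        norm, muts = make_norm_and_mutations([1, 2, 3], [4, 5, 6])
        with pytest.raises(KeyError):
            pair_metabolite_gene(norm, muts, "NOPE", "m_c")

    def test_small_groups_rejected(self):
        norm, muts = make_norm_and_mutations([1, 2, 3, 4], [5, 6])
        with pytest.raises(ValueError):
            pair_metabolite_gene(norm, muts, "GENE", "m_c")


class TestModifiedZ:
    def test_hand_example_mad_branch(self):
        z = modified_zscore([1, 2, 3, 4, 5])
        assert z[-1] == pytest.approx(1.3490, abs=1e-3)

    def test_hand_example_meanad_branch(self):
        z = modified_zscore([1, 1, 1, 1, 10])
        assert z[-1] == pytest.approx(3.9899, abs=1e-3)

    def test_constant_input_all_zero(self):
        assert np.all(modified_zscore([7.0, 7.0, 7.0]) == 0.0)

    def test_shift_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 12))
            a = float(rng.uniform(0.1, 10))
            b = float(rng.normal())
            assert np.allclose(modified_zscore(a * x + b), modified_zscore(x),
                               atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modified_zscore([])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            modified_zscore([1.0, np.nan])


def cand(met, gene, pathway, mean):
    return MGPCandidate(metabolite=met, gene=gene, pathway=pathway,
                        p_mg=0.01, p_pathway=0.01, mean_target_flux_sum=mean)


class TestSelectMGPs:
    def test_small_group_selected_wholesale(self):
        records = select_mgps([cand("m_c", "G1", "P", 1.0),
                               cand("m_c", "G2", "P", 2.0)])
        assert len(records) == 2
        assert all(r.selection_reason == "small_group" for r in records)

    def test_planted_outliers_recovered(self):
        # mirrors the two-outliers-among-42 shape
        rng = np.random.default_rng(3)
        means = rng.normal(10.0, 0.5, size=40).tolist() + [100.0, 120.0]
        cands = [cand("m_c", f"G{i}", "P", mu) for i, mu in enumerate(means)]
        records = select_mgps(cands)
        assert {r.gene for r in records} == {"G40", "G41"}
        assert all(r.selection_reason == "z_threshold" for r in records)

    def test_near_identical_group_selects_none(self):
        rng = np.random.default_rng(4)
        cands = [cand("m_c", f"G{i}", "P", 5.0 + rng.normal(0, 1e-6))
                 for i in range(10)]
        assert select_mgps(cands) == []

    def test_groups_are_per_metabolite_pathway(self):
        cands = [cand("m_c", "G1", "P1", 1.0), cand("m_c", "G2", "P2", 2.0)]
        records = select_mgps(cands)
        assert len(records) == 2  # two singleton groups


class TestDedup:
    def _pair(self, met, gene):
        return MGPairCandidate(metabolite=met, gene=gene, p_value=0.01,
                               n_mutant=3, n_wildtype=3)

    def test_compartments_merge(self):
        count, mapping = dedup_compartment_pairs(
            [self._pair("akg_c", "IDH1"), self._pair("akg_m", "IDH1")]
        )
        assert count == 1
        assert len(mapping[("akg", "IDH1")]) == 2

    def test_distinct_bases_kept(self):
        count, _ = dedup_compartment_pairs(
            [self._pair("akg_c", "IDH1"), self._pair("cit_c", "IDH1")]
        )
        assert count == 2

    def test_empty(self):
        assert dedup_compartment_pairs([]) == (0, {})


class TestPathwaySignificance:
    def _model_two_pathways(self):
        mets = {m: Metabolite(m, compartment=m.rsplit("_", 1)[1])
                for m in ["a_c", "b_c", "m_c", "m_e"]}
        rxns = {
            "R1": Reaction("R1", {"a_c": -1.0, "m_c": 1.0}, 0.0, 100.0, pathway="P1"),
            "R2": Reaction("R2", {"b_c": -1.0, "m_c": 1.0}, 0.0, 100.0, pathway="P2"),
            "T": Reaction("T", {"m_c": -1.0, "m_e": 1.0}, 0.0, 100.0,
                          pathway="Transport"),
        }
        return MetabolicModel("m", mets, rxns)

    def _norm(self, p1_mut_shift):
        from mgpflux.stats import NormalizedFluxSumMatrix

        rng = np.random.default_rng(5)
        n = 16
        samples = [f"s{i}" for i in range(n)]
        mutant = np.array([i < 6 for i in range(n)])
        p1 = rng.normal(10, 0.5, size=n) + np.where(mutant, p1_mut_shift, 0.0)
        p2 = rng.normal(10, 0.5, size=n)
        total = pd.DataFrame({"m_c": p1 + p2}, index=samples)
        target = pd.DataFrame({("m_c", "P1"): p1, ("m_c", "P2"): p2}, index=samples)
        target.columns = pd.MultiIndex.from_tuples(
            target.columns, names=["metabolite", "pathway"]
        )
        norm = NormalizedFluxSumMatrix(total=total, target=target)
        status = pd.DataFrame({"G": mutant}, index=samples)
        return norm, MutationMatrix(status=pd.DataFrame(status))

    def _candidate(self):
        return MGPairCandidate(metabolite="m_c", gene="G", p_value=0.01,
                               n_mutant=6, n_wildtype=10)

    def test_planted_pathway_significant_other_not(self):
        model = self._model_two_pathways()
        norm, muts = self._norm(p1_mut_shift=10.0)
        sig = pathway_significance(norm, muts, self._candidate(), model)
        assert [p for p, _ in sig] == ["P1"]

    def test_no_pathway_significant_drops_pair(self):
        model = self._model_two_pathways()
        norm, muts = self._norm(p1_mut_shift=0.0)
        assert pathway_significance(norm, muts, self._candidate(), model) == []

    def test_transport_pathway_excluded_without_eaa(self):
        from mgpflux.stats import NormalizedFluxSumMatrix

        model = self._model_two_pathways()
        rng = np.random.default_rng(6)
        n = 16
        samples = [f"s{i}" for i in range(n)]
        mutant = np.array([i < 6 for i in range(n)])
        # production through the transport reaction only (m_e side)
        te = rng.normal(10, 0.5, size=n) + np.where(mutant, 10.0, 0.0)
        total = pd.DataFrame({"m_e": te}, index=samples)
        target = pd.DataFrame({("m_e", "Transport"): te}, index=samples)
        target.columns = pd.MultiIndex.from_tuples(
            target.columns, names=["metabolite", "pathway"]
        )
        norm = NormalizedFluxSumMatrix(total=total, target=target)
        muts = MutationMatrix(status=pd.DataFrame({"G": mutant}, index=samples))
        pair = MGPairCandidate(metabolite="m_e", gene="G", p_value=0.01,
                               n_mutant=6, n_wildtype=10)
        assert pathway_significance(norm, muts, pair, model) == []
        # essential amino acids get the transport exception
        sig = pathway_significance(norm, muts, pair, model,
                                   essential_aa=frozenset({"m"}))
        assert [p for p, _ in sig] == ["Transport"]
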