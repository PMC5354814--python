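"""KS enrichment, connectivity scores, permutation FDR, hit selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ranking_from_order
from ewsrepo import SynConfig, syndata
from ewsrepo.connectivity import (HitList, connectivity_score, ks_enrichment,
                                  merge_hits, score_database, select_hits)
from ewsrepo.signatures import GeneSignature


def ks_oracle(positions, n):
    """Sup-deviation of the running enrichment curve, walked position by
    position — an independent route to the same statistic."""
    pos = set(int(p) for p in positions)
    t = len(pos)
    best_top = -np.inf
    best_bottom = -np.inf
    seen = 0
    for i in range(1, n + 1):
        if i in pos:
            before = seen
            seen += 1
            best_top = max(best_top, seen / t - i / n)
            best_bottom = max(best_bottom, i / n - before / t)
    return best_top if best_top >= best_bottom else -best_bottom


class TestKSEnrichment:
    def test_hand_worked_case(self):
        # n=6, t=2, positions {1,6}: a = 1/3, b = 1/2 -> statistic -1/2
        assert ks_enrichment([1, 6], 6) == pytest.approx(-0.5)

    @pytest.mark.parametrize("n,t", [(10, 2), (100, 7), (2000, 50)])
    def test_extreme_placements(self, n, t):
        top = ks_enrichment(np.arange(1, t + 1), n)
        bottom = ks_enrichment(np.arange(n - t + 1, n + 1), n)
        assert top == pytest.approx(1 - t / n)
        # the classic statistic is slightly asymmetric: the bottom-packed
        # set scores -(1 - (t-1)/n), the sup being reached at its first gene
        assert bottom == pytest.approx(-(1 - (t - 1) / n))

    def test_degenerate_sets(self):
        with pytest.raises(ValueError, match="empty"):
            ks_enrichment([], 5)
        assert ks_enrichment([1, 2, 3], 3) == 0.0

    def test_exhaustive_position_subsets_match_oracle(self):
        # the statistic depends on a ranking only through the occupied
        # positions, so this exhausts every permutation for n <= 8, t <= 3
        for n in range(2, 9):
            for t in (1, 2, 3):
                if t >= n:
                    continue
                for comb in itertools.combinations(range(1, n + 1), t):
                    got = ks_enrichment(comb, n)
                    assert got == pytest.approx(ks_oracle(comb, n)), (n, comb)

    def test_all_720_permutations_through_gene_lookup(self):
        genes = [f"G{i}" for i in range(6)]
        gene_set = ["G0", "G1"]
        for perm in itertools.permutations(genes):
            ranking = ranking_from_order(perm)
            positions = ranking.loc[gene_set].to_numpy()
            assert ks_enrichment(positions, 6) == pytest.approx(
                ks_oracle(positions, 6))


class TestConnectivityScore:
    def _sig(self):
        return GeneSignature(["G0", "G1"], ["G8", "G9"])

    def test_perfect_reversal_and_mimicry(self):
        genes = [f"G{i}" for i in range(10)]
        # reversal: down-genes at top, up-genes at bottom
        rev = ranking_from_order(["G8", "G9"] + genes[2:8] + ["G0", "G1"])
        mim = ranking_from_order(["G0", "G1"] + genes[2:8] + ["G8", "G9"])
        t, n = 2, 10
        expected = ((1 - t / n) + (1 - (t - 1) / n)) / 2
        assert connectivity_score(self._sig(), rev) == pytest.approx(-expected)
        assert connectivity_score(self._sig(), mim) == pytest.approx(expected)

    def test_same_sign_halves_zero_out(self):
        # both up and down sets at the top -> incoherent, score 0
        genes = [f"G{i}" for i in range(10)]
        ranking = ranking_from_order(["G0", "G8", "G1", "G9"]
                                     + [g for g in genes if g not in
                                        ("G0", "G1", "G8", "G9")])
        assert connectivity_score(self._sig(), ranking) == 0.0

    def test_antisymmetric_under_direction_swap(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(40)]
        sig = GeneSignature(genes[:5], genes[5:10])
        for _ in range(20):
            ranking = ranking_from_order(rng.permutation(genes))
            s = connectivity_score(sig, ranking)
            assert connectivity_score(sig.swapped(), ranking) == pytest.approx(-s)

    def test_invariant_to_nonsignature_relabeling(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        sig = GeneSignature(genes[:4], genes[4:8])
        order = list(rng.permutation(genes))
        s = connectivity_score(sig, ranking_from_order(order))
        relabel = {g: (g if g in sig.up + sig.down else f"X{g}") for g in genes}
        s2 = connectivity_score(sig, ranking_from_order([relabel[g] for g in order]))
        assert s2 == pytest.approx(s)


class TestScoreDatabase:
    def test_planted_reversers_dominate_and_reach_fdr(self, syn_small,
                                                      disease_sig, drug_db):
        res = score_database(disease_sig, drug_db, n_perm=500, seed=0,
                             approach="disease")
        planted = set(drug_db.instance_meta.loc[
            drug_db.instance_meta["role"] == "reverser", "drug_id"])
        top = res.head(len(planted))
        assert set(top["drug_id"]) == planted, \
            "no background drug may outrank a noiseless planted reverser"
        assert (top["fdr"] < 0.05).all()
        assert top["p_value"].to_numpy() == pytest.approx(1 / 501)

    def test_mimics_occupy_positive_tail(self, syn_small, disease_sig, drug_db):
        res = score_database(disease_sig, drug_db, n_perm=300, seed=0)
        mimics = set(drug_db.instance_meta.loc[
            drug_db.instance_meta["role"] == "mimic", "drug_id"])
        tail = res.tail(len(mimics))
        assert set(tail["drug_id"]) == mimics
        assert (tail["score"] > 0.8).all()

    def test_instance_order_invariance(self, disease_sig, drug_db):
        shuffled = drug_db.subset_instances(
            list(np.random.default_rng(3).permutation(drug_db.ranks.columns)))
        a = score_database(disease_sig, drug_db, n_perm=100, seed=5)
        b = score_database(disease_sig, shuffled, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(
            a.drop(columns="instance_scores"), b.drop(columns="instance_scores"))

    def test_scores_bounded_and_ranks_permutation(self, disease_sig, drug_db):
        res = score_database(disease_sig, drug_db, n_perm=100, seed=1)
        assert res["score"].between(-1, 1).all()
        assert res["p_value"].between(0, 1, inclusive="right").all()
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))

    def test_low_n_perm_warns(self, disease_sig, drug_db):
        with pytest.warns(UserWarning, match="n_perm"):
            score_database(disease_sig, drug_db, n_perm=50, seed=0)


def _fake_results(n=30, seed=0):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(-1, 1, n)
    return pd.DataFrame({
        "drug_id": [f"D{i:03d}" for i in range(n)],
        "score": scores,
        "p_value": rng.uniform(0, 0.04, n),
        "fdr": rng.uniform(0, 0.04, n),
        "n_instances": 1,
        "instance_scores": [[s] for s in scores],
        "approach": "disease"})


class TestSelectMerge:
    def test_truncates_to_k(self):
        res = _fake_results(40)
        res["score"] = -np.abs(res["score"])        # all in the negative tail
        hits = select_hits(res, "disease", "negative_tail", k=20)
        assert len(hits) == 20

    def test_negative_tail_sorted_most_negative_first(self):
        res = _fake_results()
        hits = select_hits(res, "disease", "negative_tail")
        s = hits.table["score"]
        assert (s.diff().dropna() >= 0).all() and (s < 0).all()

    def test_tie_break_by_p_then_id(self):
        res = _fake_results(4)
        res["score"] = -0.5
        res["p_value"] = [0.01, 0.01, 0.001, 0.01]
        res["fdr"] = 0.01
        res["drug_id"] = ["D2", "D1", "D3", "D0"]
        hits = select_hits(res, "disease", "negative_tail")
        assert hits.table["drug_id"].tolist() == ["D3", "D0", "D1", "D2"]

    def test_empty_pass_is_warning_not_error(self):
        res = _fake_results()
        res["fdr"] = 0.9
        hits = select_hits(res, "disease", "negative_tail")
        assert len(hits) == 0 and hits.warnings

    def test_disjoint_lists_merge_to_45(self):
        def hl(approach, ids, sign):
            t = pd.DataFrame({"drug_id": ids, "score": sign * 0.5,
                              "p_value": 0.01, "fdr": 0.01, "multiplicity": 1})
            return HitList(approach, "negative_tail", t)
        lists = [hl("disease", [f"A{i}" for i in range(13)], -1),
                 hl("sirna", [f"B{i}" for i in range(18)], 1),
                 hl("resistance", [f"C{i}" for i in range(14)], -1)]
        merged = merge_hits(lists)
        assert len(merged) == 45

    def test_shared_drug_collapses_with_flags(self):
        def hl(approach, ids):
            t = pd.DataFrame({"drug_id": ids, "score": -0.5, "p_value": 0.01,
                              "fdr": 0.01, "multiplicity": 2})
            return HitList(approach, "negative_tail", t)
        merged = merge_hits([hl("disease", ["X", "Y"]), hl("resistance", ["X"])])
        row = merged.set_index("drug_id").loc["X"]
        assert bool(row["in_disease"]) and bool(row["in_resistance"])
        assert row["n_approaches"] == 2

    def test_exclusion_list_removes_and_logs(self):
        def hl(ids):
            t = pd.DataFrame({"drug_id": ids, "score": -0.5, "p_value": 0.01,
                              "fdr": 0.01, "multiplicity": 1})
            return HitList("disease", "negative_tail", t)
        merged = merge_hits([hl(["X", "Y", "Z"])], exclusion=["y"])
        assert "Y" not in merged["drug_id"].tolist()
        assert merged.attrs["excluded_drugs"] == ["Y"]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(4, 60).flatmap(
    lambda n: st.tuples(st.just(n),
                        st.lists(st.integers(1, n), min_size=1, max_size=min(6, n - 1),
                                 unique=True))))
def test_ks_enrichment_bounds_property(args):
    n, positions = args
    s = ks_enrichment(positions, n)
    assert -1.0 < s < 1.0
    assert s == pytest.approx(ks_oracle(positions, n))
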