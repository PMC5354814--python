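"""Signature construction, overlap, resistance derivation, robustness filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewsrepo import SynConfig, syndata
from ewsrepo.signatures import (DrugProfileDB, GeneSignature,
                                derive_resistance_signature,
                                overlap_signatures, robustness_filter)


class TestGeneSignature:
    def test_direction_clash_rejected(self):
        with pytest.raises(ValueError, match="both directions"):
            GeneSignature(["G1"], ["G1"])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSignature(["G1", "G1"], [])

    def test_tsv_round_trip(self, tmp_path):
        sig = GeneSignature(["G1", "G2"], ["G9"], weights={"G1": 2.5, "G2": 1.0,
                                                           "G9": 3.0})
        sig.to_tsv(tmp_path / "s.tsv")
        back = GeneSignature.from_tsv(tmp_path / "s.tsv")
        assert back.up == sig.up and back.down == sig.down
        assert back.weights["G1"] == 2.5


class TestOverlap:
    def test_self_overlap_is_identity(self):
        a = GeneSignature(["G1", "G2", "G3"], ["G4", "G5"])
        out, rep = overlap_signatures(a, a)
        assert out.up == a.up and out.down == a.down
        assert rep.conflicts == []

    def test_hand_computed_intersection(self):
        a = GeneSignature(["G1", "G2", "G3"], [])
        b = GeneSignature(["G2", "G3", "G4"], [])
        out, _ = overlap_signatures(a, b)
        assert out.up == ["G2", "G3"] and out.down == []

    def test_direction_conflict_dropped_and_reported(self):
        a = GeneSignature(["G1"], ["G2"])
        b = GeneSignature(["G2"], ["G1"])
        with pytest.raises(ValueError, match="empty in both"):
            overlap_signatures(a, b)
        # with a surviving gene the conflicts are reported, not fatal
        a = GeneSignature(["G1", "G3"], ["G2"])
        b = GeneSignature(["G3"], ["G1", "G2"])
        out, rep = overlap_signatures(a, b)
        assert rep.conflicts == ["G1"]
        assert out.up == ["G3"] and out.down == ["G2"]

    def test_commutative(self):
        a = GeneSignature(["G1", "G2", "G3"], ["G7", "G8"])
        b = GeneSignature(["G2", "G4"], ["G8", "G9"])
        ab, _ = overlap_signatures(a, b)
        ba, _ = overlap_signatures(b, a)
        assert set(ab.up) == set(ba.up) and set(ab.down) == set(ba.down)


class TestResistanceSignature:
    def _matrix(self, seed=0, effect=2.0, n=10):
        cfg = SynConfig(seed=seed, n_genes=1000, n_per_group=n,
                        n_diff_genes=60, group_effect_sd=effect)
        return syndata.gen_responder_matrix(cfg)

    def test_identical_groups_yield_empty_signature(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(200, 6))
        expr = pd.DataFrame(np.hstack([half, half]),
                            index=[f"G{i}" for i in range(200)],
                            columns=[f"R{i}" for i in range(6)]
                            + [f"N{i}" for i in range(6)])
        groups = pd.Series(["r"] * 6 + ["n"] * 6, index=expr.columns)
        sig = derive_resistance_signature(expr, groups)
        assert sig.is_empty()

    def test_planted_genes_recovered(self):
        # sensitivity bounds frozen from a simulation oracle (exact
        # Mann-Whitney + BH on the same generator): ~0.75-0.8 at a 2 SD
        # shift with 10 per group, and essentially complete at 2.5 SD
        expr, groups, truth = self._matrix(seed=1, effect=2.0)
        sig = derive_resistance_signature(expr, groups, fdr_cut=0.05,
                                          top_n=200)
        recovered = set(sig.up + sig.down)
        planted = set(truth.up + truth.down)
        assert len(recovered & planted) / len(planted) >= 0.7
        # directions must agree with the planted shift
        assert len(set(sig.up) & set(truth.down)) == 0

        expr, groups, truth = self._matrix(seed=1, effect=2.5)
        sig = derive_resistance_signature(expr, groups, fdr_cut=0.05,
                                          top_n=200)
        planted = set(truth.up + truth.down)
        assert len(set(sig.up + sig.down) & planted) / len(planted) >= 0.9

    def test_top_n_truncation_keeps_largest_effects(self):
        expr, groups, _ = self._matrix(seed=3)
        full = derive_resistance_signature(expr, groups, top_n=1000)
        trimmed = derive_resistance_signature(expr, groups, top_n=5)
        assert len(trimmed.up) == 5
        kept = [full.weights[g] for g in trimmed.up]
        dropped = [full.weights[g] for g in full.up[5:]]
        assert min(kept) >= max(dropped)

    def test_monotone_transform_invariance(self):
        expr, groups, _ = self._matrix(seed=4, n=5)
        a = derive_resistance_signature(expr, groups, top_n=30)
        b = derive_resistance_signature(np.exp(expr / 3.0), groups, top_n=30)
        assert set(a.up) == set(b.up) and set(a.down) == set(b.down)

    def test_small_groups_rejected(self):
        expr, groups, _ = self._matrix(seed=5)
        bad = groups.copy()
        bad.iloc[:] = "x"
        bad.iloc[0] = "y"
        with pytest.raises(ValueError):
            derive_resistance_signature(expr, bad)


def _db_from_columns(cols: dict) -> DrugProfileDB:
    """Columns: instance id -> rank list; drug id = instance id prefix."""
    ranks = pd.DataFrame(cols, index=[f"G{i}" for i in range(
        len(next(iter(cols.values()))))])
    meta = pd.DataFrame({"instance_id": list(cols),
                         "drug_id": [c.split("_")[0] for c in cols],
                         "experiment": "e"})
    return DrugProfileDB(ranks, meta)


class TestRobustnessFilter:
    def test_identical_replicates_retained(self):
        db = _db_from_columns({"A_1": [1, 2, 3, 4], "A_2": [1, 2, 3, 4]})
        out, rep = robustness_filter(db, min_corr=0.99)
        assert out.n_instances == 2
        assert rep.retained["median_corr"].iloc[0] == pytest.approx(1.0)

    def test_reversed_replicates_dropped(self):
        db = _db_from_columns({"A_1": [1, 2, 3, 4], "A_2": [4, 3, 2, 1]})
        out, rep = robustness_filter(db, min_corr=-0.5)
        assert out.n_instances == 0
        assert rep.dropped["median_corr"].iloc[0] == pytest.approx(-1.0)

    def test_median_of_three_pairs_decides(self):
        # two agreeing instances and one scrambled: retention must follow
        # the hand-computed median of the three pairwise correlations
        rng = np.random.default_rng(0)
        n = 50
        base = np.arange(1, n + 1)
        near = base.copy()
        near[:4] = [2, 1, 4, 3]   # slight perturbation, rho ~ 1
        scrambled = rng.permutation(base)
        db = _db_from_columns({"A_1": base, "A_2": near, "A_3": scrambled})
        rho = np.corrcoef(np.c_[base, near, scrambled], rowvar=False)
        med = np.median(rho[np.triu_indices(3, 1)])
        out_keep, _ = robustness_filter(db, min_corr=med - 1e-9)
        out_drop, _ = robustness_filter(db, min_corr=med + 1e-9)
        assert out_keep.n_instances == 3 and out_drop.n_instances == 0

    def test_singletons_retained_and_flagged(self):
        db = _db_from_columns({"A_1": [1, 2, 3], "B_1": [3, 2, 1],
                               "B_2": [3, 2, 1]})
        out, rep = robustness_filter(db, min_corr=0.5)
        assert rep.singletons == ["A"]
        assert "A_1" in out.ranks.columns

    def test_idempotent_and_never_grows(self, drug_db):
        once, _ = robustness_filter(drug_db, min_corr=0.3)
        twice, _ = robustness_filter(once, min_corr=0.3)
        assert once.n_instances <= drug_db.n_instances
        assert list(once.ranks.columns) == list(twice.ranks.columns)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from([f"G{i}" for i in range(12)]),
                min_size=1, max_size=6, unique=True),
       st.lists(st.sampled_from([f"H{i}" for i in range(12)]),
                min_size=1, max_size=6, unique=True))
def test_overlap_idempotent_property(up, down):
    sig = GeneSignature(up, down)
    out, _ = overlap_signatures(sig, sig)
    assert out.up == sig.up and out.down == sig.down
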