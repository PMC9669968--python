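"""The three-step unique-signature derivation, co-target intersection,
per-sample scoring, and Wilcoxon group comparisons."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from arsig.signatures import (
    SignatureDefinition,
    compare_groups,
    derive_cotarget_signature,
    derive_unique_signatures,
    score_signature,
)

from conftest import make_de_table, make_target_table


def toy_inputs():
    """Hand-walkable five-gene example exercising every derivation branch.

    g1: strong A-only response (fc 3.0 vs 1.2), A target  -> in sigA
    g2: responds in both conditions, target in both       -> common, dropped
    g3: B response fc 2.0 but A fc 1.5 (ratio 1.33 < 1.5) -> dropped at step iii
    g4: B-only response fc 4.0, B target                  -> in sigB
    g5: DE in A but no binding peak                       -> dropped at step i
    """
    genes = ["g1", "g2", "g3", "g4", "g5"]
    de_a = make_de_table({
        "g1": (np.log2(3.0), 1e-4, 0.01),
        "g2": (np.log2(2.5), 1e-4, 0.01),
        "g3": (np.log2(1.5), 0.1, 0.2),
        "g4": (np.log2(1.1), 0.5, 0.7),
        "g5": (np.log2(2.2), 1e-3, 0.02),
    })
    de_b = make_de_table({
        "g1": (np.log2(1.2), 0.2, 0.3),
        "g2": (np.log2(2.8), 1e-4, 0.01),
        "g3": (np.log2(2.0), 1e-3, 0.01),
        "g4": (np.log2(4.0), 1e-5, 0.001),
        "g5": (np.log2(1.0), 0.9, 0.95),
    })
    targets_a = make_target_table(genes, {"g1", "g2", "g3"})
    targets_b = make_target_table(genes, {"g2", "g3", "g4"})
    return de_a, de_b, targets_a, targets_b


class TestUniqueSignatureDerivation:
    def test_hand_walked_three_step_example(self):
        sig_a, sig_b = derive_unique_signatures(*toy_inputs())
        assert sig_a.genes == ["g1"]  # 3.0/1.2 = 2.5 > 1.5
        assert sig_b.genes == ["g4"]  # g3 excluded: 2.0/1.5 = 1.33 < 1.5
        assert "g2" in sig_a.params["step_i"] and "g2" not in sig_a.params["step_ii"]

    def test_identical_inputs_give_empty_signatures(self):
        de_a, _, targets_a, _ = toy_inputs()
        sig_a, sig_b = derive_unique_signatures(de_a, de_a, targets_a, targets_a)
        assert sig_a.genes == [] and sig_b.genes == []

    def test_signatures_always_disjoint_and_subset_of_own_targets(self):
        de_a, de_b, ta, tb = toy_inputs()
        sig_a, sig_b = derive_unique_signatures(de_a, de_b, ta, tb)
        assert not (sig_a.gene_set & sig_b.gene_set)
        assert sig_a.gene_set <= set(sig_a.params["step_i"])
        assert sig_b.gene_set <= set(sig_b.params["step_i"])

    def test_raising_diff_ratio_never_grows_signature(self):
        de_a, de_b, ta, tb = toy_inputs()
        prev_a, prev_b = None, None
        for ratio in (1.0, 1.5, 2.0, 3.0):
            sig_a, sig_b = derive_unique_signatures(
                de_a, de_b, ta, tb, diff_ratio=ratio)
            if prev_a is not None:
                assert sig_a.gene_set <= prev_a and sig_b.gene_set <= prev_b
            prev_a, prev_b = sig_a.gene_set, sig_b.gene_set

    def test_gene_missing_from_other_table_is_neutral(self):
        de_a = make_de_table({"g9": (np.log2(3.0), 1e-4, 0.01)})
        de_b = make_de_table({"other": (0.0, 0.5, 0.8)})
        ta = make_target_table(["g9"], {"g9"})
        tb = make_target_table(["other"], set())
        sig_a, _ = derive_unique_signatures(de_a, de_b, ta, tb)
        assert sig_a.genes == ["g9"]  # folded FC 3.0 vs neutral 1.0

    def test_down_regulated_gene_uses_folded_fold_change(self):
        de_a = make_de_table({"g9": (np.log2(1 / 3.0), 1e-4, 0.01)})
        de_b = make_de_table({"g9": (0.0, 0.5, 0.8)})
        ta = make_target_table(["g9"], {"g9"})
        tb = make_target_table(["g9"], set())
        sig_a, _ = derive_unique_signatures(de_a, de_b, ta, tb)
        assert sig_a.genes == ["g9"]

    def test_difference_mode_uses_arithmetic_margin(self):
        de_a, de_b, ta, tb = toy_inputs()
        sig_a, _ = derive_unique_signatures(de_a, de_b, ta, tb, mode="difference")
        # g1: 3.0 - 1.2 = 1.8 > 1.5 still passes the arithmetic reading
        assert sig_a.genes == ["g1"]


class TestCotarget:
    def test_disjoint_external_set_gives_empty_outputs(self):
        up, down = derive_cotarget_signature({"g1", "g2"}, {"g3"}, {"x1", "x2"})
        assert up.genes == [] and down.genes == []

    def test_set_algebra_example(self):
        up, down = derive_cotarget_signature(
            {"g1", "g2", "g3"}, {"g4"}, {"g2", "g3", "g4", "g5"})
        assert up.gene_set == {"g2", "g3"}
        assert down.gene_set == {"g4"}
        assert len(up) + len(down) == 3  # full intersection size

    def test_overlapping_up_down_refused(self):
        with pytest.raises(ValueError, match="disjoint"):
            derive_cotarget_signature({"g1"}, {"g1"}, {"g1"})

    def test_planted_overlap_fraction_recovered(self, small_world):
        w = small_world
        truth = w["truth"]
        b_up = truth.planted_unique_genes_B & truth.planted_up_genes
        up, _ = derive_cotarget_signature(
            b_up, truth.planted_unique_genes_B - b_up, truth.planted_ezh2_regulated)
        frac = len(up) / len(b_up)
        # binomial CI around the planted overlap fraction 0.5
        se = np.sqrt(0.5 * 0.5 / len(b_up))
        assert abs(frac - w["cfg"].ezh2_overlap_frac) < 3 * se + 0.05


def expr_matrix(rng, n_genes=40, n_samples=12):
    return pd.DataFrame(
        rng.normal(5, 2, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestScoring:
    def test_identical_samples_score_zero(self):
        expr = pd.DataFrame(3.0, index=["g0", "g1"], columns=["a", "b", "c"])
        sig = SignatureDefinition("sig", ["g0", "g1"])
        scores = score_signature(expr, sig)
        assert (scores == 0).all()

    def test_single_gene_signature_equals_its_z(self, rng):
        expr = expr_matrix(rng)
        sig = SignatureDefinition("one", ["g3"])
        scores = score_signature(expr, sig)
        row = expr.loc["g3"]
        z = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(scores, z, atol=1e-12)

    def test_combined_z_matches_brute_force_oracle(self, rng):
        expr = expr_matrix(rng)
        genes = ["g1", "g5", "g9", "g20"]
        sig = SignatureDefinition("sig", genes)
        scores = score_signature(expr, sig)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        np.testing.assert_allclose(scores, z.loc[genes].mean(axis=0), atol=1e-12)

    def test_invariant_to_gene_and_sample_permutation(self, rng):
        expr = expr_matrix(rng)
        sig = SignatureDefinition("sig", ["g1", "g5", "g9"])
        s1 = score_signature(expr, sig)
        perm = expr.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        s2 = score_signature(perm, sig)
        np.testing.assert_allclose(s1.sort_index(), s2.sort_index(), atol=1e-12)

    def test_no_present_genes_refused_with_report(self, rng):
        expr = expr_matrix(rng)
        sig = SignatureDefinition("sig", ["zz1", "zz2"])
        with pytest.raises(ValueError, match="no genes"):
            score_signature(expr, sig)

    def test_missing_genes_logged_in_attrs(self, rng):
        expr = expr_matrix(rng)
        sig = SignatureDefinition("sig", ["g1", "zz1"])
        scores = score_signature(expr, sig)
        assert scores.attrs["missing_genes"] == ["zz1"]

    def test_ssgsea_orders_samples_by_signature_expression(self, rng):
        expr = expr_matrix(rng, 50, 6)
        genes = [f"g{i}" for i in range(10)]
        expr.loc[genes, "s0"] += 10  # s0 strongly expresses the signature
        sig = SignatureDefinition("sig", genes)
        scores = score_signature(expr, sig, method="ssgsea")
        assert scores.idxmax() == "s0"

    def test_duplicate_signature_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SignatureDefinition("bad", ["g1", "g1"])


def exact_two_sided_p(x, y):
    """Enumerate all assignments of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    n1 = len(x)
    obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for a in g1 for b in g2 if a > b) + 0.5 * sum(
            1 for a in g1 for b in g2 if a == b)
        mid = n1 * (len(pooled) - n1) / 2
        if abs(u - mid) >= abs(obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareGroups:
    def test_identical_multisets_give_p_one(self):
        scores = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=scores.index)
        out = compare_groups(scores, groups)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_fully_separated_triples_give_exact_p(self):
        scores = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=scores.index)
        out = compare_groups(scores, groups)
        assert out["p"].iloc[0] == pytest.approx(0.1)  # 2/20 partitions

    def test_matches_enumeration_oracle_at_n8(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        scores = pd.Series(np.concatenate([x, y]),
                           index=[f"s{i}" for i in range(16)])
        groups = pd.Series(["x"] * 8 + ["y"] * 8, index=scores.index)
        out = compare_groups(scores, groups)
        assert out["p"].iloc[0] == pytest.approx(exact_two_sided_p(x, y), abs=0.02)

    def test_all_pairs_reported_for_three_groups(self, rng):
        scores = pd.Series(rng.normal(0, 1, 15), index=[f"s{i}" for i in range(15)])
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=scores.index)
        out = compare_groups(scores, groups)
        assert set(map(tuple, out[["group1", "group2"]].values)) == {
            ("a", "b"), ("a", "c"), ("b", "c")}
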