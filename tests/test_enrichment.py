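"""Enrichment machinery against exhaustive enumeration and hand computation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from foxodep import (
    MotifModel,
    Ontology,
    direction_test,
    elim_fisher,
    hypergeom_test,
    motif_overlap_test,
    pca_contribution_sets,
    scan_pwm,
)
from foxodep.enrichment import pwm_score_pvalues, score_word


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_test(0, 5, 10, 20) == 1.0

    def test_saturated_universe(self):
        assert hypergeom_test(7, 7, 7, 7) == 1.0

    def test_closed_form_example(self):
        expected = comb(15, 5, exact=True) / comb(20, 10, exact=True)
        assert hypergeom_test(5, 5, 10, 20) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N,K,n", [(12, 4, 6), (20, 5, 10), (15, 7, 7)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        annotated = set(range(K))
        for k in range(max(0, K + n - N), min(K, n) + 1):
            count = sum(
                1
                for draw in itertools.combinations(range(N), n)
                if len(annotated & set(draw)) >= k
            )
            expected = count / comb(N, n, exact=True)
            assert hypergeom_test(k, K, n, N) == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_test(6, 5, 10, 20)


class TestElimFisher:
    def test_flat_ontology_elim_equals_classic(self, rng):
        genes = [f"g{i}" for i in range(60)]
        parents = {f"t{i}": ["root"] for i in range(8)}
        parents["root"] = []
        annotations = {
            f"t{i}": list(rng.choice(genes, size=12, replace=False)) for i in range(8)
        }
        onto = Ontology(parents, annotations)
        sig = list(rng.choice(genes, size=15, replace=False))
        table = elim_fisher(onto, sig, genes, alpha=0.05)
        np.testing.assert_array_equal(table["p_elim"], table["p_classic"])

    def test_two_level_hand_example(self):
        child_genes = [f"s{i}" for i in range(5)]
        extra = [f"x{i}" for i in range(5)]
        background = child_genes + extra + [f"b{i}" for i in range(40)]
        onto = Ontology(
            {"parent": [], "child": ["parent"]},
            {"child": child_genes, "parent": child_genes + extra},
        )
        table = elim_fisher(onto, child_genes, background, alpha=0.05).set_index("term")
        # child: all 5 of its genes significant out of 5 significant in 50
        child_exact = 1 / comb(50, 5, exact=True) * comb(45, 0, exact=True)
        assert table.loc["child", "p_elim"] == pytest.approx(child_exact, rel=1e-9)
        # parent tested on the 5 residual (never-significant) genes only
        assert table.loc["parent", "effective"] == 5
        assert table.loc["parent", "p_elim"] == 1.0
        # classic parent p uses all 10 genes
        assert table.loc["parent", "p_classic"] == pytest.approx(
            hypergeom_test(5, 10, 5, 50), rel=1e-12
        )

    def test_alpha_zero_disables_elimination(self, rng):
        genes = [f"g{i}" for i in range(40)]
        onto = Ontology(
            {"root": [], "a": ["root"], "b": ["a"]},
            {"a": genes[:20], "b": genes[:10], "root": []},
        )
        sig = genes[:10]
        table = elim_fisher(onto, sig, genes, alpha=0.0)
        np.testing.assert_array_equal(table["p_elim"], table["p_classic"])

    def test_enrichment_score_definition(self):
        genes = [f"g{i}" for i in range(100)]
        onto = Ontology({"root": [], "t": ["root"]}, {"t": genes[:20], "root": []})
        table = elim_fisher(onto, genes[:10], genes).set_index("term")
        expected = 20 * 10 / 100
        assert table.loc["t", "expected"] == pytest.approx(expected)
        assert table.loc["t", "score"] == pytest.approx(math.log2(10 / expected))

    def test_random_term_score_centred_near_zero(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(100)]
        onto = Ontology({"root": [], "t": ["root"]}, {"t": genes[:40], "root": []})
        scores = []
        for _ in range(200):
            sig = list(rng.choice(genes, size=50, replace=False))
            table = elim_fisher(onto, sig, genes).set_index("term")
            scores.append(table.loc["t", "score"])
        assert abs(np.mean(scores)) < 0.1

    def test_significant_outside_background_rejected(self):
        onto = Ontology({"root": []}, {"root": ["g1"]})
        with pytest.raises(ValueError, match="background"):
            elim_fisher(onto, ["g9"], ["g1"])

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cyclic"):
            Ontology({"a": ["b"], "b": ["a"]}, {})


class TestPcaTails:
    def test_median_split_partitions(self, rng):
        X = pd.DataFrame(rng.normal(size=(21, 6)), index=[f"p{i}" for i in range(21)])
        top, bottom = pca_contribution_sets(X, 0, q=0.5)
        assert len(set(top) & set(bottom)) == 0
        assert len(top) + len(bottom) == 21

    def test_duplicated_protein_stays_with_twin(self, rng):
        X = rng.normal(size=(30, 5))
        X[7] = X[3]
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(30)])
        for q in (0.1, 0.25, 0.5):
            top, bottom = pca_contribution_sets(df, 0, q=q)
            assert ("p3" in top) == ("p7" in top)
            assert ("p3" in bottom) == ("p7" in bottom)

    def test_rank_one_matrix_recovers_loading_order(self, rng):
        loadings = np.linspace(-1, 1, 40)  # zero-mean by construction
        v = rng.normal(size=8)
        X = pd.DataFrame(np.outer(loadings, v), index=[f"p{i}" for i in range(40)])
        top, bottom = pca_contribution_sets(X, 0, q=0.1)
        order = np.argsort(loadings)
        extremes_low = {f"p{i}" for i in order[:4]}
        extremes_high = {f"p{i}" for i in order[-4:]}
        assert set(top) | set(bottom) == extremes_low | extremes_high
        assert (set(top) == extremes_high) or (set(top) == extremes_low)

    def test_dimension_beyond_rank(self, rng):
        X = pd.DataFrame(np.outer(rng.normal(size=10), rng.normal(size=4)))
        with pytest.raises(ValueError, match="rank"):
            pca_contribution_sets(X, 3)


def _random_motif(width, rng, background=None):
    m = rng.dirichlet(np.ones(4) * 2, size=width)
    return MotifModel(
        matrix=m, background=background if background is not None else np.full(4, 0.25)
    )


class TestPwm:
    def test_uninformative_motif_has_no_hits(self):
        motif = MotifModel(matrix=np.full((6, 4), 0.25))
        assert scan_pwm("ACGT" * 30, motif, p_threshold=1e-4) == []

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_score_pvalues_match_enumeration(self, width, rng):
        background = np.array([0.3, 0.2, 0.2, 0.3])
        motif = _random_motif(width, rng, background)
        offset, tail = pwm_score_pvalues(motif)
        words = ["".join(w) for w in itertools.product("ACGT", repeat=width)]
        scores = np.array([score_word(w, motif) for w in words])
        probs = np.array(
            [np.prod([background["ACGT".index(c)] for c in w]) for w in words]
        )
        for s in np.unique(scores):
            expected = probs[scores >= s].sum()
            idx = s - offset
            assert tail[idx] == pytest.approx(expected, rel=1e-9, abs=1e-15)

    def test_planted_consensus_is_hit(self, rng):
        from foxodep import default_foxo_motif

        motif = default_foxo_motif()
        seq = "".join(rng.choice(list("ACGT"), size=200))
        planted = seq[:100] + motif.consensus + seq[100 + motif.width :]
        hits = scan_pwm(planted, motif)
        assert any(h.start == 100 and h.strand == "+" for h in hits)

    def test_reverse_strand_coordinates(self):
        from foxodep import default_foxo_motif

        motif = default_foxo_motif()
        rc = str.maketrans("ACGT", "TGCA")
        rc_consensus = motif.consensus.translate(rc)[::-1]
        seq = "A" * 50 + rc_consensus + "A" * 50
        hits = scan_pwm(seq, motif)
        assert any(h.start == 50 and h.strand == "-" for h in hits)

    def test_short_sequence_empty(self):
        from foxodep import default_foxo_motif

        assert scan_pwm("ACGT", default_foxo_motif()) == []

    def test_meme_round_trip(self, tmp_path, rng):
        motif = _random_motif(6, rng, np.array([0.3, 0.2, 0.2, 0.3]))
        motif.to_meme(tmp_path / "m.meme")
        back = MotifModel.from_meme(tmp_path / "m.meme")
        np.testing.assert_allclose(back.matrix, motif.matrix, atol=1e-6)
        np.testing.assert_allclose(back.background, motif.background, atol=1e-5)


class TestOverlapAndDirection:
    def test_disjoint_sets(self):
        out = motif_overlap_test(["a", "b"], ["c", "d"], ["a", "b", "c", "d", "e"])
        assert out["fraction"] == 0.0 and out["pvalue"] == 1.0

    def test_saturated_hits(self):
        bg = [f"g{i}" for i in range(10)]
        out = motif_overlap_test(bg, bg[:4], bg)
        assert out["fraction"] == 1.0 and out["pvalue"] == pytest.approx(1.0)

    def test_empty_regulated_set(self):
        with pytest.raises(ValueError):
            motif_overlap_test(["a"], [], ["a", "b"])

    def test_symmetric_values(self):
        t, p, flag = direction_test([-0.4, 0.4, -1.0, 1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0) and not flag

    def test_constant_values_flagged(self):
        t, p, flag = direction_test([1.0, 1.0, 1.0, 1.0])
        assert flag and p == 0.0 and math.isinf(t)

    def test_hand_computed_t(self):
        values = [0.2, 0.4, 0.6, 0.8]
        t, p, flag = direction_test(values)
        sd = np.std(values, ddof=1)
        assert t == pytest.approx(np.mean(values) / (sd / 2), rel=1e-12)
        assert t == pytest.approx(3.87298, abs=1e-4)
        assert not flag
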