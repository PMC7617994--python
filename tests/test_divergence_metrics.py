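"""Jaccard divergence, species-specific counts, correlations, group stats."""

import numpy as np
import pandas as pd
import pytest

from caenodiverge import divergence_metrics as dm

from oracles import bh_adjust_oracle, gene_jaccard_oracle


def binary_from_sets(classes, on_sets, gene="g"):
    """One-gene binary matrices per species from ON-class sets."""
    return {
        f"s{i + 1}": pd.DataFrame(
            {gene: [c in s for c in classes]}, index=classes
        )
        for i, s in enumerate(on_sets)
    }


TRIPLET = pd.DataFrame([{"s1": "g", "s2": "g", "s3": "g"}])


@pytest.mark.parametrize(
    "on_sets,expected",
    [
        (({"A", "B"}, {"A", "B"}, {"A", "B"}), 0.0),
        (({"A"}, {"B"}, {"C"}), 1.0),
        (({"A", "B"}, {"B", "C"}, {"B"}), 2 / 3),
    ],
)
def test_gene_jaccard_formula_examples(on_sets, expected):
    binary = binary_from_sets(["A", "B", "C", "D"], on_sets)
    out = dm.gene_jaccard(binary, TRIPLET)
    assert out["distance"].tolist() == [pytest.approx(expected)]


def test_gene_jaccard_excludes_empty_union():
    binary = binary_from_sets(["A", "B"], (set(), set(), set()))
    assert dm.gene_jaccard(binary, TRIPLET).empty


def test_gene_jaccard_pairwise_subset():
    binary = binary_from_sets(["A", "B", "C"], ({"A", "B"}, {"B", "C"}, {"B"}))
    out = dm.gene_jaccard(binary, TRIPLET, species_subset=["s1", "s2"])
    assert out["distance"].tolist() == [pytest.approx((3 - 1) / 3)]
    with pytest.raises(ValueError):
        dm.gene_jaccard(binary, TRIPLET, species_subset=["s1"])


def test_class_universe_mismatch_raises():
    binary = binary_from_sets(["A", "B"], ({"A"}, {"A"}, {"A"}))
    binary["s3"] = binary["s3"].reindex(["A", "Z"], fill_value=False)
    with pytest.raises(ValueError):
        dm.gene_jaccard(binary, TRIPLET)


def test_cell_jaccard_example():
    # class with ON genes {g1, g2}, {g2}, {g2, g3} -> (3 - 1) / 3
    classes = ["K"]
    genes = ["g1", "g2", "g3"]
    trip = pd.DataFrame([{"s1": g, "s2": g, "s3": g} for g in genes])
    mats = {
        "s1": pd.DataFrame([[1, 1, 0]], index=classes, columns=genes),
        "s2": pd.DataFrame([[0, 1, 0]], index=classes, columns=genes),
        "s3": pd.DataFrame([[0, 1, 1]], index=classes, columns=genes),
    }
    out = dm.cell_jaccard(mats, trip)
    assert out["distance"].tolist() == [pytest.approx(2 / 3)]
    with pytest.raises(ValueError):
        dm.cell_jaccard(mats, trip, gene_pool=[])


def test_jaccard_oracle_equivalence_and_symmetry(rng):
    """Both variants match set-based recomputation on random matrices."""
    classes = [f"c{i}" for i in range(10)]
    genes = [f"g{i}" for i in range(10)]
    trip = pd.DataFrame([{"s1": g, "s2": g, "s3": g} for g in genes])
    for _ in range(200):
        mats = {
            sp: pd.DataFrame(
                rng.random((10, 10)) < 0.3, index=classes, columns=genes
            ).astype(int)
            for sp in ["s1", "s2", "s3"]
        }
        gene_out = dm.gene_jaccard(mats, trip).set_index("unit")["distance"]
        for g in genes:
            want = gene_jaccard_oracle(
                [set(np.array(classes)[mats[sp][g].astype(bool)]) for sp in mats]
            )
            if want is None:
                assert g not in gene_out.index
            else:
                assert gene_out[g] == pytest.approx(want)
        cell_out = dm.cell_jaccard(mats, trip).set_index("unit")["distance"]
        for c in classes:
            want = gene_jaccard_oracle(
                [set(np.array(genes)[mats[sp].loc[c].astype(bool)]) for sp in mats]
            )
            if want is None:
                assert c not in cell_out.index
            else:
                assert cell_out[c] == pytest.approx(want)
        # species permutation invariance
        permuted = {"s1": mats["s3"], "s2": mats["s1"], "s3": mats["s2"]}
        pd.testing.assert_series_equal(
            gene_out, dm.gene_jaccard(permuted, trip).set_index("unit")["distance"]
        )


def test_triple_distance_zero_implies_pairwise_zero(rng):
    classes = [f"c{i}" for i in range(8)]
    col = rng.random(8) < 0.5
    mats = {
        sp: pd.DataFrame({"g": col}, index=classes).astype(int)
        for sp in ["s1", "s2", "s3"]
    }
    assert dm.gene_jaccard(mats, TRIPLET)["distance"].tolist() == [0.0]
    for pair in (["s1", "s2"], ["s1", "s3"], ["s2", "s3"]):
        assert dm.gene_jaccard(mats, TRIPLET, species_subset=pair)["distance"].tolist() == [0.0]


def test_count_specific_expressed():
    classes = ["X", "Y"]
    genes = [f"g{i}" for i in range(10)]
    binary = pd.DataFrame(0, index=classes, columns=genes)
    binary.loc["X"] = 1                       # X expresses all 10
    binary.loc["Y", ["g0", "g1"]] = 1
    strict = {"g0", "g1"}
    out = dm.count_specific_expressed(binary, strict)
    assert out.at["X", "n_specific_on"] == 2
    assert out.at["X", "normalized"] == pytest.approx(0.2)
    assert out.at["Y", "normalized"] == pytest.approx(1.0)
    permissive = strict | {"g2"}
    out_perm = dm.count_specific_expressed(binary, permissive)
    assert (out_perm["n_specific_on"] >= out["n_specific_on"]).all()
    # family exclusion filter removes genes from both numerator and denominator
    excl = dm.count_specific_expressed(binary, strict, exclude_genes={"g0"})
    assert excl.at["X", "n_specific_on"] == 1
    assert excl.at["X", "n_on"] == 9


def test_class_correlation_identical_and_anticorrelated():
    classes = ["X", "Y"]
    genes = ["g1", "g2", "g3", "g4"]
    profile = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]], index=classes, columns=genes
    )
    pbs = {"s1": profile, "s2": profile.copy()}
    out = dm.class_correlation(pbs, {"s1": genes, "s2": genes})
    assert out.correlation.at[("s1", "X"), ("s2", "X")] == pytest.approx(1.0)
    assert out.correlation.at[("s1", "X"), ("s2", "Y")] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        dm.class_correlation(pbs, {"s1": genes[:1], "s2": genes[:1]})


def test_homologous_classes_cluster_together(rng):
    """With modest divergence each homologous class triplet forms a pure
    3-leaf cluster."""
    n_classes, n_genes = 12, 120
    base = rng.random((n_classes, n_genes)) < 0.3
    classes = [f"c{i}" for i in range(n_classes)]
    genes = [f"g{i}" for i in range(n_genes)]
    pbs = {}
    for sp in ["s1", "s2", "s3"]:
        flip = rng.random((n_classes, n_genes)) < 0.05  # ~ Jaccard 0.2-0.3
        pbs[sp] = pd.DataFrame((base ^ flip).astype(float), index=classes, columns=genes)
    out = dm.class_correlation(pbs, {sp: genes for sp in pbs})
    labels = out.cluster_labels
    for cls in classes:
        members = labels[labels == labels[("s1", cls)]]
        assert len(members) == 3
        assert {ix[1] for ix in members.index} == {cls}


def test_group_stats_two_groups_uses_rank_sum(rng):
    vals = np.concatenate([rng.normal(size=30), rng.normal(2.0, size=30)])
    labs = np.repeat(["a", "b"], 30)
    gs = dm.group_stats(vals, labs)
    assert gs.test == "wilcoxon_rank_sum"
    assert gs.omnibus_p < 0.001


def test_group_stats_all_tied_reports_na():
    gs = dm.group_stats([1.0] * 12, np.repeat(["a", "b", "c"], 4))
    assert gs.omnibus_p is None and gs.pairwise.empty


def test_group_stats_validation():
    with pytest.raises(ValueError):
        dm.group_stats([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        dm.group_stats([1, 2, 3], ["a", "a", "b"])


def test_group_stats_detects_location_shift(rng):
    """Power > 0.9 for a 1 SD shift at n = 50 per group."""
    hits = 0
    n_sims = 200
    for _ in range(n_sims):
        vals = np.concatenate(
            [rng.normal(size=50), rng.normal(size=50), rng.normal(1.0, size=50)]
        )
        labs = np.repeat(["a", "b", "c"], 50)
        gs = dm.group_stats(vals, labs)
        shifted = gs.pairwise[
            (gs.pairwise["group_a"] == "c") | (gs.pairwise["group_b"] == "c")
        ]
        if gs.omnibus_p < 0.025 and (shifted["p_adj"] < 0.025).all():
            hits += 1
    assert hits / n_sims > 0.9


def test_benjamini_hochberg_matches_closed_form(rng):
    assert dm.benjamini_hochberg(np.array([0.01, 0.02, 0.04])).tolist() == pytest.approx(
        [0.03, 0.03, 0.04]
    )
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 15)))
        np.testing.assert_allclose(dm.benjamini_hochberg(p), bh_adjust_oracle(p))
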