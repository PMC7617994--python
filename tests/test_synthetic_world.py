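"""Generator invariants: anatomy, orthology structure, planted divergence,
count sampling, evidence and read simulation."""

import numpy as np
import pandas as pd
import pytest

from caenodiverge import synthetic_world as sw


def test_same_seed_gives_identical_world():
    cfg = sw.WorldConfig(n_classes=12, n_genes_111=50, n_genes_none=6, seed=1)
    w1, w2 = sw.make_world(cfg), sw.make_world(sw.WorldConfig(**vars(cfg)))
    pd.testing.assert_frame_equal(w1.anatomy, w2.anatomy)
    pd.testing.assert_frame_equal(w1.pair_table, w2.pair_table)
    for sp in w1.species:
        pd.testing.assert_frame_equal(w1.truth[sp], w2.truth[sp])
        pd.testing.assert_frame_equal(w1.annotations[sp], w2.annotations[sp])


def test_anatomy_invariants(small_world):
    anat = small_world.anatomy
    # every neuron: exactly one class, bundle, area
    assert anat["neuron"].is_unique
    assert anat["bundle"].between(1, sw.N_BUNDLES).all()
    assert anat["area"].isin(sw.AREAS).all()
    # the pharynx bundle is exclusive to pharyngeal neurons, and vice versa
    pharyngeal = anat["pharynx"].astype(bool)
    assert (anat.loc[pharyngeal, "bundle"] == sw.PHARYNX_BUNDLE).all()
    assert (anat.loc[~pharyngeal, "bundle"] != sw.PHARYNX_BUNDLE).all()
    assert (anat.loc[pharyngeal, "area"] == "head").all()


def test_truth_tensor_is_binary_and_triplets_unique(small_world):
    for sp in small_world.species:
        truth = small_world.truth[sp]
        assert truth.dtypes.map(lambda d: d == bool).all()
        assert truth.columns.is_unique
    for sp in small_world.species:
        assert small_world.triplets[sp].is_unique


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_realized_divergence_matches_targets(seed):
    cfg = sw.WorldConfig(seed=seed)
    world = sw.make_world(cfg)
    realized = sw.realized_family_divergence(world)
    sizes = world.genes[world.species[0]].groupby("family").size()
    for fam, target in cfg.family_divergence.items():
        if sizes.get(fam, 0) >= 30:
            assert abs(realized[fam] - target) <= 0.05, (fam, realized[fam], target)


def test_divergence_extremes():
    cfg = sw.WorldConfig(
        n_classes=20,
        n_genes_111=120,
        family_divergence={**sw.DEFAULT_FAMILY_DIVERGENCE,
                           sw.FAM_HOMEODOMAIN: 0.0, sw.FAM_OTHER_TF: 1.0},
        seed=3,
    )
    world = sw.make_world(cfg)
    neuron = world.neuron_classes
    fam = world.family_of(world.species[0])
    for _, trip in world.triplets.iterrows():
        f = fam[trip[world.species[0]]]
        cols = [world.truth[sp].loc[neuron, trip[sp]].to_numpy() for sp in world.species]
        if f == sw.FAM_HOMEODOMAIN:  # target 0: identical ON sets everywhere
            assert all((c == cols[0]).all() for c in cols)
        elif f == sw.FAM_OTHER_TF:   # target 1: empty three-way intersection
            assert not np.logical_and.reduce(cols).any()


def test_unreachable_divergence_target_raises():
    cfg = sw.WorldConfig(n_classes=1, n_genes_111=30,
                         family_divergence={sw.FAM_HOMEODOMAIN: 0.5})
    with pytest.raises(ValueError):
        sw.make_world(cfg)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        sw.WorldConfig(on_mean=1.0, off_mean=2.0).validate()
    with pytest.raises(ValueError):
        sw.WorldConfig(family_divergence={"x": 1.5}).validate()
    with pytest.raises(ValueError):
        sw.WorldConfig(n_classes=0).validate()


def test_sample_counts_noiseless_off_entries_are_zero():
    cfg = sw.WorldConfig(n_classes=10, n_genes_111=40, n_genes_none=4,
                         cells_per_class=20, off_mean=0.0, ambient_rate=0.0, seed=4)
    world = sw.make_world(cfg)
    sp = world.species[0]
    cells = sw.sample_counts(world, sp, seed=9)
    x = np.asarray(cells.counts.todense())
    truth = world.truth[sp]
    sub = world.subthreshold[sp]
    for i, cls in enumerate(cells.metadata["class_name"]):
        off = ~(truth.loc[cls].to_numpy() | sub.loc[cls].to_numpy())
        assert (x[i, off] == 0).all()


def test_sample_counts_on_mean_recovered():
    cfg = sw.WorldConfig(n_classes=10, n_genes_111=60, n_genes_none=0,
                         n_orthogroups_multi=0, cells_per_class=200,
                         off_mean=0.0, ambient_rate=0.0, seed=5)
    world = sw.make_world(cfg)
    sp = world.species[0]
    cells = sw.sample_counts(world, sp, seed=10)
    x = np.asarray(cells.counts.todense(), dtype=float)
    truth = world.truth[sp]
    means = []
    for cls, group in cells.metadata.groupby("class_name"):
        on = truth.loc[cls].to_numpy() & (world.subthreshold[sp].loc[cls].to_numpy() == 0)
        if on.sum() == 0:
            continue
        means.append(x[np.ix_(group.index.to_numpy(), np.where(on)[0])].mean())
    # lognormal depth factor has mean exp(sigma^2 / 2) ~ 1.046
    assert abs(np.mean(means) - cfg.on_mean * np.exp(0.3**2 / 2)) < 0.1 * cfg.on_mean


def test_sample_counts_two_seeds_differ(small_world):
    sp = small_world.species[0]
    a = sw.sample_counts(small_world, sp, seed=1)
    b = sw.sample_counts(small_world, sp, seed=2)
    assert (a.counts != b.counts).nnz > 0
    pd.testing.assert_frame_equal(a.metadata, b.metadata)


def test_ground_truth_full_fraction_equals_truth(small_world):
    sp = small_world.species[0]
    gt = sw.make_ground_truth(small_world, 1.0, seed=0)
    wide = gt.pivot(index="class_name", columns="gene", values="label")
    truth = small_world.neuron_truth(sp).astype(int)
    pd.testing.assert_frame_equal(
        wide.loc[truth.index, truth.columns], truth, check_names=False
    )


def test_ground_truth_fraction_counts_and_errors(small_world):
    gt = sw.make_ground_truth(small_world, 0.1, seed=0)
    n_genes = len(small_world.truth[small_world.species[0]].columns)
    assert gt["gene"].nunique() == round(0.1 * n_genes)
    with pytest.raises(ValueError):
        sw.make_ground_truth(small_world, 1e-6, seed=0)


def test_ortho_evidence_seed_stable(small_world):
    e1 = sw.make_ortho_evidence(small_world, error_rate=0.05, seed=3)
    e2 = sw.make_ortho_evidence(small_world, error_rate=0.05, seed=3)
    pd.testing.assert_frame_equal(e1, e2)
    assert set(e1["level"].unique()) <= set(range(1, 6))


def test_read_alignments_reproducible_and_ordered(small_world):
    a1 = sw.make_read_alignments(small_world, 200, divergence=0.02, seed=6)
    a2 = sw.make_read_alignments(small_world, 200, divergence=0.02, seed=6)
    pd.testing.assert_frame_equal(a1, a2)
    # the true species accumulates fewer mismatches in expectation
    wide = a1.pivot(index=["read_id", "true_species"], columns="species", values="nm")
    own = np.array([row[true_sp] for (_, true_sp), row in wide.iterrows()])
    others = np.array(
        [row.drop(true_sp).mean() for (_, true_sp), row in wide.iterrows()]
    )
    assert own.mean() < others.mean()
    assert (own <= others + 1e-9).mean() > 0.95  # near-universal per read too


def test_celldata_roundtrip(tmp_path, small_world):
    sp = small_world.species[0]
    cells = sw.sample_counts(small_world, sp, seed=1)
    cells.write(tmp_path / "counts")
    back = sw.CellData.read(tmp_path / "counts")
    assert (cells.counts != back.counts).nnz == 0
    assert cells.gene_ids == back.gene_ids
    pd.testing.assert_frame_equal(cells.metadata, back.metadata)


def test_world_tables_roundtrip(tmp_path, small_world):
    sw.write_world(small_world, tmp_path)
    anat = pd.read_csv(tmp_path / "anatomy.tsv", sep="\t")
    pd.testing.assert_frame_equal(anat, small_world.anatomy)
    truth = pd.read_csv(tmp_path / "truth_sp1.tsv", sep="\t", index_col="class_name")
    pd.testing.assert_frame_equal(
        truth.astype(bool), small_world.truth["sp1"], check_names=False
    )
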