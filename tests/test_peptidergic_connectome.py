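"""Wireless connectome construction, spatial constraints, topology and
pharynx enrichment."""

import numpy as np
import pandas as pd
import pytest

from caenodiverge import peptidergic_connectome as pc

from oracles import edge_labels_oracle, hypergeom_upper_tail


def neuron_binary(data, neurons, genes):
    return pd.DataFrame(data, index=neurons, columns=genes)


NEURONS = ["n1", "n2", "n3"]


def test_pair_network_examples():
    nb = neuron_binary([[1, 0], [0, 1], [0, 0]], NEURONS, ["npp", "gpcr"])
    net = pc.pair_network(nb, "npp", "gpcr")
    assert net.at["n1", "n2"] == 1 and net.to_numpy().sum() == 1

    silent = neuron_binary([[0, 1], [0, 1], [0, 0]], NEURONS, ["npp", "gpcr"])
    assert pc.pair_network(silent, "npp", "gpcr").to_numpy().sum() == 0

    auto = neuron_binary([[1, 1], [0, 0], [0, 0]], NEURONS, ["npp", "gpcr"])
    assert pc.pair_network(auto, "npp", "gpcr").at["n1", "n1"] == 1
    assert pc.pair_network(auto, "npp", "gpcr", allow_autocrine=False).at["n1", "n1"] == 0


def test_pair_network_unmapped_gene_warns_empty():
    nb = neuron_binary([[1], [0], [0]], NEURONS, ["npp"])
    with pytest.warns(UserWarning):
        net = pc.pair_network(nb, "npp", "missing_gpcr")
    assert net.to_numpy().sum() == 0


ANATOMY = pd.DataFrame(
    [
        {"neuron": "som_a1", "class_name": "A", "bundle": 2, "area": "head", "pharynx": False},
        {"neuron": "som_a2", "class_name": "A2", "bundle": 2, "area": "head", "pharynx": False},
        {"neuron": "som_b", "class_name": "B", "bundle": 3, "area": "head", "pharynx": False},
        {"neuron": "phx", "class_name": "P", "bundle": 1, "area": "head", "pharynx": True},
        {"neuron": "phx2", "class_name": "P2", "bundle": 1, "area": "head", "pharynx": True},
        {"neuron": "tail", "class_name": "T", "bundle": 25, "area": "tail", "pharynx": False},
    ]
)


def full_adjacency():
    neurons = ANATOMY["neuron"].tolist()
    return pd.DataFrame(1, index=neurons, columns=neurons)


def test_spatial_filter_rules():
    adj = full_adjacency()
    short = pc.spatial_filter(adj, ANATOMY, "short")
    mid = pc.spatial_filter(adj, ANATOMY, "mid")
    # same bundle, both somatic: kept at short range
    assert short.at["som_a1", "som_a2"] == 1
    # different bundles, same area: dropped short, kept mid
    assert short.at["som_a1", "som_b"] == 0 and mid.at["som_a1", "som_b"] == 1
    # pharynx <-> somatic, both in the head: dropped short, kept mid
    assert short.at["phx", "som_a1"] == 0 and mid.at["phx", "som_a1"] == 1
    # pharynx <-> pharynx: kept at both ranges
    assert short.at["phx", "phx2"] == 1 and mid.at["phx", "phx2"] == 1
    # different areas: dropped everywhere
    assert mid.at["som_a1", "tail"] == 0 and short.at["som_a1", "tail"] == 0


def test_short_range_is_subset_of_mid(rng):
    adj = full_adjacency()
    rand = adj * (rng.random(adj.shape) < 0.6)
    short = pc.spatial_filter(rand, ANATOMY, "short").to_numpy()
    mid = pc.spatial_filter(rand, ANATOMY, "mid").to_numpy()
    assert ((short == 1) <= (mid == 1)).all()


def test_spatial_filter_missing_node_raises():
    adj = pd.DataFrame(1, index=["ghost"], columns=["ghost"])
    with pytest.raises(ValueError):
        pc.spatial_filter(adj, ANATOMY, "short")
    with pytest.raises(ValueError):
        pc.spatial_filter(full_adjacency(), ANATOMY, "long")


def test_aggregate_weights_and_conservation(rng):
    neurons = [f"n{i}" for i in range(5)]
    nets = []
    for _ in range(4):
        nets.append(
            pd.DataFrame((rng.random((5, 5)) < 0.4).astype(int), index=neurons, columns=neurons)
        )
    weighted = pc.aggregate(nets)
    assert weighted.to_numpy().sum() == sum(n.to_numpy().sum() for n in nets)
    two = pc.aggregate([nets[0], nets[0]])
    assert (two.to_numpy() == 2 * nets[0].to_numpy()).all()
    with pytest.raises(ValueError):
        pc.aggregate([])


def test_cross_species_edge_labels_oracle(rng):
    """Labels equal exhaustive recomputation on random 8-node networks."""
    neurons = [f"n{i}" for i in range(8)]
    for _ in range(100):
        nets = {
            sp: pd.DataFrame(
                (rng.random((8, 8)) < 0.3).astype(int), index=neurons, columns=neurons
            )
            for sp in ["s1", "s2", "s3"]
        }
        labels = pc.cross_species_edges(nets)
        want = edge_labels_oracle({sp: nets[sp].to_numpy() for sp in nets})
        got = {
            (neurons.index(r["src"]), neurons.index(r["dst"])): r["label"]
            for _, r in labels.edges.iterrows()
        }
        assert got == want
        # conservation fractions recomputed from the oracle labels
        n_core = sum(1 for v in want.values() if v == "core")
        for sp in nets:
            n_edges = nets[sp].to_numpy().sum()
            if n_edges:
                assert labels.conservation[sp] == pytest.approx(n_core / n_edges)


def test_cross_species_node_mismatch_raises():
    a = pd.DataFrame(0, index=["x"], columns=["x"])
    b = pd.DataFrame(0, index=["y"], columns=["y"])
    with pytest.raises(ValueError):
        pc.cross_species_edges({"s1": a, "s2": b})


def test_core_pair_identity_categories():
    neurons = ["n1", "n2"]

    def net(on):
        m = pd.DataFrame(0, index=neurons, columns=neurons)
        if on:
            m.at["n1", "n2"] = 1
        return m

    binary = {sp: net(True) for sp in ["s1", "s2", "s3"]}
    labels = pc.cross_species_edges(binary)

    identical = {sp: {"P1": net(True)} for sp in binary}
    out = pc.core_pair_identity(labels, identical).set_index("category")
    assert out.at["identical", "n_edges"] == 1

    disjoint = {
        "s1": {"P1": net(True), "P2": net(False), "P3": net(False)},
        "s2": {"P1": net(False), "P2": net(True), "P3": net(False)},
        "s3": {"P1": net(False), "P2": net(False), "P3": net(True)},
    }
    out = pc.core_pair_identity(labels, disjoint).set_index("category")
    assert out.at["no_shared", "n_edges"] == 1

    partial = {
        "s1": {"P1": net(True), "P2": net(True), "P3": net(False)},
        "s2": {"P1": net(True), "P2": net(False), "P3": net(False)},
        "s3": {"P1": net(True), "P2": net(False), "P3": net(True)},
    }
    out = pc.core_pair_identity(labels, partial).set_index("category")
    assert out.at["partial", "n_edges"] == 1


@pytest.mark.parametrize(
    "n_npp,n_gpcr,expected",
    [
        (10, 120, "broadcaster"),
        (10, 10, "local"),
        (120, 130, "pervasive"),
        (120, 10, "integrative"),
        (50, 50, "local"),     # threshold is inclusive for restricted
        (51, 50, "integrative"),
    ],
)
def test_topology_classes(n_npp, n_gpcr, expected):
    assert pc.topology_class(n_npp, n_gpcr) == expected


def test_topology_difference_flag():
    neurons = [f"n{i}" for i in range(120)]
    pair_table = pd.DataFrame(
        [{"pair_id": "P1", "npp": "npp", "gpcr": "gpcr", "ec50_nm": 10.0}]
    )
    nb_local = pd.DataFrame(0, index=neurons, columns=["npp", "gpcr"])
    nb_local.iloc[:10] = 1
    nb_broad = nb_local.copy()
    nb_broad["gpcr"] = 1  # 120 receiver neurons
    out = pc.pair_topologies({"s1": nb_local, "s2": nb_broad, "s3": nb_broad}, pair_table)
    row = out.iloc[0]
    assert row["class_s1"] == "local"
    assert row["class_s2"] == row["class_s3"] == "broadcaster"
    assert bool(row["differs"])


def test_degrees_star_graph_and_conservation():
    neurons = ["hub"] + [f"leaf{i}" for i in range(5)]
    adj = pd.DataFrame(0, index=neurons, columns=neurons)
    adj.loc["hub", adj.columns != "hub"] = 1
    deg = pc.degrees(adj)
    assert deg.at["hub", "out_degree"] == 5 and deg.at["hub", "in_degree"] == 0
    assert deg["in_degree"].sum() == deg["out_degree"].sum() == 5
    corr = pc.degree_correlation({"s1": adj, "s2": adj.copy()})
    assert corr["pearson_r"].iloc[0] == pytest.approx(1.0)


def _labels_for(edges, specific):
    rows = [
        {"src": s, "dst": d, "n_species": 1 if (s, d) in specific else 3,
         "label": "specific:s1" if (s, d) in specific else "core"}
        for s, d in edges
    ]
    return pc.EdgeLabels(
        edges=pd.DataFrame(rows), conservation=pd.Series(), specific_fraction=pd.Series()
    )


def test_pharynx_enrichment_exact_example():
    """10 edges, 5 touching the pharynx, 4 specific all touching -> 5/210."""
    anatomy = pd.DataFrame(
        [
            {"neuron": "p", "class_name": "P", "bundle": 1, "area": "head", "pharynx": True},
            *[
                {"neuron": f"s{i}", "class_name": f"S{i}", "bundle": 2, "area": "head",
                 "pharynx": False}
                for i in range(6)
            ],
        ]
    )
    neurons = anatomy["neuron"].tolist()
    adj = pd.DataFrame(0, index=neurons, columns=neurons)
    touching = [("p", f"s{i}") for i in range(5)]          # 5 pharynx edges
    away = [(f"s{i}", f"s{(i + 1) % 5}") for i in range(5)]  # 5 somatic edges
    for s, d in touching + away:
        adj.at[s, d] = 1
    labels = _labels_for(touching + away, specific=set(touching[:4]))
    out = pc.pharynx_enrichment(labels, anatomy, "s1", adj)
    assert out["p"] == pytest.approx(5 / 210)
    assert out["p"] == pytest.approx(hypergeom_upper_tail(10, 5, 4, 4))

    # all edges touch the pharynx -> p = 1
    labels_all = _labels_for(touching, specific={touching[0]})
    adj_t = pd.DataFrame(0, index=neurons, columns=neurons)
    for s, d in touching:
        adj_t.at[s, d] = 1
    assert pc.pharynx_enrichment(labels_all, anatomy, "s1", adj_t)["p"] == pytest.approx(1.0)

    # zero species-specific edges -> p = 1 with a note
    labels_none = _labels_for(touching + away, specific=set())
    out = pc.pharynx_enrichment(labels_none, anatomy, "s1", adj)
    assert out["p"] == 1.0 and out["note"]


def test_planted_pharynx_rewiring_is_detected():
    """Pharynx-biased divergence yields p < 0.01 in >= 95% of seeds."""
    from caenodiverge import pipeline
    from caenodiverge import synthetic_world as sw

    hits = 0
    n_seeds = 100
    for seed in range(1, n_seeds + 1):
        # a sparse pair table keeps aggregation redundancy low enough for
        # species-specific edges to exist at all
        cfg = sw.WorldConfig(
            n_classes=40, n_genes_111=300, n_genes_none=0, n_orthogroups_multi=0,
            cells_per_class=10, n_pairs=20, pharynx_divergence_boost=8.0,
            family_divergence={**sw.DEFAULT_FAMILY_DIVERGENCE,
                               sw.FAM_NPP: 0.5, sw.FAM_GPCR_PEPTIDE: 0.6},
            seed=seed,
        )
        world = sw.make_world(cfg)
        binary = pipeline.truth_binary(world)
        _, labels, _, _, enrichment = pipeline.connectome_results(world, binary)
        if min(e["p"] for e in enrichment.values()) < 0.01:
            hits += 1
    assert hits / n_seeds >= 0.95
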