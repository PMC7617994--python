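"""Wireless neuropeptidergic connectomes.

Directed neuron-level networks inferred from co-expression of a
validated neuropeptide precursor (NPP, sender side) and its G-protein
coupled receptor (GPCR, receiver side): for pair N,
A(i, j)^N = NPP(i)^N x GPCR(j)^N. Per-pair binary networks are
constrained by anatomical signaling range (short range: same process
bundle, pharynx connectable only within the pharynx; mid range: same
anatomical area, pharynx counted inside the head) and summed into
weighted networks whose weight counts the mediating NPP-GPCR pairs.
Binarized networks from the three species are overlaid to label every
edge as core (all species), two-species, or species-specific, and to
test whether species-specific edges concentrate on the enteric
(pharyngeal) neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RANGES = ("short", "mid")
EC50_THRESHOLD_NM = 500.0


def neuron_expression(binary_classes: pd.DataFrame, anatomy: pd.DataFrame) -> pd.DataFrame:
    """Expand a class x gene binary matrix to neuron level.

    All neurons of a class share the class ON/OFF state.
    """
    missing = set(anatomy["class_name"]) - set(binary_classes.index)
    if missing:
        raise ValueError(f"classes missing from binary matrix: {sorted(missing)[:5]}")
    mat = binary_classes.loc[anatomy["class_name"]].to_numpy()
    return pd.DataFrame(mat, index=anatomy["neuron"].tolist(), columns=binary_classes.columns)


def pair_network(
    neuron_binary: pd.DataFrame,
    npp_gene: str,
    gpcr_gene: str,
    allow_autocrine: bool = True,
) -> pd.DataFrame:
    """Directed binary adjacency for one NPP-GPCR pair.

    Edge i -> j iff the NPP is ON in sender neuron i and the GPCR is
    ON in receiver neuron j. Self-edges model autocrine signaling and
    are kept by default.
    """
    neurons = neuron_binary.index
    if npp_gene not in neuron_binary.columns or gpcr_gene not in neuron_binary.columns:
        import warnings

        warnings.warn(f"unmapped gene for pair ({npp_gene}, {gpcr_gene}); empty network")
        return pd.DataFrame(
            np.zeros((len(neurons), len(neurons)), dtype=int), index=neurons, columns=neurons
        )
    send = neuron_binary[npp_gene].to_numpy(dtype=bool)
    recv = neuron_binary[gpcr_gene].to_numpy(dtype=bool)
    adj = np.outer(send, recv).astype(int)
    if not allow_autocrine:
        np.fill_diagonal(adj, 0)
    return pd.DataFrame(adj, index=neurons, columns=neurons)


def range_mask(anatomy: pd.DataFrame, signal_range: str) -> pd.DataFrame:
    """Neuron x neuron eligibility mask for a signaling range."""
    if signal_range not in RANGES:
        raise ValueError(f"range must be one of {RANGES}")
    anat = anatomy.set_index("neuron")
    neurons = anat.index
    bundle = anat["bundle"].to_numpy()
    area = anat["area"].to_numpy()
    pharynx = anat["pharynx"].to_numpy(dtype=bool)
    if signal_range == "short":
        same_bundle = bundle[:, None] == bundle[None, :]
        # pharyngeal neurons form a separate compartment at short range
        both_somatic = ~pharynx[:, None] & ~pharynx[None, :]
        both_pharynx = pharynx[:, None] & pharynx[None, :]
        mask = same_bundle & (both_somatic | both_pharynx)
    else:
        mask = area[:, None] == area[None, :]  # pharynx sits inside the head area
    return pd.DataFrame(mask.astype(int), index=neurons, columns=neurons)


def spatial_filter(
    adjacency: pd.DataFrame, anatomy: pd.DataFrame, signal_range: str
) -> pd.DataFrame:
    """Keep only edges eligible at the given anatomical range."""
    missing = set(adjacency.index) - set(anatomy["neuron"])
    if missing:
        raise ValueError(f"nodes missing from anatomy: {sorted(missing)[:5]}")
    mask = range_mask(anatomy, signal_range).loc[adjacency.index, adjacency.columns]
    return adjacency * mask


def aggregate(per_pair_networks: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-pair binary networks into a weighted network."""
    if not per_pair_networks:
        raise ValueError("no per-pair networks to aggregate")
    first = per_pair_networks[0]
    total = np.zeros(first.shape, dtype=int)
    for net in per_pair_networks:
        if not net.index.equals(first.index):
            raise ValueError("per-pair networks must share the node set")
        total += net.to_numpy()
    return pd.DataFrame(total, index=first.index, columns=first.columns)


def binarized(weighted: pd.DataFrame) -> pd.DataFrame:
    return (weighted > 0).astype(int)


@dataclass
class SpeciesNetworks:
    """Per-species per-pair and aggregate networks at one range."""

    species: str
    signal_range: str
    per_pair: dict[str, pd.DataFrame]
    weighted: pd.DataFrame

    @property
    def binary(self) -> pd.DataFrame:
        return binarized(self.weighted)


def build_species_network(
    neuron_binary: pd.DataFrame,
    pair_table: pd.DataFrame,
    anatomy: pd.DataFrame,
    species: str,
    signal_range: str = "mid",
    ec50_threshold: float = EC50_THRESHOLD_NM,
    allow_autocrine: bool = True,
) -> SpeciesNetworks:
    """Per-pair networks (EC50-passing pairs only), spatially filtered."""
    mask = range_mask(anatomy, signal_range).loc[neuron_binary.index, neuron_binary.index]
    usable = pair_table[pair_table["ec50_nm"] < ec50_threshold]
    per_pair = {}
    for _, row in usable.iterrows():
        npp = row[f"npp_{species}"] if f"npp_{species}" in pair_table.columns else row["npp"]
        gpcr = row[f"gpcr_{species}"] if f"gpcr_{species}" in pair_table.columns else row["gpcr"]
        net = pair_network(neuron_binary, npp, gpcr, allow_autocrine=allow_autocrine)
        per_pair[row["pair_id"]] = net * mask
    weighted = aggregate(list(per_pair.values())) if per_pair else pd.DataFrame(
        np.zeros((len(neuron_binary.index),) * 2, dtype=int),
        index=neuron_binary.index,
        columns=neuron_binary.index,
    )
    return SpeciesNetworks(
        species=species, signal_range=signal_range, per_pair=per_pair, weighted=weighted
    )


# ---------------------------------------------------------------------------
# Cross-species comparison
# ---------------------------------------------------------------------------


@dataclass
class EdgeLabels:
    edges: pd.DataFrame           # src, dst, n_species, label
    conservation: pd.Series       # per species: |core| / |edges(species)|
    specific_fraction: pd.Series  # per species: |specific(s)| / |edges(species)|


def cross_species_edges(binary_networks: dict[str, pd.DataFrame]) -> EdgeLabels:
    """Label every edge as core / two-species / species-specific.

    Expects binarized networks on a homologous node universe. Core
    edges are present in all species; species-specific edges in
    exactly one.
    """
    species = list(binary_networks)
    first = binary_networks[species[0]]
    for sp in species[1:]:
        net = binary_networks[sp]
        if not (net.index.equals(first.index) and net.columns.equals(first.columns)):
            raise ValueError("node universes must match across species")
    stack = np.stack([binary_networks[sp].to_numpy(dtype=bool) for sp in species])
    presence = stack.sum(axis=0)
    src_idx, dst_idx = np.nonzero(presence)
    neurons = first.index.to_numpy()
    n_present = presence[src_idx, dst_idx]

    labels = []
    for k, (i, j) in enumerate(zip(src_idx, dst_idx)):
        n = n_present[k]
        if n == len(species):
            labels.append("core")
        elif n == 1:
            owner = species[int(np.argmax(stack[:, i, j]))]
            labels.append(f"specific:{owner}")
        else:
            labels.append("two_species")
    edges = pd.DataFrame(
        {
            "src": neurons[src_idx],
            "dst": neurons[dst_idx],
            "n_species": n_present,
            "label": labels,
        }
    )
    conservation = {}
    specific_fraction = {}
    n_core = int((presence == len(species)).sum())
    for s, sp in enumerate(species):
        n_edges = int(stack[s].sum())
        n_specific = int(((presence == 1) & stack[s]).sum())
        conservation[sp] = n_core / n_edges if n_edges else np.nan
        specific_fraction[sp] = n_specific / n_edges if n_edges else np.nan
    return EdgeLabels(
        edges=edges,
        conservation=pd.Series(conservation),
        specific_fraction=pd.Series(specific_fraction),
    )


def core_pair_identity(
    edge_labels: EdgeLabels,
    per_pair_by_species: dict[str, dict[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Compare the mediating NPP-GPCR pair sets of each core edge.

    Pair ids are orthology-aligned across species. Each core edge is
    classified as 'identical' (same pair set in all species),
    'no_shared' (empty three-way intersection), or 'partial'.
    Returns per-category fractions and counts.
    """
    species = list(per_pair_by_species)
    core = edge_labels.edges[edge_labels.edges["label"] == "core"]
    cats = {"identical": 0, "no_shared": 0, "partial": 0}
    n = len(core)
    if n:
        pair_ids = list(per_pair_by_species[species[0]])
        first = per_pair_by_species[species[0]][pair_ids[0]]
        pos = {neuron: k for k, neuron in enumerate(first.index)}
        src = core["src"].map(pos).to_numpy()
        dst = core["dst"].map(pos).to_numpy()
        # species x pair x core-edge membership
        member = np.stack(
            [
                np.stack(
                    [
                        per_pair_by_species[sp][pid].to_numpy()[src, dst] > 0
                        for pid in pair_ids
                    ]
                )
                for sp in species
            ]
        )
        identical = (member == member[0]).all(axis=(0, 1))
        no_shared = ~member.all(axis=0).any(axis=0) & ~identical
        cats["identical"] = int(identical.sum())
        cats["no_shared"] = int(no_shared.sum())
        cats["partial"] = n - cats["identical"] - cats["no_shared"]
    return pd.DataFrame(
        {
            "category": list(cats),
            "n_edges": list(cats.values()),
            "fraction": [v / n if n else np.nan for v in cats.values()],
        }
    )


# ---------------------------------------------------------------------------
# Topology classes, degrees, pharynx enrichment
# ---------------------------------------------------------------------------

TOPOLOGY_THRESHOLD = 50  # neurons; restricted <= 50 < broad


def topology_class(n_npp_neurons: int, n_gpcr_neurons: int, threshold: int = TOPOLOGY_THRESHOLD) -> str:
    """Classify one pair's network by NPP/GPCR expression breadth."""
    npp_restricted = n_npp_neurons <= threshold
    gpcr_restricted = n_gpcr_neurons <= threshold
    if npp_restricted and gpcr_restricted:
        return "local"
    if npp_restricted and not gpcr_restricted:
        return "broadcaster"
    if not npp_restricted and gpcr_restricted:
        return "integrative"
    return "pervasive"


def pair_topologies(
    neuron_binary_by_species: dict[str, pd.DataFrame],
    pair_table: pd.DataFrame,
    threshold: int = TOPOLOGY_THRESHOLD,
    ec50_threshold: float = EC50_THRESHOLD_NM,
) -> pd.DataFrame:
    """Topology class per pair per species, plus a cross-species difference flag."""
    species = list(neuron_binary_by_species)
    usable = pair_table[pair_table["ec50_nm"] < ec50_threshold]
    rows = []
    for _, row in usable.iterrows():
        classes = {}
        for sp in species:
            nb = neuron_binary_by_species[sp]
            npp = row[f"npp_{sp}"] if f"npp_{sp}" in pair_table.columns else row["npp"]
            gpcr = row[f"gpcr_{sp}"] if f"gpcr_{sp}" in pair_table.columns else row["gpcr"]
            n_npp = int(nb[npp].sum()) if npp in nb.columns else 0
            n_gpcr = int(nb[gpcr].sum()) if gpcr in nb.columns else 0
            classes[sp] = topology_class(n_npp, n_gpcr, threshold)
        rec = {"pair_id": row["pair_id"], **{f"class_{sp}": c for sp, c in classes.items()}}
        rec["differs"] = len(set(classes.values())) > 1
        rows.append(rec)
    return pd.DataFrame(rows)


def degrees(binary_network: pd.DataFrame) -> pd.DataFrame:
    """Per-node in-, out- and total degree of a binary directed network."""
    adj = binary_network.to_numpy(dtype=bool)
    return pd.DataFrame(
        {
            "in_degree": adj.sum(axis=0),
            "out_degree": adj.sum(axis=1),
            "total_degree": adj.sum(axis=0) + adj.sum(axis=1),
        },
        index=binary_network.index,
    )


def degree_correlation(
    binary_networks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Pearson r between homologous nodes' total degrees, per species pair."""
    species = list(binary_networks)
    degs = {sp: degrees(binary_networks[sp])["total_degree"] for sp in species}
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            a, b = species[i], species[j]
            r = float(np.corrcoef(degs[a].to_numpy(), degs[b].to_numpy())[0, 1])
            rows.append({"species_a": a, "species_b": b, "pearson_r": r})
    return pd.DataFrame(rows)


def pharynx_enrichment(
    edge_labels: EdgeLabels,
    anatomy: pd.DataFrame,
    species: str,
    binary_network: pd.DataFrame,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Upper-tail hypergeometric test for pharynx-touching specific edges.

    Population: all edges of the species' network. Successes: edges
    with >= 1 pharyngeal endpoint. Draws: the species-specific edges.
    p = P(X >= observed). With ``smoothed=True`` the standard
    randomized p-value P(X > k) + U * P(X = k) is returned instead; it
    is exactly uniform under a random-subset null and is meant for
    calibration checks on this discrete test.
    """
    pharyngeal = set(anatomy.loc[anatomy["pharynx"].astype(bool), "neuron"])
    adj = binary_network.to_numpy(dtype=bool)
    src_idx, dst_idx = np.nonzero(adj)
    neurons = binary_network.index.to_numpy()
    touches = np.array(
        [neurons[i] in pharyngeal or neurons[j] in pharyngeal for i, j in zip(src_idx, dst_idx)]
    )
    M = len(src_idx)            # population: edges of this species
    n_success = int(touches.sum())

    specific = edge_labels.edges[edge_labels.edges["label"] == f"specific:{species}"]
    spec_set = set(zip(specific["src"], specific["dst"]))
    is_specific = np.array(
        [(neurons[i], neurons[j]) in spec_set for i, j in zip(src_idx, dst_idx)]
    )
    N_draw = int(is_specific.sum())
    k = int((touches & is_specific).sum())

    if N_draw == 0:
        return {
            "p": 1.0,
            "note": "no species-specific edges",
            "population": M,
            "successes": n_success,
            "draws": 0,
            "observed": 0,
        }
    dist = stats.hypergeom(M, n_success, N_draw)
    if smoothed:
        u = (rng or np.random.default_rng()).random()
        p = float(dist.sf(k) + u * dist.pmf(k))
    else:
        p = float(dist.sf(k - 1))
    return {
        "p": p,
        "note": "",
        "population": M,
        "successes": n_success,
        "draws": N_draw,
        "observed": k,
    }


def to_networkx(weighted: pd.DataFrame):
    """Weighted directed network as a networkx DiGraph (GraphML-ready)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(weighted.index)
    src, dst = np.nonzero(weighted.to_numpy())
    neurons = weighted.index.to_numpy()
    for i, j in zip(src, dst):
        g.add_edge(neurons[i], neurons[j], weight=int(weighted.iat[i, j]))
    return g
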