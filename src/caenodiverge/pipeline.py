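"""End-to-end orchestration of the comparative pipeline.

Chains the stages in study order on a synthetic world: count sampling,
feature construction, classifier training on the anchor species and
binarization of all species, consensus orthology from evidence tables,
Jaccard divergence, receptivity divergence, wireless connectomes, and
the secreted-protein discovery filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    divergence_metrics as dm,
    expression_binarizer as eb,
    ortho_consensus as oc,
    peptidergic_connectome as pc,
    receptor_divergence as rd,
    secreted_catalog as sc,
    synthetic_world as sw,
)

CURATED_FAMILIES = (
    sw.FAM_HOMEODOMAIN,
    sw.FAM_OTHER_TF,
    sw.FAM_NT_RECEPTOR,
    sw.FAM_NPP,
    sw.FAM_GPCR_PEPTIDE,
    sw.FAM_GPCR_ORPHAN,
    sw.FAM_NSSP,
)


@dataclass
class SpeciesData:
    cells: sw.CellData
    features: pd.DataFrame           # neuronal cells only
    binary: pd.DataFrame             # neuron classes x genes
    fraction_expressing: pd.DataFrame  # neuron classes x genes (feature B)


@dataclass
class PipelineResult:
    world: sw.SyntheticWorld
    model: eb.BinarizerModel
    species_data: dict[str, SpeciesData] = field(default_factory=dict)

    @property
    def binary_by_species(self) -> dict[str, pd.DataFrame]:
        return {sp: d.binary for sp, d in self.species_data.items()}


def _neuronal_subset(cells: sw.CellData) -> tuple:
    mask = (cells.metadata["tissue"] == "neuron").to_numpy()
    return cells.counts[mask], cells.metadata.loc[mask].reset_index(drop=True)


def binarize_world(
    world: sw.SyntheticWorld,
    seed: int,
    gt_fraction: float = 0.25,
    trees: int = 1000,
    folds: int = 0,
    split: float = 0.75,
) -> PipelineResult:
    """Sample counts, train the thresholding classifier on the anchor
    species, and binarize expression in all species."""
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(world.species) + 2)
    species_seeds = {
        sp: int(child.generate_state(1)[0] % (2**31 - 1))
        for sp, child in zip(world.species, children)
    }
    gt_seed = int(children[-2].generate_state(1)[0] % (2**31 - 1))
    train_seed = int(children[-1].generate_state(1)[0] % (2**31 - 1))

    anchor = world.species[0]
    ground_truth = sw.make_ground_truth(world, gt_fraction, gt_seed, species=anchor)

    result = PipelineResult(world=world, model=None)  # model filled below
    features_by_species = {}
    cells_by_species = {}
    for sp in world.species:
        cells = sw.sample_counts(world, sp, species_seeds[sp])
        counts_n, meta_n = _neuronal_subset(cells)
        features = eb.build_features(counts_n, meta_n, cells.gene_ids)
        cells_by_species[sp] = cells
        features_by_species[sp] = features

    model = eb.train_classifier(
        features_by_species[anchor],
        ground_truth,
        split=split,
        trees=trees,
        folds=folds,
        seed=train_seed,
    )
    result.model = model

    neuron_classes = world.neuron_classes
    for sp in world.species:
        features = features_by_species[sp]
        binary = eb.binarize(model, features).loc[neuron_classes]
        frac = (
            features["frac_expressing"].unstack("gene").loc[neuron_classes]
        )
        result.species_data[sp] = SpeciesData(
            cells=cells_by_species[sp],
            features=features,
            binary=binary,
            fraction_expressing=frac,
        )
    return result


def truth_binary(world: sw.SyntheticWorld) -> dict[str, pd.DataFrame]:
    """Planted neuron-class binary matrices (the noiseless reference)."""
    return {sp: world.neuron_truth(sp).astype(int) for sp in world.species}


# ---------------------------------------------------------------------------
# Stage wrappers
# ---------------------------------------------------------------------------


def consensus_from_world(
    world: sw.SyntheticWorld, error_rate=0.0, seed: int = 0
) -> oc.ConsensusOrthology:
    evidence = sw.make_ortho_evidence(world, error_rate=error_rate, seed=seed)
    genes_by_species = {sp: world.genes[sp]["gene"].tolist() for sp in world.species}
    return oc.call_consensus(evidence, genes_by_species, anchor=world.species[0])


def jaccard_results(
    world: sw.SyntheticWorld, binary_by_species: dict[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Gene- and cell-centered Jaccard on both gene pools."""
    triplets = world.triplets
    anchor = world.species[0]
    gene = dm.gene_jaccard(binary_by_species, triplets)
    pool_all = dm.neuronal_gene_pool(binary_by_species, triplets)
    fam = world.family_of(anchor)
    pool_curated = [g for g in pool_all if fam.get(g) in CURATED_FAMILIES]
    cell_all = dm.cell_jaccard(binary_by_species, triplets, gene_pool=pool_all)
    cell_curated = dm.cell_jaccard(binary_by_species, triplets, gene_pool=pool_curated)
    gene["family"] = gene["unit"].map(fam)
    return {"gene": gene, "cell_all": cell_all, "cell_curated": cell_curated}


def receptivity_results(
    world: sw.SyntheticWorld, binary_by_species: dict[str, pd.DataFrame]
):
    catalog = world.receptor_catalog()
    counts = rd.receptor_counts(binary_by_species, catalog)
    altered = rd.altered_receptivity(counts)
    deaf = rd.deaf_classes(counts)
    summary = rd.summarize_receptivity(altered, deaf)
    return counts, altered, deaf, summary


def connectome_results(
    world: sw.SyntheticWorld,
    binary_by_species: dict[str, pd.DataFrame],
    signal_range: str = "mid",
):
    anatomy = world.anatomy
    networks = {}
    for sp in world.species:
        neuron_binary = pc.neuron_expression(binary_by_species[sp], anatomy)
        networks[sp] = pc.build_species_network(
            neuron_binary, world.pair_table, anatomy, sp, signal_range=signal_range
        )
    labels = pc.cross_species_edges({sp: n.binary for sp, n in networks.items()})
    identity = pc.core_pair_identity(labels, {sp: n.per_pair for sp, n in networks.items()})
    degree_corr = pc.degree_correlation({sp: n.binary for sp, n in networks.items()})
    enrichment = {
        sp: pc.pharynx_enrichment(labels, anatomy, sp, networks[sp].binary)
        for sp in world.species
    }
    return networks, labels, identity, degree_corr, enrichment


def secreted_results(world: sw.SyntheticWorld, result: PipelineResult) -> dict:
    """Run the NSSP / glial-SSP / orphan-GPCR filters for every species."""
    out = {}
    anchor = world.species[0]
    npp_anchor = set(world.family_triplet_genes(sw.FAM_NPP))
    sensory = {
        c
        for c, cat in world.class_categories().items()
        if cat in sw.SENSORY_CATEGORIES
    }
    for sp in world.species:
        data = result.species_data[sp]
        cells = data.cells
        enrichment = sc.neuronal_enrichment(cells.counts, cells.metadata, cells.gene_ids)
        candidates = sc.structural_filter(
            world.annotations[sp], gene_universe=cells.gene_ids
        )
        trip_map = dict(zip(world.triplets[anchor], world.triplets[sp]))
        npp_sp = [trip_map[g] for g in npp_anchor]
        npp_reference = enrichment.loc[
            [g for g in npp_sp if g in enrichment.index], "neuronal"
        ].to_numpy()
        nssp = sc.nssp_call(candidates, enrichment, npp_reference)
        glial = sc.glial_ssp_call(candidates, enrichment, npp_reference)

        fam = world.family_of(sp)
        gpcr_list = [
            g
            for g in world.genes[sp]["gene"]
            if fam[g] in (sw.FAM_GPCR_PEPTIDE, sw.FAM_GPCR_ORPHAN, "gpcr_chemo")
        ]
        homologs = {
            g
            for g in world.genes[sp]["gene"]
            if fam[g] == sw.FAM_GPCR_PEPTIDE
            or (fam[g] == sw.FAM_NT_RECEPTOR and
                world.genes[sp].set_index("gene").at[g, "activity"] == "modulatory_metabotropic")
        }
        orphan = sc.orphan_gpcr_filter(
            gpcr_list,
            data.binary,
            homologs,
            sensory,
            data.fraction_expressing,
        )
        out[sp] = {
            "enrichment": enrichment,
            "candidates": candidates,
            "nssp": nssp,
            "glial": glial,
            "orphan": orphan,
        }
    return out
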