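# caenodiverge

Comparative analysis of neuron-class-resolved gene expression across
three *Caenorhabditis* nematode species (*C. elegans*-like anchor plus
two relatives). Nematode nervous systems keep their ~100+ homologous
neuron classes recognizable over tens of millions of years, yet the
genes each class deploys — especially neuronal signaling genes — drift
substantially. This package implements the computational layer of that
comparison as a tested, reusable pipeline for anyone working with
cross-species single-cell expression atlases of homologous cell types:

- **Species demultiplexing** of pooled reads by comparing per-genome
  alignments with an additive CIGAR score
  (`score = Σ(M,=) − NM − Σ(I,D,S)`).
- **Consensus 1:1 orthology** from five hierarchical evidence levels
  (unanimous > syntenic cDNA > syntenic protein > non-syntenic cDNA >
  non-syntenic protein), 1:1:1 triplet assembly, and strict
  ("1-to-none") / permissive species-specific gene sets.
- **Binary (ON/OFF) expression calling** per (gene, neuron class) with
  a random-forest classifier trained on reporter-derived ground truth
  over eight feature matrices (z-score fractions, expressing-cell
  fractions and counts, pseudobulks, max-normalized fractions, and
  per-gene variances).
- **Jaccard divergence**: for a gene triplet or a homologous class,
  `d = (union − intersect) / union` over ON classes (gene-centered) or
  ON genes (cell-centered), with configurable gene pools.
- **Neurotransmitter receptivity rules**: a (ligand, activity)
  category is *altered* when one species expresses ≥ 2 receptors and
  another 0; pooling activities per ligand yields
  *neurotransmitter-deaf* classes.
- **Wireless peptidergic connectomes**: directed neuron-level networks
  `A(i,j)ᴺ = NPP(i)ᴺ × GPCR(j)ᴺ` for validated neuropeptide–receptor
  pairs (EC₅₀ < 500 nM), constrained to shared process bundles (short
  range) or shared anatomical areas (mid range, pharynx inside head),
  aggregated into weighted networks, overlaid across species into
  core / two-species / species-specific edge labels, with topology
  classes (local / broadcaster / integrative / pervasive at the
  50-neuron breadth threshold), degree statistics, and a
  hypergeometric test for pharynx-concentrated rewiring.
- **Discovery filters** for neuronal small secreted proteins (NSSPs:
  < 200 aa, signal peptide, no TM or non-DUF domain, neuronal
  enrichment ≥ 2, expression above the 10% decile of conserved
  neuropeptide genes), their glial counterparts, and orphan GPCRs
  expressed in non-sensory neurons.

A first-class synthetic-world generator (`caenodiverge.synthetic_world`)
plants all of this structure — orthology relations, family-specific
divergence targets, anatomy, ligand–receptor tables, protein
annotations — and samples negative-binomial counts with ambient
background, so the entire pipeline is testable end to end without any
data download.

## Worked example

```python
from caenodiverge import synthetic_world as sw, pipeline

world = sw.make_world(sw.WorldConfig(seed=1))          # 3 species, 60 classes
result = pipeline.binarize_world(world, seed=2, trees=1000)
print(f"held-out precision {result.model.test_precision:.3f}, "
      f"recall {result.model.test_recall:.3f}")

binary = result.binary_by_species
jac = pipeline.jaccard_results(world, binary)
print("mean gene Jaccard", round(jac["gene"]["distance"].mean(), 3))

_, labels, identity, degree_corr, enrichment = pipeline.connectome_results(
    world, binary, "mid")
print("edge conservation", labels.conservation.round(3).to_dict())
```

prints (seed 1):

```
held-out precision 1.000, recall 1.000
mean gene Jaccard 0.352
edge conservation {'sp1': 0.822, 'sp2': 0.832, 'sp3': 0.84}
```

The classifier separates ON from OFF perfectly at the default
simulation regime (ON/OFF negative-binomial means 50/0.5); the mean
gene-centered Jaccard distance of 0.35 reflects the configured
family divergence targets; and 82–84% of each species' wireless
connections are present in all three species, even though the
divergence of the individual neuropeptide and receptor genes is
substantial — the redundancy of the aggregated network stabilizes its
edge structure.

There is also a thin CLI: `caenodiverge simulate`, `ortho`, `demux`,
and `run` (see `--help`).

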