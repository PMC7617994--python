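# Methods

This note documents the models, rules and numerical choices behind
`caenodiverge`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem left the
design genuinely open.

## The synthetic world

`make_world(WorldConfig)` generates the processed layer of a
three-species, whole-nervous-system single-cell study.

**Neuron classes and anatomy.** `n_classes` (default 60) homologous
neuron classes are allocated to functional categories in roughly the
proportions of the *C. elegans* nervous system: amphid/phasmid sensory
17%, other sensory 17%, interneurons 30%, motor neurons 23%,
pharyngeal (enteric) 13%. Each class expands to 1–6 member neurons
(drawn from `neurons_per_class_choices`, weighted toward bilateral
pairs), all of which share the class expression state. Neurons inherit
their class's process bundle (1–27); bundle 1 is pharynx-exclusive and
all pharyngeal classes live there; bundles map statically onto the
head / midbody / tail areas with the pharynx inside the head. A small
set of non-neuronal classes (muscle, hypodermis, intestine, glia,
gonad, epithelium) provides the non-neuronal compartment used by the
enrichment filters.

**Genes and orthology.** `n_genes_111` (default 600) genes form clean
1:1:1 triplets, partitioned into families with fixed sizes
(homeodomain TFs 40, other TFs 60, neurotransmitter receptors 60,
neuropeptide precursors 42, peptide GPCRs 47, orphan GPCRs 30,
NSSP-like 40, glial SSPs 10, remainder "other"). The NPP/GPCR family
sizes follow the validated ligand–receptor catalog the connectome is
built from. Per species, `n_genes_none` (default 40) 1-to-none novel
genes (30% chemoreceptor GPCRs, sensory-exclusive; ON classes biased
70% toward amphid/phasmid classes) and `n_orthogroups_multi` (default
15) many-to-many orthogroups complete the catalog.

**Planted expression divergence.** Each 1:1:1 gene draws an ON-class
union of size *u* from a family-specific breadth distribution
(homeodomain sparse, NPP/GPCR with a broad-expression mixture so that
both restricted and broad network topologies occur). Given the
family's target Jaccard distance *d*, the core (shared across all
species) size is *m* with **stochastic rounding** of `u·(1−d)`, so the
expected realized distance equals the target exactly; each non-core
class is ON in a random nonempty proper subset of species. For the
NPP/GPCR families, non-core classes are preferentially pharyngeal
(`pharynx_divergence_boost`, default 4), planting the enteric
rewiring hotspot the pharynx-enrichment test is designed to detect.
Family divergence defaults (homeodomain 0.10 < TFs 0.30 ≈ NPP 0.35 <
peptide GPCRs 0.50 ≈ receptors 0.55 < orphan GPCRs 0.60) encode the
qualitative ordering observed in this system: identity regulators
most conserved, receptor expression most labile.

**Counts.** `sample_counts` draws negative-binomial counts with mean
`on_mean` (50) for ON and `off_mean` (0.5) for OFF entries, shared
dispersion `nb_dispersion` (2), independent Poisson ambient background
(`ambient_rate`, 0.05) added to OFF entries, a lognormal per-cell
depth factor (σ = 0.3), and `cells_per_class` (200) cells per class.
These are the stated simulation conditions of the classifier
operating-regime check. The generator does **not** model doublets,
batch effects, UMI chemistry or transcript-length bias; passing tests
therefore demonstrate correctness of the analysis layer under the
assumed count model, not robustness to upstream artifacts real
atlases must correct before this layer.

**Decoys with guaranteed margins.** The discovery filters are checked
by exact closure, so the planted truth must be robustly decidable:
NSSP-like genes satisfy every criterion with margin (their breadth
floor sits 2 classes above the ceiling of the NPP reference's 10%
decile; they have zero non-neuronal expression, so enrichment is
infinite), and every other gene fails at least one criterion robustly
(length ≥ 200 aa, TM domain, non-DUF PFAM domain, known-NPP flag, or
strong non-neuronal expression). Glial SSPs express in glia plus a
few neuron classes, pinning enrichment well below 2. Orphan-GPCR
decoys are either sensory-exclusive or *sub-threshold*: expressed at
`dim_orphan_scale × on_mean` (mean ≈ 0.045/cell) in a few classes,
with truth OFF — they exercise the never-above-10%-of-cells removal
rule without creating unrecoverable ON labels.

**Randomness.** All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child per generation stage);
identical configuration implies byte-identical worlds.

## Consensus orthology

Evidence rows carry five hierarchical levels (1 unanimous, 2/3
syntenic cDNA/protein, 4/5 non-syntenic cDNA/protein). A gene's
*candidate* is its unique partner at the most stringent level at
which it has any partner; a pair is called iff the two genes are each
other's candidates. Under symmetric evidence this mutual rule is
equivalent to blocking a claim on a target gene whenever another gene
claims it at the same or a more stringent level — a strictly more
stringent competing claim necessarily lowers the target's own best
level, so only exact same-level ties can block, and those void all
claimants (conservative 1:1 semantics). Triplets are anchored on
species 1 (configurable): anchor gene *a* with consensus pairs to *b*
and *c* yields (a, b, c) unless an existing b↔c consensus pair
contradicts it; absent b↔c evidence does not block. Species pairs are
treated independently. Strict species-specific sets contain genes
with no evidence rows at all; permissive sets contain genes with no
consensus partner in either other species; genes with a consensus
partner in exactly one other species belong to neither.

## Species demultiplexing

The alignment support score is additive:
`Σ(M and = op lengths) − NM − Σ(I, D, S op lengths)`; hard clips
consume no bases and are ignored, X ops neither add nor subtract
(mismatches are charged through NM), unmapped reads score −∞. This
form was chosen for monotonicity (never increases with edit distance
or clip length) and tie-safety; a read is assigned only to a strictly
maximal species, ties are ambiguous and dropped. Only primary
alignments are considered.

## Binary expression calling

Eight features per (gene, class): (A) fraction of the class's cells
with per-gene z > 1.5, z-scored over all cells of the species on
normalized expression (z of a zero-variance gene is defined as 0);
(B) fraction of cells with raw count > 0; (C) their number; (D)
pseudobulk raw count sum; (E) feature B divided by the gene's maximum
class fraction; and per gene (F) variance of the pseudobulk count
matrix, (G) variance of the pseudobulk normalized matrix, (H) total
expressing cells. "Normalized expression" is depth normalization to
the median library size followed by log1p. Feature A's reduction to
class level (a per-class fraction of z-passing cells) mirrors the
other fraction features; whether the z-score should be computed
within or across cell types is ambiguous in general — here it is
across all cells of the species. The classifier is a
1000-tree random forest (any bagged tree ensemble satisfies the
contract) trained on a gene-disjoint 75/25 split with optional
gene-grouped k-fold cross validation on the training portion
(default 10 folds; the held-out precision/recall on unseen genes is
the reported operating point and is computed independently of the CV
loop). The decision threshold is the ensemble majority vote (0.5),
untuned. Classes absent from ground truth are predicted, never
trained on.

## Divergence metrics

Both Jaccard variants implement `d = (union − intersect)/union`:
gene-centered over classes (union = ON in ≥ 1 species of the compared
subset, intersect = ON in all), cell-centered over a gene pool within
one class. Units with empty unions are excluded rather than given a
distance. Gene pools are data-driven: "all neuronal" = triplets ON
anywhere in any species; "curated" = the neuronal-function families
of the catalog. Class-correlation checks use Pearson correlation of
pseudobulk profiles over marker genes with average-linkage
hierarchical clustering cut at the number of homologous classes.
Group statistics: Kruskal–Wallis omnibus, Dunn's rank-based pairwise
z-tests with tie correction, Benjamini–Hochberg adjustment
(significance α/2 = 0.025); exactly two groups use the Wilcoxon
rank-sum test; fully tied data reports NA.

## Receptivity rules

Receptor counts are tabulated per class × species × (ligand,
activity) from the binary matrices and a receptor catalog (glutamate,
GABA, pooled monoamines × excitatory-ionotropic,
inhibitory-ionotropic, modulatory-metabotropic; acetylcholine
receptors are excluded from divergence calls by catalog construction
because their broad, dim expression defeats the rule). A category is
*altered* iff max over species ≥ 2 and min = 0; pooling activities
per ligand and applying the same rule yields *deaf* calls. The rule
is implemented for any k ≥ 2 species via the same max/min form.

## Wireless connectomes

Per validated pair N (EC₅₀ < 500 nM), the directed adjacency is the
outer product of sender-side NPP expression and receiver-side GPCR
expression at neuron level; autocrine self-edges are allowed by
default (configurable; the choice only matters for degree counts).
Spatial constraints: short range requires a shared process bundle
with the pharynx as a closed compartment; mid range requires a shared
area with the pharynx inside the head. Aggregation sums per-pair
binary networks into weights; cross-species comparison binarizes
(weight ≥ 1) and labels edges core / two-species / species-specific
(two-species edges are labeled but summarized separately).
Core-edge molecular identity compares the aligned mediating pair sets
across species (identical / no shared pair / partial). Topology
classes use the 50-neuron breadth threshold (restricted ≤ 50 <
broad). Reciprocal connections count as two directed edges
throughout. Pharynx enrichment is an exact upper-tail hypergeometric
test (population = the species' edges, successes = edges touching ≥ 1
pharyngeal neuron, draws = the species-specific edges). Because the
test statistic is discrete, the exact p-value is super-uniform; for
calibration checks the standard randomized p-value
`P(X > k) + U·P(X = k)` — exactly uniform under a random-subset
null — is available via `smoothed=True`. Inference always uses the
exact p.

## Discovery filters

NSSP: length < 200 aa, signal peptide, no TM, no non-DUF domain
(DUF recognized by configurable id prefix), not a known NPP or
paralog, neuronal enrichment ≥ 2, and neuronal expression strictly
above the empirical quantile (linear-interpolation convention, fixed
for reproducibility) of the 1:1:1 NPP reference at decile 0.10 (a
per-species stringency override is an argument, e.g. 0.15 where a
species' expression distribution warrants it). Neuronal enrichment is
the ratio of *linear* depth-normalized pseudobulk means of the
neuronal vs non-neuronal compartments — on a log scale a genuine
two-fold difference would compress to ~1.2 and the ≥ 2 cutoff would
lose its meaning; an infinity sentinel marks genes absent from the
non-neuronal compartment. The glial branch applies the same filter
with enrichment < 2, making the two calls disjoint by construction.
Orphan GPCRs: remove transmitter/peptide-receptor homologs, remove
genes never expressed in > 10% of any class's cells (raw
expressing-cell fractions, not binary calls), keep genes ON in ≥ 1
non-sensory class, and flag neuron-type specificity at < 20 ON
classes.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generator defaults (60
classes × 200 cells × ~680 genes per species, 1000 trees) for the
classifier regime and closure checks, and at reduced sizes (10–40
classes, 10–40 cells/class) for combinatorial property checks; the
oracle-equivalence suites use ≥ 100 random instances of ≤ 50 genes /
8–10 nodes each. The pharynx-rewiring detection check uses a sparse
pair table (20 pairs) because at the full 84-pair redundancy the
aggregated network is so stabilized that species-specific edges
essentially vanish — itself a faithful reproduction of the
core-connectome robustness this system exhibits. Ties in the
consensus caller void all claimants; degenerate inputs (empty
evidence, empty classes, all-tied statistics, zero-variance genes,
empty unions) return empty/NA results or raise explicit errors as
documented per function.

## Known limitations

The generator's count model is deliberately simple (no doublets,
ambient correction artifacts, batch structure, or length bias), so
classifier metrics here are optimistic relative to real atlases. The
consensus caller assumes symmetric evidence rows; directed evidence
would need orientation before calling. Cross-species class
universes must be pre-aligned (homologous class names shared);
building that alignment (clustering, annotation, manifold
integration) is outside this package's scope, as are orthology
inference, domain/signal-peptide prediction, and marker scoring —
their outputs are inputs here.
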