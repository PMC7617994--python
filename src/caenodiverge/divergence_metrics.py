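"""Cross-species expression divergence metrics.

Gene-centered and cell(class)-centered Jaccard distances over binary
expression matrices, counts of species-specific gene usage per neuron
class, cross-species class-correlation checks, and the group
statistics used throughout (Kruskal-Wallis omnibus with Dunn's post
hoc z-tests and Benjamini-Hochberg adjustment; rank-sum for two
groups).

The Jaccard distance of a unit (gene triplet or homologous class) is
(union - intersect) / union where the union counts classes (genes) ON
in at least one species and the intersect counts those ON in all
compared species; units with an empty union are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def _aligned(binary_by_species: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    mats = list(binary_by_species.values())
    universe = set(mats[0].index)
    for m in mats[1:]:
        if set(m.index) != universe:
            raise ValueError("binary matrices must share the cross-species class universe")
    order = mats[0].index
    return {sp: m.loc[order] for sp, m in binary_by_species.items()}


def gene_jaccard(
    binary_by_species: dict[str, pd.DataFrame],
    triplets: pd.DataFrame,
    species_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Gene-centered Jaccard distance per ortholog triplet.

    union = number of classes in which the gene is ON in >= 1 species
    of the subset; intersect = classes ON in every species of the
    subset. Genes with an empty union (not expressed anywhere in the
    compared nervous systems) are excluded.
    """
    species = species_subset or list(binary_by_species)
    if not 2 <= len(species) <= 3:
        raise ValueError("species subset must contain 2 or 3 species")
    binary = _aligned({sp: binary_by_species[sp] for sp in species})
    rows = []
    anchor = triplets.columns[0]
    for _, trip in triplets.iterrows():
        stack = np.vstack(
            [binary[sp][trip[sp]].to_numpy(dtype=bool) for sp in species]
        )
        union = int(stack.any(axis=0).sum())
        inter = int(stack.all(axis=0).sum())
        if union == 0:
            continue
        rows.append(
            {
                "unit": trip[anchor],
                "union": union,
                "intersect": inter,
                "distance": (union - inter) / union,
            }
        )
    return pd.DataFrame(rows, columns=["unit", "union", "intersect", "distance"])


def cell_jaccard(
    binary_by_species: dict[str, pd.DataFrame],
    triplets: pd.DataFrame,
    gene_pool: list[str] | None = None,
    species_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Cell-centered Jaccard distance per homologous neuron class.

    The gene pool is a list of anchor-species triplet genes (defaults
    to all triplets); union/intersect count pool genes ON in the class
    in >= 1 / all compared species. Classes with an empty union are
    excluded.
    """
    species = species_subset or list(binary_by_species)
    if not 2 <= len(species) <= 3:
        raise ValueError("species subset must contain 2 or 3 species")
    binary = _aligned({sp: binary_by_species[sp] for sp in species})
    anchor = triplets.columns[0]
    trips = triplets
    if gene_pool is not None:
        if len(gene_pool) == 0:
            raise ValueError("gene pool must be non-empty")
        pool = set(gene_pool)
        trips = triplets[triplets[anchor].isin(pool)]
        if trips.empty:
            raise ValueError("gene pool does not intersect the triplet set")

    # species x class x gene boolean stack, aligned on triplets
    stacks = np.stack(
        [
            binary[sp][trips[sp].tolist()].to_numpy(dtype=bool)
            for sp in species
        ]
    )
    union = stacks.any(axis=0).sum(axis=1)
    inter = stacks.all(axis=0).sum(axis=1)
    classes = binary[species[0]].index
    rows = []
    for cls, u, i in zip(classes, union, inter):
        if u == 0:
            continue
        rows.append(
            {"unit": cls, "union": int(u), "intersect": int(i), "distance": (u - i) / u}
        )
    return pd.DataFrame(rows, columns=["unit", "union", "intersect", "distance"])


def neuronal_gene_pool(
    binary_by_species: dict[str, pd.DataFrame], triplets: pd.DataFrame
) -> list[str]:
    """Anchor genes of triplets ON in >= 1 class in >= 1 species."""
    binary = _aligned(binary_by_species)
    anchor = triplets.columns[0]
    pool = []
    for _, trip in triplets.iterrows():
        if any(binary[sp][trip[sp]].any() for sp in binary):
            pool.append(trip[anchor])
    return pool


def count_specific_expressed(
    binary: pd.DataFrame,
    specific_genes: set[str],
    exclude_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-class counts of species-specific genes that are ON.

    Returns absolute counts and counts normalized by the total number
    of ON genes in the class. ``exclude_genes`` supports gene-family
    exclusion filters (e.g. dropping all GPCRs).
    """
    cols = [c for c in binary.columns if exclude_genes is None or c not in exclude_genes]
    sub = binary[cols].astype(bool)
    in_set = np.array([c in specific_genes for c in cols])
    n_on = sub.to_numpy().sum(axis=1)
    n_specific = sub.to_numpy()[:, in_set].sum(axis=1) if in_set.any() else np.zeros(len(sub))
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(n_on > 0, n_specific / n_on, 0.0)
    return pd.DataFrame(
        {
            "class_name": sub.index,
            "n_specific_on": n_specific.astype(int),
            "n_on": n_on.astype(int),
            "normalized": normalized,
        }
    ).set_index("class_name")


@dataclass
class ClassCorrelation:
    correlation: pd.DataFrame      # (species, class) x (species, class) Pearson r
    cluster_labels: pd.Series      # flat-cluster labels at the 3-leaf cut


def class_correlation(
    pseudobulk_by_species: dict[str, pd.DataFrame],
    marker_genes: dict[str, list[str]],
) -> ClassCorrelation:
    """Correlate (species, class) pseudobulk profiles over marker genes.

    ``marker_genes`` maps each species to its (orthology-aligned, same
    order) marker gene columns. Pearson correlations are computed on
    the log-scaled pseudobulk profiles; profiles are clustered with
    average-linkage hierarchical clustering and cut so that the number
    of clusters equals the number of homologous classes.
    """
    n_markers = {len(v) for v in marker_genes.values()}
    if len(n_markers) != 1:
        raise ValueError("marker gene lists must be orthology-aligned (equal lengths)")
    if n_markers.pop() < 2:
        raise ValueError("need at least 2 marker genes")

    profiles = []
    labels = []
    for sp, pb in pseudobulk_by_species.items():
        sub = pb[marker_genes[sp]]
        for cls in pb.index:
            profiles.append(sub.loc[cls].to_numpy(dtype=float))
            labels.append((sp, cls))
    mat = np.vstack(profiles)
    corr = np.corrcoef(mat)
    index = pd.MultiIndex.from_tuples(labels, names=["species", "class_name"])
    corr_df = pd.DataFrame(corr, index=index, columns=index)

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    n_classes = len(next(iter(pseudobulk_by_species.values())).index)
    flat = fcluster(z, t=n_classes, criterion="maxclust")
    return ClassCorrelation(
        correlation=corr_df, cluster_labels=pd.Series(flat, index=index)
    )


# ---------------------------------------------------------------------------
# Group statistics: Kruskal-Wallis + Dunn + BH; rank-sum for two groups
# ---------------------------------------------------------------------------


@dataclass
class GroupStats:
    omnibus_stat: float | None
    omnibus_p: float | None
    test: str
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's post hoc z-tests on pooled ranks, with tie correction."""
    groups = pd.unique(labels)
    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def group_stats(values, labels, alpha: float = 0.025) -> GroupStats:
    """Omnibus + pairwise group comparison of a numeric variable.

    Three or more groups: Kruskal-Wallis omnibus followed by Dunn's
    pairwise z-tests with Benjamini-Hochberg adjustment. Exactly two
    groups: Wilcoxon rank-sum (Mann-Whitney). All-tied data yields an
    undefined omnibus reported as NA.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")

    if len(set(values.tolist())) == 1:
        return GroupStats(
            omnibus_stat=None,
            omnibus_p=None,
            test="undefined (all values tied)",
            pairwise=pd.DataFrame(columns=["group_a", "group_b", "z", "p_raw", "p_adj"]),
        )

    if len(groups) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": groups[0],
                    "group_b": groups[1],
                    "z": np.nan,
                    "p_raw": float(res.pvalue),
                    "p_adj": float(res.pvalue),
                }
            ]
        )
        return GroupStats(
            omnibus_stat=float(res.statistic),
            omnibus_p=float(res.pvalue),
            test="wilcoxon_rank_sum",
            pairwise=pairwise,
        )

    stat, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, labels)
    pairwise["p_adj"] = benjamini_hochberg(pairwise["p_raw"].to_numpy())
    return GroupStats(
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        test="kruskal_wallis_dunn_bh",
        pairwise=pairwise,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (statsmodels fdr_bh)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    mask = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj
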