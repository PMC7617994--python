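"""Discovery filters for candidate neuronal signaling proteins.

Neuronal small secreted proteins (NSSPs) are defined by four criteria:
(1) predicted protein shorter than 200 amino acids, (2) a signal
peptide, (3) no transmembrane domain and no annotated domain other
than DUF (domain of unknown function), excluding known neuropeptide
precursors and their paralogs, and (4) expression features: neuronal
enrichment >= 2 and a neuronal expression level above the 10% decile
of the conserved (1:1:1) neuropeptide precursor genes. The glial
small-secreted branch applies the same filter with neuronal
enrichment < 2. The orphan-GPCR filter selects candidate receptors
for internal signals: GPCRs that are not homologs of known
transmitter/peptide receptors, are robustly expressed somewhere
(> 10% of a class's cells), and are ON in at least one non-sensory
neuron class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_LENGTH_AA = 200
ENRICHMENT_MIN = 2.0
NPP_DECILE = 0.10
ROBUST_FRACTION = 0.10
SPECIFICITY_MAX_CLASSES = 20
DUF_PREFIXES = ("DUF",)
INF_ENRICHMENT = float("inf")


def _domain_list(domains) -> list[str]:
    if domains is None or (isinstance(domains, float) and np.isnan(domains)):
        return []
    if isinstance(domains, str):
        return [d for d in domains.replace(",", ";").split(";") if d.strip()]
    return list(domains)


def structural_filter(
    annotations: pd.DataFrame,
    gene_universe: list[str] | None = None,
    duf_prefixes: tuple[str, ...] = DUF_PREFIXES,
) -> set[str]:
    """Structurally NSSP-like genes.

    Keeps genes < 200 aa with a signal peptide, no transmembrane
    domain, not known neuropeptide precursors (or paralogs thereof),
    and no annotated domains except DUF-class ones. Genes of the
    universe missing from the annotation table are excluded with a
    warning.
    """
    ann = annotations.set_index("gene")
    if gene_universe is not None:
        missing = [g for g in gene_universe if g not in ann.index]
        if missing:
            warnings.warn(f"{len(missing)} genes lack annotations; excluded")
        ann = ann.loc[[g for g in gene_universe if g in ann.index]]
    kept = set()
    for gene, row in ann.iterrows():
        if row["length_aa"] >= MAX_LENGTH_AA:
            continue
        if not bool(row["signal_peptide"]) or bool(row["transmembrane"]):
            continue
        if bool(row.get("is_known_npp", False)):
            continue
        domains = _domain_list(row.get("domains"))
        if any(not d.startswith(duf_prefixes) for d in domains):
            continue
        kept.add(gene)
    return kept


def neuronal_enrichment(counts, metadata: pd.DataFrame, gene_ids: list[str]) -> pd.DataFrame:
    """Neuronal vs non-neuronal pseudobulk expression and their ratio.

    Cells are split on metadata.tissue == 'neuron'; each compartment's
    depth-normalized expression (linear scale, so that the enrichment
    cutoff of 2 means a genuine two-fold difference) is averaged per
    gene. The ratio carries an infinity sentinel where the
    non-neuronal compartment is zero.
    """
    from .expression_binarizer import depth_normalize

    tissue = metadata["tissue"].to_numpy()
    neuronal_mask = tissue == "neuron"
    if not neuronal_mask.any() or neuronal_mask.all():
        raise ValueError("need cells in both the neuronal and non-neuronal compartments")
    norm = depth_normalize(counts)
    neuronal = norm[neuronal_mask].mean(axis=0)
    non_neuronal = norm[~neuronal_mask].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            non_neuronal > 0, neuronal / non_neuronal,
            np.where(neuronal > 0, INF_ENRICHMENT, np.nan),
        )
    return pd.DataFrame(
        {
            "neuronal": neuronal,
            "non_neuronal": non_neuronal,
            "enrichment": ratio,
        },
        index=pd.Index(gene_ids, name="gene"),
    )


def npp_expression_threshold(
    npp_reference_values: np.ndarray, decile: float = NPP_DECILE
) -> float:
    """Empirical quantile (linear interpolation) of the NPP reference."""
    values = np.asarray(npp_reference_values, dtype=float)
    if len(values) == 0:
        raise ValueError("NPP reference values must be non-empty")
    return float(np.quantile(values, decile))


@dataclass
class NsspCall:
    genes: list[str]
    threshold: float
    audit: pd.DataFrame  # per candidate: enrichment, expression, pass flags


def nssp_call(
    candidates: set[str],
    enrichment: pd.DataFrame,
    npp_reference_values: np.ndarray,
    decile: float = NPP_DECILE,
    enrichment_min: float = ENRICHMENT_MIN,
) -> NsspCall:
    """NSSP calls among structurally filtered candidates.

    Keeps candidates with neuronal enrichment >= ``enrichment_min``
    and neuronal expression strictly above the reference decile of the
    conserved neuropeptide genes (the per-species stringency override
    is the ``decile`` argument).
    """
    threshold = npp_expression_threshold(npp_reference_values, decile)
    rows = []
    kept = []
    for gene in sorted(candidates):
        if gene not in enrichment.index:
            continue
        enr = enrichment.at[gene, "enrichment"]
        expr = enrichment.at[gene, "neuronal"]
        pass_enr = bool(enr >= enrichment_min)
        pass_expr = bool(expr > threshold)
        if pass_enr and pass_expr:
            kept.append(gene)
        rows.append(
            {
                "gene": gene,
                "enrichment": enr,
                "neuronal_expression": expr,
                "pass_enrichment": pass_enr,
                "pass_expression": pass_expr,
            }
        )
    return NsspCall(genes=kept, threshold=threshold, audit=pd.DataFrame(rows))


def glial_ssp_call(
    candidates: set[str],
    enrichment: pd.DataFrame,
    npp_reference_values: np.ndarray,
    decile: float = NPP_DECILE,
    enrichment_max: float = ENRICHMENT_MIN,
) -> NsspCall:
    """Glia-enriched branch: same filter with neuronal enrichment < 2."""
    threshold = npp_expression_threshold(npp_reference_values, decile)
    rows = []
    kept = []
    for gene in sorted(candidates):
        if gene not in enrichment.index:
            continue
        enr = enrichment.at[gene, "enrichment"]
        expr = enrichment.at[gene, "neuronal"]
        pass_enr = bool(enr < enrichment_max)
        pass_expr = bool(expr > threshold)
        if pass_enr and pass_expr:
            kept.append(gene)
        rows.append(
            {
                "gene": gene,
                "enrichment": enr,
                "neuronal_expression": expr,
                "pass_enrichment": pass_enr,
                "pass_expression": pass_expr,
            }
        )
    return NsspCall(genes=kept, threshold=threshold, audit=pd.DataFrame(rows))


@dataclass
class OrphanGpcrCall:
    genes: list[str]
    specific: pd.Series  # per kept gene: ON in < 20 classes


def orphan_gpcr_filter(
    gpcr_genes: list[str],
    binary: pd.DataFrame,
    receptor_homologs: set[str],
    sensory_classes: set[str],
    fraction_expressing: pd.DataFrame,
    robust_fraction: float = ROBUST_FRACTION,
    specificity_max: int = SPECIFICITY_MAX_CLASSES,
) -> OrphanGpcrCall:
    """Candidate internal-signaling GPCRs.

    Removes known transmitter/peptide receptor homologs (and their
    paralogs), genes never expressed in more than ``robust_fraction``
    of any class's cells, and genes ON only in sensory classes. Kept
    genes are flagged neuron-type-specific when ON in fewer than
    ``specificity_max`` classes (neuron classes only).
    """
    neuron_classes = [c for c in binary.index]
    kept = []
    specific = {}
    for gene in gpcr_genes:
        if gene in receptor_homologs:
            continue
        if gene not in binary.columns:
            continue
        max_frac = (
            float(fraction_expressing[gene].max())
            if gene in fraction_expressing.columns
            else 0.0
        )
        if max_frac <= robust_fraction:
            continue
        on_classes = {c for c in neuron_classes if binary.at[c, gene]}
        if not on_classes - sensory_classes:
            continue  # exclusively sensory (or nowhere)
        kept.append(gene)
        specific[gene] = len(on_classes) < specificity_max
    return OrphanGpcrCall(genes=kept, specific=pd.Series(specific, dtype=bool))
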