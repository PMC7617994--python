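"""Tiered consensus 1:1 orthology calling.

Orthology evidence rows rank support for a candidate gene pair into
five hierarchical levels (1 = unanimous across all discovery sources,
2/3 = syntenic cDNA/protein, 4/5 = non-syntenic cDNA/protein). The
consensus caller resolves this evidence into strict 1:1 pair maps per
species pair, assembles 1:1:1 triplets across three species, and
derives the species-specific ("1-to-none") and permissive gene sets.

Consensus semantics
-------------------
A gene's *candidate* is its unique partner at the most stringent level
at which it has any partner. A pair (A, A') is called iff A and A' are
each other's candidates. Because a competing claim on A' at a more
stringent level necessarily changes A's own best level, this mutual
rule is equivalent to blocking A whenever another gene claims A' at
the same or a more stringent level, with same-level competing claims
voiding all claimants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

EVIDENCE_COLUMNS = ("gene_a", "species_a", "gene_b", "species_b", "level")
VALID_LEVELS = frozenset(range(1, 6))


def _validate_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVIDENCE_COLUMNS) - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    bad = set(evidence["level"].unique()) - VALID_LEVELS
    if bad:
        raise ValueError(f"malformed orthology levels: {sorted(bad)}")
    if (evidence["species_a"] == evidence["species_b"]).any():
        raise ValueError("evidence rows must link genes from two different species")
    return evidence


@dataclass
class ConsensusOrthology:
    """Pair maps per species pair plus triplets and species-specific sets."""

    pair_maps: dict[frozenset, pd.DataFrame] = field(default_factory=dict)
    triplets: pd.DataFrame | None = None
    strict_specific: dict[str, set] = field(default_factory=dict)
    permissive_specific: dict[str, set] = field(default_factory=dict)


def call_consensus_pairs(
    evidence: pd.DataFrame, species_a: str, species_b: str
) -> pd.DataFrame:
    """Call the consensus 1:1 ortholog pairs between two species.

    Returns a frame with columns gene_a (species_a), gene_b (species_b)
    and level (the winning, i.e. most stringent shared, level). The
    mapping is 1:1 and symmetric by construction.
    """
    _validate_evidence(evidence)
    mask = (
        ((evidence["species_a"] == species_a) & (evidence["species_b"] == species_b))
        | ((evidence["species_a"] == species_b) & (evidence["species_b"] == species_a))
    )
    sub = evidence.loc[mask]
    if sub.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "level"])

    # orient rows as (gene in species_a, gene in species_b)
    flip = sub["species_a"] == species_b
    ga = sub["gene_a"].where(~flip, sub["gene_b"])
    gb = sub["gene_b"].where(~flip, sub["gene_a"])
    links = pd.DataFrame({"ga": ga, "gb": gb, "level": sub["level"]})
    links = links.groupby(["ga", "gb"], as_index=False)["level"].min()

    def candidates(links: pd.DataFrame, key: str, other: str) -> dict:
        best = links.groupby(key)["level"].transform("min")
        at_best = links.loc[links["level"] == best]
        counts = at_best.groupby(key)[other].nunique()
        unique = counts[counts == 1].index
        cand = (
            at_best.loc[at_best[key].isin(unique)]
            .drop_duplicates(subset=[key])
            .set_index(key)[[other, "level"]]
        )
        return {k: (row[other], row["level"]) for k, row in cand.iterrows()}

    cand_a = candidates(links, "ga", "gb")
    cand_b = candidates(links, "gb", "ga")

    rows = []
    for a, (b, lev) in cand_a.items():
        back = cand_b.get(b)
        if back is not None and back[0] == a:
            rows.append({"gene_a": a, "gene_b": b, "level": max(lev, back[1])})
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "level"])
    return out.sort_values(["gene_a"]).reset_index(drop=True)


def build_triplets(
    pair_maps: dict[frozenset, pd.DataFrame],
    species: list[str],
    anchor: str | None = None,
) -> pd.DataFrame:
    """Assemble 1:1:1 ortholog triplets anchored on one species.

    A triplet (a, b, c) is emitted when anchor gene a has consensus
    pairs to both other species. If a consensus pair between the two
    non-anchor species exists and contradicts (b maps to some c' != c),
    the triplet is dropped; absence of a b-c pair does not block.
    """
    if len(species) != 3:
        raise ValueError("triplet assembly requires exactly 3 species")
    anchor = anchor or species[0]
    if anchor not in species:
        raise ValueError(f"anchor {anchor!r} not among species {species}")
    others = [s for s in species if s != anchor]

    def oriented(sp_x: str, sp_y: str) -> dict:
        """gene-in-x -> gene-in-y from the stored pair map."""
        key = frozenset((sp_x, sp_y))
        pairs = pair_maps.get(key)
        if pairs is None or pairs.empty:
            return {}
        meta = pairs.attrs.get("species_pair", (sp_x, sp_y))
        if meta == (sp_x, sp_y):
            return dict(zip(pairs["gene_a"], pairs["gene_b"]))
        return dict(zip(pairs["gene_b"], pairs["gene_a"]))

    a_to_b = oriented(anchor, others[0])
    a_to_c = oriented(anchor, others[1])
    b_to_c = oriented(others[0], others[1])

    rows = []
    for a, b in a_to_b.items():
        c = a_to_c.get(a)
        if c is None:
            continue
        cross = b_to_c.get(b)
        if cross is not None and cross != c:
            continue  # contradictory b<->c consensus pair
        rows.append({anchor: a, others[0]: b, others[1]: c})
    return pd.DataFrame(rows, columns=[anchor, others[0], others[1]])


def species_specific_sets(
    evidence: pd.DataFrame,
    pair_maps: dict[frozenset, pd.DataFrame],
    genes_by_species: dict[str, list[str]],
) -> tuple[dict[str, set], dict[str, set]]:
    """Strict (1-to-none) and permissive species-specific gene sets.

    strict: genes with zero evidence rows to either other species.
    permissive: genes with no consensus 1:1 partner in either other
    species. Genes with a consensus partner in exactly one other
    species are excluded from both sets.
    """
    _validate_evidence(evidence)
    species = list(genes_by_species)
    evidenced: dict[str, set] = {sp: set() for sp in species}
    for col_g, col_s in (("gene_a", "species_a"), ("gene_b", "species_b")):
        for sp, group in evidence.groupby(col_s):
            if sp in evidenced:
                evidenced[sp].update(group[col_g])

    # per species: in how many *other* species does each gene have a partner
    partner_counts: dict[str, dict[str, int]] = {
        sp: {g: 0 for g in genes_by_species[sp]} for sp in species
    }
    for key, pairs in pair_maps.items():
        if pairs is None or pairs.empty:
            continue
        sp_a, sp_b = pairs.attrs.get("species_pair", tuple(sorted(key)))
        for g in pairs["gene_a"]:
            if g in partner_counts.get(sp_a, {}):
                partner_counts[sp_a][g] += 1
        for g in pairs["gene_b"]:
            if g in partner_counts.get(sp_b, {}):
                partner_counts[sp_b][g] += 1

    strict: dict[str, set] = {}
    permissive: dict[str, set] = {}
    for sp in species:
        genes = genes_by_species[sp]
        strict[sp] = {g for g in genes if g not in evidenced[sp]}
        permissive[sp] = {g for g in genes if partner_counts[sp][g] == 0}
    return strict, permissive


def call_consensus(
    evidence: pd.DataFrame,
    genes_by_species: dict[str, list[str]],
    anchor: str | None = None,
) -> ConsensusOrthology:
    """Run the full consensus workflow over all species pairs."""
    species = list(genes_by_species)
    result = ConsensusOrthology()
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            pairs = call_consensus_pairs(evidence, species[i], species[j])
            pairs.attrs["species_pair"] = (species[i], species[j])
            result.pair_maps[frozenset((species[i], species[j]))] = pairs
    if len(species) == 3:
        result.triplets = build_triplets(result.pair_maps, species, anchor)
    strict, permissive = species_specific_sets(
        evidence, result.pair_maps, genes_by_species
    )
    result.strict_specific = strict
    result.permissive_specific = permissive
    return result


def write_consensus(result: ConsensusOrthology, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, pairs in result.pair_maps.items():
        sp_a, sp_b = pairs.attrs.get("species_pair", tuple(sorted(key)))
        pairs.to_csv(out / f"pairs_{sp_a}_{sp_b}.tsv", sep="\t", index=False)
    if result.triplets is not None:
        result.triplets.to_csv(out / "triplets.tsv", sep="\t", index=False)
    for sp, genes in result.strict_specific.items():
        pd.Series(sorted(genes), name="gene").to_csv(
            out / f"strict_specific_{sp}.tsv", sep="\t", index=False
        )
    for sp, genes in result.permissive_specific.items():
        pd.Series(sorted(genes), name="gene").to_csv(
            out / f"permissive_specific_{sp}.tsv", sep="\t", index=False
        )
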