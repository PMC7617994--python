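"""Neurotransmitter receptivity divergence.

From binary expression matrices and a receptor catalog (one ligand and
one activity class per receptor gene; acetylcholine receptors are left
out of the catalog by construction because of their broad, dim
expression), counts how many receptors of each (ligand, activity)
category each neuron class expresses in each species, and applies the
altered-receptivity rule: a category is altered when at least one
species expresses >= 2 receptors in it and another species expresses
0. Aggregating all activities of a ligand with the same rule yields
"neurotransmitter-deaf" calls - complete loss/gain of receptivity to a
neurotransmitter system in one species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LIGANDS = ("glutamate", "gaba", "monoamine")
ACTIVITIES = ("excitatory_ionotropic", "inhibitory_ionotropic", "modulatory_metabotropic")


def receptor_counts(
    binary_by_species: dict[str, pd.DataFrame], catalog: pd.DataFrame
) -> pd.DataFrame:
    """Count ON receptor genes per class x species x (ligand, activity).

    ``catalog`` columns: gene (per-species gene ids via gene_<species>
    columns, or a single ``gene`` column valid for all species),
    ligand, activity. Catalog genes missing from a binary matrix are
    warned about and treated as OFF.
    """
    species = list(binary_by_species)
    classes = binary_by_species[species[0]].index
    rows = []
    for _, rec in catalog.iterrows():
        ligand, activity = rec["ligand"], rec["activity"]
        for sp in species:
            gene = rec[f"gene_{sp}"] if f"gene_{sp}" in catalog.columns else rec["gene"]
            binary = binary_by_species[sp]
            if gene not in binary.columns:
                warnings.warn(f"catalog gene {gene} absent from {sp} matrix; treated OFF")
                on = pd.Series(0, index=classes)
            else:
                on = binary[gene].astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "class_name": classes,
                        "species": sp,
                        "ligand": ligand,
                        "activity": activity,
                        "on": on.to_numpy(),
                    }
                )
            )
    if not rows:
        idx = pd.MultiIndex.from_product(
            [classes, species, [], []], names=["class_name", "species", "ligand", "activity"]
        )
        return pd.Series(0, index=idx, name="count").to_frame()
    long = pd.concat(rows, ignore_index=True)
    counts = (
        long.groupby(["class_name", "species", "ligand", "activity"], sort=True)["on"]
        .sum()
        .rename("count")
        .to_frame()
    )
    return counts


def altered_receptivity(counts: pd.DataFrame) -> pd.DataFrame:
    """Altered flag per class x (ligand, activity).

    altered = (max over species >= 2) and (min over species == 0).
    Works for any number of species >= 2.
    """
    wide = counts["count"].unstack("species")
    if wide.shape[1] < 2:
        raise ValueError("altered-receptivity rule needs >= 2 species")
    flag = (wide.max(axis=1) >= 2) & (wide.min(axis=1) == 0)
    return flag.rename("altered").to_frame()


def deaf_classes(counts: pd.DataFrame) -> pd.DataFrame:
    """Deaf flag per class x ligand: all activities pooled, same rule."""
    pooled = counts.groupby(["class_name", "species", "ligand"])["count"].sum()
    wide = pooled.unstack("species")
    if wide.shape[1] < 2:
        raise ValueError("deaf-class rule needs >= 2 species")
    flag = (wide.max(axis=1) >= 2) & (wide.min(axis=1) == 0)
    out = flag.rename("deaf").to_frame()
    # which species lost receptivity (count 0) for flagged units
    zero_species = wide.apply(
        lambda row: ",".join(sorted(c for c in wide.columns if row[c] == 0)), axis=1
    )
    out["species_at_zero"] = np.where(flag, zero_species, "")
    return out


@dataclass
class ReceptivitySummary:
    frac_classes_altered: float
    frac_classes_deaf: float
    deaf_counts_per_ligand: pd.Series
    n_classes: int


def summarize_receptivity(
    altered: pd.DataFrame, deaf: pd.DataFrame
) -> ReceptivitySummary:
    """Fractions of classes with >= 1 altered / deaf flag, per-ligand deaf counts."""
    classes_altered = altered.groupby("class_name")["altered"].any()
    classes_deaf = deaf.groupby("class_name")["deaf"].any()
    n_classes = len(classes_altered)
    deaf_per_ligand = deaf.loc[deaf["deaf"]].groupby("ligand").size()
    return ReceptivitySummary(
        frac_classes_altered=float(classes_altered.mean()) if n_classes else 0.0,
        frac_classes_deaf=float(classes_deaf.mean()) if len(classes_deaf) else 0.0,
        deaf_counts_per_ligand=deaf_per_ligand,
        n_classes=n_classes,
    )
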