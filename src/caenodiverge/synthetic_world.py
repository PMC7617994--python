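"""Synthetic three-species nervous-system worlds.

Generates a complete, seeded stand-in for the processed layer of a
cross-species *Caenorhabditis* single-cell study: homologous neuron
classes with anatomy (process bundles, anatomical areas, a pharynx
compartment), gene catalogs with mixed orthology structure (1:1:1
triplets, 1-to-none novel genes, many-to-many orthogroups), a planted
binary ON/OFF expression tensor with family-specific cross-species
divergence, negative-binomial count sampling with ambient background,
orthology-evidence tables, and mixed-species read alignments.

Every downstream stage of the pipeline is exercised against these
worlds; in the noiseless limit (``off_mean=0``, ``ambient_rate=0``,
zero evidence error) the pipeline recovers the planted truth exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sparse
from scipy.io import mmread, mmwrite

# ---------------------------------------------------------------------------
# Constants: neuron functional categories and gene families
# ---------------------------------------------------------------------------

CAT_AMPHID = "sensory_amphid_phasmid"
CAT_OTHER_SENSORY = "other_sensory"
CAT_INTER = "interneuron"
CAT_MOTOR = "motor"
CAT_PHARYNX = "pharyngeal"
NEURON_CATEGORIES = (CAT_AMPHID, CAT_OTHER_SENSORY, CAT_INTER, CAT_MOTOR, CAT_PHARYNX)
SENSORY_CATEGORIES = (CAT_AMPHID, CAT_OTHER_SENSORY)

# fraction of neuron classes per functional category (roughly the
# proportions of the 118 C. elegans classes; 14 are pharyngeal)
_CATEGORY_FRACTIONS = {
    CAT_AMPHID: 0.17,
    CAT_OTHER_SENSORY: 0.17,
    CAT_INTER: 0.30,
    CAT_MOTOR: 0.23,
    CAT_PHARYNX: 0.13,
}

FAM_HOMEODOMAIN = "homeodomain_tf"
FAM_OTHER_TF = "other_tf"
FAM_NT_RECEPTOR = "nt_receptor"
FAM_NPP = "npp"
FAM_GPCR_PEPTIDE = "gpcr_peptide"
FAM_GPCR_ORPHAN = "gpcr_orphan"
FAM_NSSP = "nssp_like"
FAM_GLIAL_SSP = "glial_ssp"
FAM_OTHER = "other"

NT_LIGANDS = ("glutamate", "gaba", "monoamine")
NT_ACTIVITIES = ("excitatory_ionotropic", "inhibitory_ionotropic", "modulatory_metabotropic")

N_BUNDLES = 27
PHARYNX_BUNDLE = 1  # the single pharynx-exclusive process bundle
AREAS = ("head", "midbody", "tail")

DEFAULT_FAMILY_DIVERGENCE = {
    FAM_HOMEODOMAIN: 0.10,
    FAM_OTHER_TF: 0.30,
    FAM_NT_RECEPTOR: 0.55,
    FAM_NPP: 0.35,
    FAM_GPCR_PEPTIDE: 0.50,
    FAM_GPCR_ORPHAN: 0.60,
    FAM_NSSP: 0.35,
    FAM_GLIAL_SSP: 0.35,
    FAM_OTHER: 0.30,
}

# fixed family sizes among the 1:1:1 triplet genes; NPP/GPCR counts follow
# the study design (42 NPP, 47 peptide GPCRs); the rest is the remainder
_FAMILY_SIZES = {
    FAM_HOMEODOMAIN: 40,
    FAM_OTHER_TF: 60,
    FAM_NT_RECEPTOR: 60,
    FAM_NPP: 42,
    FAM_GPCR_PEPTIDE: 47,
    FAM_GPCR_ORPHAN: 30,
    FAM_NSSP: 40,
    FAM_GLIAL_SSP: 10,
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class WorldConfig:
    """Simulation knobs.

    Defaults encode the study conditions: three species, 60 homologous
    neuron classes expanded into a ~200-neuron list, ON/OFF negative
    binomial means 50/0.5 with ambient background 0.05 and 200 cells
    per class.
    """

    n_species: int = 3
    n_classes: int = 60
    n_nonneuronal_classes: int = 6
    neurons_per_class_choices: tuple[int, ...] = (1, 2, 2, 2, 3, 4, 4, 6)
    n_genes_111: int = 600
    n_genes_none: int = 40          # per species, 1-to-none novel genes
    n_orthogroups_multi: int = 15   # many-to-many orthogroups
    family_divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_DIVERGENCE)
    )
    on_mean: float = 50.0
    off_mean: float = 0.5
    nb_dispersion: float = 2.0      # NB shape; var = mu + mu^2 / dispersion
    ambient_rate: float = 0.05      # Poisson mean added to OFF entries
    cells_per_class: int = 200
    n_pairs: int = 95               # candidate NPP-GPCR pairs (~84 pass EC50)
    n_dim_orphans: int = 3          # orphan-GPCR decoys with sub-threshold expression
    dim_orphan_scale: float = 0.0009  # on_mean multiplier for sub-threshold classes
    pharynx_divergence_boost: float = 4.0
    sensory_novel_bias: float = 0.7  # fraction of novel-gene ON classes in amphid/phasmid
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_classes": self.n_classes,
            "n_genes_111": self.n_genes_111,
            "cells_per_class": self.cells_per_class,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for fam, d in self.family_divergence.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"divergence target for {fam} must be in [0, 1], got {d}")
        if not self.on_mean > self.off_mean >= 0:
            raise ValueError("need on_mean > off_mean >= 0")
        if self.ambient_rate < 0:
            raise ValueError("ambient_rate must be >= 0")
        if any(d > 0 for d in self.family_divergence.values()) and self.n_classes < 2:
            raise ValueError(
                "non-zero divergence targets are unreachable with fewer than 2 neuron classes"
            )


# ---------------------------------------------------------------------------
# World container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    """The planted ground truth all pipeline stages are measured against."""

    config: WorldConfig
    species: list[str]
    classes: pd.DataFrame      # class_name, category, tissue, n_neurons
    anatomy: pd.DataFrame      # neuron, class_name, bundle, area, pharynx
    genes: dict[str, pd.DataFrame]   # per species: gene, family, orthology, ...
    triplets: pd.DataFrame     # one column per species; 1:1:1 ortholog triplets
    truth: dict[str, pd.DataFrame]   # per species: classes x genes bool
    subthreshold: dict[str, pd.DataFrame]  # classes x genes bool; dim expression, truth OFF
    pair_table: pd.DataFrame   # pair_id, npp_<sp>.., gpcr_<sp>.., ec50_nm, validated
    annotations: dict[str, pd.DataFrame]
    true_nssp: dict[str, set]
    true_glial_ssp: dict[str, set]
    true_orphan_gpcr: dict[str, set]
    multi_groups: list[dict[str, list[str]]]

    @property
    def neuron_classes(self) -> list[str]:
        return self.classes.loc[self.classes["tissue"] == "neuron", "class_name"].tolist()

    @property
    def nonneuronal_classes(self) -> list[str]:
        return self.classes.loc[self.classes["tissue"] != "neuron", "class_name"].tolist()

    def neuron_truth(self, species: str) -> pd.DataFrame:
        """Planted ON/OFF restricted to neuron classes."""
        return self.truth[species].loc[self.neuron_classes]

    def class_categories(self) -> pd.Series:
        return self.classes.set_index("class_name")["category"]

    def family_of(self, species: str) -> pd.Series:
        return self.genes[species].set_index("gene")["family"]

    def receptor_catalog(self) -> pd.DataFrame:
        """Neurotransmitter-receptor catalog with per-species gene columns."""
        anchor = self.species[0]
        genes = self.genes[anchor].set_index("gene")
        rows = []
        for _, trip in self.triplets.iterrows():
            g = trip[anchor]
            if genes.at[g, "family"] != FAM_NT_RECEPTOR:
                continue
            row = {f"gene_{sp}": trip[sp] for sp in self.species}
            row["ligand"] = genes.at[g, "ligand"]
            row["activity"] = genes.at[g, "activity"]
            row["is_111"] = True
            rows.append(row)
        return pd.DataFrame(rows)

    def family_triplet_genes(self, family: str) -> list[str]:
        """Anchor-species 1:1:1 gene ids belonging to a family."""
        anchor = self.species[0]
        fam = self.family_of(anchor)
        return [g for g in self.triplets[anchor] if fam.get(g) == family]


@dataclass
class CellData:
    """Sampled cell x gene counts plus per-cell metadata."""

    counts: sparse.csr_matrix  # cells x genes
    gene_ids: list[str]
    metadata: pd.DataFrame     # cell_id, species, class_name, category, tissue

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mmwrite(str(out / "matrix.mtx"), self.counts.tocoo(), field="integer")
        pd.Series(self.gene_ids, name="gene").to_csv(out / "genes.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "cells.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "CellData":
        src = Path(in_dir)
        counts = sparse.csr_matrix(mmread(str(src / "matrix.mtx")))
        genes = pd.read_csv(src / "genes.tsv", sep="\t")["gene"].tolist()
        meta = pd.read_csv(src / "cells.tsv", sep="\t")
        return cls(counts=counts, gene_ids=genes, metadata=meta)


# ---------------------------------------------------------------------------
# Gene catalog helpers
# ---------------------------------------------------------------------------


def _allocate_categories(n_classes: int) -> list[str]:
    """Deterministically split n_classes into functional categories."""
    alloc = {c: int(np.floor(f * n_classes)) for c, f in _CATEGORY_FRACTIONS.items()}
    remainder = n_classes - sum(alloc.values())
    order = sorted(_CATEGORY_FRACTIONS, key=_CATEGORY_FRACTIONS.get, reverse=True)
    for i in range(remainder):
        alloc[order[i % len(order)]] += 1
    cats: list[str] = []
    for c in NEURON_CATEGORIES:
        cats.extend([c] * alloc[c])
    return cats


def _family_plan(n_genes_111: int) -> list[str]:
    sized = dict(_FAMILY_SIZES)
    fixed = sum(sized.values())
    if n_genes_111 < fixed:
        # scale family sizes down proportionally for small worlds
        scale = n_genes_111 / fixed
        sized = {f: max(1, int(round(s * scale))) for f, s in sized.items()}
        while sum(sized.values()) > n_genes_111:
            biggest = max(sized, key=sized.get)
            sized[biggest] -= 1
    fams: list[str] = []
    for fam, n in sized.items():
        fams.extend([fam] * n)
    fams.extend([FAM_OTHER] * (n_genes_111 - len(fams)))
    return fams


def _breadth(rng: np.random.Generator, family: str, n_classes: int) -> int:
    """Draw the size of a gene's ON-class union (its expression breadth)."""
    def ri(lo: int, hi: int) -> int:
        hi = min(hi, n_classes)
        lo = min(lo, hi)
        return int(rng.integers(lo, hi + 1))

    if family == FAM_HOMEODOMAIN:
        return ri(2, 8)
    if family == FAM_OTHER_TF:
        return ri(2, 12)
    if family == FAM_NT_RECEPTOR:
        return ri(2, 15)
    if family in (FAM_NPP, FAM_GPCR_PEPTIDE):
        broad = rng.random() < (0.30 if family == FAM_NPP else 0.40)
        return ri(16, 30) if broad else ri(3, 12)
    if family == FAM_GPCR_ORPHAN:
        return ri(2, 10)
    if family in (FAM_NSSP, FAM_GLIAL_SSP):
        return ri(4, 12)
    return ri(2, 20)


# ---------------------------------------------------------------------------
# make_world
# ---------------------------------------------------------------------------


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world from ``config``.

    Family divergence targets are realized exactly by construction: each
    1:1:1 gene receives a union of ON classes of size ``u`` of which
    ``round(u * (1 - d))`` form the cross-species core; the remaining
    classes are each ON in a random nonempty proper subset of species.
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["anatomy", "genes", "expression", "pairs", "annotations"], seq.spawn(5)
        )
    }

    species = [f"sp{i + 1}" for i in range(config.n_species)]

    # --- neuron classes, neurons, anatomy -------------------------------
    rng = rngs["anatomy"]
    categories = _allocate_categories(config.n_classes)
    class_names = [f"NC{i + 1:03d}" for i in range(config.n_classes)]
    nonneuronal = ["muscle", "hypodermis", "intestine", "glia", "gonad", "epithelium"][
        : config.n_nonneuronal_classes
    ]

    # bundle -> area layout: bundle 1 is pharynx-exclusive and sits in the
    # head; the remaining 26 bundles split across head / midbody / tail
    bundle_area = {}
    for b in range(1, N_BUNDLES + 1):
        if b <= 12:
            bundle_area[b] = "head"
        elif b <= 20:
            bundle_area[b] = "midbody"
        else:
            bundle_area[b] = "tail"

    rows_anatomy = []
    n_neurons_per_class = []
    for cls, cat in zip(class_names, categories):
        k = int(rng.choice(config.neurons_per_class_choices))
        n_neurons_per_class.append(k)
        if cat == CAT_PHARYNX:
            bundle = PHARYNX_BUNDLE
        else:
            bundle = int(rng.integers(2, N_BUNDLES + 1))
        for j in range(k):
            rows_anatomy.append(
                {
                    "neuron": f"{cls}n{j + 1}",
                    "class_name": cls,
                    "bundle": bundle,
                    "area": bundle_area[bundle],
                    "pharynx": cat == CAT_PHARYNX,
                }
            )
    anatomy = pd.DataFrame(rows_anatomy)

    classes = pd.DataFrame(
        {
            "class_name": class_names + nonneuronal,
            "category": categories + ["non_neuronal"] * len(nonneuronal),
            "tissue": ["neuron"] * config.n_classes + ["non_neuronal"] * len(nonneuronal),
            "n_neurons": n_neurons_per_class + [0] * len(nonneuronal),
        }
    )
    all_class_names = classes["class_name"].tolist()

    # --- 1:1:1 gene catalog with planted divergence ---------------------
    rng = rngs["genes"]
    families = _family_plan(config.n_genes_111)
    for fam in set(families):
        d = config.family_divergence.get(fam, 0.0)
        if 0.0 < d and config.n_classes < 2:
            raise ValueError(f"divergence target {d} for {fam} unreachable with n_classes < 2")

    pharynx_classes = set(
        classes.loc[classes["category"] == CAT_PHARYNX, "class_name"]
    )
    sensory_classes = [
        c for c, cat in zip(class_names, categories) if cat in SENSORY_CATEGORIES
    ]
    amphid_classes = [c for c, cat in zip(class_names, categories) if cat == CAT_AMPHID]
    nonsensory_classes = [c for c in class_names if c not in set(sensory_classes)]

    gene_rows: dict[str, list[dict]] = {sp: [] for sp in species}
    truth_cols: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}
    triplet_rows = []
    class_index = {c: i for i, c in enumerate(all_class_names)}
    n_all = len(all_class_names)

    # a handful of planted decoys among orphan GPCRs: dim decoys express only
    # below the robust-detection threshold (truth OFF), sensory-only decoys
    # never leave the sensory classes
    orphan_idx = [i for i, f in enumerate(families) if f == FAM_GPCR_ORPHAN]
    dim_orphans = set(orphan_idx[: config.n_dim_orphans])
    sensory_only_orphans = set(orphan_idx[config.n_dim_orphans:config.n_dim_orphans + 3])

    # pre-draw NPP breadths so that the NSSP/glial-SSP breadth floor can be
    # placed a safe margin above the 10%-decile NPP reference threshold
    npp_breadths = {
        i: _breadth(rng, FAM_NPP, config.n_classes)
        for i, f in enumerate(families)
        if f == FAM_NPP
    }
    if npp_breadths:
        b10 = int(np.ceil(np.quantile(list(npp_breadths.values()), 0.10)))
    else:
        b10 = 2
    ssp_lo = min(b10 + 2, config.n_classes)
    ssp_hi = min(b10 + 10, config.n_classes)

    nonneuronal_idx = [class_index[c] for c in nonneuronal]
    glia_idx = class_index["glia"] if "glia" in class_index else None

    subset_choices = []
    for mask in range(1, 2 ** config.n_species - 1):
        subset_choices.append(
            [s for s in range(config.n_species) if mask >> s & 1]
        )

    true_orphan: dict[str, set] = {sp: set() for sp in species}

    subthreshold_cols: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}

    for i, fam in enumerate(families):
        d = config.family_divergence.get(fam, 0.0)
        gene_ids = {sp: f"{sp}_g{i:04d}" for sp in species}
        triplet_rows.append(gene_ids)

        if i in dim_orphans:
            # sub-threshold expression in a few classes; planted truth is OFF
            dim_classes = rng.choice(class_names, size=int(rng.integers(3, 8)), replace=False)
            col = np.zeros(n_all, dtype=bool)
            for c in dim_classes:
                col[class_index[c]] = True
            for sp in species:
                gene_rows[sp].append(
                    {
                        "gene": gene_ids[sp],
                        "family": fam,
                        "orthology": "111",
                        "expression_scale": 1.0,
                        "ligand": "",
                        "activity": "",
                    }
                )
                truth_cols[sp][gene_ids[sp]] = np.zeros(n_all, dtype=bool)
                subthreshold_cols[sp][gene_ids[sp]] = col
            continue

        if i in sensory_only_orphans:
            pool = sensory_classes
        elif fam == FAM_GPCR_ORPHAN:
            pool = nonsensory_classes  # guarantee >=1 non-sensory ON class
        else:
            pool = class_names
        if fam in (FAM_NSSP, FAM_GLIAL_SSP):
            u = int(rng.integers(ssp_lo, ssp_hi + 1))
        elif fam == FAM_NPP:
            u = npp_breadths[i]
        else:
            u = _breadth(rng, fam, config.n_classes)
        u = min(u, len(pool))
        if d > 0:
            u = max(u, 2)
        union = rng.choice(pool, size=u, replace=False)
        # stochastic rounding of the core size: E[(u - m) / u] = d exactly
        t = u * (1.0 - d)
        m = int(np.floor(t))
        if rng.random() < t - m:
            m += 1
        # pharynx-biased selection of the variable (species-divergent) classes
        weights = np.array(
            [config.pharynx_divergence_boost if c in pharynx_classes else 1.0 for c in union]
        )
        if fam in (FAM_NPP, FAM_GPCR_PEPTIDE):
            p = weights / weights.sum()
        else:
            p = np.full(u, 1.0 / u)
        variable = rng.choice(union, size=u - m, replace=False, p=p)
        variable_set = set(variable)
        core = [c for c in union if c not in variable_set]

        on = np.zeros((config.n_species, n_all), dtype=bool)
        for c in core:
            on[:, class_index[c]] = True
        for c in variable:
            members = subset_choices[rng.integers(0, len(subset_choices))]
            for s in members:
                on[s, class_index[c]] = True

        # conserved non-neuronal expression for selected families
        if fam == FAM_GLIAL_SSP and glia_idx is not None:
            on[:, glia_idx] = True
        elif fam in (FAM_OTHER, FAM_NT_RECEPTOR, FAM_OTHER_TF):
            prob = 0.3 if fam == FAM_OTHER else 0.1
            for ci in nonneuronal_idx:
                if rng.random() < prob:
                    on[:, ci] = True

        if fam == FAM_NT_RECEPTOR:
            ligand = NT_LIGANDS[rng.integers(0, len(NT_LIGANDS))]
            activity = NT_ACTIVITIES[rng.integers(0, len(NT_ACTIVITIES))]
        else:
            ligand = activity = ""
        for s, sp in enumerate(species):
            gene_rows[sp].append(
                {
                    "gene": gene_ids[sp],
                    "family": fam,
                    "orthology": "111",
                    "expression_scale": 1.0,
                    "ligand": ligand,
                    "activity": activity,
                }
            )
            truth_cols[sp][gene_ids[sp]] = on[s]

        if fam == FAM_GPCR_ORPHAN and i not in sensory_only_orphans:
            for s, sp in enumerate(species):
                on_classes = {all_class_names[j] for j in np.where(on[s])[0]}
                if on_classes - set(sensory_classes) and len(on_classes) > 0:
                    true_orphan[sp].add(gene_ids[sp])

    # --- species-specific (1-to-none) genes -----------------------------
    for s, sp in enumerate(species):
        for i in range(config.n_genes_none):
            gid = f"{sp}_n{i:03d}"
            fam = "gpcr_chemo" if rng.random() < 0.3 else "novel_other"
            u = int(rng.integers(1, 7))
            n_amphid = int(round(u * config.sensory_novel_bias))
            n_amphid = min(n_amphid, len(amphid_classes))
            chosen = list(rng.choice(amphid_classes, size=n_amphid, replace=False))
            # chemoreceptor GPCRs stay sensory-exclusive; other novel genes
            # spill into the wider nervous system
            rest_pool = [
                c
                for c in (sensory_classes if fam == "gpcr_chemo" else class_names)
                if c not in chosen
            ]
            chosen += list(
                rng.choice(rest_pool, size=min(u - n_amphid, len(rest_pool)), replace=False)
            )
            col = np.zeros(n_all, dtype=bool)
            for c in chosen:
                col[class_index[c]] = True
            gene_rows[sp].append(
                {
                    "gene": gid,
                    "family": fam,
                    "orthology": "none",
                    "expression_scale": 1.0,
                    "ligand": "",
                    "activity": "",
                }
            )
            truth_cols[sp][gid] = col

    # --- many-to-many orthogroups ---------------------------------------
    multi_groups: list[dict[str, list[str]]] = []
    for g in range(config.n_orthogroups_multi):
        group: dict[str, list[str]] = {}
        shared = rng.choice(class_names, size=int(rng.integers(2, 7)), replace=False)
        for sp in species:
            k = int(rng.integers(2, 4))
            members = []
            for j in range(k):
                gid = f"{sp}_m{g:02d}_{j}"
                members.append(gid)
                col = np.zeros(n_all, dtype=bool)
                keep = rng.random(len(shared)) < 0.7
                for c, kflag in zip(shared, keep):
                    if kflag:
                        col[class_index[c]] = True
                gene_rows[sp].append(
                    {
                        "gene": gid,
                        "family": "duplicated",
                        "orthology": "multi",
                        "expression_scale": 1.0,
                        "ligand": "",
                        "activity": "",
                    }
                )
                truth_cols[sp][gid] = col
            group[sp] = members
        multi_groups.append(group)

    genes = {sp: pd.DataFrame(gene_rows[sp]) for sp in species}
    truth = {
        sp: pd.DataFrame(truth_cols[sp], index=all_class_names)
        for sp in species
    }
    subthreshold = {}
    for sp in species:
        sub = pd.DataFrame(
            np.zeros((n_all, len(truth_cols[sp])), dtype=bool),
            index=all_class_names,
            columns=list(truth_cols[sp]),
        )
        for gid, col in subthreshold_cols[sp].items():
            sub[gid] = col
        subthreshold[sp] = sub
    triplets = pd.DataFrame(triplet_rows)

    # --- NPP-GPCR pair table with EC50 ----------------------------------
    rng = rngs["pairs"]
    fam_series = genes[species[0]].set_index("gene")["family"]
    npp_genes = [g for g in fam_series.index if fam_series[g] == FAM_NPP]
    gpcr_genes = [g for g in fam_series.index if fam_series[g] == FAM_GPCR_PEPTIDE]
    sp1_to_triplet = {row[species[0]]: row for row in triplet_rows}
    seen = set()
    pair_rows = []
    n_pairs = min(config.n_pairs, len(npp_genes) * len(gpcr_genes))
    while len(pair_rows) < n_pairs:
        npp = npp_genes[rng.integers(0, len(npp_genes))]
        gpcr = gpcr_genes[rng.integers(0, len(gpcr_genes))]
        if (npp, gpcr) in seen:
            continue
        seen.add((npp, gpcr))
        # ~90% of candidate pairs pass the 500 nM in vitro threshold
        if rng.random() < 0.9:
            ec50 = float(np.exp(rng.normal(np.log(50.0), 1.0)))
            ec50 = min(ec50, 499.0)
        else:
            ec50 = float(rng.uniform(500.0, 5000.0))
        row = {"pair_id": f"P{len(pair_rows) + 1:03d}", "ec50_nm": ec50, "validated": True}
        for sp in species:
            row[f"npp_{sp}"] = sp1_to_triplet[npp][sp]
            row[f"gpcr_{sp}"] = sp1_to_triplet[gpcr][sp]
        pair_rows.append(row)
    pair_table = pd.DataFrame(pair_rows)

    # --- protein annotations and planted secreted-protein truth ---------
    rng = rngs["annotations"]
    annotations: dict[str, pd.DataFrame] = {}
    true_nssp: dict[str, set] = {sp: set() for sp in species}
    true_glial: dict[str, set] = {sp: set() for sp in species}
    for sp in species:
        rows = []
        for _, grow in genes[sp].iterrows():
            gid, fam = grow["gene"], grow["family"]
            if fam in (FAM_NSSP, FAM_GLIAL_SSP, FAM_NPP):
                length = int(rng.integers(60, 191))
                sp_flag, tm_flag = True, False
                domains = "DUF%04d" % rng.integers(1, 5000) if rng.random() < 0.4 else ""
                known_npp = fam == FAM_NPP
                if fam == FAM_NSSP:
                    true_nssp[sp].add(gid)
                elif fam == FAM_GLIAL_SSP:
                    true_glial[sp].add(gid)
            else:
                # every other gene robustly fails >=1 structural criterion
                mode = rng.integers(0, 4)
                length = int(rng.integers(210, 900)) if mode == 0 else int(rng.integers(60, 600))
                sp_flag = mode != 1 and rng.random() < 0.5
                tm_flag = mode == 2 or (mode != 1 and rng.random() < 0.4)
                domains = "" if mode in (1, 2) and length < 200 else "PF%05d" % rng.integers(1, 20000)
                if mode == 3 and length < 200:
                    domains = "PF%05d" % rng.integers(1, 20000)
                known_npp = False
                if length < 200 and sp_flag and not tm_flag and not (
                    domains and not domains.startswith("DUF")
                ):
                    # close every loophole: mark as a known NPP paralog
                    known_npp = True
            rows.append(
                {
                    "gene": gid,
                    "length_aa": length,
                    "signal_peptide": sp_flag,
                    "transmembrane": tm_flag,
                    "domains": domains,
                    "is_known_npp": known_npp,
                }
            )
        annotations[sp] = pd.DataFrame(rows)

    return SyntheticWorld(
        config=config,
        species=species,
        classes=classes,
        anatomy=anatomy,
        genes=genes,
        triplets=triplets,
        truth=truth,
        subthreshold=subthreshold,
        pair_table=pair_table,
        annotations=annotations,
        true_nssp=true_nssp,
        true_glial_ssp=true_glial,
        true_orphan_gpcr=true_orphan,
        multi_groups=multi_groups,
    )


def realized_family_divergence(world: SyntheticWorld) -> pd.Series:
    """Mean planted gene-level Jaccard distance per family (1:1:1 genes).

    Computed directly on the truth tensor over neuron classes; used to
    verify that realized divergence matches the configured targets.
    """
    neuron_classes = world.neuron_classes
    fam = world.family_of(world.species[0])
    per_gene = {}
    for _, trip in world.triplets.iterrows():
        mats = [
            world.truth[sp].loc[neuron_classes, trip[sp]].to_numpy()
            for sp in world.species
        ]
        stack = np.vstack(mats)
        union = stack.any(axis=0).sum()
        inter = stack.all(axis=0).sum()
        if union == 0:
            continue
        per_gene[trip[world.species[0]]] = (union - inter) / union
    s = pd.Series(per_gene)
    return s.groupby(fam.reindex(s.index)).mean()


# ---------------------------------------------------------------------------
# sample_counts
# ---------------------------------------------------------------------------


def sample_counts(world: SyntheticWorld, species: str, seed: int) -> CellData:
    """Sample a cell x gene count matrix for one species.

    Counts are negative binomial with mean ``on_mean * expression_scale``
    where the truth tensor is ON and ``off_mean`` where OFF; OFF entries
    additionally receive independent Poisson(``ambient_rate``) ambient
    background. Each cell carries a lognormal depth factor.
    """
    if species not in world.species:
        raise ValueError(f"unknown species {species!r}")
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truth = world.truth[species]
    gene_ids = truth.columns.tolist()
    scales = (
        world.genes[species].set_index("gene")["expression_scale"].reindex(gene_ids).to_numpy()
    )
    class_meta = world.classes.set_index("class_name")

    sub = world.subthreshold[species]
    blocks = []
    meta_rows = []
    for cls in truth.index:
        on = truth.loc[cls].to_numpy()
        dim = sub.loc[cls].to_numpy()
        mu_row = np.where(on, cfg.on_mean * scales, cfg.off_mean)
        mu_row = np.where(dim & ~on, cfg.on_mean * cfg.dim_orphan_scale, mu_row)
        depth = rng.lognormal(mean=0.0, sigma=0.3, size=cfg.cells_per_class)
        mu = depth[:, None] * mu_row[None, :]
        counts = np.zeros(mu.shape, dtype=np.int64)
        pos = mu > 0
        if pos.any():
            r = cfg.nb_dispersion
            p = r / (r + mu[pos])
            counts[pos] = rng.negative_binomial(r, p)
        if cfg.ambient_rate > 0:
            off_mask = np.broadcast_to(~on, mu.shape)
            ambient = rng.poisson(cfg.ambient_rate, size=mu.shape)
            counts = counts + np.where(off_mask, ambient, 0)
        blocks.append(sparse.csr_matrix(counts))
        cat = class_meta.loc[cls, "category"]
        tissue = class_meta.loc[cls, "tissue"]
        for j in range(cfg.cells_per_class):
            meta_rows.append(
                {
                    "cell_id": f"{species}_{cls}_c{j + 1:04d}",
                    "species": species,
                    "class_name": cls,
                    "category": cat,
                    "tissue": tissue,
                }
            )
    return CellData(
        counts=sparse.vstack(blocks).tocsr(),
        gene_ids=gene_ids,
        metadata=pd.DataFrame(meta_rows),
    )


# ---------------------------------------------------------------------------
# make_ground_truth
# ---------------------------------------------------------------------------


def make_ground_truth(
    world: SyntheticWorld, fraction_genes: float, seed: int, species: str | None = None
) -> pd.DataFrame:
    """Sample a labeled (gene, class, label) ground-truth table.

    Labels are read off the planted truth tensor (neuron classes only)
    for a random subset of genes, emulating a reporter-validated
    ground-truth expression matrix.
    """
    if not 0 < fraction_genes <= 1:
        raise ValueError("fraction_genes must be in (0, 1]")
    species = species or world.species[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truth = world.neuron_truth(species)
    gene_ids = np.array(truth.columns)
    n = int(round(fraction_genes * len(gene_ids)))
    if n < 2:
        raise ValueError("fraction_genes yields fewer than 2 labeled genes")
    chosen = rng.choice(gene_ids, size=n, replace=False) if fraction_genes < 1 else gene_ids
    sub = truth[chosen]
    long = sub.stack().reset_index()
    long.columns = ["class_name", "gene", "label"]
    long["label"] = long["label"].astype(int)
    return long[["gene", "class_name", "label"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# make_ortho_evidence
# ---------------------------------------------------------------------------


def make_ortho_evidence(
    world: SyntheticWorld,
    error_rate: float | dict[int, float] = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a 5-level orthology-evidence table consistent with the truth.

    Level 1 rows mark unanimous orthologs (all sources agree); levels
    2-5 are synteny x sequence-source combinations. Planted errors add
    spurious partner rows and delete true rows at ``error_rate``
    (scalar, or a per-level mapping).
    """
    if isinstance(error_rate, dict):
        rates = {lv: float(error_rate.get(lv, 0.0)) for lv in range(1, 6)}
    else:
        rates = {lv: float(error_rate) for lv in range(1, 6)}
    for lv, r in rates.items():
        if not 0 <= r < 1:
            raise ValueError(f"error rate for level {lv} must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    species = world.species
    rows = []

    gene_pools = {sp: world.genes[sp]["gene"].tolist() for sp in species}

    for _, trip in world.triplets.iterrows():
        unanimous = rng.random() < 0.5
        levels = [1, 2, 3, 4, 5] if unanimous else sorted(
            rng.choice([2, 3, 4, 5], size=rng.integers(1, 4), replace=False)
        )
        for a in range(len(species)):
            for b in range(a + 1, len(species)):
                spa, spb = species[a], species[b]
                for lv in levels:
                    if rates[lv] > 0 and rng.random() < rates[lv]:
                        continue  # missing row
                    rows.append(
                        {
                            "gene_a": trip[spa],
                            "species_a": spa,
                            "gene_b": trip[spb],
                            "species_b": spb,
                            "level": int(lv),
                        }
                    )
                # spurious extra partner (never at level 1: unanimity excludes it)
                for lv in levels:
                    if lv > 1 and rates[lv] > 0 and rng.random() < rates[lv]:
                        decoy = gene_pools[spb][rng.integers(0, len(gene_pools[spb]))]
                        if decoy != trip[spb]:
                            rows.append(
                                {
                                    "gene_a": trip[spa],
                                    "species_a": spa,
                                    "gene_b": decoy,
                                    "species_b": spb,
                                    "level": int(lv),
                                }
                            )

    # many-to-many orthogroups: all cross-species member pairs at levels 4-5
    for group in world.multi_groups:
        for a in range(len(species)):
            for b in range(a + 1, len(species)):
                spa, spb = species[a], species[b]
                for ga in group[spa]:
                    for gb in group[spb]:
                        for lv in (4, 5):
                            rows.append(
                                {
                                    "gene_a": ga,
                                    "species_a": spa,
                                    "gene_b": gb,
                                    "species_b": spb,
                                    "level": lv,
                                }
                            )

    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# make_read_alignments
# ---------------------------------------------------------------------------

READ_LENGTH = 150
_BASE_ERROR = 0.005       # sequencing/alignment mismatches shared across genomes
_ARTIFACT_ERROR = 0.0005  # species-independent alignment artifacts


def make_read_alignments(
    world: SyntheticWorld,
    n_reads: int,
    divergence: float | dict[tuple[str, str], float] = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-read alignments of mixed-species reads to all genomes.

    Each read has a true source species. Its alignment to the true
    genome carries only shared base errors; alignments to the other
    genomes accumulate additional mismatches at the pairwise divergence
    rate, so the true genome scores better in expectation.
    Returns one row per (read, species) with a CIGAR string and NM tag.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    species = world.species

    def div(s: str, t: str) -> float:
        if s == t:
            return 0.0
        if isinstance(divergence, dict):
            return float(divergence.get((s, t), divergence.get((t, s), 0.0)))
        return float(divergence)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n_reads):
        true_sp = species[rng.integers(0, len(species))]
        base_mm = rng.binomial(READ_LENGTH, _BASE_ERROR)
        clip = int(rng.integers(0, 21)) if rng.random() < 0.2 else 0
        aligned = READ_LENGTH - clip
        cigar = f"{clip}S{aligned}M" if clip else f"{aligned}M"
        for sp in species:
            extra = rng.binomial(aligned, div(true_sp, sp))
            artifact = rng.binomial(aligned, _ARTIFACT_ERROR)
            rows.append(
                {
                    "read_id": f"r{i:06d}",
                    "true_species": true_sp,
                    "species": sp,
                    "cigar": cigar,
                    "nm": int(base_mm + extra + artifact),
                }
            )
    return pd.DataFrame(rows)


def write_alignments_sam(
    alignments: pd.DataFrame, out_dir: str | Path, reference_length: int = 100000
) -> dict[str, Path]:
    """Write one minimal SAM file per species (CIGAR + NM:i tag)."""
    import pysam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sp, sub in alignments.groupby("species"):
        path = out / f"{sp}.sam"
        header = {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"LN": reference_length, "SN": "chr1"}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for _, row in sub.sort_values("read_id").iterrows():
                a = pysam.AlignedSegment(fh.header)
                a.query_name = row["read_id"]
                a.reference_id = 0
                a.reference_start = 0
                a.mapping_quality = 60
                a.cigarstring = row["cigar"]
                a.query_sequence = "A" * READ_LENGTH
                a.set_tag("NM", int(row["nm"]))
                fh.write(a)
        paths[sp] = path
    return paths


# ---------------------------------------------------------------------------
# World writers (TSV round trips)
# ---------------------------------------------------------------------------


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.classes.to_csv(out / "classes.tsv", sep="\t", index=False)
    world.anatomy.to_csv(out / "anatomy.tsv", sep="\t", index=False)
    world.triplets.to_csv(out / "triplets.tsv", sep="\t", index=False)
    world.pair_table.to_csv(out / "pairs.tsv", sep="\t", index=False)
    for sp in world.species:
        world.genes[sp].to_csv(out / f"genes_{sp}.tsv", sep="\t", index=False)
        world.annotations[sp].to_csv(out / f"annotations_{sp}.tsv", sep="\t", index=False)
        truth = world.truth[sp].astype(int)
        truth.index.name = "class_name"
        truth.to_csv(out / f"truth_{sp}.tsv", sep="\t")
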