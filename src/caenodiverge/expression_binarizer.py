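"""Binary (ON/OFF) expression calling from single-cell counts.

Expression of each gene in each neuron class is thresholded into a
binary call by a random-forest classifier trained on reporter-derived
ground-truth labels. The feature set combines five (gene, class)-level
matrices and three gene-level summaries:

A. fraction of a class's cells whose z-scored normalized expression
   exceeds 1.5 (z computed per gene over all cells of the species),
B. fraction of expressing cells (raw count > 0) per class,
C. number of expressing cells per class,
D. pseudobulked raw counts per class,
E. feature B divided by the gene's maximum class fraction
   ("percentile thresholding"),
F. variance of the pseudobulk count matrix per gene,
G. variance of the pseudobulk normalized-expression matrix per gene,
H. total number of expressing cells per gene.

Normalized expression is depth normalization to the median library
size followed by log1p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import GroupKFold, cross_val_score

FEATURE_NAMES = [
    "zfrac",
    "frac_expressing",
    "n_expressing",
    "pseudobulk",
    "max_norm_frac",
    "pseudobulk_var",
    "pseudobulk_norm_var",
    "total_expressing",
]

Z_CUTOFF = 1.5


def _to_dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=np.float64)
    return np.asarray(counts, dtype=np.float64)


def depth_normalize(counts) -> np.ndarray:
    """Scale each cell to the median library size (linear scale)."""
    x = _to_dense(counts)
    lib = x.sum(axis=1)
    med = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
    scale = np.divide(med, lib, out=np.ones_like(lib), where=lib > 0)
    return x * scale[:, None]


def normalize_counts(counts) -> np.ndarray:
    """Depth-normalize to the median library size, then log1p."""
    return np.log1p(depth_normalize(counts))


def pseudobulk(
    counts,
    metadata: pd.DataFrame,
    normalized: bool = False,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class aggregate expression: class x gene matrix.

    Raw mode sums counts within a class; normalized mode averages the
    depth-normalized log-scaled expression. Classes with no cells get
    a row of zeros (with a warning).
    """
    if "class_name" not in metadata.columns:
        raise ValueError("metadata must carry a class_name column")
    x = normalize_counts(counts) if normalized else _to_dense(counts)
    classes = metadata["class_name"].to_numpy()
    uniq = pd.unique(classes)
    rows = []
    for cls in uniq:
        mask = classes == cls
        if not mask.any():
            warnings.warn(f"class {cls} has no cells; emitting zeros")
            rows.append(np.zeros(x.shape[1]))
        elif normalized:
            rows.append(x[mask].mean(axis=0))
        else:
            rows.append(x[mask].sum(axis=0))
    out = pd.DataFrame(np.vstack(rows), index=pd.Index(uniq, name="class_name"))
    if gene_ids is not None:
        out.columns = gene_ids
    return out


def build_features(counts, metadata: pd.DataFrame, gene_ids: list[str]) -> pd.DataFrame:
    """Compute the eight-feature table, one row per (gene, class)."""
    x = _to_dense(counts)
    if x.shape[0] != len(metadata):
        raise ValueError("counts and metadata disagree on the number of cells")
    if x.shape[1] != len(gene_ids):
        raise ValueError("counts and gene_ids disagree on the number of genes")
    norm = normalize_counts(x)
    classes = metadata["class_name"].to_numpy()
    uniq = list(pd.unique(classes))
    n_classes, n_genes = len(uniq), len(gene_ids)

    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (norm - mu) / sd, 0.0)  # zero-variance genes -> z = 0
    z_on = z > Z_CUTOFF
    expressing = x > 0

    zfrac = np.zeros((n_classes, n_genes))
    frac = np.zeros((n_classes, n_genes))
    n_expr = np.zeros((n_classes, n_genes))
    pb_raw = np.zeros((n_classes, n_genes))
    pb_norm = np.zeros((n_classes, n_genes))
    for i, cls in enumerate(uniq):
        mask = classes == cls
        n_cells = mask.sum()
        zfrac[i] = z_on[mask].mean(axis=0) if n_cells else 0.0
        frac[i] = expressing[mask].mean(axis=0) if n_cells else 0.0
        n_expr[i] = expressing[mask].sum(axis=0)
        pb_raw[i] = x[mask].sum(axis=0)
        pb_norm[i] = norm[mask].mean(axis=0) if n_cells else 0.0

    max_frac = frac.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        max_norm_frac = np.where(max_frac > 0, frac / max_frac, 0.0)

    pb_var = pb_raw.var(axis=0)
    pb_norm_var = pb_norm.var(axis=0)
    total_expr = expressing.sum(axis=0)

    index = pd.MultiIndex.from_product([gene_ids, uniq], names=["gene", "class_name"])
    table = pd.DataFrame(
        {
            "zfrac": zfrac.T.ravel(),
            "frac_expressing": frac.T.ravel(),
            "n_expressing": n_expr.T.ravel(),
            "pseudobulk": pb_raw.T.ravel(),
            "max_norm_frac": max_norm_frac.T.ravel(),
            "pseudobulk_var": np.repeat(pb_var, n_classes),
            "pseudobulk_norm_var": np.repeat(pb_norm_var, n_classes),
            "total_expressing": np.repeat(total_expr, n_classes),
        },
        index=index,
    )
    return table


@dataclass
class BinarizerModel:
    model: RandomForestClassifier
    feature_names: list[str]
    seed: int
    test_precision: float | None = None
    test_recall: float | None = None
    cv_scores: list[float] | None = None
    test_genes: list[str] | None = None


def train_classifier(
    features: pd.DataFrame,
    ground_truth: pd.DataFrame,
    split: float = 0.75,
    trees: int = 1000,
    folds: int = 10,
    seed: int = 0,
) -> BinarizerModel:
    """Train the thresholding classifier on ground-truth labels.

    The labeled genes are split gene-disjointly into training (``split``)
    and held-out test fractions; ``folds``-fold gene-grouped cross
    validation is run on the training portion when ``folds >= 2``.
    Returns the fitted model with held-out precision and recall.
    """
    labeled = ground_truth.set_index(["gene", "class_name"])["label"]
    common = features.index.intersection(labeled.index)
    if common.empty:
        raise ValueError("no overlap between features and ground truth")
    X = features.loc[common, FEATURE_NAMES]
    y = labeled.loc[common].astype(int)
    if y.nunique() < 2:
        raise ValueError("ground truth must contain both ON and OFF labels")

    genes = np.array(sorted(common.get_level_values("gene").unique()))
    per_gene_any_on = ground_truth.groupby("gene")["label"].max()
    if (per_gene_any_on == 1).sum() < 2:
        raise ValueError("ground truth must cover at least 2 genes per label class")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(genes)
    n_train = int(round(split * len(genes)))
    train_genes = set(perm[:n_train])
    test_genes = [g for g in genes if g not in train_genes]

    gene_level = common.get_level_values("gene")
    train_mask = np.array([g in train_genes for g in gene_level])
    X_train, y_train = X[train_mask], y[train_mask]
    X_test, y_test = X[~train_mask], y[~train_mask]

    model = RandomForestClassifier(
        n_estimators=trees, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
    )

    cv_scores = None
    if folds and folds >= 2:
        groups = gene_level[train_mask]
        cv = GroupKFold(n_splits=min(folds, len(set(groups))))
        cv_scores = cross_val_score(
            model, X_train, y_train, groups=groups, cv=cv, scoring="f1"
        ).tolist()

    model.fit(X_train, y_train)
    if len(y_test) and y_test.nunique() > 1:
        pred = model.predict(X_test)
        test_precision = float(precision_score(y_test, pred, zero_division=0))
        test_recall = float(recall_score(y_test, pred, zero_division=0))
    else:
        test_precision = test_recall = None

    return BinarizerModel(
        model=model,
        feature_names=list(FEATURE_NAMES),
        seed=seed,
        test_precision=test_precision,
        test_recall=test_recall,
        cv_scores=cv_scores,
        test_genes=test_genes,
    )


def binarize(model: BinarizerModel, features: pd.DataFrame) -> pd.DataFrame:
    """Predict the full class x gene binary (ON/OFF) matrix."""
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise ValueError(f"feature schema mismatch; missing {sorted(missing)}")
    pred = model.model.predict(features[model.feature_names])
    out = pd.Series(pred, index=features.index, name="on").unstack("gene")
    return out.astype(int)
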