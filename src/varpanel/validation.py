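"""Panel validation: cross-cohort classification AUC and pathway enrichment.

A gene panel's diagnostic value is assessed by rotation over independent
expression cohorts: each dataset in turn serves as the training set for a
seeded random-forest classifier over the panel genes (restricted to genes
present in both cohorts), every remaining dataset is scored, and the
per-round ROC AUC is summarized by mean and median over the n*(n-1) rounds.

Two comparators complete the protocol: a differential-expression panel
(Welch t-test per gene, Benjamini-Hochberg FDR < 0.05 and |log2 fold
change| >= 1.5), and hypergeometric over-representation against pathway
gene sets, where a disease-relevant panel should rank the disease's target
pathway near the top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .panel import Panel

__all__ = [
    "ExpressionDataset",
    "ValidationReport",
    "cross_dataset_auc",
    "deg_panel",
    "enrichment_rank",
    "panel_overlap_check",
    "read_expression_tsv",
    "read_gmt",
]

HEALTHY, DISEASE = "HEALTHY", "DISEASE"
DEFAULT_N_TREES = 500


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with binary clinical labels."""

    dataset_id: str
    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    labels: pd.Series  # per sample: HEALTHY or DISEASE

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.labels.index):
            raise ValueError(f"{self.dataset_id}: sample ids of matrix and labels differ")
        classes = set(self.labels)
        if not classes <= {HEALTHY, DISEASE}:
            raise ValueError(f"{self.dataset_id}: labels must be HEALTHY/DISEASE, got {classes}")
        if classes != {HEALTHY, DISEASE}:
            raise ValueError(f"{self.dataset_id}: both label classes must be present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def y(self) -> np.ndarray:
        return (self.labels == DISEASE).to_numpy(dtype=int)


@dataclass
class ValidationReport:
    rounds: list[tuple[str, str, float]] = field(default_factory=list)
    skipped_rounds: list[tuple[str, str, str]] = field(default_factory=list)
    overlap_pct: dict[str, float] = field(default_factory=dict)

    @property
    def aucs(self) -> list[float]:
        return [auc for _, _, auc in self.rounds]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs)) if self.rounds else float("nan")

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs)) if self.rounds else float("nan")


def read_expression_tsv(
    matrix_path: str | Path, labels_path: str | Path, dataset_id: str | None = None
) -> ExpressionDataset:
    """Read a genes-in-rows TSV matrix plus a (sample, label) TSV."""
    matrix_path = Path(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "label"])
    labels = pd.Series(labels_df["label"].to_numpy(), index=labels_df["sample"])
    labels = labels.reindex(values.columns)
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem, values=values, labels=labels
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT pathway gene sets (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def _panel_genes(panel: Panel | Sequence[str]) -> list[str]:
    if isinstance(panel, Panel):
        return panel.gene_symbols
    return sorted(set(panel))


def cross_dataset_auc(
    panel: Panel | Sequence[str],
    datasets: Sequence[ExpressionDataset],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ValidationReport:
    """Leave-one-dataset-in rotation: train on one cohort, test on the rest.

    Features in each round are the panel genes present in both the training
    and the testing cohort.  The random forest is fully determined by
    ``seed``; per-sample disease scores are class-1 probabilities and the
    round's AUC is the rank statistic over them.  Rounds with no overlapping
    panel gene are skipped with a warning.
    """
    genes = _panel_genes(panel)
    if not genes:
        raise ValueError("panel is empty")
    if len(datasets) < 2:
        raise ValueError("need at least two expression datasets")

    report = ValidationReport()
    report.overlap_pct = panel_overlap_check(genes, datasets)[0]
    for train in datasets:
        for test in datasets:
            if test.dataset_id == train.dataset_id:
                continue
            feats = [g for g in genes if g in train.values.index and g in test.values.index]
            if not feats:
                warnings.warn(
                    f"no overlapping panel genes for round "
                    f"({train.dataset_id} -> {test.dataset_id}); skipped"
                )
                report.skipped_rounds.append(
                    (train.dataset_id, test.dataset_id, "no overlapping panel genes")
                )
                continue
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            clf.fit(train.values.loc[feats].T.to_numpy(), train.y)
            scores = clf.predict_proba(test.values.loc[feats].T.to_numpy())[:, 1]
            auc = float(roc_auc_score(test.y, scores))
            report.rounds.append((train.dataset_id, test.dataset_id, auc))
    return report


def deg_panel(
    dataset: ExpressionDataset,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
) -> set[str]:
    """Differentially expressed gene comparator panel.

    Per gene, a Welch two-sample t-test between classes; p-values are
    Benjamini-Hochberg adjusted.  A gene enters the panel iff adjusted
    p < ``fdr_threshold`` and |log2 fold change of class means| >=
    ``lfc_threshold``.  Non-positive class means fall back to a small
    positive floor so the fold change stays defined.
    """
    y = dataset.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least two samples")
    X = dataset.values.to_numpy(dtype=float)
    disease, healthy = X[:, y == 1], X[:, y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(disease, healthy, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    floor = 1e-9
    m1 = np.maximum(disease.mean(axis=1), floor)
    m0 = np.maximum(healthy.mean(axis=1), floor)
    lfc = np.log2(m1 / m0)
    keep = (padj < fdr_threshold) & (np.abs(lfc) >= lfc_threshold)
    return {g for g, k in zip(dataset.values.index, keep) if k}


def enrichment_rank(
    panel: Panel | Sequence[str],
    pathway_sets: Mapping[str, set[str]],
    universe: set[str],
    target_pathway: str | None = None,
) -> tuple[list[tuple[str, int, float, int]], int | None]:
    """Hypergeometric over-representation ranking of pathways.

    For each pathway, p = P(X >= overlap) drawing |pathway| genes from a
    universe of |universe| genes of which |panel| are panel members.
    Pathways are ranked by ascending p, ties by larger overlap then name.
    Returns the ranked rows (pathway, overlap, p, rank) and the target
    pathway's rank when requested.
    """
    genes = set(_panel_genes(panel))
    offenders = genes - universe
    if offenders:
        raise ValueError(f"panel genes outside the universe: {sorted(offenders)}")
    for name, pset in pathway_sets.items():
        if not pset <= universe:
            raise ValueError(f"pathway {name!r} has genes outside the universe")

    M, n = len(universe), len(genes)
    rows: list[tuple[str, int, float]] = []
    for name, pset in pathway_sets.items():
        overlap = len(genes & pset)
        # upper tail P(X >= overlap), hypergeometric(M, n successes, |pset| draws)
        p = float(stats.hypergeom.sf(overlap - 1, M, n, len(pset)))
        rows.append((name, overlap, min(p, 1.0)))
    rows.sort(key=lambda r: (r[2], -r[1], r[0]))
    ranked = [(name, overlap, p, i + 1) for i, (name, overlap, p) in enumerate(rows)]
    target_rank = None
    if target_pathway is not None:
        for name, _, _, rank in ranked:
            if name == target_pathway:
                target_rank = rank
                break
    return ranked, target_rank


def panel_overlap_check(
    panel: Panel | Sequence[str],
    datasets: Sequence[ExpressionDataset],
    warn_below: float = 80.0,
) -> tuple[dict[str, float], float]:
    """Percentage of panel genes measured in each cohort, plus the average.

    A low average (below 80% by default) means much of the panel cannot
    contribute features to the classification rounds, and draws a warning.
    """
    genes = set(_panel_genes(panel))
    if not genes:
        raise ValueError("panel is empty")
    per_dataset = {
        ds.dataset_id: 100.0 * len(genes & set(ds.genes)) / len(genes)
        for ds in datasets
    }
    average = float(np.mean(list(per_dataset.values()))) if per_dataset else float("nan")
    if per_dataset and average < warn_below:
        warnings.warn(
            f"average panel/dataset gene overlap {average:.1f}% is below {warn_below:.0f}%"
        )
    return per_dataset, average
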