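"""End-to-end orchestration: relevance filter -> NER -> linking -> panels.

The library entry points work on in-memory objects
(:func:`extract_from_documents`, :func:`validate_panel`); the config-driven
wrappers (:func:`run_extraction`, :func:`run_validation`) add file IO around
them for the command-line interface.  Every stage's intake and eliminations
are counted in the run report, and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .association import (
    LinkResult,
    PairStatus,
    VariantGenePair,
    assign_disease,
    link_variant_gene,
    load_resolver_table,
    resolve_coordinates,
)
from .corpus_io import Document, EntityClass, Mention, read_jsonl_corpus
from .evaluation import GoldStandard, PRF, compare_methods
from .ner import CoordinateRecord, dictionary_match, find_variant_mentions, normalize_variant
from .panel import Panel, Triplet, aggregate_triplets, build_panel, write_panel_tsv, write_triplets_tsv
from .relevance import KeywordList, build_keyword_list, is_variant_relevant
from .resources import default_disease_lexicon, default_gene_lexicon
from .validation import (
    ExpressionDataset,
    ValidationReport,
    cross_dataset_auc,
    deg_panel,
    enrichment_rank,
    panel_overlap_check,
    read_expression_tsv,
    read_gmt,
)

logger = logging.getLogger("varpanel")

__all__ = [
    "PipelineConfig",
    "ExtractionResult",
    "ValidationSummary",
    "extract_from_documents",
    "validate_panel",
    "run_extraction",
    "run_validation",
]


@dataclass
class PipelineConfig:
    corpus_path: str | None = None
    gene_lexicon_path: str | None = None
    disease_lexicon_path: str | None = None
    resolver_path: str | None = None
    keyword_list_path: str | None = None
    gold_path: str | None = None
    expression: list[tuple[str, str]] = field(default_factory=list)  # (matrix, labels)
    pathways_path: str | None = None
    target_pathway: str | None = None
    relevance_threshold: float = 0.10
    aggregation: str = "max"
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.5
    n_trees: int = 500
    seed: int = 0
    output_dir: str = "varpanel_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cfg

    def check_paths(self) -> None:
        for p in (self.corpus_path, self.gene_lexicon_path, self.disease_lexicon_path,
                  self.resolver_path, self.keyword_list_path, self.gold_path,
                  self.pathways_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        for m, l in self.expression:
            for p in (m, l):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


@dataclass
class ExtractionResult:
    documents: list[Document]
    relevant_ids: list[str]
    keywords: KeywordList
    mentions_by_doc: dict[str, list[Mention]]
    pairs_by_doc: dict[str, list[VariantGenePair]]
    associations_by_doc: dict[str, list]
    triplets: list[Triplet]
    panels: dict[str, Panel]
    report: dict[str, int | float]


def _split_mentions(mentions: Sequence[Mention]) -> tuple[list[Mention], list[Mention], list[Mention]]:
    v = [m for m in mentions if m.entity_class is EntityClass.VARIANT]
    g = [m for m in mentions if m.entity_class is EntityClass.GENE]
    d = [m for m in mentions if m.entity_class is EntityClass.DISEASE]
    return v, g, d


def extract_from_documents(
    documents: Sequence[Document],
    gene_lexicon: Mapping[str, str] | None = None,
    disease_lexicon: Mapping[str, str] | None = None,
    resolver: Mapping[tuple[str, str], CoordinateRecord] | None = None,
    keywords: KeywordList | None = None,
    external_mentions: Mapping[str, Sequence[Mention]] | None = None,
    relevance_threshold: float = 0.10,
    aggregation: str = "max",
) -> ExtractionResult:
    """Run the full extraction pipeline over parsed documents.

    Stages: keyword-coverage relevance filter; entity recognition (external
    standoff mentions take precedence over the built-in recognizers, per
    document); nearest-gene linking; coordinate resolution (unresolved pairs
    are dropped as false positives); disease assignment; triplet
    aggregation; per-disease panels.  When no keyword list is supplied one
    is built from the input documents that contain a recognizable variant.
    """
    gene_lexicon = dict(gene_lexicon or default_gene_lexicon())
    disease_lexicon = dict(disease_lexicon or default_disease_lexicon())
    resolver = resolver or {}
    external_mentions = external_mentions or {}

    report: dict[str, int | float] = {"documents_in": len(documents)}

    if keywords is None:
        positives = [d for d in documents if find_variant_mentions(d)]
        if not positives:
            raise ValueError("no variant-positive documents to build a keyword list from")
        keywords = build_keyword_list(positives)
    report["keyword_terms"] = len(keywords)

    relevant: list[Document] = []
    for doc in documents:
        if is_variant_relevant(doc, keywords, threshold=relevance_threshold).relevant:
            relevant.append(doc)
    report["documents_relevant"] = len(relevant)
    report["documents_filtered_out"] = len(documents) - len(relevant)

    mentions_by_doc: dict[str, list[Mention]] = {}
    pairs_by_doc: dict[str, list[VariantGenePair]] = {}
    associations_by_doc: dict[str, list] = {}
    n_mentions = n_pairs = n_unpaired = n_unresolved = n_assigned = 0

    for doc in relevant:
        if doc.doc_id in external_mentions:
            mentions = list(external_mentions[doc.doc_id])
        else:
            mentions = list(find_variant_mentions(doc))
            mentions += dictionary_match(doc, gene_lexicon, EntityClass.GENE)
            mentions += dictionary_match(doc, disease_lexicon, EntityClass.DISEASE)
        mentions_by_doc[doc.doc_id] = mentions
        n_mentions += len(mentions)
        vms, gms, dms = _split_mentions(mentions)

        link: LinkResult = link_variant_gene(doc, vms, gms)
        n_unpaired += len(link.unpaired)
        pairs = resolve_coordinates(link.pairs, resolver)
        n_pairs += len(pairs)
        n_unresolved += sum(1 for p in pairs if p.status is PairStatus.UNRESOLVED)
        pairs_by_doc[doc.doc_id] = pairs

        assocs = []
        for canonical in sorted({m.normalized_id for m in vms}):
            res = assign_disease(
                doc, normalize_variant(canonical), vms, dms, aggregation=aggregation
            )
            if res.assigned_disease is not None:
                n_assigned += 1
            assocs.append(res)
        associations_by_doc[doc.doc_id] = assocs

    triplets = aggregate_triplets(associations_by_doc, pairs_by_doc)
    panels = {
        disease: build_panel(triplets, disease)
        for disease in sorted({t.disease_id for t in triplets})
    }
    report.update(
        mentions_total=n_mentions,
        variant_gene_pairs=n_pairs,
        variants_unpaired=n_unpaired,
        pairs_eliminated_unresolved=n_unresolved,
        disease_assignments=n_assigned,
        triplets=len(triplets),
        panels=len(panels),
    )
    if report["documents_relevant"] == 0:
        logger.warning("no documents survived the relevance filter; outputs are empty")
    return ExtractionResult(
        documents=list(documents),
        relevant_ids=[d.doc_id for d in relevant],
        keywords=keywords,
        mentions_by_doc=mentions_by_doc,
        pairs_by_doc=pairs_by_doc,
        associations_by_doc=associations_by_doc,
        triplets=triplets,
        panels=panels,
        report=report,
    )


@dataclass
class ValidationSummary:
    overlap_pct: dict[str, float]
    overlap_avg: float
    reports: dict[str, ValidationReport]  # per panel name
    deg_genes: set[str] | None = None
    enrichment: list[tuple[str, int, float, int]] | None = None
    target_pathway_rank: int | None = None

    def comparison_rows(self) -> list[tuple[str, int, float, float]]:
        """(panel name, n genes usable, mean AUC, median AUC) per panel."""
        rows = []
        for name, rep in self.reports.items():
            rows.append((name, len(rep.rounds), rep.mean_auc, rep.median_auc))
        return rows


def validate_panel(
    panel: Panel | Sequence[str],
    datasets: Sequence[ExpressionDataset],
    pathway_sets: Mapping[str, set[str]] | None = None,
    target_pathway: str | None = None,
    comparator_panels: Mapping[str, Sequence[str]] | None = None,
    include_deg_comparator: bool = True,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
    n_trees: int = 500,
    seed: int = 0,
) -> ValidationSummary:
    """Validation protocol: overlap check, cross-cohort AUC rotation,
    DEG comparator panel, and (optionally) pathway-enrichment ranking.

    The DEG comparator is derived from the first dataset only, mirroring
    the situation where a differential-expression panel is built on one
    cohort and must generalize to the others.
    """
    overlap_pct, overlap_avg = panel_overlap_check(panel, datasets)
    reports: dict[str, ValidationReport] = {
        "proposed": cross_dataset_auc(panel, datasets, n_trees=n_trees, seed=seed)
    }
    deg: set[str] | None = None
    if include_deg_comparator:
        deg = deg_panel(datasets[0], fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold)
        if deg:
            reports["deg"] = cross_dataset_auc(sorted(deg), datasets, n_trees=n_trees, seed=seed)
        else:
            logger.warning("DEG comparator panel is empty; comparator AUC skipped")
    for name, genes in (comparator_panels or {}).items():
        reports[name] = cross_dataset_auc(list(genes), datasets, n_trees=n_trees, seed=seed)

    enrichment = None
    target_rank = None
    if pathway_sets:
        universe = set()
        for ds in datasets:
            universe |= set(ds.genes)
        for pset in pathway_sets.values():
            universe |= pset
        genes = panel.gene_symbols if isinstance(panel, Panel) else list(panel)
        universe |= set(genes)
        enrichment, target_rank = enrichment_rank(
            panel, pathway_sets, universe, target_pathway=target_pathway
        )
    return ValidationSummary(
        overlap_pct=overlap_pct,
        overlap_avg=overlap_avg,
        reports=reports,
        deg_genes=deg,
        enrichment=enrichment,
        target_pathway_rank=target_rank,
    )


def _load_lexicon(path: str | None, default: Mapping[str, str]) -> dict[str, str]:
    if path is None:
        return dict(default)
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 columns")
        out[parts[0].strip()] = parts[1].strip()
    return out


def run_extraction(config: PipelineConfig) -> ExtractionResult:
    """Config-driven extraction run; writes triplet and panel tables."""
    config.check_paths()
    if config.corpus_path is None:
        raise ValueError("config.corpus_path is required")
    documents = read_jsonl_corpus(config.corpus_path)
    keywords = (
        KeywordList.from_tsv(config.keyword_list_path)
        if config.keyword_list_path
        else None
    )
    resolver = load_resolver_table(config.resolver_path) if config.resolver_path else {}
    result = extract_from_documents(
        documents,
        gene_lexicon=_load_lexicon(config.gene_lexicon_path, default_gene_lexicon()),
        disease_lexicon=_load_lexicon(config.disease_lexicon_path, default_disease_lexicon()),
        resolver=resolver,
        keywords=keywords,
        relevance_threshold=config.relevance_threshold,
        aggregation=config.aggregation,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_triplets_tsv(result.triplets, out / "triplets.tsv")
    for disease, panel in result.panels.items():
        write_panel_tsv(panel, out / f"panel_{disease}.tsv")
    result.keywords.to_tsv(out / "keywords.tsv")
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        for k, v in result.report.items():
            fh.write(f"{k}\t{v}\n")
    return result


def run_validation(
    config: PipelineConfig, panel: Panel | Sequence[str]
) -> ValidationSummary:
    """Config-driven validation run; writes the comparison table."""
    config.check_paths()
    datasets = [
        read_expression_tsv(m, l) for m, l in config.expression
    ]
    pathway_sets = read_gmt(config.pathways_path) if config.pathways_path else None
    summary = validate_panel(
        panel,
        datasets,
        pathway_sets=pathway_sets,
        target_pathway=config.target_pathway,
        fdr_threshold=config.fdr_threshold,
        lfc_threshold=config.lfc_threshold,
        n_trees=config.n_trees,
        seed=config.seed,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "validation.tsv", "w", encoding="utf-8") as fh:
        fh.write("panel\tn_rounds\tmean_auc\tmedian_auc\n")
        for name, n, mean, median in summary.comparison_rows():
            fh.write(f"{name}\t{n}\t{mean:.4f}\t{median:.4f}\n")
    if summary.enrichment is not None:
        with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write("pathway\toverlap\tp_value\trank\n")
            for name, overlap, p, rank in summary.enrichment:
                fh.write(f"{name}\t{overlap}\t{p:.6g}\t{rank}\n")
    return summary


def evaluate_against_gold(
    result: ExtractionResult, gold: GoldStandard
) -> tuple[PRF, PRF]:
    """Score the run's relevant documents against a gold standard with both
    the composite method and the co-occurrence baseline."""
    docs = [d for d in result.documents if d.doc_id in set(result.relevant_ids)]
    v_by_doc = {
        d: [m for m in ms if m.entity_class is EntityClass.VARIANT]
        for d, ms in result.mentions_by_doc.items()
    }
    d_by_doc = {
        d: [m for m in ms if m.entity_class is EntityClass.DISEASE]
        for d, ms in result.mentions_by_doc.items()
    }
    return compare_methods(docs, v_by_doc, d_by_doc, gold)
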